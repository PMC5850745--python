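"""Population-genetic summary statistics on genotype matrices.

All estimators work from alt-allele dosages with per-site sample sizes, so
missing genotypes are excluded (never imputed) from every frequency
computation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix

__all__ = [
    "nucleotide_diversity",
    "expected_heterozygosity",
    "segregating_sites",
    "tajimas_d",
    "fst_weir_cockerham",
    "fst_hudson",
    "binned_scan",
    "haplotype_blocks",
    "n50",
    "sumstat_vector",
    "SummaryStatisticVector",
    "BinnedStat",
    "HaplotypeBlockSet",
]


def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (allele copies genotyped, alt copies) for a dosage block."""
    nonmiss = calls != MISSING
    n = 2 * nonmiss.sum(axis=1)
    alt = np.where(nonmiss, calls, 0).sum(axis=1)
    return n.astype(np.int64), alt.astype(np.int64)


def _pop_calls(gm: GenotypeMatrix, pop: str | None) -> np.ndarray:
    if pop is None:
        return gm.calls
    return gm.calls[:, gm.pop_indices(pop)]


def _per_site_pi(calls: np.ndarray) -> np.ndarray:
    """Unbiased per-site mean pairwise difference 2*p*q*n/(n-1)."""
    n, alt = _allele_counts(calls)
    out = np.zeros(len(n))
    ok = n >= 2
    p = np.zeros(len(n))
    p[ok] = alt[ok] / n[ok]
    out[ok] = 2.0 * p[ok] * (1.0 - p[ok]) * n[ok] / (n[ok] - 1.0)
    return out


def nucleotide_diversity(gm: GenotypeMatrix, pop: str | None, span: float) -> float:
    """Mean pairwise diversity per site over ``span`` bp (or assayed sites)."""
    if span <= 0:
        raise ValueError(f"span must be positive, got {span}")
    calls = _pop_calls(gm, pop)
    return float(_per_site_pi(calls).sum() / span)


def expected_heterozygosity(gm: GenotypeMatrix, pop: str | None) -> float:
    """Mean expected heterozygosity 2*p*q across assayed sites."""
    calls = _pop_calls(gm, pop)
    if calls.shape[0] == 0:
        return 0.0
    n, alt = _allele_counts(calls)
    het = np.zeros(len(n))
    ok = n >= 1
    p = np.zeros(len(n))
    p[ok] = alt[ok] / n[ok]
    het[ok] = 2.0 * p[ok] * (1.0 - p[ok])
    return float(het.mean())


def segregating_sites(gm: GenotypeMatrix, pop: str | None) -> int:
    n, alt = _allele_counts(_pop_calls(gm, pop))
    return int(np.sum((alt > 0) & (alt < n)))


def _tajima_constants(n: int) -> tuple[float, ...]:
    # Tajima (1989) a1,a2,b1,b2,c1,c2,e1,e2 for sample size n (allele copies)
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def tajimas_d(gm: GenotypeMatrix, pop: str | None = None) -> float:
    """Tajima's D; NaN (with a warning) when no sites segregate.

    With missing data the per-site sample size enters pi directly; the
    harmonic constants use the median per-site sample size over segregating
    sites (documented approximation).
    """
    calls = _pop_calls(gm, pop)
    n_copies, alt = _allele_counts(calls)
    seg = (alt > 0) & (alt < n_copies) & (n_copies >= 2)
    S = int(seg.sum())
    if S == 0:
        warnings.warn("Tajima's D undefined: no segregating sites")
        return math.nan
    pi_total = float(_per_site_pi(calls)[seg].sum())
    n = int(np.median(n_copies[seg]))
    if n < 2:
        warnings.warn("Tajima's D undefined: fewer than 2 allele copies")
        return math.nan
    a1, _, _, _, _, _, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_total - S / a1) / math.sqrt(var)


def _wc_components(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham (1984) variance components (a, a+b+c), r=2."""
    r = 2.0
    na_i = (calls_a != MISSING).sum(axis=1).astype(float)  # individuals
    nb_i = (calls_b != MISSING).sum(axis=1).astype(float)
    ok = (na_i >= 1) & (nb_i >= 1)
    pa = np.where(
        na_i > 0, np.where(calls_a != MISSING, calls_a, 0).sum(axis=1) / (2 * np.maximum(na_i, 1)), 0.0
    )
    pb = np.where(
        nb_i > 0, np.where(calls_b != MISSING, calls_b, 0).sum(axis=1) / (2 * np.maximum(nb_i, 1)), 0.0
    )
    ha = np.where(na_i > 0, (calls_a == 1).sum(axis=1) / np.maximum(na_i, 1), 0.0)
    hb = np.where(nb_i > 0, (calls_b == 1).sum(axis=1) / np.maximum(nb_i, 1), 0.0)

    nbar = (na_i + nb_i) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (na_i**2 + nb_i**2) / (r * nbar)) / (r - 1.0)
        pbar = (na_i * pa + nb_i * pb) / (r * nbar)
        s2 = (na_i * (pa - pbar) ** 2 + nb_i * (pb - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (na_i * ha + nb_i * hb) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1.0) * (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    tot = a + b + c
    # only sites genotyped in both pops and with nbar > 1 contribute
    ok &= nbar > 1
    a = np.where(ok, a, 0.0)
    tot = np.where(ok, tot, 0.0)
    return np.nan_to_num(a), np.nan_to_num(tot)


def fst_weir_cockerham(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham theta, ratio of summed variance components."""
    calls_a = gm.calls[:, gm.pop_indices(pop_a)]
    calls_b = gm.calls[:, gm.pop_indices(pop_b)]
    a, tot = _wc_components(calls_a, calls_b)
    denom = tot.sum()
    if denom == 0:
        return math.nan
    return float(a.sum() / denom)


def fst_hudson(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Hudson's Fst (ratio of sums of between minus within over between)."""
    ca = gm.calls[:, gm.pop_indices(pop_a)]
    cb = gm.calls[:, gm.pop_indices(pop_b)]
    na, aa = _allele_counts(ca)
    nb, ab = _allele_counts(cb)
    ok = (na >= 2) & (nb >= 2)
    pa, pb = aa[ok] / na[ok], ab[ok] / nb[ok]
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na[ok] - 1) - pb * (1 - pb) / (nb[ok] - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    if den.sum() == 0:
        return math.nan
    return float(num.sum() / den.sum())


# ---------------------------------------------------------------------------
# Binned genome scan
# ---------------------------------------------------------------------------


@dataclass
class BinnedStat:
    chrom: str
    bin_start: int
    bin_end: int
    n_variants: int
    pi: dict[str, float]
    tajima_d: dict[str, float]
    fst: dict[tuple[str, str], float]


def binned_scan(
    gm: GenotypeMatrix,
    pops: list[str] | None = None,
    bin_size: int = 100_000,
    min_variants: int = 3,
    pi_per_bp: bool = True,
) -> list[BinnedStat]:
    """Fixed tiles from position 1; bins with < ``min_variants`` are dropped.

    ``pi_per_bp`` normalises pi by the bin width (the windowed-scan
    convention); otherwise by the number of variants in the bin.
    """
    pops = pops if pops is not None else gm.populations()
    out: list[BinnedStat] = []
    for c in pd.unique(gm.chrom):
        sel = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[sel]
        bins = (pos - 1) // bin_size
        for b in np.unique(bins):
            idx = sel[bins == b]
            if len(idx) < min_variants:
                continue
            sub = gm.take_sites(idx)
            span = float(bin_size) if pi_per_bp else float(len(idx))
            pi = {p: nucleotide_diversity(sub, p, span) for p in pops}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                td = {p: tajimas_d(sub, p) for p in pops}
                fst = {
                    (pa, pb): fst_weir_cockerham(sub, pa, pb)
                    for i, pa in enumerate(pops)
                    for pb in pops[i + 1 :]
                }
            out.append(
                BinnedStat(
                    chrom=str(c),
                    bin_start=int(b * bin_size + 1),
                    bin_end=int((b + 1) * bin_size),
                    n_variants=len(idx),
                    pi=pi,
                    tajima_d=td,
                    fst=fst,
                )
            )
    return out


def scan_to_frame(scan: list[BinnedStat]) -> pd.DataFrame:
    rows = []
    for s in scan:
        row: dict[str, object] = {
            "chrom": s.chrom,
            "bin_start": s.bin_start,
            "bin_end": s.bin_end,
            "n_variants": s.n_variants,
        }
        row.update({f"pi_{p}": v for p, v in s.pi.items()})
        row.update({f"tajima_d_{p}": v for p, v in s.tajima_d.items()})
        row.update({f"fst_{a}_{b}": v for (a, b), v in s.fst.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def genome_means(scan: list[BinnedStat]) -> dict[str, float]:
    """Unweighted mean over qualifying bins of every per-bin statistic."""
    df = scan_to_frame(scan)
    if df.empty:
        return {}
    cols = [c for c in df.columns if c.startswith(("pi_", "tajima_d_", "fst_"))]
    return {c: float(df[c].mean()) for c in cols}


# ---------------------------------------------------------------------------
# Haplotype blocks (Gabriel-style, D' confidence intervals)
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeBlockSet:
    blocks: list[tuple[str, int, int, int]]  # chrom, start, end, n_snps
    n50: float
    total_blocks: int


def _dprime_ci(
    h00: int, h01: int, h10: int, h11: int, grid: int = 101
) -> tuple[float, float]:
    """Likelihood-based 90% CI (5th-95th percentile) for |D'|.

    Haplotype counts for alleles (0/1 at locus A) x (0/1 at locus B); allele
    frequencies fixed at their MLEs, |D'| profiled on a grid.
    """
    n = h00 + h01 + h10 + h11
    if n == 0:
        return 0.0, 1.0
    pa = (h10 + h11) / n  # freq of allele 1 at A
    pb = (h01 + h11) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return 0.0, 1.0  # uninformative pair
    d_obs = h11 / n - pa * pb
    sign = 1.0 if d_obs >= 0 else -1.0
    if sign > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        return 0.0, 1.0
    dp_grid = np.linspace(0.0, 1.0, grid)
    d = sign * dp_grid * dmax
    f11 = np.clip(pa * pb + d, 1e-12, 1.0)
    f10 = np.clip(pa * (1 - pb) - d, 1e-12, 1.0)
    f01 = np.clip((1 - pa) * pb - d, 1e-12, 1.0)
    f00 = np.clip((1 - pa) * (1 - pb) + d, 1e-12, 1.0)
    ll = h11 * np.log(f11) + h10 * np.log(f10) + h01 * np.log(f01) + h00 * np.log(f00)
    like = np.exp(ll - ll.max())
    cdf = np.cumsum(like) / like.sum()
    lo = float(dp_grid[np.searchsorted(cdf, 0.05)])
    hi = float(dp_grid[min(np.searchsorted(cdf, 0.95), grid - 1)])
    return lo, hi


def _classify_pairs(
    haps: np.ndarray,
    strong_lo: float,
    strong_hi: float,
    recomb_hi: float,
) -> np.ndarray:
    """Pairwise classification matrix: 1 strong LD, -1 strong recomb, 0 neither."""
    m = haps.shape[1]
    cls = np.zeros((m, m), dtype=np.int8)
    for i in range(m):
        for j in range(i + 1, m):
            ok = (haps[:, i] >= 0) & (haps[:, j] >= 0)
            a, b = haps[ok, i], haps[ok, j]
            h11 = int(np.sum((a == 1) & (b == 1)))
            h10 = int(np.sum((a == 1) & (b == 0)))
            h01 = int(np.sum((a == 0) & (b == 1)))
            h00 = int(np.sum((a == 0) & (b == 0)))
            lo, hi = _dprime_ci(h00, h01, h10, h11)
            if lo >= strong_lo and hi >= strong_hi:
                cls[i, j] = cls[j, i] = 1
            elif hi < recomb_hi:
                cls[i, j] = cls[j, i] = -1
    return cls


def haplotype_blocks(
    gm: GenotypeMatrix,
    pop: str | None = None,
    window: int = 2_000_000,
    min_len: int = 100,
    strong_lo: float = 0.70,
    strong_hi: float = 0.98,
    recomb_hi: float = 0.90,
    informative_frac: float = 0.95,
) -> HaplotypeBlockSet:
    """Gabriel-style blocks from pairwise |D'| confidence intervals.

    Heterozygous genotypes are unphased and are excluded pairwise; homozygous
    genotypes contribute two identical haplotypes (appropriate for highly
    selfing panels).  Candidate spans whose end pair is strong LD and whose
    informative pairs are >= ``informative_frac`` strong LD become blocks,
    chosen greedily by span length; blocks <= ``min_len`` bp are discarded.
    """
    idx = gm.pop_indices(pop) if pop is not None else np.arange(gm.n_indiv)
    blocks: list[tuple[str, int, int, int]] = []
    for c in pd.unique(gm.chrom):
        sel = np.flatnonzero(gm.chrom == c)
        if len(sel) < 2:
            continue
        pos = gm.pos[sel]
        calls = gm.calls[np.ix_(sel, idx)]
        # haplotype per individual: 0/1 for homozygous, -1 het or missing
        haps = np.where(calls == 0, 0, np.where(calls == 2, 1, -1)).T  # indiv x snps
        cls = _classify_pairs(haps, strong_lo, strong_hi, recomb_hi)
        m = len(sel)
        cand: list[tuple[int, int, int]] = []  # (span, i, j)
        for i in range(m):
            for j in range(i + 1, m):
                if pos[j] - pos[i] > window:
                    break
                if cls[i, j] != 1:
                    continue
                sub = cls[i : j + 1, i : j + 1]
                iu = np.triu_indices(j - i + 1, k=1)
                vals = sub[iu]
                informative = np.sum(vals != 0)
                if informative == 0:
                    continue
                if np.sum(vals == 1) / informative >= informative_frac:
                    cand.append((int(pos[j] - pos[i]), i, j))
        cand.sort(key=lambda t: (-t[0], t[1]))
        used = np.zeros(m, dtype=bool)
        for span, i, j in cand:
            if used[i : j + 1].any():
                continue
            if span <= min_len:
                continue
            used[i : j + 1] = True
            blocks.append((str(c), int(pos[i]), int(pos[j]), j - i + 1))
    lengths = [e - s for _, s, e, _ in blocks]
    return HaplotypeBlockSet(
        blocks=sorted(blocks),
        n50=n50(lengths) if lengths else 0.0,
        total_blocks=len(blocks),
    )


def n50(lengths: list[int] | np.ndarray) -> float:
    """Smallest L with sum(lengths >= L) >= half the total length."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("n50 of an empty length list")
    if np.any(arr <= 0):
        raise ValueError("n50 requires positive lengths")
    srt = np.sort(arr)[::-1]
    csum = np.cumsum(srt)
    k = int(np.searchsorted(csum, csum[-1] / 2.0))
    return float(srt[k])


# ---------------------------------------------------------------------------
# ABC summary-statistic vector
# ---------------------------------------------------------------------------


@dataclass
class SummaryStatisticVector:
    """Fixed-order named statistics shared by observed and simulated data."""

    names: list[str] = field(default_factory=list)
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, dtype=float)

    def write_tsv(self, path) -> None:
        self.to_series().rename("value").rename_axis("statistic").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "SummaryStatisticVector":
        s = pd.read_csv(path, sep="\t", index_col=0)["value"]
        return cls(names=list(s.index), values=s.to_numpy(dtype=float))


def sumstat_names(pops: list[str]) -> list[str]:
    names = []
    for p in pops:
        names += [f"S_{p}", f"pi_{p}", f"H_{p}", f"D_{p}"]
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            names.append(f"fst_{a}_{b}")
    names += ["S_total", "H_total"]
    return names


def sumstat_vector(
    gm: GenotypeMatrix, pops: list[str], d_fill: float | None = 0.0
) -> SummaryStatisticVector:
    """The default ABC statistic vector: per-pop S, pi, H, D; pairwise Fst;
    global S and H.  pi is per assayed site.

    A population monomorphic across every assayed SNP leaves Tajima's D
    undefined; since its numerator pi - S/a1 vanishes as S -> 0, the vector
    records ``d_fill`` (default 0) there, identically for observed and
    simulated data.  ``d_fill=None`` keeps NaN.  An undefined Fst (no shared
    polymorphism) stays NaN; reference-table construction redraws such
    simulations."""
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for p in pops:
        if len(gm.pop_indices(p)) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
    vals: list[float] = []
    span = max(gm.n_sites, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in pops:
            vals.append(segregating_sites(gm, p))
            vals.append(nucleotide_diversity(gm, p, span))
            vals.append(expected_heterozygosity(gm, p))
            d = tajimas_d(gm, p)
            if math.isnan(d) and d_fill is not None:
                d = d_fill
            vals.append(d)
        for i, a in enumerate(pops):
            for b in pops[i + 1 :]:
                vals.append(fst_weir_cockerham(gm, a, b))
        vals.append(segregating_sites(gm, None))
        vals.append(expected_heterozygosity(gm, None))
    return SummaryStatisticVector(names=sumstat_names(pops), values=np.array(vals))
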