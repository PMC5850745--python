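"""Genotype matrices, VCF/annotation I/O, the SNP filter chain and
neutral-site classification.

Coordinate conventions: positions and annotation intervals are held 1-based
inclusive internally (the VCF/GFF3 convention).  BED input is converted from
0-based half-open at the parsing boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # dosage code for a missing diploid genotype


class VcfParseError(ValueError):
    """Malformed VCF input; carries the offending line number when known."""


class ConfigError(ValueError):
    pass


class EmptyCohortError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes: sites x individuals alt-allele dosages.

    ``calls[s, i]`` is 0/1/2 (alt dosage) or :data:`MISSING`.  ``gq``/``dp``
    are optional per-call arrays with the same shape (negative = absent).
    ``multiallelic`` flags records that carried >1 ALT allele at read time;
    such records keep the dosage of the first ALT and are removed by
    :func:`apply_filters`.
    """

    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int64, 1-based
    ref: np.ndarray  # (n_sites,) str
    alt: np.ndarray  # (n_sites,) str
    calls: np.ndarray  # (n_sites, n_indiv) int8
    sample_ids: list[str]
    pop_labels: list[str]
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    multiallelic: np.ndarray | None = None  # (n_sites,) bool

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.multiallelic is None:
            self.multiallelic = np.zeros(self.n_sites, dtype=bool)
        self.validate()

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_indiv(self) -> int:
        return self.calls.shape[1]

    def validate(self) -> None:
        if len(self.pop_labels) != self.n_indiv:
            raise ValueError(
                f"{len(self.pop_labels)} pop labels for {self.n_indiv} individuals"
            )
        if len(self.sample_ids) != self.n_indiv:
            raise ValueError("sample_ids length mismatch")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2,missing}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            calls=self.calls[idx],
            sample_ids=list(self.sample_ids),
            pop_labels=list(self.pop_labels),
            gq=None if self.gq is None else self.gq[idx],
            dp=None if self.dp is None else self.dp[idx],
            multiallelic=self.multiallelic[idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            calls=self.calls[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            pop_labels=[self.pop_labels[i] for i in idx],
            gq=None if self.gq is None else self.gq[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
            multiallelic=self.multiallelic,
        )

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.pop_labels) if p == pop])
        if idx.size == 0:
            raise KeyError(f"population {pop!r} not present")
        return idx

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p, None)
        return list(seen)


@dataclass
class FilterConfig:
    """Thresholds of the five-step filter chain.

    Boundary conventions (each switchable):
    - GQ: mask call if GQ < ``min_gq``.
    - DP: mask call if DP < ``min_dp`` (``dp_exclusive`` masks DP <= min_dp).
    - individuals dropped when missing fraction > ``max_indiv_missing``.
    - sites dropped when missing fraction > ``max_site_missing``.
    - sites dropped when MAF < ``min_maf`` (``maf_exclusive`` drops <=).
    """

    min_gq: float | None = 10.0
    min_dp: float | None = 3.0
    max_indiv_missing: float = 0.1
    max_site_missing: float = 0.2
    min_maf: float = 0.05
    dp_exclusive: bool = False
    maf_exclusive: bool = False

    def __post_init__(self) -> None:
        for name in ("max_indiv_missing", "max_site_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ConfigError(f"min_maf={self.min_maf} outside [0,0.5]")


@dataclass
class FilterReport:
    """Per-step removal counts; steps sum to input = output + removed."""

    n_sites_in: int
    n_indiv_in: int
    calls_masked_gq: int = 0
    calls_masked_dp: int = 0
    sites_removed_multiallelic: int = 0
    indiv_removed_missing: int = 0
    sites_removed_missing: int = 0
    sites_removed_maf: int = 0
    n_sites_out: int = 0
    n_indiv_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_sites", self.n_sites_in),
            ("input_individuals", self.n_indiv_in),
            ("calls_masked_gq", self.calls_masked_gq),
            ("calls_masked_dp", self.calls_masked_dp),
            ("sites_removed_multiallelic", self.sites_removed_multiallelic),
            ("individuals_removed_missing", self.indiv_removed_missing),
            ("sites_removed_missing", self.sites_removed_missing),
            ("sites_removed_maf", self.sites_removed_maf),
            ("output_sites", self.n_sites_out),
            ("output_individuals", self.n_indiv_out),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationIndex:
    """Sorted, per-chromosome feature intervals, 1-based inclusive."""

    features: dict[str, np.ndarray] = field(default_factory=dict)
    # each value: (n, 2) int array of [start, end], sorted by start

    def __post_init__(self) -> None:
        for c, iv in self.features.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            order = np.argsort(iv[:, 0], kind="stable")
            iv = iv[order]
            if np.any(iv[:, 0] > iv[:, 1]):
                raise ValueError(f"interval with start > end on {c}")
            self.features[c] = iv

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[tuple[str, int, int]]
    ) -> "AnnotationIndex":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in intervals:
            by_chrom.setdefault(str(c), []).append((int(s), int(e)))
        return cls({c: np.array(v) for c, v in by_chrom.items()})

    @classmethod
    def from_gff3(cls, path: str | Path) -> "AnnotationIndex":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 3, 4],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
        return cls.from_intervals(list(df.itertuples(index=False, name=None)))

    @classmethod
    def from_bed(cls, path: str | Path) -> "AnnotationIndex":
        # BED is 0-based half-open: [start, end) -> 1-based inclusive
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
        ivs = [(c, s + 1, e) for c, s, e in df.itertuples(index=False, name=None)]
        return cls.from_intervals(ivs)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, population) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str)
    return dict(zip(df["sample"], df["pop"]))


def read_vcf(path: str | Path, pop_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Parse a VCF 4.x file into a :class:`GenotypeMatrix`.

    Multiallelic records are retained and flagged (dosage of the first ALT;
    genotypes carrying other ALTs set missing).  GQ and DP are kept when the
    FORMAT declares them.  Samples absent from ``pop_map`` are labelled
    ``"unassigned"``.
    """
    from cyvcf2 import VCF

    pop_map = pop_map or {}
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error paths vary
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise VcfParseError(f"duplicated sample id(s): {dup}")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    calls_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    multi: list[bool] = []
    has_gq = has_dp = False

    for lineno, var in enumerate(vcf, start=1):
        n_alt = len(var.ALT)
        is_multi = n_alt > 1
        gts = var.genotype.array()  # (n_samples, ploidy+1)
        a0 = gts[:, 0].astype(np.int32)
        a1 = gts[:, 1].astype(np.int32)
        dos = np.where(
            (a0 < 0) | (a1 < 0),
            MISSING,
            (a0 == 1).astype(np.int32) + (a1 == 1).astype(np.int32),
        )
        if is_multi:  # calls carrying a non-first ALT are uninterpretable here
            dos = np.where((a0 > 1) | (a1 > 1), MISSING, dos)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(",".join(var.ALT) if var.ALT else ".")
        calls_rows.append(dos.astype(np.int8))
        multi.append(is_multi)

        try:  # cyvcf2 raises KeyError when the header lacks the field
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            has_gq = True
            gq_rows.append(np.nan_to_num(gq[:, 0], nan=-1).astype(np.int32))
        else:
            gq_rows.append(np.full(len(samples), -1, dtype=np.int32))
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_dp = True
            dp_rows.append(
                np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32)
            )
        else:
            dp_rows.append(np.full(len(samples), -1, dtype=np.int32))

    if not calls_rows:
        raise VcfParseError(f"no variant records in {path}")

    labels = [pop_map.get(s, "unassigned") for s in samples]
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        calls=np.vstack(calls_rows),
        sample_ids=samples,
        pop_labels=labels,
        gq=np.vstack(gq_rows) if has_gq else None,
        dp=np.vstack(dp_rows) if has_dp else None,
        multiallelic=np.array(multi, dtype=bool),
    )


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 representation of the matrix."""
    with_gq = gm.gq is not None
    with_dp = gm.dp is not None
    fmt = "GT" + (":GQ" if with_gq else "") + (":DP" if with_dp else "")
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if with_gq:
        lines.append(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">'
        )
    if with_dp:
        lines.append(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">'
        )
    for c in pd.unique(gm.chrom):
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids)
    )
    for s in range(gm.n_sites):
        cells = []
        for i in range(gm.n_indiv):
            cell = _GT_CODE[int(gm.calls[s, i])]
            if with_gq:
                v = int(gm.gq[s, i])
                cell += f":{v}" if v >= 0 else ":."
            if with_dp:
                v = int(gm.dp[s, i])
                cell += f":{v}" if v >= 0 else ":."
            cells.append(cell)
        lines.append(
            f"{gm.chrom[s]}\t{gm.pos[s]}\t.\t{gm.ref[s]}\t{gm.alt[s]}\t.\t.\t.\t{fmt}\t"
            + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_pop_map(gm: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame({"sample": gm.sample_ids, "pop": gm.pop_labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Filter chain
# ---------------------------------------------------------------------------


def apply_filters(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the five-step filter chain in fixed order.

    1. mask calls failing GQ / DP thresholds;
    2. drop multiallelic sites;
    3. drop individuals exceeding the per-individual missingness cap;
    4. drop sites exceeding the per-site missingness cap;
    5. drop sites below the MAF threshold (non-missing calls only).
    """
    cfg = cfg or FilterConfig()
    rep = FilterReport(n_sites_in=gm.n_sites, n_indiv_in=gm.n_indiv)

    calls = gm.calls.copy()
    # step 1: per-call masks
    if cfg.min_gq is not None and gm.gq is not None:
        mask = (gm.gq >= 0) & (gm.gq < cfg.min_gq) & (calls != MISSING)
        rep.calls_masked_gq = int(mask.sum())
        calls[mask] = MISSING
    if cfg.min_dp is not None and gm.dp is not None:
        if cfg.dp_exclusive:
            low = gm.dp <= cfg.min_dp
        else:
            low = gm.dp < cfg.min_dp
        mask = (gm.dp >= 0) & low & (calls != MISSING)
        rep.calls_masked_dp = int(mask.sum())
        calls[mask] = MISSING

    work = replace(gm)
    work.calls = calls

    # step 2: biallelic only
    keep = ~work.multiallelic
    rep.sites_removed_multiallelic = int((~keep).sum())
    work = work.take_sites(np.flatnonzero(keep))

    # step 3: individual missingness
    if work.n_sites > 0:
        miss_frac = (work.calls == MISSING).mean(axis=0)
    else:
        miss_frac = np.zeros(work.n_indiv)
    keep_ind = miss_frac <= cfg.max_indiv_missing
    rep.indiv_removed_missing = int((~keep_ind).sum())
    if not keep_ind.any():
        raise EmptyCohortError("all individuals removed by missingness filter")
    work = work.take_individuals(np.flatnonzero(keep_ind))

    # step 4: site missingness
    site_miss = (work.calls == MISSING).mean(axis=1)
    keep = site_miss <= cfg.max_site_missing
    rep.sites_removed_missing = int((~keep).sum())
    work = work.take_sites(np.flatnonzero(keep))

    # step 5: MAF on non-missing calls
    nonmiss = work.calls != MISSING
    n_copies = 2 * nonmiss.sum(axis=1)
    alt = np.where(nonmiss, work.calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_copies > 0, alt / np.maximum(n_copies, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    if cfg.maf_exclusive:
        keep = maf > cfg.min_maf
    else:
        keep = maf >= cfg.min_maf
    keep &= n_copies > 0
    rep.sites_removed_maf = int((~keep).sum())
    work = work.take_sites(np.flatnonzero(keep))

    rep.n_sites_out = work.n_sites
    rep.n_indiv_out = work.n_indiv
    return work, rep


# ---------------------------------------------------------------------------
# Neutral classification
# ---------------------------------------------------------------------------


@dataclass
class SitePartition:
    """Exhaustive, disjoint site index partition."""

    genic: np.ndarray
    neutral: np.ndarray
    intermediate: np.ndarray


def classify_neutral(
    gm: GenotypeMatrix, ann: AnnotationIndex, min_dist: int = 5000
) -> SitePartition:
    """Partition sites by distance to the nearest annotated feature.

    genic = inside a feature; neutral = nearest feature >= ``min_dist`` away
    (boundary inclusive); intermediate = remainder.  Sites on chromosomes
    absent from the annotation are classed neutral with a warning.
    """
    cls = np.empty(gm.n_sites, dtype=object)
    warned: set[str] = set()
    for c in pd.unique(gm.chrom):
        sel = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[sel]
        iv = ann.features.get(str(c))
        if iv is None or len(iv) == 0:
            if str(c) not in warned:
                warnings.warn(f"chromosome {c} absent from annotation; sites classed neutral")
                warned.add(str(c))
            cls[sel] = "neutral"
            continue
        dist = _distance_to_features(pos, iv)
        cat = np.where(dist == 0, "genic", np.where(dist >= min_dist, "neutral", "intermediate"))
        cls[sel] = cat
    return SitePartition(
        genic=np.flatnonzero(cls == "genic"),
        neutral=np.flatnonzero(cls == "neutral"),
        intermediate=np.flatnonzero(cls == "intermediate"),
    )


def _distance_to_features(pos: np.ndarray, iv: np.ndarray) -> np.ndarray:
    """Distance (bp) from each position to the nearest interval; 0 inside."""
    starts, ends = iv[:, 0], iv[:, 1]
    # merge overlapping intervals so cummax(ends) is monotone
    ends = np.maximum.accumulate(ends)
    dist = np.full(pos.shape, np.iinfo(np.int64).max, dtype=np.int64)
    # nearest interval starting at or after pos
    j = np.searchsorted(starts, pos, side="left")
    has_next = j < len(starts)
    dist[has_next] = starts[j[has_next]] - pos[has_next]
    # nearest interval (merged) ending before or covering pos
    k = np.searchsorted(starts, pos, side="right") - 1
    has_prev = k >= 0
    prev_end = ends[np.maximum(k, 0)]
    inside = has_prev & (pos <= prev_end)
    d_prev = np.where(inside, 0, pos - prev_end)
    dist = np.where(has_prev, np.minimum(dist, d_prev), dist)
    return dist
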