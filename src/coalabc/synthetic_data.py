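"""Pseudo-observed bundles and planted-defect fixtures.

Every generator bundles its own expected outcome, derived by independent
plain-loop bookkeeping that shares no code with the implementation under
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coalescent_sim import SimulatedDataset, simulate_dataset
from .demography import (
    REDUCED_PROFILE,
    FULL_PROFILE,
    DemographicParameters,
    build_model,
)
from .popgen_stats import SummaryStatisticVector, sumstat_vector
from .variant_io import FilterReport, write_pop_map, write_vcf

#: generator truth mirroring the published point estimates; these are inputs
#: to simulation, never expected outputs.
TABLE3_LIKE = dict(
    T1=87_410.0,
    T2=373_060.0,
    N_MW=50_000.0,
    N_AW=20_000.0,
    N_PhI=10_000.0,
    N_ANC=50_000.0,
    NF_MW=300.0,
    NF_AW=300.0,
    NF_PhI=300.0,
)


@dataclass
class PseudoObservedSet:
    dataset: SimulatedDataset
    true_model: str
    true_params: DemographicParameters
    observed: SummaryStatisticVector
    seed: int


def make_pseudo_observed(
    model_name: str,
    params: DemographicParameters | str = "table3-like",
    sample_profile: str | dict[str, int] = "reduced",
    seed: int = 0,
    n_chrom: int = 5,
    snps_per_chrom: int = 200,
    maf_min: float = 0.05,
) -> PseudoObservedSet:
    """Simulate a dataset with known generating truth plus its statistics."""
    if params == "table3-like":
        params = DemographicParameters(**TABLE3_LIKE)
    elif isinstance(params, str):
        raise ValueError(f"unknown parameter preset {params!r}")
    if sample_profile == "reduced":
        sizes = dict(REDUCED_PROFILE)
    elif sample_profile == "full":
        sizes = dict(FULL_PROFILE)
    else:
        sizes = dict(sample_profile)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    model = build_model(model_name, params)
    ds = simulate_dataset(
        model,
        params,
        sizes,
        rng,
        n_chrom=n_chrom,
        snps_per_chrom=snps_per_chrom,
        maf_min=maf_min,
    )
    ds.seed = seed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vec = sumstat_vector(ds.gm, [d for d in model.sample_demes if sizes.get(d, 0) > 0])
    return PseudoObservedSet(
        dataset=ds,
        true_model=model_name,
        true_params=params,
        observed=vec,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Planted-defect toy VCF
# ---------------------------------------------------------------------------

DEFECTS = ("multiallelic", "low-maf", "missingness", "low-gq", "low-dp")


def make_toy_vcf(
    out_dir: str | Path,
    n_sites: int = 12,
    n_indiv: int = 6,
    planted_defects: tuple[str, ...] = (),
    seed: int = 0,
    min_gq: int = 10,
    min_dp: int = 3,
    max_indiv_missing: float = 0.1,
    max_site_missing: float = 0.2,
    min_maf: float = 0.05,
) -> tuple[Path, Path, FilterReport]:
    """Write a toy VCF + pop map exercising the requested filter branches.

    Returns (vcf path, pop map path, expected FilterReport).  The expected
    report is tallied with plain nested loops over the raw arrays --
    independent of :func:`coalabc.variant_io.apply_filters`.
    """
    if n_sites < 1 or n_indiv < 1:
        raise ValueError("need at least one site and one individual")
    for d in planted_defects:
        if d not in DEFECTS:
            raise ValueError(f"unknown defect {d!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # defect planting is random, so a heavy draw can wipe out the whole
    # cohort; redraw from derived sub-seeds until at least one individual
    # (and one site, when attainable) survives -- deterministic given seed
    for attempt in range(100):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        # healthy baseline: common alleles, full calls, high GQ/DP
        calls = np.zeros((n_sites, n_indiv), dtype=int)
        for s in range(n_sites):
            # target a comfortably intermediate frequency
            n_alt = int(rng.integers(max(1, n_indiv // 2), n_indiv + 1))
            carriers = rng.choice(n_indiv, size=n_alt, replace=False)
            calls[s, carriers] = rng.integers(1, 3, size=n_alt)
        gq = rng.integers(min_gq + 10, min_gq + 40, size=(n_sites, n_indiv))
        dp = rng.integers(min_dp + 5, min_dp + 30, size=(n_sites, n_indiv))
        multi = np.zeros(n_sites, dtype=bool)

        if "multiallelic" in planted_defects:
            k = max(1, n_sites // 6)
            multi[rng.choice(n_sites, size=k, replace=False)] = True
        if "low-gq" in planted_defects:
            k = max(1, (n_sites * n_indiv) // 25)
            flat = rng.choice(n_sites * n_indiv, size=k, replace=False)
            gq.ravel()[flat] = rng.integers(0, min_gq, size=k)
        if "low-dp" in planted_defects:
            k = max(1, (n_sites * n_indiv) // 25)
            flat = rng.choice(n_sites * n_indiv, size=k, replace=False)
            dp.ravel()[flat] = rng.integers(0, min_dp, size=k)
        if "missingness" in planted_defects:
            # heavily missing sites plus one heavily missing individual
            for s in rng.choice(n_sites, size=max(1, n_sites // 5), replace=False):
                k = int(np.ceil(max_site_missing * n_indiv)) + 1
                calls[s, rng.choice(n_indiv, size=min(k, n_indiv), replace=False)] = -1
            bad_ind = int(rng.integers(n_indiv))
            k = int(np.ceil(max_indiv_missing * n_sites)) + 1
            calls[rng.choice(n_sites, size=min(k, n_sites), replace=False), bad_ind] = -1
        if "low-maf" in planted_defects:
            for s in rng.choice(n_sites, size=max(1, n_sites // 5), replace=False):
                calls[s, :] = 0
                if rng.random() < 0.5 and n_indiv >= 10:
                    calls[s, int(rng.integers(n_indiv))] = 1  # near-private allele

        expected = _expected_filter_report(
            calls, gq, dp, multi,
            min_gq=min_gq, min_dp=min_dp,
            max_indiv_missing=max_indiv_missing,
            max_site_missing=max_site_missing,
            min_maf=min_maf,
        )
        if expected.n_indiv_out >= 1:
            break
    else:  # pragma: no cover - 100 redraws never all fail in practice
        raise RuntimeError("could not plant defects without emptying the cohort")

    # serialize
    samples = [f"S{i + 1}" for i in range(n_indiv)]
    pops = ["MW" if i % 2 == 0 else "AW" for i in range(n_indiv)]
    vcf_path = out_dir / "toy.vcf"
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">',
        "##contig=<ID=chr1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    for s in range(n_sites):
        alt = "T,G" if multi[s] else "T"
        cells = [
            f"{gt_code[int(calls[s, i])]}:{int(gq[s, i])}:{int(dp[s, i])}"
            for i in range(n_indiv)
        ]
        lines.append(
            f"chr1\t{(s + 1) * 100}\t.\tA\t{alt}\t.\t.\t.\tGT:GQ:DP\t" + "\t".join(cells)
        )
    vcf_path.write_text("\n".join(lines) + "\n")
    pop_path = out_dir / "toy.popmap.tsv"
    pop_path.write_text("".join(f"{s}\t{p}\n" for s, p in zip(samples, pops)))
    return vcf_path, pop_path, expected


def _expected_filter_report(
    calls: np.ndarray,
    gq: np.ndarray,
    dp: np.ndarray,
    multi: np.ndarray,
    *,
    min_gq: int,
    min_dp: int,
    max_indiv_missing: float,
    max_site_missing: float,
    min_maf: float,
) -> FilterReport:
    """Plain-loop tally of the five filter steps (independent bookkeeping)."""
    n_sites, n_indiv = calls.shape
    rep = FilterReport(n_sites_in=n_sites, n_indiv_in=n_indiv)
    work = [[int(calls[s][i]) for i in range(n_indiv)] for s in range(n_sites)]
    for s in range(n_sites):
        for i in range(n_indiv):
            if work[s][i] != -1 and gq[s][i] < min_gq:
                rep.calls_masked_gq += 1
                work[s][i] = -1
    for s in range(n_sites):
        for i in range(n_indiv):
            if work[s][i] != -1 and dp[s][i] < min_dp:
                rep.calls_masked_dp += 1
                work[s][i] = -1
    sites = [s for s in range(n_sites) if not multi[s]]
    rep.sites_removed_multiallelic = n_sites - len(sites)
    indivs = []
    for i in range(n_indiv):
        miss = sum(1 for s in sites if work[s][i] == -1)
        if len(sites) == 0 or miss / len(sites) <= max_indiv_missing:
            indivs.append(i)
    rep.indiv_removed_missing = n_indiv - len(indivs)
    if not indivs:  # the filter chain errors here; report the empty state
        rep.n_sites_out = 0
        rep.n_indiv_out = 0
        return rep
    kept = []
    for s in sites:
        miss = sum(1 for i in indivs if work[s][i] == -1)
        if miss / len(indivs) <= max_site_missing:
            kept.append(s)
    rep.sites_removed_missing = len(sites) - len(kept)
    final = []
    for s in kept:
        copies = sum(2 for i in indivs if work[s][i] != -1)
        alt = sum(work[s][i] for i in indivs if work[s][i] != -1)
        if copies == 0:
            continue
        p = alt / copies
        maf = min(p, 1 - p)
        if maf >= min_maf:
            final.append(s)
    rep.sites_removed_maf = len(kept) - len(final)
    rep.n_sites_out = len(final)
    rep.n_indiv_out = len(indivs)
    return rep


# ---------------------------------------------------------------------------
# Annotation fixture
# ---------------------------------------------------------------------------


def make_annotation_fixture(
    out_dir: str | Path,
    n_features: int = 5,
    n_sites: int = 20,
    spacing: int = 20_000,
    min_dist: int = 5000,
    seed: int = 0,
) -> dict:
    """Paired GFF3/BED feature files plus an expected site partition.

    The expected partition is computed by a brute-force all-pairs distance
    scan over the interval list (independent bookkeeping).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom = "chr1"
    feats = []
    cursor = 1000
    for _ in range(n_features):
        start = cursor + int(rng.integers(0, spacing))
        end = start + int(rng.integers(200, 3000))
        feats.append((start, end))
        cursor = end + spacing
    positions = np.sort(
        rng.choice(np.arange(1, cursor + 2 * spacing), size=n_sites, replace=False)
    ).astype(int)

    expected = []
    for pos in positions:
        best = None
        for s, e in feats:
            if s <= pos <= e:
                d = 0
            elif pos < s:
                d = s - pos
            else:
                d = pos - e
            best = d if best is None else min(best, d)
        if best == 0:
            expected.append("genic")
        elif best >= min_dist:
            expected.append("neutral")
        else:
            expected.append("intermediate")

    gff = out_dir / "features.gff3"
    gff.write_text(
        "##gff-version 3\n"
        + "".join(
            f"{chrom}\tsrc\tgene\t{s}\t{e}\t.\t+\t.\tID=g{k}\n"
            for k, (s, e) in enumerate(feats)
        )
    )
    bed = out_dir / "features.bed"  # 0-based half-open
    bed.write_text("".join(f"{chrom}\t{s - 1}\t{e}\n" for s, e in feats))
    return {
        "gff3": gff,
        "bed": bed,
        "chrom": chrom,
        "positions": positions,
        "features": feats,
        "expected": expected,
    }


def export_bundle(bundle: PseudoObservedSet, out_dir: str | Path) -> dict[str, Path]:
    """Write a pseudo-observed bundle as VCF + pop map + statistics TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf = out_dir / "pseudo_observed.vcf"
    popmap = out_dir / "pseudo_observed.popmap.tsv"
    stats = out_dir / "pseudo_observed.stats.tsv"
    write_vcf(bundle.dataset.gm, vcf)
    write_pop_map(bundle.dataset.gm, popmap)
    bundle.observed.write_tsv(stats)
    return {"vcf": vcf, "popmap": popmap, "stats": stats}
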