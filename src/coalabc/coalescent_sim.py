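"""Structured Kingman coalescent with SNP ascertainment and ABC reference
tables.

Chromosomes are fully linked internally and independent of each other (no
intra-chromosome recombination; an independent-sites mode is available).
Mutations are placed in SNP-ascertainment mode: one mutation per site on a
branch chosen proportionally to its length, rejected and redrawn until the
pooled minor allele frequency clears the ascertainment threshold, so the
mutation rate is absorbed by the conditioning on polymorphism.
"""

from __future__ import annotations

import json
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import (
    DemographicModel,
    DemographicParameters,
    PriorSpec,
    build_model,
    sample_prior,
)
from .popgen_stats import SummaryStatisticVector, sumstat_vector
from .variant_io import GenotypeMatrix


class SimulationError(RuntimeError):
    pass


@dataclass
class Genealogy:
    """A single coalescent tree: node times and parent links.

    Leaves are nodes ``0..n_leaves-1`` (time 0, grouped by deme in
    ``leaf_demes`` order); internal nodes are appended in coalescence order,
    so every parent index exceeds its children's indices.
    """

    times: np.ndarray  # (2n-1,) float, generations
    parent: np.ndarray  # (2n-1,) int, -1 at the root
    n_leaves: int
    leaf_demes: list[str]  # deme label per leaf

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        v = np.arange(self.n_nodes - 1)
        return self.times[self.parent[v]] - self.times[v]

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_sets(self) -> np.ndarray:
        """(n_nodes, n_leaves) boolean descendant-leaf matrix."""
        ls = np.zeros((self.n_nodes, self.n_leaves), dtype=bool)
        ls[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        for v in range(self.n_nodes - 1):
            ls[self.parent[v]] |= ls[v]
        return ls

    def tmrca(self) -> float:
        return float(self.times[self.root])


def simulate_genealogy(
    model: DemographicModel,
    sample_sizes: dict[str, int],
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy of the structured coalescent.

    ``sample_sizes`` are diploid counts per sampled deme (haplotypes = 2x).
    Within each deme and epoch pairs coalesce at rate k(k-1)/2 per 2N
    generations; at each merge event every lineage of the derived deme
    transfers to the source deme; the process runs to the MRCA.
    """
    demes = model.demes
    n_hap = {d: 2 * sample_sizes.get(d, 0) for d in demes}
    n = sum(n_hap.values())
    if n == 0:
        raise SimulationError("no samples")
    leaf_demes: list[str] = []
    lineages: dict[str, list[int]] = {d: [] for d in demes}
    node = 0
    for d in demes:
        for _ in range(n_hap[d]):
            lineages[d].append(node)
            leaf_demes.append(d)
            node += 1
    n_nodes = 2 * n - 1
    times = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    if n == 1:
        return Genealogy(times[:1], parent[:1], 1, leaf_demes)

    # piecewise-constant sizes: per-deme (boundaries, sizes) backward in time
    bounds: dict[str, np.ndarray] = {}
    sizes: dict[str, np.ndarray] = {}
    all_breaks: set[float] = set()
    for d in demes:
        eps = sorted(model.epochs[d], key=lambda e: e.t_start)
        bounds[d] = np.array([e.t_start for e in eps])
        sizes[d] = np.array([e.size for e in eps])
        if np.any(sizes[d] <= 0):
            raise SimulationError(f"non-positive size in an epoch of deme {d}")
        all_breaks.update(e.t_start for e in eps if 0 < e.t_start < np.inf)
    merge_at: dict[float, list] = {}
    for ev in model.events:
        merge_at.setdefault(ev.time, []).append(ev)
        all_breaks.add(ev.time)
    breaks = sorted(all_breaks)

    def size_at(d: str, t: float) -> float:
        i = int(np.searchsorted(bounds[d], t, side="right")) - 1
        return float(sizes[d][i])

    t = 0.0
    bi = 0
    active = [d for d in demes]
    k_total = n
    exp = rng.exponential
    while k_total > 1:
        rates = []
        rdeme_list = []
        for d in active:
            k = len(lineages[d])
            if k >= 2:
                rates.append(k * (k - 1) / 2.0 / (2.0 * size_at(d, t)))
                rdeme_list.append(d)
        total = sum(rates)
        t_break = breaks[bi] if bi < len(breaks) else np.inf
        if total > 0:
            t_next = t + exp(1.0 / total)
        else:
            t_next = np.inf
        if t_next >= t_break:
            if t_break == np.inf:
                raise SimulationError("coalescent stalled with isolated lineages")
            t = t_break
            for ev in merge_at.get(t_break, []):
                lineages[ev.source].extend(lineages[ev.derived])
                lineages[ev.derived] = []
            bi += 1
            continue
        t = t_next
        # pick deme proportional to its rate, then a uniform pair
        u = rng.random() * total
        acc = 0.0
        d_hit = rdeme_list[-1]
        for d, rt in zip(rdeme_list, rates):
            acc += rt
            if u <= acc:
                d_hit = d
                break
        lin = lineages[d_hit]
        i = int(rng.integers(len(lin)))
        j = int(rng.integers(len(lin) - 1))
        if j >= i:
            j += 1
        a, b = lin[i], lin[j]
        times[node] = t
        parent[a] = node
        parent[b] = node
        # remove the two children, append the parent
        for x in sorted((i, j), reverse=True):
            lin.pop(x)
        lin.append(node)
        node += 1
        k_total -= 1
    return Genealogy(times, parent, n, leaf_demes)


def drop_snps(
    gen: Genealogy,
    n_snps: int,
    maf_min: float,
    rng: np.random.Generator,
    max_rounds: int = 60,
) -> np.ndarray:
    """Ascertain ``n_snps`` biallelic SNPs on a genealogy.

    Each SNP's mutation lands on a branch with probability proportional to
    branch length; carriers below it get the derived allele.  SNPs whose
    pooled MAF falls below ``maf_min`` are rejected and redrawn.  Returns a
    (n_haplotypes, n_snps) 0/1 matrix.
    """
    if gen.n_leaves < 2:
        raise SimulationError("need >= 2 haplotypes to place SNPs")
    lengths = gen.branch_lengths()
    total = lengths.sum()
    if total <= 0:
        raise SimulationError("zero total branch length")
    probs = lengths / total
    ls = gen.leaf_sets()
    counts = ls.sum(axis=1)
    n = gen.n_leaves
    ok_nodes = np.flatnonzero(
        np.minimum(counts[:-1], n - counts[:-1]) / n >= maf_min - 1e-12
    )
    if ok_nodes.size == 0:
        raise SimulationError(
            f"no branch can yield a SNP with MAF >= {maf_min} (n={n})"
        )
    cols: list[np.ndarray] = []
    got = 0
    for _ in range(max_rounds):
        batch = max(2 * (n_snps - got), 64)
        picks = rng.choice(gen.n_nodes - 1, size=batch, p=probs)
        c = counts[picks]
        keep = np.minimum(c, n - c) / n >= maf_min - 1e-12
        picks = picks[keep][: n_snps - got]
        if picks.size:
            cols.append(ls[picks].T)
            got += picks.size
        if got >= n_snps:
            return np.hstack(cols).astype(np.int8)
    raise SimulationError(
        f"MAF ascertainment failed after {max_rounds} rounds (n={n})"
    )


@dataclass
class SimulatedDataset:
    gm: GenotypeMatrix
    model_name: str
    params: DemographicParameters
    seed: int | None = None


def simulate_dataset(
    model: DemographicModel | str,
    params: DemographicParameters,
    sample_sizes: dict[str, int],
    rng: np.random.Generator,
    n_chrom: int = 5,
    snps_per_chrom: int = 200,
    maf_min: float = 0.05,
    chrom_length: int = 10_000_000,
    linked: bool = True,
) -> SimulatedDataset:
    """Simulate a multi-chromosome SNP dataset under one demographic model.

    One independent genealogy per chromosome (all SNPs on it fully linked)
    unless ``linked=False``, in which case every SNP segregates on its own
    genealogy.  Diploids are formed by pairing consecutive haplotypes within
    a deme (haplotypes are exchangeable, so this is random mating).
    """
    if isinstance(model, str):
        model = build_model(model, params)
    pops = [d for d in model.sample_demes if sample_sizes.get(d, 0) > 0]
    blocks: list[np.ndarray] = []
    chroms: list[str] = []
    poss: list[np.ndarray] = []
    for c in range(n_chrom):
        if linked:
            gen = simulate_genealogy(model, sample_sizes, rng)
            haps = drop_snps(gen, snps_per_chrom, maf_min, rng)
        else:
            cols = []
            for _ in range(snps_per_chrom):
                gen = simulate_genealogy(model, sample_sizes, rng)
                cols.append(drop_snps(gen, 1, maf_min, rng))
            haps = np.hstack(cols)
        blocks.append(haps)
        pos = np.sort(rng.choice(chrom_length - 1, size=snps_per_chrom, replace=False)) + 1
        poss.append(pos)
        chroms.append(f"chr{c + 1}")

    # haplotypes -> diploid dosages, per chromosome then stacked over sites
    calls_parts = []
    for haps in blocks:
        dosage = haps[0::2] + haps[1::2]  # (n_indiv, n_snps)
        calls_parts.append(dosage.T.astype(np.int8))
    calls = np.vstack(calls_parts)
    n_sites = calls.shape[0]
    pop_labels: list[str] = []
    sample_ids: list[str] = []
    for d in model.sample_demes:
        for i in range(sample_sizes.get(d, 0)):
            pop_labels.append(d)
            sample_ids.append(f"{d}_{i + 1}")
    gm = GenotypeMatrix(
        chrom=np.repeat(chroms, snps_per_chrom).astype(object),
        pos=np.concatenate(poss),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        calls=calls,
        sample_ids=sample_ids,
        pop_labels=pop_labels,
    )
    assert pops  # at least one sampled deme
    return SimulatedDataset(gm=gm, model_name=model.name, params=params)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Rows of (sim_id, model, flattened parameters, summary statistics)."""

    df: pd.DataFrame
    param_names: list[str]
    stat_names: list[str]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def models(self) -> list[str]:
        return list(pd.unique(self.df["model"]))

    def stats_matrix(self) -> np.ndarray:
        return self.df[self.stat_names].to_numpy(dtype=float)

    def params_matrix(self) -> np.ndarray:
        return self.df[self.param_names].to_numpy(dtype=float)

    def restrict(self, model: str) -> "ReferenceTable":
        sub = self.df[self.df["model"] == model].reset_index(drop=True)
        return ReferenceTable(sub, list(self.param_names), list(self.stat_names), dict(self.meta))

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        # %.17g keeps float64 round-trip exact so resumed builds stay
        # bit-identical to uninterrupted ones
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        meta = dict(self.meta)
        meta["param_names"] = self.param_names
        meta["stat_names"] = self.stat_names
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ReferenceTable":
        path = Path(path)
        # round_trip parsing: the default fast parser is not correctly
        # rounded and would break bit-identical resumption
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        pn = meta.get("param_names") or [
            c for c in df.columns if c.startswith(("N_", "NF_", "T", "mu", "bottleneck"))
        ]
        sn = meta.get("stat_names") or [
            c for c in df.columns if c not in {"sim_id", "model", "seed"} and c not in pn
        ]
        return cls(df, pn, sn, meta)


def _one_simulation(
    sim_id: int,
    model_name: str,
    prior: PriorSpec,
    sample_sizes: dict[str, int],
    master_seed: int,
    n_chrom: int,
    snps_per_chrom: int,
    maf_min: float,
    pops: list[str],
    max_retries: int = 25,
) -> tuple[dict, int]:
    """One reference-table row; failed draws (NaN statistics) are redrawn
    with fresh parameters from the same child stream.  Returns (row, retries)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(sim_id,))
    rng = np.random.default_rng(ss)
    retries = 0
    for _ in range(max_retries):
        params = sample_prior(prior, rng)
        try:
            ds = simulate_dataset(
                model_name,
                params,
                sample_sizes,
                rng,
                n_chrom=n_chrom,
                snps_per_chrom=snps_per_chrom,
                maf_min=maf_min,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vec = sumstat_vector(ds.gm, pops)
        except SimulationError:
            retries += 1
            continue
        if np.all(np.isfinite(vec.values)):
            row = {"sim_id": sim_id, "model": model_name}
            row.update(params.as_dict())
            row.update(dict(zip(vec.names, vec.values)))
            return row, retries
        retries += 1
    raise SimulationError(
        f"sim {sim_id} ({model_name}): no valid dataset after {max_retries} draws"
    )


def build_reference_table(
    models: list[str],
    priors: PriorSpec | dict[str, PriorSpec],
    n_sims_per_model: int,
    sample_sizes: dict[str, int],
    master_seed: int,
    n_chrom: int = 5,
    snps_per_chrom: int = 200,
    maf_min: float = 0.05,
    max_failure_rate: float = 0.01,
    out_path: str | Path | None = None,
    chunk_size: int = 500,
    workers: int = 1,
    progress: bool = False,
) -> ReferenceTable:
    """Build a balanced reference table (equal simulation counts per model).

    Fully deterministic given ``master_seed`` regardless of worker count or
    interruption: each sim id owns a seed stream derived from
    (master_seed, sim_id).  With ``out_path`` the table is streamed to TSV in
    chunks and a partially written file is resumed from its last full row.
    """
    if n_sims_per_model < 1:
        raise ValueError("n_sims_per_model must be >= 1")
    # canonical deme order (not the dict's key order, which config files may
    # alphabetize) so statistic names match observed vectors
    from .demography import DEMES

    canonical = [d for d in DEMES if sample_sizes.get(d, 0) > 0]
    extra = [d for d, k in sample_sizes.items() if k > 0 and d not in canonical]
    pops = canonical + extra
    jobs: list[tuple[int, str]] = []
    sim_id = 0
    for i in range(n_sims_per_model):
        for m in models:
            jobs.append((sim_id, m))
            sim_id += 1

    out_path = Path(out_path) if out_path is not None else None
    done_rows: list[dict] = []
    start_at = 0
    if out_path is not None and out_path.exists():
        prev = pd.read_csv(out_path, sep="\t", float_precision="round_trip")
        done_rows = prev.to_dict("records")
        start_at = len(done_rows)

    def prior_for(m: str) -> PriorSpec:
        return priors[m] if isinstance(priors, dict) else priors

    pending = jobs[start_at:]
    rows: list[dict] = list(done_rows)
    total_retries = 0
    header_written = start_at > 0
    t0 = _time.time()

    def run(job: tuple[int, str]) -> tuple[dict, int]:
        sid, m = job
        return _one_simulation(
            sid, m, prior_for(m), sample_sizes, master_seed,
            n_chrom, snps_per_chrom, maf_min, pops,
        )

    for chunk_start in range(0, len(pending), chunk_size):
        chunk = pending[chunk_start : chunk_start + chunk_size]
        if workers > 1:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=workers)(delayed(run)(j) for j in chunk)
        else:
            results = [run(j) for j in chunk]
        new_rows = []
        for row, retries in results:
            total_retries += retries
            new_rows.append(row)
        rows.extend(new_rows)
        if out_path is not None:
            pd.DataFrame(new_rows).to_csv(
                out_path, sep="\t", index=False, mode="a" if header_written else "w",
                header=not header_written, float_format="%.17g",
            )
            header_written = True
        if progress:
            done = start_at + chunk_start + len(chunk)
            rate = done / max(_time.time() - t0, 1e-9)
            print(f"  [reference table] {done}/{len(jobs)} sims ({rate:.0f}/s)")

    n_new = len(pending)
    # a handful of redraws on a small run is sampling noise, not pathology:
    # only abort once the count is informative
    if n_new > 0 and total_retries > max(10.0, max_failure_rate * n_new):
        raise SimulationError(
            f"simulation redraw rate {total_retries}/{n_new} exceeds "
            f"{max_failure_rate:.2%}: check priors / sample sizes"
        )

    df = pd.DataFrame(rows)
    param_names = list(DemographicParameters().as_dict())
    stat_names = [c for c in df.columns if c not in {"sim_id", "model", *param_names}]
    meta = {
        "master_seed": master_seed,
        "models": models,
        "n_sims_per_model": n_sims_per_model,
        "sample_sizes": sample_sizes,
        "n_chrom": n_chrom,
        "snps_per_chrom": snps_per_chrom,
        "maf_min": maf_min,
        "redraws": total_retries,
    }
    table = ReferenceTable(df, param_names, stat_names, meta)
    if out_path is not None:
        table.write_tsv(out_path)  # rewrite with final metadata sidecar
    return table
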