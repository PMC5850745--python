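import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coalabc import popgen_stats as pg
from coalabc.popgen_stats import (
    binned_scan,
    fst_weir_cockerham,
    genome_means,
    haplotype_blocks,
    n50,
    nucleotide_diversity,
    sumstat_vector,
    tajimas_d,
)

from conftest import make_gm, random_gm


# ---------------------------------------------------------------------------
# Independent oracles (plain transcriptions, no shared code with the package)
# ---------------------------------------------------------------------------


def oracle_pi(calls, span):
    """All-pairs-of-allele-copies mean difference per site."""
    total = 0.0
    for site in calls:
        copies = []
        for g in site:
            if g != -1:
                copies += [1] * int(g) + [0] * (2 - int(g))
        n = len(copies)
        if n < 2:
            continue
        diff = sum(
            1 for a, b in itertools.combinations(range(n), 2) if copies[a] != copies[b]
        )
        total += diff / (n * (n - 1) / 2)
    return total / span


def oracle_tajima_d(calls):
    """Direct transcription of the published D formula, complete data."""
    calls = np.asarray(calls)
    n = 2 * calls.shape[1]
    counts = calls.sum(axis=1)
    seg = [c for c in counts if 0 < c < n]
    S = len(seg)
    if S == 0:
        return math.nan
    pi = sum(2 * (c / n) * (1 - c / n) * n / (n - 1) for c in seg)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_wc_fst(calls_a, calls_b):
    """Scalar-loop transcription of Weir & Cockerham (1984), r = 2."""
    calls_a, calls_b = np.asarray(calls_a), np.asarray(calls_b)
    num = den = 0.0
    for s in range(calls_a.shape[0]):
        ga = [g for g in calls_a[s] if g != -1]
        gb = [g for g in calls_b[s] if g != -1]
        n1, n2 = len(ga), len(gb)
        if n1 < 1 or n2 < 1 or n1 + n2 < 3:
            continue
        p1 = sum(ga) / (2 * n1)
        p2 = sum(gb) / (2 * n2)
        h1 = sum(1 for g in ga if g == 1) / n1
        h2 = sum(1 for g in gb if g == 1) / n2
        nbar = (n1 + n2) / 2
        if nbar <= 1:
            continue
        nc = (2 * nbar - (n1**2 + n2**2) / (2 * nbar)) / 1.0
        pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den != 0 else math.nan


def oracle_n50(lengths):
    lengths = sorted(lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


class TestPi:
    def test_monomorphic_zero(self):
        gm = make_gm(np.zeros((10, 4), dtype=int))
        assert nucleotide_diversity(gm, None, 10) == 0.0

    def test_two_haplotypes_one_diff(self):
        # one diploid (2 haplotypes), 1 het site among 100
        calls = np.zeros((100, 1), dtype=int)
        calls[42, 0] = 1
        gm = make_gm(calls, pops=["A"])
        assert nucleotide_diversity(gm, "A", 100) == pytest.approx(0.01)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(20):
            gm = random_gm(rng, n_sites=10, n_indiv=5, miss_frac=0.1)
            got = nucleotide_diversity(gm, None, 10)
            want = oracle_pi(gm.calls, 10)
            assert got == pytest.approx(want, rel=1e-12)

    def test_span_validation(self):
        gm = make_gm([[0, 1]])
        with pytest.raises(ValueError):
            nucleotide_diversity(gm, None, 0)
        with pytest.raises(KeyError):
            nucleotide_diversity(gm, "nope", 10)

    def test_allele_relabel_invariance(self, rng):
        gm = random_gm(rng, n_sites=20, n_indiv=6)
        flipped = make_gm(np.where(gm.calls == -1, -1, 2 - gm.calls))
        assert nucleotide_diversity(gm, None, 20) == pytest.approx(
            nucleotide_diversity(flipped, None, 20)
        )
        assert pg.expected_heterozygosity(gm, None) == pytest.approx(
            pg.expected_heterozygosity(flipped, None)
        )


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


class TestTajimasD:
    def test_no_segregating_sites_missing(self):
        gm = make_gm(np.zeros((5, 4), dtype=int))
        with pytest.warns(UserWarning, match="no segregating"):
            assert math.isnan(tajimas_d(gm))

    def test_four_haplotypes_three_sites(self):
        # alt-copy counts {1, 2, 1} among n=4 copies (2 diploids)
        calls = np.array([[1, 0], [1, 1], [0, 1]])
        gm = make_gm(calls, pops=["A", "A"])
        assert tajimas_d(gm, "A") == pytest.approx(oracle_tajima_d(calls), rel=1e-12)

    def test_random_fixtures_match_oracle(self, rng):
        hits = 0
        while hits < 20:
            gm = random_gm(rng, n_sites=15, n_indiv=6)
            want = oracle_tajima_d(gm.calls)
            if math.isnan(want):
                continue
            assert tajimas_d(gm) == pytest.approx(want, rel=1e-12)
            hits += 1

    def test_neutral_mean_near_zero(self):
        # SNP-ascertained constant-size sims: E[pi_total] = S/a1 exactly,
        # so mean D over replicates ~ 0
        from coalabc.coalescent_sim import drop_snps, simulate_genealogy
        from coalabc.demography import DemographicParameters, build_model

        model = build_model("mesoamerican", DemographicParameters())
        rng = np.random.default_rng(77)
        ds = []
        for _ in range(2000):
            gen = simulate_genealogy(model, {"MW": 5}, rng)
            haps = drop_snps(gen, 30, 0.0, rng)
            calls = (haps[0::2] + haps[1::2]).T
            gm = make_gm(calls, pops=["A"] * 5, pos=np.arange(1, 31))
            d = tajimas_d(gm, "A")
            ds.append(d)
        ds = np.array(ds)
        assert np.isfinite(ds).all()
        assert abs(ds.mean()) < 0.15
        assert np.mean((ds > -3) & (ds < 3)) > 0.99


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------


class TestFst:
    def test_complete_fixation(self):
        calls = np.hstack([np.full((50, 4), 2), np.zeros((50, 4), dtype=int)])
        gm = make_gm(calls, pops=["A"] * 4 + ["B"] * 4)
        assert fst_weir_cockerham(gm, "A", "B") == pytest.approx(1.0)

    def test_identical_pops_near_zero(self, rng):
        # HWE genotypes; duplicating the cohort forces s2 = 0, so theta
        # carries only the O(1/n) finite-sample term
        p = rng.uniform(0.2, 0.8, size=250)
        half = rng.binomial(2, p[:, None], size=(250, 50)).astype(np.int8)
        calls = np.hstack([half, half])
        gm = make_gm(calls, pops=["A"] * 50 + ["B"] * 50)
        assert abs(fst_weir_cockerham(gm, "A", "B")) < 0.05

    def test_single_locus_closed_form(self):
        # popA: 10 copies 8 alt (2,2,2,1,1); popB: 10 copies 2 alt (1,1,0,0,0)
        calls = np.array([[2, 2, 2, 1, 1, 1, 1, 0, 0, 0]])
        gm = make_gm(calls, pops=["A"] * 5 + ["B"] * 5)
        want = oracle_wc_fst(calls[:, :5], calls[:, 5:])
        assert fst_weir_cockerham(gm, "A", "B") == pytest.approx(want, rel=1e-12)

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(20):
            gm = random_gm(rng, n_sites=12, n_indiv=8, miss_frac=0.1)
            ia, ib = gm.pop_indices("A"), gm.pop_indices("B")
            want = oracle_wc_fst(gm.calls[:, ia], gm.calls[:, ib])
            got = fst_weir_cockerham(gm, "A", "B")
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-10)

    def test_symmetry(self, rng):
        gm = random_gm(rng, n_sites=30, n_indiv=10)
        assert fst_weir_cockerham(gm, "A", "B") == pytest.approx(
            fst_weir_cockerham(gm, "B", "A")
        )

    def test_no_shared_polymorphism_missing(self):
        gm = make_gm(np.zeros((5, 4), dtype=int))
        assert math.isnan(fst_weir_cockerham(gm, "A", "B"))


# ---------------------------------------------------------------------------
# binned scan
# ---------------------------------------------------------------------------


class TestBinnedScan:
    def _gm_three_bins(self):
        # bins of 100 kb with 5, 2, 4 variants
        pos = (
            list(range(1000, 6000, 1000))
            + [100_500, 150_000]
            + [200_100, 210_000, 220_000, 230_000]
        )
        calls = np.tile([0, 1, 2, 1, 0, 1], (len(pos), 1))
        calls[::2, 0] = 2
        return make_gm(calls, pos=pos, pops=["A"] * 3 + ["B"] * 3)

    def test_sparse_bin_absent(self):
        scan = binned_scan(self._gm_three_bins())
        starts = [s.bin_start for s in scan]
        assert starts == [1, 200_001]  # the 2-variant bin is dropped

    def test_all_variants_one_bin(self):
        gm = make_gm(np.tile([0, 1, 1, 0], (5, 1)), pos=[10, 20, 30, 40, 50])
        scan = binned_scan(gm)
        assert len(scan) == 1
        assert scan[0].n_variants == 5

    def test_genome_mean_is_hand_average(self):
        gm = self._gm_three_bins()
        scan = binned_scan(gm)
        means = genome_means(scan)
        for key in means:
            vals = []
            for s in scan:
                for d in (s.pi, s.tajima_d):
                    for p, v in d.items():
                        if key == f"{'pi' if d is s.pi else 'tajima_d'}_{p}":
                            vals.append(v)
                for (a, b), v in s.fst.items():
                    if key == f"fst_{a}_{b}":
                        vals.append(v)
            assert means[key] == pytest.approx(np.mean(vals))

    def test_pi_normalization_modes(self):
        gm = self._gm_three_bins()
        per_bp = binned_scan(gm, pi_per_bp=True)
        per_site = binned_scan(gm, pi_per_bp=False)
        ratio = per_site[0].pi["A"] / per_bp[0].pi["A"]
        assert ratio == pytest.approx(100_000 / 5)


# ---------------------------------------------------------------------------
# haplotype blocks & N50
# ---------------------------------------------------------------------------


class TestHaplotypeBlocks:
    def _perfect_ld_gm(self, gap):
        # 20 individuals, two SNPs in complete LD, all homozygous
        col = np.array([2] * 10 + [0] * 10)
        calls = np.vstack([col, col])
        return make_gm(calls, pos=[1000, 1000 + gap], pops=["A"] * 20)

    def test_perfect_pair_becomes_block(self):
        bs = haplotype_blocks(self._perfect_ld_gm(500), "A")
        assert bs.total_blocks == 1
        assert bs.blocks[0][1:3] == (1000, 1500)
        assert bs.n50 == 500

    def test_short_block_removed(self):
        bs = haplotype_blocks(self._perfect_ld_gm(50), "A")
        assert bs.total_blocks == 0

    def test_window_excludes_distant_pairs(self):
        bs = haplotype_blocks(self._perfect_ld_gm(3_000_000), "A")
        assert bs.total_blocks == 0  # beyond the 2 Mb window

    def test_planted_breakpoint_matches_exhaustive_oracle(self, rng):
        # 8 SNPs: left four in complete LD, right four in complete LD,
        # recombination between the two groups
        n = 30
        left = rng.integers(0, 2, size=n)
        right = rng.permutation(left)
        calls = np.vstack([np.tile(2 * left, (4, 1)), np.tile(2 * right, (4, 1))])
        pos = np.array([1000, 1400, 1800, 2200, 2600, 3000, 3400, 3800])
        gm = make_gm(calls, pos=pos, pops=["A"] * n)
        bs = haplotype_blocks(gm, "A")

        # oracle: same pair classification, exhaustive search over all
        # contiguous spans, greedy by length
        haps = np.where(calls == 0, 0, np.where(calls == 2, 1, -1)).T
        cls = pg._classify_pairs(haps, 0.70, 0.98, 0.90)
        cand = []
        for i in range(8):
            for j in range(i + 1, 8):
                if cls[i, j] != 1:
                    continue
                pairs = [cls[a, b] for a in range(i, j + 1) for b in range(a + 1, j + 1)]
                inf = [p for p in pairs if p != 0]
                if inf and sum(1 for p in inf if p == 1) / len(inf) >= 0.95:
                    cand.append((pos[j] - pos[i], i, j))
        cand.sort(key=lambda t: (-t[0], t[1]))
        used = set()
        expect = []
        for span, i, j in cand:
            if span <= 100 or used & set(range(i, j + 1)):
                continue
            used |= set(range(i, j + 1))
            expect.append((int(pos[i]), int(pos[j])))
        got = [(b[1], b[2]) for b in bs.blocks]
        assert sorted(got) == sorted(expect)
        # and the breakpoint is respected: no block spans SNP 3 -> 4
        for s, e in got:
            assert not (s <= 2200 and e >= 2600)

    def test_too_few_snps(self):
        gm = make_gm([[0, 2]], pops=["A", "A"])
        assert haplotype_blocks(gm, "A").total_blocks == 0


class TestN50:
    def test_singleton(self):
        assert n50([7]) == 7

    def test_hand_case(self):
        assert n50([4, 3, 3, 2, 2, 2]) == 3

    def test_empty_error(self):
        with pytest.raises(ValueError):
            n50([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1, max_size=30))
    def test_matches_brute_force(self, lengths):
        assert n50(lengths) == oracle_n50(lengths)


# ---------------------------------------------------------------------------
# summary-statistic vector
# ---------------------------------------------------------------------------


class TestSumstatVector:
    def test_monomorphic(self):
        gm = make_gm(np.zeros((8, 6), dtype=int))
        vec = sumstat_vector(gm, ["A", "B"]).to_series()
        assert vec["S_A"] == 0
        assert vec["pi_A"] == 0
        assert vec["D_A"] == 0.0  # undefined D recorded at its S->0 limit
        assert math.isnan(vec["fst_A_B"])
        assert vec["S_total"] == 0
        raw = sumstat_vector(gm, ["A", "B"], d_fill=None).to_series()
        assert math.isnan(raw["D_A"])

    def test_individual_order_invariance(self, rng):
        gm = random_gm(rng, n_sites=25, n_indiv=10)
        perm = rng.permutation(10)
        gm2 = gm.take_individuals(perm)
        v1 = sumstat_vector(gm, ["A", "B"])
        v2 = sumstat_vector(gm2, ["A", "B"])
        assert v1.names == v2.names
        np.testing.assert_allclose(v1.values, v2.values, rtol=1e-12)

    def test_components_equal_standalone_ops(self, rng):
        gm = random_gm(rng, n_sites=25, n_indiv=10, miss_frac=0.05)
        vec = sumstat_vector(gm, ["A", "B"]).to_series()
        assert vec["S_A"] == pg.segregating_sites(gm, "A")
        assert vec["pi_B"] == pytest.approx(nucleotide_diversity(gm, "B", 25))
        assert vec["H_A"] == pytest.approx(pg.expected_heterozygosity(gm, "A"))
        d = tajimas_d(gm, "A")
        assert vec["D_A"] == pytest.approx(0.0 if math.isnan(d) else d)
        assert vec["fst_A_B"] == pytest.approx(fst_weir_cockerham(gm, "A", "B"))

    def test_requires_two_pops_and_two_indiv(self, rng):
        gm = random_gm(rng, n_sites=5, n_indiv=4)
        with pytest.raises(ValueError):
            sumstat_vector(gm, ["A"])
        gm2 = random_gm(rng, n_sites=5, n_indiv=3, pops=["A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            sumstat_vector(gm2, ["A", "B"])

    def test_tsv_round_trip(self, rng, tmp_path):
        from coalabc.popgen_stats import SummaryStatisticVector

        gm = random_gm(rng, n_sites=25, n_indiv=10)
        vec = sumstat_vector(gm, ["A", "B"])
        vec.write_tsv(tmp_path / "v.tsv")
        back = SummaryStatisticVector.read_tsv(tmp_path / "v.tsv")
        assert back.names == vec.names
        np.testing.assert_allclose(back.values, vec.values)
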