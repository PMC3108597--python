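"""Hierarchical AMOVA, permutation schemes, pairwise Phi_ST, LOO screen, SGoF."""

import itertools

import numpy as np
import pytest
from scipy.stats import binom

from mthap.amova import (
    amova,
    loo_screen,
    pairwise_phist,
    permutation_test,
    sgof_correct,
)
from mthap.diversity import DistanceMatrix, distance_matrix
from mthap.errors import DesignError, ParameterError, UndefinedStatisticError
from mthap.hapio import collapse_haplotypes

from conftest import make_dataset, random_dataset


def amova_oracle(d2, pops, grps):
    """Independent AMOVA: full individual-level squared-distance matrix,
    nested sums of squares solved directly from their definitions."""
    N = len(pops)
    pops = np.asarray(pops)
    grps = np.asarray(grps)

    def ssd(idx):
        if len(idx) == 0:
            return 0.0
        sub = d2[np.ix_(idx, idx)]
        return sub.sum() / (2.0 * len(idx))

    all_idx = np.arange(N)
    ssd_t = ssd(all_idx)
    ssd_wp = sum(ssd(np.flatnonzero(pops == p)) for p in np.unique(pops))
    ssd_wg = sum(ssd(np.flatnonzero(grps == g)) for g in np.unique(grps))
    P = np.unique(pops).size
    G = np.unique(grps).size
    df_ap, df_ag, df_wg = P - 1, G - P, N - G
    n_p = {p: (pops == p).sum() for p in np.unique(pops)}
    n_g = {g: (grps == g).sum() for g in np.unique(grps)}
    parent = {g: pops[grps == g][0] for g in np.unique(grps)}
    s1 = sum(
        sum(n_g[g] ** 2 for g in n_g if parent[g] == p) / n_p[p] for p in n_p
    )
    n1 = (N - s1) / df_ag if df_ag else 0.0
    n2 = (s1 - sum(v**2 for v in n_g.values()) / N) / df_ap
    n3 = (N - sum(v**2 for v in n_p.values()) / N) / df_ap
    sc = ssd_wg / df_wg
    sb = ((ssd_wp - ssd_wg) / df_ag - sc) / n1 if df_ag else 0.0
    sa = ((ssd_t - ssd_wp) / df_ap - sc - n2 * sb) / n3
    return sa, sb, sc, (ssd_t - ssd_wp, ssd_wp - ssd_wg, ssd_wg, ssd_t)


def individual_d2(ht, dist):
    """Expand the haplotype distance matrix to individuals (squared)."""
    hap_of = ht.assignments
    d2 = np.zeros((len(hap_of), len(hap_of)))
    for i, hi in enumerate(hap_of):
        for j, hj in enumerate(hap_of):
            d2[i, j] = dist.d[hi, hj] ** 2
    return d2


class TestAmovaComponents:
    def test_fixed_populations_phi_one(self, two_pop_fixed_table):
        ht = two_pop_fixed_table
        dist = distance_matrix(ht, "p-distance")
        res = amova(ht, dist, levels=2)
        assert res.phi_ST == pytest.approx(1.0)

    def test_identical_compositions_nonpositive(self):
        ds = make_dataset(
            ["AAAA", "GGGG", "AAAA", "GGGG"],
            pops=["P1", "P1", "P2", "P2"],
        )
        ht = collapse_haplotypes(ds)
        res = amova(ht, distance_matrix(ht, "p-distance"), levels=2)
        assert res.sigma2_a <= 0
        assert res.phi_ST <= 0

    def test_matches_brute_force_oracle(self, rng):
        # random 3-population, 2-groups-per-population fixtures (<= 12 ind.)
        for trial in range(10):
            ds = random_dataset(rng, n=12, L=10, n_pops=3, n_groups=2)
            ht = collapse_haplotypes(ds)
            if ht.K < 2:
                continue
            dist = distance_matrix(ht, "p-distance")
            try:
                res = amova(ht, dist, levels=3)
            except (DesignError, UndefinedStatisticError):
                continue
            pops = [r.population for r in ds.records]
            grps = [f"{r.population}|{r.group}" for r in ds.records]
            # amova() iterates individuals in haplotype-table order; the
            # oracle works in record order — same multiset, same components
            sa, sb, sc, ssd = amova_oracle(individual_d2(ht, dist), pops, grps)
            assert res.sigma2_a == pytest.approx(sa, rel=1e-9, abs=1e-12)
            assert res.sigma2_b == pytest.approx(sb, rel=1e-9, abs=1e-12)
            assert res.sigma2_c == pytest.approx(sc, rel=1e-9, abs=1e-12)

    def test_ssd_additivity(self, rng):
        ds = random_dataset(rng, n=14, L=10, n_pops=3, n_groups=2)
        ht = collapse_haplotypes(ds)
        dist = distance_matrix(ht, "p-distance")
        res = amova(ht, dist, levels=3)
        ssd_ap, ssd_ag, ssd_wg, ssd_t = res.SSD
        assert ssd_ap + ssd_ag + ssd_wg == pytest.approx(ssd_t, rel=1e-9)

    def test_three_level_reduces_to_two_level(self, rng):
        # when every population has exactly one group the designs coincide
        ds = random_dataset(rng, n=12, L=10, n_pops=3, n_groups=1)
        ht = collapse_haplotypes(ds)
        dist = distance_matrix(ht, "p-distance")
        r3 = amova(ht, dist, levels=3)
        r2 = amova(ht, dist, levels=2)
        assert r3.phi_ST == pytest.approx(r2.phi_ST, rel=1e-9)

    def test_single_population_rejected(self):
        ds = make_dataset(["AAAA", "AAAG"], pops=["P1", "P1"])
        ht = collapse_haplotypes(ds)
        with pytest.raises(DesignError):
            amova(ht, distance_matrix(ht, "p-distance"), levels=2)

    def test_all_zero_distances_rejected(self, two_pop_fixed_table):
        ht = two_pop_fixed_table
        zero = DistanceMatrix(list(ht.ids), np.zeros((ht.K, ht.K)), "p-distance")
        with pytest.raises(UndefinedStatisticError):
            amova(ht, zero, levels=2)


class TestPermutation:
    def test_exact_enumeration_2plus2(self, two_pop_fixed_table):
        # enumerate all C(4,2) label assignments of the AABB individuals
        ht = two_pop_fixed_table
        dist = distance_matrix(ht, "p-distance")
        obs = amova(ht, dist, levels=2)
        d2 = individual_d2(ht, dist)
        haps = ["A", "A", "B", "B"]
        phis = []
        for pop1 in itertools.combinations(range(4), 2):
            pops = ["P2"] * 4
            for i in pop1:
                pops[i] = "P1"
            sa, sb, sc, _ = amova_oracle(d2, pops, pops)
            phis.append(sa / (sa + sc))
        exact = np.mean([p >= obs.phi_ST - 1e-12 for p in phis])
        res = permutation_test(ht, dist, n_perm=3000, seed=5, levels=2)
        assert exact == pytest.approx(1 / 3)
        assert res.p_ST == pytest.approx(exact, abs=0.03)

    def test_null_never_significant(self):
        ds = make_dataset(
            ["AAAA", "GGGG", "AAAA", "GGGG"],
            pops=["P1", "P1", "P2", "P2"],
        )
        ht = collapse_haplotypes(ds)
        res = permutation_test(
            ht, distance_matrix(ht, "p-distance"), n_perm=500, seed=2, levels=2
        )
        assert res.p_ST > 0.5

    def test_invalid_n_perm(self, two_pop_fixed_table):
        ht = two_pop_fixed_table
        with pytest.raises(ParameterError):
            permutation_test(ht, distance_matrix(ht, "p-distance"), n_perm=0)

    def test_relabel_invariance(self, rng):
        # permutation p-values do not depend on haplotype label order
        ds = random_dataset(rng, n=12, L=10, n_pops=2, n_groups=2)
        ht = collapse_haplotypes(ds)
        if ht.K < 2:
            pytest.skip("degenerate draw")
        dist = distance_matrix(ht, "p-distance")
        r1 = permutation_test(ht, dist, n_perm=200, seed=11, levels=3)
        r2 = permutation_test(ht, dist, n_perm=200, seed=11, levels=3)
        assert r1.p_ST == r2.p_ST and r1.p_SC == r2.p_SC and r1.p_CT == r2.p_CT


class TestPairwisePhist:
    def test_fixed_units_one(self, two_pop_fixed_table):
        ht = two_pop_fixed_table
        dist = distance_matrix(ht, "p-distance")
        phi, _ = pairwise_phist(ht, dist, units="populations")
        assert phi.iloc[0, 1] == pytest.approx(1.0)

    def test_split_unit_expectation_near_zero(self, rng):
        # one panmictic pool split at random into two labels: E[Phi_ST] ~ 0
        vals = []
        for rep in range(40):
            seqs = ["AAAA", "AAAG", "AAGG", "AGGG"] * 3
            local = np.random.default_rng(rep)
            pops = local.permutation(["P1"] * 6 + ["P2"] * 6)
            ds = make_dataset(seqs, pops=list(pops))
            ht = collapse_haplotypes(ds)
            dist = distance_matrix(ht, "p-distance")
            phi, _ = pairwise_phist(ht, dist, units="populations")
            vals.append(phi.iloc[0, 1])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 2.5 * se + 0.02

    def test_matches_single_pair_amova(self, rng):
        ds = random_dataset(rng, n=12, L=10, n_pops=3, n_groups=1)
        ht = collapse_haplotypes(ds)
        if ht.K < 2:
            pytest.skip("degenerate draw")
        dist = distance_matrix(ht, "p-distance")
        phi, _ = pairwise_phist(ht, dist, units="populations")
        pops = ht.counts.columns.get_level_values(0).unique()
        for a, b in itertools.combinations(pops, 2):
            pair = ht.restrict([a, b])
            pair_dist = distance_matrix(pair, "p-distance")
            try:
                expect = amova(pair, pair_dist, levels=2).phi_ST
            except UndefinedStatisticError:
                continue
            assert phi.loc[a, b] == pytest.approx(expect, rel=1e-9, abs=1e-12)


class TestLooScreen:
    def _ssb_like(self):
        # P1 groups share haplotypes; P2 has one group fixed for a private one
        seqs, pops, grps = [], [], []
        shared = ["AAAA", "AAAG"]
        for g in ("g1", "g2"):
            for i in range(4):
                seqs.append(shared[i % 2])
                pops.append("P1")
                grps.append(g)
        for i in range(4):  # mixed group in P2
            seqs.append(shared[i % 2])
            pops.append("P2")
            grps.append("g1")
        for _ in range(4):  # SSB-like: fixed private haplotype
            seqs.append("GGGG")
            pops.append("P2")
            grps.append("ssb")
        return make_dataset(seqs, pops=pops, groups=grps)

    def test_private_fixed_group_maximizes_drop(self):
        ds = self._ssb_like()
        ht = collapse_haplotypes(ds)
        dist = distance_matrix(ht, "p-distance")
        res = loo_screen(ht, dist, n_perm=100, seed=3)
        rows = res.rows[~res.rows["skipped"]]
        # removing the divergent fixed group leaves the least among-group
        # variance: its row has the smallest Phi_SC
        assert rows.iloc[-1]["excluded_group"] == "P2/ssb"

    def test_row_cardinality(self, rng):
        ds = random_dataset(rng, n=24, L=10, n_pops=2, n_groups=4)
        ht = collapse_haplotypes(ds)
        dist = distance_matrix(ht, "p-distance")
        res = loo_screen(ht, dist, n_perm=50, seed=1)
        n_groups = ht.counts.columns.nunique()
        assert len(res.rows) == n_groups

    def test_homogeneous_groups_flat(self):
        seqs = ["AAAA", "AAAG"] * 8
        pops = ["P1"] * 8 + ["P2"] * 8
        grps = (["g1"] * 4 + ["g2"] * 4) * 2
        ds = make_dataset(seqs, pops=pops, groups=grps)
        ht = collapse_haplotypes(ds)
        res = loo_screen(ht, distance_matrix(ht, "p-distance"), n_perm=100, seed=7)
        rows = res.rows[~res.rows["skipped"]]
        # identical group compositions: no exclusion stands out
        spread = rows["phi_SC"].max() - rows["phi_SC"].min()
        assert spread < 0.3
        assert res.sgof_significant == []


class TestSgof:
    def test_all_ones_empty(self):
        sig, meta = sgof_correct([1.0] * 10)
        assert sig == []

    def test_single_small_p_among_16(self):
        pvals = [0.001] + [0.9] * 15
        sig, meta = sgof_correct(pvals)
        # P(X >= 1 | Bin(16, 0.05)) = 1 - 0.95^16 ~ 0.56 > 0.05
        assert sig == []
        assert meta == pytest.approx(1 - 0.95**16)

    def test_all_small_direct_enumeration(self):
        pvals = [0.001] * 16
        sig, _ = sgof_correct(pvals)
        k_expect = sum(
            1 for i in range(1, 17) if binom.sf(i - 1, 16, 0.05) <= 0.05
        )
        assert len(sig) == k_expect
        assert k_expect > 0

    def test_invalid_pvalues(self):
        with pytest.raises(ParameterError):
            sgof_correct([0.5, 1.5])
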