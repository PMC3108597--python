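"""Hierarchical analysis of molecular variance (AMOVA) with Phi statistics.

Decomposes squared inter-individual genetic distances into variance components
among populations (sigma2_a), among social groups within populations
(sigma2_b), and within groups (sigma2_c), following the sums-of-squared-
deviations formulation with unequal-sample-size coefficients.  Fixation
indices:

    Phi_CT = sigma2_a / sigma2_total
    Phi_SC = sigma2_b / (sigma2_b + sigma2_c)
    Phi_ST = (sigma2_a + sigma2_b) / sigma2_total

Significance comes from permutation schemes that mirror each index's null:
individuals among populations (Phi_ST), individuals among groups within their
population (Phi_SC), and whole groups among populations (Phi_CT).  Negative
variance components are reported as computed, never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .diversity import DistanceMatrix
from .errors import DesignError, ParameterError, UndefinedStatisticError
from .hapio import HaplotypeTable


@dataclass
class AmovaResult:
    """Variance components, Phi statistics and (optional) permutation p-values."""

    sigma2_a: float
    sigma2_b: float
    sigma2_c: float
    phi_CT: float
    phi_SC: float
    phi_ST: float
    df: tuple[int, ...]
    SSD: tuple[float, ...]
    levels: int
    p_CT: float | None = None
    p_SC: float | None = None
    p_ST: float | None = None
    n_permutations: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("among_populations", self.sigma2_a, self.phi_CT, self.p_CT),
            ("among_groups_within_populations", self.sigma2_b, self.phi_SC, self.p_SC),
            ("within_groups", self.sigma2_c, self.phi_ST, self.p_ST),
        ]
        return pd.DataFrame(rows, columns=["level", "sigma2", "phi", "p"])


@dataclass
class _Design:
    """Individual-level view of the data: haplotype index, population, group."""

    hap: np.ndarray  # haplotype index per individual
    pop: np.ndarray  # population index per individual
    grp: np.ndarray  # global group index per individual
    grp_pop: np.ndarray  # population index per group
    pop_labels: list[str]
    grp_labels: list[tuple[str, str]]


def _design_from_table(ht: HaplotypeTable) -> _Design:
    hap, pop, grp = [], [], []
    pop_labels: list[str] = []
    grp_labels: list[tuple[str, str]] = []
    col_of: dict = {}
    for j, (p, g) in enumerate(ht.counts.columns):
        if p not in pop_labels:
            pop_labels.append(p)
        grp_labels.append((p, g))
        col_of[j] = (pop_labels.index(p), len(grp_labels) - 1)
    mat = ht.counts.to_numpy()
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            c = int(mat[i, j])
            if c:
                pi, gi = col_of[j]
                hap.extend([i] * c)
                pop.extend([pi] * c)
                grp.extend([gi] * c)
    grp_pop = np.array([pop_labels.index(p) for p, _ in grp_labels])
    return _Design(
        np.asarray(hap), np.asarray(pop), np.asarray(grp), grp_pop,
        pop_labels, grp_labels,
    )


def _ssd(hap: np.ndarray, D2: np.ndarray, K: int) -> float:
    """Sum of squared deviations for one unit: sum_{i<j} d^2_ij / n."""
    n = hap.size
    if n == 0:
        return 0.0
    c = np.bincount(hap, minlength=K).astype(float)
    return float(c @ D2 @ c) / (2.0 * n)


def _components(
    hap: np.ndarray,
    pop: np.ndarray,
    grp: np.ndarray,
    D2: np.ndarray,
    K: int,
):
    """SSDs, dfs and variance components for the three-level nested design."""
    N = hap.size
    pops = np.unique(pop)
    grps = np.unique(grp)
    P, G = pops.size, grps.size
    ssd_t = _ssd(hap, D2, K)
    ssd_wp = sum(_ssd(hap[pop == p], D2, K) for p in pops)
    ssd_wg = sum(_ssd(hap[grp == g], D2, K) for g in grps)
    ssd_ag = ssd_wp - ssd_wg
    ssd_ap = ssd_t - ssd_wp
    df_ap, df_ag, df_wg = P - 1, G - P, N - G
    # unequal-sample-size coefficients of the expected mean squares
    n_p = np.array([(pop == p).sum() for p in pops], dtype=float)
    n_g = np.array([(grp == g).sum() for g in grps], dtype=float)
    grp_parent = np.array([pop[grp == g][0] for g in grps])
    sum_ng2_over_np = sum(
        (n_g[grp_parent == p] ** 2).sum() / n_p[i]
        for i, p in enumerate(pops)
    )
    n1 = (N - sum_ng2_over_np) / df_ag if df_ag > 0 else 0.0
    n2 = (sum_ng2_over_np - (n_g**2).sum() / N) / df_ap
    n3 = (N - (n_p**2).sum() / N) / df_ap
    sigma_c = ssd_wg / df_wg if df_wg > 0 else 0.0
    if df_ag > 0 and n1 > 0:
        sigma_b = (ssd_ag / df_ag - sigma_c) / n1
    else:
        sigma_b = 0.0
    sigma_a = (ssd_ap / df_ap - sigma_c - n2 * sigma_b) / n3
    return (
        (sigma_a, sigma_b, sigma_c),
        (df_ap, df_ag, df_wg),
        (ssd_ap, ssd_ag, ssd_wg, ssd_t),
    )


def _phis(sigma_a: float, sigma_b: float, sigma_c: float):
    total = sigma_a + sigma_b + sigma_c
    if total == 0:
        raise UndefinedStatisticError("all distances zero: Phi statistics are 0/0")
    phi_ct = sigma_a / total
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else np.nan
    phi_st = (sigma_a + sigma_b) / total
    return phi_ct, phi_sc, phi_st


def amova(
    ht: HaplotypeTable,
    dist: DistanceMatrix,
    levels: int = 3,
) -> AmovaResult:
    """Nested AMOVA over the (population, group) structure of ``ht``.

    ``levels=3`` decomposes among populations / among groups within
    populations / within groups; ``levels=2`` ignores group labels and
    decomposes among / within populations (sigma2_b is then reported as 0 and
    Phi_SC is undefined).  Distances are squared internally.
    """
    if list(dist.labels) != list(ht.ids):
        raise DesignError("distance matrix labels do not match haplotype table")
    des = _design_from_table(ht)
    D2 = dist.d**2
    K = ht.K
    if levels == 2:
        grp = des.pop  # one group per population collapses the middle level
    elif levels == 3:
        grp = des.grp
    else:
        raise ParameterError(f"levels must be 2 or 3 (got {levels})")
    if np.unique(des.pop).size < 2:
        raise DesignError("AMOVA needs at least 2 populations")
    if np.all(D2 == 0):
        raise UndefinedStatisticError("all pairwise distances are zero")
    (sa, sb, sc), df, ssd = _components(des.hap, des.pop, grp, D2, K)
    if levels == 2:
        # the middle level is vacuous: its component is structurally zero
        sb = 0.0
    phi_ct, phi_sc, phi_st = _phis(sa, sb, sc)
    return AmovaResult(sa, sb, sc, phi_ct, phi_sc, phi_st, df, ssd, levels)


def permutation_test(
    ht: HaplotypeTable,
    dist: DistanceMatrix,
    n_perm: int = 16000,
    seed: int | None = None,
    levels: int = 3,
) -> AmovaResult:
    """AMOVA with permutation p-values for each Phi statistic.

    p = (#{Phi* >= Phi_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    obs = amova(ht, dist, levels=levels)
    rng = np.random.default_rng(seed)
    des = _design_from_table(ht)
    D2 = dist.d**2
    K = ht.K
    grp = des.pop if levels == 2 else des.grp

    ge_st = ge_sc = ge_ct = 0
    n_groups = des.grp_pop.size
    for _ in range(n_perm):
        # Phi_ST: individuals permuted among populations (design fixed)
        perm = rng.permutation(des.hap)
        (sa, sb, sc), _, _ = _components(perm, des.pop, grp, D2, K)
        if levels == 2:
            sb = 0.0
        tot = sa + sb + sc
        phi_st = (sa + sb) / tot if tot != 0 else -np.inf
        if phi_st >= obs.phi_ST - 1e-12:
            ge_st += 1
        if levels == 3:
            # Phi_SC: individuals permuted among groups within their population
            perm = des.hap.copy()
            for p in np.unique(des.pop):
                idx = np.flatnonzero(des.pop == p)
                perm[idx] = perm[rng.permutation(idx)]
            (sa, sb, sc), _, _ = _components(perm, des.pop, des.grp, D2, K)
            phi_sc = sb / (sb + sc) if (sb + sc) != 0 else -np.inf
            if phi_sc >= obs.phi_SC - 1e-12:
                ge_sc += 1
            # Phi_CT: whole groups permuted among populations
            new_parent = des.grp_pop[rng.permutation(n_groups)]
            pop_star = new_parent[des.grp]
            (sa, sb, sc), _, _ = _components(des.hap, pop_star, des.grp, D2, K)
            tot = sa + sb + sc
            phi_ct = sa / tot if tot != 0 else -np.inf
            if phi_ct >= obs.phi_CT - 1e-12:
                ge_ct += 1
    obs.p_ST = (ge_st + 1) / (n_perm + 1)
    if levels == 3:
        obs.p_SC = (ge_sc + 1) / (n_perm + 1)
        obs.p_CT = (ge_ct + 1) / (n_perm + 1)
    obs.n_permutations = n_perm
    return obs


def pairwise_phist(
    ht: HaplotypeTable,
    dist: DistanceMatrix,
    units: str = "groups",
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise Phi_ST matrix between groups (default) or populations.

    Each pair is a two-level AMOVA; negative values are reported as computed.
    With ``n_perm > 0`` a second DataFrame of permutation p-values is returned.
    """
    des = _design_from_table(ht)
    if units == "groups":
        labels = [f"{p}/{g}" for p, g in des.grp_labels]
        unit_of = des.grp
    elif units == "populations":
        labels = list(des.pop_labels)
        unit_of = des.pop
    else:
        raise ParameterError(f"units must be 'groups' or 'populations' (got {units!r})")
    U = len(labels)
    if U < 2:
        raise DesignError("pairwise Phi_ST needs at least 2 units")
    sizes = np.bincount(unit_of, minlength=U)
    if np.any(sizes == 0):
        raise DesignError("a unit has no individuals")
    D2 = dist.d**2
    K = ht.K
    rng = np.random.default_rng(seed)
    phi = np.full((U, U), 0.0)
    pmat = np.full((U, U), np.nan) if n_perm else None

    def _two_level_phi(hap, pop):
        (sa, sb, sc), _, _ = _components(hap, pop, pop, D2, K)
        tot = sa + sc
        return sa / tot if tot != 0 else np.nan

    for i in range(U):
        for j in range(i + 1, U):
            mask = (unit_of == i) | (unit_of == j)
            hap = des.hap[mask]
            pop = (unit_of[mask] == j).astype(int)
            val = _two_level_phi(hap, pop)
            phi[i, j] = phi[j, i] = val
            if n_perm:
                ge = 0
                for _ in range(n_perm):
                    hap_star = rng.permutation(hap)
                    v = _two_level_phi(hap_star, pop)
                    if not np.isnan(v) and v >= val - 1e-12:
                        ge += 1
                pmat[i, j] = pmat[j, i] = (ge + 1) / (n_perm + 1)
    phi_df = pd.DataFrame(phi, index=labels, columns=labels)
    p_df = pd.DataFrame(pmat, index=labels, columns=labels) if n_perm else None
    return phi_df, p_df


@dataclass
class ScreenResult:
    """Leave-one-group-out AMOVA screen with SGoF multiple-test correction."""

    rows: pd.DataFrame  # excluded_group, phi_CT, phi_SC, phi_ST, p_SC, skipped
    sgof_significant: list[str] = field(default_factory=list)
    sgof_meta_p: float = float("nan")


def loo_screen(
    ht: HaplotypeTable,
    dist: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    gamma: float = 0.05,
) -> ScreenResult:
    """One three-level AMOVA per excluded social group.

    Identifies groups that drive the among-group-within-population component:
    rows are sorted by Phi_SC descending, and the SGoF procedure flags which
    exclusions leave a significant Phi_SC.  An exclusion that would empty a
    population is flagged skipped rather than fatal.
    """
    des = _design_from_table(ht)
    if np.unique(des.pop).size < 2:
        raise DesignError("leave-one-group-out screen needs >= 2 populations")
    rng = np.random.default_rng(seed)
    rows = []
    for g, (p, glab) in enumerate(des.grp_labels):
        mask = des.grp != g
        label = f"{p}/{glab}"
        remaining_pops = np.unique(des.pop[mask])
        if remaining_pops.size < 2:
            rows.append(
                {"excluded_group": label, "phi_CT": np.nan, "phi_SC": np.nan,
                 "phi_ST": np.nan, "p_SC": np.nan, "skipped": True}
            )
            continue
        sub = _subset_table(ht, mask, des)
        sub_dist = DistanceMatrix(
            [ht.ids[i] for i in sub._kept_haps],
            dist.d[np.ix_(sub._kept_haps, sub._kept_haps)],
            dist.model,
        )
        res = permutation_test(
            sub.table, sub_dist, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)), levels=3,
        )
        rows.append(
            {"excluded_group": label, "phi_CT": res.phi_CT, "phi_SC": res.phi_SC,
             "phi_ST": res.phi_ST, "p_SC": res.p_SC, "skipped": False}
        )
    df = pd.DataFrame(rows).sort_values("phi_SC", ascending=False, ignore_index=True)
    tested = df[~df["skipped"]]
    sig_idx, meta_p = sgof_correct(tested["p_SC"].to_numpy(), alpha=alpha, gamma=gamma)
    significant = tested.iloc[sorted(sig_idx)]["excluded_group"].tolist()
    return ScreenResult(df, significant, meta_p)


class _SubTable:
    def __init__(self, table: HaplotypeTable, kept_haps: list[int]):
        self.table = table
        self._kept_haps = kept_haps


def _subset_table(ht: HaplotypeTable, mask: np.ndarray, des: _Design) -> _SubTable:
    """Haplotype table restricted to the individuals selected by ``mask``."""
    hap = des.hap[mask]
    pop = des.pop[mask]
    grp = des.grp[mask]
    kept = sorted(set(hap.tolist()))
    remap = {h: i for i, h in enumerate(kept)}
    cols: dict[tuple[str, str], int] = {}
    for g in np.unique(grp):
        p, glab = des.grp_labels[g]
        cols[(p, glab)] = len(cols)
    mat = np.zeros((len(kept), len(cols)), dtype=int)
    for h, g in zip(hap, grp):
        p, glab = des.grp_labels[g]
        mat[remap[h], cols[(p, glab)]] += 1
    columns = pd.MultiIndex.from_tuples(list(cols), names=["population", "group"])
    ids = [ht.ids[h] for h in kept]
    counts = pd.DataFrame(mat, index=pd.Index(ids, name="haplotype_id"), columns=columns)
    haps = [ht.haplotypes[h] for h in kept]
    assignments = [remap[h] for h in hap]
    return _SubTable(HaplotypeTable(haps, counts, assignments, ht.L), kept)


def sgof_correct(
    pvalues: Sequence[float],
    alpha: float = 0.05,
    gamma: float = 0.05,
) -> tuple[list[int], float]:
    """Sequential goodness-of-fit multiple-test correction.

    With N tests and R = #{p <= gamma}, compares R against Binomial(N, gamma):
    k = #{ i in 1..R : P(X >= i) <= alpha } hypotheses are declared
    significant, taken as the k smallest p-values.  Returns their indices
    (into the input order) and the meta-test probability P(X >= R).
    One-sided exact binomial, no continuity correction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return [], float("nan")
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    N = p.size
    R = int((p <= gamma).sum())
    meta_p = float(binom.sf(R - 1, N, gamma)) if R >= 1 else 1.0
    k = 0
    for i in range(1, R + 1):
        if binom.sf(i - 1, N, gamma) <= alpha:
            k += 1
    order = np.argsort(p, kind="stable")
    return order[:k].tolist(), meta_p
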