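"""Neutrality statistics, coalescent null distributions, and effective size.

Implements four tests of the constant-size neutral coalescent widely used to
probe demographic history from a single non-recombining locus:

* Fu's Fs — based on the Ewens sampling probability of observing at least the
  sampled number of haplotypes given theta estimated from mean pairwise
  differences; large negative values indicate an excess of haplotypes
  (star-like genealogies, expansion).
* Fu & Li's D* and F* — contrast the total number of mutations (and mean
  pairwise differences) with the number of singleton mutations, without an
  outgroup; singleton excess drives them negative.
* Ramos-Onsins & Rozas' R2 — the scaled deviation between per-sequence
  singleton counts and half the mean pairwise difference; low values indicate
  expansion.

Significance comes from simulating standard neutral constant-size coalescent
genealogies for n tips with the observed number of segregating sites placed
uniformly at random on the branches (fixed-S conditioning, the desk-tool
convention), recomputing each statistic per replicate.

Also houses the Watterson and Tajima theta estimators and the effective-size
arithmetic N_ef = theta / (2 mu tau) with interval propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .diversity import mean_pairwise_differences
from .errors import ParameterError, SampleSizeError, UndefinedStatisticError
from .hapio import BASES, HaplotypeTable, classify_sites


class Boundary:
    """Marker for a statistic pinned at a boundary (e.g. Fs with K = 1)."""

    def __init__(self, statistic: str, side: str):
        self.statistic = statistic
        self.side = side

    def __repr__(self) -> str:
        return f"<{self.statistic} boundary: {self.side}>"


# ---------------------------------------------------------------------------
# Ewens sampling probabilities / Fu's Fs
# ---------------------------------------------------------------------------

def _log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    prev = np.full(n + 1, -np.inf)
    prev[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        cur = np.full(n + 1, -np.inf)
        # |s(m,k)| = |s(m-1,k-1)| + (m-1)|s(m-1,k)|
        cur[1 : m + 1] = prev[0:m]
        with np.errstate(invalid="ignore"):
            grow = np.log(m - 1) + prev if m > 1 else np.full(n + 1, -np.inf)
        cur = np.logaddexp(cur, grow)
        prev = cur
    return prev


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k | theta, n) for k = 0..n under the Ewens sampling distribution."""
    if theta <= 0:
        raise ParameterError("theta must be positive")
    log_s = _log_stirling_first(n)
    k = np.arange(n + 1)
    log_num = log_s + k * math.log(theta)
    log_den = sum(math.log(theta + i) for i in range(n))
    log_p = log_num - log_den
    p = np.exp(log_p)
    p[~np.isfinite(p)] = 0.0
    return p


def fu_fs_from_summaries(n: int, k_obs: int, theta_pi: float) -> float | Boundary:
    """Fu's Fs from sample size, observed haplotype count, and mean pairwise diffs."""
    if n < 2:
        raise SampleSizeError("Fs needs n >= 2")
    if k_obs <= 1 or theta_pi <= 0:
        return Boundary("Fs", "K=1 or theta=0: S' = 1")
    p = ewens_k_distribution(n, theta_pi)
    s_prime = float(p[k_obs:].sum())
    if s_prime >= 1.0:
        return Boundary("Fs", "S' = 1")
    if s_prime <= 0.0:
        return Boundary("Fs", "S' = 0")
    return math.log(s_prime / (1.0 - s_prime))


def fu_fs(ht: HaplotypeTable) -> float | Boundary:
    """Fu's Fs for a sample, with theta estimated by mean pairwise differences."""
    summary = classify_sites(ht)
    if summary.S == 0:
        raise UndefinedStatisticError("Fs undefined with no segregating sites")
    n = ht.n
    theta = mean_pairwise_differences(ht)
    return fu_fs_from_summaries(n, ht.K, theta)


# ---------------------------------------------------------------------------
# Fu & Li D* and F*
# ---------------------------------------------------------------------------

def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n + 1))


def _harmonic2(n: int) -> float:
    return sum(1.0 / i**2 for i in range(1, n + 1))


def _fu_li_coefficients(n: int):
    """Variance coefficients for D* and F* (Simonsen-corrected published forms)."""
    if n < 3:
        raise SampleSizeError("Fu & Li statistics need n >= 3")
    nn = float(n)
    a = _harmonic(n - 1)
    b = _harmonic2(n - 1)
    a1 = _harmonic(n)  # a_{n+1} in the published notation
    c = 2.0 * (nn * a - 2.0 * (nn - 1.0)) / ((nn - 1.0) * (nn - 2.0))
    d = c + (nn - 2.0) / (nn - 1.0) ** 2 + 2.0 / (nn - 1.0) * (
        1.5 - (2.0 * a1 - 3.0) / (nn - 2.0) - 1.0 / nn
    )
    v_d = (
        (nn / (nn - 1.0)) ** 2 * b
        + a**2 * d
        - 2.0 * (nn * a * (a + 1.0)) / (nn - 1.0) ** 2
    ) / (a**2 + b)
    u_d = (nn / (nn - 1.0)) * (a - nn / (nn - 1.0)) - v_d
    v_f = (
        d
        + 2.0 * (nn**2 + nn + 3.0) / (9.0 * nn * (nn - 1.0))
        - 2.0 / (nn - 1.0) * (4.0 * b - 6.0 + 8.0 / nn)
    ) / (a**2 + b)
    u_f = (
        nn / (nn - 1.0)
        + (nn + 1.0) / (3.0 * (nn - 1.0))
        - 4.0 / (nn * (nn - 1.0))
        + 2.0 * (nn + 1.0) / (nn - 1.0) ** 2 * (a1 - 2.0 * nn / (nn + 1.0))
    ) / a - v_f
    return a, u_d, v_d, u_f, v_f


def fu_li_from_summaries(
    n: int, eta: int, eta_s: int, k_bar: float
) -> tuple[float, float]:
    """D* and F* from sample size, mutation counts and mean pairwise differences."""
    if eta < 1:
        raise UndefinedStatisticError("D*/F* undefined with no mutations")
    a, u_d, v_d, u_f, v_f = _fu_li_coefficients(n)
    nn = float(n)
    d_star = (nn / (nn - 1.0) * eta - a * eta_s) / math.sqrt(
        u_d * eta + v_d * eta**2
    )
    f_star = (k_bar - (nn - 1.0) / nn * eta_s) / math.sqrt(u_f * eta + v_f * eta**2)
    return d_star, f_star


def fu_li(ht: HaplotypeTable) -> tuple[float, float]:
    """Fu & Li's outgroup-free D* and F* for a sample."""
    summary = classify_sites(ht)
    return fu_li_from_summaries(
        ht.n, summary.eta, summary.eta_s, mean_pairwise_differences(ht)
    )


# ---------------------------------------------------------------------------
# Ramos-Onsins & Rozas R2
# ---------------------------------------------------------------------------

def r2_from_summaries(u: Sequence[float], k_bar: float, S: int) -> float:
    """R2 = sqrt(mean (U_i - k_bar/2)^2) / S from per-sequence singleton counts."""
    if S < 1:
        raise UndefinedStatisticError("R2 undefined with no segregating sites")
    u = np.asarray(u, dtype=float)
    return float(math.sqrt(np.mean((u - k_bar / 2.0) ** 2)) / S)


def singletons_per_individual(ht: HaplotypeTable) -> np.ndarray:
    """U_i: number of sites at which individual i alone carries its state.

    Count-weighted: a state qualifies when exactly one sampled individual
    carries it, which implies its haplotype has total count 1.
    """
    counts = ht.total_counts()
    n = int(counts.sum())
    seqs = ht.sequences
    u_hap = np.zeros(ht.K)
    for pos in range(ht.L):
        tally: dict[str, int] = {}
        carrier: dict[str, int] = {}
        for h, s in enumerate(seqs):
            c = s[pos]
            if c in BASES:
                tally[c] = tally.get(c, 0) + int(counts[h])
                carrier[c] = h
        if len(tally) < 2:
            continue
        for base, cnt in tally.items():
            if cnt == 1:
                u_hap[carrier[base]] += 1
    # expand to individuals: haplotypes with count != 1 have u_hap == 0
    u = []
    for h, c in enumerate(counts):
        u.extend([u_hap[h]] * int(c))
    assert len(u) == n
    return np.asarray(u)


def ramos_onsins_r2(ht: HaplotypeTable) -> float:
    """Ramos-Onsins & Rozas' R2 for a sample (count-weighted haplotypes)."""
    summary = classify_sites(ht)
    if summary.S == 0:
        raise UndefinedStatisticError("R2 undefined with no segregating sites")
    u = singletons_per_individual(ht)
    k_bar = mean_pairwise_differences(ht)
    return r2_from_summaries(u, k_bar, summary.S)


# ---------------------------------------------------------------------------
# Fixed-S coalescent null distributions
# ---------------------------------------------------------------------------

def _simulate_replicate(n: int, S: int, rng: np.random.Generator):
    """One constant-size coalescent genealogy with S mutations placed on it.

    Returns (mutation_sizes, per-leaf singleton counts U, K, k_bar, eta_s).
    Branch lengths in coalescent units; only relative lengths matter for
    mutation placement under fixed-S conditioning.
    """
    # build genealogy: each active lineage tracked as (leafset bitmask, birth time)
    masks = [1 << i for i in range(n)]
    births = [0.0] * n
    branch_masks: list[int] = []
    branch_lengths: list[float] = []
    t = 0.0
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        for idx in (i, j):
            branch_masks.append(masks[idx])
            branch_lengths.append(t - births[idx])
        merged = masks[i] | masks[j]
        masks[j] = masks[k - 1]
        births[j] = births[k - 1]
        masks[i] = merged
        births[i] = t
        masks.pop()
        births.pop()
        k -= 1
    lengths = np.asarray(branch_lengths)
    muts = rng.multinomial(S, lengths / lengths.sum())
    full = (1 << n) - 1
    sizes = []
    u = np.zeros(n)
    sig: dict[int, list[int]] = {}
    for b, m in enumerate(muts):
        if m == 0:
            continue
        mask = branch_masks[b]
        c = mask.bit_count()
        sizes.extend([c] * m)
        if c == 1:
            u[mask.bit_length() - 1] += m
        if c == n - 1:  # at n = 2 both carriers hold their state alone
            u[(full ^ mask).bit_length() - 1] += m
        for leaf in range(n):
            if mask >> leaf & 1:
                sig.setdefault(leaf, []).append(b)
    signatures = {tuple(sig.get(leaf, ())) for leaf in range(n)}
    K = len(signatures)
    sizes = np.asarray(sizes)
    k_bar = float(np.sum(sizes * (n - sizes))) / (n * (n - 1) / 2.0)
    eta_s = int(np.sum((sizes == 1) | (sizes == n - 1)))
    return sizes, u, K, k_bar, eta_s


_STATISTICS = ("Fs", "D_star", "F_star", "R2")


def simulate_null(
    statistic: str,
    n: int,
    S: int,
    n_sims: int,
    seed: int | None = None,
) -> np.ndarray:
    """Null sample of a neutrality statistic under the fixed-S coalescent.

    Replicates where the statistic sits at a boundary (Fs with K = 1) are
    assigned +inf so they count as extreme in the conservative direction for
    the lower-tail tests.
    """
    if statistic not in _STATISTICS:
        raise ParameterError(f"unknown statistic {statistic!r}")
    return _simulate_all(n, S, n_sims, seed)[statistic]


def _simulate_all(
    n: int, S: int, n_sims: int, seed: int | None = None
) -> dict[str, np.ndarray]:
    if n < 2:
        raise SampleSizeError("coalescent null needs n >= 2")
    if S < 1:
        raise ParameterError("fixed-S conditioning needs S >= 1")
    rng = np.random.default_rng(seed)
    out = {s: np.empty(n_sims) for s in _STATISTICS}
    for r in range(n_sims):
        sizes, u, K, k_bar, eta_s = _simulate_replicate(n, S, rng)
        fs = fu_fs_from_summaries(n, K, k_bar)
        out["Fs"][r] = np.inf if isinstance(fs, Boundary) else fs
        if n >= 3:
            d_star, f_star = fu_li_from_summaries(n, S, eta_s, k_bar)
        else:
            d_star = f_star = np.nan
        out["D_star"][r] = d_star
        out["F_star"][r] = f_star
        out["R2"][r] = r2_from_summaries(u, k_bar, S)
    return out


def coalescent_pvalue(
    statistic: str,
    stat_obs: float,
    n: int,
    S_obs: int,
    n_sims: int = 50000,
    tail: str = "lower",
    seed: int | None = None,
) -> float:
    """p = (#{stat* <= stat_obs} + 1) / (n_sims + 1) for lower-tail statistics.

    ``tail`` may be "lower" (default; the convention for Fs, D*, F* and R2,
    whose departures of interest are negative/small) or "upper".
    """
    if tail not in ("lower", "upper"):
        raise ParameterError(f"tail must be 'lower' or 'upper' (got {tail!r})")
    null = simulate_null(statistic, n, S_obs, n_sims, seed)
    null = null[~np.isnan(null)]
    if tail == "lower":
        hits = int(np.sum(null <= stat_obs + 1e-12))
    else:
        hits = int(np.sum(null >= stat_obs - 1e-12))
    return (hits + 1) / (null.size + 1)


@dataclass
class NeutralitySuite:
    """The four neutrality statistics with coalescent-simulated p-values."""

    Fs: float | Boundary
    D_star: float
    F_star: float
    R2: float
    p_Fs: float
    p_Dstar: float
    p_Fstar: float
    p_R2: float
    n_sims: int
    conditioning: str = "fixed-S"


def neutrality_suite(
    ht: HaplotypeTable,
    n_sims: int = 50000,
    seed: int | None = None,
) -> NeutralitySuite:
    """All four tests for one sample, sharing one batch of null simulations."""
    summary = classify_sites(ht)
    if summary.S == 0:
        raise UndefinedStatisticError("neutrality tests undefined with S = 0")
    n = ht.n
    fs = fu_fs(ht)
    d_star, f_star = fu_li(ht)
    r2 = ramos_onsins_r2(ht)
    nulls = _simulate_all(n, summary.S, n_sims, seed)

    def p_of(name: str, obs: float) -> float:
        null = nulls[name]
        null = null[~np.isnan(null)]
        return (int(np.sum(null <= obs + 1e-12)) + 1) / (null.size + 1)

    p_fs = 1.0 if isinstance(fs, Boundary) else p_of("Fs", fs)
    return NeutralitySuite(
        fs, d_star, f_star, r2,
        p_fs, p_of("D_star", d_star), p_of("F_star", f_star), p_of("R2", r2),
        n_sims,
    )


# ---------------------------------------------------------------------------
# Theta estimators and effective size
# ---------------------------------------------------------------------------

def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's theta per site: S / (a_{n-1} L), a_{n-1} = sum_{i<n} 1/i."""
    if n < 2:
        raise SampleSizeError("Watterson theta needs n >= 2")
    if S == 0:
        return 0.0
    return S / (_harmonic(n - 1) * L)


def tajima_theta(pi: float) -> float:
    """Tajima's theta per site is nucleotide diversity itself."""
    return float(pi)


@dataclass
class EffectiveSizeResult:
    """Long-term effective number of females and total effective size.

    ``n_ef`` is theta / (2 mu tau) with mu in substitutions/site/year and tau
    the generation time in years (so mu*tau is the per-generation rate);
    ``n_e`` doubles it under an assumed long-term 1:1 sex ratio.
    """

    n_ef: float
    n_ef_low: float
    n_ef_high: float
    n_e: float
    theta: float
    theta_interval: tuple[float, float] | None
    mu: float
    mu_interval: tuple[float, float] | None
    tau_range: tuple[float, float]


def effective_size(
    theta: float,
    mu: float,
    tau_range: tuple[float, float],
    theta_interval: tuple[float, float] | None = None,
    mu_interval: tuple[float, float] | None = None,
) -> EffectiveSizeResult:
    """N_ef = theta / (2 mu tau) with worst-case interval propagation.

    The point estimate uses the supplied medians and the midpoint of
    ``tau_range``; the interval combines the extremes that minimize and
    maximize the quotient: [theta_low/(2 mu_high tau_high),
    theta_high/(2 mu_low tau_low)].
    """
    tau_low, tau_high = tau_range
    if theta <= 0 or mu <= 0 or tau_low <= 0 or tau_low > tau_high:
        raise ParameterError("theta, mu and tau must be positive with tau_low <= tau_high")
    tau_mid = (tau_low + tau_high) / 2.0
    point = theta / (2.0 * mu * tau_mid)
    th_lo, th_hi = theta_interval if theta_interval else (theta, theta)
    mu_lo, mu_hi = mu_interval if mu_interval else (mu, mu)
    if th_lo <= 0 or mu_lo <= 0 or th_lo > th_hi or mu_lo > mu_hi:
        raise ParameterError("invalid theta or mu interval")
    low = th_lo / (2.0 * mu_hi * tau_high)
    high = th_hi / (2.0 * mu_lo * tau_low)
    return EffectiveSizeResult(
        point, low, high, 2.0 * point,
        theta, theta_interval, mu, mu_interval, (tau_low, tau_high),
    )
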