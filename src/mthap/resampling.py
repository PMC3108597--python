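"""Randomization chi-square tests, isolation-by-distance, and rarefaction.

Three resampling analyses used to probe haplotype-frequency evenness, the
relationship between genetic and geographic distance, and haplotype richness
standardized to a common sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import skbio

from .errors import DesignError, ParameterError, SampleSizeError


@dataclass
class ChiSqRandResult:
    """Chi-square evenness test with a randomized null distribution."""

    chi2_obs: float
    p: float
    n_replicates: int
    null_model: str
    seed: int | None


def chisq_randomization(
    counts: Sequence[int],
    expected_probs: Sequence[float] | None = None,
    n_rep: int = 10000,
    seed: int | None = None,
    resample_observed: bool = False,
) -> ChiSqRandResult:
    """Randomization chi-square test of haplotype-frequency evenness.

    ``expected_probs`` defines the null frequencies over the observed
    haplotype categories (default: equal, i.e. expected count N/K per
    haplotype).  Replicates of size N are drawn multinomially from the null
    frequencies and chi-square recomputed for each; p is the proportion of
    replicates with chi-square >= observed (with add-one smoothing so
    p >= 1/(n_rep+1)).  ``resample_observed=True`` draws replicates from the
    observed frequencies instead — the literal published recipe, kept for
    comparison; it is not a calibrated null.
    """
    obs = np.asarray(counts, dtype=float)
    N = obs.sum()
    if N < 1:
        raise SampleSizeError("chi-square test needs at least one observation")
    if n_rep < 1:
        raise ParameterError("n_rep must be >= 1")
    k = obs.size
    if expected_probs is None:
        probs = np.full(k, 1.0 / k)
        null_model = "equal"
    else:
        probs = np.asarray(expected_probs, dtype=float)
        if probs.size != k:
            raise ParameterError("expected_probs length must match counts")
        if np.any(probs[obs > 0] <= 0):
            raise ParameterError("null probability 0 for an observed category")
        probs = probs / probs.sum()
        null_model = "supplied-frequencies"
    E = probs * N
    chi2_obs = float(np.sum((obs - E) ** 2 / E))
    rng = np.random.default_rng(seed)
    draw_probs = obs / N if resample_observed else probs
    reps = rng.multinomial(int(N), draw_probs, size=n_rep)
    chi2_rep = ((reps - E) ** 2 / E).sum(axis=1)
    ge = int(np.sum(chi2_rep >= chi2_obs - 1e-12))
    p = (ge + 1) / (n_rep + 1)
    return ChiSqRandResult(chi2_obs, p, n_rep,
                           "resample-observed" if resample_observed else null_model,
                           seed)


@dataclass
class MantelResult:
    """Mantel matrix correlation with reduced-major-axis regression line."""

    r: float
    p: float
    rma_slope: float
    rma_intercept: float
    n_permutations: int


def mantel_test(
    gen,
    geo,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> MantelResult:
    """Mantel test of matrix correlation plus RMA regression of gen on geo.

    ``gen`` and ``geo`` are square symmetric matrices (DataFrames, arrays, or
    the package's DistanceMatrix) over the same units in the same order.  r is
    the Pearson correlation of the off-diagonal upper triangles; the null
    permutes rows/columns of one matrix simultaneously.
    """
    g1 = _as_square(gen)
    g2 = _as_square(geo)
    if g1.shape != g2.shape:
        raise DesignError("matrices differ in size")
    n = g1.shape[0]
    if n < 3:
        raise DesignError("Mantel test needs at least 3 units")
    iu = np.triu_indices(n, k=1)
    x, y = g1[iu], g2[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise DesignError("a matrix is constant: correlation undefined")
    rng = np.random.default_rng(seed)
    r, p, _ = skbio.stats.distance.mantel(
        skbio.DistanceMatrix(g1),
        skbio.DistanceMatrix(g2),
        method="pearson",
        permutations=n_perm,
        alternative=alternative,
        seed=rng,
    )
    slope, intercept = rma_regression(y, x)  # genetic on geographic
    return MantelResult(float(r), float(p), slope, intercept, n_perm)


def _as_square(m) -> np.ndarray:
    if hasattr(m, "d"):  # DistanceMatrix
        m = m.d
    if isinstance(m, pd.DataFrame):
        m = m.to_numpy()
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DesignError("expected a square matrix")
    if not np.allclose(m, m.T):
        raise DesignError("matrix is not symmetric")
    return m


def rma_regression(x, y) -> tuple[float, float]:
    """Reduced major axis regression of y on x.

    slope = sign(r) * sd(y)/sd(x); intercept = mean(y) - slope * mean(x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise DesignError("RMA needs >= 2 paired points")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise DesignError("zero variance in RMA input")
    r = np.corrcoef(x, y)[0, 1]
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def great_circle_km(coords: pd.DataFrame) -> pd.DataFrame:
    """Great-circle distances (km) from per-unit x=longitude, y=latitude degrees."""
    lon = np.radians(coords["x"].to_numpy(dtype=float))
    lat = np.radians(coords["y"].to_numpy(dtype=float))
    n = lon.size
    d = np.zeros((n, n))
    R = 6371.0
    for i in range(n):
        for j in range(i + 1, n):
            h = (
                np.sin((lat[j] - lat[i]) / 2) ** 2
                + np.cos(lat[i]) * np.cos(lat[j]) * np.sin((lon[j] - lon[i]) / 2) ** 2
            )
            d[i, j] = d[j, i] = 2 * R * np.arcsin(np.sqrt(h))
    return pd.DataFrame(d, index=coords.index, columns=coords.index)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

@dataclass
class AccumulationCurve:
    """Sample-based accumulation of haplotype richness."""

    levels: np.ndarray  # cumulative sample counts
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_randomizations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": self.levels, "mean_richness": self.mean_richness,
             "sd_richness": self.sd_richness}
        )


def accumulation_curve(
    pool: Sequence,
    step: int = 10,
    events: int = 7,
    n_rand: int = 1000,
    seed: int | None = None,
) -> AccumulationCurve:
    """Mean and SD of distinct-haplotype counts at cumulative sample sizes.

    ``pool`` is the multiset of individual haplotype labels.  For each of
    ``n_rand`` random orderings of the pool (sampling without replacement) the
    number of distinct labels among the first step, 2*step, ... individuals is
    recorded.  Levels beyond the pool size are truncated with a warning.
    """
    if step < 1:
        raise ParameterError("step must be >= 1")
    labels = np.asarray(pool)
    N = labels.size
    if N == 0:
        raise SampleSizeError("empty pool")
    levels = np.array([step * t for t in range(1, events + 1)])
    if levels[-1] > N:
        import warnings

        warnings.warn(
            f"pool of {N} cannot support {events} events of {step}; truncating"
        )
        levels = levels[levels <= N]
        if levels.size == 0:
            levels = np.array([N])
    # map labels to integers for speed
    _, coded = np.unique(labels, return_inverse=True)
    rng = np.random.default_rng(seed)
    rich = np.empty((n_rand, levels.size))
    for r in range(n_rand):
        order = rng.permutation(coded)
        seen = np.zeros(coded.max() + 1, dtype=bool)
        count = 0
        pos = 0
        for li, lev in enumerate(levels):
            for idx in order[pos:lev]:
                if not seen[idx]:
                    seen[idx] = True
                    count += 1
            pos = lev
            rich[r, li] = count
    return AccumulationCurve(levels, rich.mean(axis=0), rich.std(axis=0, ddof=0), n_rand)


def hypergeometric_rarefaction(counts: Sequence[int], g: int) -> float:
    """Closed-form expected richness in a draw of g individuals without replacement.

    E[K_g] = sum_h [1 - C(N - c_h, g) / C(N, g)].
    """
    c = np.asarray(counts, dtype=int)
    N = int(c.sum())
    if g > N:
        raise ParameterError("subsample larger than pool")
    from scipy.special import gammaln

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = 0.0
    for ch in c:
        if N - ch < g:
            out += 1.0
        else:
            out += 1.0 - np.exp(log_choose(N - ch, g) - log_choose(N, g))
    return float(out)


@dataclass
class RarefactionResult:
    """Paired comparison of rarefied haplotype richness between two pools."""

    richness_a: np.ndarray
    richness_b: np.ndarray
    t: float
    df: int
    p: float
    n_replicates: int
    k: int


def richness_paired_test(
    pool_a: Sequence,
    pool_b: Sequence,
    k: int = 10,
    n_rep: int = 20,
    seed: int | None = None,
) -> RarefactionResult:
    """Paired t-test of rarefied richness between two pools of haplotype labels.

    Each of ``n_rep`` replicates draws ``k`` individuals without replacement
    (independently) from each pool and counts distinct haplotypes; a two-
    tailed paired t-test on the per-replicate (A, B) richness pairs follows,
    with df = n_rep - 1.
    """
    a = np.asarray(pool_a)
    b = np.asarray(pool_b)
    if a.size < k or b.size < k:
        raise SampleSizeError(f"both pools must hold at least k={k} individuals")
    if n_rep < 2:
        raise ParameterError("n_rep must be >= 2")
    root = np.random.default_rng(seed)
    rich_a = np.empty(n_rep)
    rich_b = np.empty(n_rep)
    for r in range(n_rep):
        # independent streams per replicate, salted by the replicate index
        sa = np.random.default_rng(root.integers(2**31 - 1))
        sb = np.random.default_rng(root.integers(2**31 - 1))
        rich_a[r] = np.unique(sa.choice(a, size=k, replace=False)).size
        rich_b[r] = np.unique(sb.choice(b, size=k, replace=False)).size
    if np.allclose(rich_a - rich_b, (rich_a - rich_b)[0]) and np.std(rich_a - rich_b) == 0:
        diff = rich_a - rich_b
        if diff[0] == 0:
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(diff[0]), 0.0
    else:
        t, p = sps.ttest_rel(rich_a, rich_b)
    return RarefactionResult(rich_a, rich_b, float(t), n_rep - 1, float(p), n_rep, k)


def pool_from_table(ht, populations: Sequence[str]) -> np.ndarray:
    """Individual-level haplotype labels pooled over the named populations."""
    labels = []
    for pop in populations:
        cts = ht.population_counts(pop)
        for hid, c in zip(ht.ids, cts):
            labels.extend([hid] * int(c))
    return np.asarray(labels)
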