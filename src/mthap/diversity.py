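"""Diversity indices and model-corrected pairwise distances.

Implements Nei's unbiased haplotype (gene) diversity

    h = n (1 - sum p_i^2) / (n - 1),

nucleotide diversity pi (mean per-site pairwise difference, with pairwise
deletion of missing/indel positions), and the Tamura-Nei (1993) two-
transition-class distance correction used for the AMOVA distance kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SampleSizeError, SaturationError, DesignError
from .hapio import BASES, GAP, IUPAC, HaplotypeTable

PURINES = ("A", "G")
PYRIMIDINES = ("C", "T")


@dataclass
class DiversityIndices:
    """Per-sample diversity summary: h, pi (per site), S segregating sites, n."""

    h: float
    pi: float
    S: int
    n: int


def haplotype_diversity(counts: Iterable[int]) -> float:
    """Nei's unbiased gene diversity from per-haplotype counts.

    Equals n/(n-1) times the probability that two individuals drawn at random
    (with replacement) carry different haplotypes; equivalently the probability
    for a draw without replacement.
    """
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise SampleSizeError(f"haplotype diversity needs n >= 2 (got n={int(n)})")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def _pair_diff(seq_a: str, seq_b: str, per_site: bool = True) -> float:
    """Observed differences between two sequences with pairwise deletion.

    Positions where either sequence has a gap or an ambiguity code are skipped.
    Returns differences per compared site (or the raw count).
    """
    diff = 0
    compared = 0
    for a, b in zip(seq_a, seq_b):
        if a in BASES and b in BASES:
            compared += 1
            if a != b:
                diff += 1
    if compared == 0:
        raise SaturationError("no shared unambiguous sites between sequences")
    return diff / compared if per_site else float(diff)


def nucleotide_diversity(ht: HaplotypeTable, model: str = "p-distance") -> float:
    """Mean pairwise difference per site over all unordered individual pairs.

    ``model`` may be ``"p-distance"`` (uncorrected, the conventional Nei pi)
    or ``"TN93"`` for the Tamura-Nei corrected variant.
    """
    counts = ht.total_counts()
    n = int(counts.sum())
    if n < 2:
        raise SampleSizeError(f"nucleotide diversity needs n >= 2 (got n={n})")
    seqs = ht.sequences
    total = 0.0
    npairs = n * (n - 1) / 2
    for i in range(ht.K):
        for j in range(i, ht.K):
            if i == j:
                w = counts[i] * (counts[i] - 1) / 2
                d = 0.0
            else:
                w = counts[i] * counts[j]
                d = (
                    tn93_distance(seqs[i], seqs[j])
                    if model == "TN93"
                    else _pair_diff(seqs[i], seqs[j])
                )
            total += w * d
    return float(total / npairs)


def mean_pairwise_differences(ht: HaplotypeTable) -> float:
    """Mean number of raw pairwise differences k-bar (not per site)."""
    counts = ht.total_counts()
    n = int(counts.sum())
    if n < 2:
        raise SampleSizeError(f"mean pairwise differences need n >= 2 (got n={n})")
    seqs = ht.sequences
    total = 0.0
    for i in range(ht.K):
        for j in range(i + 1, ht.K):
            total += counts[i] * counts[j] * _pair_diff(seqs[i], seqs[j], per_site=False)
    return float(total / (n * (n - 1) / 2))


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected proportion of differing sites (pairwise deletion)."""
    return _pair_diff(seq_a, seq_b)


def tn93_distance(
    seq_a: str,
    seq_b: str,
    base_freqs: Sequence[float] | None = None,
) -> float:
    """Tamura-Nei (1993) distance between two aligned sequences.

    Distinguishes the two transition classes (A<->G within purines, C<->T
    within pyrimidines) from transversions and corrects for unequal base
    frequencies.  Frequencies default to the empirical frequencies of the
    pair (averaged); pass ``base_freqs`` (order A, C, G, T) to override.
    Raises :class:`SaturationError` when a logarithm argument is non-positive.
    """
    pairs = [
        (a, b)
        for a, b in zip(seq_a, seq_b)
        if a in BASES and b in BASES
    ]
    if not pairs:
        raise SaturationError("no shared unambiguous sites between sequences")
    m = len(pairs)
    # observed proportions
    P1 = sum(1 for a, b in pairs if a != b and {a, b} == {"A", "G"}) / m
    P2 = sum(1 for a, b in pairs if a != b and {a, b} == {"C", "T"}) / m
    Q = sum(1 for a, b in pairs if a != b and ((a in PURINES) != (b in PURINES))) / m
    if P1 == P2 == Q == 0.0:
        return 0.0
    if base_freqs is None:
        tally = {b: 0 for b in BASES}
        for a, b in pairs:
            tally[a] += 1
            tally[b] += 1
        tot = 2 * m
        gA, gC, gG, gT = (tally[b] / tot for b in BASES)
    else:
        gA, gC, gG, gT = (float(f) for f in base_freqs)
        s = gA + gC + gG + gT
        gA, gC, gG, gT = gA / s, gC / s, gG / s, gT / s
    gR = gA + gG
    gY = gC + gT
    if min(gR, gY) <= 0 or (gA * gG == 0 and P1 > 0) or (gC * gT == 0 and P2 > 0):
        raise SaturationError("degenerate base frequencies for TN93")
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR) if k1 > 0 else 1.0
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY) if k2 > 0 else 1.0
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError(
            f"TN93 saturation between sequences (P1={P1:.4f}, P2={P2:.4f}, Q={Q:.4f})"
        )
    d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    return max(d, 0.0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix (substitutions/site) with labels."""

    labels: list[str]
    d: np.ndarray
    model: str

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise DesignError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise DesignError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DesignError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise DesignError("distance matrix has non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab[:10].ljust(10) + " ".join(f"{v:.6f}" for v in row) + "\n")


def distance_matrix(
    ht: HaplotypeTable,
    model: str = "TN93",
    base_freqs: Sequence[float] | None = None,
) -> DistanceMatrix:
    """Full pairwise distance matrix between haplotypes (label order = table order)."""
    if ht.K < 2:
        raise DesignError("distance matrix needs at least 2 haplotypes")
    if model not in ("TN93", "p-distance"):
        raise ValueError(f"unknown model {model!r}")
    seqs = ht.sequences
    d = np.zeros((ht.K, ht.K))
    for i in range(ht.K):
        for j in range(i + 1, ht.K):
            if model == "TN93":
                d[i, j] = tn93_distance(seqs[i], seqs[j], base_freqs)
            else:
                d[i, j] = p_distance(seqs[i], seqs[j])
            d[j, i] = d[i, j]
    return DistanceMatrix(list(ht.ids), d, model)


def diversity_indices(ht: HaplotypeTable, model: str = "p-distance") -> DiversityIndices:
    """h, pi and S for one sample (typically one population's sub-table)."""
    from .hapio import classify_sites

    counts = ht.total_counts()
    summary = classify_sites(ht)
    return DiversityIndices(
        h=haplotype_diversity(counts),
        pi=nucleotide_diversity(ht, model=model),
        S=summary.S,
        n=int(counts.sum()),
    )
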