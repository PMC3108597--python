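"""Data model, alignment IO, haplotype collapsing and polymorphic-site classification.

The universal input is an :class:`AlignedDataset`: one aligned sequence per
sampled individual plus a population label and an optional social-group label.
Collapsing identical sequences yields a :class:`HaplotypeTable`, the basis of
every downstream statistic, and :func:`classify_sites` tallies segregating
sites, transition/transversion changes, singletons and parsimony-informative
sites the way sequence-polymorphism desk tools report them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    CollapsingError,
    InputError,
    MetadataError,
)

#: IUPAC nucleotide ambiguity codes mapped to the sets of bases they stand for.
IUPAC = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
GAP = "-"
BASES = ("A", "C", "G", "T")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

#: Group label used when a sample carries no social-group information.
NO_GROUP = "-"


@dataclass(frozen=True)
class SampleRecord:
    """One sampled individual: id, population, optional social group, aligned sequence."""

    sample_id: str
    population: str
    group: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set(IUPAC) - {GAP}
        if bad:
            raise AlignmentError(
                f"sample {self.sample_id!r}: illegal characters {sorted(bad)}"
            )


class AlignedDataset:
    """A same-length alignment of sampled individuals with population/group labels."""

    def __init__(self, records: Sequence[SampleRecord]):
        records = list(records)
        if not records:
            raise InputError("dataset has no records")
        L = len(records[0].sequence)
        for r in records:
            if len(r.sequence) != L:
                raise AlignmentError(
                    f"sample {r.sample_id!r} has length {len(r.sequence)}, expected {L}"
                )
        ids = [r.sample_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate sample ids: {dupes}")
        self.records: list[SampleRecord] = records
        self.L: int = L

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-occurrence order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.population, None)
        return list(seen)

    @property
    def groups_by_population(self) -> dict[str, list[str]]:
        out: dict[str, dict[str, None]] = {}
        for r in self.records:
            out.setdefault(r.population, {}).setdefault(r.group, None)
        return {p: list(g) for p, g in out.items()}

    def subset(self, keep) -> "AlignedDataset":
        """New dataset with the records for which ``keep(record)`` is true."""
        return AlignedDataset([r for r in self.records if keep(r)])

    def __eq__(self, other) -> bool:
        return isinstance(other, AlignedDataset) and self.records == other.records

    def __repr__(self) -> str:
        return f"AlignedDataset(n={self.n}, L={self.L}, populations={len(self.populations)})"


@dataclass
class HaplotypeTable:
    """Distinct sequences with per-(population, group) counts.

    ``counts`` is a DataFrame indexed by haplotype id with a (population, group)
    column MultiIndex; ``assignments`` maps each input record (by position) to
    its haplotype index.
    """

    haplotypes: list[tuple[str, str]]
    counts: pd.DataFrame
    assignments: list[int]
    L: int

    @property
    def K(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.haplotypes]

    @property
    def ids(self) -> list[str]:
        return [h for h, _ in self.haplotypes]

    def total_counts(self) -> np.ndarray:
        """Per-haplotype counts summed over all populations and groups."""
        return self.counts.to_numpy().sum(axis=1).astype(int)

    def population_counts(self, population: str) -> np.ndarray:
        sub = self.counts.loc[:, self.counts.columns.get_level_values(0) == population]
        return sub.to_numpy().sum(axis=1).astype(int)

    def restrict(self, populations: Iterable[str]) -> "HaplotypeTable":
        """Table restricted to the named populations, dropping empty haplotypes."""
        keep = set(populations)
        cols = [c for c in self.counts.columns if c[0] in keep]
        counts = self.counts.loc[:, cols]
        nonzero = counts.to_numpy().sum(axis=1) > 0
        counts = counts.loc[nonzero]
        haps = [h for h, keep_h in zip(self.haplotypes, nonzero) if keep_h]
        old_to_new = {}
        j = 0
        for i, keep_h in enumerate(nonzero):
            if keep_h:
                old_to_new[i] = j
                j += 1
        assignments = [old_to_new[a] for a in self.assignments if a in old_to_new]
        return HaplotypeTable(haps, counts, assignments, self.L)


def _states_compatible(a: str, b: str) -> bool:
    if a == b:
        return True
    if a == GAP or b == GAP:
        return False
    return bool(IUPAC[a] & IUPAC[b])


def _merge_states(a: str, b: str) -> str:
    """The more specific of two compatible states (smaller IUPAC set wins)."""
    if a == b or a == GAP:
        return a
    if len(IUPAC[a]) <= len(IUPAC[b]):
        return a
    return b


def collapse_haplotypes(ds: AlignedDataset, missing_policy: str = "strict") -> HaplotypeTable:
    """Group identical sequences into haplotypes.

    missing_policy
        ``"strict"`` (default): sequences must match character-for-character, so
        an N or ambiguity code only matches itself.  ``"merge-compatible"``:
        a sequence joins the first existing haplotype whose states are IUPAC-
        compatible at every site; the representative sequence keeps the more
        specific state at each position.

    Haplotype ids are assigned in first-occurrence order (h1, h2, ...).
    """
    if missing_policy not in ("strict", "merge-compatible"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    for r in ds.records:
        if all(c == GAP or (c in IUPAC and len(IUPAC[c]) == 4) for c in r.sequence):
            raise CollapsingError(
                f"sample {r.sample_id!r} is entirely ambiguous/missing; cannot assign a haplotype"
            )

    reps: list[str] = []  # representative sequence per haplotype
    assignments: list[int] = []
    for r in ds.records:
        hit = None
        if missing_policy == "strict":
            try:
                hit = reps.index(r.sequence)
            except ValueError:
                hit = None
        else:
            for i, rep in enumerate(reps):
                if all(_states_compatible(a, b) for a, b in zip(rep, r.sequence)):
                    hit = i
                    reps[i] = "".join(
                        _merge_states(a, b) for a, b in zip(rep, r.sequence)
                    )
                    break
        if hit is None:
            reps.append(r.sequence)
            hit = len(reps) - 1
        assignments.append(hit)

    ids = [f"h{i + 1}" for i in range(len(reps))]
    cols: dict[str, None] = {}
    for r in ds.records:
        cols.setdefault((r.population, r.group), None)
    columns = pd.MultiIndex.from_tuples(list(cols), names=["population", "group"])
    mat = np.zeros((len(reps), len(columns)), dtype=int)
    col_idx = {c: j for j, c in enumerate(cols)}
    for r, a in zip(ds.records, assignments):
        mat[a, col_idx[(r.population, r.group)]] += 1
    counts = pd.DataFrame(mat, index=pd.Index(ids, name="haplotype_id"), columns=columns)
    return HaplotypeTable(list(zip(ids, reps)), counts, assignments, ds.L)


def expand_to_records(ht: HaplotypeTable) -> AlignedDataset:
    """Inverse of collapsing: one synthetic record per counted individual."""
    records = []
    i = 0
    for (hid, seq), row in zip(ht.haplotypes, ht.counts.to_numpy()):
        for (pop, group), c in zip(ht.counts.columns, row):
            for _ in range(int(c)):
                i += 1
                records.append(SampleRecord(f"{hid}_ind{i}", pop, group, seq))
    return AlignedDataset(records)


# ---------------------------------------------------------------------------
# Polymorphic-site classification
# ---------------------------------------------------------------------------

@dataclass
class SiteRecord:
    """Classification of one alignment column (1-based position in reports)."""

    position: int  # 0-based internally
    states: dict[str, int]  # unambiguous base -> weighted count
    segregating: bool
    indel: bool
    n_transitions: int
    n_transversions: int
    parsimony_informative: bool
    singletons: int


@dataclass
class SiteSummary:
    """Alignment-wide polymorphism tallies."""

    S: int
    eta: int
    eta_s: int
    n_transitions: int
    n_transversions: int
    n_indel_sites: int
    parsimony_informative: int
    sites: list[SiteRecord] = field(repr=False, default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": s.position + 1,  # 1-based for reports
                "states": "/".join(f"{b}:{c}" for b, c in sorted(s.states.items())),
                "segregating": s.segregating,
                "indel": s.indel,
                "transitions": s.n_transitions,
                "transversions": s.n_transversions,
                "parsimony_informative": s.parsimony_informative,
                "singletons": s.singletons,
            }
            for s in self.sites
            if s.segregating or s.indel
        ]
        return pd.DataFrame(rows)


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def classify_sites(ht: HaplotypeTable, weighted: bool = True) -> SiteSummary:
    """Tally polymorphic sites over the haplotypes of ``ht``.

    With ``weighted=True`` (default) each haplotype contributes its sample
    count to the per-state tallies, so singletons and parsimony-informative
    sites are judged over individuals; with ``weighted=False`` each distinct
    haplotype counts once.

    Columns containing a gap in any sequence are flagged indel sites and are
    excluded from the segregating-site and transition/transversion tallies.
    Ambiguity codes (including N) are treated as missing at that site.  A site
    with k (>1) observed bases contributes k-1 mutations to eta; each
    non-majority base is classed transition/transversion against the majority
    base.
    """
    weights = ht.total_counts() if weighted else np.ones(ht.K, dtype=int)
    seqs = ht.sequences
    S = eta = eta_s = n_ts = n_tv = n_indel = n_pi = 0
    sites: list[SiteRecord] = []
    for pos in range(ht.L):
        column = [s[pos] for s in seqs]
        indel = any(c == GAP for c in column)
        states: dict[str, int] = {}
        if not indel:
            for c, w in zip(column, weights):
                if c in BASES:
                    states[c] = states.get(c, 0) + int(w)
        seg = len(states) > 1
        ts = tv = single = 0
        pi_site = False
        if indel:
            n_indel += 1
        elif seg:
            S += 1
            eta += len(states) - 1
            major = max(states, key=lambda b: (states[b], b))
            for b, c in states.items():
                if b != major:
                    if _is_transition(b, major):
                        ts += 1
                    else:
                        tv += 1
                if c == 1 and len(states) > 1:
                    single += 1
            # a site can have at most one singleton *mutation* when biallelic
            # with counts (1, n-1); with counts (1, 1) both states are rare but
            # only one mutation happened: cap singletons at eta for the site
            single = min(single, len(states) - 1)
            pi_site = sum(1 for c in states.values() if c >= 2) >= 2
            n_ts += ts
            n_tv += tv
            eta_s += single
            if pi_site:
                n_pi += 1
        sites.append(
            SiteRecord(pos, states, seg, indel, ts, tv, pi_site, single)
        )
    return SiteSummary(S, eta, eta_s, n_ts, n_tv, n_indel, n_pi, sites)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("sample_id", "population", "group", "x", "y")


def read_alignment(fasta_path, metadata_path) -> AlignedDataset:
    """Read an aligned FASTA plus a sample-metadata TSV.

    The TSV must have a header with at least ``sample_id`` and ``population``;
    ``group``, ``x`` and ``y`` (site coordinates, decimal degrees) are optional.
    Record order follows the FASTA file.
    """
    fasta_path = Path(fasta_path)
    metadata_path = Path(metadata_path)
    try:
        seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    except FileNotFoundError:
        raise InputError(f"FASTA file not found: {fasta_path}")
    if not seqs:
        raise InputError(f"no FASTA records in {fasta_path}")
    try:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    except FileNotFoundError:
        raise InputError(f"metadata file not found: {metadata_path}")
    if meta.empty:
        raise InputError(f"no rows in metadata {metadata_path}")
    for col in ("sample_id", "population"):
        if col not in meta.columns:
            raise MetadataError(f"metadata lacks required column {col!r}")
    meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        raise MetadataError("metadata has duplicate sample_id rows")
    records = []
    for rec in seqs:
        if rec.id not in meta.index:
            raise MetadataError(f"FASTA id {rec.id!r} missing from metadata")
        row = meta.loc[rec.id]
        group = row.get("group")
        if group is None or pd.isna(group):
            group = NO_GROUP
        records.append(
            SampleRecord(rec.id, str(row["population"]), str(group), str(rec.seq))
        )
    return AlignedDataset(records)


def read_coordinates(metadata_path) -> pd.DataFrame:
    """Per-population mean x/y coordinates from the metadata TSV (if present)."""
    meta = pd.read_csv(metadata_path, sep="\t")
    if "x" not in meta.columns or "y" not in meta.columns:
        raise MetadataError("metadata has no x/y coordinate columns")
    return meta.groupby("population")[["x", "y"]].mean()


def write_alignment(ds: AlignedDataset, fasta_path, metadata_path) -> None:
    """Write the dataset back out as FASTA + metadata TSV (round-trip safe)."""
    recs = [
        SeqRecord(Seq(r.sequence), id=r.sample_id, description="")
        for r in ds.records
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    rows = [
        {"sample_id": r.sample_id, "population": r.population, "group": r.group}
        for r in ds.records
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def write_haplotype_table(ht: HaplotypeTable, path) -> None:
    """Long-format TSV: haplotype_id, sequence, population, group, count."""
    rows = []
    for (hid, seq), row in zip(ht.haplotypes, ht.counts.to_numpy()):
        for (pop, group), c in zip(ht.counts.columns, row):
            if c > 0:
                rows.append(
                    {
                        "haplotype_id": hid,
                        "sequence": seq,
                        "population": pop,
                        "group": group,
                        "count": int(c),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_site_summary(summary: SiteSummary, path) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False)
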