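"""Coalescent metapopulation simulator for single-locus mtDNA-like data.

Generates aligned haploid sequences with the statistical structure the
analysis modules assume: K demes of effective female size N_f exchanging
female migrants under an island model (or splitting from a common ancestor in
star or stepwise histories), sequences evolving under HKY with a fixed
invariant-site mask and a strong transition bias, and samples subdivided
into labeled social groups within demes.

Ancestry and mutations come from msprime (haploid samples; pairwise
coalescence time N_f generations, so theta per site = 2 N_f mu per
generation, the mtDNA convention).  The defaults mirror a 366-bp
hypervariable control-region fragment: base frequencies A=0.3721, C=0.2469,
G=0.1286, T=0.2524, transition/transversion ratio R=33, proportion of
invariant sites 0.9017, substitution rate 3.7e-8/site/year, generation time
17.5 years.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np

from .errors import ConfigError
from .hapio import AlignedDataset, SampleRecord, NO_GROUP

DEFAULT_BASE_FREQS = (0.3721, 0.2469, 0.1286, 0.2524)  # A, C, G, T
DEFAULT_TSTV_RATIO = 33.0
DEFAULT_P_INVARIANT = 0.9017
DEFAULT_MU_PER_YEAR = 3.7e-8
DEFAULT_TAU_YEARS = 17.5
DEFAULT_L = 366

#: per-population sample sizes of a Table-1-like study design (n = 152)
STUDY_SAMPLE_SIZES = (23, 2, 17, 32, 1, 64, 11, 2)


def kappa_from_tstv(ratio: float, base_freqs=DEFAULT_BASE_FREQS) -> float:
    """HKY kappa implied by an expected transition/transversion ratio R.

    Under HKY the expected ts/tv ratio at equilibrium is

        R = kappa * (gA*gG + gC*gT) / (gR*gY)

    with gR = gA+gG, gY = gC+gT, so kappa = R * gR*gY / (gA*gG + gC*gT).
    """
    gA, gC, gG, gT = base_freqs
    gR, gY = gA + gG, gC + gT
    return ratio * gR * gY / (gA * gG + gC * gT)


@dataclass
class SimulationConfig:
    """Parameters of one metapopulation simulation.

    ``migration`` is the scaled symmetric per-deme migration rate (fraction of
    a deme replaced by migrants per generation); ``split_time`` (generations,
    optional) replaces ongoing migration with a divergence history: "star"
    splits all demes from the ancestor at once, "stepwise" peels them off one
    at a time at equal intervals ending at ``split_time``.
    """

    n_demes: int = 1
    deme_female_sizes: tuple[float, ...] | float = 13900.0
    samples_per_deme: tuple[int, ...] | int = 20
    groups_per_deme: int = 1
    migration: float = 0.0
    split_time: float | None = None
    history: str = "island"  # island | star | stepwise
    growth_rate: float = 0.0  # per-generation exponential growth (forward)
    L: int = DEFAULT_L
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    tstv_ratio: float = DEFAULT_TSTV_RATIO
    p_invariant: float = DEFAULT_P_INVARIANT
    mu_per_year: float = DEFAULT_MU_PER_YEAR
    tau_years: float = DEFAULT_TAU_YEARS
    group_mode: str = "random"  # random | founder
    seed: int | None = None

    def __post_init__(self):
        if isinstance(self.deme_female_sizes, (int, float)):
            self.deme_female_sizes = (float(self.deme_female_sizes),) * self.n_demes
        else:
            self.deme_female_sizes = tuple(float(x) for x in self.deme_female_sizes)
        if isinstance(self.samples_per_deme, int):
            self.samples_per_deme = (self.samples_per_deme,) * self.n_demes
        else:
            self.samples_per_deme = tuple(int(x) for x in self.samples_per_deme)
        if len(self.deme_female_sizes) != self.n_demes:
            raise ConfigError("deme_female_sizes length must equal n_demes")
        if len(self.samples_per_deme) != self.n_demes:
            raise ConfigError("samples_per_deme length must equal n_demes")
        if sum(self.samples_per_deme) == 0:
            raise ConfigError("no samples in any deme")
        if any(s < 0 for s in self.samples_per_deme):
            raise ConfigError("negative sample size")
        if any(x <= 0 for x in self.deme_female_sizes):
            raise ConfigError("deme sizes must be positive")
        if self.migration < 0:
            raise ConfigError("migration must be >= 0")
        if abs(sum(self.base_freqs) - 1.0) > 1e-6:
            raise ConfigError("base frequencies must sum to 1")
        if not (0.0 <= self.p_invariant < 1.0):
            raise ConfigError("p_invariant must lie in [0, 1)")
        if self.history not in ("island", "star", "stepwise"):
            raise ConfigError(f"unknown history {self.history!r}")
        if self.history == "island" and self.n_demes > 1 and self.migration == 0:
            raise ConfigError(
                "island model with several demes and zero migration never coalesces; "
                "set migration > 0 or a split history"
            )
        if self.history in ("star", "stepwise") and self.split_time is None:
            raise ConfigError("split histories need split_time")

    @property
    def mu_per_generation(self) -> float:
        return self.mu_per_year * self.tau_years

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("deme_female_sizes", "samples_per_deme", "base_freqs"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthRecord:
    """Ground truth of one simulation for parameter-recovery tests."""

    theta_per_site: tuple[float, ...]  # 2 N_f mu per site per generation, per deme
    migration: float
    history: str
    split_time: float | None
    tmrca_per_deme: dict[str, float]
    tmrca_total: float
    n_invariant_masked: int
    seed: int | None


def _demography(cfg: SimulationConfig) -> msprime.Demography:
    demo = msprime.Demography()
    for i, size in enumerate(cfg.deme_female_sizes):
        demo.add_population(
            name=f"pop{i}", initial_size=size, growth_rate=cfg.growth_rate
        )
    if cfg.n_demes == 1:
        return demo
    if cfg.history == "island":
        demo.set_symmetric_migration_rate(
            [f"pop{i}" for i in range(cfg.n_demes)], cfg.migration
        )
    else:
        demo.add_population(
            name="ancestral", initial_size=float(np.mean(cfg.deme_female_sizes))
        )
        if cfg.history == "star":
            demo.add_population_split(
                time=cfg.split_time,
                derived=[f"pop{i}" for i in range(cfg.n_demes)],
                ancestral="ancestral",
            )
        else:  # stepwise: peel demes off one at a time, oldest last
            times = np.linspace(
                cfg.split_time / cfg.n_demes, cfg.split_time, cfg.n_demes - 1
            )
            for j, t in enumerate(times):
                # popN-1 merges into popN-2 first, ... finally pop1 joins pop0's
                # lineage which becomes the ancestral population
                src = cfg.n_demes - 1 - j
                dst = src - 1
                demo.add_mass_migration(
                    time=float(t), source=f"pop{src}", dest=f"pop{dst}", proportion=1.0
                )
        if cfg.migration:
            demo.set_symmetric_migration_rate(
                [f"pop{i}" for i in range(cfg.n_demes)], cfg.migration
            )
    demo.sort_events()
    return demo


def simulate_metapopulation(cfg: SimulationConfig) -> tuple[AlignedDataset, TruthRecord]:
    """Simulate one aligned dataset plus its ground truth.

    Fully deterministic given ``cfg`` (including ``cfg.seed``).
    """
    rng = np.random.default_rng(cfg.seed)
    anc_seed, mut_seed = (int(s) for s in rng.integers(1, 2**31 - 1, size=2))
    demo = _demography(cfg)
    samples = [
        msprime.SampleSet(s, population=f"pop{i}", ploidy=1)
        for i, s in enumerate(cfg.samples_per_deme)
        if s > 0
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demo,
        ploidy=1,
        sequence_length=cfg.L,
        discrete_genome=True,
        random_seed=anc_seed,
    )
    # fixed invariant-site mask: mutation rate zero at masked positions
    n_mask = int(np.floor(cfg.p_invariant * cfg.L))
    masked = rng.choice(cfg.L, size=n_mask, replace=False)
    model = msprime.HKY(
        kappa=kappa_from_tstv(cfg.tstv_ratio, cfg.base_freqs),
        equilibrium_frequencies=list(cfg.base_freqs),
    )
    # msprime's matrix models count silent events (state -> same state) in the
    # event rate; rescale so the realized substitution rate equals mu at
    # equilibrium base composition
    pi = np.asarray(cfg.base_freqs)
    silent = float(np.sum(pi * np.diag(model.transition_matrix)))
    event_rate = cfg.mu_per_generation / (1.0 - silent)
    # mu is the sequence-wide average rate (the "+I" convention): the masked
    # sites carry none of it, so the variable fraction carries it all
    concentration = 1.0 / (1.0 - n_mask / cfg.L) if n_mask < cfg.L else 0.0
    rates = np.full(cfg.L, event_rate * concentration)
    rates[masked] = 0.0
    rate_map = msprime.RateMap(position=np.arange(cfg.L + 1, dtype=float), rate=rates)
    mts = msprime.sim_mutations(ts, rate=rate_map, model=model, random_seed=mut_seed)

    # ancestral sequence from the equilibrium frequencies, then apply variants
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=cfg.L, p=cfg.base_freqs)
    n_total = sum(cfg.samples_per_deme)
    aln = np.tile(seq, (n_total, 1))
    for var in mts.variants():
        pos = int(var.site.position)
        alleles = np.array(var.alleles, dtype="U1")
        aln[:, pos] = alleles[var.genotypes]

    # sample bookkeeping: map tree-sequence sample nodes to demes
    node_pop = [mts.node(u).population for u in mts.samples()]
    pop_names = {p.id: p.metadata.get("name", f"pop{p.id}") for p in mts.populations()}
    records = []
    per_deme_nodes: dict[str, list[int]] = {}
    for row, u in enumerate(mts.samples()):
        per_deme_nodes.setdefault(pop_names[node_pop[row]], []).append(row)
    # group labels within demes
    group_of: dict[int, str] = {}
    for deme, rows in per_deme_nodes.items():
        g = cfg.groups_per_deme
        if g <= 1:
            for r in rows:
                group_of[r] = NO_GROUP
            continue
        if cfg.group_mode == "founder":
            # one group seeded from a single matriline: all copies of the
            # modal haplotype in the deme form group 1
            seqs_here = ["".join(aln[r]) for r in rows]
            uniq, counts = np.unique(seqs_here, return_counts=True)
            modal = uniq[np.argmax(counts)]
            founders = [r for r, s in zip(rows, seqs_here) if s == modal]
            others = [r for r in rows if r not in founders]
            for r in founders:
                group_of[r] = "g1"
            labels = rng.integers(2, g + 1, size=len(others))
            for r, lab in zip(others, labels):
                group_of[r] = f"g{lab}"
        else:
            labels = rng.integers(1, g + 1, size=len(rows))
            for r, lab in zip(rows, labels):
                group_of[r] = f"g{lab}"
    for row in range(n_total):
        deme = pop_names[node_pop[row]]
        records.append(
            SampleRecord(
                f"ind{row + 1}", deme, group_of.get(row, NO_GROUP), "".join(aln[row])
            )
        )
    ds = AlignedDataset(records)

    tmrca_per_deme = {}
    tree = mts.first()
    for deme, rows in per_deme_nodes.items():
        nodes = [list(mts.samples())[r] for r in rows]
        if len(nodes) >= 2:
            tmrca_per_deme[deme] = float(tree.tmrca(*nodes))
    truth = TruthRecord(
        theta_per_site=tuple(
            2.0 * Nf * cfg.mu_per_generation for Nf in cfg.deme_female_sizes
        ),
        migration=cfg.migration,
        history=cfg.history,
        split_time=cfg.split_time,
        tmrca_per_deme=tmrca_per_deme,
        tmrca_total=float(tree.time(tree.root)),
        n_invariant_masked=n_mask,
        seed=cfg.seed,
    )
    return ds, truth


def scenario_library(seed: int | None = None) -> dict[str, SimulationConfig]:
    """Ready-made configurations used by calibration and power tests.

    * ``panmixia-constant`` — one deme, constant size: the null for the
      neutrality-test calibration.
    * ``island-low|mid|high`` — 4 demes at three migration levels.
    * ``star-holocene`` — star split of 4 demes, no ongoing migration.
    * ``stepwise`` — sequential splits of 4 demes.
    * ``growth`` — one deme under strong exponential growth.
    * ``study-design`` — 8 demes with Table-1-like sample sizes (n = 152),
      island migration, grouped demes.
    """
    lib = {
        "panmixia-constant": SimulationConfig(
            n_demes=1, samples_per_deme=30, seed=seed
        ),
        "island-low": SimulationConfig(
            n_demes=4, samples_per_deme=15, migration=1e-4, seed=seed
        ),
        "island-mid": SimulationConfig(
            n_demes=4, samples_per_deme=15, migration=1e-3, seed=seed
        ),
        "island-high": SimulationConfig(
            n_demes=4, samples_per_deme=15, migration=1e-2, seed=seed
        ),
        "star-holocene": SimulationConfig(
            n_demes=4, samples_per_deme=15, history="star",
            split_time=500.0, migration=0.0, seed=seed,
        ),
        "stepwise": SimulationConfig(
            n_demes=4, samples_per_deme=15, history="stepwise",
            split_time=2000.0, migration=0.0, seed=seed,
        ),
        "growth": SimulationConfig(
            n_demes=1, samples_per_deme=30, deme_female_sizes=20000.0,
            growth_rate=5e-4, seed=seed,
        ),
        # 8 demes with Table-1-like sample sizes; per-deme size chosen so the
        # metapopulation-wide theta matches the study scale (~0.018/site),
        # yielding study-like K ~ 20, h ~ 0.9, pi ~ 0.014, S ~ 21
        "study-design": SimulationConfig(
            n_demes=8,
            samples_per_deme=STUDY_SAMPLE_SIZES,
            deme_female_sizes=1750.0,
            groups_per_deme=4,
            migration=1e-3,
            seed=seed,
        ),
    }
    return lib


def get_scenario(name: str, seed: int | None = None) -> SimulationConfig:
    lib = scenario_library(seed)
    if name not in lib:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(lib)}"
        )
    return lib[name]
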