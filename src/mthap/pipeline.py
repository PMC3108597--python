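"""Orchestration: run the full study-style analysis from one entry point.

Stage order mirrors a single-locus population survey: haplotype collapsing
and per-population diversity, hierarchical structure (AMOVA, pairwise
Phi_ST, leave-one-group-out screen), frequency/distance resampling tests,
demographic-history statistics with effective size, and the haplotype
network.  Every stage's seed and parameters are recorded in a manifest so a
run can be repeated bit-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amova import loo_screen, pairwise_phist, permutation_test
from .diversity import distance_matrix, diversity_indices, nucleotide_diversity
from .errors import MthapError
from .hapio import (
    AlignedDataset,
    classify_sites,
    collapse_haplotypes,
    read_alignment,
    write_haplotype_table,
    write_site_summary,
)
from .neutrality import (
    Boundary,
    effective_size,
    neutrality_suite,
    tajima_theta,
    watterson_theta,
)
from .network import annotate_edges, median_joining, write_network
from .resampling import chisq_randomization, mantel_test, pool_from_table, \
    accumulation_curve, great_circle_km


@dataclass
class RunConfig:
    """Tunable parameters of a full run."""

    seed: int = 0
    min_n_report: int = 10  # smallest per-population n for h/pi reporting
    min_n_amova: int = 10  # populations below this are excluded from AMOVA
    n_perm_amova: int = 16000
    n_perm_mantel: int = 10000
    n_rep_chisq: int = 10000
    n_sims_neutrality: int = 50000
    distance_model: str = "TN93"
    rarefaction_step: int = 10
    rarefaction_events: int = 7
    rarefaction_randomizations: int = 1000
    mu_per_year: float = 3.7e-8
    mu_interval: tuple[float, float] | None = (2.1e-8, 6.0e-8)
    tau_range: tuple[float, float] = (15.0, 20.0)
    external_theta: float | None = None
    external_theta_interval: tuple[float, float] | None = None


def population_table(ds: AlignedDataset, min_n: int = 10) -> pd.DataFrame:
    """Per-population diversity table (area-style rows, Table-1 schema).

    h, pi and s are reported only for populations with more than ``min_n``
    individuals; haplotype counts are reported for all.
    """
    ht_all = collapse_haplotypes(ds)
    rows = []
    for pop in ds.populations:
        sub = ds.subset(lambda r, p=pop: r.population == p)
        ht = collapse_haplotypes(sub)
        n = sub.n
        private = 0
        pop_counts = ht_all.population_counts(pop)
        other = ht_all.total_counts() - pop_counts
        private = int(np.sum((pop_counts > 0) & (other == 0)))
        row = {
            "population": pop,
            "n": n,
            "haplotypes": ht.K,
            "unique_haplotypes": private,
        }
        if n >= min_n:
            idx = diversity_indices(ht)
            row.update(h=round(idx.h, 3), pi=round(idx.pi, 4), s=idx.S)
        else:
            row.update(h=np.nan, pi=np.nan, s=np.nan)
        rows.append(row)
    total = diversity_indices(ht_all)
    rows.append(
        {
            "population": "overall",
            "n": ds.n,
            "haplotypes": ht_all.K,
            "unique_haplotypes": np.nan,
            "h": round(total.h, 3),
            "pi": round(total.pi, 4),
            "s": total.S,
        }
    )
    return pd.DataFrame(rows)


def run_full(
    fasta,
    metadata,
    outdir,
    config: RunConfig | None = None,
    geographic_distances: pd.DataFrame | None = None,
) -> dict:
    """Execute the whole analysis; returns the manifest (also written as JSON)."""
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    seeds = {
        name: int(rng.integers(2**31 - 1))
        for name in ("amova", "loo", "pairwise", "chisq", "mantel",
                     "rarefaction", "neutrality")
    }
    manifest: dict = {
        "version": __version__,
        "inputs": {"fasta": str(fasta), "metadata": str(metadata)},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
        "seeds": seeds,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except MthapError as exc:
                manifest["stages"][name] = {"status": f"failed: {exc}"}
                _write_manifest(manifest, outdir)
                raise MthapError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok",
                "outputs": out,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            return out

        return deco

    ds = read_alignment(fasta, metadata)
    ht = collapse_haplotypes(ds)

    @stage("diversity")
    def _diversity():
        table = population_table(ds, cfg.min_n_report)
        table.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        summary = classify_sites(ht)
        write_site_summary(summary, outdir / "sites.tsv")
        write_haplotype_table(ht, outdir / "haplotypes.tsv")
        return ["diversity.tsv", "sites.tsv", "haplotypes.tsv"]

    big_pops = [
        p for p in ds.populations
        if sum(1 for r in ds.records if r.population == p) >= cfg.min_n_amova
    ]
    ht_big = ht.restrict(big_pops) if len(big_pops) >= 2 else None

    @stage("structure")
    def _structure():
        outputs = []
        if ht_big is None:
            return ["skipped: fewer than 2 populations pass min_n_amova"]
        dist = distance_matrix(ht_big, cfg.distance_model)
        dist.write_tsv(outdir / "distances.tsv")
        outputs.append("distances.tsv")
        has_groups = ht_big.counts.columns.get_level_values(1).nunique() > 1
        levels = 3 if has_groups else 2
        res = permutation_test(
            ht_big, dist, n_perm=cfg.n_perm_amova, seed=seeds["amova"],
            levels=levels,
        )
        res.to_frame().to_csv(outdir / "amova.tsv", sep="\t", index=False)
        outputs.append("amova.tsv")
        units = "groups" if has_groups else "populations"
        phi, pvals = pairwise_phist(
            ht_big, dist, units=units, n_perm=min(cfg.n_perm_amova, 1000),
            seed=seeds["pairwise"],
        )
        phi.to_csv(outdir / "pairwise_phist.tsv", sep="\t")
        outputs.append("pairwise_phist.tsv")
        if pvals is not None:
            pvals.to_csv(outdir / "pairwise_phist_p.tsv", sep="\t")
            outputs.append("pairwise_phist_p.tsv")
        if has_groups and levels == 3:
            try:
                screen = loo_screen(
                    ht_big, dist, n_perm=min(cfg.n_perm_amova, 1000),
                    seed=seeds["loo"],
                )
                screen.rows.to_csv(outdir / "loo_screen.tsv", sep="\t", index=False)
                outputs.append("loo_screen.tsv")
            except MthapError:
                pass
        return outputs

    @stage("resampling")
    def _resampling():
        outputs = []
        rows = []
        rng_local = np.random.default_rng(seeds["chisq"])
        for pop in ds.populations:
            cts = ht.population_counts(pop)
            cts = cts[cts > 0]
            if cts.size >= 2 and cts.sum() >= cfg.min_n_report:
                res = chisq_randomization(
                    cts, n_rep=cfg.n_rep_chisq,
                    seed=int(rng_local.integers(2**31 - 1)),
                )
                rows.append(
                    {"population": pop, "chi2": res.chi2_obs, "p": res.p,
                     "null": res.null_model}
                )
        if rows:
            pd.DataFrame(rows).to_csv(outdir / "chisq.tsv", sep="\t", index=False)
            outputs.append("chisq.tsv")
        # accumulation curves for every population pool large enough
        curves = []
        for pop in ds.populations:
            pool = pool_from_table(ht, [pop])
            if pool.size >= cfg.rarefaction_step:
                curve = accumulation_curve(
                    pool, step=cfg.rarefaction_step,
                    events=cfg.rarefaction_events,
                    n_rand=cfg.rarefaction_randomizations,
                    seed=seeds["rarefaction"],
                )
                df = curve.to_frame()
                df.insert(0, "population", pop)
                curves.append(df)
        if curves:
            pd.concat(curves).to_csv(
                outdir / "accumulation.tsv", sep="\t", index=False
            )
            outputs.append("accumulation.tsv")
        # Mantel against geographic distances when available
        if ht_big is not None and len(big_pops) >= 3:
            geo = geographic_distances
            if geo is None:
                try:
                    from .hapio import read_coordinates

                    coords = read_coordinates(metadata)
                    coords = coords.loc[[p for p in big_pops if p in coords.index]]
                    if len(coords) == len(big_pops):
                        geo = great_circle_km(coords)
                except MthapError:
                    geo = None
            if geo is not None:
                dist = distance_matrix(ht_big, cfg.distance_model)
                phi, _ = pairwise_phist(ht_big, dist, units="populations")
                phi = phi.loc[big_pops, big_pops]
                geo = geo.loc[big_pops, big_pops]
                res = mantel_test(
                    phi, geo, n_perm=cfg.n_perm_mantel, seed=seeds["mantel"]
                )
                with open(outdir / "mantel.json", "w") as fh:
                    json.dump(vars(res), fh, indent=1)
                outputs.append("mantel.json")
        return outputs

    @stage("demography")
    def _demography():
        suite = neutrality_suite(
            ht, n_sims=cfg.n_sims_neutrality, seed=seeds["neutrality"]
        )
        summary = classify_sites(ht)
        theta_w = watterson_theta(summary.S, ds.n, ds.L)
        theta_pi = tajima_theta(nucleotide_diversity(ht))
        record = {
            "Fs": repr(suite.Fs) if isinstance(suite.Fs, Boundary) else suite.Fs,
            "D_star": suite.D_star,
            "F_star": suite.F_star,
            "R2": suite.R2,
            "p_Fs": suite.p_Fs,
            "p_Dstar": suite.p_Dstar,
            "p_Fstar": suite.p_Fstar,
            "p_R2": suite.p_R2,
            "n_sims": suite.n_sims,
            "conditioning": suite.conditioning,
            "theta_watterson": theta_w,
            "theta_pi": theta_pi,
        }
        theta = cfg.external_theta if cfg.external_theta else theta_pi
        if theta > 0:
            ne = effective_size(
                theta,
                cfg.mu_per_year,
                cfg.tau_range,
                theta_interval=cfg.external_theta_interval,
                mu_interval=cfg.mu_interval,
            )
            record["N_ef"] = ne.n_ef
            record["N_ef_interval"] = [ne.n_ef_low, ne.n_ef_high]
            record["N_e"] = ne.n_e
        with open(outdir / "demography.json", "w") as fh:
            json.dump(record, fh, indent=1)
        return ["demography.json"]

    @stage("network")
    def _network():
        if ht.K < 2:
            return ["skipped: single haplotype"]
        net = median_joining(ht)
        annotate_edges(net, ht)
        write_network(
            net, outdir / "network_edges.tsv", outdir / "network_nodes.tsv",
            outdir / "network.gml",
        )
        return ["network_edges.tsv", "network_nodes.tsv", "network.gml"]

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
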