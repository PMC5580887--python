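"""End-to-end orchestration: simulate (or load) → estimate → analyze.

``run_full_analysis`` produces a results bundle mirroring the study's table
layouts: a heritability table (broad-sense, REML narrow-sense, and model r²
per trait), QTL hit tables, model-fit coefficient tables, group mean
increments, mutual-information results, a VCF of de novo calls, and a JSON
manifest recording every seed and threshold.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import heritability as herit
from . import mi as mi_mod
from . import models as models_mod
from . import mutations as mut_mod
from . import qtl as qtl_mod
from .synthetic import (
    ENVIRONMENTS,
    CrossConfig,
    SimulatedDataset,
    default_config,
    focal_alleles,
    simulate_dataset,
)

log = logging.getLogger("evoherit")


@dataclass
class PipelineConfig:
    """Either a simulation config or paths to input tables (exactly one)."""

    cross: CrossConfig | None = None
    input_dir: str | Path | None = None
    output_dir: str | Path = "evoherit_results"
    seed: int = 0
    n_perm_qtl: int = 1000
    n_perm_mi: int = 2000
    n_jackknife: int = 200
    alpha: float = 0.05
    run_qtl: bool = True
    run_reml: bool = True
    run_mutations: bool = True

    def __post_init__(self) -> None:
        if (self.cross is None) == (self.input_dir is None):
            raise ValueError("exactly one of cross config / input_dir must be set")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cross = None
        if "cross" in raw:
            cross_kw = dict(raw["cross"])
            for key in ("qtl_spec", "epistasis_spec"):
                if key in cross_kw:
                    cross_kw[key] = [tuple(_as_tuples(x)) for x in cross_kw[key]]
            if "mutation_targets" in cross_kw:
                cross_kw["mutation_targets"] = {
                    tuple(k.split("/")): tuple(v)
                    for k, v in cross_kw["mutation_targets"].items()
                }
            cross = (default_config(**cross_kw) if cross_kw.pop("defaults", False)
                     else CrossConfig(**cross_kw))
        return cls(cross=cross, **raw.get("pipeline", {}))


def _as_tuples(x):
    return [tuple(v) if isinstance(v, list) else v for v in x]


# ---------------------------------------------------------------------------
# measurement summaries


def founder_summaries(fitness_table: pd.DataFrame, founders: list[str]) -> pd.DataFrame:
    """Per-founder mean fitness and error variance of the mean, per environment."""
    rows = []
    sub = fitness_table[fitness_table["strain_id"].isin(set(founders))]
    for (strain, env), grp in sub.groupby(["strain_id", "environment"], sort=False):
        s = grp["fitness"].to_numpy()
        rows.append(
            {"founder_id": strain, "environment": env, "mean": s.mean(),
             "error_var": s.var(ddof=1) / s.size if s.size > 1 else 0.0,
             "n_reps": s.size}
        )
    return pd.DataFrame(rows)


def population_increments(
    fitness_table: pd.DataFrame,
    populations: pd.DataFrame,
    founder_summary: pd.DataFrame,
) -> pd.DataFrame:
    """Measured fitness increments ΔX = X′(population) − X̄(founder), per
    population per measurement environment, labeled home/away."""
    fmean = founder_summary.set_index(["founder_id", "environment"])["mean"]
    pop_info = populations.set_index("population_id")
    sub = fitness_table[fitness_table["strain_id"].isin(set(populations["population_id"]))]
    rows = []
    for (pop, env), grp in sub.groupby(["strain_id", "environment"], sort=False):
        founder = pop_info.at[pop, "founder_id"]
        evolved = pop_info.at[pop, "environment"]
        rows.append(
            {
                "population_id": pop,
                "founder_id": founder,
                "evolved_env": evolved,
                "measured_env": env,
                "role": "home" if env == evolved else "away",
                "final_fitness": grp["fitness"].mean(),
                "increment": grp["fitness"].mean() - fmean[(founder, env)],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full analysis


@dataclass
class ResultsBundle:
    outdir: Path
    heritability: pd.DataFrame
    qtl_hits: pd.DataFrame
    model_fits: pd.DataFrame
    group_means: pd.DataFrame
    mi_results: pd.DataFrame | None
    manifest: dict
    extras: dict = field(default_factory=dict)


def run_full_analysis(config: PipelineConfig) -> ResultsBundle:
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "call_min_freq": 0.5, "call_min_support": 4,
            "parental_min_lines": 6, "artifact_freq": 0.10,
            "artifact_min_pops": 5, "alpha": config.alpha,
            "lod_decline": 1.5, "allele_code": 0.5, "p_nonfluor_HT": 0.015,
        },
        "stages": {},
    }

    if config.cross is not None:
        ds = simulate_dataset(config.cross)
        manifest["mode"] = "simulation"
        manifest["cross_seed"] = config.cross.seed
    else:
        ds = _load_dataset(Path(config.input_dir))
        manifest["mode"] = "input"
    geno = ds.genotypes
    pops = ds.populations.table
    manifest["stages"]["data"] = {
        "n_founders": geno.n_founders, "n_loci": geno.n_loci,
        "n_populations": len(pops), "elapsed_s": round(time.time() - t0, 2),
    }
    log.info("data ready: %s", manifest["stages"]["data"])

    fsum = founder_summaries(ds.fitness_table, geno.founders)
    incr = population_increments(ds.fitness_table, pops, fsum)
    focal = focal_alleles(geno, ds.config) if ds.config else None

    # --- heritability table (Table 1 layout) -------------------------------
    trait_cols = {}
    for env in ENVIRONMENTS:
        sub = fsum[fsum["environment"] == env].set_index("founder_id").loc[geno.founders]
        trait_cols[f"fitness_{env}"] = ("fitness", env, sub)
    herit_rows = {}
    qtl_tables = []
    model_rows = []
    detected_loci: dict[str, list[int]] = {}

    for env in ENVIRONMENTS:
        sub = trait_cols[f"fitness_{env}"][2]
        vc = herit.broad_sense_fitness(sub["mean"], sub["error_var"])
        herit_rows[f"fitness_{env}"] = {"H2": vc.H2}
        if config.run_reml:
            kin = herit.kinship_matrix(geno)
            reml = herit.narrow_sense_reml(sub["mean"].to_numpy(), kin)
            herit_rows[f"fitness_{env}"]["h2"] = reml.h2

    home = incr[incr["role"] == "home"]
    away = incr[incr["role"] == "away"]
    for env in ENVIRONMENTS:
        grp = {
            f: g["increment"].to_numpy()
            for f, g in home[home["evolved_env"] == env].groupby("founder_id")
        }
        vc = herit.broad_sense_increment(grp)
        herit_rows[f"adaptability_{env}"] = {"H2": vc.H2}
        other = "HT" if env == "OT" else "OT"
        grp_a = {
            f: g["increment"].to_numpy()
            for f, g in away[away["evolved_env"] == env].groupby("founder_id")
        }
        vc_a = herit.broad_sense_increment(grp_a)
        herit_rows[f"pleiotropy_{env}_pops_at_{other}"] = {"H2": vc_a.H2}

        # founder-mean traits for REML / QTL / models
        dmean = home[home["evolved_env"] == env].groupby("founder_id")["increment"].mean()
        dmean = dmean.loc[[f for f in geno.founders if f in dmean.index]]
        x = trait_cols[f"fitness_{env}"][2]["mean"].loc[dmean.index]
        if config.run_reml:
            idx = [geno.founders.index(f) for f in dmean.index]
            kin_sub = herit.kinship_matrix(geno.subset_founders(idx))
            herit_rows[f"adaptability_{env}"]["h2"] = herit.narrow_sense_reml(
                dmean.to_numpy(), kin_sub
            ).h2

        fit_model = models_mod.fit_adaptability_vs_fitness(dmean.to_numpy(), x.to_numpy())
        herit_rows[f"adaptability_{env}"]["r2_fitness"] = fit_model.r2
        model_rows.append(
            {"model": f"adaptability_vs_fitness_{env}",
             "term": "fitness", "estimate": fit_model.params["fitness"],
             "se": fit_model.bse["fitness"], "p": fit_model.pvalues["fitness"],
             "r2": fit_model.r2, "n": fit_model.n}
        )

        if config.run_qtl:
            weights = np.sqrt(
                trait_cols[f"fitness_{env}"][2]["n_reps"].loc[dmean.index].to_numpy()
            )
            hits_fit = qtl_mod.forward_scan(
                geno, trait_cols[f"fitness_{env}"][2]["mean"].to_numpy(),
                alpha=config.alpha, n_perm=config.n_perm_qtl,
                seed=config.seed + 101 + ENVIRONMENTS.index(env),
            )
            idx_sub = [geno.founders.index(f) for f in dmean.index]
            hits_ad = qtl_mod.forward_scan(
                geno.subset_founders(idx_sub), dmean.to_numpy(), weights=weights,
                alpha=config.alpha, n_perm=config.n_perm_qtl,
                seed=config.seed + 201 + ENVIRONMENTS.index(env),
            )
            for trait_name, hits in ((f"fitness_{env}", hits_fit),
                                     (f"adaptability_{env}", hits_ad)):
                detected_loci[trait_name] = [h.locus for h in hits]
                for h in hits:
                    qtl_tables.append(
                        {"trait": trait_name, "chrom": h.chrom, "peak_pos": h.pos,
                         "lod": h.lod, "p": h.p_value, "ci_lo": h.ci_lo,
                         "ci_hi": h.ci_hi, "effect": h.effect}
                    )
            if hits_fit:
                herit_rows[f"fitness_{env}"]["r2_qtl"] = qtl_mod.additive_model_r2(
                    geno, [h.locus for h in hits_fit],
                    trait_cols[f"fitness_{env}"][2]["mean"].to_numpy(),
                )
            if hits_ad:
                herit_rows[f"adaptability_{env}"]["r2_qtl"] = qtl_mod.additive_model_r2(
                    geno.subset_founders(idx_sub), [h.locus for h in hits_ad],
                    dmean.to_numpy(), weights=weights,
                )
            # combined fitness + QTL model on the master QTL list
            master = sorted(
                set(detected_loci.get(f"fitness_{env}", []))
                | set(detected_loci.get(f"adaptability_{env}", []))
            )
            focal_locus = ds.config.focal_locus if ds.config else None
            if master and focal_locus is not None:
                codes = geno.codes()[idx_sub]
                qtl_codes = pd.DataFrame(
                    {f"L{l}": codes[:, l] for l in master if l != focal_locus}
                )
                combined = models_mod.fit_combined_model(
                    dmean.to_numpy(), x.to_numpy(), qtl_codes,
                    codes[:, focal_locus], alpha=config.alpha,
                )
                herit_rows[f"adaptability_{env}"]["r2_combined"] = combined.full.r2
                for term in combined.full.terms:
                    model_rows.append(
                        {"model": f"combined_{env}", "term": term,
                         "estimate": combined.full.params[term],
                         "se": combined.full.bse[term],
                         "p": combined.full.pvalues_adj[term],
                         "r2": combined.full.r2, "n": combined.full.n}
                    )

    # pleiotropy fitness models (away increments vs away/home founder fitness)
    for env in ENVIRONMENTS:
        other = "HT" if env == "OT" else "OT"
        dmean_a = away[away["evolved_env"] == env].groupby("founder_id")["increment"].mean()
        dmean_a = dmean_a.loc[[f for f in geno.founders if f in dmean_a.index]]
        x_away = trait_cols[f"fitness_{other}"][2]["mean"].loc[dmean_a.index]
        x_home = trait_cols[f"fitness_{env}"][2]["mean"].loc[dmean_a.index]
        pm = models_mod.fit_pleiotropy_model(
            dmean_a.to_numpy(), x_away.to_numpy(), x_home.to_numpy()
        )
        herit_rows[f"pleiotropy_{env}_pops_at_{other}"]["r2_fitness"] = pm.r2
        for term in pm.terms:
            model_rows.append(
                {"model": f"pleiotropy_{env}_pops_at_{other}", "term": term,
                 "estimate": pm.params[term], "se": pm.bse[term],
                 "p": pm.pvalues[term], "r2": pm.r2, "n": pm.n}
            )

    herit_df = pd.DataFrame(herit_rows).T
    herit_df.index.name = "trait"
    manifest["stages"]["heritability"] = {"elapsed_s": round(time.time() - t0, 2)}

    # --- Table 2 group means and the normalized-difference analysis --------
    if focal is not None:
        finals = incr.merge(focal.rename("focal_allele"), on="founder_id")
        gm = models_mod.group_mean_increments(
            finals.rename(columns={"final_fitness": "fitness"})[
                ["population_id", "focal_allele", "evolved_env", "measured_env", "fitness"]
            ],
            seed=config.seed + 301,
        )
    else:
        gm = pd.DataFrame()

    fig4 = _difference_analysis(trait_cols, home, geno, config.seed + 401)
    manifest["stages"]["models"] = {"elapsed_s": round(time.time() - t0, 2)}

    # --- de novo mutation analysis ------------------------------------------
    mi_df = None
    if config.run_mutations and ds.truth is not None and len(ds.truth.mutations):
        mi_df = _mutation_analysis(ds, outdir, config, manifest)

    # --- write the bundle ----------------------------------------------------
    herit_df.to_csv(outdir / "heritability.tsv", sep="\t")
    pd.DataFrame(qtl_tables).to_csv(outdir / "qtl_hits.tsv", sep="\t", index=False)
    pd.DataFrame(model_rows).to_csv(outdir / "model_fit.tsv", sep="\t", index=False)
    gm.to_csv(outdir / "group_means.tsv", sep="\t", index=False)
    if mi_df is not None:
        mi_df.to_csv(outdir / "mi_results.tsv", sep="\t", index=False)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return ResultsBundle(
        outdir=outdir, heritability=herit_df,
        qtl_hits=pd.DataFrame(qtl_tables), model_fits=pd.DataFrame(model_rows),
        group_means=gm, mi_results=mi_df, manifest=manifest,
        extras={"fig4": fig4, "founder_summaries": fsum, "increments": incr},
    )


def _difference_analysis(trait_cols, home, geno, seed):
    """Normalized fitness/increment differences between environments and
    their correlation (the home-environment specificity test)."""
    dm = {}
    for env in ENVIRONMENTS:
        d = home[home["evolved_env"] == env].groupby("founder_id")["increment"].mean()
        dm[env] = d
    common = [f for f in geno.founders if f in dm["OT"].index and f in dm["HT"].index]
    if len(common) < 10:
        return None
    x = trait_cols["fitness_OT"][2]["mean"].loc[common].to_numpy()
    y = trait_cols["fitness_HT"][2]["mean"].loc[common].to_numpy()
    xt = models_mod.normalize_traits(x)
    yt = models_mod.normalize_traits(y)
    dxt = models_mod.normalize_traits(dm["OT"].loc[common].to_numpy())
    dyt = models_mod.normalize_traits(dm["HT"].loc[common].to_numpy())
    return models_mod.difference_correlation(xt - yt, dxt - dyt, n_boot=2000, seed=seed)


def _mutation_analysis(ds: SimulatedDataset, outdir: Path, config: PipelineConfig,
                       manifest: dict) -> pd.DataFrame:
    """Site-count synthesis (simulation mode), filtering, calling, multi-hit
    tally, and the hierarchical mutual-information tests."""
    genes_df, counts = synthesize_site_counts(ds, seed=config.seed + 501)
    filtered, removal_log = mut_mod.apply_site_filters(counts)
    calls = mut_mod.call_mutations(filtered)
    pop2founder = dict(zip(ds.populations.table["population_id"],
                           ds.populations.table["founder_id"]))
    calls, removed = mut_mod.remove_shared_founder_snvs(calls, pop2founder)
    assigned, multihit = mut_mod.assign_genes_and_multihit(calls, genes_df)
    mut_mod.write_vcf(assigned, outdir / "calls.vcf")
    manifest["stages"]["mutations"] = {
        "sites_removed": len(removal_log), "n_calls": len(assigned),
        "n_multihit": len(multihit), "shared_founder_snvs_removed": len(removed),
    }
    pops = ds.populations.table
    events = assigned[assigned["gene"].notna()][["population_id", "gene"]]
    matrix = mi_mod.MutationMatrix.from_events(
        list(pops["population_id"]), events, multihit
    )
    focal = focal_alleles(ds.genotypes, ds.config)
    labels = pops["founder_id"].map(focal).to_numpy()
    return mi_mod.hierarchical_analysis(
        labels, pops["environment"].to_numpy(), pops["founder_id"].to_numpy(),
        matrix, n_perm=config.n_perm_mi, seed=config.seed + 601,
    )


def synthesize_site_counts(
    ds: SimulatedDataset, seed: int = 0, depth: int = 25,
) -> tuple[pd.DataFrame, mut_mod.SiteCountTable]:
    """Turn simulated mutation events into a per-site read-count table.

    Genes get consecutive 1.5-kb intervals on a dedicated contig; each event
    becomes an alt-majority site in its population (binomial reads around 85%
    frequency).  A few parent-difference and error-prone decoy sites are
    added so the site filters have work to do.
    """
    rng = np.random.default_rng(seed)
    gene_names = sorted(
        {g for targets in ds.config.mutation_targets.values() for g in targets}
    )
    genes_df = pd.DataFrame(
        {"gene": gene_names, "chrom": "chrMut",
         "start": [1 + 2000 * i for i in range(len(gene_names))],
         "end": [1500 + 2000 * i for i in range(len(gene_names))]}
    )
    starts = dict(zip(genes_df["gene"], genes_df["start"]))
    pops = list(ds.populations.table["population_id"])
    pop_idx = {p: i for i, p in enumerate(pops)}
    site_key = {}
    next_offset = {g: 0 for g in gene_names}
    rows = []
    placements = []  # (site index, population index)
    for _, ev in ds.truth.mutations.iterrows():
        # one site per (gene, population); repeat events in the same
        # population and gene share it, distinct populations never do
        key = (ev["gene"], ev["population_id"])
        if key not in site_key:
            pos = starts[ev["gene"]] + next_offset[ev["gene"]]
            next_offset[ev["gene"]] += 1
            site_key[key] = len(rows)
            rows.append({"chrom": "chrMut", "pos": pos, "ref": "A", "alt": "T"})
        placements.append((site_key[key], pop_idx[ev["population_id"]]))
    n_sites = len(rows)
    ref = np.full((n_sites, len(pops)), depth, dtype=int)
    alt = np.zeros((n_sites, len(pops)), dtype=int)
    for si, pj in placements:
        a = int(rng.binomial(depth, 0.85))
        a = max(a, 4)  # calls need >50% and >=4 reads; depth 25 keeps both
        a = max(a, depth // 2 + 1)
        alt[si, pj] = a
        ref[si, pj] = depth - a
    # decoys: parental fixed differences (majority in many pops) and
    # error-prone sites (low-frequency alt in many pops)
    decoy_rows = []
    n_par, n_err = 5, 5
    for d in range(n_par):
        decoy_rows.append({"chrom": "chrMut", "pos": 900000 + d, "ref": "G", "alt": "C"})
    for d in range(n_err):
        decoy_rows.append({"chrom": "chrMut", "pos": 950000 + d, "ref": "G", "alt": "C"})
    dref = np.full((n_par + n_err, len(pops)), depth, dtype=int)
    dalt = np.zeros((n_par + n_err, len(pops)), dtype=int)
    carriers = rng.choice(len(pops), size=max(6, len(pops) // 2), replace=False)
    dalt[:n_par][:, carriers] = depth - 5
    dref[:n_par][:, carriers] = 5
    err_carriers = rng.choice(len(pops), size=max(5, len(pops) // 3), replace=False)
    dalt[n_par:][:, err_carriers] = 4  # 16% frequency at depth 25
    dref[n_par:][:, err_carriers] = depth - 4
    sites = pd.DataFrame(rows + decoy_rows)
    counts = mut_mod.SiteCountTable(
        sites=sites, populations=pops,
        ref_counts=np.vstack([ref, dref]), alt_counts=np.vstack([alt, dalt]),
    )
    return genes_df, counts


def _load_dataset(indir: Path) -> SimulatedDataset:
    """Load a dataset previously written by SimulatedDataset.write (or real
    tables in the same schema)."""
    from .synthetic import EvolvedPopulationSet, GenotypeMatrix, TrueState

    geno = GenotypeMatrix.from_tsv(indir / "genotypes.tsv")
    fitness_table = pd.read_csv(indir / "fitness.tsv", sep="\t")
    pops = pd.read_csv(indir / "populations.tsv", sep="\t")
    truth = None
    if (indir / "truth.tsv").exists():
        pop_truth = pd.read_csv(indir / "truth.tsv", sep="\t")
        mut_path = indir / "mutations.tsv"
        muts = (pd.read_csv(mut_path, sep="\t") if mut_path.exists()
                else pd.DataFrame(columns=["population_id", "founder_id",
                                           "environment", "gene"]))
        truth = TrueState(
            config=None, founder_fitness=None, founder_deviation=None,
            populations=pop_truth, mutations=muts,
        )
    return SimulatedDataset(
        config=None, genotypes=geno, truth=truth,
        populations=EvolvedPopulationSet(table=pops), fitness_table=fitness_table,
    )
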