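"""Synthetic RM×BY cross and experimental-evolution generator.

Emulates the statistical structure of a large yeast segregant panel evolved
in two environments: 230 haploid founders carrying random mosaics of two
parental genomes (RM, BY), replicate populations evolved at an optimal
temperature (OT) and a high temperature (HT), fitness gains that decline
linearly with founder fitness, and de novo mutation spectra whose gene-level
targets depend on the allele at a focal large-effect locus and on the
evolution environment.

Everything downstream of this module treats the generated tables exactly as
it would treat real measurements; the generator additionally returns the
latent ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ENVIRONMENTS = ("OT", "HT")

RM, BY = 0, 1
ALLELE_NAMES = {RM: "RM", BY: "BY"}

# named RNG substreams so each stage is independently reproducible
_STREAMS = {"genotypes": 11, "fitness": 23, "evolution": 37, "measurement": 53}


class ConfigurationError(ValueError):
    """Raised when a CrossConfig violates its invariants."""


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[name]])


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CrossConfig:
    """Parameters of the synthetic cross and evolution experiment.

    Fitness units are per-generation selection coefficients (dimensionless);
    effects are the BY-minus-RM fitness difference at a locus.  Environments
    are keyed "OT" and "HT" throughout; per-environment mappings must cover
    both.
    """

    n_founders: int = 230
    chromosome_lengths: Sequence[int] = (75,) * 16
    crossover_prob: float = 0.05
    # (locus, effect at OT, effect at HT); BY allele adds +effect/2, RM -effect/2
    qtl_spec: Sequence[tuple[int, float, float]] = ()
    # ((locus a, locus b), (interaction at OT, interaction at HT))
    epistasis_spec: Sequence[tuple[tuple[int, int], tuple[float, float]]] = ()
    fitness_residual_sd: Mapping[str, float] = field(
        default_factory=lambda: {"OT": 0.034, "HT": 0.061}
    )
    focal_locus: int = 0
    # (allele name, environment) -> accessible de novo target genes
    mutation_targets: Mapping[tuple[str, str], tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_TARGETS)
    )
    # environment -> (intercept a, slope b) of expected home-env gain vs founder fitness
    adaptability_rule: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"OT": (0.065, -0.5), "HT": (0.15, -0.5)}
    )
    # environment -> (a, b) for the increment *measured in* that environment of
    # populations that evolved elsewhere; defaults to a damped home rule
    away_rule: Mapping[str, tuple[float, float]] | None = None
    founder_effect_sd: float = 0.018
    pop_noise_sd: Mapping[str, float] | float = field(
        default_factory=lambda: {"OT": 0.029, "HT": 0.046}
    )
    home_away_corr: float = 0.5
    meas_error_sd: Mapping[str, float] = field(
        default_factory=lambda: {"OT": 0.01, "HT": 0.01}
    )
    n_tech_reps: int = 4
    n_pop_reps: int = 1
    n_pops_per_env: int = 4
    # environment -> mean de novo high-frequency mutation count at fitness 0
    mut_rate: Mapping[str, float] = field(
        default_factory=lambda: {"OT": 1.3, "HT": 3.6}
    )
    # additive fitness dependence of the Poisson mean (counts per unit fitness)
    mut_fitness_coef: float = -3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths or any(l < 1 for l in self.chromosome_lengths):
            raise ConfigurationError("chromosome_lengths must be nonempty positive counts")
        if not 0.0 <= self.crossover_prob <= 0.5:
            raise ConfigurationError(
                f"crossover_prob must lie in [0, 0.5], got {self.crossover_prob}"
            )
        if self.founder_effect_sd < 0:
            raise ConfigurationError("founder_effect_sd must be >= 0")
        if any(self.pop_noise(env) < 0 for env in ENVIRONMENTS):
            raise ConfigurationError("pop_noise_sd must be >= 0")
        if any(v < 0 for v in self.meas_error_sd.values()):
            raise ConfigurationError("meas_error_sd values must be >= 0")
        if not -1.0 <= self.home_away_corr <= 1.0:
            raise ConfigurationError("home_away_corr must lie in [-1, 1]")
        n_loci = sum(self.chromosome_lengths)
        for locus, *_ in self.qtl_spec:
            if not 0 <= locus < n_loci:
                raise ConfigurationError(f"QTL locus {locus} out of range (m={n_loci})")
        if self.qtl_spec:
            hits = [q for q in self.qtl_spec if q[0] == self.focal_locus]
            if len(hits) != 1:
                raise ConfigurationError(
                    "focal_locus must appear exactly once in qtl_spec"
                )

    @property
    def n_loci(self) -> int:
        return sum(self.chromosome_lengths)

    def pop_noise(self, env: str) -> float:
        """Evolutionary-stochasticity s.d. of increments measured in ``env``."""
        if isinstance(self.pop_noise_sd, Mapping):
            return self.pop_noise_sd[env]
        return float(self.pop_noise_sd)

    def away_rule_resolved(self) -> Mapping[str, tuple[float, float]]:
        if self.away_rule is not None:
            return self.away_rule
        return {env: (0.7 * a, 0.7 * b) for env, (a, b) in self.adaptability_rule.items()}


# Default gene universe.  The "RBG" class stands in for the ribosome-biogenesis
# pathway reachable only from the RM allele at the focal locus; the cAMP class
# is reachable only from the BY allele; SIR-like genes are HT-specific.
RIBOSOME_BIOGENESIS_GENES = tuple(["KRE33"] + [f"RBG{i}" for i in range(2, 11)])
CAMP_GENES = ("GPB1", "GPB2", "PDE2", "IRA2", "RAS2")
HT_SPECIFIC_GENES = ("SIR3", "SIR4")
SHARED_GENES = tuple(f"GEN{i}" for i in range(1, 9))

DEFAULT_MUTATION_TARGETS: dict[tuple[str, str], tuple[str, ...]] = {
    ("RM", "OT"): RIBOSOME_BIOGENESIS_GENES + SHARED_GENES,
    ("RM", "HT"): RIBOSOME_BIOGENESIS_GENES + HT_SPECIFIC_GENES + SHARED_GENES,
    ("BY", "OT"): CAMP_GENES + SHARED_GENES,
    ("BY", "HT"): CAMP_GENES + HT_SPECIFIC_GENES + SHARED_GENES,
}


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Biallelic founder genotypes with genome coordinates.

    ``alleles`` is founders × loci with entries 0 (RM) / 1 (BY).
    """

    founders: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def codes(self) -> np.ndarray:
        """±1/2 effect codes: BY -> +0.5, RM -> -0.5."""
        return self.alleles.astype(float) - 0.5

    def by_frequency(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def monomorphic_mask(self) -> np.ndarray:
        freq = self.by_frequency()
        return (freq == 0.0) | (freq == 1.0)

    def subset_loci(self, loci: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            founders=list(self.founders),
            chrom=self.chrom[loci],
            pos=self.pos[loci],
            alleles=self.alleles[:, loci],
        )

    def subset_founders(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            founders=[self.founders[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            alleles=self.alleles[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]
        data = np.where(self.alleles == BY, "BY", "RM")
        df = pd.DataFrame(data, columns=cols)
        df.insert(0, "founder_id", self.founders)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str)
        founders = df["founder_id"].tolist()
        loci = df.columns[1:]
        chrom = np.array([c.rsplit(":", 1)[0] for c in loci])
        pos = np.array([int(c.rsplit(":", 1)[1]) for c in loci])
        alleles = (df[loci].to_numpy() == "BY").astype(np.int8)
        return cls(founders=founders, chrom=chrom, pos=pos, alleles=alleles)


@dataclass
class TrueState:
    """Latent ground truth of one simulated experiment."""

    config: CrossConfig
    founder_fitness: pd.DataFrame  # index founder_id, columns OT/HT (true values)
    founder_deviation: pd.DataFrame  # founder-level adaptability deviations per env
    populations: pd.DataFrame  # one row per evolved population (true increments)
    mutations: pd.DataFrame  # one row per de novo mutation event


@dataclass
class EvolvedPopulationSet:
    """Per-population records: founder, home environment, replicate, increments."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# simulation stages


def simulate_genotypes(config: CrossConfig) -> GenotypeMatrix:
    """Draw founder genotypes as independent two-state Markov chains.

    Along each chromosome, the first locus is RM or BY with probability 1/2
    and each subsequent locus switches parental origin with probability
    ``crossover_prob`` (no interference).
    """
    rng = _stream(config.seed, "genotypes")
    n = config.n_founders
    blocks = []
    chrom_labels = []
    pos = []
    for c, length in enumerate(config.chromosome_lengths, start=1):
        first = rng.integers(0, 2, size=(n, 1))
        if length > 1:
            switches = rng.random((n, length - 1)) < config.crossover_prob
            cum = np.cumsum(switches, axis=1) % 2
            alleles = np.concatenate([first, (first + cum) % 2], axis=1)
        else:
            alleles = first
        blocks.append(alleles.astype(np.int8))
        chrom_labels.extend([f"chr{c:02d}"] * length)
        # loci spaced 1 kb apart, 1-based
        pos.extend(1 + 1000 * np.arange(length))
    founders = [f"F{i:04d}" for i in range(1, n + 1)]
    return GenotypeMatrix(
        founders=founders,
        chrom=np.array(chrom_labels),
        pos=np.array(pos, dtype=int),
        alleles=np.concatenate(blocks, axis=1),
    )


def simulate_founder_fitness(geno: GenotypeMatrix, config: CrossConfig) -> pd.DataFrame:
    """True founder fitness per environment from additive + epistatic QTL effects.

    X_i = Σ_q effect_q · c_iq + Σ_(a,b) w_ab · c_ia · c_ib + N(0, residual sd)
    with c = ±1/2 (BY positive).
    """
    for locus, *_ in config.qtl_spec:
        if locus >= geno.n_loci:
            raise ConfigurationError(f"QTL locus {locus} outside genotype matrix")
    rng = _stream(config.seed, "fitness")
    codes = geno.codes()
    out = {}
    for e_idx, env in enumerate(ENVIRONMENTS):
        fit = np.zeros(geno.n_founders)
        for locus, eff_ot, eff_ht in config.qtl_spec:
            fit += (eff_ot, eff_ht)[e_idx] * codes[:, locus]
        for (la, lb), effs in config.epistasis_spec:
            fit += effs[e_idx] * codes[:, la] * codes[:, lb]
        sd = config.fitness_residual_sd[env]
        if sd > 0:
            fit = fit + rng.normal(0.0, sd, size=geno.n_founders)
        out[env] = fit
    return pd.DataFrame(out, index=pd.Index(geno.founders, name="founder_id"))


def focal_alleles(geno: GenotypeMatrix, config: CrossConfig) -> pd.Series:
    """Allele name ("RM"/"BY") at the focal locus per founder."""
    a = geno.alleles[:, config.focal_locus]
    return pd.Series(
        np.where(a == BY, "BY", "RM"), index=pd.Index(geno.founders, name="founder_id")
    )


def simulate_evolution(
    fitness: pd.DataFrame, geno: GenotypeMatrix, config: CrossConfig
) -> tuple[TrueState, EvolvedPopulationSet]:
    """Draw true fitness increments and de novo mutations for every population.

    For a population of founder i evolved in home environment h:
      Δ_home = a_h + b_h·X_ih + u_ih + e          (founder deviation + pop noise)
      Δ_away = a'_w + b'_w·X_iw + u_iw' + e'      (rule of the away environment)
    with corr(u, u') = corr(e, e') = ``home_away_corr``.  Mutation counts are
    Poisson with mean max(0, λ_h + c·X_ih); gene labels are drawn uniformly
    from the target set accessible to (focal allele, home environment).
    """
    if set(fitness.index) != set(geno.founders):
        raise ConfigurationError("fitness must be defined for all founders")
    fitness = fitness.loc[geno.founders]
    rng = _stream(config.seed, "evolution")
    rho = config.home_away_corr
    away = config.away_rule_resolved()
    alleles = focal_alleles(geno, config)
    n = geno.n_founders

    # founder-level deviations, one correlated pair per home environment
    dev_rows = {}
    for env in ENVIRONMENTS:
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        u_home = config.founder_effect_sd * z1
        u_away = config.founder_effect_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        dev_rows[f"{env}_home"] = u_home
        dev_rows[f"{env}_away"] = u_away
    deviations = pd.DataFrame(dev_rows, index=fitness.index)

    pop_rows = []
    mut_rows = []
    for env in ENVIRONMENTS:
        other = "HT" if env == "OT" else "OT"
        a_h, b_h = config.adaptability_rule[env]
        a_w, b_w = away[other]
        lam0 = config.mut_rate[env]
        for i, founder in enumerate(geno.founders):
            x_home = fitness.at[founder, env]
            x_away = fitness.at[founder, other]
            mu_home = a_h + b_h * x_home + deviations.at[founder, f"{env}_home"]
            mu_away = a_w + b_w * x_away + deviations.at[founder, f"{env}_away"]
            z1 = rng.normal(size=config.n_pops_per_env)
            z2 = rng.normal(size=config.n_pops_per_env)
            e_home = config.pop_noise(env) * z1
            e_away = config.pop_noise(other) * (rho * z1 + np.sqrt(1 - rho**2) * z2)
            lam = max(0.0, lam0 + config.mut_fitness_coef * x_home)
            counts = rng.poisson(lam, size=config.n_pops_per_env)
            targets = config.mutation_targets[(alleles.iloc[i], env)]
            for j in range(config.n_pops_per_env):
                pop_id = f"{founder}_{env}_r{j + 1}"
                d_home = mu_home + e_home[j]
                d_away = mu_away + e_away[j]
                pop_rows.append(
                    {
                        "population_id": pop_id,
                        "founder_id": founder,
                        "environment": env,
                        "replicate": j + 1,
                        "delta_home": d_home,
                        "delta_away": d_away,
                        "final_home": x_home + d_home,
                        "final_away": x_away + d_away,
                        "n_mutations": int(counts[j]),
                    }
                )
                if counts[j] > 0:
                    genes = rng.choice(targets, size=counts[j], replace=True)
                    for g in genes:
                        mut_rows.append(
                            {"population_id": pop_id, "founder_id": founder,
                             "environment": env, "gene": str(g)}
                        )
    populations = pd.DataFrame(pop_rows)
    mutations = pd.DataFrame(
        mut_rows, columns=["population_id", "founder_id", "environment", "gene"]
    )
    truth = TrueState(
        config=config,
        founder_fitness=fitness,
        founder_deviation=deviations,
        populations=populations,
        mutations=mutations,
    )
    return truth, EvolvedPopulationSet(table=populations)


def simulate_measurements(truth: TrueState, config: CrossConfig | None = None) -> pd.DataFrame:
    """Noisy replicate fitness measurements of founders and evolved populations.

    Founders are measured ``n_tech_reps`` times in each environment; evolved
    populations ``n_pop_reps`` times in each environment.  Each replicate is
    truth + N(0, meas_error_sd[environment]).
    """
    config = config or truth.config
    if config.n_tech_reps < 2:
        raise ConfigurationError("n_tech_reps must be >= 2 (error variance inestimable)")
    rng = _stream(config.seed, "measurement")
    frames = []

    def _measure(strains: np.ndarray, truths: np.ndarray, env: str, n_reps: int):
        sd = config.meas_error_sd[env]
        vals = np.repeat(truths, n_reps)
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=vals.size)
        frames.append(
            pd.DataFrame(
                {"strain_id": np.repeat(strains, n_reps), "environment": env,
                 "replicate": np.tile(np.arange(1, n_reps + 1), strains.size),
                 "fitness": vals}
            )
        )

    founders = truth.founder_fitness.index.to_numpy()
    for env in ENVIRONMENTS:
        _measure(founders, truth.founder_fitness[env].to_numpy(), env,
                 config.n_tech_reps)
    pops = truth.populations
    home_env = pops["environment"].to_numpy()
    for env in ENVIRONMENTS:
        finals = np.where(home_env == env, pops["final_home"], pops["final_away"])
        _measure(pops["population_id"].to_numpy(), finals, env, config.n_pop_reps)
    return pd.concat(frames, ignore_index=True)


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulation run produces."""

    config: CrossConfig
    genotypes: GenotypeMatrix
    truth: TrueState
    populations: EvolvedPopulationSet
    fitness_table: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": outdir / "genotypes.tsv",
            "fitness": outdir / "fitness.tsv",
            "populations": outdir / "populations.tsv",
            "mutations": outdir / "mutations.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.genotypes.to_tsv(paths["genotypes"])
        self.fitness_table.to_csv(paths["fitness"], sep="\t", index=False)
        self.populations.table[
            ["population_id", "founder_id", "environment", "replicate"]
        ].to_csv(paths["populations"], sep="\t", index=False)
        self.truth.mutations.to_csv(paths["mutations"], sep="\t", index=False)
        self.truth.populations.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_dataset(config: CrossConfig) -> SimulatedDataset:
    """Run all four stages under one seed with named substreams."""
    geno = simulate_genotypes(config)
    fitness = simulate_founder_fitness(geno, config)
    truth, pops = simulate_evolution(fitness, geno, config)
    fitness_table = simulate_measurements(truth, config)
    return SimulatedDataset(
        config=config, genotypes=geno, truth=truth, populations=pops,
        fitness_table=fitness_table,
    )


def default_config(seed: int = 0, **overrides) -> CrossConfig:
    """Study-scale configuration: 230 founders, 16 chromosomes, a focal
    large-effect locus (BY allele +0.09 at OT, +0.19 at HT), five further
    shared QTLs, and the declining-adaptability rule with slope -0.5."""
    qtl_spec = (
        (1013, 0.09, 0.19),  # focal large-effect locus, chr 14
        (113, 0.05, 0.06),
        (294, 0.04, 0.05),
        (468, 0.03, 0.04),
        (642, 0.03, 0.03),
        (871, 0.02, 0.03),
    )
    base = CrossConfig(qtl_spec=qtl_spec, focal_locus=1013, seed=seed)
    return replace(base, **overrides) if overrides else base


def expected_increment_heritability(config: CrossConfig, env: str) -> float:
    """Expected broad-sense heritability of the measured fitness increment.

    Founder component: b²·Var(X) + founder_effect_sd² plus the shared
    founder-mean measurement error (meas²/n_tech_reps, which enters every
    increment of a founder with the same sign).  Population component:
    pop_noise_sd² plus the final-fitness measurement error meas²/n_pop_reps.
    Var(X) is the expected founder-fitness variance implied by the QTL
    effects (±1/2 codes have variance 1/4) and the residual s.d.
    """
    e_idx = ENVIRONMENTS.index(env)
    var_x = sum(q[1 + e_idx] ** 2 for q in config.qtl_spec) / 4.0
    var_x += sum(e[1][e_idx] ** 2 for e in config.epistasis_spec) / 16.0
    var_x += config.fitness_residual_sd[env] ** 2
    b = config.adaptability_rule[env][1]
    me2 = config.meas_error_sd[env] ** 2
    sigma_f2 = b**2 * var_x + config.founder_effect_sd**2 + me2 / config.n_tech_reps
    sigma_p2 = config.pop_noise(env) ** 2 + me2 / config.n_pop_reps
    return sigma_f2 / (sigma_f2 + sigma_p2)
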