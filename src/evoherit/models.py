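"""Declining-adaptability, pleiotropy, and combined fitness+QTL models.

The core empirical rule is that the mean fitness gain of populations
descended from a founder declines linearly with the founder's fitness in
the evolution environment:

    ΔX̄_i = α + β·X_i + ε_i            (β < 0: declining adaptability)

Extensions fitted here: a noise-robustness variant that adds the known
measurement error back onto the predictor; a two-predictor pleiotropy model
for gains in the away environment; a combined model with the focal-locus
indicator, QTL main effects, and focal×QTL interactions selected by
Bonferroni-corrected F-tests; and the normalized-difference analysis that
tests whether adaptability tracks home-environment fitness specifically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class ModelFit:
    """A fitted linear model: term names exclude the intercept."""

    terms: list[str]
    params: pd.Series  # includes "const"
    bse: pd.Series
    pvalues: pd.Series  # raw per-term F/t p-values
    pvalues_adj: pd.Series | None
    r2: float
    n: int
    resid: np.ndarray
    flags: list[str] = field(default_factory=list)


def _fit_ols(y: np.ndarray, x: pd.DataFrame, adjust: bool = False) -> ModelFit:
    design = sm.add_constant(x, has_constant="add")
    res = sm.OLS(y, design).fit()
    terms = [t for t in design.columns if t != "const"]
    adj = None
    if adjust and terms:
        adj = (res.pvalues[terms] * len(terms)).clip(upper=1.0)
    degenerate = res.df_model == 0 or res.centered_tss == 0
    return ModelFit(
        terms=terms,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        pvalues_adj=adj,
        r2=0.0 if degenerate else float(res.rsquared),
        n=int(res.nobs),
        resid=np.asarray(res.resid),
    )


def fit_adaptability_vs_fitness(delta_mean, founder_fitness) -> ModelFit:
    """OLS of founder mean fitness increments on founder fitness."""
    y = np.asarray(delta_mean, dtype=float)
    x = np.asarray(founder_fitness, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 founders")
    if np.var(x) == 0:
        raise ValueError("zero variance in founder fitness")
    return _fit_ols(y, pd.DataFrame({"fitness": x}))


@dataclass
class NoiseRobustness:
    mean_r2: float
    sd_r2: float
    r2_draws: np.ndarray
    baseline_r2: float


def noise_robustness_fit(
    delta_mean, founder_fitness, error_vars, n_draws: int = 100,
    seed: int | None = None,
) -> NoiseRobustness:
    """Refit the adaptability regression after adding N(0, σ²_{ε,i}) noise to
    each founder's fitness, n_draws times; reports the spread of r².

    Spurious correlation control: measurement error in X also enters ΔX with
    opposite sign, so re-adding an independent copy of the error shows how
    much of the observed correlation it could generate.
    """
    y = np.asarray(delta_mean, dtype=float)
    x = np.asarray(founder_fitness, dtype=float)
    ev = np.asarray(error_vars, dtype=float)
    if np.any(ev < 0):
        raise ValueError("error variances must be >= 0")
    baseline = fit_adaptability_vs_fitness(y, x).r2
    if not np.any(ev > 0):
        draws = np.full(n_draws, baseline)
        return NoiseRobustness(baseline, 0.0, draws, baseline)
    rng = np.random.default_rng(seed)
    sd = np.sqrt(ev)
    draws = np.empty(n_draws)
    for d in range(n_draws):
        draws[d] = fit_adaptability_vs_fitness(y, x + rng.normal(0.0, sd)).r2
    return NoiseRobustness(
        mean_r2=float(draws.mean()), sd_r2=float(draws.std(ddof=1)),
        r2_draws=draws, baseline_r2=baseline,
    )


def fit_pleiotropy_model(delta_away, fitness_away, fitness_home) -> ModelFit:
    """Two-predictor OLS: away-environment gains on away and home founder
    fitness.  Flags near-collinear predictors (|corr| > 0.999)."""
    y = np.asarray(delta_away, dtype=float)
    xa = np.asarray(fitness_away, dtype=float)
    xh = np.asarray(fitness_home, dtype=float)
    fit = _fit_ols(y, pd.DataFrame({"fitness_away": xa, "fitness_home": xh}))
    if abs(np.corrcoef(xa, xh)[0, 1]) > 0.999:
        fit.flags.append("collinear")
        warnings.warn("away and home fitness are collinear (|r| > 0.999)")
    return fit


@dataclass
class CombinedFit:
    full: ModelFit
    refit: ModelFit
    significant_terms: list[str]


def fit_combined_model(
    delta_mean,
    founder_fitness,
    qtl_codes: pd.DataFrame,
    focal_code,
    alpha: float = 0.05,
) -> CombinedFit:
    """Combined fitness + QTL model with focal-locus interactions.

    Terms: founder fitness, the focal-locus indicator g* (±1/2), each QTL's
    main-effect code (±1/2), and each g*×QTL interaction.  Every non-intercept
    term's F-test p-value is Bonferroni-corrected over the tested terms; the
    model is refit once on the significant terms only.
    """
    y = np.asarray(delta_mean, dtype=float)
    gstar = np.asarray(focal_code, dtype=float)
    x = pd.DataFrame({"fitness": np.asarray(founder_fitness, dtype=float),
                      "focal": gstar})
    for col in qtl_codes.columns:
        x[f"qtl_{col}"] = qtl_codes[col].to_numpy()
        x[f"focal_x_{col}"] = gstar * qtl_codes[col].to_numpy()
    # drop aliased (duplicated/constant) columns before fitting
    flags = []
    keep = []
    seen = {}
    for col in x.columns:
        v = x[col].to_numpy()
        if np.var(v) == 0:
            flags.append(f"dropped constant term {col}")
            continue
        key = tuple(np.round(v / np.abs(v).max(), 12))
        if key in seen or tuple(-np.asarray(key)) in seen:
            flags.append(f"dropped aliased term {col} (duplicates {seen.get(key)})")
            continue
        seen[key] = col
        keep.append(col)
    if flags:
        warnings.warn("; ".join(flags))
    full = _fit_ols(y, x[keep], adjust=True)
    full.flags.extend(flags)
    sig = [t for t in full.terms if full.pvalues_adj[t] <= alpha]
    refit = _fit_ols(y, x[sig]) if sig else _fit_ols(y, x[[]])
    return CombinedFit(full=full, refit=refit, significant_terms=sig)


def normalize_traits(values, strata=None) -> np.ndarray:
    """Center and scale to unit sample s.d. (n−1), optionally within strata.

    With ``strata`` (e.g. the focal-locus allele per founder), means and
    standard deviations are taken within each stratum separately.
    """
    v = np.asarray(values, dtype=float)
    if strata is None:
        if v.size < 3:
            raise ValueError("need >= 3 values")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero standard deviation")
        return (v - v.mean()) / sd
    strata = np.asarray(strata)
    out = np.empty_like(v)
    for s in np.unique(strata):
        mask = strata == s
        if mask.sum() < 3:
            raise ValueError(f"stratum {s!r} has < 3 founders")
        sd = v[mask].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero standard deviation in stratum {s!r}")
        out[mask] = (v[mask] - v[mask].mean()) / sd
    return out


@dataclass
class DifferenceCorrelation:
    r: float
    r2: float
    p_negative: float  # one-sided bootstrap p for r < 0
    ci: tuple[float, float]  # percentile bootstrap CI on r


def difference_correlation(
    fitness_diff, increment_diff, n_boot: int = 10000, seed: int | None = None
) -> DifferenceCorrelation:
    """Correlation between X̃−Ỹ and ΔX̃−ΔỸ with bootstrap-over-founders
    inference.  A negative correlation indicates that adaptability tracks
    fitness in the home environment specifically, not a shared factor."""
    d1 = np.asarray(fitness_diff, dtype=float)
    d2 = np.asarray(increment_diff, dtype=float)
    n = d1.size
    if n < 10:
        raise ValueError("need >= 10 founders")
    r = float(np.corrcoef(d1, d2)[0, 1])
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        with np.errstate(invalid="ignore"):
            boot[b] = np.corrcoef(d1[idx], d2[idx])[0, 1]
    boot = boot[np.isfinite(boot)]
    p = (1 + int((boot >= 0).sum())) / (1 + boot.size)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return DifferenceCorrelation(r=r, r2=r * r, p_negative=float(p), ci=(float(lo), float(hi)))


def group_mean_increments(
    final_fitness: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean final fitness per (focal allele × evolution env × measured env).

    Expects a long table with columns (population_id, focal_allele,
    evolved_env, measured_env, fitness); returns the 2×2×2 cell means with
    95% bootstrap CIs over populations.  Empty cells are flagged NaN.
    """
    required = {"population_id", "focal_allele", "evolved_env", "measured_env", "fitness"}
    missing = required - set(final_fitness.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    keys = ["focal_allele", "evolved_env", "measured_env"]
    groups = dict(list(final_fitness.groupby(keys)))
    import itertools
    for combo in itertools.product(
        sorted(final_fitness["focal_allele"].unique()),
        sorted(final_fitness["evolved_env"].unique()),
        sorted(final_fitness["measured_env"].unique()),
    ):
        grp = groups.get(combo)
        if grp is None or grp.empty:
            warnings.warn(f"empty cell {combo}")
            rows.append(dict(zip(keys, combo), mean=np.nan, ci_lo=np.nan,
                             ci_hi=np.nan, n=0))
            continue
        vals = grp["fitness"].to_numpy()
        boots = np.array([
            vals[rng.integers(0, vals.size, size=vals.size)].mean()
            for _ in range(n_boot)
        ])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(dict(zip(keys, combo), mean=float(vals.mean()),
                         ci_lo=float(lo), ci_hi=float(hi), n=int(vals.size)))
    return pd.DataFrame(rows)
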