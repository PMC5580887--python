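"""Broad- and narrow-sense heritability of fitness and adaptability.

Broad-sense heritability H² partitions observed trait variance into a
founder-genotype component and a noise component (measurement error for
founder fitness; measurement error plus evolutionary stochasticity for
fitness increments).  All divisors follow the population-style 1/n
convention of the defining equations.

Narrow-sense heritability h² is estimated by REML on a standardized
genomic relationship (kinship) matrix, V = R·σ²_a + I·σ²_e, with an
intercept-only fixed effect; h² = σ̂²_a / Var(y).

Confidence intervals for either quantity come from a seeded
leave-half-out (delete-n/2) jackknife over founders.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .synthetic import GenotypeMatrix


class MonomorphicLocusError(ValueError):
    pass


@dataclass
class VarianceComponents:
    """Total / noise / founder variance partition of a trait.

    ``sigma_f2`` retains its raw (possibly negative) value; ``H2`` is NaN
    when the total variance is zero, and ``H2_clipped`` truncates to [0, 1].
    """

    sigma_t2: float
    sigma_noise2: float
    sigma_f2: float
    H2: float
    H2_clipped: float
    n: int
    ci: tuple[float, float] | None = None

    @classmethod
    def from_partition(
        cls, sigma_t2: float, sigma_noise2: float, n: int
    ) -> "VarianceComponents":
        sigma_f2 = sigma_t2 - sigma_noise2
        h2 = sigma_f2 / sigma_t2 if sigma_t2 > 0 else math.nan
        clipped = min(1.0, max(0.0, h2)) if math.isfinite(h2) else 0.0
        return cls(
            sigma_t2=float(sigma_t2), sigma_noise2=float(sigma_noise2),
            sigma_f2=float(sigma_f2), H2=float(h2), H2_clipped=float(clipped), n=n,
        )


def broad_sense_fitness(founder_means, founder_error_vars) -> VarianceComponents:
    """H² of founder fitness from per-founder means and error variances.

    σ²_t = (1/n)Σ(X_i − X̄)²; σ²_ε = (1/n)Σσ²_{ε,i}; σ²_f = σ²_t − σ²_ε.
    """
    means = np.asarray(founder_means, dtype=float)
    evars = np.asarray(founder_error_vars, dtype=float)
    if means.size < 2:
        raise ValueError("need >= 2 founders")
    if means.shape != evars.shape:
        raise ValueError("means and error variances must align")
    if np.any(evars < 0):
        raise ValueError("error variances must be nonnegative")
    sigma_t2 = np.mean((means - means.mean()) ** 2)
    sigma_e2 = evars.mean()
    return VarianceComponents.from_partition(sigma_t2, sigma_e2, n=means.size)


def broad_sense_increment(increments: Mapping[object, Sequence[float]]) -> VarianceComponents:
    """H² of the fitness increment from per-founder population values.

    σ²_p = (1/n) Σ_i [n_i/(n_i−1)] Σ_j (ΔX_ij − mean_i)² pools within-founder
    spread (measurement error plus evolutionary stochasticity); σ²_t is the
    per-population variance about the grand mean; n is the total number of
    populations.  Founders contributing a single population are excluded
    with a warning.
    """
    groups = {}
    for founder, vals in increments.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            warnings.warn(
                f"founder {founder!r} has a single population; excluded from the "
                "increment partition"
            )
            continue
        groups[founder] = vals
    if not groups:
        raise ValueError("no founder contributes >= 2 populations")
    all_vals = np.concatenate(list(groups.values()))
    n = all_vals.size
    grand = all_vals.mean()
    sigma_t2 = np.mean((all_vals - grand) ** 2)
    sigma_p2 = 0.0
    for vals in groups.values():
        ni = vals.size
        sigma_p2 += ni / (ni - 1) * np.sum((vals - vals.mean()) ** 2)
    sigma_p2 /= n
    return VarianceComponents.from_partition(sigma_t2, sigma_p2, n=n)


def increments_by_founder(populations: pd.DataFrame, value_col: str = "delta_home",
                          founder_col: str = "founder_id") -> dict:
    """Group a long population table into the mapping broad_sense_increment needs."""
    return {
        f: grp[value_col].to_numpy()
        for f, grp in populations.groupby(founder_col, sort=False)
    }


def delete_half_jackknife(
    statistic: Callable[[Sequence], float],
    founders: Sequence,
    n_resamples: int = 1000,
    seed: int | None = None,
    max_failure_frac: float = 0.2,
) -> tuple[float, float]:
    """95% CI from leave-n/2-out resampling over founders.

    ``statistic`` is called with a subset of ``founders`` of size ⌈n/2⌉; the
    interval is the 2.5–97.5 percentile range of the resample distribution.
    Subsets on which the statistic raises are dropped; more than
    ``max_failure_frac`` failures is an error.
    """
    founders = list(founders)
    n = len(founders)
    if n < 4:
        raise ValueError("need >= 4 founders for the delete-half jackknife")
    rng = np.random.default_rng(seed)
    k = math.ceil(n / 2)
    vals = []
    failures = 0
    for _ in range(n_resamples):
        idx = rng.choice(n, size=k, replace=False)
        subset = [founders[i] for i in idx]
        try:
            v = statistic(subset)
        except Exception:
            failures += 1
            continue
        if v is not None and math.isfinite(v):
            vals.append(v)
        else:
            failures += 1
    if failures > max_failure_frac * n_resamples:
        raise RuntimeError(
            f"statistic failed on {failures}/{n_resamples} jackknife subsets"
        )
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# kinship and REML


@dataclass
class KinshipMatrix:
    founders: list
    values: np.ndarray  # symmetric founders × founders

    def subset(self, idx: Sequence[int]) -> "KinshipMatrix":
        idx = np.asarray(idx)
        return KinshipMatrix(
            founders=[self.founders[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
        )


def standardized_genotypes(geno: GenotypeMatrix) -> np.ndarray:
    """Per-locus standardized codes g_ik = (allele_ik − p_k)/√(m·p_k·(1−p_k)),
    where p_k is the BY-allele frequency and m the locus count (BY alleles get
    (1−p), RM alleles −p, before scaling)."""
    p = geno.by_frequency()
    mono = (p == 0.0) | (p == 1.0)
    if mono.any():
        k = int(np.flatnonzero(mono)[0])
        raise MonomorphicLocusError(
            f"monomorphic locus at {geno.chrom[k]}:{geno.pos[k]} (index {k}); "
            "exclude monomorphic loci before building kinship"
        )
    m = geno.n_loci
    return (geno.alleles - p) / np.sqrt(m * p * (1.0 - p))


def kinship_matrix(geno: GenotypeMatrix) -> KinshipMatrix:
    """Genomic relationship matrix R = G·Gᵀ from standardized genotypes."""
    g = standardized_genotypes(geno)
    r = g @ g.T
    r = (r + r.T) / 2.0
    return KinshipMatrix(founders=list(geno.founders), values=r)


@dataclass
class REMLResult:
    h2: float
    sigma_a2: float
    sigma_e2: float
    loglik: float
    ratio: float  # σ²_a / (σ²_a + σ²_e) at the optimum
    boundary: bool
    ci: tuple[float, float] | None = None


def reml_loglik(trait, kinship: KinshipMatrix, sigma_a2: float, sigma_e2: float) -> float:
    """Restricted log-likelihood of V = R·σ²_a + I·σ²_e with an intercept."""
    y = np.asarray(trait, dtype=float)
    lam, u = np.linalg.eigh(kinship.values)
    return _reml_loglik_rotated(u.T @ y, u.T @ np.ones_like(y), lam, sigma_a2, sigma_e2)


def _reml_loglik_rotated(yt, xt, lam, sigma_a2, sigma_e2) -> float:
    d = sigma_a2 * lam + sigma_e2
    if np.any(d <= 0):
        return -np.inf
    xtv = xt**2 / d
    sx = xtv.sum()
    beta = (xt * yt / d).sum() / sx
    resid = yt - xt * beta
    quad = (resid**2 / d).sum()
    n = yt.size
    return -0.5 * (np.log(d).sum() + np.log(sx) + quad + (n - 1) * np.log(2 * np.pi))


def narrow_sense_reml(
    trait,
    kinship: KinshipMatrix,
    tol: float = 1e-6,
    boundary_eps: float = 1e-4,
) -> REMLResult:
    """REML fit of the additive variance on a kinship matrix.

    The restricted likelihood is profiled over the total variance and
    maximized over the variance ratio h = σ²_a/(σ²_a+σ²_e) ∈ [0, 1] by
    bounded 1-D search on the eigenbasis of R.  h² = σ̂²_a / Var(y) with the
    sample (n−1) variance of the trait.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if n < 20:
        raise ValueError("need >= 20 founders for REML")
    if len(kinship.founders) != n:
        raise ValueError("kinship and trait must share founder order")
    lam, u = np.linalg.eigh(kinship.values)
    lam = np.maximum(lam, 0.0)
    yt = u.T @ y
    xt = u.T @ np.ones(n)

    def profiled(h):
        # weights of V/σ²_tot; σ²_tot profiled out analytically
        d = h * lam + (1.0 - h)
        if np.any(d <= 0):
            return np.inf
        xtv = xt**2 / d
        sx = xtv.sum()
        beta = (xt * yt / d).sum() / sx
        quad = ((yt - xt * beta) ** 2 / d).sum()
        s2 = quad / (n - 1)
        return 0.5 * (np.log(d).sum() + np.log(sx) + (n - 1) * (1.0 + np.log(2 * np.pi * s2)))

    res = minimize_scalar(profiled, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                          options={"xatol": tol})
    if not res.success:
        raise RuntimeError(f"REML optimization did not converge: {res.message}")
    h = float(res.x)
    d = h * lam + (1.0 - h)
    sx = (xt**2 / d).sum()
    beta = (xt * yt / d).sum() / sx
    s2 = ((yt - xt * beta) ** 2 / d).sum() / (n - 1)
    sigma_a2 = h * s2
    sigma_e2 = (1.0 - h) * s2
    vary = y.var(ddof=1)
    return REMLResult(
        h2=float(sigma_a2 / vary),
        sigma_a2=float(sigma_a2),
        sigma_e2=float(sigma_e2),
        loglik=float(_reml_loglik_rotated(yt, xt, lam, sigma_a2, sigma_e2)),
        ratio=h,
        boundary=bool(h < boundary_eps or h > 1.0 - boundary_eps),
    )


def narrow_sense_with_ci(
    trait: pd.Series,
    geno: GenotypeMatrix,
    n_resamples: int = 200,
    seed: int | None = None,
) -> REMLResult:
    """REML h² with a delete-half jackknife CI; the panel allele frequencies
    (hence the kinship standardization) are fixed from the full panel."""
    trait = trait.loc[geno.founders]
    kin = kinship_matrix(geno)
    full = narrow_sense_reml(trait.to_numpy(), kin)
    index = {f: i for i, f in enumerate(geno.founders)}

    def stat(subset):
        idx = [index[f] for f in subset]
        return narrow_sense_reml(trait.to_numpy()[idx], kin.subset(idx)).h2

    full.ci = delete_half_jackknife(stat, geno.founders, n_resamples=n_resamples,
                                    seed=seed)
    return full
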