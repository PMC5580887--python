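"""Iterative forward QTL detection with LOD scores and permutation thresholds.

At each iteration the trait is residualized on the QTLs already found
(ordinary least squares on ±1/2 allele codes), every locus is scored by the
weighted Pearson correlation between its allele code and the residuals,

    LOD_ℓ = −(n/2)·log10(1 − r²_ℓ),

and the genome-wide maximum is tested against a permutation null (residual
values permuted, weights kept attached to the genotypes).  Detection stops
when the top locus is no longer significant.  Each hit carries a positional
confidence interval from a 1.5-LOD decline on its chromosome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import GenotypeMatrix


@dataclass
class QTLHit:
    locus: int  # column index into the genotype matrix
    chrom: str
    pos: int  # 1-based peak position
    lod: float
    p_value: float
    ci_lo: int  # 1-based, inclusive
    ci_hi: int
    effect: float  # additive effect from the joint OLS fit over all hits
    r2: float  # squared correlation with the residual trait at detection
    perfect_fit: bool = False  # r² = 1 at the peak (LOD infinite)


def weighted_pearson(x, y, weights) -> float:
    """Pearson correlation with observation weights.

    Moments are taken with normalized weights; equal weights reduce exactly
    to the unweighted correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (x.shape == y.shape == w.shape) or x.size < 3:
        raise ValueError("x, y, weights must share length >= 3")
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    w = w / w.sum()
    xm = x - (w * x).sum()
    ym = y - (w * y).sum()
    vx = (w * xm**2).sum()
    vy = (w * ym**2).sum()
    if vx == 0 or vy == 0:
        raise ZeroDivisionError("zero weighted variance; correlation undefined")
    r = (w * xm * ym).sum() / math.sqrt(vx * vy)
    return float(min(1.0, max(-1.0, r)))


def lod_score(r2: float, n_g: int) -> float:
    """LOD = −(n_g/2)·log10(1 − r²); infinite (flagged by the caller) at r²=1."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    if n_g < 2:
        raise ValueError("n_g must be >= 2")
    if r2 == 1.0:
        return math.inf
    return -(n_g / 2.0) * math.log10(1.0 - r2)


def _profile_r2(codes: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Squared weighted correlation of each genotype column with y (vectorized).

    Zero-variance (monomorphic) columns get r² = 0.
    """
    w = w / w.sum()
    ym = y - (w * y).sum()
    vy = (w * ym**2).sum()
    colmean = w @ codes
    xm = codes - colmean
    cov = (w * ym) @ xm
    vx = w @ (xm**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((vx > 0) & (vy > 0), cov**2 / (vx * vy), 0.0)
    return np.clip(r2, 0.0, 1.0)


def _ols_residuals(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and coefficients of unweighted OLS with an intercept."""
    x = np.column_stack([np.ones_like(y), design]) if design.size else np.ones((y.size, 1))
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef, coef


def forward_scan(
    geno: GenotypeMatrix,
    trait,
    weights=None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    max_qtls: int = 20,
) -> list[QTLHit]:
    """Iterative genome scan; returns the significant hits in detection order."""
    y = np.asarray(trait, dtype=float)
    if y.size != geno.n_founders:
        raise ValueError("trait and genotypes must align")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    codes = geno.codes()
    poly = ~geno.monomorphic_mask()
    if not poly.any():
        raise ValueError("no polymorphic loci to scan")
    n = y.size
    rng = np.random.default_rng(seed)
    hits: list[QTLHit] = []

    while len(hits) < max_qtls:
        detected = codes[:, [h.locus for h in hits]] if hits else np.empty((n, 0))
        resid, _ = _ols_residuals(y, detected)
        r2 = _profile_r2(codes, resid, w)
        r2[~poly] = 0.0
        peak = int(np.argmax(r2))  # argmax takes the lowest index on ties
        peak_r2 = float(r2[peak])
        peak_lod = lod_score(peak_r2, n)
        # genome-wide permutation null for the max-LOD statistic
        exceed = 0
        for _ in range(n_perm):
            perm_r2 = _profile_r2(codes, rng.permutation(resid), w)
            perm_r2[~poly] = 0.0
            if perm_r2.max() >= peak_r2:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        if p > alpha:
            break
        on_chrom = geno.chrom == geno.chrom[peak]
        lods = np.where(
            on_chrom, [lod_score(min(v, 1.0 - 1e-300), n) for v in r2], -np.inf
        )
        ci_lo, ci_hi = _lod_interval(lods, peak, peak_lod, on_chrom)
        hits.append(
            QTLHit(
                locus=peak,
                chrom=str(geno.chrom[peak]),
                pos=int(geno.pos[peak]),
                lod=peak_lod,
                p_value=p,
                ci_lo=int(geno.pos[ci_lo]),
                ci_hi=int(geno.pos[ci_hi]),
                effect=math.nan,
                r2=peak_r2,
                perfect_fit=bool(peak_r2 >= 1.0),
            )
        )
        if peak_r2 >= 1.0:
            warnings.warn("trait is an exact copy of a locus code; r²=1 at the peak")
            break

    if hits:
        _, coef = _ols_residuals(y, codes[:, [h.locus for h in hits]])
        for h, a in zip(hits, coef[1:]):
            h.effect = float(a)
    return hits


def _lod_interval(lods, peak, peak_lod, on_chrom) -> tuple[int, int]:
    """Maximal contiguous locus run on the peak chromosome with LOD ≥ peak−1.5."""
    thresh = peak_lod - 1.5
    ok = (lods >= thresh) & on_chrom
    lo = peak
    while lo - 1 >= 0 and ok[lo - 1]:
        lo -= 1
    hi = peak
    while hi + 1 < len(ok) and ok[hi + 1]:
        hi += 1
    return lo, hi


def additive_model_r2(geno: GenotypeMatrix, loci, trait, weights=None) -> float:
    """Coefficient of determination of the (weighted) least-squares fit of the
    trait on the ±1/2 codes of the given QTL set."""
    loci = list(loci)
    if not loci:
        raise ValueError("QTL set must be nonempty")
    y = np.asarray(trait, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    x = np.column_stack([np.ones_like(y), geno.codes()[:, loci]])
    # drop collinear predictors by rank-revealing QR via lstsq on weighted system
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(sw[:, None] * x, sw * y, rcond=None)
    if rank < x.shape[1]:
        warnings.warn("collinear QTL predictors; aliased terms effectively dropped")
    fitted = x @ coef
    wmean = (w * y).sum() / w.sum()
    ss_res = (w * (y - fitted) ** 2).sum()
    ss_tot = (w * (y - wmean) ** 2).sum()
    return float(1.0 - ss_res / ss_tot)
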