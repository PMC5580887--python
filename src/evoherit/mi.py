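"""Mutual-information association test between population labels and de novo
mutation incidence.

For each gene g with binary incidence indicator m across populations and a
categorical population label W (e.g. the focal-locus allele, the evolution
environment, or the founder), the mutual information in bits is

    I(W, g) = Σ_w p(w) Σ_m p(m|w) log2[ p(m|w) / p(m) ],

optionally conditioned on further labels Z (averaging the within-stratum
information with weights p(Z)).  The test statistic sums I over a gene set
(default: the multi-hit genes), and its null distribution is obtained by
permuting mutation events among populations while holding each population's
event count fixed, then re-binarizing — so both the per-population counts
and the pooled gene-label multiset are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MutationMatrix:
    """Binary populations × genes incidence plus the underlying event lists.

    ``event_genes``/``event_pops`` give one entry per mutation event (all
    events, including genes outside the scored universe, so the permutation
    null conserves total per-population mutation counts).
    """

    populations: list[str]
    genes: list[str]
    incidence: np.ndarray  # populations × genes, {0,1}
    event_pops: np.ndarray  # population index per event
    event_genes: np.ndarray  # gene label per event (string, any gene)

    def __post_init__(self) -> None:
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        counts = np.bincount(self.event_pops, minlength=len(self.populations))
        if (self.incidence.sum(axis=1) > counts).any():
            raise ValueError("per-population event counts must be >= incidence row sums")

    @property
    def event_counts(self) -> np.ndarray:
        return np.bincount(self.event_pops, minlength=len(self.populations))

    @classmethod
    def from_events(
        cls, populations: list[str], events: pd.DataFrame, genes: list[str]
    ) -> "MutationMatrix":
        """Build from an event table with columns (population_id, gene).

        ``populations`` fixes row order (and includes populations with zero
        events); ``genes`` fixes the scored gene universe.
        """
        pop_index = {p: i for i, p in enumerate(populations)}
        missing = set(events["population_id"]) - set(pop_index)
        if missing:
            raise KeyError(f"events reference unknown populations: {sorted(missing)}")
        event_pops = events["population_id"].map(pop_index).to_numpy(dtype=int)
        event_genes = events["gene"].to_numpy(dtype=object)
        incidence = _binarize(event_pops, event_genes, len(populations), genes)
        return cls(
            populations=list(populations), genes=list(genes),
            incidence=incidence, event_pops=event_pops, event_genes=event_genes,
        )


def _gene_indices(event_genes, genes) -> np.ndarray:
    """Index of each event's gene in the scored universe (−1 if outside)."""
    gene_index = {g: j for j, g in enumerate(genes)}
    return np.array([gene_index.get(g, -1) for g in event_genes], dtype=int)


def _binarize_idx(event_pops, gene_idx, n_pops, n_genes) -> np.ndarray:
    inc = np.zeros((n_pops, n_genes), dtype=np.int8)
    ok = gene_idx >= 0
    inc[event_pops[ok], gene_idx[ok]] = 1
    return inc


def _binarize(event_pops, event_genes, n_pops, genes) -> np.ndarray:
    return _binarize_idx(event_pops, _gene_indices(event_genes, genes),
                         n_pops, len(genes))


def _codes(labels) -> np.ndarray:
    return pd.factorize(np.asarray(labels))[0]


def _strata(condition) -> np.ndarray:
    """Combine one or several conditioning label vectors into stratum codes."""
    if condition is None:
        return None
    if isinstance(condition, (list, tuple)) and len(condition) and not np.isscalar(condition[0]):
        frame = pd.DataFrame({i: np.asarray(c) for i, c in enumerate(condition)})
        return pd.factorize(frame.apply(tuple, axis=1))[0]
    return _codes(condition)


def _per_gene_information(
    incidence: np.ndarray, w: np.ndarray, z: np.ndarray | None
) -> np.ndarray:
    """I(W, g | Z) in bits for every gene column, vectorized over genes."""
    n = incidence.shape[0]
    if z is None:
        z = np.zeros(n, dtype=int)
    info = np.zeros(incidence.shape[1])
    for zs in np.unique(z):
        zmask = z == zs
        nz = int(zmask.sum())
        if nz == 0:
            continue
        pz = nz / n
        p_m1_z = incidence[zmask].mean(axis=0)  # p(m=1 | z) per gene
        stratum = np.zeros(incidence.shape[1])
        for ws in np.unique(w[zmask]):
            wmask = zmask & (w == ws)
            nw = int(wmask.sum())
            pw = nw / nz
            p_m1_wz = incidence[wmask].mean(axis=0)
            for pm_wz, pm_z in ((p_m1_wz, p_m1_z), (1.0 - p_m1_wz, 1.0 - p_m1_z)):
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = pm_wz * np.log2(pm_wz / pm_z)
                stratum += pw * np.where(pm_wz > 0, term, 0.0)
        info += pz * stratum
    return np.maximum(info, 0.0)  # clip tiny negative float error


def mutual_information(labels, gene_column, condition=None) -> float:
    """I(W, g) (or I(W, g | Z)) in bits for one gene's incidence column."""
    m = np.asarray(gene_column, dtype=np.int8).reshape(-1, 1)
    return float(_per_gene_information(m, _codes(labels), _strata(condition))[0])


def mi_statistic(labels, matrix: MutationMatrix, condition=None) -> tuple[float, pd.Series]:
    """M = Σ_genes I(W, g | Z); returns the total and per-gene contributions."""
    per_gene = _per_gene_information(matrix.incidence, _codes(labels), _strata(condition))
    series = pd.Series(per_gene, index=matrix.genes, name="information_bits")
    return float(per_gene.sum()), series


@dataclass
class MIResult:
    statistic: float  # observed M
    null_mean: float
    centered: float  # M − null mean (the reported quantity)
    null_interval: tuple[float, float]  # 95% of the null distribution
    p_value: float
    per_gene: pd.Series
    n_perm: int


def permutation_null(
    labels, matrix: MutationMatrix, condition=None, n_perm: int = 10000,
    seed: int | None = None,
) -> MIResult:
    """Count-preserving permutation test of M.

    Each permutation shuffles the pooled multiset of event gene labels and
    deals them back to populations in their original event counts, then
    re-binarizes; p = (1 + #{null M ≥ observed}) / (1 + n_perm).
    """
    if matrix.event_pops.size == 0:
        raise ValueError("no mutation events; the permutation null is undefined")
    w = _codes(labels)
    z = _strata(condition)
    observed, per_gene = mi_statistic(labels, matrix, condition)
    rng = np.random.default_rng(seed)
    n_pops = len(matrix.populations)
    null = np.empty(n_perm)
    gene_idx = _gene_indices(matrix.event_genes, matrix.genes)
    n_genes = len(matrix.genes)
    for b in range(n_perm):
        shuffled = gene_idx[rng.permutation(gene_idx.size)]
        inc = _binarize_idx(matrix.event_pops, shuffled, n_pops, n_genes)
        null[b] = _per_gene_information(inc, w, z).sum()
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return MIResult(
        statistic=observed,
        null_mean=float(null.mean()),
        centered=float(observed - null.mean()),
        null_interval=(float(lo), float(hi)),
        p_value=float(p),
        per_gene=per_gene,
        n_perm=n_perm,
    )


def hierarchical_analysis(
    focal_allele, environment, founder, matrix: MutationMatrix,
    n_perm: int = 10000, seed: int | None = None,
) -> pd.DataFrame:
    """The nested label analysis: M(focal), M(environment | focal), and
    M(founder | focal, environment), each against its permutation null."""
    analyses = [
        ("focal_allele", focal_allele, None),
        ("environment|focal", environment, focal_allele),
        ("founder|focal,environment", founder, (focal_allele, environment)),
    ]
    rows = []
    for i, (name, w, z) in enumerate(analyses):
        res = permutation_null(w, matrix, condition=z, n_perm=n_perm,
                               seed=None if seed is None else seed + i)
        rows.append(
            {"analysis": name, "statistic": res.statistic,
             "null_mean": res.null_mean, "centered": res.centered,
             "null_lo": res.null_interval[0], "null_hi": res.null_interval[1],
             "p_value": res.p_value}
        )
    return pd.DataFrame(rows)
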