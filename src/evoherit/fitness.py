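"""Relative-fitness estimation from competitive flow-cytometry counts.

A strain's fitness is measured by competing it against a fluorescent
reference and counting both types at two timepoints τ generations apart:

    s = (1/τ) · ln[ ((n_ef − p·n_rf) / n_rf) · (n_ri / (n_ei − p·n_ri)) ]

where p is the non-fluorescent proportion of reference cells (p > 0 corrects
for reference cells miscounted as the query strain; p = 0 recovers the plain
log-ratio estimator).  Defaults: p = 0.015 in the high-temperature (HT)
assay, p = 0 at optimal temperature (OT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default non-fluorescent reference fraction per assay environment
DEFAULT_NONFLUORESCENT = {"OT": 0.0, "HT": 0.015}


class CompetitionDomainError(ValueError):
    """Corrected count is non-positive; the estimator is undefined."""


@dataclass(frozen=True)
class CompetitionCounts:
    """Cell counts of a single competition assay.

    Counts may be nonnegative reals (flow proportions × totals), not only
    integers.
    """

    ne_i: float  # evolved/query cells, initial timepoint
    nr_i: float  # reference cells, initial timepoint
    ne_f: float  # evolved/query cells, final timepoint
    nr_f: float  # reference cells, final timepoint
    tau: float  # elapsed generations between the timepoints
    p: float = 0.0  # non-fluorescent proportion of reference cells

    def __post_init__(self) -> None:
        for name in ("ne_i", "nr_i", "ne_f", "nr_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0.0 <= self.p < 1.0:
            raise ValueError("p must lie in [0, 1)")


def estimate_fitness(counts: CompetitionCounts) -> float:
    """Per-generation selection coefficient of the query strain vs reference."""
    ce_i = counts.ne_i - counts.p * counts.nr_i
    ce_f = counts.ne_f - counts.p * counts.nr_f
    if ce_i <= 0:
        raise CompetitionDomainError(
            f"corrected query count at the initial timepoint is {ce_i:g} <= 0"
        )
    if ce_f <= 0:
        raise CompetitionDomainError(
            f"corrected query count at the final timepoint is {ce_f:g} <= 0"
        )
    return math.log((ce_f / counts.nr_f) * (counts.nr_i / ce_i)) / counts.tau


def counts_for_fitness(
    s: float,
    tau: float,
    p: float = 0.0,
    n_initial: float = 15000.0,
    n_reference: float = 15000.0,
) -> CompetitionCounts:
    """Competition counts exactly consistent with fitness ``s`` (round-trip
    inverse of :func:`estimate_fitness`; reference counts held constant)."""
    ne_f = p * n_reference + (n_initial - p * n_reference) * math.exp(s * tau)
    return CompetitionCounts(
        ne_i=n_initial, nr_i=n_reference, ne_f=ne_f, nr_f=n_reference, tau=tau, p=p
    )


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    error_var: float  # variance of the mean by default (see summarize_replicates)
    n_reps: int


def summarize_replicates(values, of_mean: bool = True) -> ReplicateSummary:
    """Mean fitness and its error variance from ≥ 2 technical replicates.

    With ``of_mean`` (default), the error variance is the unbiased sample
    variance divided by the number of replicates — the variance of the mean
    estimate, which is what the broad-sense variance partition subtracts.
    ``of_mean=False`` returns the raw replicate sample variance instead.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 replicate values to estimate error variance")
    var = values.var(ddof=1)
    return ReplicateSummary(
        mean=float(values.mean()),
        error_var=float(var / values.size if of_mean else var),
        n_reps=int(values.size),
    )


def fitness_from_competitions(
    table: pd.DataFrame,
    tau_per_day: dict[str, float] | None = None,
    p_nonfluor: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-assay fitness from a long competition-count table.

    Expects columns (population_id, environment, timepoint_day, count_evolved,
    count_reference) with exactly two timepoints per (population, environment).
    τ is (day difference) × generations/day (default 10 at OT, 9 at HT).
    """
    tau_per_day = tau_per_day or {"OT": 10.0, "HT": 9.0}
    p_nonfluor = p_nonfluor or dict(DEFAULT_NONFLUORESCENT)
    rows = []
    for (pop, env), grp in table.groupby(["population_id", "environment"], sort=False):
        grp = grp.sort_values("timepoint_day")
        if len(grp) != 2:
            raise ValueError(
                f"expected 2 timepoints for ({pop}, {env}), got {len(grp)}"
            )
        first, last = grp.iloc[0], grp.iloc[1]
        tau = (last["timepoint_day"] - first["timepoint_day"]) * tau_per_day[env]
        counts = CompetitionCounts(
            ne_i=first["count_evolved"], nr_i=first["count_reference"],
            ne_f=last["count_evolved"], nr_f=last["count_reference"],
            tau=tau, p=p_nonfluor[env],
        )
        rows.append(
            {"population_id": pop, "environment": env,
             "fitness": estimate_fitness(counts)}
        )
    return pd.DataFrame(rows)
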