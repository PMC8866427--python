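"""Monte-Carlo error grids: condition x interval x method x replicate.

For each simulation family (behaviour *frequency* with 1-s events every
f in {3, 30, 300} s, or behaviour *duration* with one d in {3, 30, 300} s
bout per 600-s block) the grid simulates ``n_reps`` independent hours per
condition and samples **each** hour with both recording methods at every
interval length — the method comparison is paired within replicate, which
is what makes the downstream paired Wilcoxon tests well defined.

The per-replicate quantity of interest is the signed error
``estimate - truth`` of the activity-budget proportion.  Each
(condition, interval, method) cell is summarized by its mean error and the
empirical 2.5th / 97.5th percentiles of the replicate errors (a 95%
percentile interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .sampling import RecordingMethod, SamplingPlan, one_zero_estimate, pinpoint_estimate
from .streams import (
    ConfigurationError,
    EventProcessConfig,
    ObservationConfig,
    OccupancyStream,
    StateProcessConfig,
    replicate_rng,
    simulate_event_stream,
    simulate_state_stream,
    true_occupancy_proportion,
)

__all__ = [
    "Family",
    "EstimateRecord",
    "ConditionSummary",
    "signed_error",
    "summarize_condition",
    "analytic_event_one_zero_error",
    "run_condition_grid",
    "summarize_grid",
]

Family = Literal["frequency", "duration"]
_FAMILY_CODE = {"frequency": 0, "duration": 1}

TIDY_COLUMNS = [
    "family",
    "condition",
    "interval",
    "method",
    "replicate",
    "estimate",
    "truth",
    "error",
]


@dataclass(frozen=True)
class EstimateRecord:
    """One replicate's estimate for one (condition, interval, method) cell."""

    simulation_family: str
    condition: int
    interval_L: int
    method: RecordingMethod
    replicate_index: int
    estimate: float
    truth: float
    error: float


@dataclass(frozen=True)
class ConditionSummary:
    """Mean error and 95% percentile interval over replicates for one cell."""

    simulation_family: str
    condition: int
    interval_L: int
    method: RecordingMethod
    n_reps: int
    mean_error: float
    pct_2_5: float
    pct_97_5: float


def signed_error(estimate: float, truth: float) -> float:
    """Signed estimation error ``estimate - truth`` in [-1, 1]."""
    if not (0.0 <= estimate <= 1.0 and 0.0 <= truth <= 1.0):
        raise ValueError("estimate and truth must both lie in [0, 1]")
    return estimate - truth


def summarize_condition(
    errors: Sequence[float],
    n_reps: int | None = None,
    quantile_method: str = "linear",
) -> tuple[float, float, float]:
    """Mean and empirical 2.5th / 97.5th percentiles of replicate errors.

    Percentiles use linear interpolation between order statistics by
    default; ``quantile_method`` accepts any numpy quantile method name.
    Returns ``(mean, pct_2_5, pct_97_5)``.
    """
    arr = np.asarray(errors, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty error sequence")
    if n_reps is not None and arr.size != n_reps:
        raise ValueError(f"expected {n_reps} errors, got {arr.size}")
    lo, hi = np.percentile(arr, [2.5, 97.5], method=quantile_method)
    return float(arr.mean()), float(lo), float(hi)


def analytic_event_one_zero_error(f: int, L: int, T: int = 3600) -> float | None:
    """Closed-form one-zero error for 1-s events, where one exists.

    Two regimes admit an exact, zero-variance answer:

    * every interval (including a trailing partial one) contains at least
      one complete f-block, so every interval is scored: error = 1 - 1/f;
    * L < f with L dividing f: block and interval boundaries align, each
      event scores exactly one interval, so the estimate is L/f and the
      error (L - 1)/f.

    Returns ``None`` when neither regime applies (no closed form).
    """
    if T % f != 0:
        raise ConfigurationError(f"f={f} must divide T={T}")
    if L < 1 or L > T:
        raise ConfigurationError(f"L must be in [1, {T}], got {L}")
    if L >= f:
        starts = np.arange(0, T, L)
        stops = np.minimum(starts + L, T)
        # interval [a, b) contains a full block iff ceil(a/f)*f + f <= b
        first_block_end = (-(-starts // f)) * f + f
        if np.all(first_block_end <= stops):
            return 1.0 - 1.0 / f
        return None
    if f % L == 0:
        return (L - 1) / f
    return None


def _simulate(
    family: Family, condition: int, total_seconds: int, offset_support: str, rng
) -> OccupancyStream:
    obs = ObservationConfig(total_seconds=total_seconds)
    if family == "frequency":
        return simulate_event_stream(obs, EventProcessConfig(block_length_f=condition), rng=rng)
    return simulate_state_stream(
        obs,
        StateProcessConfig(state_duration_d=condition, offset_support=offset_support),
        rng=rng,
    )


def run_condition_grid(
    family: Family,
    conditions: Iterable[int] = (3, 30, 300),
    intervals: Iterable[int] = (5, 50, 500),
    n_reps: int = 100,
    total_seconds: int = 3600,
    base_seed: int = 0,
    offset_support: str = "exclusive",
    pinpoint_at: str = "start",
) -> pd.DataFrame:
    """Run the full grid for one family and return tidy replicate records.

    Each replicate stream is simulated once per condition and sampled by
    both methods at every interval length (paired design).  With the
    defaults this yields 3 x 3 x 100 = 900 sampled data sets per method.

    Returns a DataFrame with one row per
    (condition, interval, method, replicate).
    """
    if family not in _FAMILY_CODE:
        raise ConfigurationError(f"unknown simulation family {family!r}")
    conditions = list(conditions)
    intervals = list(intervals)
    if not conditions or not intervals or n_reps < 1:
        raise ConfigurationError("conditions, intervals must be non-empty and n_reps >= 1")
    fam_code = _FAMILY_CODE[family]

    rows: list[tuple] = []
    for condition in conditions:
        for rep in range(n_reps):
            rng = replicate_rng(base_seed, fam_code, condition, rep)
            stream = _simulate(family, condition, total_seconds, offset_support, rng)
            truth = true_occupancy_proportion(stream)
            for L in intervals:
                pp = pinpoint_estimate(
                    stream, SamplingPlan(RecordingMethod.PINPOINT, L, pinpoint_at=pinpoint_at)
                )
                oz = one_zero_estimate(stream, SamplingPlan(RecordingMethod.ONE_ZERO, L))
                for method, est in (
                    (RecordingMethod.PINPOINT, pp),
                    (RecordingMethod.ONE_ZERO, oz),
                ):
                    rows.append(
                        (family, condition, L, method.value, rep, est, truth, signed_error(est, truth))
                    )
    tidy = pd.DataFrame(rows, columns=TIDY_COLUMNS)
    # sanity: the grid size contract (cells x reps per method)
    expected = len(conditions) * len(intervals) * n_reps
    assert (tidy["method"] == "one_zero").sum() == expected
    return tidy


def summarize_grid(tidy: pd.DataFrame, quantile_method: str = "linear") -> pd.DataFrame:
    """Collapse tidy replicate records into per-cell summaries.

    One row per (family, condition, interval, method) with the replicate
    count, mean error, and the 2.5 / 97.5 empirical error percentiles.
    """

    def _agg(group: pd.DataFrame) -> pd.Series:
        mean, lo, hi = summarize_condition(group["error"].to_numpy(), quantile_method=quantile_method)
        return pd.Series(
            {
                "truth": group["truth"].mean(),
                "n_reps": len(group),
                "mean_error": mean,
                "pct_2_5": lo,
                "pct_97_5": hi,
            }
        )

    out = (
        tidy.groupby(["family", "condition", "interval", "method"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_reps"] = out["n_reps"].astype(int)
    return out
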