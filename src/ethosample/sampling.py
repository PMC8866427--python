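"""Pinpoint and one-zero recording rules applied to occupancy streams.

Both rules partition the observation ``[0, T)`` into ``ceil(T/L)``
half-open intervals of length ``L`` (the final interval may be shorter and
is kept as a regular interval):

* **pinpoint** (instantaneous / momentary time sampling): occupancy is
  read at the first second of each interval, i.e. at instants ``t = k*L``;
  the estimate is the fraction of instants at which the behaviour was
  observed.
* **one-zero** (partial-interval recording, PIR): an interval scores 1 if
  the behaviour occupies at least one second of it; the estimate is the
  unweighted fraction of scored intervals.

Both estimates are therefore quantized to multiples of ``1/ceil(T/L)``.
One-zero can never underestimate the true proportion, because each scored
interval contains at most L occupied seconds and ``ceil(T/L)*L >= T``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Literal

import numpy as np

from .streams import ConfigurationError, OccupancyStream

__all__ = [
    "RecordingMethod",
    "SamplingPlan",
    "IntervalPartition",
    "build_interval_partition",
    "pinpoint_estimate",
    "one_zero_estimate",
    "apply_plan",
]


class RecordingMethod(str, Enum):
    PINPOINT = "pinpoint"
    ONE_ZERO = "one_zero"


@dataclass(frozen=True)
class SamplingPlan:
    """Recording rule plus interval length.

    ``pinpoint_at`` selects the instant sampled within each interval:
    its first second (``"start"``, default) or its last (``"end"``).
    """

    method: RecordingMethod
    interval_L: int
    pinpoint_at: Literal["start", "end"] = "start"

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", RecordingMethod(self.method))
        if self.interval_L < 1:
            raise ConfigurationError(
                f"interval_L must be >= 1, got {self.interval_L}"
            )
        if self.pinpoint_at not in ("start", "end"):
            raise ConfigurationError(
                f"pinpoint_at must be 'start' or 'end', got {self.pinpoint_at!r}"
            )


@dataclass(frozen=True)
class IntervalPartition:
    """Contiguous half-open second ranges covering ``[0, T)`` exactly."""

    starts: np.ndarray
    stops: np.ndarray

    @property
    def n_intervals(self) -> int:
        return int(self.starts.size)


def build_interval_partition(total_seconds: int, interval_L: int) -> IntervalPartition:
    """Partition ``[0, T)`` into ``ceil(T/L)`` ranges; the last may be short."""
    if interval_L < 1 or interval_L > total_seconds:
        raise ConfigurationError(
            f"interval_L must be in [1, {total_seconds}], got {interval_L}"
        )
    starts = np.arange(0, total_seconds, interval_L)
    stops = np.minimum(starts + interval_L, total_seconds)
    return IntervalPartition(starts=starts, stops=stops)


def _check_plan(stream: OccupancyStream, plan: SamplingPlan, method: RecordingMethod) -> IntervalPartition:
    if plan.method is not method:
        raise ConfigurationError(
            f"plan method is {plan.method.value!r}, expected {method.value!r}"
        )
    return build_interval_partition(stream.total_seconds, plan.interval_L)


def pinpoint_estimate(stream: OccupancyStream, plan: SamplingPlan) -> float:
    """Fraction of sampled instants at which the behaviour occurred."""
    part = _check_plan(stream, plan, RecordingMethod.PINPOINT)
    if plan.pinpoint_at == "start":
        instants = part.starts
    else:
        instants = part.stops - 1
    return float(stream.occupancy[instants].mean())


def one_zero_estimate(stream: OccupancyStream, plan: SamplingPlan) -> float:
    """Unweighted fraction of intervals containing any occupied second."""
    part = _check_plan(stream, plan, RecordingMethod.ONE_ZERO)
    # reduceat sums each [start, next start); last segment runs to T
    counts = np.add.reduceat(stream.occupancy.astype(np.int64), part.starts)
    return float((counts > 0).mean())


def apply_plan(stream: OccupancyStream, plan: SamplingPlan) -> float:
    """Dispatch on the plan's recording method."""
    if plan.method is RecordingMethod.PINPOINT:
        return pinpoint_estimate(stream, plan)
    return one_zero_estimate(stream, plan)
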