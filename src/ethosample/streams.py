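"""Block-randomized behaviour streams on a discrete 1-second grid.

A simulated observation hour is a boolean occupancy vector with one entry
per second: ``True`` means the focal behaviour is occurring during that
second.  Two generating processes are provided:

* **event streams** — short (1-s) behaviours occurring exactly once per
  ``f``-second block, modelling behaviour frequency (an activity such as
  sneezing or pecking);
* **state streams** — one contiguous ``d``-second bout per 600-s block,
  modelling behaviour duration (an activity such as feeding or resting).

Block randomization (one occurrence per predefined block, placed uniformly
at random within it) mimics the quasi-regular structure of real behaviour,
as opposed to a fully random (Poisson-like) placement.

Time conventions: second index 0 is the first second of the observation;
a behaviour occupying ``[t, t + dur)`` marks seconds ``t .. t + dur - 1``.
All intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ObservationConfig",
    "EventProcessConfig",
    "StateProcessConfig",
    "OccupancyStream",
    "simulate_event_stream",
    "simulate_state_stream",
    "true_occupancy_proportion",
    "replicate_rng",
]

STATE_BLOCK_LENGTH = 600


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class ObservationConfig:
    """Length and seeding of one simulated observation.

    Parameters
    ----------
    total_seconds:
        Observation length in seconds.  The conventional observation
        window in this field is one hour (3600 s).
    rng_seed:
        Base seed for the random placement of behaviours.
    """

    total_seconds: int = 3600
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.total_seconds <= 0:
            raise ConfigurationError(
                f"total_seconds must be positive, got {self.total_seconds}"
            )


@dataclass(frozen=True)
class EventProcessConfig:
    """One 1-second event per ``block_length_f``-second block.

    ``block_length_f`` is the reciprocal frequency of the behaviour: one
    occurrence every f seconds, i.e. 3 s / 30 s / 300 s blocks give
    high / medium / low frequency behaviours.
    """

    block_length_f: int
    event_duration: int = 1

    def __post_init__(self) -> None:
        if self.block_length_f < 1:
            raise ConfigurationError(
                f"block_length_f must be >= 1, got {self.block_length_f}"
            )
        if self.event_duration != 1:
            raise ConfigurationError(
                "event_duration is fixed at 1 s for event behaviours; "
                f"got {self.event_duration}"
            )


@dataclass(frozen=True)
class StateProcessConfig:
    """One ``state_duration_d``-second bout per 600-s block.

    ``offset_support`` controls the support of the uniformly random bout
    start offset within its block:

    * ``"exclusive"`` (default): ``{0, ..., block_length - d - 1}`` — the
      bout never ends exactly at the block boundary (except when
      ``d == block_length``, where the offset collapses to 0);
    * ``"inclusive"``: ``{0, ..., block_length - d}``.
    """

    state_duration_d: int
    block_length: int = STATE_BLOCK_LENGTH
    offset_support: Literal["exclusive", "inclusive"] = "exclusive"

    def __post_init__(self) -> None:
        if not 1 <= self.state_duration_d <= self.block_length:
            raise ConfigurationError(
                f"state_duration_d must be in [1, {self.block_length}], "
                f"got {self.state_duration_d}"
            )
        if self.offset_support not in ("exclusive", "inclusive"):
            raise ConfigurationError(
                f"offset_support must be 'exclusive' or 'inclusive', "
                f"got {self.offset_support!r}"
            )


@dataclass(frozen=True)
class OccupancyStream:
    """Per-second boolean occupancy record — the continuous ground truth.

    ``occupancy[t]`` is True iff the behaviour occurs during second
    ``[t, t+1)``.  ``provenance`` records the generating configuration.
    """

    occupancy: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 1 or occ.size == 0:
            raise ConfigurationError("occupancy must be a non-empty 1-D vector")

    @property
    def total_seconds(self) -> int:
        return int(self.occupancy.size)

    def occupied_seconds(self) -> int:
        return int(self.occupancy.sum())


def replicate_rng(base_seed: int, *indices: int) -> np.random.Generator:
    """Independent substream for one (condition, ..., replicate) cell.

    Keyed on the full index tuple so any single replicate is reproducible
    in isolation without generating the ones before it.
    """
    return np.random.default_rng([base_seed, *indices])


def _check_divisible(total_seconds: int, block: int, what: str) -> None:
    if total_seconds % block != 0:
        raise ConfigurationError(
            f"total_seconds={total_seconds} is not a multiple of the "
            f"{what} block length {block}"
        )


def simulate_event_stream(
    obs: ObservationConfig,
    proc: EventProcessConfig,
    rng: np.random.Generator | None = None,
) -> OccupancyStream:
    """Generate a block-randomized event stream.

    Each block ``[k*f, (k+1)*f)`` receives exactly one occupied second at
    a start offset drawn uniformly from ``{0, ..., f-1}``.  The occupied
    total is therefore exactly ``total_seconds / f`` for every seed.
    """
    f = proc.block_length_f
    _check_divisible(obs.total_seconds, f, "event")
    if rng is None:
        rng = np.random.default_rng(obs.rng_seed)
    n_blocks = obs.total_seconds // f
    offsets = rng.integers(0, f, size=n_blocks)
    occ = np.zeros(obs.total_seconds, dtype=bool)
    occ[np.arange(n_blocks) * f + offsets] = True
    return OccupancyStream(
        occ,
        provenance={
            "kind": "event",
            "block_length_f": f,
            "total_seconds": obs.total_seconds,
            "rng_seed": obs.rng_seed,
        },
    )


def simulate_state_stream(
    obs: ObservationConfig,
    proc: StateProcessConfig,
    rng: np.random.Generator | None = None,
) -> OccupancyStream:
    """Generate a block-randomized state stream.

    Each 600-s block receives one contiguous run of ``d`` occupied
    seconds, fully contained in its block (a bout never slips into the
    next block).  Start offsets are uniform on the configured support.
    """
    d = proc.state_duration_d
    block = proc.block_length
    _check_divisible(obs.total_seconds, block, "state")
    if rng is None:
        rng = np.random.default_rng(obs.rng_seed)
    n_blocks = obs.total_seconds // block
    if proc.offset_support == "exclusive":
        high = max(block - d, 1)  # {0, ..., block-d-1}; collapses to {0} at d == block
    else:
        high = block - d + 1  # {0, ..., block-d}
    offsets = rng.integers(0, high, size=n_blocks)
    occ = np.zeros(obs.total_seconds, dtype=bool)
    starts = np.arange(n_blocks) * block + offsets
    for s in starts:
        occ[s : s + d] = True
    return OccupancyStream(
        occ,
        provenance={
            "kind": "state",
            "state_duration_d": d,
            "block_length": block,
            "offset_support": proc.offset_support,
            "total_seconds": obs.total_seconds,
            "rng_seed": obs.rng_seed,
        },
    )


def true_occupancy_proportion(stream: OccupancyStream) -> float:
    """Occupied seconds divided by total seconds.

    This is the continuous ("gold standard") activity-budget proportion
    against which the interval sampling methods are scored.
    """
    return stream.occupied_seconds() / stream.total_seconds


def write_stream_csv(stream: OccupancyStream, path) -> None:
    """Debug dump: two-column CSV of (second, occupied)."""
    import pandas as pd

    pd.DataFrame(
        {"second": np.arange(stream.total_seconds), "occupied": stream.occupancy.astype(int)}
    ).to_csv(path, index=False)
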