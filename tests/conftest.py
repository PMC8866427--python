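"""Shared fixtures and brute-force reference implementations.

The reference samplers below are deliberately naive second-by-second
scans; they exist only as independent oracles for the vectorized
implementations in the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ethosample import run_condition_grid

BASE_SEED = 1


def reference_pinpoint(occupancy: np.ndarray, L: int, at: str = "start") -> float:
    """Second-scan pinpoint estimate: occupancy at one instant per interval."""
    T = len(occupancy)
    n_intervals = math.ceil(T / L)
    hits = 0
    for k in range(n_intervals):
        start = k * L
        stop = min(start + L, T)
        t = start if at == "start" else stop - 1
        if occupancy[t]:
            hits += 1
    return hits / n_intervals


def reference_one_zero(occupancy: np.ndarray, L: int) -> float:
    """Second-scan one-zero estimate: any occupied second scores the interval."""
    T = len(occupancy)
    n_intervals = math.ceil(T / L)
    scored = 0
    for k in range(n_intervals):
        seconds = occupancy[k * L : min((k + 1) * L, T)]
        if any(bool(s) for s in seconds):
            scored += 1
    return scored / n_intervals


def analytic_pinpoint_duration_error(
    d: int, L: int, T: int = 3600, block: int = 600, support: str = "exclusive"
) -> float:
    """Exact expected pinpoint error for a state condition, by enumeration.

    Averages the pinpoint estimate over every admissible bout start offset
    (uniform support), then subtracts the true proportion.  Independent of
    the simulator: builds each candidate stream explicitly.
    """
    n_offsets = max(block - d, 1) if support == "exclusive" else block - d + 1
    instants = np.arange(0, T, L)
    total = 0.0
    for s in range(n_offsets):
        occ = np.zeros(T, dtype=bool)
        for k in range(T // block):
            occ[block * k + s : block * k + s + d] = True
        total += occ[instants].mean()
    truth = (T // block) * d / T
    return total / n_offsets - truth


@pytest.fixture(scope="session")
def freq_tidy():
    """Full frequency-family grid at the study conditions (3x3x100)."""
    return run_condition_grid("frequency", base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def dur_tidy():
    """Full duration-family grid at the study conditions (3x3x100)."""
    return run_condition_grid("duration", base_seed=BASE_SEED)
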