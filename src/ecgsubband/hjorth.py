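"""Hjorth descriptors: activity, mobility, complexity.

Three time-domain statistics of a real-valued sequence x(n), n = 0..N-1,
built from the population standard deviations of the signal and its
successive differences:

    activity   = var(x) = sigma_x**2
    mobility   = sigma_x' / sigma_x
    complexity = (sigma_x'' / sigma_x') / (sigma_x' / sigma_x)

where x' and x'' are the first and second difference sequences (defined
for n = 1..N-1, length N-1, the only consistent reading of the backward
difference). Activity measures signal variance, mobility the standard
deviation of the slope relative to the amplitude, and complexity how many
"standard slopes" fit in one standard amplitude — a shape measure that
equals 1 for a pure sinusoid.

All standard deviations divide by N (population form). Degenerate inputs
(constant signal, exact linear ramp) raise typed errors rather than
returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, DegenerateSlopeError, SignalTooShortError


@dataclass(frozen=True)
class HjorthFeatures:
    activity: float
    mobility: float
    complexity: float


def first_difference(x: np.ndarray) -> np.ndarray:
    """Backward first difference x(n) - x(n-1) for n = 1..N-1 (length N-1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise SignalTooShortError("first difference needs at least 2 samples")
    return np.diff(x)


def _pop_sd(x: np.ndarray) -> float:
    return float(np.std(x))  # ddof=0: population form


def hjorth_features(x: np.ndarray) -> HjorthFeatures:
    """Compute (activity, mobility, complexity) of a sequence.

    Raises
    ------
    DegenerateSignalError
        Constant input (sigma_x = 0, mobility undefined).
    DegenerateSlopeError
        Exact linear ramp (sigma_x' = 0, complexity undefined).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise SignalTooShortError("Hjorth descriptors need at least 3 samples")
    sd_x = _pop_sd(x)
    if sd_x == 0 or np.ptp(x) == 0:
        raise DegenerateSignalError("constant sequence: sigma_x = 0")
    dx = first_difference(x)
    sd_dx = _pop_sd(dx)
    if sd_dx == 0:
        raise DegenerateSlopeError("linear ramp: first difference is constant")
    ddx = first_difference(dx)
    sd_ddx = _pop_sd(ddx)
    mobility = sd_dx / sd_x
    return HjorthFeatures(
        activity=sd_x**2,
        mobility=mobility,
        complexity=(sd_ddx / sd_dx) / mobility,
    )
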