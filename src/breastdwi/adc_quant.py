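"""ADC quantification from dual-b-value diffusion-weighted signals.

The apparent diffusion coefficient is estimated from the mono-exponential
signal decay S2 = S1 * exp(-(b2 - b1) * ADC) between two diffusion
weightings b1 < b2 (here, defaults b1 = 0 and b2 = 750 s/mm^2), i.e.

    ADC = ln(S1 / S2) / (b2 - b1)

Note the sign: the equivalent form ln(S2/S1)/(b2-b1) sometimes seen in print
yields negative numbers for decaying signal; this module uses the physically
standard orientation so that ADC >= 0 whenever S2 <= S1.  Values are
returned in the clinical display unit of 1e-3 mm^2/s.

The per-lesion measurement convention is to draw at least three regions of
interest and accept the lowest ADC (the most cellular, most suspicious part
of the lesion) as the lesion's value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SignalPair", "RoiMeasurementSet", "adc_from_signals",
           "lesion_adc", "adc_map", "forward_signal"]

#: Default diffusion weightings, s/mm^2.
DEFAULT_B1 = 0.0
DEFAULT_B2 = 750.0


@dataclass(frozen=True)
class SignalPair:
    """Signal intensities of one ROI at the low and high b-value."""

    s1: float
    s2: float
    b1: float = DEFAULT_B1
    b2: float = DEFAULT_B2

    def __post_init__(self) -> None:
        if not (self.s1 > 0 and self.s2 > 0):
            raise ValueError(f"signals must be positive, got s1={self.s1}, s2={self.s2}")
        if not self.b2 > self.b1:
            raise ValueError(f"need b2 > b1, got b1={self.b1}, b2={self.b2}")


@dataclass(frozen=True)
class RoiMeasurementSet:
    """ADC measurements (1e-3 mm^2/s) from the ROIs of a single lesion."""

    adc_values: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.adc_values) == 0:
            raise ValueError("at least one ROI measurement is required")
        if any(v <= 0 for v in self.adc_values):
            raise ValueError(f"ADC measurements must be positive: {self.adc_values}")


def adc_from_signals(pair: SignalPair) -> float:
    """ADC of one ROI, in 1e-3 mm^2/s.

    ``ln(s1/s2)/(b2-b1)`` gives mm^2/s; the factor 1e3 rescales to the
    display unit.  Negative results (s2 > s1, pure noise) are returned
    as-is here; :func:`adc_map` clamps them.
    """
    return math.log(pair.s1 / pair.s2) / (pair.b2 - pair.b1) * 1e3


def forward_signal(s1: float, adc: float, b1: float = DEFAULT_B1,
                   b2: float = DEFAULT_B2) -> float:
    """Mono-exponential forward model: the b2 signal for a given ADC
    (1e-3 mm^2/s).  Inverse of :func:`adc_from_signals`."""
    return s1 * math.exp(-(b2 - b1) * adc * 1e-3)


def lesion_adc(measurements: RoiMeasurementSet | Sequence[float]) -> float:
    """Per-lesion ADC: the lowest value among the lesion's ROI measurements."""
    values = (measurements.adc_values
              if isinstance(measurements, RoiMeasurementSet)
              else tuple(measurements))
    if len(values) == 0:
        raise ValueError("at least one ROI measurement is required")
    return min(values)


def adc_map(signal_b1: np.ndarray, signal_b2: np.ndarray,
            b1: float = DEFAULT_B1, b2: float = DEFAULT_B2,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise ADC map from two signal images.

    Returns ``(adc, clamped)`` where ``adc`` is in 1e-3 mm^2/s and
    ``clamped`` is a boolean mask of voxels where the high-b signal exceeded
    the low-b signal (noise); those voxels are set to 0 rather than left
    negative so the map stays in the valid domain for dichotomization.
    """
    a = np.asarray(signal_b1, dtype=float)
    b = np.asarray(signal_b2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not b2 > b1:
        raise ValueError(f"need b2 > b1, got b1={b1}, b2={b2}")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("all signals must be positive")
    adc = np.log(a / b) / (b2 - b1) * 1e3
    clamped = adc < 0
    adc = np.where(clamped, 0.0, adc)
    return adc, clamped
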