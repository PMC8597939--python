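"""Dissolution time-course analysis and f1/f2 profile comparison.

Converts per-timepoint assay readouts into cumulative percent-released
profiles — via a UV calibration curve (direct concentration) or the HPLC
external-standard formula — corrects for the volume withdrawn at each
sampling, and compares two profiles with the regulatory fit factors:

    f1 = 100 * Σ|R_t − T_t| / Σ R_t          (difference factor)
    f2 = 50 * log10(100 / sqrt(1 + MSD))     (similarity factor)

where MSD is the mean squared pointwise difference between the reference
profile R and test profile T.  Conventional similarity requires f1 ≤ 15 and
f2 ≥ 50; f2 = 50 falls exactly at MSD = 99.  Times are minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "DetectionMode",
    "DissolutionProfile",
    "HplcReleaseInput",
    "FitFactors",
    "SamplingScheme",
    "Verdict",
    "percent_released_conc",
    "percent_released_hplc",
    "correct_cumulative",
    "fit_factor_f1",
    "fit_factor_f2",
    "compute_fit_factors",
    "similarity_verdict",
    "release_rate",
]


class DetectionMode(str, Enum):
    UV = "UV"
    HPLC = "HPLC"


class Verdict(str, Enum):
    SIMILAR = "similar"
    NOT_SIMILAR = "not_similar"


@dataclass
class DissolutionProfile:
    """Cumulative percent released over time for one vessel/replicate.

    ``values`` are percent of the theoretical dose; modest assay overshoot
    above 100 % is tolerated (up to 120).
    """

    formulation_id: str
    detection_mode: DetectionMode
    replicate_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.detection_mode = DetectionMode(self.detection_mode)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 120):
            raise ValueError("percent released must lie in [0, 120]")


@dataclass(frozen=True)
class HplcReleaseInput:
    """Inputs to the HPLC external-standard percent-released formula."""

    sample_area: float
    standard_average_area: float
    ws_mg: float  # weight of the drug working standard, mg
    wu_pct: float  # assay percentage of the working standard

    def __post_init__(self) -> None:
        if self.standard_average_area <= 0 or self.ws_mg <= 0 or self.wu_pct <= 0:
            raise ValueError("standard area, Ws and Wu must all be positive")
        if self.sample_area < 0:
            raise ValueError("sample_area must be non-negative")


@dataclass(frozen=True)
class SamplingScheme:
    """Withdrawal scheme of a paddle dissolution run."""

    vessel_volume_ml: float
    sample_volume_ml: float
    replace_with_medium: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.sample_volume_ml < self.vessel_volume_ml):
            raise ValueError("need 0 < sample_volume < vessel_volume")


@dataclass(frozen=True)
class FitFactors:
    f1: float
    f2: float
    n_points: int
    point_times: tuple[float, ...] = field(default=())


def percent_released_conc(concentration: float, theoretical_max: float) -> float:
    """Percent released from a measured concentration against the
    theoretical maximum concentration of a fully dissolved dose."""
    if theoretical_max <= 0:
        raise ValueError("theoretical_max must be positive")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    return 100.0 * concentration / theoretical_max


# Fixed factors of the external-standard formula: the working standard is
# diluted 1:20 relative to the assay and one tablet assays at 1.5 (theoretical).
_HPLC_DILUTION = 20.0
_HPLC_TABLET_ASSAY = 1.5


def percent_released_hplc(inp: HplcReleaseInput) -> float:
    """Percent released from an HPLC peak area against the external standard:
    ``area_sample * Ws * Wu / (area_standard * 20 * 1.5)``."""
    return (inp.sample_area * inp.ws_mg * inp.wu_pct) / (
        inp.standard_average_area * _HPLC_DILUTION * _HPLC_TABLET_ASSAY
    )


def correct_cumulative(
    raw: Sequence[tuple[float, float]], scheme: SamplingScheme
) -> list[tuple[float, float]]:
    """Correct measured concentrations for analyte removed by sampling.

    When each withdrawal is replaced with fresh medium, the analyte taken
    out at earlier samplings is added back:
    ``c'_k = c_k + (v_s / V) * Σ_{j<k} c_j``.  Identity when replacement
    is disabled (no correction defined for shrinking volume here).
    """
    times = [t for t, _ in raw]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    if not scheme.replace_with_medium:
        return [(float(t), float(c)) for t, c in raw]
    frac = scheme.sample_volume_ml / scheme.vessel_volume_ml
    out: list[tuple[float, float]] = []
    prior = 0.0
    for t, c in raw:
        out.append((float(t), float(c) + frac * prior))
        prior += float(c)
    return out


def _paired(R: Sequence[float], T: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(R, dtype=float)
    t = np.asarray(T, dtype=float)
    if r.shape != t.shape or r.ndim != 1 or r.size < 1:
        raise ValueError("R and T must be 1-d sequences of equal length >= 1")
    return r, t


def fit_factor_f1(R: Sequence[float], T: Sequence[float]) -> float:
    """Difference factor f1 = 100·Σ|R−T|/ΣR (asymmetric: R is reference)."""
    r, t = _paired(R, T)
    denom = r.sum()
    if denom <= 0:
        raise ValueError("reference profile must have positive total release")
    return 100.0 * np.abs(r - t).sum() / denom


def fit_factor_f2(R: Sequence[float], T: Sequence[float]) -> float:
    """Similarity factor f2 = 50·log10(100·(1 + MSD)^-0.5), base-10 log."""
    r, t = _paired(R, T)
    msd = np.mean((r - t) ** 2)
    return 50.0 * np.log10(100.0 * (1.0 + msd) ** -0.5)


def compute_fit_factors(
    R: Sequence[float],
    T: Sequence[float],
    point_times: Sequence[float] | None = None,
    until_reference_pct: float | None = None,
) -> FitFactors:
    """f1 and f2 on matched time points.

    ``until_reference_pct`` optionally truncates the point set after the
    first time the reference exceeds that release level (the guidance-style
    85 % rule); off by default.
    """
    r, t = _paired(R, T)
    times = (
        np.asarray(point_times, dtype=float)
        if point_times is not None
        else np.arange(r.size, dtype=float)
    )
    if times.size != r.size:
        raise ValueError("point_times length must match profiles")
    if until_reference_pct is not None:
        above = np.nonzero(r >= until_reference_pct)[0]
        cut = (above[0] + 1) if above.size else r.size
        r, t, times = r[:cut], t[:cut], times[:cut]
    return FitFactors(
        f1=fit_factor_f1(r, t),
        f2=fit_factor_f2(r, t),
        n_points=int(r.size),
        point_times=tuple(float(x) for x in times),
    )


def similarity_verdict(
    factors: FitFactors, f1_max: float = 15.0, f2_min: float = 50.0
) -> Verdict:
    """Similar iff f1 ≤ f1_max and f2 ≥ f2_min (thresholds configurable)."""
    ok = factors.f1 <= f1_max and factors.f2 >= f2_min
    return Verdict.SIMILAR if ok else Verdict.NOT_SIMILAR


def release_rate(
    profile: DissolutionProfile, dose_ug: float, plateau_fraction: float = 0.95
) -> float:
    """Average release rate to plateau, µg/min.

    The plateau time t* is the first sampling at which the profile reaches
    ``plateau_fraction`` of the theoretical dose (100 %); the rate is the
    mass released by then divided by t*.  A profile that never gets there
    raises ``"profile not at plateau"``.
    """
    if profile.times.size == 0:
        raise ValueError("empty profile")
    thresh = plateau_fraction * 100.0
    idx = np.nonzero(profile.values >= thresh)[0]
    if idx.size == 0:
        raise ValueError("profile not at plateau")
    k = idx[0]
    t_star = profile.times[k]
    if t_star <= 0:
        raise ValueError("plateau at non-positive time")
    return dose_ug * (profile.values[k] / 100.0) / t_star
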