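"""Linear calibration curves for UV-absorbance and HPLC-peak-area quantitation.

A calibration curve maps instrument response (dimensionless absorbance or
peak area) linearly onto analyte mass concentration (µg/ml), following the
Beer–Lambert regime for UV and detector linearity for HPLC.  The module
fits curves from standard solutions by ordinary least squares, inverts
responses to concentrations, derives limits of detection and quantitation
from the calibration uncertainty, and screens analyte stability over time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "ExtrapolationWarning",
    "StabilityResult",
    "fit_calibration",
    "invert_calibration",
    "detection_limits",
    "check_stability",
]


class ExtrapolationWarning(UserWarning):
    """A response was inverted outside the fitted concentration range."""


@dataclass(frozen=True)
class CalibrationStandard:
    """One standard-solution measurement.

    Parameters
    ----------
    concentration : float
        Analyte concentration of the standard, µg/ml. Must be positive.
    response : float
        Instrument response (absorbance units or peak area).
    """

    concentration: float
    response: float

    def __post_init__(self) -> None:
        if not (self.concentration > 0):
            raise ValueError(f"standard concentration must be > 0, got {self.concentration}")
        if not math.isfinite(self.response):
            raise ValueError("standard response must be finite")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted linear response-vs-concentration map.

    ``response = slope * concentration + intercept``; standard errors of the
    coefficients carry the calibration uncertainty used for LoD/LoQ.
    """

    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    r_squared: float
    conc_range: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")
        if not (self.conc_range[0] < self.conc_range[1]):
            raise ValueError("conc_range must satisfy min < max")
        if self.n_points < 3:
            raise ValueError("a calibration curve needs at least 3 points")

    def predict(self, concentration: float) -> float:
        """Forward map: expected response at a given concentration (µg/ml)."""
        return self.slope * float(concentration) + self.intercept

    def inverse(self, response: float) -> float:
        """Inverse map: concentration (µg/ml) from a response; see
        :func:`invert_calibration` for range checking."""
        return invert_calibration(self, response)


def fit_calibration(standards: Iterable[CalibrationStandard]) -> CalibrationCurve:
    """Fit a calibration curve to standard solutions by unweighted OLS.

    Response is regressed on concentration.  Requires at least three
    standards spanning at least two distinct concentrations.

    Raises
    ------
    ValueError
        With message ``"insufficient calibration design"`` when fewer than
        3 standards are given or all concentrations coincide.
    """
    pts = list(standards)
    conc = np.array([p.concentration for p in pts], dtype=float)
    resp = np.array([p.response for p in pts], dtype=float)
    if len(pts) < 3 or np.unique(conc).size < 2:
        raise ValueError("insufficient calibration design")

    fit = _st.linregress(conc, resp)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_sd=float(fit.stderr),
        intercept_sd=float(fit.intercept_stderr),
        r_squared=min(float(fit.rvalue) ** 2, 1.0),
        conc_range=(float(conc.min()), float(conc.max())),
        n_points=len(pts),
    )


def invert_calibration(curve: CalibrationCurve, response: float) -> float:
    """Invert a response to a concentration: ``(response - intercept) / slope``.

    Values outside the fitted concentration range are returned (early
    dissolution samples sit near zero) but raise an
    :class:`ExtrapolationWarning`.
    """
    if not math.isfinite(response):
        raise ValueError("response must be finite")
    conc = (float(response) - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    span = hi - lo
    # tolerance absorbs round-off at the range edges
    if not (lo - 1e-9 * span <= conc <= hi + 1e-9 * span):
        warnings.warn(
            f"concentration {conc:.4g} µg/ml lies outside the calibrated "
            f"range [{lo:g}, {hi:g}] µg/ml (extrapolated)",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return conc


def detection_limits(curve: CalibrationCurve) -> tuple[float, float]:
    """Limit of detection and quantitation, µg/ml.

    Uses the σ-of-blank convention with σ taken as the intercept standard
    error, the only uncertainty a calibration fit itself provides:
    LoD = 3.3 σ / slope, LoQ = 10 σ / slope.
    """
    if curve.slope == 0:
        raise ValueError("slope must be nonzero")
    s = abs(curve.slope)
    return 3.3 * curve.intercept_sd / s, 10.0 * curve.intercept_sd / s


class StabilityResult(NamedTuple):
    stable: bool
    observed_max_drift: float


def check_stability(
    series: Sequence[tuple[float, float]], max_rel_drift: float = 0.05
) -> StabilityResult:
    """Screen an absorbance time series (hours, response) for drift.

    The analyte is declared stable when the largest relative deviation from
    the initial response stays within ``max_rel_drift``.  Used to pick the
    highest donor concentration that survives a multi-day incubation.
    """
    if len(series) < 2:
        raise ValueError("stability screen needs at least 2 time points")
    t0, r0 = series[0]
    if r0 <= 0:
        raise ValueError("initial response must be positive")
    drift = max(abs(r - r0) / r0 for _, r in series)
    return StabilityResult(stable=drift <= max_rel_drift, observed_max_drift=drift)
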