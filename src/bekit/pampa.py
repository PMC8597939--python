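"""PAMPA percent transport and effective permeability.

A parallel artificial membrane permeability assay incubates a donor well
(volume Vd) against an acceptor well (Vr) across a phospholipid-coated
filter of area S.  With passive diffusion and no membrane retention, the
fraction transported after time t follows the two-compartment closed form,
inverted here to the effective permeability

    Pe = Vd*Vr / ((Vd+Vr)*S*t) * ln( %T_eq / (%T_eq - %T) )

with %T = 100 * Vr*Ar / (Vd*Ad0): acceptor absorbance after incubation over
initial donor absorbance, volume-corrected.  Absorbance units cancel in %T,
so Pe needs no calibration curve.  %T has an equilibrium ceiling of
%T_eq = 100*Vr/(Vd+Vr) (50 % for equal volumes, where the expression
coincides with the commonly printed 100*Vd/(Vd+Vr) form); wells at or
beyond it carry no permeability information and are excluded, not clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _st

from .stats import summarize

__all__ = [
    "PampaGeometry",
    "PampaWell",
    "PermeabilityResult",
    "percent_transport",
    "permeability",
    "well_permeability",
    "pe_timecourse",
    "validate_reference_panel",
]


@dataclass(frozen=True)
class PampaGeometry:
    """Plate geometry: donor/receptor volumes (cm³) and membrane area (cm²).

    Defaults are the 96-well MultiScreen sandwich: 180 µl per compartment,
    0.266 cm² filter.
    """

    Vd: float = 0.18
    Vr: float = 0.18
    S: float = 0.266

    def __post_init__(self) -> None:
        if self.Vd <= 0 or self.Vr <= 0 or self.S <= 0:
            raise ValueError("geometry volumes and area must be positive")

    @property
    def equilibrium_ceiling(self) -> float:
        """Largest %T reachable by passive equilibration: 100·Vr/(Vd+Vr).

        At equilibrium the donor and acceptor concentrations match, so the
        acceptor holds a Vr/(Vd+Vr) share of the initial donor amount.
        """
        return 100.0 * self.Vr / (self.Vd + self.Vr)


@dataclass(frozen=True)
class PampaWell:
    """One donor/acceptor absorbance pair after incubation time t (seconds)."""

    well_id: str
    Ad0: float
    Ar: float
    t: float
    sample_label: str = ""

    def __post_init__(self) -> None:
        if self.Ad0 <= 0:
            raise ValueError("initial donor absorbance Ad0 must be positive")
        if self.Ar < 0:
            raise ValueError("acceptor absorbance Ar must be non-negative")
        if self.t <= 0:
            raise ValueError("incubation time must be positive")


@dataclass(frozen=True)
class PermeabilityResult:
    """Replicate-aggregated Pe for one (sample, incubation-time) group."""

    sample_label: str
    t: float
    pe_mean: float
    pe_sd: float
    rsd_pct: float
    n_wells: int
    n_excluded: int

    @property
    def valid(self) -> bool:
        return self.n_wells >= 1


def percent_transport(well: PampaWell, geom: PampaGeometry) -> float:
    """%T = 100 * (Vr*Ar) / (Ad0*Vd); equals 100*Ar/Ad0 for equal volumes."""
    return 100.0 * (geom.Vr * well.Ar) / (well.Ad0 * geom.Vd)


def permeability(pctT: float, geom: PampaGeometry, t: float) -> float:
    """Effective permeability Pe (cm/s) from percent transport after t seconds.

    Raises for %T at or beyond the equilibrium ceiling, where the
    closed-form log diverges and Pe is undefined.
    """
    if t <= 0:
        raise ValueError("incubation time must be positive")
    if pctT < 0:
        raise ValueError("%T must be non-negative")
    if pctT >= geom.equilibrium_ceiling:
        raise ValueError("at/beyond equilibrium: Pe undefined")
    Vd, Vr, S = geom.Vd, geom.Vr, geom.S
    pre = Vd * Vr / ((Vd + Vr) * S * t)
    return pre * math.log(100.0 * Vr / (100.0 * Vr - pctT * (Vd + Vr)))


def well_permeability(well: PampaWell, geom: PampaGeometry) -> float:
    """Per-well Pe; raises when the well is at/beyond equilibrium."""
    return permeability(percent_transport(well, geom), geom, well.t)


def pe_timecourse(
    wells: Iterable[PampaWell], geom: PampaGeometry
) -> list[PermeabilityResult]:
    """Group wells by (sample_label, incubation time) and aggregate Pe.

    Wells whose %T sits at or beyond the equilibrium ceiling are excluded
    from the mean and counted in ``n_excluded``; a group whose wells are all
    excluded is returned with ``n_wells = 0`` (flagged invalid).  Results
    are ordered by sample label then time.
    """
    groups: dict[tuple[str, float], list[PampaWell]] = {}
    for w in wells:
        groups.setdefault((w.sample_label, w.t), []).append(w)

    out: list[PermeabilityResult] = []
    for (label, t), grp in sorted(groups.items()):
        pes: list[float] = []
        excluded = 0
        for w in grp:
            try:
                pes.append(well_permeability(w, geom))
            except ValueError:
                excluded += 1
        if not pes:
            out.append(PermeabilityResult(label, t, math.nan, math.nan, math.nan, 0, excluded))
            continue
        s = summarize(pes)
        out.append(
            PermeabilityResult(
                sample_label=label,
                t=t,
                pe_mean=s.mean,
                pe_sd=s.sd,
                rsd_pct=s.rsd_pct,
                n_wells=s.n,
                n_excluded=excluded,
            )
        )
    return out


def validate_reference_panel(
    experimental: Sequence[tuple[str, float]],
    reference: Sequence[tuple[str, float]],
    qc_r2_min: float = 0.95,
) -> tuple[float, float, float, bool]:
    """Correlate experimental Pe against literature Pe for QC compounds.

    Compounds are matched by name; OLS of experimental on reference Pe.
    Returns ``(r_squared, slope, intercept, passed)`` where the assay passes
    QC when r² exceeds ``qc_r2_min``.
    """
    ref = dict(reference)
    pairs = [(ref[name], pe) for name, pe in experimental if name in ref]
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched QC compounds")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    fit = _st.linregress(x, y)
    r2 = float(fit.rvalue) ** 2
    return r2, float(fit.slope), float(fit.intercept), r2 > qc_r2_min
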