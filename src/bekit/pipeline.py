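"""Glue between raw records and domain objects.

Turns raw dissolution records (instrument responses) into percent-released
profiles through a per-detection-mode calibration curve, optionally applying
the cumulative withdrawal correction of the sampling scheme.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, invert_calibration
from .dissolution import (
    DetectionMode,
    DissolutionProfile,
    SamplingScheme,
    correct_cumulative,
    percent_released_conc,
)

__all__ = ["profiles_from_raw"]


def profiles_from_raw(
    records: pd.DataFrame,
    curves: dict[str, CalibrationCurve] | None,
    theoretical_max_ug_ml: float,
    scheme: SamplingScheme | None = None,
) -> list[DissolutionProfile]:
    """Build percent-released profiles from raw dissolution records.

    ``curves`` maps detection-mode names ("UV", "HPLC") to calibration
    curves; a mode with no curve (or ``curves=None``) treats the response
    as percent released directly (the simulator's convention).  When a
    ``scheme`` is given, concentrations are corrected for withdrawal before
    conversion to percent.
    """
    profiles: list[DissolutionProfile] = []
    grouped: dict[tuple[str, str, str], list[tuple[float, float]]] = defaultdict(list)
    for row in records.itertuples():
        grouped[(str(row.formulation_id), str(row.detection_mode), str(row.replicate_id))].append(
            (float(row.time_min), float(row.response))
        )
    for (fid, mode, rid), pts in sorted(grouped.items()):
        pts.sort()
        times = np.array([t for t, _ in pts])
        resp = np.array([r for _, r in pts])
        curve = (curves or {}).get(mode)
        if curve is None:
            values = resp
        else:
            conc = [(t, invert_calibration(curve, r)) for t, r in zip(times, resp)]
            if scheme is not None and scheme.replace_with_medium:
                conc = correct_cumulative(conc, scheme)
            values = np.array(
                [percent_released_conc(max(c, 0.0), theoretical_max_ug_ml) for _, c in conc]
            )
        profiles.append(
            DissolutionProfile(
                formulation_id=fid,
                detection_mode=DetectionMode(mode),
                replicate_id=rid,
                times=times,
                values=np.clip(values, 0.0, 120.0),
            )
        )
    return profiles
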