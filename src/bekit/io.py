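"""CSV readers and writers for the pipeline's tabular interfaces.

The dialect is strict: UTF-8, header row required, dot decimal separator.
European comma decimals are rejected with the offending line numbers —
silent misparsing of `1,32` as something other than 1.32 is worse than an
error.  All readers validate schema up front and name missing columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .calibration import CalibrationStandard
from .dissolution import DissolutionProfile
from .pampa import PampaWell, PermeabilityResult

__all__ = [
    "CsvFormatError",
    "read_calibration_csv",
    "read_stability_csv",
    "read_dissolution_csv",
    "read_plate_csv",
    "write_dissolution_csv",
    "write_plate_csv",
    "write_calibration_csv",
    "write_profile_summary_csv",
    "write_pampa_results_csv",
]

SECONDS_PER_HOUR = 3600.0


class CsvFormatError(ValueError):
    """Malformed CSV input (schema or dialect violation)."""


def _load(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, encoding="utf-8", skipinitialspace=True)
    except Exception as exc:  # noqa: BLE001 - surface parser failures uniformly
        raise CsvFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CsvFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _numeric(df: pd.DataFrame, path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    """Convert columns to float under the strict dot-decimal dialect."""
    out = df.copy()
    for col in columns:
        raw = out[col].astype(str).str.strip()
        bad = raw[raw.str.contains(",", na=True)]
        converted = pd.to_numeric(raw.str.replace(" ", "", regex=False), errors="coerce")
        bad_rows = df.index[converted.isna() | raw.str.contains(",", na=True)]
        if len(bad_rows):
            # +2: header line plus 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad_rows[:10])
            raise CsvFormatError(
                f"{path}: column '{col}' has non-numeric values (dot decimal "
                f"separator required) at line(s) {lines}"
            )
        out[col] = converted
    return out


def read_calibration_csv(path: str | Path) -> list[CalibrationStandard]:
    """Read standards: columns ``concentration_ug_ml, response``."""
    df = _numeric(
        _load(path, ["concentration_ug_ml", "response"]),
        path,
        ["concentration_ug_ml", "response"],
    )
    return [
        CalibrationStandard(concentration=row.concentration_ug_ml, response=row.response)
        for row in df.itertuples()
    ]


def read_stability_csv(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read stability series keyed by concentration label:
    columns ``time_h, response, concentration_label``."""
    df = _numeric(
        _load(path, ["time_h", "response", "concentration_label"]),
        path,
        ["time_h", "response"],
    )
    series: dict[str, list[tuple[float, float]]] = {}
    for row in df.itertuples():
        series.setdefault(str(row.concentration_label), []).append(
            (row.time_h, row.response)
        )
    return {k: sorted(v) for k, v in series.items()}


def read_dissolution_csv(path: str | Path) -> pd.DataFrame:
    """Read raw dissolution records:
    columns ``formulation_id, replicate_id, detection_mode, time_min, response``.

    Responses are instrument readouts; conversion to concentration happens
    downstream through a named calibration curve.
    """
    cols = ["formulation_id", "replicate_id", "detection_mode", "time_min", "response"]
    df = _numeric(_load(path, cols), path, ["time_min", "response"])
    bad_mode = df[~df["detection_mode"].isin(["UV", "HPLC"])]
    if len(bad_mode):
        lines = ", ".join(str(i + 2) for i in bad_mode.index[:10])
        raise CsvFormatError(
            f"{path}: detection_mode must be 'UV' or 'HPLC' at line(s) {lines}"
        )
    return df[cols]


def read_plate_csv(path: str | Path) -> list[PampaWell]:
    """Read PAMPA wells: columns ``well_id, sample_label, t_h, Ad0, Ar``.

    Incubation time is given in hours and converted to seconds.  Duplicate
    well ids are rejected.
    """
    cols = ["well_id", "sample_label", "t_h", "Ad0", "Ar"]
    df = _numeric(_load(path, cols), path, ["t_h", "Ad0", "Ar"])
    dup = df["well_id"][df["well_id"].duplicated()]
    if len(dup):
        raise CsvFormatError(
            f"{path}: duplicate well_id value(s): {', '.join(sorted(set(dup)))}"
        )
    return [
        PampaWell(
            well_id=str(row.well_id),
            sample_label=str(row.sample_label),
            t=row.t_h * SECONDS_PER_HOUR,
            Ad0=row.Ad0,
            Ar=row.Ar,
        )
        for row in df.itertuples()
    ]


def write_dissolution_csv(
    path: str | Path, profiles: Sequence[DissolutionProfile], response_scale: float = 1.0
) -> None:
    """Write profiles in the raw dissolution dialect.

    ``response_scale`` maps percent released back to an instrument response
    (e.g. a calibration slope times theoretical-max/100); the default writes
    percent released directly as the response.
    """
    rows = []
    for p in profiles:
        for t, v in zip(p.times, p.values):
            rows.append(
                {
                    "formulation_id": p.formulation_id,
                    "replicate_id": p.replicate_id,
                    "detection_mode": p.detection_mode.value,
                    "time_min": t,
                    "response": v * response_scale,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_plate_csv(path: str | Path, wells: Sequence[PampaWell]) -> None:
    rows = [
        {
            "well_id": w.well_id,
            "sample_label": w.sample_label,
            "t_h": w.t / SECONDS_PER_HOUR,
            "Ad0": w.Ad0,
            "Ar": w.Ar,
        }
        for w in wells
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_calibration_csv(path: str | Path, standards: Sequence[CalibrationStandard]) -> None:
    pd.DataFrame(
        {
            "concentration_ug_ml": [s.concentration for s in standards],
            "response": [s.response for s in standards],
        }
    ).to_csv(path, index=False)


def write_profile_summary_csv(path: str | Path, summary: pd.DataFrame) -> None:
    """Write the per-formulation profile summary:
    ``formulation_id, time_min, mean_pct, sd_pct, rsd_pct, n``."""
    cols = ["formulation_id", "time_min", "mean_pct", "sd_pct", "rsd_pct", "n"]
    summary.loc[:, cols].to_csv(path, index=False)


def write_pampa_results_csv(path: str | Path, results: Sequence[PermeabilityResult]) -> None:
    """Write Pe results in the tabular layout of the permeability summary:
    mean Pe in 1e-6 cm/s alongside RSD% and well counts."""
    rows = [
        {
            "sample_label": r.sample_label,
            "t_h": r.t / SECONDS_PER_HOUR,
            "pe_mean_e6_cm_s": r.pe_mean * 1e6,
            "rsd_pct": r.rsd_pct,
            "n_wells": r.n_wells,
            "n_excluded": r.n_excluded,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
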