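"""Combined bioequivalence-risk report.

Ties the dissolution-similarity and permeability arms together: per
formulation and detection mode it summarises the release profiles,
computes f1/f2 against the reference formulation per detection mode,
tabulates replicate-aggregated Pe per (sample, incubation time), runs the
two-group Pe comparison at each shared condition, and raises an overall
flag when the two detection modes disagree on similarity or permeability
differs significantly anywhere — the fingerprints of insoluble
drug–excipient aggregates that dissolution alone can miss.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig
from .dissolution import (
    DetectionMode,
    DissolutionProfile,
    Verdict,
    compute_fit_factors,
    similarity_verdict,
)
from .pampa import PampaWell, pe_timecourse, well_permeability
from .stats import compare_groups, summarize

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = ["SCHEMA_VERSION", "profile_summary", "run_be_report", "render_text_report"]


def profile_summary(profiles: Sequence[DissolutionProfile]) -> pd.DataFrame:
    """Per (formulation, mode, time) mean/SD/RSD% across replicates."""
    rows = []
    groups: dict[tuple[str, str], list[DissolutionProfile]] = defaultdict(list)
    for p in profiles:
        groups[(p.formulation_id, p.detection_mode.value)].append(p)
    for (fid, mode), ps in sorted(groups.items()):
        times = ps[0].times
        for p in ps[1:]:
            if not np.array_equal(p.times, times):
                raise ValueError(
                    f"replicates of {fid}/{mode} sampled at different times"
                )
        mat = np.vstack([p.values for p in ps])
        for j, t in enumerate(times):
            s = summarize(mat[:, j])
            rows.append(
                {
                    "formulation_id": fid,
                    "detection_mode": mode,
                    "time_min": float(t),
                    "mean_pct": s.mean,
                    "sd_pct": s.sd,
                    "rsd_pct": s.rsd_pct,
                    "n": s.n,
                }
            )
    return pd.DataFrame(rows)


def _mean_profile(profiles: list[DissolutionProfile]) -> tuple[np.ndarray, np.ndarray]:
    times = profiles[0].times
    return times, np.vstack([p.values for p in profiles]).mean(axis=0)


def _formulation_of(sample_label: str) -> str:
    """Formulation id encoded as the prefix of a 'formulation:tag' label."""
    return sample_label.split(":", 1)[0]


def run_be_report(
    study: StudyConfig,
    profiles: Sequence[DissolutionProfile],
    wells: Sequence[PampaWell] = (),
) -> dict:
    """Build the combined report as a JSON-serialisable dict.

    Dissolution profiles must cover at least two formulations; plate data
    is optional (the permeability section is then marked absent).  Well
    sample labels use the ``formulation[:tag]`` convention so permeability
    groups can be matched back to formulations.
    """
    profiles = list(profiles)
    formulations = sorted({p.formulation_id for p in profiles})
    if len(formulations) < 2:
        raise ValueError("report needs at least 2 formulations in dissolution data")
    if wells:
        plate_forms = {_formulation_of(w.sample_label) for w in wells}
        unmatched = plate_forms - set(formulations)
        if unmatched:
            raise ValueError(
                f"plate sample labels reference unknown formulation(s): {sorted(unmatched)}"
            )

    ref_id = study.reference_formulation or formulations[0]
    if ref_id not in formulations:
        raise ValueError(f"reference formulation '{ref_id}' absent from dissolution data")
    test_ids = [f for f in formulations if f != ref_id]
    thr = study.thresholds

    logger.info(
        "report: %d profiles, %d formulations (reference %s), %d wells",
        len(profiles), len(formulations), ref_id, len(wells),
    )

    summary = profile_summary(profiles)

    # f1/f2 per (test formulation, detection mode) against the reference
    comparisons = []
    verdict_by_mode: dict[str, dict[str, str]] = defaultdict(dict)
    for mode in (DetectionMode.UV, DetectionMode.HPLC):
        ref_profiles = [
            p for p in profiles if p.formulation_id == ref_id and p.detection_mode is mode
        ]
        if not ref_profiles:
            continue
        t_ref, r_mean = _mean_profile(ref_profiles)
        for tid in test_ids:
            tst = [
                p for p in profiles if p.formulation_id == tid and p.detection_mode is mode
            ]
            if not tst:
                continue
            t_tst, t_mean = _mean_profile(tst)
            if not np.array_equal(t_ref, t_tst):
                raise ValueError(
                    f"time grids differ between {ref_id} and {tid} in {mode.value} mode"
                )
            ff = compute_fit_factors(r_mean, t_mean, point_times=t_ref)
            verdict = similarity_verdict(ff, thr.f1_max, thr.f2_min)
            verdict_by_mode[tid][mode.value] = verdict.value
            comparisons.append(
                {
                    "reference": ref_id,
                    "test": tid,
                    "detection_mode": mode.value,
                    "f1": ff.f1,
                    "f2": ff.f2,
                    "n_points": ff.n_points,
                    "point_times": list(ff.point_times),
                    "verdict": verdict.value,
                    "thresholds": {"f1_max": thr.f1_max, "f2_min": thr.f2_min},
                }
            )

    mode_disagreements = [
        tid
        for tid, by_mode in verdict_by_mode.items()
        if len(set(by_mode.values())) > 1
    ]

    # Permeability arm
    geom = study.geometry.to_geometry()
    pe_section: dict = {"present": bool(wells)}
    significant_pe: list[dict] = []
    if wells:
        results = pe_timecourse(wells, geom)
        pe_section["results"] = [
            {
                "sample_label": r.sample_label,
                "t_h": r.t / 3600.0,
                "pe_mean_e6_cm_s": r.pe_mean * 1e6 if r.n_wells else None,
                "rsd_pct": r.rsd_pct if r.n_wells > 1 else None,
                "n_wells": r.n_wells,
                "n_excluded": r.n_excluded,
            }
            for r in results
        ]
        # pairwise comparison of per-well Pe between formulations sharing (tag, t)
        pe_by_group: dict[tuple[str, str, float], list[float]] = defaultdict(list)
        for w in wells:
            fid = _formulation_of(w.sample_label)
            tag = w.sample_label.split(":", 1)[1] if ":" in w.sample_label else ""
            try:
                pe_by_group[(fid, tag, w.t)].append(well_permeability(w, geom))
            except ValueError:
                pass
        pe_comparisons = []
        for tid in test_ids:
            for (fid, tag, t), ref_vals in sorted(pe_by_group.items()):
                if fid != ref_id:
                    continue
                test_vals = pe_by_group.get((tid, tag, t), [])
                if len(ref_vals) < 2 or len(test_vals) < 2:
                    continue
                cmp_res = compare_groups(ref_vals, test_vals, alpha=thr.alpha)
                entry = {
                    "reference": ref_id,
                    "test": tid,
                    "tag": tag,
                    "t_h": t / 3600.0,
                    "reference_pe_mean_e6": float(np.mean(ref_vals)) * 1e6,
                    "test_pe_mean_e6": float(np.mean(test_vals)) * 1e6,
                    "p_value": cmp_res.p_value,
                    "significant": cmp_res.significant,
                    "alpha": thr.alpha,
                }
                pe_comparisons.append(entry)
                if cmp_res.significant:
                    significant_pe.append(entry)
        pe_section["comparisons"] = pe_comparisons

    flag = bool(mode_disagreements or significant_pe)
    reasons = []
    for tid in mode_disagreements:
        reasons.append(
            f"dissolution similarity verdicts disagree between detection modes for "
            f"'{tid}': {verdict_by_mode[tid]}"
        )
    for e in significant_pe:
        reasons.append(
            f"Pe differs significantly between '{e['reference']}' and '{e['test']}' "
            f"(tag '{e['tag']}', {e['t_h']:g} h incubation, p = {e['p_value']:.3g})"
        )

    return {
        "schema_version": SCHEMA_VERSION,
        "reference_formulation": ref_id,
        "formulations": formulations,
        "dissolution": {
            "profile_summary": summary.to_dict(orient="records"),
            "fit_factors": comparisons,
        },
        "permeability": pe_section,
        "be_risk_flag": flag,
        "be_risk_reasons": reasons,
    }


def render_text_report(report: dict) -> str:
    """Human-readable rendering of :func:`run_be_report` output."""
    lines = [
        f"BE risk report (schema v{report['schema_version']})",
        f"Reference formulation: {report['reference_formulation']}",
        "",
        "Dissolution profile comparison (f1/f2):",
    ]
    for c in report["dissolution"]["fit_factors"]:
        lines.append(
            f"  {c['test']} vs {c['reference']} [{c['detection_mode']}]: "
            f"f1 = {c['f1']:.1f}, f2 = {c['f2']:.1f} -> {c['verdict']} "
            f"(n = {c['n_points']})"
        )
    perm = report["permeability"]
    if perm.get("present"):
        lines.append("")
        lines.append("Effective permeability (Pe, 1e-6 cm/s):")
        for r in perm["results"]:
            pe = "n/a" if r["pe_mean_e6_cm_s"] is None else f"{r['pe_mean_e6_cm_s']:.2f}"
            rsd = "n/a" if r["rsd_pct"] is None else f"{r['rsd_pct']:.1f}"
            lines.append(
                f"  {r['sample_label']} @ {r['t_h']:g} h: Pe = {pe}, RSD% = {rsd}, "
                f"n = {r['n_wells']} (excluded {r['n_excluded']})"
            )
        for c in perm.get("comparisons", []):
            star = "*" if c["significant"] else ""
            lines.append(
                f"  compare {c['test']} vs {c['reference']} (tag '{c['tag']}', "
                f"{c['t_h']:g} h): p = {c['p_value']:.3g}{star}"
            )
    else:
        lines.append("")
        lines.append("Permeability: absent (no plate data)")
    lines.append("")
    if report["be_risk_flag"]:
        lines.append("OVERALL: BE RISK FLAG RAISED")
        for r in report["be_risk_reasons"]:
            lines.append(f"  - {r}")
    else:
        lines.append("OVERALL: no bioequivalence risk signal")
    return "\n".join(lines)
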