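"""Cohort-level pipeline: CSV tables in, scores / labels / analysis out.

The stages are re-runnable from any intermediate table -- scoring consumes
the monitoring and therapy CSVs, classification consumes monitoring +
therapy + microbiology (to tell saline shams apart), analysis consumes the
scores and microbiology tables.  No hidden state passes between stages.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierPolicy, FulminantPolicy, classify_animal, flag_fulminant
from .samples import MonitoringSample, TherapyState
from .scoring import Mode, PSofaResult, compute_psofa
from .stats import CorrelationResult, kruskal_wallis_dunn, spearman

__all__ = [
    "samples_from_frame",
    "therapy_from_frame",
    "score_cohort",
    "animal_mean_scores",
    "classify_cohort",
    "analyze_cohort",
]

_THERAPY_COLS = (
    "norepinephrine_ug_kg_min",
    "furosemide_cum_mg",
    "crystalloid_ml_kg_h",
    "minutes_on_fluid_resuscitation",
)


def _clean(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def samples_from_frame(df: pd.DataFrame) -> dict[str, list[MonitoringSample]]:
    """Per-animal time-sorted MonitoringSample lists from a tidy table."""
    if "animal_id" not in df.columns or "time_h" not in df.columns:
        raise ValueError("monitoring table needs animal_id and time_h columns")
    known = set(MonitoringSample.field_names())
    out: dict[str, list[MonitoringSample]] = {}
    for aid, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("time_h")
        out[str(aid)] = [
            MonitoringSample(
                **{
                    k: _clean(v)
                    for k, v in row.items()
                    if k in known and _clean(v) is not None
                }
            )
            for row in g.to_dict("records")
        ]
    return out


def therapy_from_frame(
    df: pd.DataFrame | None,
) -> dict[str, list[tuple[float, TherapyState]]]:
    """animal_id -> time-sorted (time_h, TherapyState) from a therapy log."""
    if df is None or len(df) == 0:
        return {}
    out: dict[str, list[tuple[float, TherapyState]]] = {}
    for row in df.to_dict("records"):
        out.setdefault(str(row["animal_id"]), []).append(
            (
                float(row["time_h"]),
                TherapyState(
                    **{c: float(row.get(c, 0.0) or 0.0) for c in _THERAPY_COLS}
                ),
            )
        )
    for states in out.values():
        states.sort(key=lambda p: p[0])
    return out


_ZERO_STATE = TherapyState()


def _therapy_at(
    lookup: dict[str, list[tuple[float, TherapyState]]], aid: str, t: float
) -> TherapyState:
    """Most recent therapy state at or before t (zero state if none)."""
    best = _ZERO_STATE
    for tt, state in lookup.get(aid, ()):
        if tt > t:
            break
        best = state
    return best


def score_cohort(
    monitoring: pd.DataFrame,
    therapy: pd.DataFrame | None = None,
    window: tuple[float, float] = (16.0, 24.0),
    mode: Mode = "pig",
) -> pd.DataFrame:
    """One scored row per animal-hour inside the scoring window."""
    if len(monitoring) == 0:
        raise ValueError("empty monitoring table")
    per_animal = samples_from_frame(monitoring)
    lookup = therapy_from_frame(therapy)
    lo, hi = window
    rows = []
    for aid, samples in per_animal.items():
        for s in samples:
            if not (lo <= s.time_h <= hi):
                continue
            r = compute_psofa(s, _therapy_at(lookup, aid, s.time_h), mode)
            rows.append(
                {
                    "animal_id": aid,
                    "time_h": r.time_h,
                    "respiration": r.respiration,
                    "cardiovascular": r.cardiovascular,
                    "renal": r.renal,
                    "liver": r.liver,
                    "coagulation": r.coagulation,
                    "total_3d": r.total_3d,
                    "total_5d": r.total_5d,
                    "mode": mode,
                }
            )
    return pd.DataFrame(rows)


def animal_mean_scores(
    monitoring: pd.DataFrame,
    therapy: pd.DataFrame | None = None,
    window: tuple[float, float] = (16.0, 24.0),
    mode: Mode = "pig",
) -> pd.DataFrame:
    """Unrounded per-animal means of the hourly totals over the window.

    Animals whose trajectory ends before the window (humanely terminated)
    are scored over their available hours instead and flagged
    ``windowed = False``, so severity recovery can include them.
    """
    per_animal = samples_from_frame(monitoring)
    lookup = therapy_from_frame(therapy)
    lo, hi = window
    rows = []
    for aid, samples in per_animal.items():
        in_win = [s for s in samples if lo <= s.time_h <= hi]
        windowed = bool(in_win)
        used = in_win if windowed else samples
        results = [
            compute_psofa(s, _therapy_at(lookup, aid, s.time_h), mode)
            for s in used
        ]
        rows.append(
            {
                "animal_id": aid,
                "n_hours": len(results),
                "mean_3d": float(np.mean([r.total_3d for r in results])),
                "mean_5d": (
                    float(np.mean([r.total_5d for r in results]))
                    if all(r.total_5d is not None for r in results)
                    else np.nan
                ),
                "windowed": windowed,
            }
        )
    return pd.DataFrame(rows)


def classify_cohort(
    monitoring: pd.DataFrame,
    therapy: pd.DataFrame | None = None,
    microbiology: pd.DataFrame | None = None,
    policy: ClassifierPolicy | None = None,
    fulminant_policy: FulminantPolicy | None = None,
    mode: Mode = "pig",
) -> pd.DataFrame:
    """Severity label per animal with the criteria audit trail.

    Saline shams are recognized by a zero/absent inoculum record; animals
    whose trajectory ends before the monitoring window are checked against
    the humane-endpoint rule and must satisfy it (otherwise the trajectory
    is invalid and an error is raised).
    """
    policy = policy or ClassifierPolicy()
    per_animal = samples_from_frame(monitoring)
    lookup = therapy_from_frame(therapy)
    inoculated: dict[str, float] = {}
    if microbiology is not None:
        for row in microbiology.to_dict("records"):
            inoculated[str(row["animal_id"])] = float(row.get("total_cfu", 0.0))

    rows = []
    for aid, samples in per_animal.items():
        is_sham = inoculated.get(aid, 0.0) <= 0 if inoculated else False
        t_max = max(s.time_h for s in samples)
        fulminant_flag = False
        fulminant_time = None
        if not is_sham and t_max < 16.0:
            fired, _reasons = flag_fulminant(samples, fulminant_policy)
            fulminant_flag = fired
            fulminant_time = t_max

        scores: list[PSofaResult] = []
        if not fulminant_flag and t_max >= policy.allocation_time_h:
            scores = [
                compute_psofa(s, _therapy_at(lookup, aid, s.time_h), mode)
                for s in samples
                if s.time_h >= 16.0
            ]
        label = classify_animal(
            scores,
            [(s.time_h, s.lactate_mmol_L) for s in samples
             if s.lactate_mmol_L is not None],
            lookup.get(aid, []),
            policy,
            is_sham=is_sham,
            fulminant_flag=fulminant_flag,
            fulminant_time_h=fulminant_time,
            map_series=[(s.time_h, s.map_mmHg) for s in samples
                        if s.map_mmHg is not None],
        )
        rows.append(
            {
                "animal_id": aid,
                "label": label.label,
                "decision_time_h": label.decision_time_h,
                "criteria_met": ";".join(label.criteria_met),
            }
        )
    return pd.DataFrame(rows)


def analyze_cohort(
    monitoring: pd.DataFrame,
    therapy: pd.DataFrame | None,
    microbiology: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    window: tuple[float, float] = (16.0, 24.0),
    mode: Mode = "pig",
    include_labels: Sequence[str] | None = ("sepsis", "septic_shock"),
) -> dict:
    """Severity-vs-load correlation analysis and between-group rank tests.

    Correlates log10 inoculum CFU (and, where positive, log10 hemoculture
    CFU) against the per-animal mean 3D and 5D scores, Spearman
    throughout.  ``include_labels`` restricts the correlation to the given
    label set (default: the septic animals, as in the study design); pass
    None to use every inoculated animal.
    """
    means = animal_mean_scores(monitoring, therapy, window, mode)
    if labels is None:
        labels = classify_cohort(monitoring, therapy, microbiology)
        label_col = "label"
    else:
        label_col = "true_label" if "true_label" in labels.columns else "label"
    df = (
        means.merge(microbiology, on="animal_id")
        .merge(labels[["animal_id", label_col]], on="animal_id")
        .rename(columns={label_col: "label"})
    )
    inoc = df[df["total_cfu"] > 0]
    if include_labels is not None:
        inoc = inoc[inoc["label"].isin(include_labels)]

    out: dict = {"per_animal": df}
    correlations = {}
    for score_col in ("mean_3d", "mean_5d"):
        sub = inoc.dropna(subset=[score_col])
        if len(sub) >= 3 and sub[score_col].nunique() > 1:
            correlations[f"inoculum_vs_{score_col}"] = spearman(
                np.log10(sub["total_cfu"]), sub[score_col]
            )
        hc = sub[sub.get("hemoculture_cfu_per_ml", pd.Series(0, index=sub.index)) > 0]
        if len(hc) >= 3 and hc[score_col].nunique() > 1:
            correlations[f"hemoculture_vs_{score_col}"] = spearman(
                np.log10(hc["hemoculture_cfu_per_ml"]), hc[score_col]
            )
    out["correlations"] = correlations

    groups, names = [], []
    for lbl, g in df.dropna(subset=["mean_5d"]).groupby("label"):
        if len(g) >= 2:
            groups.append(g["mean_5d"].to_numpy())
            names.append(lbl)
    if len(groups) >= 2:
        out["group_test"] = kruskal_wallis_dunn(groups, names)
    return out
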