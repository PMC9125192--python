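"""Pig-specific SOFA (pSOFA) domain scoring.

Five organ-dysfunction domains are each scored 0-4: respiration
(PaO2/FiO2), cardiovascular (MAP / norepinephrine), renal (urine output /
furosemide), liver (bilirubin) and coagulation (platelets).  The 3-domain
total (respiration + cardiovascular + renal, range 0-12) needs online
measurements only; the 5-domain total (plus liver and coagulation, range
0-20) additionally needs laboratory values.

Interval convention: each category is half-open, and the healthy "0"
category is closed at its printed boundary (PaO2/FiO2 >= 400, MAP >= 75,
urine >= 0.5, bilirubin <= 20, platelets >= 200 all score 0).  Drug-based
scores (vasopressor, diuretic) dominate measurement-based scores: the final
domain score is the maximum of the two pathways.

Pig thresholds differ from the human convention for MAP (normal >= 75 vs
>= 70 mmHg, reflecting anesthesia-induced hypotension) and platelets
(normal >= 200e9/L vs >= 150e9/L, pigs having a broader platelet range);
``mode="human"`` selects the human bands, including the human vasopressor
dose bands (dopamine/epinephrine/dobutamine).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .samples import MonitoringSample, TherapyState

__all__ = [
    "DomainScore",
    "PSofaResult",
    "TimeseriesSummary",
    "score_respiration",
    "score_cardiovascular",
    "score_renal",
    "score_liver",
    "score_coagulation",
    "compute_psofa",
    "score_timeseries",
    "cohort_score_table",
]

Mode = Literal["pig", "human"]

DOMAINS = ("respiration", "cardiovascular", "renal", "liver", "coagulation")


@dataclass(frozen=True)
class DomainScore:
    domain: str
    score: int

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.score not in (0, 1, 2, 3, 4):
            raise ValueError(f"score must be in 0..4, got {self.score!r}")


@dataclass(frozen=True)
class PSofaResult:
    """Domain scores and totals at one time point.

    ``total_5d`` is ``None`` (and ``three_d_only`` True) when a laboratory
    domain was unavailable; missing laboratory values are never imputed as
    healthy.
    """

    time_h: float
    respiration: int
    cardiovascular: int
    renal: int
    liver: Optional[int]
    coagulation: Optional[int]
    total_3d: int
    total_5d: Optional[int]
    three_d_only: bool

    @property
    def domain_scores(self) -> tuple[DomainScore, ...]:
        out = [
            DomainScore("respiration", self.respiration),
            DomainScore("cardiovascular", self.cardiovascular),
            DomainScore("renal", self.renal),
        ]
        if not self.three_d_only:
            out.append(DomainScore("liver", self.liver))
            out.append(DomainScore("coagulation", self.coagulation))
        return tuple(out)


def _check_finite_nonneg(name: str, value: float) -> None:
    if value is None or not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


def score_respiration(pao2_fio2: float) -> DomainScore:
    """Respiration score from the PaO2/FiO2 ratio (dimensionless)."""
    _check_finite_nonneg("pao2_fio2", pao2_fio2)
    if pao2_fio2 >= 400:
        s = 0
    elif pao2_fio2 >= 300:
        s = 1
    elif pao2_fio2 >= 200:
        s = 2
    elif pao2_fio2 >= 100:
        s = 3
    else:
        s = 4
    return DomainScore("respiration", s)


def score_cardiovascular(
    map_mmHg: float,
    therapy: TherapyState | None = None,
    mode: Mode = "pig",
) -> DomainScore:
    """Cardiovascular score from MAP and vasopressor support.

    Pig mode: MAP >= 75 -> 0, < 75 -> 1, < 65 -> 2; norepinephrine
    <= 0.1 ug/kg/min -> 3, > 0.1 -> 4.  Human mode uses MAP 70 mmHg and the
    human catecholamine dose bands.  The vasopressor pathway takes
    precedence (maximum of the two pathways).
    """
    if map_mmHg is None or not math.isfinite(map_mmHg) or map_mmHg <= 0:
        raise ValueError(f"map_mmHg must be finite and > 0, got {map_mmHg!r}")
    therapy = therapy or TherapyState()
    ne = therapy.norepinephrine_ug_kg_min

    if mode == "pig":
        if map_mmHg >= 75:
            s = 0
        elif map_mmHg >= 65:
            s = 1
        else:
            s = 2
        if ne > 0.1:
            drug = 4
        elif ne > 0:
            drug = 3
        else:
            drug = 0
    elif mode == "human":
        dop = therapy.dopamine_ug_kg_min
        epi = therapy.epinephrine_ug_kg_min
        dob = therapy.dobutamine_ug_kg_min
        s = 0 if map_mmHg >= 70 else 1
        drug = 0
        if (0 < dop <= 5) or dob > 0:
            drug = 2
        if dop > 5 or (0 < epi <= 0.1) or (0 < ne <= 0.1):
            drug = 3
        if dop > 15 or epi > 0.1 or ne > 0.1:
            drug = 4
    else:
        raise ValueError(f"mode must be 'pig' or 'human', got {mode!r}")
    return DomainScore("cardiovascular", max(s, drug))


def score_renal(
    urine_output_ml_kg_h: float, therapy: TherapyState | None = None
) -> DomainScore:
    """Renal score from hourly urine output and cumulative furosemide.

    Urine >= 0.5 mL/kg/h -> 0, < 0.5 -> 1, < 0.25 -> 2; furosemide given
    and cumulative dose <= 10 mg -> 3, > 10 mg -> 4 (diuretic pathway
    dominates).
    """
    _check_finite_nonneg("urine_output_ml_kg_h", urine_output_ml_kg_h)
    therapy = therapy or TherapyState()
    furo = therapy.furosemide_cum_mg
    if urine_output_ml_kg_h >= 0.5:
        s = 0
    elif urine_output_ml_kg_h >= 0.25:
        s = 1
    else:
        s = 2
    if furo > 10:
        drug = 4
    elif furo > 0:
        drug = 3
    else:
        drug = 0
    return DomainScore("renal", max(s, drug))


def score_liver(bilirubin_umol_L: float) -> DomainScore:
    """Liver score from plasma bilirubin (umol/L); <= 20 is normal."""
    _check_finite_nonneg("bilirubin_umol_L", bilirubin_umol_L)
    if bilirubin_umol_L <= 20:
        s = 0
    elif bilirubin_umol_L <= 32:
        s = 1
    elif bilirubin_umol_L <= 101:
        s = 2
    elif bilirubin_umol_L <= 204:
        s = 3
    else:
        s = 4
    return DomainScore("liver", s)


_PLATELET_EDGES = {"pig": (200, 150, 100, 50), "human": (150, 100, 50, 20)}


def score_coagulation(platelets_1e9_L: float, mode: Mode = "pig") -> DomainScore:
    """Coagulation score from platelet count (1e9/L); pig-normal >= 200."""
    _check_finite_nonneg("platelets_1e9_L", platelets_1e9_L)
    if mode not in _PLATELET_EDGES:
        raise ValueError(f"mode must be 'pig' or 'human', got {mode!r}")
    e0, e1, e2, e3 = _PLATELET_EDGES[mode]
    if platelets_1e9_L >= e0:
        s = 0
    elif platelets_1e9_L >= e1:
        s = 1
    elif platelets_1e9_L >= e2:
        s = 2
    elif platelets_1e9_L >= e3:
        s = 3
    else:
        s = 4
    return DomainScore("coagulation", s)


def compute_psofa(
    sample: MonitoringSample,
    therapy: TherapyState | None = None,
    mode: Mode = "pig",
) -> PSofaResult:
    """Score one monitoring sample; 3D-only if laboratory values are absent.

    Raises ``ValueError`` if any of the three online domains (respiration,
    cardiovascular, renal) is missing: the 3-domain score is the minimum
    reportable result and is never imputed.
    """
    therapy = therapy or TherapyState()
    missing = [
        n
        for n, v in (
            ("pao2_fio2", sample.pao2_fio2),
            ("map_mmHg", sample.map_mmHg),
            ("urine_output_ml_kg_h", sample.urine_output_ml_kg_h),
        )
        if v is None
    ]
    if missing:
        raise ValueError(f"3D-pSOFA inputs missing: {', '.join(missing)}")

    resp = score_respiration(sample.pao2_fio2).score
    cardio = score_cardiovascular(sample.map_mmHg, therapy, mode).score
    renal = score_renal(sample.urine_output_ml_kg_h, therapy).score
    total_3d = resp + cardio + renal

    liver = coag = total_5d = None
    three_d_only = (
        sample.bilirubin_umol_L is None or sample.platelets_1e9_L is None
    )
    if not three_d_only:
        liver = score_liver(sample.bilirubin_umol_L).score
        coag = score_coagulation(sample.platelets_1e9_L, mode).score
        total_5d = total_3d + liver + coag
    return PSofaResult(
        time_h=sample.time_h,
        respiration=resp,
        cardiovascular=cardio,
        renal=renal,
        liver=liver,
        coagulation=coag,
        total_3d=total_3d,
        total_5d=total_5d,
        three_d_only=three_d_only,
    )


@dataclass(frozen=True)
class TimeseriesSummary:
    """Per-animal summary over the scoring window: unrounded means of the
    hourly totals.  ``mean_5d`` is None if any in-window hour was 3D-only."""

    window: tuple[float, float]
    n_hours: int
    mean_3d: float
    mean_5d: Optional[float]
    results: tuple[PSofaResult, ...]


def score_timeseries(
    samples: Sequence[MonitoringSample],
    therapies: Sequence[TherapyState] | TherapyState | None = None,
    window: tuple[float, float] = (16.0, 24.0),
    mode: Mode = "pig",
) -> TimeseriesSummary:
    """Score every in-window sample of one animal's ordered trajectory.

    ``therapies`` may be a parallel sequence (one state per sample), a
    single state applied throughout, or None.  The summary mean is the
    arithmetic mean of the hourly integer totals, left unrounded;
    classification decisions elsewhere use the per-time-point totals.
    """
    times = [s.time_h for s in samples]
    if times != sorted(times):
        raise ValueError("samples must be sorted by time_h")
    if isinstance(therapies, TherapyState) or therapies is None:
        therapies = [therapies or TherapyState()] * len(samples)
    if len(therapies) != len(samples):
        raise ValueError("therapies must parallel samples")

    lo, hi = window
    results = [
        compute_psofa(s, t, mode)
        for s, t in zip(samples, therapies)
        if lo <= s.time_h <= hi
    ]
    if not results:
        raise ValueError(f"no samples in scoring window [{lo}, {hi}]")
    mean_3d = float(np.mean([r.total_3d for r in results]))
    mean_5d = None
    if all(not r.three_d_only for r in results):
        mean_5d = float(np.mean([r.total_5d for r in results]))
    return TimeseriesSummary(
        window=(lo, hi),
        n_hours=len(results),
        mean_3d=mean_3d,
        mean_5d=mean_5d,
        results=tuple(results),
    )


def cohort_score_table(
    per_animal: dict[str, TimeseriesSummary]
) -> pd.DataFrame:
    """Tidy score table for a cohort plus per-hour cross-animal medians.

    Returns one row per animal-hour with the five domain columns and both
    totals; the per-hour median across animals is available by grouping on
    ``time_h`` (provided here as the ``median_*`` convenience columns).
    """
    rows = []
    for animal, summ in per_animal.items():
        for r in summ.results:
            rows.append(
                {
                    "animal_id": animal,
                    "time_h": r.time_h,
                    "respiration": r.respiration,
                    "cardiovascular": r.cardiovascular,
                    "renal": r.renal,
                    "liver": r.liver,
                    "coagulation": r.coagulation,
                    "total_3d": r.total_3d,
                    "total_5d": r.total_5d,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    med = df.groupby("time_h")[["total_3d", "total_5d"]].median()
    df = df.join(
        med.rename(
            columns={"total_3d": "median_3d", "total_5d": "median_5d"}
        ),
        on="time_h",
    )
    return df
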