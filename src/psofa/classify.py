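"""Sepsis-3-adapted severity classification of animal trajectories.

Inoculated animals are allocated at a fixed decision time (default 18 h
after inoculation) using the consensus criteria: *sepsis* requires organ
damage (total pSOFA >= 2) together with lactate >= 2 mmol/L; *septic
shock* is sepsis with vasopressor-dependent hypotension (norepinephrine
required to hold MAP >= 65 mmHg despite adequate fluid resuscitation).
Animals meeting neither criterion through the end of observation are
*non-responders*; saline controls pass through as *sham*; animals whose
early (<= 15 h) course meets the humane-endpoint deterioration rule are
*fulminant* and never reach the monitoring window.

The organ-damage criterion uses the 5-domain total when available and
falls back to the 3-domain total otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .samples import MonitoringSample, TherapyState
from .scoring import PSofaResult

__all__ = [
    "SeverityLabel",
    "ClassifierPolicy",
    "FulminantPolicy",
    "classify_animal",
    "flag_fulminant",
]

LABELS = ("sham", "non_responder", "sepsis", "septic_shock", "fulminant")


@dataclass(frozen=True)
class SeverityLabel:
    label: str
    decision_time_h: float
    criteria_met: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class ClassifierPolicy:
    """Allocation-rule knobs.

    ``strict_shock`` additionally requires documented hypotension (MAP <
    the shock MAP target on >= 2 consecutive hourly samples while off
    vasopressor) and, when lactate data allow, persistent lactate >= 2 --
    the stricter consensus reading; the default requires only vasopressor
    dependence at allocation on top of the sepsis criteria.
    """

    allocation_time_h: float = 18.0
    sofa_threshold: int = 2
    lactate_threshold_mmol_L: float = 2.0
    shock_map_target_mmHg: float = 65.0
    use_5d: bool = True
    strict_shock: bool = False


@dataclass(frozen=True)
class FulminantPolicy:
    """Humane-endpoint early-deterioration rule (conjunctive default):
    at the check time, lactate and bilirubin above baseline by the given
    multiples AND SvO2 and albumin below baseline by the given fractions;
    explicit acute respiratory/circulatory failure flags short-circuit."""

    check_time_h: float = 6.0
    horizon_h: float = 15.0
    lactate_multiple: float = 2.0
    bilirubin_multiple: float = 1.5
    svo2_drop_fraction: float = 0.20
    albumin_drop_fraction: float = 0.20


def _total(result: PSofaResult, use_5d: bool) -> int:
    if use_5d and result.total_5d is not None:
        return result.total_5d
    return result.total_3d


def _at_time(rows: Sequence, time_h: float, key=lambda r: r.time_h):
    """Last entry at or before time_h, or None."""
    best = None
    for r in rows:
        if key(r) <= time_h:
            best = r
    return best


def flag_fulminant(
    early_samples: Sequence[MonitoringSample],
    policy: FulminantPolicy | None = None,
    *,
    acute_failure_flags: Sequence[str] = (),
) -> tuple[bool, tuple[str, ...]]:
    """Evaluate the early-deterioration humane-endpoint rule on <= 15 h data.

    The first sample is the baseline.  Returns (fired, reasons); the rule
    is conjunctive over the four plasma/oxygenation conditions unless an
    acute respiratory/circulatory failure flag is supplied.
    """
    policy = policy or FulminantPolicy()
    if acute_failure_flags:
        return True, tuple(f"acute_failure:{f}" for f in acute_failure_flags)
    early = [s for s in early_samples if s.time_h <= policy.horizon_h]
    if len(early) < 2:
        return False, ()
    base = early[0]
    probe = _at_time(early[1:], policy.check_time_h)
    if probe is None or probe.time_h == base.time_h:
        return False, ()

    reasons = []

    def _ratio_ok(val, ref):
        return val is not None and ref is not None and ref > 0

    if _ratio_ok(probe.lactate_mmol_L, base.lactate_mmol_L) and (
        probe.lactate_mmol_L >= policy.lactate_multiple * base.lactate_mmol_L
    ):
        reasons.append("lactate_rise")
    if _ratio_ok(probe.bilirubin_umol_L, base.bilirubin_umol_L) and (
        probe.bilirubin_umol_L
        >= policy.bilirubin_multiple * base.bilirubin_umol_L
    ):
        reasons.append("bilirubin_rise")
    if _ratio_ok(probe.svo2_fraction, base.svo2_fraction) and (
        probe.svo2_fraction
        <= (1 - policy.svo2_drop_fraction) * base.svo2_fraction
    ):
        reasons.append("svo2_fall")
    if _ratio_ok(probe.albumin_g_L, base.albumin_g_L) and (
        probe.albumin_g_L
        <= (1 - policy.albumin_drop_fraction) * base.albumin_g_L
    ):
        reasons.append("albumin_fall")

    fired = len(reasons) == 4
    return fired, tuple(reasons) if fired else ()


def classify_animal(
    scores: Sequence[PSofaResult],
    lactate: Sequence[tuple[float, float]],
    therapy_log: Sequence[tuple[float, TherapyState]],
    policy: ClassifierPolicy | None = None,
    *,
    is_sham: bool = False,
    fulminant_flag: bool = False,
    fulminant_time_h: Optional[float] = None,
    map_series: Sequence[tuple[float, float]] = (),
) -> SeverityLabel:
    """Assign the severity label from one animal's trajectories.

    ``lactate`` and ``map_series`` are (time_h, value) pairs; the therapy
    log is (time_h, TherapyState).  A trajectory ending before the
    allocation time without a fulminant flag is an error: the animal's
    outcome is undefined.
    """
    policy = policy or ClassifierPolicy()
    t_alloc = policy.allocation_time_h

    if is_sham:
        return SeverityLabel("sham", t_alloc, ("saline_control",))
    if fulminant_flag:
        t = fulminant_time_h if fulminant_time_h is not None else 6.0
        if t >= 16.0:
            raise ValueError(
                "fulminant decisions must precede the invasive-monitoring window"
            )
        return SeverityLabel("fulminant", t, ("humane_endpoint",))

    if not scores or max(r.time_h for r in scores) < t_alloc:
        raise ValueError(
            "trajectory ends before the allocation time without a fulminant flag"
        )

    score_at = _at_time(scores, t_alloc)
    lact_at = _at_time(lactate, t_alloc, key=lambda p: p[0])
    ther_at = _at_time(therapy_log, t_alloc, key=lambda p: p[0])

    criteria: list[str] = []
    total = _total(score_at, policy.use_5d)
    sofa_ok = total >= policy.sofa_threshold
    lact_ok = (
        lact_at is not None and lact_at[1] >= policy.lactate_threshold_mmol_L
    )
    if sofa_ok:
        criteria.append(f"sofa_total>={policy.sofa_threshold}")
    if lact_ok:
        criteria.append(f"lactate>={policy.lactate_threshold_mmol_L}")
    sepsis = sofa_ok and lact_ok

    on_pressor = (
        ther_at is not None and ther_at[1].norepinephrine_ug_kg_min > 0
    )
    # documented hypotension before vasopressor start, for the audit trail
    pre_pressor_hypo = _consecutive_hypotension(
        map_series, therapy_log, policy.shock_map_target_mmHg, t_alloc
    )
    shock = sepsis and on_pressor
    if policy.strict_shock:
        shock = shock and pre_pressor_hypo
    if on_pressor:
        criteria.append("vasopressor_dependent")
    if pre_pressor_hypo:
        criteria.append("persistent_hypotension")

    if shock:
        return SeverityLabel("septic_shock", t_alloc, tuple(criteria))
    if sepsis:
        return SeverityLabel("sepsis", t_alloc, tuple(criteria))
    return SeverityLabel("non_responder", t_alloc, tuple(criteria))


def _consecutive_hypotension(
    map_series: Sequence[tuple[float, float]],
    therapy_log: Sequence[tuple[float, TherapyState]],
    target: float,
    t_alloc: float,
) -> bool:
    """MAP < target on >= 2 consecutive hourly samples while off vasopressor."""
    run = 0
    for t, m in sorted(map_series):
        if t > t_alloc:
            break
        ther = _at_time(therapy_log, t, key=lambda p: p[0])
        off = ther is None or ther[1].norepinephrine_ug_kg_min == 0
        if off and m < target:
            run += 1
            if run >= 2:
                return True
        else:
            run = 0
    return False
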