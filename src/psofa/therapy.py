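"""Goal-directed supportive-therapy trigger rules.

The protocol these rules encode: goal-directed crystalloid resuscitation
toward a physiological stroke volume index (SVI 35-45 mL/beat/m2), with
norepinephrine started only for fluid-refractory hypotension (MAP down to
55 mmHg after at least 60 min of crystalloid challenge) and furosemide
(10 mg iv boluses, repeated if refractory) for oliguria (< 0.25 mL/kg/h
despite fluids) or pulmonary fluid overload (ELWI > 10 mL/kg).

The trigger engine is a pure function of (sample, therapy state, policy);
it emits actions, it does not mutate state.  Dose titration of a running
norepinephrine infusion (start 0.05 ug/kg/min, doubling each unresponsive
hour) is a simulator convention, not part of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import FrozenSet

from .samples import MonitoringSample, TherapyState

__all__ = ["TherapyAction", "TherapyPolicy", "evaluate_triggers", "titrate_norepinephrine"]


class TherapyAction(str, Enum):
    START_NOREPINEPHRINE = "start_norepinephrine"
    GIVE_FUROSEMIDE = "give_furosemide"
    GIVE_FLUID_BOLUS = "give_fluid_bolus"


@dataclass(frozen=True)
class TherapyPolicy:
    """Thresholds of the goal-directed protocol (defaults as administered)."""

    map_norepi_trigger_mmHg: float = 55.0
    min_fluid_minutes_before_norepi: float = 60.0
    urine_furosemide_trigger: float = 0.25      # mL/kg/h
    elwi_furosemide_trigger: float = 10.0       # mL/kg
    furosemide_bolus_mg: float = 10.0
    svi_target_range: tuple[float, float] = (35.0, 45.0)  # mL/beat/m2
    cvp_range: tuple[float, float] = (5.0, 8.0)           # mmHg
    fluid_bolus_ml_kg: float = 15.0
    glucose_range_mmol_L: tuple[float, float] = (4.1, 5.6)
    ppv_range_pct: tuple[float, float] = (8.0, 12.0)
    norepi_start_ug_kg_min: float = 0.05       # simulator titration start
    refractory_rel_tol: float = 0.10           # furosemide response tolerance

    def __post_init__(self) -> None:
        for name in (
            "map_norepi_trigger_mmHg", "min_fluid_minutes_before_norepi",
            "urine_furosemide_trigger", "elwi_furosemide_trigger",
            "furosemide_bolus_mg", "fluid_bolus_ml_kg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("svi_target_range", "cvp_range", "glucose_range_mmol_L",
                     "ppv_range_pct"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered (lo, hi) pair")


def evaluate_triggers(
    sample: MonitoringSample,
    therapy: TherapyState,
    policy: TherapyPolicy | None = None,
    *,
    time_h: float | None = None,
) -> FrozenSet[TherapyAction]:
    """Return the set of supportive-therapy actions warranted right now.

    - start_norepinephrine: MAP at/below the trigger despite at least the
      minimum duration of ongoing crystalloid resuscitation, and no
      norepinephrine running yet.
    - give_furosemide: oliguria below the trigger despite ongoing fluids,
      or ELWI above its trigger; repeatable on refractory oliguria.
    - give_fluid_bolus: SVI below its target range.

    ``time_h`` cross-checks that sample and therapy refer to the same time
    point when the caller tracks therapy rows with timestamps.
    """
    policy = policy or TherapyPolicy()
    if time_h is not None and time_h != sample.time_h:
        raise ValueError(
            f"therapy time {time_h} does not match sample time {sample.time_h}"
        )
    actions: set[TherapyAction] = set()

    if (
        sample.map_mmHg is not None
        and sample.map_mmHg <= policy.map_norepi_trigger_mmHg
        and therapy.minutes_on_fluid_resuscitation
        >= policy.min_fluid_minutes_before_norepi
        and therapy.norepinephrine_ug_kg_min == 0
    ):
        actions.add(TherapyAction.START_NOREPINEPHRINE)

    oliguric = (
        sample.urine_output_ml_kg_h is not None
        and sample.urine_output_ml_kg_h < policy.urine_furosemide_trigger
        and therapy.crystalloid_ml_kg_h > 0
    )
    wet_lung = (
        sample.elwi_ml_kg is not None
        and sample.elwi_ml_kg > policy.elwi_furosemide_trigger
    )
    if oliguric or wet_lung:
        actions.add(TherapyAction.GIVE_FUROSEMIDE)

    if sample.ci_L_min_m2 is not None and sample.hr_bpm:
        svi = sample.ci_L_min_m2 / sample.hr_bpm * 1000.0
        if svi < policy.svi_target_range[0]:
            actions.add(TherapyAction.GIVE_FLUID_BOLUS)

    return frozenset(actions)


def titrate_norepinephrine(
    current_dose: float, map_mmHg: float, policy: TherapyPolicy | None = None
) -> float:
    """Simulator dose rule: start at the policy's starting rate, double each
    hour the MAP stays at/below the trigger, halve toward zero once above."""
    policy = policy or TherapyPolicy()
    if current_dose == 0:
        return policy.norepi_start_ug_kg_min
    if map_mmHg <= policy.map_norepi_trigger_mmHg:
        return current_dose * 2.0
    return current_dose
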