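"""Core record types for porcine sepsis monitoring.

A :class:`MonitoringSample` is one animal-hour of physiological and
laboratory measurements; a :class:`TherapyState` is the supportive-therapy
record (vasopressor dose rate, cumulative diuretic dose, fluid state) at the
same time point.  Both are plain frozen dataclasses: most laboratory fields
are optional because the simplified 3-domain score is computed from online
measurements only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

__all__ = ["MonitoringSample", "TherapyState"]

#: fields that must be non-negative when present
_NONNEG = (
    "time_h", "pao2_fio2", "urine_output_ml_kg_h", "bilirubin_umol_L",
    "platelets_1e9_L", "lactate_mmol_L", "pao2_mmHg", "hb_g_dL", "co_L_min",
    "ci_L_min_m2", "hr_bpm", "ast_U_L", "alt_U_L", "creatinine_umol_L",
    "albumin_g_L", "wbc_1e9_L", "elwi_ml_kg", "tnfa", "il10", "bet", "hmgb1",
)
#: fields that must lie in [0, 1]
_FRACTIONS = ("fio2_fraction", "sao2_fraction", "svo2_fraction")


@dataclass(frozen=True)
class MonitoringSample:
    """One animal-hour of measurements, time in hours since inoculation.

    Concentration units follow the bedside conventions of the model:
    pressures in mmHg, bilirubin and creatinine in umol/L, platelets and WBC
    in 1e9/L, lactate in mmol/L, hemoglobin in g/dL, saturations as
    fractions in [0, 1].  ``pao2_fio2`` may be given directly or derived
    from ``pao2_mmHg / fio2_fraction``.
    """

    time_h: float
    map_mmHg: Optional[float] = None
    pao2_fio2: Optional[float] = None
    urine_output_ml_kg_h: Optional[float] = None
    bilirubin_umol_L: Optional[float] = None
    platelets_1e9_L: Optional[float] = None
    lactate_mmol_L: Optional[float] = None
    pao2_mmHg: Optional[float] = None
    fio2_fraction: Optional[float] = None
    sao2_fraction: Optional[float] = None
    svo2_fraction: Optional[float] = None
    hb_g_dL: Optional[float] = None
    co_L_min: Optional[float] = None
    ci_L_min_m2: Optional[float] = None
    cvp_mmHg: Optional[float] = None
    hr_bpm: Optional[float] = None
    ast_U_L: Optional[float] = None
    alt_U_L: Optional[float] = None
    creatinine_umol_L: Optional[float] = None
    albumin_g_L: Optional[float] = None
    wbc_1e9_L: Optional[float] = None
    elwi_ml_kg: Optional[float] = None
    tnfa: Optional[float] = None
    il10: Optional[float] = None
    bet: Optional[float] = None
    hmgb1: Optional[float] = None

    def __post_init__(self) -> None:
        for name in _NONNEG:
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in _FRACTIONS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.map_mmHg is not None and self.map_mmHg < 0:
            raise ValueError("map_mmHg must be >= 0")
        if (
            self.pao2_fio2 is None
            and self.pao2_mmHg is not None
            and self.fio2_fraction
        ):
            object.__setattr__(
                self, "pao2_fio2", self.pao2_mmHg / self.fio2_fraction
            )

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class TherapyState:
    """Supportive-therapy state at one time point.

    ``norepinephrine_ug_kg_min`` is an instantaneous dose rate;
    ``furosemide_cum_mg`` the cumulative dose within the monitoring window.
    The dopamine/epinephrine/dobutamine fields exist only for human-mode
    cardiovascular scoring and default to zero.
    """

    norepinephrine_ug_kg_min: float = 0.0
    furosemide_cum_mg: float = 0.0
    crystalloid_ml_kg_h: float = 0.0
    minutes_on_fluid_resuscitation: float = 0.0
    dopamine_ug_kg_min: float = 0.0
    epinephrine_ug_kg_min: float = 0.0
    dobutamine_ug_kg_min: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v!r}")
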