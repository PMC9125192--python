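"""Derived oxygen-transport, hemodynamic and microcirculatory quantities.

Oxygen delivery and consumption follow the bedside formulas

    DO2 = CO x [(1.38 x Hb x SaO2) + (0.003 x PaO2)]
    VO2 = CO x [(1.38 x Hb x (SaO2 - SvO2)) + (0.003 x PaO2)]

with CO in L/min, Hb in g/dL, saturations as fractions and PaO2 in mmHg.
``units_mode="paper_literal"`` (default) multiplies exactly as written;
``"ml_per_min"`` applies the conventional x10 dL->L factor so DO2/VO2 come
out in mL O2/min.  Oxygen extraction ExO2 = VO2/DO2 is the extraction
fraction; the inverse ratio is available via ``inverse=True``.

SVRI and SVI are the standard indexed quantities: SVRI = (MAP - CVP)/flow,
SVI = CI/HR x 1000 (mL/beat/m2, matching the resuscitation target range
35-45).  PPV is the proportion of perfused vessels from sublingual
videomicroscopy segment tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = ["OxygenProfile", "oxygen_profile", "svri", "svi", "de_ritis", "ppv"]

UnitsMode = Literal["paper_literal", "ml_per_min"]


@dataclass(frozen=True)
class OxygenProfile:
    do2: float
    vo2: float
    exo2_fraction: float
    units_mode: str


def oxygen_profile(
    co: float,
    hb: float,
    sao2: float,
    svo2: float,
    pao2: float,
    units_mode: UnitsMode = "paper_literal",
    *,
    inverse: bool = False,
) -> OxygenProfile:
    """Compute DO2, VO2 and the extraction ratio ExO2 = VO2/DO2.

    Requires 0 <= SvO2 <= SaO2 <= 1 (venous saturation cannot exceed
    arterial: negative extraction is rejected).
    """
    if co <= 0 or hb <= 0:
        raise ValueError("co and hb must be > 0")
    if not (0.0 <= sao2 <= 1.0 and 0.0 <= svo2 <= 1.0):
        raise ValueError("saturations must be fractions in [0, 1]")
    if svo2 > sao2:
        raise ValueError(f"svo2 ({svo2}) > sao2 ({sao2}): negative extraction")
    if pao2 < 0:
        raise ValueError("pao2 must be >= 0")
    scale = 10.0 if units_mode == "ml_per_min" else 1.0
    if units_mode not in ("paper_literal", "ml_per_min"):
        raise ValueError(f"unknown units_mode {units_mode!r}")
    do2 = scale * co * (1.38 * hb * sao2 + 0.003 * pao2)
    vo2 = scale * co * (1.38 * hb * (sao2 - svo2) + 0.003 * pao2)
    ex = vo2 / do2
    if inverse:
        ex = 1.0 / ex
    return OxygenProfile(do2=do2, vo2=vo2, exo2_fraction=ex, units_mode=units_mode)


def svri(map_mmHg: float, cvp_mmHg: float, flow: float) -> float:
    """Vascular resistance index (MAP - CVP)/flow.

    ``flow`` is CI for the body-surface-indexed form or CO for the raw
    form; the caller chooses which flow it passes.
    """
    if flow <= 0:
        raise ValueError("flow must be > 0")
    if map_mmHg <= cvp_mmHg:
        raise ValueError(f"map ({map_mmHg}) must exceed cvp ({cvp_mmHg})")
    return (map_mmHg - cvp_mmHg) / flow


def svi(ci_L_min_m2: float, hr_bpm: float) -> float:
    """Stroke volume index CI/HR in mL/beat/m2 (x1000 L->mL)."""
    if ci_L_min_m2 <= 0:
        raise ValueError("ci must be > 0")
    if hr_bpm <= 0:
        raise ValueError("hr must be > 0")
    return ci_L_min_m2 / hr_bpm * 1000.0


def de_ritis(ast_U_L: float, alt_U_L: float) -> float:
    """De Ritis ratio AST/ALT (liver-damage pattern marker)."""
    if alt_U_L <= 0:
        raise ValueError("alt must be > 0")
    if ast_U_L < 0:
        raise ValueError("ast must be >= 0")
    return ast_U_L / alt_U_L


def ppv(segments: pd.DataFrame, *, quarter_col: str | None = None) -> float:
    """Proportion of perfused vessels (%) from a vessel-segment table.

    ``segments`` needs columns ``length_um`` (> 0) and ``perfused``
    (boolean or 0/1).  With ``quarter_col`` given, the ratio is computed
    per video quarter and the quarter means are averaged, mirroring the
    four-quarter analysis of each sublingual video clip.
    """
    if len(segments) == 0:
        raise ValueError("empty segment table")
    lengths = np.asarray(segments["length_um"], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("segment lengths must be > 0")
    perf = np.asarray(segments["perfused"], dtype=bool)
    if quarter_col is not None:
        vals = [
            100.0 * g.loc[g["perfused"].astype(bool), "length_um"].sum()
            / g["length_um"].sum()
            for _, g in segments.groupby(quarter_col)
        ]
        return float(np.mean(vals))
    return float(100.0 * lengths[perf].sum() / lengths.sum())
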