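"""Microbial load quantification and inoculum severity bands.

Viable counts come from serial-dilution plating: CFU/mL = colonies x
dilution factor / plated volume (protocol plates 0.1 mL).  The total load
of the 200-mL inducer suspension maps onto ordered severity bands:
below 1.34e7 CFU no septic reaction develops (*sub_septic*), above 4e8 CFU
sepsis and septic shock become likely (*sepsis_likely*), above 8e9 CFU the
course is *fulminant*; the region in between is *indeterminate*.
Boundary values fall in the lower band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "BANDS",
    "BAND_EDGES",
    "InoculumProfile",
    "cfu_from_plate",
    "severity_band",
]

BANDS = ("sub_septic", "indeterminate", "sepsis_likely", "fulminant")

#: total-CFU upper edges of the first three bands (inclusive)
BAND_EDGES = (1.34e7, 4e8, 8e9)

DEFAULT_SUSPENSION_ML = 200.0


@dataclass(frozen=True)
class InoculumProfile:
    """Microbial load of one inducer suspension."""

    cfu_per_ml: float
    suspension_volume_ml: float = DEFAULT_SUSPENSION_ML
    species: tuple[str, ...] = ()
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.cfu_per_ml < 0 or self.suspension_volume_ml <= 0:
            raise ValueError("cfu_per_ml >= 0 and volume > 0 required")

    @property
    def total_cfu(self) -> float:
        return self.cfu_per_ml * self.suspension_volume_ml

    @property
    def severity_band(self) -> str:
        return severity_band(self.total_cfu)


def cfu_from_plate(
    colonies: int, dilution_factor: float, plated_volume_ml: float = 0.1
) -> float:
    """CFU per mL of the undiluted sample from one countable plate.

    Zero colonies return 0.0: the caller should flag the sample as below
    the detection limit rather than treat it as sterile.
    """
    if colonies < 0:
        raise ValueError("colonies must be >= 0")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if plated_volume_ml <= 0:
        raise ValueError("plated_volume_ml must be > 0")
    return colonies * dilution_factor / plated_volume_ml


def severity_band(total_cfu: float) -> str:
    """Map total inoculum CFU to its ordered severity band."""
    if total_cfu <= 0:
        raise ValueError("total_cfu must be > 0")
    if total_cfu < BAND_EDGES[0]:
        return "sub_septic"
    if total_cfu <= BAND_EDGES[1]:
        return "indeterminate"
    if total_cfu <= BAND_EDGES[2]:
        return "sepsis_likely"
    return "fulminant"
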