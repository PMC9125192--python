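"""Independent chain-of-ifs pSOFA scoring oracle.

Transcribed directly from the published 5-row threshold table, separately
from the package implementation, so the two can be compared on dense input
grids.  Deliberately plain and unvectorized.
"""


def oracle_respiration(pf):
    if pf >= 400:
        return 0
    if pf < 100:
        return 4
    if pf < 200:
        return 3
    if pf < 300:
        return 2
    return 1


def oracle_cardiovascular(map_mmHg, norepi):
    if norepi > 0.1:
        return 4
    if norepi > 0:
        return 3
    if map_mmHg >= 75:
        return 0
    if map_mmHg < 65:
        return 2
    return 1


def oracle_renal(urine, furosemide_mg):
    if furosemide_mg > 10:
        return 4
    if furosemide_mg > 0:
        return 3
    if urine >= 0.5:
        return 0
    if urine < 0.25:
        return 2
    return 1


def oracle_liver(bilirubin):
    if bilirubin > 204:
        return 4
    if bilirubin > 101:
        return 3
    if bilirubin > 32:
        return 2
    if bilirubin > 20:
        return 1
    return 0


def oracle_coagulation(platelets):
    if platelets >= 200:
        return 0
    if platelets < 50:
        return 4
    if platelets < 100:
        return 3
    if platelets < 150:
        return 2
    return 1
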