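"""Reference study conditions: e-beam-irradiated polylactide films.

Published initial properties (number-average molecular weight and
polydispersity after irradiation, i.e. at the start of hydrolysis) and
the hydrolysis constants fitted to the corresponding literature
molecular-weight decay curves, for film specimens irradiated at four
electron-beam doses.  These quadruples parameterize the bundled
synthetic datasets and the round-trip recovery studies.
"""

from __future__ import annotations

from typing import NamedTuple


class DoseCondition(NamedTuple):
    """Initial state and fitted hydrolysis constant for one dose."""

    dose_mrad: float      #: radiation dose, Mrad (1 Mrad = 10 kGy)
    Mn0: float            #: initial number-average MW, g mol^-1
    PD0: float            #: initial polydispersity
    kd: float             #: fitted degradation constant, cm^6 mol^-2 s^-1


#: Dose label -> condition; dose 0 is the non-irradiated reference.
DOSE_TABLE: dict[str, DoseCondition] = {
    "0 Mrad": DoseCondition(0.0, 406_000.0, 1.60, 3.85e-5),
    "5 Mrad": DoseCondition(5.0, 64_700.0, 1.68, 1.27e-4),
    "10 Mrad": DoseCondition(10.0, 43_200.0, 1.73, 1.47e-4),
    "20 Mrad": DoseCondition(20.0, 23_100.0, 1.76, 1.21e-4),
}

REFERENCE_LABEL = "0 Mrad"


def dose_label(dose: float) -> str:
    """Canonical label for a dose in Mrad (``7.5 -> '7.5 Mrad'``)."""
    return f"{dose:g} Mrad"
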