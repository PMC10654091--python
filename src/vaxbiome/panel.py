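"""Antigen panel definitions and seroprotective thresholds.

The vaccine panel comprises the six DTaP/Hib antigens and the 13
pneumococcal conjugate vaccine (PCV13) serotype capsular polysaccharides.
Responder classification uses established (or presumed) protective
thresholds for the DTaP/Hib antigens only; no protective correlate is
assumed for the individual PCV serotypes.
"""

from __future__ import annotations

import pandas as pd

#: The six antigens of the DTaP/Hib combination vaccine.
DTAP_HIB_ANTIGENS: tuple[str, ...] = ("DT", "TT", "PT", "FHA", "PRN", "PRP")

#: The 13 serotypes of the 13-valent pneumococcal conjugate vaccine.
PCV_ANTIGENS: tuple[str, ...] = (
    "PCV1", "PCV3", "PCV4", "PCV5", "PCV6A", "PCV6B", "PCV7F",
    "PCV9V", "PCV14", "PCV18C", "PCV19A", "PCV19F", "PCV23F",
)

ANTIGEN_PANEL: tuple[str, ...] = DTAP_HIB_ANTIGENS + PCV_ANTIGENS

#: Antigen-specific concentration units.
ANTIGEN_UNITS: dict[str, str] = {
    "DT": "IU/mL", "TT": "IU/mL", "PT": "EU/mL", "FHA": "IU/mL",
    "PRN": "IU/mL", "PRP": "ug/mL",
    **{a: "ug/mL" for a in PCV_ANTIGENS},
}

#: Seroprotective thresholds; a titer strictly below its threshold counts
#: toward low-responder status.
PROTECTIVE_THRESHOLDS: dict[str, float] = {
    "DT": 0.1,   # IU/mL
    "TT": 0.1,   # IU/mL
    "PRP": 0.15, # ug/mL
    "PT": 8.0,   # EU/mL
    "PRN": 8.0,  # IU/mL
    "FHA": 8.0,  # IU/mL
}

TIMEPOINTS: tuple[str, ...] = ("2mo", "1yr", "2yr")


def threshold_table() -> pd.DataFrame:
    """Protective thresholds as a tidy table (antigen, threshold, units)."""
    return pd.DataFrame(
        {
            "antigen": list(PROTECTIVE_THRESHOLDS),
            "threshold": [PROTECTIVE_THRESHOLDS[a] for a in PROTECTIVE_THRESHOLDS],
            "units": [ANTIGEN_UNITS[a] for a in PROTECTIVE_THRESHOLDS],
        }
    )
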