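"""Published reference values for the IPMN autoantibody marker study.

The serum cohort behind this pipeline's defaults is not publicly
deposited, so its headline numbers are carried here as data: the cohort
composition, the array design bookkeeping, and the reported per-marker
sensitivity/specificity for the low-risk vs high-risk IPMN distinction.
They parameterize the synthetic generator's defaults and let the
panel-selection arithmetic (specificity gating, panel membership,
summary statistics) be exercised against real reported values.
"""

from __future__ import annotations

import pandas as pd

#: Serum samples per group in the reference cohort (PDAC = T1 + T2).
REFERENCE_CLASS_SIZES = {
    "Co": 54,
    "IPMN-LG": 91,
    "IPMN-HG": 66,
    "IPMN-CA": 30,
    "PDAC": 137,
}

#: PDAC substage split within the reference cohort.
REFERENCE_PDAC_STAGES = {"T1": 24, "T2": 113}

#: Antigen-selection bookkeeping for the reference array: of 364
#: literature-selected candidates, 281 were available in the cDNA
#: library and 32 of those failed PCR amplification, leaving the final
#: printed antigen count.
ARRAY_DESIGN_COUNTS = {
    "candidates_screened": 364,
    "library_available": 281,
    "amplification_failures": 32,
}

#: Reported per-marker performance for distinguishing low-risk (LR =
#: low-grade) from high-risk (HR = high-grade or with associated
#: invasive carcinoma) IPMN. ``direction`` is the group the marker is
#: specific for; sensitivity/specificity are percentages as published.
_MARKER_ROWS = [
    # antigen, direction, sensitivity %, specificity %
    ("GPR3", "LR", 13.3, 96.5),
    ("CFI", "LR", 19.3, 88.4),
    ("GPR173", "LR", 14.5, 87.2),
    ("CCKBR", "LR", 16.9, 84.9),
    ("CD99L2", "HR", 9.3, 100.0),
    ("RPL22", "HR", 4.7, 100.0),
    ("HCFC1R1", "HR", 3.5, 100.0),
    ("ANXA4", "HR", 4.7, 98.8),
    ("FXYD7", "HR", 9.3, 95.2),
    ("HDAC3", "HR", 7.0, 94.0),
    ("TP53", "HR", 9.3, 91.6),
    ("TOR1B", "HR", 17.4, 85.5),
    ("SLC22A15", "HR", 19.8, 80.7),
    ("PRDX2", "HR", 31.4, 71.1),
]

REFERENCE_MARKERS = pd.DataFrame(
    _MARKER_ROWS, columns=["antigen", "direction", "sensitivity_pct", "specificity_pct"]
).set_index("antigen")


def reference_panel(specificity_gate_pct: float = 90.0) -> list[str]:
    """HR-markers whose published specificity strictly exceeds the gate."""
    t = REFERENCE_MARKERS
    return list(
        t.index[(t["direction"] == "HR") & (t["specificity_pct"] > specificity_gate_pct)]
    )


def final_antigen_count() -> int:
    """Printed antigens = library-available candidates minus PCR failures."""
    return (
        ARRAY_DESIGN_COUNTS["library_available"]
        - ARRAY_DESIGN_COUNTS["amplification_failures"]
    )
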