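"""Published summary data bundled for convenience and for tests.

Only main-text summary values are bundled: the 18 recombinant inbred
advanced intercross lines (RIAILs) with intermediate par-1-induced
lethality, together with their genotypes at the markers flanking ppw-1,
and the observed F2 sensitivity-class counts from the N2 x CB4856
intercross.  Raw per-plate counts were not published and are emulated by
:mod:`rnaimap.simulate` instead.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "load_intermediate_riails",
    "OBSERVED_F2_COUNTS",
    "RIAIL_CLASS_COUNTS",
    "F2_TO_ADDITIVE_MERGE",
]

# 18 RIAILs with induced lethality strictly between 0 and 1, with the
# genotypes of the two markers flanking ppw-1 (chromosome I).
_INTERMEDIATE_RIAILS_CSV = """\
strain,mean_induced_lethality,ppw1_5p_marker,ppw1_3p_marker
QX57,0.00098,CB4856,CB4856
QX56,0.00279,CB4856,CB4856
QX145,0.00380,CB4856,CB4856
QX236,0.00403,CB4856,CB4856
QX113,0.00420,CB4856,CB4856
QX169,0.00549,CB4856,CB4856
QX127,0.01111,CB4856,CB4856
QX115,0.02231,CB4856,CB4856
QX1,0.02427,CB4856,CB4856
QX218,0.0324,CB4856,CB4856
QX158,0.07819,CB4856,CB4856
QX7,0.11031,CB4856,CB4856
QX168,0.11475,CB4856,CB4856
QX217,0.15780,N2,N2
QX24,0.34959,N2,N2
QX64,0.55530,N2,N2
QX13,0.97357,N2,N2
QX222,0.97357,CB4856,CB4856
"""

#: Observed sensitivity classes among 181 N2 x CB4856 F2.
OBSERVED_F2_COUNTS = {"full": 109, "high": 22, "intermediate": 12, "low": 38}

#: RIAIL panel class counts (149 lines phenotyped).
RIAIL_CLASS_COUNTS = {"full": 120, "zero": 11, "intermediate": 18}

#: Merge of observed F2 classes onto the additive two-locus model's
#: classes used for goodness-of-fit testing (an inferred convention:
#: fully sensitive F2 map to the model's high-sensitivity class, the
#: observed high and intermediate classes jointly to intermediate).
F2_TO_ADDITIVE_MERGE = {
    "full": "high",
    "high": "intermediate",
    "intermediate": "intermediate",
    "low": "low",
}


def load_intermediate_riails() -> pd.DataFrame:
    """The 18 intermediate-lethality RIAILs with ppw-1 flanking markers.

    Columns: strain, mean_induced_lethality (mean of two replicate assay
    pairs), ppw1_5p_marker, ppw1_3p_marker (N2 or CB4856).
    """
    return pd.read_csv(io.StringIO(_INTERMEDIATE_RIAILS_CSV))
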