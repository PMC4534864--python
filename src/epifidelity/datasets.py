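"""Published summary statistics from the cassava micropropagation survey.

The pipeline emulates a study of five cassava cultivars (Kiroba, Kizimbani,
Kibandameno, Mfaransa, Mzungu) propagated by field cuttings or *in vitro*
meristem culture. No raw data accession exists for that survey, so these
printed summary tables serve as fixture inputs for validating the summary
operations (cross-cultivar averaging, count bookkeeping) and as realistic
reference magnitudes for the simulators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CULTIVARS = ("Kibandameno", "Mzungu", "Mfaransa", "Kizimbani", "Kiroba")

#: Per-cultivar tissue-pair PhiPT by enzyme and propagation condition.
#: NaN marks cultivar/tissue combinations without data (one field tissue of
#: one cultivar was not sampled). Tissue pairs: Ylv=young leaf,
#: Mlv=mature leaf, Rt=root.
_TISSUE_PHIPT_RAW = {
    ("Ylv-Mlv", "HpaII", "field"): [0.208, 0.000, np.nan, 0.171, 0.259],
    ("Ylv-Mlv", "HpaII", "in_vitro"): [0.070, 0.042, 0.112, 0.000, 0.178],
    ("Ylv-Mlv", "MspI", "field"): [0.237, 0.239, np.nan, 0.114, 0.260],
    ("Ylv-Mlv", "MspI", "in_vitro"): [0.000, 0.192, 0.209, 0.071, 0.118],
    ("Ylv-Rt", "HpaII", "field"): [0.447, 0.000, 0.401, 0.142, 0.264],
    ("Ylv-Rt", "HpaII", "in_vitro"): [0.296, 0.162, 0.260, 0.272, 0.098],
    ("Ylv-Rt", "MspI", "field"): [0.308, 0.461, 0.538, 0.654, 0.250],
    ("Ylv-Rt", "MspI", "in_vitro"): [0.197, 0.178, 0.148, 0.286, 0.090],
    ("Mlv-Rt", "HpaII", "field"): [0.196, 0.108, np.nan, 0.263, 0.357],
    ("Mlv-Rt", "HpaII", "in_vitro"): [0.301, 0.344, 0.408, 0.139, 0.201],
    ("Mlv-Rt", "MspI", "field"): [0.049, 0.459, np.nan, 0.550, 0.344],
    ("Mlv-Rt", "MspI", "in_vitro"): [0.362, 0.386, 0.375, 0.250, 0.212],
}


def tissue_phipt_table() -> pd.DataFrame:
    """Cultivar x (tissue_pair, enzyme, condition) PhiPT values."""
    df = pd.DataFrame(_TISSUE_PHIPT_RAW, index=list(CULTIVARS))
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["tissue_pair", "enzyme", "condition"]
    )
    return df


#: Published cross-cultivar averages of the table above (same column keys).
TISSUE_PHIPT_AVERAGES = {
    ("Ylv-Mlv", "HpaII", "field"): 0.1595,
    ("Ylv-Mlv", "HpaII", "in_vitro"): 0.0804,
    ("Ylv-Mlv", "MspI", "field"): 0.2125,
    ("Ylv-Mlv", "MspI", "in_vitro"): 0.118,
    ("Ylv-Rt", "HpaII", "field"): 0.2508,
    ("Ylv-Rt", "HpaII", "in_vitro"): 0.2176,
    ("Ylv-Rt", "MspI", "field"): 0.4422,
    ("Ylv-Rt", "MspI", "in_vitro"): 0.1798,
    ("Mlv-Rt", "HpaII", "field"): 0.231,
    ("Mlv-Rt", "HpaII", "in_vitro"): 0.2786,
    ("Mlv-Rt", "MspI", "field"): 0.3505,
    ("Mlv-Rt", "MspI", "in_vitro"): 0.317,
}

#: MSAP locus partition across the isoschizomer pair.
LOCUS_PARTITION = {"unique_hpaii": 13, "unique_mspi": 22, "shared": 129}
TOTAL_LOCI = 164

#: Per-cultivar counts of differentially abundant msGBS tags by phase.
DIFFERENTIAL_TAG_COUNTS = pd.DataFrame(
    {
        "in_vitro": [185, 16021, 2245, 1918, 5068],
        "field": [1844, 17888, 23438, 1380, 12634],
    },
    index=["Mfaransa", "Mzungu", "Kizimbani", "Kiroba", "Kibandameno"],
)

#: Cross-cultivar consensus epimark counts.
CONSENSUS_SUMMARY = {
    "n_consensus": 105,
    "n_up_in_field": 101,
    "n_up_in_vitro": 4,
    "n_unique_tags": 357_271,
    "percent_of_unique": 0.03,
}
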