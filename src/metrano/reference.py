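"""Bundled reference inputs for the worked examples and validation checks.

These small tables come from a reader study of automated versus expert
treatment-response assessment on 20 serial MRI pairs: 4x4 CR/PR/SD/PD
agreement tables for the one-dimensional and the volumetric reading of
the modified RANO-BM criteria, plus lesion-detection counts used to
illustrate binomial confidence intervals.
"""

from __future__ import annotations

import numpy as np

from .evaluate import ConfusionTable4

__all__ = [
    "RESPONSE_AGREEMENT_1D",
    "RESPONSE_AGREEMENT_VOLUMETRIC",
    "DETECTION_COUNTS",
    "agreement_table_1d",
    "agreement_table_volumetric",
]

# rows: automated call (CR, PR, SD, PD); columns: expert ground truth
RESPONSE_AGREEMENT_1D = np.array(
    [
        [2, 1, 1, 0],
        [0, 3, 3, 2],
        [0, 1, 0, 0],
        [0, 0, 1, 6],
    ]
)

RESPONSE_AGREEMENT_VOLUMETRIC = np.array(
    [
        [2, 1, 0, 1],
        [0, 3, 1, 1],
        [0, 0, 3, 1],
        [0, 0, 0, 7],
    ]
)

# detected / total lesion counts (>= 5 mm) in three validation cohorts
DETECTION_COUNTS = {
    "temporal_1": (199, 265),
    "geographic": (57, 65),
    "temporal_2": (18, 19),
}


def agreement_table_1d() -> ConfusionTable4:
    return ConfusionTable4(RESPONSE_AGREEMENT_1D.copy())


def agreement_table_volumetric() -> ConfusionTable4:
    return ConfusionTable4(RESPONSE_AGREEMENT_VOLUMETRIC.copy())
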