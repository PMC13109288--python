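"""Published lesion-wise detection counts for the lymph-node dose study.

These are the raw TP/FP/FN counts reported for two 3D nnU-Net models — one
trained on full-dose CT only ("no_augmentation") and one trained on full-
plus reduced-dose CT ("augmentation") — evaluated on the TCIA NIH CT Lymph
Nodes test split (61 volumes, 4878 eligible nodes) at six simulated dose
levels, and on the fully annotated subset of the TCIA Mediastinal LNQ
collection (120 volumes, 967 eligible nodes) at full dose.

The counts are inputs: precision, sensitivity and F1 are *derived* from them
with :func:`ctnodes.metrics.detection_metrics`, which reproduces the
published percentages.  Eligible nodes are those with SAD >= 3 mm; every row
satisfies TP + FN = total eligible nodes of its dataset.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["detection_counts", "ELIGIBLE_NODES"]

ELIGIBLE_NODES = {"nih": 4878, "lnq": 967}

_ROWS = [
    # dataset, dose fraction, model, TP, FP, FN
    ("nih", 1.00, "no_augmentation", 4092, 1692, 786),
    ("nih", 1.00, "augmentation",    4129, 2010, 749),
    ("nih", 0.75, "no_augmentation", 4073, 1628, 805),
    ("nih", 0.75, "augmentation",    4122, 1977, 756),
    ("nih", 0.50, "no_augmentation", 4027, 1513, 851),
    ("nih", 0.50, "augmentation",    4111, 1893, 767),
    ("nih", 0.25, "no_augmentation", 3858, 1299, 1020),
    ("nih", 0.25, "augmentation",    4056, 1769, 822),
    ("nih", 0.10, "no_augmentation", 3432, 980, 1446),
    ("nih", 0.10, "augmentation",    3854, 1507, 1024),
    ("nih", 0.05, "no_augmentation", 2927, 766, 1951),
    ("nih", 0.05, "augmentation",    3600, 1198, 1278),
    ("lnq", 1.00, "no_augmentation", 777, 651, 190),
    ("lnq", 1.00, "augmentation",    789, 694, 178),
]


def detection_counts() -> pd.DataFrame:
    """The published detection counts as a tidy DataFrame."""
    return pd.DataFrame(_ROWS, columns=["dataset", "dose", "model",
                                        "tp", "fp", "fn"])
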