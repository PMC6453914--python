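"""Reference category counts from the White Leghorn x Cornish chick study.

These are the reported gene counts of the day-old-chick reciprocal-cross
RNA-seq experiment this pipeline models: per-tissue, per-group
inheritance-mode classification counts, differential-expression counts
between the parental breeds, and four-way-consistent gene totals. They are
inputs for worked examples and for recomputing every summary ratio and
rank test from reported counts; the underlying read data are not public.
"""

from __future__ import annotations

import pandas as pd

from .classify import CLASS_MODES

_MODE_COLS = list(CLASS_MODES)

#: groups x modes classification counts per tissue
#: (conserved, additive, cor_dominant, wl_dominant, over_dominant, under_dominant)
_CLASSIFICATION_ROWS = {
    "brain": {
        "MC": (8754, 847, 2283, 1497, 1026, 910),
        "FC": (8688, 822, 2341, 1461, 1110, 946),
        "MR": (8389, 882, 2033, 1969, 1091, 961),
        "FR": (7733, 715, 2641, 1470, 1379, 1286),
    },
    "liver": {
        "MC": (4317, 1306, 3083, 2504, 1720, 1230),
        "FC": (4195, 1508, 2795, 2757, 1615, 1261),
        "MR": (3883, 1292, 2477, 3069, 2318, 1146),
        "FR": (4393, 1305, 2352, 2651, 1632, 1546),
    },
    "muscle": {
        "MC": (3900, 961, 3926, 1775, 2264, 1946),
        "FC": (4015, 1066, 3626, 1946, 2211, 1889),
        "MR": (5185, 1169, 1742, 4136, 979, 1590),
        "FR": (3772, 1090, 2864, 2953, 1408, 2609),
    },
}


def classification_counts(tissue: str) -> pd.DataFrame:
    """Groups x modes inheritance-classification count table for a tissue."""
    rows = _CLASSIFICATION_ROWS[tissue]
    return pd.DataFrame.from_dict(rows, orient="index", columns=_MODE_COLS).rename_axis(
        index="group", columns="mode"
    )


def all_classification_counts() -> dict[str, pd.DataFrame]:
    return {t: classification_counts(t) for t in _CLASSIFICATION_ROWS}


#: tissue -> (genes detected in both sexes, up-regulated, down-regulated)
#: from the between-breed differential-expression comparison (FDR < 0.05)
DIVERGENCE_COUNTS = {
    "brain": (24267, 104, 91),
    "liver": (20943, 1502, 1704),
    "muscle": (22705, 1505, 1118),
}

#: tissue -> (genes with the same mode in all four groups, conserved among them)
FOURWAY_CONSISTENT_COUNTS = {
    "brain": (5426, 5138),
    "liver": (1851, 1252),
    "muscle": (1361, 1054),
}

#: genes retained per tissue after normalization and filtering
GENES_AFTER_FILTERING = {"brain": 15810, "liver": 14864, "muscle": 15390}
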