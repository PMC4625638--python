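"""Reference summaries from a published four-cancer TCGA survival comparison.

These are the worked-example inputs for the reporting utilities: the
c-index grid (cohort x algorithm x data type, 0-100 integer scale, with
significance tiers from the median-split log-rank test) and the feature
source composition of the twelve models selected on the merged (MERGE)
data.  ``None`` marks a cell where no model was generated.

The printed overall model-size total of that comparison (216) is
inconsistent with its own column sums (108); utilities here report the
true sums.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COHORTS = ("OV", "LUAD", "BRCA", "GBM")
ALGORITHMS = ("CPSO", "NFS", "LASSO")
DATA_TYPES = ("EXPR", "MIRNA", "CNA", "MUT", "MERGE")

# (cohort, algorithm) -> {data type: (c-index x100, tier)}
CINDEX_GRID = {
    ("OV", "CPSO"): {"EXPR": (66, "b"), "MIRNA": (61, "b"), "CNA": (64, "c"), "MUT": (10, "c"), "MERGE": (65, "c")},
    ("OV", "NFS"): {"EXPR": (60, "a"), "MIRNA": (53, "none"), "CNA": (56, "b"), "MUT": (11, "c"), "MERGE": (63, "c")},
    ("OV", "LASSO"): {"EXPR": (68, "c"), "MIRNA": (62, "c"), "CNA": (64, "c"), "MUT": None, "MERGE": (68, "c")},
    ("LUAD", "CPSO"): {"EXPR": (74, "b"), "MIRNA": (70, "none"), "CNA": (74, "b"), "MUT": (52, "c"), "MERGE": (75, "b")},
    ("LUAD", "NFS"): {"EXPR": (71, "b"), "MIRNA": (73, "b"), "CNA": (65, "a"), "MUT": (29, "b"), "MERGE": (64, "none")},
    ("LUAD", "LASSO"): {"EXPR": (72, "c"), "MIRNA": (75, "c"), "CNA": (66, "c"), "MUT": (52, "c"), "MERGE": (78, "c")},
    ("BRCA", "CPSO"): {"EXPR": (85, "c"), "MIRNA": (82, "c"), "CNA": (92, "none"), "MUT": (38, "c"), "MERGE": (83, "c")},
    ("BRCA", "NFS"): {"EXPR": (79, "none"), "MIRNA": (76, "none"), "CNA": (70, "none"), "MUT": (28, "c"), "MERGE": (84, "none")},
    ("BRCA", "LASSO"): {"EXPR": (81, "c"), "MIRNA": (80, "b"), "CNA": (83, "c"), "MUT": (53, "c"), "MERGE": (86, "c")},
    ("GBM", "CPSO"): {"EXPR": (63, "c"), "MIRNA": (59, "c"), "CNA": (57, "b"), "MUT": (16, "c"), "MERGE": (59, "none")},
    ("GBM", "NFS"): {"EXPR": (60, "c"), "MIRNA": (61, "c"), "CNA": (58, "b"), "MUT": (3, "b"), "MERGE": (63, "c")},
    ("GBM", "LASSO"): {"EXPR": (60, "c"), "MIRNA": (61, "c"), "CNA": (53, "c"), "MUT": (5, "none"), "MERGE": (61, "c")},
}

# MERGE model compositions: (algorithm, cohort) -> feature counts per source
MERGE_COMPOSITIONS = {
    ("CPSO", "BRCA"): {"EXPR": 6, "MIRNA": 0, "CNA": 3, "MUT": 1},
    ("CPSO", "LUAD"): {"EXPR": 6, "MIRNA": 0, "CNA": 3, "MUT": 0},
    ("CPSO", "GBM"): {"EXPR": 2, "MIRNA": 2, "CNA": 1, "MUT": 5},
    ("CPSO", "OV"): {"EXPR": 6, "MIRNA": 0, "CNA": 4, "MUT": 0},
    ("NFS", "BRCA"): {"EXPR": 0, "MIRNA": 0, "CNA": 4, "MUT": 0},
    ("NFS", "LUAD"): {"EXPR": 3, "MIRNA": 0, "CNA": 1, "MUT": 0},
    ("NFS", "GBM"): {"EXPR": 4, "MIRNA": 0, "CNA": 5, "MUT": 0},
    ("NFS", "OV"): {"EXPR": 4, "MIRNA": 0, "CNA": 4, "MUT": 1},
    ("LASSO", "BRCA"): {"EXPR": 4, "MIRNA": 0, "CNA": 2, "MUT": 5},
    ("LASSO", "LUAD"): {"EXPR": 3, "MIRNA": 3, "CNA": 1, "MUT": 2},
    ("LASSO", "GBM"): {"EXPR": 10, "MIRNA": 1, "CNA": 1, "MUT": 1},
    ("LASSO", "OV"): {"EXPR": 10, "MIRNA": 0, "CNA": 0, "MUT": 0},
}


def cindex_frame() -> pd.DataFrame:
    """Published c-index grid as a (cohort, algorithm) x data-type frame."""
    index = pd.MultiIndex.from_tuples(CINDEX_GRID, names=["cohort", "algorithm"])
    rows = []
    for key in CINDEX_GRID:
        rows.append([
            CINDEX_GRID[key][dt][0] if CINDEX_GRID[key][dt] else np.nan
            for dt in DATA_TYPES
        ])
    return pd.DataFrame(rows, index=index, columns=list(DATA_TYPES))


def composition_frame() -> pd.DataFrame:
    index = pd.MultiIndex.from_tuples(MERGE_COMPOSITIONS, names=["algorithm", "cohort"])
    return pd.DataFrame(
        [MERGE_COMPOSITIONS[k] for k in MERGE_COMPOSITIONS], index=index
    )
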