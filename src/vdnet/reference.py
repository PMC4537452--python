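"""Published pathway over-representation statistics for vitamin-D-treated
prostate cancer cells.

The table below is the printed ranking of altered WikiPathways-collection
pathways in LNCaP prostate cancer cells treated with 1,25-dihydroxyvitamin D3,
as produced by a PathVisio over-representation analysis of the underlying
microarray study.  Columns: pathway name, number of criterion-positive
(differentially expressed) genes, number of measured genes in the pathway,
Z score, permutation p-value, and whether the pathway is cancer-specific or
a more general (mostly cell-cycle-related) pathway.

It is shipped so the pathway-selection rule can be exercised against a real
published ranking without any download.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_pathway_statistics"]

_ROWS = [
    ("Retinoblastoma (RB) in cancer", 35, 87, 12.63, 0.001, "cancer"),
    ("DNA replication", 22, 42, 11.91, 0.001, "general"),
    ("Cell cycle", 34, 100, 11.04, 0.001, "general"),
    ("Gastric cancer network 1", 15, 26, 10.44, 0.001, "cancer"),
    ("Histone modifications", 25, 64, 10.44, 0.001, "general"),
    ("G1-to-S cell cycle control", 23, 67, 9.12, 0.001, "general"),
    ("DNA damage response", 15, 64, 5.40, 0.001, "general"),
    ("Gastric cancer network 2", 9, 30, 5.13, 0.001, "cancer"),
    ("ATM signalling pathway", 10, 38, 4.87, 0.001, "general"),
    ("Fluoropyrimidine activity", 8, 32, 4.16, 0.001, "general"),
    ("Integrated pancreatic cancer pathway", 27, 195, 4.08, 0.001, "cancer"),
    ("Integrated cancer pathway", 8, 35, 3.85, 0.005, "cancer"),
    ("Integrated breast cancer pathway", 21, 157, 3.41, 0.002, "cancer"),
    ("Arylhydrocarbon receptor (AhR) signalling pathway",
     5, 27, 2.47, 0.015, "general"),
    ("Signalling pathways in glioblastoma", 10, 82, 2.02, 0.048, "cancer"),
]


def published_pathway_statistics() -> pd.DataFrame:
    """The published ranking as a DataFrame.

    Columns: ``pathway`` (name), ``r`` (criterion-positive genes), ``n``
    (measured genes), ``z`` (Z score), ``perm_p`` (permutation p-value) and
    ``category`` (cancer / general).  Rows keep the published Z-descending
    order.
    """
    return pd.DataFrame(
        _ROWS, columns=["pathway", "r", "n", "z", "perm_p", "category"]
    )
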