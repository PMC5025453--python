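"""Published reference data shipped with the package.

``duplicate_pairs()`` returns the published duplicate-pair statistics
for the Brachypodium distachyon MAPKKK family: per pair the protein
identity, Ka, Ks, the Ka/Ks ratio, the divergence-time estimate (Myr),
the duplication type (TD = tandem, CSD = chromosomal segment
duplication) and, where measurable, the expression Pearson correlation
of the two duplicates.  These serve as inputs to the ratio/clock
arithmetic and to the identity-vs-expression correlation summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_ROWS = [
    # gene_a, chr_a, gene_b, chr_b, identity, ka, ks, ratio, t_myr, type, pcc
    ("BdMAPKKK21", 4, "BdMAPKKK16", 3, 65.53, 0.1927, 1.2025, 0.160249, 98.57, "CSD", 0.94),
    ("BdMAPKKK22", 5, "BdMAPKKK17", 3, 61.15, 0.2864, 0.8544, 0.335206, 70.03, "CSD", 0.61),
    ("BdMAPKKK23", 5, "BdMAPKKK18", 3, 73.52, 0.1511, 0.7296, 0.2071, 59.80, "CSD", 0.74),
    ("BdMAPKKK2", 1, "BdMAPKKK6", 1, 68.34, 0.3325, 1.9176, 0.173394, 157.18, "CSD", None),
    ("BdMAPKKK26", 1, "BdMAPKKK59", 4, 67.59, 0.2313, 1.4031, 0.164849, 115.01, "CSD", None),
    ("BdMAPKKK57", 3, "BdMAPKKK33", 1, 67.82, 0.1978, 0.8084, 0.244681, 66.26, "CSD", 0.75),
    ("BdMAPKKK52", 3, "BdMAPKKK35", 1, 61.84, 0.267, 0.8802, 0.30334, 72.15, "CSD", 0.76),
    ("BdMAPKKK38", 2, "BdMAPKKK40", 2, 83.06, 0.0954, 0.676, 0.141124, 55.41, "CSD", 0.40),
    ("BdMAPKKK39", 2, "BdMAPKKK42", 2, 56.54, 0.2911, 1.3928, 0.209003, 114.16, "CSD", 0.45),
    ("BdMAPKKK56", 3, "BdMAPKKK44", 2, 59.33, 0.3391, 1.519, 0.223239, 124.51, "CSD", 0.31),
    ("BdMAPKKK49", 3, "BdMAPKKK67", 5, 51.04, 0.4184, 1.1184, 0.374106, 91.67, "CSD", None),
    ("BdMAPKKK11", 2, "BdMAPKKK7", 2, 67.05, 0.4393, 1.0533, 0.41707, 86.34, "CSD", 0.09),
    ("BdMAPKKK8", 2, "BdMAPKKK7", 2, 73.56, 0.1977, 0.6532, 0.302664, 53.54, "TD", 0.51),
    ("BdMAPKKK10", 2, "BdMAPKKK7", 2, 88.19, 0.1085, 0.3825, 0.28366, 31.35, "TD", 0.56),
    ("BdMAPKKK26", 1, "BdMAPKKK27", 1, 98.14, 0.0091, 0.1896, 0.047996, 15.54, "TD", 0.81),
]

COLUMNS = ["gene_a", "chr_a", "gene_b", "chr_b", "identity_pct", "ka", "ks",
           "ratio", "t_myr", "dup_type", "expr_pcc"]


def duplicate_pairs() -> pd.DataFrame:
    df = pd.DataFrame(_ROWS, columns=COLUMNS)
    df["expr_pcc"] = df["expr_pcc"].astype(float)
    return df


def identity_expression_correlation(df: pd.DataFrame | None = None) -> float:
    """Pearson correlation of pair protein identity with pair expression
    PCC, over the pairs that have a measured expression PCC."""
    df = duplicate_pairs() if df is None else df
    sub = df.dropna(subset=["expr_pcc"])
    x = sub["identity_pct"].to_numpy(dtype=float)
    y = sub["expr_pcc"].to_numpy(dtype=float)
    return float(np.corrcoef(x, y)[0, 1])
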