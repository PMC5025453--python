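"""Mutual-Rank co-expression network and MAPK-cascade triad prediction.

MR(i,j) is the geometric mean of the reciprocal correlation ranks:
rank_i(j) is the position of j when i's partners are sorted by
descending Pearson correlation (self excluded, 1 = most correlated,
ties broken by ascending gene id).  Low MR means strong co-expression;
edges with MR strictly below the cutoff are retained.  Cascade triads
are (MAPKKK, MKK, MPK) triples supported by MAPKKK-MKK and MKK-MPK
edges whose three members share one subcellular localization; a direct
MAPKKK-MPK edge is not required.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .models import CascadeTriad, ExpressionMatrix

log = logging.getLogger("mapkascade")


def pcc_matrix(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation; zero-variance genes are dropped
    with a warning."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    arr = values.to_numpy(dtype=float)
    keep = arr.std(axis=1) > 0
    dropped = list(values.index[~keep])
    if dropped:
        log.warning("dropping %d zero-variance gene(s): %s", len(dropped), dropped)
    genes = values.index[keep]
    corr = np.corrcoef(arr[keep])
    return pd.DataFrame(corr, index=genes, columns=genes)


def mutual_rank(pcc: pd.DataFrame) -> pd.DataFrame:
    """MR matrix from a symmetric PCC matrix; MR(i,j) >= 1, diagonal 0."""
    n = pcc.shape[0]
    if n < 2:
        raise ValueError("need >= 2 genes")
    if pcc.shape[0] != pcc.shape[1] or not np.allclose(pcc.values, pcc.values.T):
        raise ValueError("PCC matrix must be square and symmetric")
    genes = list(pcc.index)
    ranks = np.zeros((n, n))
    for i in range(n):
        partners = [(j, pcc.iat[i, j]) for j in range(n) if j != i]
        # descending correlation, ties by ascending gene id
        partners.sort(key=lambda jr: (-jr[1], genes[jr[0]]))
        for position, (j, _) in enumerate(partners, start=1):
            ranks[i, j] = position
    mr = np.sqrt(ranks * ranks.T)
    return pd.DataFrame(mr, index=genes, columns=genes)


def build_network(mr: pd.DataFrame, cutoff: float = 1500.0) -> pd.DataFrame:
    """Undirected edge table (gene_a < gene_b lexicographically) with
    MR strictly below the cutoff."""
    genes = list(mr.index)
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = sorted((genes[i], genes[j]))
            value = mr.loc[a, b]
            if value < cutoff:
                rows.append((a, b, float(value)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "mr"])


def predict_cascades(
    edges: pd.DataFrame,
    families: Mapping[str, str],
    localizations: Mapping[str, str],
) -> list[CascadeTriad]:
    """Enumerate colocalized MAPKKK-MKK-MPK triads over the edge set,
    sorted by (mapkkk, mkk, mpk).  Every gene appearing in the edge
    table must carry a family label and a localization."""
    mr_of: dict[frozenset, float] = {}
    for row in edges.itertuples(index=False):
        for gene in (row.gene_a, row.gene_b):
            if gene not in families:
                raise KeyError(f"gene {gene!r} has no family label")
            if gene not in localizations:
                raise KeyError(f"gene {gene!r} has no localization")
        mr_of[frozenset((row.gene_a, row.gene_b))] = float(row.mr)

    def neighbors(gene: str, family: str) -> list[str]:
        out = []
        for pair in mr_of:
            if gene in pair:
                other = next(iter(pair - {gene}))
                if families.get(other) == family:
                    out.append(other)
        return out

    mkks = sorted(g for g, fam in families.items() if fam == "MKK")
    triads = []
    for mkk in mkks:
        for kkk in sorted(neighbors(mkk, "MAPKKK")):
            for mpk in sorted(neighbors(mkk, "MPK")):
                loc = localizations[mkk]
                if localizations[kkk] == loc == localizations[mpk]:
                    triads.append(CascadeTriad(
                        mapkkk=kkk, mkk=mkk, mpk=mpk, localization=loc,
                        mr_kkk_mkk=mr_of[frozenset((kkk, mkk))],
                        mr_mkk_mpk=mr_of[frozenset((mkk, mpk))],
                    ))
    triads.sort(key=lambda t: (t.mapkkk, t.mkk, t.mpk))
    return triads


def cascade_table(triads: list[CascadeTriad]) -> pd.DataFrame:
    return pd.DataFrame([
        {"cascade": i + 1, "mapkkk": t.mapkkk, "mkk": t.mkk, "mpk": t.mpk,
         "localization": t.localization, "mr_kkk_mkk": t.mr_kkk_mkk,
         "mr_mkk_mpk": t.mr_mkk_mpk}
        for i, t in enumerate(triads)
    ])
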