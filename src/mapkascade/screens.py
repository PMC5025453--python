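"""Expression screens: coefficient of variation, log2 fold-change
rules, a SAM-style permutation test, balanced two-way ANOVA with
interaction, duplicate-pair expression correlation, and isoform
fold-change comparison.

Log-ratio screens use log2(x + pseudocount) with pseudocount 1 by
default; set pseudocount 0 for data that is already on a log scale.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ExpressionMatrix


def cv_percent(values: Sequence[float]) -> Optional[float]:
    """Coefficient of variation: sample (n-1) standard deviation over the
    mean, as a percentage.  Undefined (``None``) when the mean is <= 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = x.mean()
    if mean <= 0:
        return None
    return float(x.std(ddof=1) / mean * 100.0)


def cv_screen(matrix: ExpressionMatrix, samples: Optional[Sequence[str]] = None,
              low_pct: float = 20.0, high_pct: float = 200.0) -> pd.DataFrame:
    """Per-gene CV with flags for the stable (< low) and stage-specific
    (> high) bands."""
    cols = list(samples) if samples is not None else list(matrix.values.columns)
    out = []
    for gene, row in matrix.values[cols].iterrows():
        cv = cv_percent(row.to_numpy())
        out.append({
            "gene": gene, "cv_pct": cv,
            "stable": cv is not None and cv < low_pct,
            "variable": cv is not None and cv > high_pct,
        })
    return pd.DataFrame(out).set_index("gene")


def fold_change_screen(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    log2_cutoff: float = 1.0,
    floor_exclusion: bool = True,
    floor: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2 fold change of group-b mean over group-a mean per gene.

    Genes whose means in both groups are below ``floor`` are excluded
    (flag False, excluded True) when ``floor_exclusion`` is on.  A gene
    passes when |log2fc| >= cutoff; direction follows the sign.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("empty group")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    mean_a = matrix.values[group_a].mean(axis=1)
    mean_b = matrix.values[group_b].mean(axis=1)
    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    excluded = floor_exclusion & (mean_a < floor) & (mean_b < floor)
    flag = (~excluded) & (log2fc.abs() >= log2_cutoff)
    direction = np.where(~flag, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame({
        "log2fc": log2fc, "excluded": excluded, "flag": flag,
        "direction": direction,
    }, index=matrix.values.index)


def _sam_d(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray,
           s0: Optional[float] = None) -> tuple[np.ndarray, float]:
    na, nb = mask_a.sum(), mask_b.sum()
    ma = values[:, mask_a].mean(axis=1)
    mb = values[:, mask_b].mean(axis=1)
    ssa = ((values[:, mask_a] - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((values[:, mask_b] - mb[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))
    if s0 is None:
        s0 = float(np.median(s))
    d = (mb - ma) / (s + s0)
    return d, s0


def sam_test(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
    q_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Two-class unpaired SAM-style screen with permutation q-values.

    d = (mean_b - mean_a) / (s + s0) with s0 the median of the per-gene
    standard errors.  For each observed |d| threshold, q is the expected
    number of permutation scores at least as extreme (averaged over
    label permutations) divided by the observed count, then made
    monotone non-increasing in |d| and capped at 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    cols = group_a + group_b
    n_arrangements = math.comb(len(cols), len(group_a))
    if n_arrangements < 2:
        raise ValueError("fewer than 2 permutable label arrangements")
    values = matrix.values[cols].to_numpy(dtype=float)
    mask_a = np.zeros(len(cols), dtype=bool)
    mask_a[: len(group_a)] = True
    d, s0 = _sam_d(values, mask_a, ~mask_a)

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(d)
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    # observed count at each gene's threshold = its 1-based rank
    observed = np.arange(1, len(d) + 1, dtype=float)
    expected = np.zeros(len(d))
    for _ in range(n_permutations):
        perm = rng.permutation(len(cols))
        pa = np.zeros(len(cols), dtype=bool)
        pa[perm[: len(group_a)]] = True
        dp, _ = _sam_d(values, pa, ~pa, s0=s0)
        # count permuted |d| >= each observed threshold
        dp_sorted = np.sort(np.abs(dp))
        expected += len(dp) - np.searchsorted(dp_sorted, thresholds, side="left")
    expected /= n_permutations
    q_sorted = np.minimum(expected / observed, 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(len(d))
    q[order] = q_sorted
    return pd.DataFrame({
        "d": d, "q": q, "flag": q < q_cutoff,
        "direction": np.where(q >= q_cutoff, "none",
                              np.where(d > 0, "up", "down")),
    }, index=matrix.values.index)


def two_way_anova(
    matrix: ExpressionMatrix,
    factor_a: str,
    factor_b: str,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction, per gene, on a
    complete balanced design with replicates; p-values are
    Benjamini-Hochberg adjusted across genes per factor.

    ``factor_a`` / ``factor_b`` name columns of the sample metadata.
    Raises ValueError on unbalanced or replicate-free designs.
    """
    meta = matrix.samples.loc[list(matrix.values.columns)]
    levels_a = sorted(meta[factor_a].unique())
    levels_b = sorted(meta[factor_b].unique())
    cells = {}
    r = None
    for la in levels_a:
        for lb in levels_b:
            cols = meta.index[(meta[factor_a] == la) & (meta[factor_b] == lb)]
            if r is None:
                r = len(cols)
            elif len(cols) != r:
                raise ValueError("unbalanced design")
            cells[(la, lb)] = list(cols)
    if r is None or r < 2:
        raise ValueError("design needs >= 2 replicates per cell")
    a, b = len(levels_a), len(levels_b)
    data = np.stack([
        matrix.values[cells[(la, lb)]].to_numpy(dtype=float)
        for la in levels_a for lb in levels_b
    ], axis=1)  # genes x (a*b cells) x r
    data = data.reshape(matrix.n_genes, a, b, r)

    grand = data.mean(axis=(1, 2, 3), keepdims=True)
    mean_a = data.mean(axis=(2, 3), keepdims=True)
    mean_b = data.mean(axis=(1, 3), keepdims=True)
    mean_ab = data.mean(axis=3, keepdims=True)
    ss_a = (b * r) * ((mean_a - grand) ** 2).sum(axis=(1, 2, 3))
    ss_b = (a * r) * ((mean_b - grand) ** 2).sum(axis=(1, 2, 3))
    ss_ab = r * ((mean_ab - mean_a - mean_b + grand) ** 2).sum(axis=(1, 2, 3))
    ss_err = ((data - mean_ab) ** 2).sum(axis=(1, 2, 3))
    # squash rounding noise: an SS term mathematically zero comes out
    # ~1e-30 in floats and would turn 0/0 into a spurious F; tolerance
    # is relative to the gene's total SS and to its value magnitude
    scale = np.abs(grand).reshape(-1)
    tol = (1e-12 * (ss_a + ss_b + ss_ab + ss_err)
           + (np.finfo(float).eps * 100 * scale) ** 2 * (a * b * r))
    ss_a = np.where(ss_a <= tol, 0.0, ss_a)
    ss_b = np.where(ss_b <= tol, 0.0, ss_b)
    ss_ab = np.where(ss_ab <= tol, 0.0, ss_ab)
    ss_err = np.where(ss_err <= tol, 0.0, ss_err)
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = a * b * (r - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_err = ss_err / df_err
        f_a = (ss_a / df_a) / ms_err
        f_b = (ss_b / df_b) / ms_err
        f_ab = (ss_ab / df_ab) / ms_err
    out = pd.DataFrame(index=matrix.values.index)
    for name, f, df_num in ((factor_a, f_a, df_a), (factor_b, f_b, df_b),
                            ("interaction", f_ab, df_ab)):
        p = stats.f.sf(f, df_num, df_err)
        p = np.where(np.isnan(f), 1.0, p)
        out[f"F_{name}"] = f
        out[f"p_{name}"] = p
        out[f"p_adj_{name}"] = multipletests(p, method=adjust)[1]
    return out


def duplicate_pair_pcc(matrix: ExpressionMatrix,
                       pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Pearson correlation of the two genes of each duplicate pair over
    shared samples.  Pairs with a missing gene get NaN ("-" in print);
    zero-variance genes also give NaN (undefined)."""
    if matrix.n_samples < 3:
        raise ValueError("need >= 3 samples")
    rows = []
    for gene_a, gene_b in pairs:
        if gene_a not in matrix.values.index or gene_b not in matrix.values.index:
            rows.append((gene_a, gene_b, np.nan))
            continue
        x = matrix.values.loc[gene_a].to_numpy(dtype=float)
        y = matrix.values.loc[gene_b].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            rows.append((gene_a, gene_b, np.nan))
            continue
        rows.append((gene_a, gene_b, float(np.corrcoef(x, y)[0, 1])))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc"])


def isoform_fold_change(
    matrix: ExpressionMatrix,
    transcript_pairs: Sequence[tuple[str, str]],
    condition_factor: str = "condition",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-condition log2 ratio of the first isoform's mean expression
    over the second's (".1" vs ".2" transcripts of one gene)."""
    meta = matrix.samples.loc[list(matrix.values.columns)]
    conditions = list(dict.fromkeys(meta[condition_factor]))
    rows = []
    for iso1, iso2 in transcript_pairs:
        for cond in conditions:
            cols = meta.index[meta[condition_factor] == cond]
            m1 = matrix.values.loc[iso1, cols].mean()
            m2 = matrix.values.loc[iso2, cols].mean()
            rows.append({
                "isoform_1": iso1, "isoform_2": iso2, "condition": cond,
                "log2_ratio": math.log2(m1 + pseudocount) - math.log2(m2 + pseudocount),
            })
    return pd.DataFrame(rows)
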