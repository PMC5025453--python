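"""Diurnal/circadian cycling detection by cosine-template correlation.

A gene's time course under one light/temperature regime (LDHH, LDHC,
LLHC, ...) is correlated against phase-shifted cosine templates
cos(2*pi*(t - phase)/period); the gene is called cycling in that
condition when the best correlation reaches the cutoff (default 0.8).
The default template grid is a single 24-h period with a 1-h phase
step.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import CircadianFit, ExpressionMatrix


def cycling_score(
    series: Sequence[float],
    timepoints: Sequence[float],
    periods: Sequence[float] = (24.0,),
    phase_step: float = 1.0,
    cutoff: float = 0.8,
    gene_id: str = "",
    condition: str = "",
) -> CircadianFit:
    """Best cosine-template Pearson correlation over the period/phase
    grid.  Ties break deterministically on (smallest period, smallest
    phase).  A constant series has undefined correlation and is not
    cycling."""
    y = np.asarray(series, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if y.shape != t.shape:
        raise ValueError("series/timepoints length mismatch")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    for period in periods:
        if t[-1] - t[0] < 2 * period:
            raise ValueError(f"need >= 2 full periods of {period} h sampled")
    if np.std(y) == 0:
        return CircadianFit(gene_id, condition, None, None, None, False)
    best = None
    yc = y - y.mean()
    ynorm = np.sqrt((yc ** 2).sum())
    for period in periods:
        for phase in np.arange(0.0, period, phase_step):
            template = np.cos(2 * np.pi * (t - phase) / period)
            tc = template - template.mean()
            denom = ynorm * np.sqrt((tc ** 2).sum())
            if denom == 0:
                continue
            r = float((yc * tc).sum() / denom)
            # round for tie comparison so equal-by-construction templates
            # (float jitter apart) resolve by (period, phase), not noise
            key = (-round(r, 12), period, phase)
            if best is None or key < best[0]:
                best = (key, r, period, phase)
    _, r, period, phase = best
    return CircadianFit(gene_id, condition, r, period, phase, r >= cutoff)


def detect_cycling(
    matrix: ExpressionMatrix,
    condition_factor: str = "condition",
    time_factor: str = "time_h",
    conditions: Optional[Sequence[str]] = None,
    cutoff: float = 0.8,
    periods: Sequence[float] = (24.0,),
    phase_step: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply ``cycling_score`` per gene per condition.

    Returns the per-gene/condition fits and a summary with the number
    of genes cycling in at least one condition and in all conditions.
    """
    meta = matrix.samples.loc[list(matrix.values.columns)]
    if conditions is None:
        conditions = list(dict.fromkeys(meta[condition_factor]))
    rows = []
    for cond in conditions:
        cols = meta.index[meta[condition_factor] == cond]
        times = meta.loc[cols, time_factor].to_numpy(dtype=float)
        order = np.argsort(times, kind="stable")
        cols = list(np.asarray(cols)[order])
        times = times[order]
        for gene in matrix.values.index:
            fit = cycling_score(
                matrix.values.loc[gene, cols].to_numpy(dtype=float), times,
                periods=periods, phase_step=phase_step, cutoff=cutoff,
                gene_id=gene, condition=cond,
            )
            rows.append({
                "gene": gene, "condition": cond, "best_r": fit.best_r,
                "best_period": fit.best_period, "best_phase": fit.best_phase,
                "cycling": fit.cycling,
            })
    fits = pd.DataFrame(rows)
    per_gene = fits.groupby("gene")["cycling"].agg(["sum"])
    summary = {
        "cycling_any": int((per_gene["sum"] >= 1).sum()),
        "cycling_all": int((per_gene["sum"] == len(conditions)).sum()),
    }
    return fits, summary
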