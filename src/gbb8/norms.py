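"""Sum scores, convergent-validity correlations and percentile-rank norms.

Subscale sums range 0-8 (two items, 0-4 each) and the total 0-32. A
respondent with any missing item in a scale is flagged incomplete for that
scale and excluded from its norm table; no imputation is performed.

The percentile rank of a sum score s is the rounded percentage of the norm
sample scoring at or below s (cumulative-inclusive convention), evaluated
at every achievable score, so norm columns rise monotonically and the
maximum attained score maps to 100. A mid-rank variant (average of "below"
and "at or below") is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ItemDataset

TOTAL = "total"


@dataclass
class ScoreTable:
    """Per-respondent subscale and total sums with completeness flags."""

    scores: pd.DataFrame     # columns: subscales + 'total'
    complete: pd.DataFrame   # same columns, boolean

    def complete_scores(self, scale: str) -> np.ndarray:
        return self.scores.loc[self.complete[scale], scale].to_numpy()


def sum_scores(data: ItemDataset,
               subscales: dict[str, tuple[str, str]] | None = None) -> ScoreTable:
    """Subscale and total raw sums over non-missing items.

    Sums are computed over the available items, but any missingness within
    a scale clears its completeness flag (and the total's).
    """
    subscales = subscales or data.subscales
    resp = data.responses
    scores = {}
    complete = {}
    for scale, items in subscales.items():
        block = resp[list(items)]
        scores[scale] = block.sum(axis=1, skipna=True)
        complete[scale] = ~block.isna().any(axis=1)
    scores[TOTAL] = resp.sum(axis=1, skipna=True)
    complete[TOTAL] = ~resp.isna().any(axis=1)
    return ScoreTable(scores=pd.DataFrame(scores),
                      complete=pd.DataFrame(complete))


def percentile_ranks(scores: np.ndarray, max_score: int | None = None,
                     midrank: bool = False) -> pd.Series:
    """Percentile rank at every achievable score value 0..max.

    ``PR(s) = round(100 * P(score <= s))``; with ``midrank``,
    ``round(100 * (P(score < s) + P(score <= s)) / 2)``.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if len(scores) == 0:
        raise ValueError("no complete scores to build norms from")
    top = int(max_score) if max_score is not None else int(scores.max())
    grid = np.arange(0, top + 1)
    le = (scores[None, :] <= grid[:, None]).mean(axis=1)
    if midrank:
        lt = (scores[None, :] < grid[:, None]).mean(axis=1)
        pr = np.round(100 * (le + lt) / 2).astype(int)
    else:
        pr = np.round(100 * le).astype(int)
    return pd.Series(pr, index=pd.Index(grid, name="sum_score"),
                     name="percentile_rank")


def norms_table(score_table: ScoreTable, midrank: bool = False) -> pd.DataFrame:
    """Percentile-rank norms per subscale (max 8) and total (max 32),
    computed on the scale-wise complete cases."""
    cols = {}
    for scale in score_table.scores.columns:
        vals = score_table.complete_scores(scale)
        max_score = 32 if scale == TOTAL else 8
        cols[scale] = percentile_ranks(vals, max_score=min(max_score,
                                                           int(vals.max())),
                                       midrank=midrank)
    return pd.DataFrame(cols)


def convergent_correlations(
    score_table: ScoreTable, covariates: pd.DataFrame,
    alpha: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations among subscales, total and
    covariates, with two-sided p-values (t transform) and significance
    marks at ``alpha``.

    Returns ``(r, p, significant)`` DataFrames; a zero-variance column
    yields NaN cells. The matrix is symmetric with a unit diagonal.
    """
    cols = pd.concat([score_table.scores, covariates.reset_index(drop=True)],
                     axis=1)
    # sums over incomplete scales are not comparable; mask them out
    for scale in score_table.scores.columns:
        cols.loc[~score_table.complete[scale], scale] = np.nan
    names = list(cols.columns)
    k = len(names)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x, y = cols[names[i]], cols[names[j]]
            mask = x.notna() & y.notna()
            n = int(mask.sum())
            if n < 3:
                continue
            xv, yv = x[mask].to_numpy(), y[mask].to_numpy()
            if xv.std() == 0 or yv.std() == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            rij = float(np.corrcoef(xv, yv)[0, 1])
            rij = float(np.clip(rij, -1.0, 1.0))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1 - rij**2))
                pij = float(2 * stats.t.sf(abs(t), df=n - 2))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    r_df = pd.DataFrame(r, index=names, columns=names)
    p_df = pd.DataFrame(p, index=names, columns=names)
    sig = p_df < alpha
    return r_df, p_df, sig
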