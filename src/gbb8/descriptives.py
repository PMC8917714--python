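"""Item-level descriptive statistics and multivariate outlier screening.

Produces the standard validation-report item table — mean, SD, skewness,
kurtosis, the within-subscale inter-item correlation and the item-total
correlation — and flags multivariate outliers by the squared Mahalanobis
distance against a chi-square reference.

Conventions (each stated because more than one is in circulation):

* SD uses the n-1 denominator; skewness and kurtosis use central moments
  with the n denominator.
* Kurtosis is *raw* (a normal distribution scores 3), not excess.
* ``r_subscale`` is the Pearson correlation of an item with its subscale
  partner item (for two-item subscales both items of a pair necessarily
  share the value).
* ``r_it`` is the uncorrected item-total correlation (the total includes
  the item); a corrected item-rest variant ``r_ir`` is also emitted.
* Moments and correlations use pairwise deletion; Mahalanobis distances use
  complete cases only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ItemDataset
from .instrument import partner_item


@dataclass
class OutlierReport:
    """Squared Mahalanobis distances and chi-square-based outlier flags."""

    d2: np.ndarray            # squared distances, complete cases
    case_index: np.ndarray    # positional row indices of the complete cases
    df: int                   # chi-square reference df (= number of items)
    alpha: float
    flags: np.ndarray         # boolean, aligned with d2

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    @property
    def prop_flagged(self) -> float:
        return float(self.flags.mean()) if len(self.flags) else float("nan")


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd_{n-1}, skewness m3/m2^1.5, raw kurtosis m4/m2^2)."""
    x = x[~np.isnan(x)]
    n = len(x)
    mean = x.mean()
    d = x - mean
    m2 = (d**2).mean()
    if m2 == 0:
        return mean, 0.0, np.nan, np.nan
    sd = np.sqrt((d**2).sum() / (n - 1)) if n > 1 else np.nan
    skew = (d**3).mean() / m2**1.5
    kurt = (d**4).mean() / m2**2
    return mean, sd, skew, kurt


def item_descriptives(data: ItemDataset) -> pd.DataFrame:
    """Item table: M, SD, skewness, kurtosis, r_subscale, r_it (+ r_ir).

    Requires at least two non-missing values per item. A constant item gets
    NaN skewness/kurtosis with a warning rather than an error, since the
    mean is still reportable.
    """
    resp = data.responses
    rows = {}
    for item in data.item_names:
        x = resp[item].to_numpy()
        if (~np.isnan(x)).sum() < 2:
            raise ValueError(f"item {item!r} has fewer than 2 non-missing values")
        mean, sd, skew, kurt = _moments(x)
        if np.isnan(skew):
            warnings.warn(f"item {item!r} is constant; skewness/kurtosis undefined")
        rows[item] = {"M": mean, "SD": sd, "skewness": skew, "kurtosis": kurt}
    table = pd.DataFrame.from_dict(rows, orient="index")
    corr = item_correlations(data)
    return table.join(corr)


def item_correlations(data: ItemDataset) -> pd.DataFrame:
    """Partner-item, item-total and item-rest Pearson correlations.

    Pairwise-complete observations; raises on a zero-variance item (its
    correlation is undefined), naming the item.
    """
    resp = data.responses
    total = resp.sum(axis=1, skipna=False)  # total only defined for complete rows
    out = {}
    for item in data.item_names:
        x = resp[item]
        if np.nanvar(x.to_numpy()) == 0:
            raise ValueError(f"item {item!r} has zero variance; correlations undefined")
        partner = resp[partner_item(item, data.subscales)]
        r_sub = x.corr(partner)
        r_it = x.corr(total)
        r_ir = x.corr(total - x)
        out[item] = {"r_subscale": r_sub, "r_it": r_it, "r_ir": r_ir}
    return pd.DataFrame.from_dict(out, orient="index")


def mahalanobis_outliers(data: ItemDataset, alpha: float = 0.001) -> OutlierReport:
    """Flag multivariate outliers on the complete cases.

    ``D2_i = (x_i - xbar)' S^{-1} (x_i - xbar)`` with S the n-1-denominator
    covariance of the complete cases; a case is flagged when the upper-tail
    chi-square(p) probability of its D2 falls below ``alpha``. Flagged cases
    are reported, not removed. By construction ``sum(D2) = (n-1) * p``.

    Raises on a singular covariance matrix (suggesting item removal or an
    explicit ridge) rather than silently regularizing.
    """
    mask = data.complete_cases()
    X = data.responses.to_numpy()[mask]
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} complete cases, have {n}")
    S = np.cov(X, rowvar=False, ddof=1)
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or logdet < -1e12 or np.linalg.cond(S) > 1e12:
        raise np.linalg.LinAlgError(
            "covariance of complete cases is singular; consider removing a "
            "redundant item or applying an explicit ridge before screening"
        )
    centred = X - X.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centred, np.linalg.inv(S), centred)
    flags = stats.chi2.sf(d2, df=p) < alpha
    return OutlierReport(
        d2=d2,
        case_index=np.flatnonzero(mask),
        df=p,
        alpha=alpha,
        flags=flags,
    )
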