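"""Fit indices with qualitative labels, and McDonald's omega reliability.

Fit-index conventions:

* CFI and TLI compare the model against the per-group independence
  (baseline) model.
* RMSEA uses N (not N-1) and multiplies by the group count in multi-group
  fits; with free item intercepts it is identical whether means are
  saturated or excluded.
* SRMR averages squared correlation-metric residuals over the unique
  covariance elements (diagonal included, means excluded), per group,
  weighted by group size.

Decision labels follow the common two-tier guideline: CFI/TLI > 0.95
acceptable, > 0.97 good; RMSEA < 0.08 acceptable, < 0.05 good;
SRMR < 0.10 acceptable, < 0.05 good. The chi-square p-value is reported
but never used alone to reject a model.

Reliability: omega of a congeneric subscale is
``(sum lambda)^2 / ((sum lambda)^2 + sum theta)``. For the second-order
model the two-level decomposition gives the reliability attributable to
the general factor of the unit-weighted item total (level 1) and of the
first-order factor composite (level 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: (acceptable, good) cutoffs per index.
FIT_THRESHOLDS = {
    "cfi": (0.95, 0.97),
    "tli": (0.95, 0.97),
    "rmsea": (0.08, 0.05),
    "srmr": (0.10, 0.05),
}


@dataclass
class FitIndexSet:
    chi2: float
    df: int
    pvalue: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float

    @property
    def labels(self) -> dict[str, str]:
        out = {}
        for name in ("cfi", "tli", "rmsea", "srmr"):
            v = getattr(self, name)
            acc, good = FIT_THRESHOLDS[name]
            if name in ("cfi", "tli"):
                out[name] = "good" if v > good else "acceptable" if v > acc else "poor"
            else:
                out[name] = "good" if v < good else "acceptable" if v < acc else "poor"
        return out

    def as_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.pvalue,
                "cfi": self.cfi, "tli": self.tli,
                "rmsea": self.rmsea, "srmr": self.srmr}


def fit_indices_from_stats(
    chi2_m: float, df_m: int, chi2_b: float, df_b: int,
    n_total: int, n_groups: int = 1,
    implied: list[tuple[np.ndarray, np.ndarray]] | None = None,
    sample: list[tuple[np.ndarray, np.ndarray]] | None = None,
    group_ns: list[int] | None = None,
) -> FitIndexSet:
    """Assemble CFI/TLI/RMSEA (and SRMR when moments are supplied)."""
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0
    if df_m > 0 and df_b > 0 and chi2_b / df_b > 1:
        tli = ((chi2_b / df_b) - (chi2_m / df_m)) / ((chi2_b / df_b) - 1.0)
        tli = float(np.clip(tli, 0.0, 1.0))
    else:
        tli = 1.0
    rmsea = (np.sqrt(n_groups * max(chi2_m - df_m, 0.0) / (df_m * n_total))
             if df_m > 0 else np.nan)
    srmr = np.nan
    if implied is not None and sample is not None:
        srmr = _srmr(implied, sample, group_ns or [n_total])
    p = float(stats.chi2.sf(chi2_m, df_m)) if df_m > 0 else np.nan
    return FitIndexSet(chi2=chi2_m, df=df_m, pvalue=p, cfi=cfi, tli=tli,
                       rmsea=float(rmsea), srmr=float(srmr))


def _srmr(implied, sample, group_ns) -> float:
    vals = []
    weights = []
    for (mu_i, Sig_i), (mu_s, Sig_s), n in zip(implied, sample, group_ns):
        sd = np.sqrt(np.diag(Sig_s))
        D = np.outer(sd, sd)
        resid = (Sig_s - Sig_i) / D
        iu = np.triu_indices(len(sd))
        vals.append(np.mean(resid[iu] ** 2))
        weights.append(n)
    return float(np.sqrt(np.average(vals, weights=weights)))


def fit_indices(results, n_total: int | None = None) -> FitIndexSet:
    """Fit indices of a :class:`~gbb8.model.CFAResults`."""
    n_total = n_total if n_total is not None else results.n_total
    return fit_indices_from_stats(
        results.chi2, results.df, results.chi2_baseline, results.df_baseline,
        n_total, results.spec.n_groups,
        implied=results.implied_moments(), sample=results.sample_moments(),
        group_ns=[g.n for g in results.model.groups_data],
    )


# ======================================================================
# Reliability
# ======================================================================

@dataclass
class ReliabilityReport:
    omega_subscale: dict[str, float]
    omega_l1: float
    omega_l2: float


def omega_subscale(loadings: np.ndarray, thetas: np.ndarray) -> float:
    """McDonald's omega of a congeneric composite (unstandardized)."""
    loadings = np.asarray(loadings, float)
    thetas = np.asarray(thetas, float)
    if np.any(thetas < 0):
        raise ValueError("negative residual variance; resolve the Heywood "
                         "case before computing omega")
    s = loadings.sum()
    return float(s**2 / (s**2 + thetas.sum()))


def omega_higher_order(lam1: np.ndarray, lam2: np.ndarray, psi_d: np.ndarray,
                       theta: np.ndarray, phi: float,
                       factor_of_item: np.ndarray) -> tuple[float, float]:
    """Two-level reliability of a second-order model.

    * level 1 — share of the unit-weighted item total's variance explained
      by the general factor: ``(1'b)^2 phi / (1' Sigma 1)`` with
      ``b = Lambda1 Lambda2`` the item loadings on the general factor;
    * level 2 — reliability of the first-order factor composite:
      ``(1'Lambda2)^2 phi / ((1'Lambda2)^2 phi + 1'Psi_d 1)``.
    """
    lam1 = np.asarray(lam1, float)
    lam2 = np.asarray(lam2, float)
    psi_d = np.asarray(psi_d, float)
    theta = np.asarray(theta, float)
    p = len(lam1)
    L1 = np.zeros((p, len(lam2)))
    L1[np.arange(p), factor_of_item] = lam1
    b = L1 @ lam2
    Sigma = phi * np.outer(b, b) + L1 @ np.diag(psi_d) @ L1.T + np.diag(theta)
    total_var = float(Sigma.sum())
    if total_var <= 0:
        raise ValueError("non-positive total variance")
    omega_l1 = float(b.sum() ** 2 * phi / total_var)
    s2 = lam2.sum()
    den2 = s2**2 * phi + psi_d.sum()
    if den2 <= 0:
        raise ValueError("non-positive composite variance at level 2")
    omega_l2 = float(s2**2 * phi / den2)
    return omega_l1, omega_l2


def reliability(results) -> ReliabilityReport:
    """Omega per subscale and the two-level omegas from a second-order fit
    (reference group's parameters in multi-group fits)."""
    spec = results.spec
    if spec.kind != "second_order":
        raise ValueError("reliability decomposition requires the second-order model")
    g = results.params[0]
    fac = spec.factor_of_item
    out = {}
    for j, scale in enumerate(spec.factor_names):
        items = fac == j
        # congeneric loadings of the items on their own first-order factor,
        # on the factor's total-variance scale
        fac_var = g["lambda2"][j] ** 2 * g["phi"][0] + g["psi_d"][j]
        lam = g["loading"][items] * np.sqrt(fac_var)
        out[scale] = omega_subscale(lam, g["theta"][items])
    l1, l2 = omega_higher_order(g["loading"], g["lambda2"], g["psi_d"],
                                g["theta"], g["phi"][0], fac)
    return ReliabilityReport(omega_subscale=out, omega_l1=l1, omega_l2=l2)
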