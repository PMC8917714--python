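"""Full-information maximum-likelihood estimation of the CFA structures.

The casewise (FIML) Gaussian log-likelihood is evaluated by grouping
respondents by missingness pattern: each pattern contributes through its
sufficient statistics (count, mean and scatter of the observed columns)
against the row/column-subsetted model-implied mean and covariance, so the
cost of one likelihood evaluation is independent of the sample size. With
complete data this reduces exactly to the standard ML log-likelihood from
sample moments.

Estimation maximises the log-likelihood by quasi-Newton iteration (L-BFGS-B)
with analytic gradients assembled from the pattern-wise derivatives with
respect to the implied mean and covariance. Variances are optimised on the
log scale, which enforces positivity; a variance estimated at the boundary
(below 1e-6) is reported as a Heywood warning.

Reference fits:

* saturated model — per-group unstructured mean and covariance; with
  complete data these are the sample moments, with missing data they are
  obtained by expectation-maximisation run to a 1e-8 relative
  log-likelihood change;
* baseline (independence) model — free means and variances, zero
  covariances; its FIML solution factorises per variable and is closed
  form.

The model chi-square is ``2*(ll_saturated - ll_model)``, clamped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .data import ItemDataset
from .specs import (FactorModelSpec, ParamTemplate, build_template,
                    implied_moments)

_HEYWOOD_TOL = 1e-6
_LOG_2PI = float(np.log(2 * np.pi))


class FitError(RuntimeError):
    """Raised when an optimisation fails to converge."""


# ======================================================================
# Pattern-compressed per-group data
# ======================================================================

@dataclass
class _Pattern:
    obs: np.ndarray      # observed column indices
    n: int
    mean: np.ndarray     # mean of observed columns
    scatter: np.ndarray  # n-denominator covariance about the pattern mean


@dataclass
class GroupData:
    """Sufficient statistics of one group, compressed by missingness pattern."""

    label: str
    patterns: list[_Pattern]
    n: int                      # respondents contributing (not all-missing)
    n_dropped: int = 0          # respondents missing every item
    p: int = 0

    @property
    def complete(self) -> bool:
        return len(self.patterns) == 1 and len(self.patterns[0].obs) == self.p

    def observed_means_vars(self) -> tuple[np.ndarray, np.ndarray]:
        """Available-case mean and ML variance per item (baseline solution)."""
        n_j = np.zeros(self.p)
        s1 = np.zeros(self.p)
        s2 = np.zeros(self.p)
        for pat in self.patterns:
            n_j[pat.obs] += pat.n
            s1[pat.obs] += pat.n * pat.mean
            s2[pat.obs] += pat.n * (np.diag(pat.scatter) + pat.mean**2)
        with np.errstate(invalid="ignore"):
            mean = s1 / n_j
            var = s2 / n_j - mean**2
        return mean, var


def _make_group_data(X: np.ndarray, label: str) -> GroupData:
    """Compress a raw (possibly incomplete) response matrix into patterns."""
    p = X.shape[1]
    obs_mask = ~np.isnan(X)
    keep = obs_mask.any(axis=1)
    n_dropped = int((~keep).sum())
    X = X[keep]
    obs_mask = obs_mask[keep]
    patterns = []
    codes = obs_mask @ (1 << np.arange(p))
    for code in np.unique(codes):
        rows = X[codes == code]
        obs = np.flatnonzero(obs_mask[codes == code][0])
        vals = rows[:, obs]
        m = vals.mean(axis=0)
        d = vals - m
        patterns.append(
            _Pattern(obs=obs, n=len(vals), mean=m, scatter=(d.T @ d) / len(vals))
        )
    return GroupData(label=label, patterns=patterns, n=len(X),
                     n_dropped=n_dropped, p=p)


def _loglik_mu_sigma(gd: GroupData, mu: np.ndarray, Sigma: np.ndarray,
                     want_grad: bool = False):
    """FIML log-likelihood (and accumulators dll/dSigma, dll/dmu) for one
    group under arbitrary mean/covariance."""
    p = gd.p
    ll = 0.0
    A = np.zeros((p, p)) if want_grad else None
    g = np.zeros(p) if want_grad else None
    for pat in gd.patterns:
        o = pat.obs
        So = Sigma[np.ix_(o, o)]
        try:
            c, low = cho_factor(So, check_finite=False)
        except np.linalg.LinAlgError:
            return (-np.inf, None, None) if want_grad else -np.inf
        logdet = 2 * np.log(np.diag(c)).sum()
        d = pat.mean - mu[o]
        W = pat.scatter + np.outer(d, d)
        Sinv_W = cho_solve((c, low), W, check_finite=False)
        ll += -0.5 * pat.n * (len(o) * _LOG_2PI + logdet + np.trace(Sinv_W))
        if want_grad:
            Sinv = cho_solve((c, low), np.eye(len(o)), check_finite=False)
            A[np.ix_(o, o)] += 0.5 * pat.n * (Sinv_W @ Sinv - Sinv)
            g[o] += pat.n * (Sinv @ d)
    return (ll, A, g) if want_grad else ll


# ======================================================================
# Structured likelihood and analytic gradient
# ======================================================================

def _group_loglik_grad(spec: FactorModelSpec, g: dict, gd: GroupData):
    """Log-likelihood and natural-scale parameter gradient for one group."""
    mu, Sigma = implied_moments(spec, g)
    ll, A, gmu = _loglik_mu_sigma(gd, mu, Sigma, want_grad=True)
    if not np.isfinite(ll):
        return -np.inf, None
    fac = spec.factor_of_item
    lam1 = g["loading"]
    K = spec.n_factors
    J = np.zeros((spec.p, K))
    J[np.arange(spec.p), fac] = 1.0

    if spec.kind == "second_order":
        l2 = g["lambda2"]
        phi = g["phi"][0]
        B = np.outer(l2, l2) * phi + np.diag(g["psi_d"])
        kappa = g["tau"] + l2 * g["alpha"][0]
    else:
        B = np.diag(g["psi_diag"]).astype(float)
        iu = np.triu_indices(K, 1)
        B[iu] = g["psi_off"]
        B = B + np.triu(B, 1).T
        kappa = np.zeros(K)

    # chain rule through Sigma = L1 B L1' + Theta, mu = nu + L1 kappa
    Lam1B = lam1[:, None] * B[fac, :]            # p x K  (rows of L1 @ B)
    dLam1_full = 2.0 * (A @ Lam1B) + np.outer(gmu, kappa)
    grad = {
        "loading": dLam1_full[np.arange(spec.p), fac],
        "nu": gmu,
        "theta": np.diag(A).copy(),
    }
    Aw = lam1[:, None] * A * lam1[None, :]
    C = J.T @ Aw @ J                              # K x K = L1' A L1
    h = J.T @ (lam1 * gmu)                        # K     = L1' gmu

    if spec.kind == "second_order":
        grad["lambda2"] = 2.0 * phi * (C @ l2) + g["alpha"][0] * h
        grad["psi_d"] = np.diag(C).copy()
        grad["phi"] = np.array([l2 @ C @ l2])
        grad["tau"] = h
        grad["alpha"] = np.array([l2 @ h])
    else:
        grad["psi_diag"] = np.diag(C).copy()
        iu = np.triu_indices(K, 1)
        grad["psi_off"] = (C + C.T)[iu]
    return ll, grad


def _neg_loglik_and_grad(x, spec, template, groups_data):
    x = np.clip(x, -30.0, 30.0)
    params = template.unpack(x)
    total = 0.0
    grads = []
    for g, gd in zip(params, groups_data):
        ll, grad = _group_loglik_grad(spec, g, gd)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(x)
        total += ll
        grads.append(grad)
    return -total, -template.scatter_grad(grads, params)


def fiml_loglik(params: list[dict], data_or_groups, spec: FactorModelSpec) -> float:
    """FIML log-likelihood of structured parameters on (possibly incomplete)
    data: the sum over respondents of the Gaussian log-density of each
    respondent's observed items under the subsetted implied moments."""
    groups_data = _coerce_groups(data_or_groups, spec)
    total = 0.0
    for g, gd in zip(params, groups_data):
        mu, Sigma = implied_moments(spec, g)
        ll = _loglik_mu_sigma(gd, mu, Sigma)
        if not np.isfinite(ll):
            raise FitError("model-implied covariance not positive definite "
                           "on an observed pattern")
        total += ll
    return total


def _coerce_groups(data_or_groups, spec) -> list[GroupData]:
    if isinstance(data_or_groups, list):
        return data_or_groups
    if isinstance(data_or_groups, ItemDataset):
        return [_make_group_data(data_or_groups.responses.to_numpy(), spec.groups[0])]
    raise TypeError("expected ItemDataset or list of GroupData")


# ======================================================================
# Saturated and baseline reference fits
# ======================================================================

@dataclass
class ReferenceFit:
    llf: float
    n_free: int
    df: int
    moments: list[tuple[np.ndarray, np.ndarray]]  # per group (mu, Sigma)
    n_iter: int = 0
    converged: bool = True


def fit_saturated(groups_data: list[GroupData], tol: float = 1e-8,
                  maxiter: int = 500) -> ReferenceFit:
    """Per-group unstructured MVN fit by EM (exact moments when complete)."""
    total_ll = 0.0
    moments = []
    iters = 0
    converged = True
    for gd in groups_data:
        mu, Sigma, ll, it, ok = _saturated_one_group(gd, tol, maxiter)
        total_ll += ll
        moments.append((mu, Sigma))
        iters = max(iters, it)
        converged = converged and ok
    p = groups_data[0].p
    n_free = len(groups_data) * (p + p * (p + 1) // 2)
    return ReferenceFit(llf=total_ll, n_free=n_free, df=0, moments=moments,
                        n_iter=iters, converged=converged)


def _saturated_one_group(gd: GroupData, tol: float, maxiter: int):
    p = gd.p
    if gd.complete:
        pat = gd.patterns[0]
        mu, Sigma = pat.mean.copy(), pat.scatter.copy()
        ll = _loglik_mu_sigma(gd, mu, Sigma)
        return mu, Sigma, ll, 0, True
    mu, var = gd.observed_means_vars()
    mu = np.nan_to_num(mu)
    Sigma = np.diag(np.where(np.isfinite(var) & (var > 0), var, 1.0))
    ll_old = _loglik_mu_sigma(gd, mu, Sigma)
    for it in range(1, maxiter + 1):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for pat in gd.patterns:
            o = pat.obs
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            n_p = pat.n
            sd = n_p * (pat.mean - mu[o])                     # sum of deviations
            # SD = sum_r d_r d_r' with d_r = x_o,r - mu_o
            SD = n_p * pat.scatter + n_p * np.outer(pat.mean - mu[o], pat.mean - mu[o])
            s1[o] += n_p * pat.mean
            s2[np.ix_(o, o)] += SD + np.outer(mu[o], sd) + np.outer(sd, mu[o]) \
                + n_p * np.outer(mu[o], mu[o])
            if len(m):
                Soo = Sigma[np.ix_(o, o)]
                c, low = cho_factor(Soo, check_finite=False)
                Kmat = cho_solve((c, low), Sigma[np.ix_(o, m)], check_finite=False).T
                Ccond = Sigma[np.ix_(m, m)] - Kmat @ Sigma[np.ix_(o, m)]
                sum_M = n_p * mu[m] + Kmat @ sd
                # cross products with observed block
                Sx_d = SD + np.outer(mu[o], sd)               # sum x_r d_r'
                XoM = np.outer(n_p * pat.mean, mu[m]) + Sx_d @ Kmat.T
                MM = (n_p * np.outer(mu[m], mu[m])
                      + np.outer(mu[m], sd) @ Kmat.T
                      + Kmat @ np.outer(sd, mu[m])
                      + Kmat @ SD @ Kmat.T
                      + n_p * Ccond)
                s1[m] += sum_M
                s2[np.ix_(o, m)] += XoM
                s2[np.ix_(m, o)] += XoM.T
                s2[np.ix_(m, m)] += MM
        mu = s1 / gd.n
        Sigma = s2 / gd.n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = _loglik_mu_sigma(gd, mu, Sigma)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            return mu, Sigma, ll, it, True
        ll_old = ll
    warnings.warn("saturated EM did not reach tolerance; returning last iterate")
    return mu, Sigma, ll_old, maxiter, False


def fit_baseline(groups_data: list[GroupData]) -> ReferenceFit:
    """Independence model: free means/variances, zero covariances (closed
    form — the casewise likelihood factorises per variable)."""
    total_ll = 0.0
    moments = []
    p = groups_data[0].p
    for gd in groups_data:
        mean, var = gd.observed_means_vars()
        n_j = np.zeros(p)
        for pat in gd.patterns:
            n_j[pat.obs] += pat.n
        ll = float((-0.5 * n_j * (_LOG_2PI + np.log(var) + 1.0)).sum())
        total_ll += ll
        moments.append((mean, np.diag(var)))
    n_free = len(groups_data) * 2 * p
    n_mom = len(groups_data) * (p + p * (p + 1) // 2)
    return ReferenceFit(llf=total_ll, n_free=n_free, df=n_mom - n_free,
                        moments=moments)


# ======================================================================
# Model / Results
# ======================================================================

class CFAModel:
    """A confirmatory factor model bound to data (statsmodels-style).

    Construct from an :class:`ItemDataset` (optionally split by a grouping
    column) or from per-group sufficient statistics, then call :meth:`fit`.
    """

    def __init__(self, groups_data: list[GroupData], spec: FactorModelSpec):
        if len(groups_data) != spec.n_groups:
            raise ValueError("number of data groups does not match the spec")
        self.spec = spec
        self.groups_data = groups_data
        self.template: ParamTemplate = build_template(spec)
        self._saturated: ReferenceFit | None = None
        self._baseline: ReferenceFit | None = None

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_dataset(cls, data: ItemDataset, spec: FactorModelSpec,
                     group_col: str | None = None) -> "CFAModel":
        if group_col is None:
            X = data.responses.to_numpy()
            gds = [_make_group_data(X, spec.groups[0])]
        else:
            split = data.split_by(group_col)
            if tuple(sorted(split)) != tuple(sorted(spec.groups)):
                raise ValueError(
                    f"groups in data {sorted(split)} do not match spec "
                    f"groups {sorted(spec.groups)}"
                )
            gds = [_make_group_data(split[g].responses.to_numpy(), g)
                   for g in spec.groups]
        dropped = sum(g.n_dropped for g in gds)
        if dropped:
            warnings.warn(f"dropped {dropped} respondents with all items missing")
        return cls(gds, spec)

    @classmethod
    def from_moments(cls, moments: dict, spec: FactorModelSpec,
                     cov_is_ml: bool = True) -> "CFAModel":
        """Build from per-group ``(n, mean, cov)`` sufficient statistics.

        ``cov_is_ml`` says whether the covariance uses the n denominator;
        pass False for the usual n-1 (unbiased) convention.
        """
        gds = []
        for label in spec.groups:
            n, mean, cov = moments[label]
            cov = np.asarray(cov, dtype=float)
            if not cov_is_ml:
                cov = cov * (n - 1) / n
            p = len(mean)
            gds.append(GroupData(
                label=label,
                patterns=[_Pattern(obs=np.arange(p), n=int(n),
                                   mean=np.asarray(mean, float), scatter=cov)],
                n=int(n), p=p,
            ))
        return cls(gds, spec)

    # -- reference fits ---------------------------------------------------
    @property
    def saturated(self) -> ReferenceFit:
        if self._saturated is None:
            self._saturated = fit_saturated(self.groups_data)
        return self._saturated

    @property
    def baseline(self) -> ReferenceFit:
        if self._baseline is None:
            self._baseline = fit_baseline(self.groups_data)
        return self._baseline

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups_data)

    # -- starting values ---------------------------------------------------
    def start_params(self) -> np.ndarray:
        """Deterministic starting values: loadings 1, residuals half the
        observed item variance, disturbances and factor variances 0.5,
        intercepts at the observed means."""
        params = []
        for gd in self.groups_data:
            mean, var = gd.observed_means_vars()
            var = np.where(np.isfinite(var) & (var > 0), var, 1.0)
            mean = np.nan_to_num(mean)
            K = self.spec.n_factors
            g = {
                "loading": np.ones(self.spec.p),
                "nu": mean,
                "theta": var / 2.0,
            }
            if self.spec.kind == "second_order":
                g.update({
                    "lambda2": np.ones(K),
                    "psi_d": np.full(K, 0.5),
                    "phi": np.array([0.5]),
                    "tau": np.zeros(K),
                    "alpha": np.zeros(1),
                })
            else:
                g.update({
                    "psi_diag": np.full(K, 0.5),
                    "psi_off": np.full(K * (K - 1) // 2, 0.2),
                })
            params.append(g)
        return self.template.pack(params)

    # -- fitting -----------------------------------------------------------
    def fit(self, start: np.ndarray | None = None,
            warm_from: "CFAResults | None" = None,
            maxiter: int = 500, ftol: float = 1e-10, gtol: float = 1e-5,
            raise_on_fail: bool = True) -> "CFAResults":
        """Maximise the FIML log-likelihood; returns a :class:`CFAResults`.

        ``warm_from`` seeds the optimisation with another fit's parameter
        values (used down the invariance ladder); shared slots take the
        warm fit's reference-group values.
        """
        if start is None and warm_from is not None:
            start = self.template.pack(warm_from.params)
        if start is None:
            start = self.start_params()
        res = optimize.minimize(
            _neg_loglik_and_grad, start, jac=True, method="L-BFGS-B",
            args=(self.spec, self.template, self.groups_data),
            options={"maxiter": maxiter, "maxfun": 20 * maxiter,
                     "ftol": ftol, "gtol": gtol},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        converged = bool(res.success) or grad_norm < 1e-3
        if not converged and raise_on_fail:
            raise FitError(
                f"optimisation did not converge: {res.message} "
                f"(max |gradient| = {grad_norm:.2e})"
            )
        x = np.clip(res.x, -30.0, 30.0)
        params = self.template.unpack(x)
        heywood = []
        for g, label in zip(params, self.spec.groups):
            for cls in ("theta", "psi_d", "phi", "psi_diag"):
                if cls in g and np.any(g[cls] < _HEYWOOD_TOL):
                    heywood.append((label, cls))
        if heywood:
            warnings.warn(f"variance at boundary (Heywood) in {heywood}")
        return CFAResults(
            model=self, free_params=x, params=params, llf=float(-res.fun),
            converged=converged, grad_norm=grad_norm,
            n_iter=int(res.nit), heywood=heywood,
        )


@dataclass
class CFAResults:
    """Estimates, fit statistics and derived quantities of one CFA fit."""

    model: CFAModel
    free_params: np.ndarray
    params: list[dict[str, np.ndarray]]
    llf: float
    converged: bool
    grad_norm: float
    n_iter: int
    heywood: list = field(default_factory=list)
    _bse_cache: np.ndarray | None = field(default=None, repr=False)

    # -- bookkeeping -------------------------------------------------------
    @property
    def spec(self) -> FactorModelSpec:
        return self.model.spec

    @property
    def n_free(self) -> int:
        return self.model.template.nfree

    @property
    def df(self) -> int:
        return self.spec.n_moments() - self.n_free

    @property
    def n_total(self) -> int:
        return self.model.n_total

    @property
    def group_ns(self) -> dict[str, int]:
        return {g.label: g.n for g in self.model.groups_data}

    # -- chi-square --------------------------------------------------------
    @property
    def chi2(self) -> float:
        return max(2.0 * (self.model.saturated.llf - self.llf), 0.0)

    @property
    def pvalue(self) -> float:
        return float(stats.chi2.sf(self.chi2, self.df)) if self.df > 0 else np.nan

    @property
    def chi2_baseline(self) -> float:
        return max(2.0 * (self.model.saturated.llf - self.model.baseline.llf), 0.0)

    @property
    def df_baseline(self) -> int:
        return self.model.baseline.df

    # -- implied and sample moments ---------------------------------------
    def implied_moments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [implied_moments(self.spec, g) for g in self.params]

    def sample_moments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return self.model.saturated.moments

    # -- standardized solution --------------------------------------------
    def standardized_loadings(self) -> list[dict[str, np.ndarray]]:
        """Per group: standardized first-order (and second-order) loadings."""
        out = []
        fac = self.spec.factor_of_item
        for g in self.params:
            mu, Sigma = implied_moments(self.spec, g)
            item_sd = np.sqrt(np.diag(Sigma))
            if self.spec.kind == "second_order":
                l2, phi = g["lambda2"], g["phi"][0]
                B = np.outer(l2, l2) * phi + np.diag(g["psi_d"])
            else:
                K = self.spec.n_factors
                B = np.diag(g["psi_diag"]).astype(float)
                iu = np.triu_indices(K, 1)
                B[iu] = g["psi_off"]
                B = B + np.triu(B, 1).T
            fac_sd = np.sqrt(np.diag(B))
            std = {"loading": g["loading"] * fac_sd[fac] / item_sd}
            if self.spec.kind == "second_order":
                std["lambda2"] = g["lambda2"] * np.sqrt(g["phi"][0]) / fac_sd
            else:
                std["factor_corr"] = B / np.outer(fac_sd, fac_sd)
            out.append(std)
        return out

    # -- standard errors ---------------------------------------------------
    @property
    def bse(self) -> np.ndarray:
        """SEs of the free vector from the observed information (numeric
        Hessian of the analytic gradient)."""
        if self._bse_cache is None:
            H = self._hessian()
            cov = np.linalg.pinv(H)
            var = np.clip(np.diag(cov), 0, None)
            self._bse_cache = np.sqrt(var)
        return self._bse_cache

    def _hessian(self, h: float = 1e-5) -> np.ndarray:
        x0 = self.free_params
        n = len(x0)
        H = np.zeros((n, n))
        for i in range(n):
            e = np.zeros(n); e[i] = h
            _, gp = _neg_loglik_and_grad(x0 + e, self.spec, self.model.template,
                                         self.model.groups_data)
            _, gm = _neg_loglik_and_grad(x0 - e, self.spec, self.model.template,
                                         self.model.groups_data)
            H[i] = (gp - gm) / (2 * h)
        return 0.5 * (H + H.T)

    # -- comparisons -------------------------------------------------------
    def lrt(self, other: "CFAResults") -> "LRTResult":
        """Likelihood-ratio test of self (constrained) against ``other``."""
        return lrt(self, other)

    # -- display -----------------------------------------------------------
    def param_table(self) -> pd.DataFrame:
        rows = []
        for g, label in zip(self.params, self.spec.groups):
            for cls, vals in g.items():
                names = _param_names(self.spec, cls)
                for name, v in zip(names, np.atleast_1d(vals)):
                    rows.append({"group": label, "class": cls,
                                 "param": name, "estimate": float(v)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"{self.spec.label()}  (groups: {', '.join(self.spec.groups)})",
            f"n = {self.n_total}   free parameters = {self.n_free}   df = {self.df}",
            f"log-likelihood = {self.llf:.3f}",
            f"chi2({self.df}) = {self.chi2:.3f}   p = {self.pvalue:.4f}",
            f"converged = {self.converged}   max|grad| = {self.grad_norm:.2e}",
        ]
        if self.heywood:
            lines.append(f"WARNING Heywood boundary: {self.heywood}")
        tab = self.param_table()
        lines.append(tab.to_string(index=False,
                                   float_format=lambda v: f"{v: .3f}"))
        return "\n".join(lines)


def _param_names(spec: FactorModelSpec, cls: str) -> list[str]:
    if cls in ("loading", "nu", "theta"):
        return list(spec.item_names)
    if cls in ("lambda2", "psi_d", "tau", "psi_diag"):
        return list(spec.factor_names)
    if cls in ("phi", "alpha"):
        return ["g"]
    if cls == "psi_off":
        K = spec.n_factors
        names = list(spec.factor_names)
        return [f"{names[i]}~{names[j]}" for i in range(K) for j in range(i + 1, K)]
    return [cls]


@dataclass
class LRTResult:
    """Nested-model likelihood-ratio (chi-square difference) test."""

    dchi2: float
    ddf: int
    pvalue: float


def lrt(constrained: CFAResults, free: CFAResults) -> LRTResult:
    """Chi-square difference test between nested fits on the same data.

    Raises when the df difference is not positive (models identical or not
    nested in the required direction).
    """
    ddf = constrained.df - free.df
    if ddf <= 0:
        raise ValueError("constrained model must have strictly more df "
                         "(models not nested or identical)")
    dchi2 = max(constrained.chi2 - free.chi2, 0.0)
    return LRTResult(dchi2=dchi2, ddf=ddf,
                     pvalue=float(stats.chi2.sf(dchi2, ddf)))
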