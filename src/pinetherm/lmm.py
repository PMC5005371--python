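"""Random-intercept linear mixed models by profiled likelihood.

The marginal covariance of a tree's observations is
``sigma_eps^2 * (W + theta * 11')`` where ``theta = sigma_0^2 / sigma_eps^2``
is the variance ratio of the tree-level random intercept and ``W`` is a
diagonal variance-function matrix (identity, per-treatment, or a power of
the fitted values).  For fixed variance parameters, the fixed effects and
the residual scale have closed-form GLS solutions, so the optimizer only
searches over ``log theta`` (plus one variance-function parameter where
applicable).  Group-wise Woodbury identities keep every likelihood
evaluation O(n * p).

Both maximum likelihood (for model comparison: AIC, drop1) and REML (for
the reported final fits) are supported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .design import ModelSpec, build_design, build_response

__all__ = [
    "ModelFit",
    "ContrastResult",
    "ConvergenceError",
    "fit_lmm",
    "r2_glmm",
    "bh_adjust",
    "pairwise_z_contrasts",
]

_LOG_THETA_BOUNDS = (-18.0, 10.0)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ModelFit:
    """A fitted random-intercept mixed model.

    ``sigma0_sq`` is the random-intercept variance, ``sigma_eps_sq`` the
    residual variance (for non-identity variance functions, the base-level
    residual variance; ``var_params`` holds the structure parameters).
    ``aic = -2 logLik + 2 k`` with ``k`` counting fixed effects plus both
    variance components plus any variance-function parameters.
    """

    spec: ModelSpec
    method: str
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    sigma0_sq: float
    sigma_eps_sq: float
    var_params: Mapping[str, float] = field(default_factory=dict)
    loglik: float = np.nan
    aic: float = np.nan
    n_obs: int = 0
    n_groups: int = 0
    fixed_pred: Optional[np.ndarray] = None
    converged: bool = True
    notes: tuple = ()

    @property
    def k_params(self) -> int:
        return len(self.params) + 2 + len(self.var_params)

    def contrast(self, c: np.ndarray) -> Tuple[float, float, float, float]:
        """Estimate, SE, z and two-sided p for the linear combination c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov_params.to_numpy() @ c))
        z = est / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        return est, se, z, p

    def wald(self, C: np.ndarray) -> Tuple[float, int, float]:
        """Joint Wald chi-square test of C beta = 0."""
        C = np.atleast_2d(np.asarray(C, dtype=float))
        d = C @ self.params.to_numpy()
        V = C @ self.cov_params.to_numpy() @ C.T
        stat = float(d @ np.linalg.solve(V, d))
        df = C.shape[0]
        return stat, df, float(stats.chi2.sf(stat, df))


@dataclass
class ContrastResult:
    """Pairwise contrasts with raw and BH-FDR-adjusted p-values."""

    family: str
    table: pd.DataFrame  # columns: a, b, estimate, se, stat, df, p_raw, p_adj


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _group_indices(groups: np.ndarray) -> list:
    _, inv = np.unique(groups, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    bounds = np.flatnonzero(np.diff(inv[order])) + 1
    return [order[s] for s in np.split(np.arange(len(order)), bounds)]


def _profiled_quantities(theta: float, Xg, yg, wg, n: int, p: int):
    """GLS solution and profiled deviance pieces for a given variance ratio."""
    A = np.zeros((p, p))
    b = np.zeros(p)
    q = 0.0
    ld = 0.0
    for X, y, w in zip(Xg, yg, wg):
        wi = 1.0 / w
        s = wi.sum()
        c = theta / (1.0 + theta * s)
        Xw = X * wi[:, None]
        yw = y * wi
        x1 = Xw.sum(axis=0)
        y1 = yw.sum()
        A += X.T @ Xw - c * np.outer(x1, x1)
        b += X.T @ yw - c * x1 * y1
        q += y @ yw - c * y1 * y1
        ld += np.log(w).sum() + np.log1p(theta * s)
    beta = np.linalg.solve(A, b)
    rss = max(q - beta @ b, 1e-300)
    return A, beta, rss, ld


def _deviance(theta, Xg, yg, wg, n, p, reml):
    A, beta, rss, ld = _profiled_quantities(theta, Xg, yg, wg, n, p)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, ldA = np.linalg.slogdet(A)
        dev = dof * (np.log(2 * np.pi * sigma2) + 1.0) + ld + ldA
    else:
        sigma2 = rss / n
        dev = n * (np.log(2 * np.pi * sigma2) + 1.0) + ld
    return dev, beta, sigma2, A


def _weights(structure, delta, df, strata, fitted):
    if structure == "homoscedastic":
        return None  # signal unit weights
    if structure == "per_treatment":
        return np.where(strata, np.exp(2.0 * delta), 1.0)
    if structure == "power":
        return np.clip(np.abs(fitted), 1e-4, None) ** (2.0 * delta)
    raise ValueError(structure)


def fit_lmm(spec: ModelSpec, obs: pd.DataFrame, method: str = "REML") -> ModelFit:
    """Fit the mixed model described by ``spec`` to an observation table.

    ``method`` is ``"ML"`` (used for AIC-based comparisons) or ``"REML"``
    (used for the reported final fit).  Raises :class:`ConvergenceError`
    with the final gradient norm if the optimizer fails, and a
    ``ValueError`` when the random intercept is unidentifiable (fewer than
    two trees).
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    reml = method == "REML"
    X, names = build_design(spec, obs)
    y = build_response(spec, obs)
    groups = obs["tree_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("random intercept unidentifiable: need at least 2 trees")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"more fixed-effect columns ({p}) than observations ({n})")
    idx = _group_indices(groups)
    Xg = [X[i] for i in idx]
    yg = [y[i] for i in idx]
    ones = [np.ones(len(i)) for i in idx]
    # per-treatment variance: delta is the log residual-SD ratio of the
    # drought stratum relative to control
    strata = (obs["treatment"].to_numpy() == "drought") if "treatment" in obs.columns else None
    if spec.variance_structure == "per_treatment" and strata is None:
        raise ValueError("per-treatment variance structure requires a treatment column")

    structure = spec.variance_structure
    var_params: dict = {}
    fitted = None

    def solve(theta, delta=0.0):
        w = _weights(structure, delta, obs, strata, fitted)
        wg = ones if w is None else [w[i] for i in idx]
        return _deviance(theta, Xg, yg, wg, n, p, reml)

    if structure == "homoscedastic":
        res = optimize.minimize_scalar(
            lambda lt: solve(np.exp(lt))[0],
            bounds=_LOG_THETA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-8},
        )
        log_theta = float(res.x)
        delta = 0.0
        converged = bool(res.success)
    else:
        # outer IGLS loop refreshes fitted-value weights for the power class
        x0 = np.array([0.0, 0.0])
        converged = True
        for _ in range(3 if structure == "power" else 1):
            if structure == "power" and fitted is None:
                # initialize fitted values from a homoscedastic fit
                base = fit_lmm(
                    ModelSpec(
                        response=spec.response,
                        terms=spec.terms,
                        centering=spec.centering,
                        variance_structure="homoscedastic",
                        provenance_levels=spec.provenance_levels,
                        kind=spec.kind,
                    ),
                    obs,
                    method=method,
                )
                fitted = base.fixed_pred
            res = optimize.minimize(
                lambda v: solve(np.exp(np.clip(v[0], *_LOG_THETA_BOUNDS)), v[1])[0],
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1000},
            )
            x0 = res.x
            converged = converged and bool(res.success)
            if structure == "power":
                th = np.exp(np.clip(res.x[0], *_LOG_THETA_BOUNDS))
                _, beta_tmp, _, _ = solve(th, res.x[1])
                fitted = X @ beta_tmp
        log_theta = float(np.clip(res.x[0], *_LOG_THETA_BOUNDS))
        delta = float(res.x[1])
        var_params["delta"] = delta

    theta = float(np.exp(log_theta))
    dev, beta, sigma2, A = solve(theta, delta)
    if not converged:
        grad = optimize.approx_fprime(
            np.array([log_theta]), lambda lt: solve(np.exp(lt[0]), delta)[0], 1e-6
        )
        raise ConvergenceError(
            f"mixed-model optimizer failed; |grad| = {float(np.abs(grad).max()):.3g}"
        )

    cov = sigma2 * np.linalg.inv(A)
    loglik = -0.5 * dev
    params = pd.Series(beta, index=names)
    covdf = pd.DataFrame(cov, index=names, columns=names)
    k = p + 2 + len(var_params)
    fit = ModelFit(
        spec=spec,
        method=method,
        params=params,
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov_params=covdf,
        sigma0_sq=theta * sigma2,
        sigma_eps_sq=sigma2,
        var_params=var_params,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        n_obs=n,
        n_groups=len(idx),
        fixed_pred=X @ beta,
        converged=True,
    )
    return fit


def r2_glmm(fit: ModelFit) -> Tuple[float, float]:
    """Marginal and conditional R^2 for a Gaussian mixed model.

    Variance-partitioning form: the marginal R^2 is
    ``var(X beta) / (var(X beta) + sigma_0^2 + sigma_eps^2)`` and the
    conditional R^2 adds the random-intercept variance to the numerator.
    For non-identity variance functions the residual term uses the mean
    implied residual variance.
    """
    var_f = float(np.var(fit.fixed_pred, ddof=1))
    sig_e = fit.sigma_eps_sq
    if fit.spec.variance_structure == "power" and "delta" in fit.var_params:
        w = np.clip(np.abs(fit.fixed_pred), 1e-4, None) ** (2 * fit.var_params["delta"])
        sig_e = fit.sigma_eps_sq * float(np.mean(w))
    denom = var_f + fit.sigma0_sq + sig_e
    return var_f / denom, (var_f + fit.sigma0_sq) / denom


def pairwise_z_contrasts(
    fit: ModelFit,
    effects: Mapping[str, np.ndarray],
    family: str,
) -> ContrastResult:
    """All pairwise z-contrasts among named effects, BH-FDR adjusted.

    ``effects`` maps a label to the contrast vector giving that label's
    effect on the linear predictor; pair (a, b) tests effect_a - effect_b.
    """
    labels = list(effects)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        c = effects[a] - effects[b]
        est, se, z, pr = fit.contrast(c)
        rows.append({"a": a, "b": b, "estimate": est, "se": se, "stat": z, "df": 1, "p_raw": pr})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    return ContrastResult(family=family, table=table)
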