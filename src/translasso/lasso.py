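"""Box-constrained L1-penalized binomial (logistic) regression.

Solves

    min_{b0, b}  (1/n) * sum_i [ -y_i * eta_i + log(1 + exp(eta_i)) ]
                 + lambda * ||b||_1
    subject to   lower <= b_j <= upper,    eta_i = b0 + x_i . b

by outer iteratively-reweighted least squares (IRLS) and inner cyclic
coordinate descent, where each coordinate update is the penalized-quadratic
soft-threshold solution clipped to the box.  The intercept is unpenalized
and unconstrained.  The objective is non-increasing across accepted outer
iterations (a step-halving safeguard interpolates toward the previous
iterate when the quadratic approximation oversteps), and convergence is
certified by an explicit Karush-Kuhn-Tucker (KKT) residual.

The one-dimensional coordinate problem is convex piecewise-quadratic, so
clipping its unconstrained soft-threshold minimizer to the box is exact.

Coefficients and bounds live on the standardized-predictor scale: design
columns are centered and scaled to unit variance (1/n denominator), which
makes a common bound magnitude comparable across features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import expit

from .io import ValidationError, logger

__all__ = [
    "DesignMatrix",
    "LassoFit",
    "soft_threshold",
    "make_design",
    "project_design",
    "fit_bounded_lasso",
    "fit_lambda_path",
    "lambda_max",
    "kkt_check",
    "predict_proba",
    "objective",
]

ACTIVE_TOL = 1e-8  # |beta_j| above this counts as active (nonzero)
COEF_TOL = 1e-7
KKT_TOL = 1e-6
MAX_OUTER = 200
MAX_SWEEPS = 10_000
WEIGHT_FLOOR = 1e-5


@dataclass
class DesignMatrix:
    """Standardized samples x features design with binary labels.

    ``mean`` and ``sd`` are the training standardization parameters, kept
    for projecting held-out samples onto the training scale.
    """

    feature_ids: list[str]
    X: np.ndarray  # (n_samples, n_features), float64
    y: np.ndarray  # (n_samples,), 0/1
    mean: np.ndarray
    sd: np.ndarray

    def validate(self) -> None:
        if set(np.unique(self.y)) != {0, 1}:
            raise ValidationError("labels must contain both classes")
        live = self.X.std(axis=0) > 0
        col_mean = self.X[:, live].mean(axis=0)
        col_sd = self.X[:, live].std(axis=0)
        if np.abs(col_mean).max(initial=0.0) > 1e-8:
            raise ValidationError("design columns are not centered")
        if np.abs(col_sd - 1).max(initial=0.0) > 1e-8:
            raise ValidationError("design columns are not unit-variance")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class LassoFit:
    """A fitted box-constrained lasso model at one penalty value."""

    feature_ids: list[str]
    intercept: float
    beta: np.ndarray
    lam: float
    lower: float
    upper: float
    n_iter: int
    converged: bool
    max_kkt_violation: float
    objective: float

    @property
    def active_set(self) -> np.ndarray:
        """Indices of features with |beta| above the activity threshold."""
        return np.flatnonzero(np.abs(self.beta) > ACTIVE_TOL)

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_ids": self.feature_ids,
                "intercept": self.intercept,
                "beta": self.beta.tolist(),
                "lambda": self.lam,
                "lower": self.lower,
                "upper": self.upper,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "max_kkt_violation": self.max_kkt_violation,
                "objective": self.objective,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "LassoFit":
        d = json.loads(text)
        return cls(
            feature_ids=d["feature_ids"],
            intercept=d["intercept"],
            beta=np.asarray(d["beta"], dtype=float),
            lam=d["lambda"],
            lower=d["lower"],
            upper=d["upper"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            max_kkt_violation=d["max_kkt_violation"],
            objective=d["objective"],
        )


def soft_threshold(z: float, gamma: float) -> float:
    """``sign(z) * max(|z| - gamma, 0)`` — the lasso shrinkage kernel."""
    if gamma < 0:
        raise ValidationError("gamma must be >= 0")
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def make_design(
    X_raw: np.ndarray, y: np.ndarray, feature_ids: list[str] | None = None
) -> DesignMatrix:
    """Standardize raw features (1/n variance) into a :class:`DesignMatrix`.

    Constant columns get sd 1 so they standardize to all-zero and can never
    enter the active set; they are logged.
    """
    X_raw = np.asarray(X_raw, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(X_raw.shape[1])]
    mean = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0)  # 1/n denominator
    n_const = int((sd == 0).sum())
    if n_const:
        logger.warning("%d constant feature(s) in design; they stay inactive", n_const)
    sd = np.where(sd == 0, 1.0, sd)
    X = (X_raw - mean) / sd
    return DesignMatrix(list(feature_ids), np.ascontiguousarray(X), y, mean, sd)


def project_design(d: DesignMatrix, X_test_raw: np.ndarray) -> np.ndarray:
    """Project held-out samples onto the training standardization."""
    return (np.asarray(X_test_raw, dtype=np.float64) - d.mean) / d.sd


def objective(
    X: np.ndarray, y: np.ndarray, intercept: float, beta: np.ndarray, lam: float
) -> float:
    """Penalized average negative binomial log-likelihood."""
    eta = intercept + X @ beta
    nll = float(np.mean(-y * eta + np.logaddexp(0.0, eta)))
    return nll + lam * float(np.abs(beta).sum())


@njit(cache=True)
def _cd_sweeps(XT, w, z, beta, beta0, lam, lower, upper, tol, max_sweeps):
    """Cyclic coordinate descent on the weighted least-squares surrogate.

    Minimizes (1/(2n)) sum_i w_i (z_i - beta0 - x_i.b)^2 + lam * ||b||_1
    over the box.  XT is features x samples (C-contiguous).  Alternates
    full sweeps with sweeps over the current active set.  Returns
    (beta0, sweeps used).
    """
    p, n = XT.shape
    r = z.copy()
    for i in range(n):
        acc = beta0
        for j in range(p):
            acc += XT[j, i] * beta[j]
        r[i] = z[i] - acc
    sweeps = 0
    while sweeps < max_sweeps:
        # full sweep
        sweeps += 1
        max_delta = 0.0
        sw = 0.0
        swr = 0.0
        for i in range(n):
            sw += w[i]
            swr += w[i] * r[i]
        d0 = swr / sw
        beta0 += d0
        for i in range(n):
            r[i] -= d0
        if abs(d0) > max_delta:
            max_delta = abs(d0)
        for j in range(p):
            bj = beta[j]
            nu = 0.0
            rho = 0.0
            for i in range(n):
                xij = XT[j, i]
                nu += w[i] * xij * xij
                rho += w[i] * xij * (r[i] + xij * bj)
            nu /= n
            rho /= n
            if nu <= 0.0:
                continue
            if rho > lam:
                bnew = (rho - lam) / nu
            elif rho < -lam:
                bnew = (rho + lam) / nu
            else:
                bnew = 0.0
            if bnew > upper:
                bnew = upper
            elif bnew < lower:
                bnew = lower
            d = bnew - bj
            if d != 0.0:
                beta[j] = bnew
                for i in range(n):
                    r[i] -= XT[j, i] * d
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < tol:
            break
        # active-set sweeps until stable
        while sweeps < max_sweeps:
            sweeps += 1
            max_delta = 0.0
            sw = 0.0
            swr = 0.0
            for i in range(n):
                sw += w[i]
                swr += w[i] * r[i]
            d0 = swr / sw
            beta0 += d0
            for i in range(n):
                r[i] -= d0
            if abs(d0) > max_delta:
                max_delta = abs(d0)
            for j in range(p):
                bj = beta[j]
                if bj == 0.0:
                    continue
                nu = 0.0
                rho = 0.0
                for i in range(n):
                    xij = XT[j, i]
                    nu += w[i] * xij * xij
                    rho += w[i] * xij * (r[i] + xij * bj)
                nu /= n
                rho /= n
                if nu <= 0.0:
                    continue
                if rho > lam:
                    bnew = (rho - lam) / nu
                elif rho < -lam:
                    bnew = (rho + lam) / nu
                else:
                    bnew = 0.0
                if bnew > upper:
                    bnew = upper
                elif bnew < lower:
                    bnew = lower
                d = bnew - bj
                if d != 0.0:
                    beta[j] = bnew
                    for i in range(n):
                        r[i] -= XT[j, i] * d
                    if abs(d) > max_delta:
                        max_delta = abs(d)
            if max_delta < tol:
                break
    return beta0, sweeps


def fit_bounded_lasso(
    d: DesignMatrix,
    lam: float,
    lower: float,
    upper: float,
    warm_start: LassoFit | None = None,
    coef_tol: float = COEF_TOL,
    kkt_tol: float = KKT_TOL,
    max_outer: int = MAX_OUTER,
    max_sweeps: int = MAX_SWEEPS,
) -> LassoFit:
    """Fit the box-constrained lasso logistic model at one ``lam``.

    Non-convergence within the iteration budget returns a fit flagged
    ``converged=False`` with a logged warning; it never raises.
    """
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    if not (lower < 0 < upper):
        raise ValidationError("bounds must satisfy lower < 0 < upper")
    X, y = d.X, d.y
    n, p = X.shape
    XT = np.ascontiguousarray(X.T)
    ybar = float(y.mean())
    if not 0 < ybar < 1:
        raise ValidationError("labels must contain both classes")
    if warm_start is not None:
        beta = np.clip(warm_start.beta.astype(np.float64).copy(), lower, upper)
        beta0 = float(warm_start.intercept)
    else:
        beta = np.zeros(p)
        beta0 = float(np.log(ybar / (1 - ybar)))
    obj = objective(X, y, beta0, beta, lam)
    sweeps_left = max_sweeps
    n_outer = 0
    converged = False
    for _ in range(max_outer):
        n_outer += 1
        eta = beta0 + X @ beta
        prob = expit(eta)
        w = np.maximum(prob * (1.0 - prob), WEIGHT_FLOOR)
        z = eta + (y - prob) / w
        new_beta = beta.copy()
        new_beta0, used = _cd_sweeps(
            XT, w, z, new_beta, beta0, lam, lower, upper, coef_tol,
            max(1, sweeps_left),
        )
        sweeps_left -= used
        # step-halving safeguard: the IRLS surrogate may overstep
        t = 1.0
        cand_beta, cand_beta0 = new_beta, new_beta0
        cand_obj = objective(X, y, cand_beta0, cand_beta, lam)
        while cand_obj > obj + 1e-12 and t > 1e-4:
            t *= 0.5
            cand_beta = beta + t * (new_beta - beta)
            cand_beta0 = beta0 + t * (new_beta0 - beta0)
            cand_obj = objective(X, y, cand_beta0, cand_beta, lam)
        if cand_obj > obj + 1e-12:
            break  # no descent direction left at this precision
        max_change = max(
            float(np.abs(cand_beta - beta).max(initial=0.0)),
            abs(cand_beta0 - beta0),
        )
        beta, beta0, obj = cand_beta, cand_beta0, cand_obj
        if max_change < coef_tol or sweeps_left <= 0:
            break
    # snap numerically-zero coefficients (below the activity threshold) to
    # exact zero so the reported active set and the coefficients agree
    beta[np.abs(beta) <= ACTIVE_TOL] = 0.0
    obj = objective(X, y, beta0, beta, lam)
    fit = LassoFit(
        feature_ids=list(d.feature_ids),
        intercept=beta0,
        beta=beta,
        lam=lam,
        lower=lower,
        upper=upper,
        n_iter=n_outer,
        converged=False,
        max_kkt_violation=np.inf,
        objective=obj,
    )
    viol = kkt_check(d, fit)
    fit.max_kkt_violation = viol
    fit.converged = viol <= kkt_tol
    if not fit.converged:
        logger.warning(
            "lasso fit at lambda=%.4g did not converge (KKT violation %.3g)",
            lam, viol,
        )
    return fit


def fit_lambda_path(
    d: DesignMatrix,
    lambdas: tuple[float, ...],
    lower: float,
    upper: float,
    **kwargs,
) -> list[LassoFit]:
    """Fit every lambda from largest to smallest with warm starts.

    Returns fits in the order of the input grid.
    """
    order = np.argsort(lambdas)[::-1]
    fits: list[LassoFit | None] = [None] * len(lambdas)
    warm = None
    for k in order:
        fit = fit_bounded_lasso(d, lambdas[k], lower, upper, warm_start=warm, **kwargs)
        fits[k] = fit
        warm = fit
    return fits  # type: ignore[return-value]


def lambda_max(d: DesignMatrix) -> float:
    """Smallest penalty at which the all-zero coefficient vector is optimal.

    With the intercept at logit(mean(y)), the zero vector satisfies the
    KKT conditions iff ``max_j |(1/n) x_j^T (y - ybar)| <= lambda``.
    """
    ybar = d.y.mean()
    return float(np.abs(d.X.T @ (d.y - ybar)).max() / d.n)


def kkt_check(d: DesignMatrix, fit: LassoFit, bound_tol: float = 1e-9) -> float:
    """Maximum first-order optimality violation of ``fit``.

    With g_j = (1/n) x_j^T (p - y): an inactive coordinate must satisfy
    |g_j| <= lambda; an interior active one g_j = -lambda * sign(beta_j);
    one at a bound is violated only when the projected subgradient points
    back inside the box.  The (unpenalized) intercept gradient is included.
    """
    X, y = d.X, d.y
    lam = fit.lam
    lower, upper = fit.lower, fit.upper
    eta = fit.intercept + X @ fit.beta
    prob = expit(eta)
    g = X.T @ (prob - y) / d.n
    viol = abs(float(np.mean(prob - y)))
    for j in range(len(fit.beta)):
        b = fit.beta[j]
        if b >= upper - bound_tol:
            v = max(0.0, g[j] + lam)
        elif b <= lower + bound_tol:
            v = max(0.0, -(g[j] - lam))
        elif abs(b) <= ACTIVE_TOL:
            v = max(0.0, abs(g[j]) - lam)
        else:
            v = abs(g[j] + lam * np.sign(b))
        if v > viol:
            viol = v
    return float(viol)


def predict_proba(fit: LassoFit, X: np.ndarray, feature_ids: list[str] | None = None) -> np.ndarray:
    """Per-sample case probabilities ``1 / (1 + exp(-(b0 + x.b)))``.

    ``X`` must already be on the training standardization scale (see
    :func:`project_design`).  If ``feature_ids`` is given it must match the
    fit's features exactly.
    """
    if feature_ids is not None and list(feature_ids) != list(fit.feature_ids):
        raise ValidationError("feature ids do not match the fitted model")
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != len(fit.beta):
        raise ValidationError(
            f"design has {X.shape[1]} features, fit has {len(fit.beta)}"
        )
    eta = fit.intercept + X @ fit.beta
    return expit(eta)
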