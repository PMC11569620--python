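"""Lasso with exact post-selection inference.

The penalized fit minimizes ``(1/2n)||y - b0 - X b||^2 + lambda ||b||_1`` by
cyclic coordinate descent on internally standardized columns. The penalty is
chosen on a held-out validation split. Inference then conditions on the
selection event {active set, signs}, which is a polyhedron ``{y : A y <= b}``
in the response; for each selected feature the least-squares contrast
``eta' y`` restricted to that polyhedron follows a truncated Gaussian, giving
exact p-values and confidence intervals by inverting the truncated-Gaussian
pivot.

The reported per-feature ``estimate`` is the median-unbiased value (pivot =
1/2), which always lies inside the equal-tailed selective interval; the raw
contrast ``eta' y`` and the penalized coefficient are reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

logger = logging.getLogger(__name__)

try:  # optional JIT for the coordinate-descent sweep
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _cd_sweeps(Xs, r, beta, lam, n, max_iter, tol):
    """Cyclic coordinate descent on unit-variance columns. ``r`` is the
    running residual ``y_c - Xs @ beta`` and is updated in place.

    Alternates one full sweep with cheap sweeps restricted to the current
    active set until the largest coordinate update falls below ``tol``;
    convergence is declared only after a full sweep moves nothing.
    """
    p = beta.shape[0]
    n_iter = 0
    while n_iter < max_iter:
        # full sweep
        n_iter += 1
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            g = bj + np.dot(Xs[:, j], r) / n
            if g > lam:
                bnew = g - lam
            elif g < -lam:
                bnew = g + lam
            else:
                bnew = 0.0
            if bnew != bj:
                d = bnew - bj
                r -= Xs[:, j] * d
                beta[j] = bnew
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            return n_iter, True
        # active-set sweeps
        while n_iter < max_iter:
            n_iter += 1
            max_delta = 0.0
            for j in range(p):
                bj = beta[j]
                if bj == 0.0:
                    continue
                g = bj + np.dot(Xs[:, j], r) / n
                if g > lam:
                    bnew = g - lam
                elif g < -lam:
                    bnew = g + lam
                else:
                    bnew = 0.0
                d = bnew - bj
                if d != 0.0:
                    r -= Xs[:, j] * d
                    beta[j] = bnew
                    ad = abs(d)
                    if ad > max_delta:
                        max_delta = ad
            if max_delta < tol:
                break
    return n_iter, False


if _HAVE_NUMBA:
    _cd_sweeps_jit = _njit(cache=False)(_cd_sweeps)
else:  # pragma: no cover
    _cd_sweeps_jit = _cd_sweeps


@dataclass
class LassoFit:
    lam: float
    intercept: float
    coef: np.ndarray              # original-scale coefficients
    coef_std: np.ndarray          # coefficients on standardized columns
    active_set: np.ndarray        # indices with nonzero coefficient
    signs: np.ndarray             # +-1 per active index
    col_mean: np.ndarray
    col_scale: np.ndarray
    y_mean: float
    converged: bool
    n_iter: int
    kkt_residual: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X) @ self.coef

    def standardized(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.col_mean) / self.col_scale


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def kkt_violation(Xs: np.ndarray, yc: np.ndarray, beta: np.ndarray,
                  lam: float) -> float:
    """Max violation of the stationarity conditions: inactive gradients must
    satisfy ``|x_j'(y - Xb)/n| <= lambda``; active ones equal
    ``lambda * sign(b_j)``."""
    n = Xs.shape[0]
    g = Xs.T @ (yc - Xs @ beta) / n
    active = beta != 0
    v_inactive = np.max(np.abs(g[~active]) - lam, initial=0.0)
    v_active = np.max(np.abs(g[active] - lam * np.sign(beta[active])),
                      initial=0.0)
    return float(max(v_inactive, v_active, 0.0))


def fit_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-9,
    max_iter: int = 100000,
    warm_start: np.ndarray | None = None,
    use_numba: bool = True,
    warn: bool = True,
    active_tol: float = 1e-10,
) -> LassoFit:
    """Solve the lasso at one penalty value.

    ``tol`` bounds the largest single-coordinate update in a full sweep;
    exceeding ``max_iter`` sweeps returns the fit with ``converged=False``.
    Standardized coefficients with magnitude at most ``active_tol`` are
    zeroed: they are features sitting numerically at their entry point on
    the penalty path, indistinguishable from inactive ones, and keeping
    them puts the selection event on the boundary of its own polyhedron.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y must be aligned, X two-dimensional")
    if X.shape[0] < 2:
        raise ValueError("need at least two observations")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    n, p = X.shape
    Xs, mean, scale = _standardize(X)
    Xs = np.asfortranarray(Xs)
    y_mean = float(y.mean())
    yc = y - y_mean
    beta = (np.zeros(p) if warm_start is None
            else np.asarray(warm_start, dtype=float).copy())
    r = yc - Xs @ beta
    kernel = _cd_sweeps_jit if (use_numba and _HAVE_NUMBA) else _cd_sweeps
    n_iter, converged = kernel(Xs, r, beta, float(lam), float(n),
                               int(max_iter), float(tol))
    if not converged and warn:
        logger.warning("lasso did not converge in %d sweeps (lam=%g)",
                       max_iter, lam)
    beta[np.abs(beta) <= active_tol] = 0.0
    active = np.flatnonzero(beta)
    coef = beta / scale
    intercept = y_mean - float(coef @ mean)
    return LassoFit(
        lam=float(lam),
        intercept=intercept,
        coef=coef,
        coef_std=beta,
        active_set=active,
        signs=np.sign(beta[active]).astype(int),
        col_mean=mean,
        col_scale=scale,
        y_mean=y_mean,
        converged=bool(converged),
        n_iter=int(n_iter),
        kkt_residual=kkt_violation(Xs, yc, beta, lam),
    )


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the solution is entirely zero."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    yc = y - np.mean(y)
    return float(np.max(np.abs(Xs.T @ yc)) / X.shape[0])


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 50,
                ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced grid from ``lambda_max`` down to ``ratio * lambda_max``."""
    lmax = lambda_max(X, y)
    if lmax == 0:
        return np.zeros(1)
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def select_lambda(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    grid: np.ndarray | None = None,
    path_tol: float = 1e-5,
    path_max_iter: int = 1000,
    tol: float = 1e-9,
    max_iter: int = 100000,
) -> tuple[float, LassoFit]:
    """Pick the grid penalty minimizing validation MSE of the training fit.

    The path is fit from the sparse end with warm starts at a moderate
    tolerance (sufficient for validation scoring); the winning penalty is
    then refit tightly, warm-started from its path solution, and that fit is
    returned. Exact ties go to the larger (sparser) penalty.
    """
    if len(np.atleast_1d(y_val)) == 0:
        raise ValueError("validation set must be non-empty")
    if grid is None:
        grid = lambda_grid(X_train, y_train)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    best = None
    warm = None
    n_loose = 0
    for lam in grid:
        fit = fit_lasso(X_train, y_train, lam, tol=path_tol,
                        max_iter=path_max_iter, warm_start=warm, warn=False)
        n_loose += not fit.converged
        warm = fit.coef_std
        mse = float(np.mean((y_val - fit.predict(X_val)) ** 2))
        if best is None or mse < best[0]:
            best = (mse, lam, fit)
    if n_loose:
        logger.info("%d/%d path fits hit the sweep cap (validation scoring "
                    "only; the selected penalty is refit tightly)",
                    n_loose, grid.size)
    _, lam, path_fit = best
    fit = fit_lasso(X_train, y_train, lam, tol=tol, max_iter=max_iter,
                    warm_start=path_fit.coef_std)
    return float(lam), fit


def estimate_sigma(X: np.ndarray, y: np.ndarray, fit: LassoFit) -> float:
    """Noise scale from an unpenalized refit on the active set.

    Empty active set falls back to the sample SD of ``y``. A saturated
    active set (``n <= |E| + 1``) has no residual degrees of freedom and is
    an error directing the user to supply sigma.
    """
    y = np.asarray(y, dtype=float)
    E = fit.active_set
    n = y.shape[0]
    if E.size == 0:
        return float(np.std(y, ddof=1))
    if n <= E.size + 1:
        raise ValueError(
            "active set saturates the sample; supply sigma explicitly")
    Z = np.column_stack([np.ones(n), np.asarray(X, dtype=float)[:, E]])
    resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    dof = n - E.size - 1
    sigma = float(np.sqrt(resid @ resid / dof))
    if sigma == 0.0:
        logger.warning("estimate_sigma: exact fit, sigma estimate is 0")
    return sigma


# ---------------------------------------------------------------------------
# Truncated Gaussian survival function


def _right_tail_ratio(xi: float, a: float, b: float) -> float:
    """P(Z > xi | a < Z < b) for 0 <= a <= xi <= b via log survival values."""
    ls_x, ls_a = log_ndtr(-xi), log_ndtr(-a)
    ls_b = log_ndtr(-b) if np.isfinite(b) else -np.inf
    num = np.expm1(ls_b - ls_x)      # (sf(b) - sf(x)) / sf(x), in (-1, 0]
    den = np.expm1(ls_b - ls_a)
    return float(np.exp(ls_x - ls_a) * num / den)


def truncated_gaussian_sf(x: float, mu: float, sigma: float,
                          a: float, b: float) -> float:
    """P(Z > x | a < Z < b) for Z ~ Normal(mu, sigma^2), stable in the tails.

    ``x`` outside (a, b) clamps to 1 (below a) or 0 (above b) with a warning.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not a < b:
        raise ValueError(f"need a < b, got a={a}, b={b}")
    al, be, xi = (a - mu) / sigma, (b - mu) / sigma, (x - mu) / sigma
    if xi <= al:
        warnings.warn("x at or below the lower truncation bound; sf = 1")
        return 1.0
    if xi >= be:
        warnings.warn("x at or above the upper truncation bound; sf = 0")
        return 0.0
    if al >= 0:
        return _right_tail_ratio(xi, al, be)
    if be <= 0:
        return 1.0 - _right_tail_ratio(-xi, -be, -al)
    # truncation interval straddles the mean: denominator is O(1)
    den = np.exp(log_ndtr(be)) - np.exp(log_ndtr(al))
    if xi >= 0:
        num = np.exp(log_ndtr(-xi)) - (np.exp(log_ndtr(-be))
                                       if np.isfinite(be) else 0.0)
    else:
        num = den - (np.exp(log_ndtr(xi)) - np.exp(log_ndtr(al)))
    return float(min(max(num / den, 0.0), 1.0))


def _truncated_cdf(x: float, mu: float, sigma: float, a: float, b: float) -> float:
    return 1.0 - truncated_gaussian_sf(x, mu, sigma, a, b)


# ---------------------------------------------------------------------------
# Polyhedral inference


@dataclass
class SelectiveSummary:
    indices: np.ndarray                       # active column indices
    lasso_coef: np.ndarray                    # penalized estimates (orig scale)
    observed: np.ndarray                      # eta' y per active feature
    estimate: np.ndarray                      # median-unbiased selective estimate
    p_value: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    v_minus: np.ndarray
    v_plus: np.ndarray
    sigma: float
    alpha: float
    names: list[str] | None = None

    def __len__(self) -> int:
        return len(self.indices)


def _selection_polyhedron(Xs, fit, n):
    """Rows (A, b) of the selection event {A y <= b} for conditioning on
    {active set, signs} at the fitted penalty."""
    E, s = fit.active_set, fit.signs.astype(float)
    lam_eff = n * fit.lam
    XE = Xs[:, E]
    M = np.linalg.pinv(XE.T @ XE)
    eta_rows = M @ XE.T                       # (k, n); rows are the contrasts
    A_parts = [-(s[:, None] * eta_rows)]
    b_parts = [-lam_eff * s * (M @ s)]
    inactive = np.setdiff1d(np.arange(Xs.shape[1]), E)
    if inactive.size and lam_eff > 0:
        Xm = Xs[:, inactive]
        Q = (Xm.T - (Xm.T @ XE) @ eta_rows) / lam_eff
        u = Xm.T @ (XE @ (M @ s))
        A_parts += [Q, -Q]
        b_parts += [1.0 - u, 1.0 + u]
    return np.vstack(A_parts), np.concatenate(b_parts), eta_rows


def _invert_pivot(T, sd, vm, vp, target, bracket_sds=30.0, max_expand=60):
    """Solve pivot(mu) = P_mu(Z <= T | [vm, vp]) = target for mu by
    bisection; the pivot is monotone decreasing in mu.

    Brackets by geometric expansion. When the observed statistic sits
    within rounding distance of a truncation bound the pivot can saturate
    before crossing ``target``; the expansion then stops after
    ``max_expand`` doublings and the reached bound (an effectively
    unbounded endpoint) is returned."""
    step = bracket_sds * sd
    lo, hi = T - step, T + step
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(max_expand):
            if _truncated_cdf(T, lo, sd, vm, vp) >= target:
                break
            step *= 2.0
            lo -= step
        else:
            logger.warning("pivot inversion: lower bracket saturated")
            return lo
        step = bracket_sds * sd
        for _ in range(max_expand):
            if _truncated_cdf(T, hi, sd, vm, vp) <= target:
                break
            step *= 2.0
            hi += step
        else:
            logger.warning("pivot inversion: upper bracket saturated")
            return hi
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if _truncated_cdf(T, mid, sd, vm, vp) >= target:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-10 * sd:
                break
    return 0.5 * (lo + hi)


def polyhedral_inference(
    X: np.ndarray,
    y: np.ndarray,
    fit: LassoFit,
    sigma: float,
    alpha: float = 0.05,
    names: list[str] | None = None,
) -> SelectiveSummary:
    """Exact post-selection p-values and CIs for the lasso-selected features.

    For each active feature with least-squares contrast ``eta`` (row of the
    active-set pseudo-inverse on standardized columns), the truncation bounds
    ``V-(y) < eta'y < V+(y)`` are computed from the selection polyhedron; the
    p-value is the truncated-Gaussian tail in the direction of the selected
    sign under ``H0: eta'mu = 0``, and the CI inverts the pivot at ``alpha``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    E = fit.active_set
    if E.size == 0:
        z = np.zeros(0)
        return SelectiveSummary(E, z, z, z, z, z, z, z, z, sigma, alpha,
                                names=[])
    n = X.shape[0]
    Xs = fit.standardized(X)
    yc = y - fit.y_mean
    A, b, eta_rows = _selection_polyhedron(Xs, fit, n)

    slack = b - A @ yc
    if slack.min() < -1e-6 * max(1.0, np.abs(b).max()):
        logger.warning(
            "observed y violates the selection polyhedron by %g "
            "(loose lasso convergence?)", -slack.min())

    k = E.size
    out = {key: np.empty(k) for key in
           ("observed", "estimate", "p_value", "ci_lower", "ci_upper",
            "v_minus", "v_plus")}
    for j in range(k):
        eta = eta_rows[j]
        s2 = float(eta @ eta)
        c = eta / s2
        T = float(eta @ yc)
        z = yc - c * T
        rho = A @ c
        num = b - A @ z
        neg, pos = rho < -1e-14, rho > 1e-14
        vm = np.max(num[neg] / rho[neg]) if neg.any() else -np.inf
        vp = np.min(num[pos] / rho[pos]) if pos.any() else np.inf
        if not vm < vp:
            raise ValueError(
                f"degenerate truncation interval for feature {E[j]}: "
                f"V-={vm:.6g} >= V+={vp:.6g}")
        T = float(np.clip(T, vm + 1e-12 * sigma, vp - 1e-12 * sigma))
        sd = sigma * np.sqrt(s2)
        if fit.signs[j] > 0:
            p = truncated_gaussian_sf(T, 0.0, sd, vm, vp)
        else:
            p = _truncated_cdf(T, 0.0, sd, vm, vp)
        out["observed"][j] = T
        out["v_minus"][j], out["v_plus"][j] = vm, vp
        out["p_value"][j] = p
        out["ci_lower"][j] = _invert_pivot(T, sd, vm, vp, 1.0 - alpha / 2.0)
        out["ci_upper"][j] = _invert_pivot(T, sd, vm, vp, alpha / 2.0)
        out["estimate"][j] = _invert_pivot(T, sd, vm, vp, 0.5)
    return SelectiveSummary(
        indices=E,
        lasso_coef=fit.coef[E],
        observed=out["observed"],
        estimate=out["estimate"],
        p_value=out["p_value"],
        ci_lower=out["ci_lower"],
        ci_upper=out["ci_upper"],
        v_minus=out["v_minus"],
        v_plus=out["v_plus"],
        sigma=float(sigma),
        alpha=float(alpha),
        names=[names[i] for i in E] if names is not None else None,
    )
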