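"""L1-penalized logistic regression and repeated characteristic selection.

The model is the ordinary logistic regression of malignancy on the
dummy-coded characteristics, fitted by maximizing the penalized average
log-likelihood

    (1/n) sum_i [ y_i eta_i - log(1 + exp(eta_i)) ]  -  lambda * sum_j |beta_j|

with eta_i = beta_0 + x_i' beta and an unpenalized intercept.  Covariates
are standardized to unit variance internally (the penalty acts on the
standardized scale, the convention of the reference R implementation) and
coefficients are mapped back to the original scale on return.

The solver is a proximal-Newton coordinate descent: an outer
iteratively-reweighted least-squares (IRLS) loop builds a local quadratic
model, an inner cyclic coordinate-descent loop with soft-thresholding solves
it, and an active-set strategy confines most sweeps to the nonzero
coefficients.  Solutions are certified against the subgradient (KKT)
optimality conditions.

Characteristic selection follows the study design: split the cohort 60/20/20
stratified by outcome, run 10-fold cross-validation over a descending
lambda grid on the training split, refit at lambda.1se (the largest lambda
within one standard error of the minimum cross-validated deviance), call a
characteristic active when any of its columns has a nonzero coefficient,
repeat over many random splits, and retain the characteristics selected in
at least half the repetitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort import CharacteristicSpec, Cohort, DesignMatrix, encode_design, stratified_split

__all__ = [
    "PenalizedLRFit",
    "LambdaPath",
    "SelectionSummary",
    "fit_penalized_lr",
    "lambda_path",
    "select_active",
    "repeated_selection",
    "kkt_residuals",
]

ZERO_THRESHOLD = 1e-10
_P_CLIP = 1e-9


@dataclass
class PenalizedLRFit:
    """A solution of the penalized likelihood problem at one lambda."""

    beta0: float
    beta: np.ndarray  # original (unstandardized) scale
    lam: float
    objective: float  # penalized mean log-likelihood at the solution
    converged: bool
    n_iter: int
    columns: list[str] = field(default_factory=list)
    beta_std: np.ndarray | None = None  # standardized scale, for KKT checks


@dataclass
class LambdaPath:
    lambdas: np.ndarray  # strictly decreasing
    cv_mean: np.ndarray  # mean held-out binomial deviance per lambda
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float


@dataclass
class SelectionSummary:
    frequency: dict[str, float]
    retained: list[str]
    repetitions: int
    failures: int = 0
    per_repetition: list[dict] = field(default_factory=list)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns stay (harmlessly) zero
    return (X - mean) / sd, mean, sd


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # mean log-likelihood, computed stably
    return float(np.mean(y * eta - np.logaddexp(0.0, eta)))


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_solve(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta0: float,
    beta: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[float, np.ndarray, bool, int]:
    """Proximal-Newton coordinate descent on standardized X (in place on beta)."""
    n, m = X.shape
    X = np.asfortranarray(X)  # column slices as views
    cols = [X[:, j] for j in range(m)]
    eta = beta0 + X @ beta
    for it in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-8, None)
        z = eta + (y - p) / w
        r = z - eta  # working residual
        wsum = w.sum()
        v = (w @ (X * X)) / n  # per-column curvature, fixed within the IRLS step

        def sweep(idx) -> float:
            nonlocal beta0, r
            max_delta = 0.0
            d0 = float(w @ r) / wsum
            if d0 != 0.0:
                beta0 += d0
                r -= d0
                max_delta = abs(d0)
            for j in idx:
                xj = cols[j]
                gj = float(w @ (xj * r)) / n + v[j] * beta[j]
                bj = _soft(gj, lam) / v[j]
                d = bj - beta[j]
                if d != 0.0:
                    beta[j] = bj
                    r -= d * xj
                    max_delta = max(max_delta, abs(d))
            return max_delta

        # full sweep, converge on the active set, re-check with a full sweep
        sweep(range(m))
        for _ in range(1000):
            active = np.flatnonzero(beta)
            while sweep(active) >= tol / 10:
                pass
            if sweep(range(m)) < tol / 10:
                break
        eta_new = z - r
        change = np.max(np.abs(eta_new - eta)) if n else 0.0
        eta = eta_new
        if change < tol:
            return beta0, beta, True, it
    return beta0, beta, False, max_iter


def kkt_residuals(
    Xs: np.ndarray, y: np.ndarray, beta0: float, beta_std: np.ndarray, lam: float
) -> np.ndarray:
    """Subgradient optimality residuals on the standardized scale.

    For beta_j = 0 the residual is max(|g_j| - lam, 0); otherwise it is
    |g_j - lam * sign(beta_j)|, with g the gradient of the mean log-likelihood.
    """
    n = len(y)
    eta = beta0 + Xs @ beta_std
    p = 1.0 / (1.0 + np.exp(-eta))
    g = Xs.T @ (y - p) / n
    res = np.empty_like(g)
    zero = np.abs(beta_std) <= ZERO_THRESHOLD
    res[zero] = np.maximum(np.abs(g[zero]) - lam, 0.0)
    res[~zero] = np.abs(g[~zero] - lam * np.sign(beta_std[~zero]))
    return res


def fit_penalized_lr(
    design: DesignMatrix,
    lam: float,
    tol: float = 1e-9,
    max_iter: int = 200,
    warm: tuple[float, np.ndarray] | None = None,
) -> PenalizedLRFit:
    """Fit the L1-penalized logistic model at penalty *lam* (>= 0).

    Non-convergence within *max_iter* IRLS iterations is flagged via
    ``converged`` and a warning, never silently ignored.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    y = np.asarray(design.y, dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    Xs, mean, sd = _standardize(np.asarray(design.values, dtype=float))
    pbar = y.mean()
    if warm is not None:
        beta0, beta = warm[0], warm[1].copy()
    else:
        beta0, beta = float(np.log(pbar / (1 - pbar))), np.zeros(design.m)
    beta0, beta, converged, n_iter = _cd_solve(Xs, y, lam, beta0, beta, tol, max_iter)
    if not converged:
        warnings.warn(f"penalized LR did not converge in {max_iter} IRLS iterations (lam={lam})")
    eta = beta0 + Xs @ beta
    objective = _loglik(y, eta) - lam * float(np.abs(beta).sum())
    beta_orig = beta / sd
    beta0_orig = beta0 - float(mean @ beta_orig)
    return PenalizedLRFit(
        beta0=beta0_orig,
        beta=beta_orig,
        lam=lam,
        objective=objective,
        converged=converged,
        n_iter=n_iter,
        columns=list(design.columns),
        beta_std=beta,
    )


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, n_lambda: int, ratio: float) -> np.ndarray:
    n = len(y)
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean())))) / n
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def _path_coefs(
    Xs: np.ndarray, y: np.ndarray, lambdas: np.ndarray, tol: float = 1e-7, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started solutions along a descending lambda grid (standardized
    scale); returns (intercepts, coefficient matrix)."""
    m = Xs.shape[1]
    pbar = y.mean()
    beta0 = float(np.log(pbar / (1 - pbar)))
    beta = np.zeros(m)
    b0s = np.empty(len(lambdas))
    betas = np.empty((len(lambdas), m))
    for k, lam in enumerate(lambdas):
        beta0, beta, _, _ = _cd_solve(Xs, y, float(lam), beta0, beta, tol, max_iter)
        b0s[k] = beta0
        betas[k] = beta
    return b0s, betas


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lambda_path(
    design: DesignMatrix,
    folds: int = 10,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    seed: int = 0,
) -> LambdaPath:
    """Cross-validated lambda grid with the lambda.min / lambda.1se rule.

    The grid is log-spaced over [ratio * lambda_max, lambda_max] with
    lambda_max the smallest penalty shrinking every slope to zero; folds are
    stratified by outcome and the held-out criterion is the mean binomial
    deviance.
    """
    y = np.asarray(design.y, dtype=float)
    if design.n < folds:
        raise ValueError("need at least as many records as folds")
    Xs, _, _ = _standardize(np.asarray(design.values, dtype=float))
    lambdas = _lambda_grid(Xs, y, n_lambda, lambda_min_ratio)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.empty((folds, len(lambdas)))
    for f, (tr, te) in enumerate(skf.split(Xs, y)):
        ytr = y[tr]
        if ytr.min() == ytr.max() or y[te].size == 0:
            raise ValueError(f"degenerate cross-validation fold {f}")
        # held-out columns standardized with the training fold's moments
        Xtr, mean, sd = _standardize(design.values[tr])
        Xte = (design.values[te] - mean) / sd
        b0s, betas = _path_coefs(Xtr, ytr, lambdas)
        etas = b0s[None, :] + Xte @ betas.T
        p = 1.0 / (1.0 + np.exp(-etas))
        pc = np.clip(p, _P_CLIP, 1 - _P_CLIP)
        yte = y[te][:, None]
        dev[f] = -2.0 * np.mean(yte * np.log(pc) + (1 - yte) * np.log(1 - pc), axis=0)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    k_min = int(np.argmin(cv_mean))
    lambda_min = float(lambdas[k_min])
    within = cv_mean <= cv_mean[k_min] + cv_se[k_min]
    lambda_1se = float(lambdas[np.flatnonzero(within)[0]])  # grid is descending
    return LambdaPath(lambdas, cv_mean, cv_se, lambda_min, lambda_1se)


def select_active(fit: PenalizedLRFit, schema: list[CharacteristicSpec]) -> list[str]:
    """Characteristics with any nonzero coefficient (grouped over the level
    indicators of a categorical characteristic)."""
    if not fit.converged:
        raise ValueError("cannot select from an unconverged fit")
    nonzero_cols = {
        col for col, b in zip(fit.columns, fit.beta) if abs(b) > ZERO_THRESHOLD
    }
    selected = []
    for spec in schema:
        if spec.kind == "categorical":
            cols = {f"{spec.name}={lv}" for lv in spec.non_reference_levels}
            if cols & nonzero_cols:
                selected.append(spec.name)
        elif spec.name in nonzero_cols:
            selected.append(spec.name)
    return selected


def repeated_selection(
    cohort: Cohort,
    R: int = 100,
    retention_threshold: float = 0.5,
    seed: int = 0,
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    folds: int = 10,
    n_lambda: int = 100,
) -> SelectionSummary:
    """Selection frequency of each characteristic over *R* random splits.

    Each repetition draws a fresh stratified 60/20/20 split, cross-validates
    the penalty on the training split, refits at lambda.1se and records the
    active characteristics.  A characteristic is retained when selected in at
    least ``retention_threshold`` of the repetitions.  Failed repetitions are
    skipped with a warning; more than 10% failures abort the run.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(R, 2))
    names = [s.name for s in cohort.schema]
    counts = dict.fromkeys(names, 0)
    per_rep: list[dict] = []
    failures = 0
    for r in range(R):
        try:
            labels = stratified_split(cohort, proportions, seed=int(rep_seeds[r, 0]))
            train = cohort.subset(labels == "train")
            design = encode_design(train)
            path = lambda_path(
                design, folds=folds, n_lambda=n_lambda, seed=int(rep_seeds[r, 1])
            )
            fit = fit_penalized_lr(design, path.lambda_1se)
            active = select_active(fit, cohort.schema)
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures += 1
            warnings.warn(f"selection repetition {r} failed: {exc}")
            continue
        for name in active:
            counts[name] += 1
        per_rep.append({"repetition": r, "lambda_1se": path.lambda_1se, "selected": active})
    if failures > 0.1 * R:
        raise RuntimeError(f"{failures}/{R} selection repetitions failed")
    effective = R - failures
    freq = {name: counts[name] / effective for name in names}
    retained = [name for name in names if freq[name] >= retention_threshold]
    return SelectionSummary(
        frequency=freq,
        retained=retained,
        repetitions=effective,
        failures=failures,
        per_repetition=per_rep,
    )
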