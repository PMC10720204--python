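"""Multi-metabolite signature derivation by cross-validated elastic net.

The signature for an olive-oil exposure is built in three stages:

1. *Tuning* (:func:`tune_enr`): the mixing parameter alpha is scanned from 0
   (ridge) to 1 (lasso) in 0.1 steps; for each alpha a tenfold
   cross-validation curve over a geometric lambda path yields the
   minimum-MSE lambda and the more conservative within-one-SD lambda.
2. *Derivation* (:func:`derive_signature`): ten reseeded tenfold-CV elastic
   nets are run on the whole discovery sample, each refit at its own
   lambda.min; metabolites with a nonzero coefficient in all ten iterations
   form the *consistency-selected* set, and their mean coefficient across
   iterations is the signature weight.  In parallel the sample is
   partitioned into 10 disjoint 90/10 train/validation splits: each
   training split is refit at the stage-1 tuned lambda and its held-out 10%
   is scored with the coefficients restricted to the consistency set (the
   multi-metabolite model), giving honest out-of-split predictions.
3. *Validation* (:func:`validate_signature`): the Pearson correlation
   between the metabolite score and FFQ-derived intake, with a Fisher-z 95%
   confidence interval — pooled out-of-split multi-metabolite scores in the
   discovery sample, the averaged final model on external (e.g. 1-year)
   data.

Elastic-net solutions are delegated to scikit-learn's coordinate descent
(closed-form ridge for alpha = 0) and certified post hoc by the
Karush-Kuhn-Tucker residual (:func:`kkt_residual`), which is an
optimality check independent of the solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

__all__ = [
    "solve_elastic_net",
    "kkt_residual",
    "lambda_path",
    "tune_enr",
    "derive_signature",
    "apply_signature",
    "validate_signature",
    "fisher_ci",
    "TuningResult",
    "SignatureModel",
    "CorrelationResult",
    "PAPER_ALPHAS",
]

#: tuned mixing parameters reported for the three exposures (config presets)
PAPER_ALPHAS = {"total_oo": 0.4, "voo": 0.2, "coo": 0.3}

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Exact ridge solution of (1/2n)||y - Xb||^2 + (lam/2)||b||^2."""
    n, p = X.shape
    A = X.T @ X / n + lam * np.eye(p)
    return np.linalg.solve(A, X.T @ y / n)


def solve_elastic_net(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float,
    tol: float = 1e-10, max_iter: int = 100_000,
) -> np.ndarray:
    """Minimize (1/2n)||y - Xb||^2 + lam * (alpha ||b||_1 + (1-alpha)/2 ||b||_2^2).

    ``X`` is expected column-standardized and ``y`` centered.  ``alpha`` is
    the L1/L2 mixing parameter (0 = ridge, 1 = lasso); ``lam`` the penalty
    strength.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if lam == 0 or alpha == 0:
        if lam == 0:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return beta
        return _ridge_solve(X, y, lam)
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                       tol=tol, max_iter=max_iter)
    model.fit(X, y)
    return model.coef_.copy()


def kkt_residual(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                 alpha: float, lam: float) -> float:
    """Max violation of the elastic-net subgradient optimality conditions.

    For the objective of :func:`solve_elastic_net` the stationarity condition
    reads g_j = lam * alpha * sign(b_j) when b_j != 0 and |g_j| <= lam*alpha
    when b_j = 0, with g = X'(y - Xb)/n - lam*(1-alpha)*b.
    """
    n = X.shape[0]
    g = X.T @ (y - X @ beta) / n - lam * (1 - alpha) * beta
    nz = beta != 0
    viol_nz = np.abs(g[nz] - lam * alpha * np.sign(beta[nz]))
    viol_z = np.maximum(np.abs(g[~nz]) - lam * alpha, 0.0)
    return float(max(viol_nz.max(initial=0.0), viol_z.max(initial=0.0)))


def lambda_path(X: np.ndarray, y: np.ndarray, alpha: float,
                n_lambdas: int = 50, eps: float = 1e-3) -> np.ndarray:
    """Geometric lambda path from the all-zero threshold down to eps of it.

    For alpha > 0 the smallest lambda with an all-zero solution is
    max_j |X_j'y| / (n alpha); for alpha near 0 the threshold is computed at
    a floor of 0.001 so a ridge path remains finite.
    """
    n = X.shape[0]
    lam_max = np.abs(X.T @ y).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


@dataclass
class TuningResult:
    """Cross-validation surface over (alpha, lambda) and the chosen values."""

    alpha_grid: list[float]
    lambdas: dict[float, np.ndarray]
    cv_mean: dict[float, np.ndarray]
    cv_sd: dict[float, np.ndarray]  # SD of held-out MSE across folds
    cv_se: dict[float, np.ndarray]  # SD / sqrt(k): SE of the CV mean
    alpha_best: float
    lambda_min: float
    lambda_1se: float

    def lambda_for(self, rule: str) -> float:
        if rule in ("min", "lambda.min"):
            return self.lambda_min
        if rule in ("1se", "within_1sd", "lambda.1se"):
            return self.lambda_1se
        raise ValueError(f"unknown lambda rule: {rule!r}")


def _cv_mse_path(X, y, alpha, lambdas, folds, tol=1e-4):
    """Held-out MSE for each lambda, per fold (rows = folds)."""
    out = np.empty((len(folds), len(lambdas)))
    for i, (tr, va) in enumerate(folds):
        Xtr, ytr = X[tr], y[tr]
        mu, sd = Xtr.mean(0), Xtr.std(0)
        sd[sd == 0] = 1.0
        Xs = (Xtr - mu) / sd
        yc = ytr - ytr.mean()
        Xv = (X[va] - mu) / sd
        if alpha == 0:
            U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
            uy = U.T @ yc
            n_tr = len(tr)
            for k, lam in enumerate(lambdas):
                coef = Vt.T @ ((s / n_tr) * uy / (s**2 / n_tr + lam))
                pred = Xv @ coef + ytr.mean()
                out[i, k] = np.mean((y[va] - pred) ** 2)
        else:
            _, coefs, _ = enet_path(Xs, yc, l1_ratio=alpha,
                                    alphas=np.asarray(lambdas), tol=tol)
            preds = Xv @ coefs + ytr.mean()
            out[i] = np.mean((y[va][:, None] - preds) ** 2, axis=0)
    return out


def tune_enr(
    X: np.ndarray | pd.DataFrame, y: np.ndarray,
    alpha_grid=DEFAULT_ALPHA_GRID, k_folds: int = 10, seed: int = 0,
    n_lambdas: int = 50, eps: float = 1e-3,
) -> TuningResult:
    """Scan alpha (and lambda per alpha) by k-fold cross-validation.

    Folds are fixed across the alpha grid so the CV surfaces are comparable.
    Returns both the minimum-MSE lambda and the largest lambda whose mean CV
    MSE stays within one standard error of the minimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k_folds:
        raise ValueError("need at least k_folds observations")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    if any(len(va) == 0 for _, va in folds):
        raise ValueError("degenerate (empty) folds")
    mu, sd = X.mean(0), X.std(0)
    sd[sd == 0] = 1.0
    Xs_full = (X - mu) / sd
    yc_full = y - y.mean()

    lambdas, cv_mean, cv_sd, cv_se = {}, {}, {}, {}
    best = (np.inf, None, None)
    for alpha in alpha_grid:
        alpha = float(alpha)
        lams = lambda_path(Xs_full, yc_full, alpha, n_lambdas=n_lambdas, eps=eps)
        fold_mse = _cv_mse_path(X, y, alpha, lams, folds)
        m = fold_mse.mean(0)
        s = fold_mse.std(0, ddof=1)
        lambdas[alpha], cv_mean[alpha], cv_sd[alpha] = lams, m, s
        cv_se[alpha] = s / np.sqrt(len(folds))
        k = int(np.argmin(m))
        if m[k] < best[0]:
            best = (m[k], alpha, k)
    _, alpha_best, k_min = best
    m = cv_mean[alpha_best]
    se = cv_se[alpha_best]
    lams = lambdas[alpha_best]
    lambda_min = float(lams[k_min])
    within = m <= m[k_min] + se[k_min]
    lambda_1se = float(lams[within].max())
    return TuningResult(
        alpha_grid=[float(a) for a in alpha_grid],
        lambdas=lambdas, cv_mean=cv_mean, cv_sd=cv_sd, cv_se=cv_se,
        alpha_best=float(alpha_best), lambda_min=lambda_min, lambda_1se=lambda_1se,
    )


@dataclass
class SignatureModel:
    """A derived multi-metabolite signature for one exposure.

    ``split_coefficients`` holds the ten whole-sample CV-iteration
    coefficient vectors on the standardized-metabolite scale;
    ``selection_count`` counts nonzero appearances across them.
    """

    exposure: str
    alpha: float
    metabolites: list[str]
    split_coefficients: np.ndarray  # n_splits x p, standardized scale
    split_lambdas: list[float]
    selection_count: np.ndarray  # per metabolite, 0..n_splits
    selected: list[str]  # consistency set: nonzero in every iteration
    mean_coef: dict[str, float]  # mean across iterations, selected metabolites
    sd_coef: dict[str, float]
    center: dict[str, float]  # full-sample standardization parameters
    scale: dict[str, float]
    intercept: float
    n_splits: int
    seed: int
    lambda_rule: str
    oof_prediction: np.ndarray = field(repr=False, default=None)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "exposure": self.exposure,
            "alpha": self.alpha,
            "metabolites": self.metabolites,
            "split_coefficients": self.split_coefficients.tolist(),
            "split_lambdas": self.split_lambdas,
            "selection_count": self.selection_count.tolist(),
            "selected": self.selected,
            "mean_coef": self.mean_coef,
            "sd_coef": self.sd_coef,
            "center": self.center,
            "scale": self.scale,
            "intercept": self.intercept,
            "n_splits": self.n_splits,
            "seed": self.seed,
            "lambda_rule": self.lambda_rule,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SignatureModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            exposure=d["exposure"], alpha=d["alpha"], metabolites=d["metabolites"],
            split_coefficients=np.asarray(d["split_coefficients"]),
            split_lambdas=d["split_lambdas"],
            selection_count=np.asarray(d["selection_count"]),
            selected=d["selected"], mean_coef=d["mean_coef"], sd_coef=d["sd_coef"],
            center=d["center"], scale=d["scale"], intercept=d["intercept"],
            n_splits=d["n_splits"], seed=d["seed"], lambda_rule=d["lambda_rule"],
        )


def _pick_lambda(lams: np.ndarray, fold_mse: np.ndarray, rule: str) -> float:
    m = fold_mse.mean(0)
    se = fold_mse.std(0, ddof=1) / np.sqrt(fold_mse.shape[0])
    k_min = int(np.argmin(m))
    if rule in ("min", "lambda.min"):
        return float(lams[k_min])
    if rule in ("1se", "within_1sd", "lambda.1se"):
        return float(lams[m <= m[k_min] + se[k_min]].max())
    raise ValueError(f"unknown lambda rule: {rule!r}")


def derive_signature(
    X: pd.DataFrame, y: np.ndarray, alpha: float,
    n_splits: int = 10, seed: int = 0, lambda_rule: str = "min",
    cv_folds: int = 10, n_lambdas: int = 50, eps: float = 1e-3,
    exposure: str = "exposure", cv_tol: float = 1e-4, final_tol: float = 1e-9,
) -> SignatureModel:
    """Derive a consistency-selected signature and out-of-split scores.

    Stage 1 tunes lambda once by ``cv_folds``-fold CV on the whole sample
    (rule ``lambda_rule``: "min" or "within_1sd").  Stage 2 runs
    ``n_splits`` reseeded tenfold-CV elastic nets on the whole sample, each
    refit at its own CV-chosen lambda; nonzero-in-all-iterations metabolites
    form the consistency set and their mean coefficients the signature
    weights.  Stage 3 partitions the sample into ``n_splits`` disjoint
    90/10 train/validation splits, refits each training part at the stage-1
    lambda, and scores the held-out 10% with the coefficients restricted to
    the consistency set — the pooled out-of-split multi-metabolite score
    used for the discovery validation correlation.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{j}" for j in range(np.asarray(X).shape[1])])
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n < n_splits * 2:
        raise ValueError("sample too small for 90/10 splitting")
    mu_full, sd_full = Xv.mean(0), Xv.std(0)
    sd_full[sd_full == 0] = 1.0
    Xs_full = (Xv - mu_full) / sd_full
    yc_full = y - y.mean()
    lams = lambda_path(Xs_full, yc_full, alpha, n_lambdas=n_lambdas, eps=eps)

    # stage 1: tune lambda once on the whole sample
    folds0 = list(KFold(n_splits=cv_folds, shuffle=True,
                        random_state=seed + 7).split(Xv))
    lam0 = _pick_lambda(lams, _cv_mse_path(Xv, y, alpha, lams, folds0, tol=cv_tol),
                        lambda_rule)

    # stage 2: reseeded whole-sample CV iterations -> reported coefficients
    coefs = np.zeros((n_splits, p))
    lams_used: list[float] = []
    for it in range(n_splits):
        f = list(KFold(n_splits=cv_folds, shuffle=True,
                       random_state=seed * 100 + it).split(Xv))
        lam_it = _pick_lambda(lams, _cv_mse_path(Xv, y, alpha, lams, f, tol=cv_tol),
                              lambda_rule)
        coefs[it] = solve_elastic_net(Xs_full, yc_full, alpha, lam_it, tol=final_tol)
        lams_used.append(lam_it)
    count = (coefs != 0).sum(0)
    sel_idx = np.flatnonzero(count == n_splits)
    selected = [X.columns[j] for j in sel_idx]

    # stage 3: disjoint 90/10 splits -> out-of-split multi-metabolite scores
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    oof = np.empty(n)
    for tr, va in kf.split(Xv):
        Xtr, ytr = Xv[tr], y[tr]
        mu, sd = Xtr.mean(0), Xtr.std(0)
        sd[sd == 0] = 1.0
        beta = solve_elastic_net((Xtr - mu) / sd, ytr - ytr.mean(), alpha, lam0,
                                 tol=final_tol)
        restricted = np.zeros(p)
        restricted[sel_idx] = beta[sel_idx]
        oof[va] = (Xv[va] - mu) / sd @ restricted + ytr.mean()

    mean_coef = {m: float(coefs[:, j].mean()) for m, j in zip(selected, sel_idx)}
    sd_coef = {m: float(coefs[:, j].std(ddof=1)) for m, j in zip(selected, sel_idx)}
    return SignatureModel(
        exposure=exposure, alpha=float(alpha), metabolites=list(X.columns),
        split_coefficients=coefs, split_lambdas=lams_used,
        selection_count=count, selected=selected,
        mean_coef=mean_coef, sd_coef=sd_coef,
        center={m: float(mu_full[j]) for m, j in zip(selected, sel_idx)},
        scale={m: float(sd_full[j]) for m, j in zip(selected, sel_idx)},
        intercept=float(y.mean()), n_splits=n_splits, seed=seed,
        lambda_rule=lambda_rule, oof_prediction=oof,
    )


def apply_signature(model: SignatureModel, X_new: pd.DataFrame) -> np.ndarray:
    """Score new samples: sum of mean coefficients times standardized columns.

    Columns are aligned by metabolite name using the model's stored training
    standardization; metabolites outside the selected set are ignored.
    """
    missing = [m for m in model.selected if m not in X_new.columns]
    if missing:
        raise ValueError(f"missing selected metabolite columns: {missing}")
    if not model.selected:
        return np.zeros(len(X_new))
    Z = np.column_stack([
        (X_new[m].to_numpy(dtype=float) - model.center[m]) / model.scale[m]
        for m in model.selected
    ])
    w = np.array([model.mean_coef[m] for m in model.selected])
    return Z @ w


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if abs(r) >= 1:
        return (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    label: str


def validate_signature(
    model: SignatureModel, y_intake: np.ndarray,
    X: pd.DataFrame | None = None, mode: str = "discovery",
    label: str | None = None,
) -> CorrelationResult:
    """Pearson correlation between the metabolite score and reported intake.

    ``mode="discovery"`` correlates the pooled out-of-split predictions with
    intake in the derivation sample; ``mode="external"`` applies the averaged
    final model to ``X`` (e.g. the 1-year visit).
    """
    y = np.asarray(y_intake, dtype=float)
    if mode == "discovery":
        if model.oof_prediction is None:
            raise ValueError("model carries no out-of-split predictions")
        score = model.oof_prediction
        label = label or "discovery-baseline"
    elif mode == "external":
        if X is None:
            raise ValueError("external mode requires a metabolite matrix")
        score = apply_signature(model, X)
        label = label or "validation-year1"
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if len(score) != len(y):
        raise ValueError("score and intake are misaligned")
    if len(y) < 4:
        raise ValueError("need n >= 4")
    if np.std(score) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(score, y)[0, 1])
    lo, hi = fisher_ci(r, len(y))
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, n=len(y), label=label)
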