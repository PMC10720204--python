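"""Case-cohort Cox regression with Barlow weights and robust variance.

A nested case-cohort sample (a random subcohort plus all incident cases) is
analyzed with the classical Barlow weighting: subcohort non-cases carry
weight 1/f (f = subcohort sampling fraction) for their whole follow-up,
cases outside the subcohort enter the risk set just before their own failure
with weight 1, and subcohort cases are time-split — weight 1/f up to just
before failure, weight 1 at failure.  The weighted partial likelihood is
maximized with stratum-specific baseline hazards (intervention group x
recruitment center) and a robust sandwich variance clustered on participant,
so the confidence intervals account for both the weighting and the
time-split duplication.

Hazard ratios are reported per 1 SD of the metabolite score.  The weighted,
left-truncated, stratified partial likelihood (Breslow tie handling) and the
clustered sandwich variance are implemented here directly by Newton
iteration — the score-residual aggregation matches the ``coxph(...,
weights, cluster(id))`` construction — since the combination of sampling
weights, delayed entry, and cluster-robust variance is exactly the corner
this design lives in.  The module also provides the Barlow design
construction, the nested model-1..4 covariate sequence, and interaction
likelihood-ratio tests on the weighted pseudo-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .screen import build_covariate_design
from .synthetic_cohort import CaseCohortDesign

__all__ = [
    "ModelSpec",
    "CoxResult",
    "barlow_weights",
    "fit_case_cohort_cox",
    "interaction_lr_test",
    "run_model_sequence",
    "default_model_specs",
]

_MODEL1 = ["age", "sex", "ps_1", "ps_2"]
_MODEL2_EXTRA = [
    "bmi", "smoking", "alcohol", "alcohol_sq", "education", "physical_activity",
    "family_history_cvd", "dyslipidemia", "hypertension",
    "dyslipidemia_med", "hypertension_med",
]
_MODEL3_EXTRA = [
    "vegetables", "fruits", "cereals", "nuts", "eggs", "legumes", "fish",
    "meat", "dairy",
]
DEFAULT_STRATA = ["intervention_group", "center"]


@dataclass
class ModelSpec:
    """One step of the nested covariate sequence (models 1-4)."""

    model_id: int
    covariates: list[str]
    strata: list[str] = field(default_factory=lambda: list(DEFAULT_STRATA))


def default_model_specs(exposure: str = "total_oo") -> list[ModelSpec]:
    """The nested model-1..4 covariate sets.

    Model 1: age, sex, propensity scores (stratified by intervention group
    and center).  Model 2: + BMI, smoking, alcohol (linear + quadratic),
    education, physical activity, family history of CVD, dyslipidemia and
    hypertension status and treatment.  Model 3: + food groups (g/day).
    Model 4: + the self-reported intake the signature was derived from.
    """
    m1 = list(_MODEL1)
    m2 = m1 + _MODEL2_EXTRA
    m3 = m2 + _MODEL3_EXTRA
    m4 = m3 + [f"intake_{exposure}" if not exposure.startswith("intake_") else exposure]
    return [
        ModelSpec(1, m1), ModelSpec(2, m2), ModelSpec(3, m3), ModelSpec(4, m4),
    ]


@dataclass
class CoxResult:
    hr_per_sd: float
    ci_low: float
    ci_high: float
    p: float
    n_cases: int
    n_total: int
    model_id: int
    outcome: str
    exposure: str = ""
    log_hr: float = float("nan")
    robust_se: float = float("nan")

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome, "exposure": self.exposure,
            "model": self.model_id, "hr_per_sd": self.hr_per_sd,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
            "cases": self.n_cases, "total": self.n_total,
        }


def barlow_weights(design: CaseCohortDesign, eps: float | None = None) -> pd.DataFrame:
    """Expand a case-cohort sample into weighted, possibly time-split rows.

    Returns a DataFrame with columns participant_id, entry, stop, event,
    weight.  With f = 1 there is nothing to re-weight and each participant
    contributes a single unweighted row.
    """
    f = design.sampling_fraction
    if f <= 0:
        raise ValueError("sampling fraction must be positive")
    d = design.data
    if eps is None:
        eps = 1e-8 * float(d["time"].max())
    rows = []
    if f == 1:
        out = d[["participant_id", "time", "event"]].copy()
        out.insert(1, "entry", 0.0)
        out = out.rename(columns={"time": "stop"})
        out["weight"] = 1.0
        return out.reset_index(drop=True)
    w_sub = 1.0 / f
    for pid, t, ev, sub in zip(d["participant_id"], d["time"],
                               d["event"].astype(bool), d["in_subcohort"]):
        if sub and not ev:
            rows.append((pid, 0.0, t, 0, w_sub))
        elif sub and ev:
            # time-split: subcohort weight before failure, own-case weight at failure
            if t > 2 * eps:
                rows.append((pid, 0.0, t - eps, 0, w_sub))
            rows.append((pid, max(t - eps, 0.0), t, 1, 1.0))
        else:  # case outside the subcohort: enters just before failure
            rows.append((pid, max(t - eps, 0.0), t, 1, 1.0))
    return pd.DataFrame(rows, columns=["participant_id", "entry", "stop", "event", "weight"])


class CoxConvergenceError(RuntimeError):
    """Newton iterations for the weighted partial likelihood failed."""


class WeightedCoxFit:
    """Weighted stratified Cox fit (Breslow ties, delayed entry).

    Attributes: ``params`` (pd.Series), ``naive_cov``, ``robust_cov``
    (cluster-aggregated sandwich), ``log_likelihood`` (weighted log partial
    likelihood at the optimum), ``n_events``.
    """

    def __init__(self, params, naive_cov, robust_cov, log_likelihood, n_events, names):
        self.params = pd.Series(params, index=names)
        self.naive_cov = pd.DataFrame(naive_cov, index=names, columns=names)
        self.robust_cov = pd.DataFrame(robust_cov, index=names, columns=names)
        self.log_likelihood = float(log_likelihood)
        self.n_events = int(n_events)

    def robust_se(self, name: str) -> float:
        return float(np.sqrt(self.robust_cov.loc[name, name]))

    def naive_se(self, name: str) -> float:
        return float(np.sqrt(self.naive_cov.loc[name, name]))


def _loglik_parts(beta, X, entry, stop, event, weight, strata_codes):
    """Weighted Breslow log partial likelihood, gradient, Hessian, and the
    per-row score residuals needed for the clustered sandwich."""
    n, p = X.shape
    eta = X @ beta
    # guard against overflow in exp for extreme steps
    eta = np.clip(eta, -200, 200)
    rexp = weight * np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    resid = np.zeros((n, p))
    for s in np.unique(strata_codes):
        in_s = strata_codes == s
        Xs, es, ts, ds, ws, rs = (X[in_s], entry[in_s], stop[in_s],
                                  event[in_s], weight[in_s], rexp[in_s])
        ev_times = np.unique(ts[ds == 1])
        res_s = np.zeros_like(Xs, dtype=float)
        for t in ev_times:
            at_risk = (es < t) & (ts >= t)
            fail = (ts == t) & (ds == 1)
            dw = ws[fail].sum()
            r_risk = rs[at_risk]
            S0 = r_risk.sum()
            S1 = r_risk @ Xs[at_risk]
            xbar = S1 / S0
            S2 = (r_risk[:, None] * Xs[at_risk]).T @ Xs[at_risk]
            ll += (ws[fail] * (Xs[fail] @ beta)).sum() - dw * np.log(S0)
            grad += ws[fail] @ Xs[fail] - dw * xbar
            hess -= dw * (S2 / S0 - np.outer(xbar, xbar))
            # expected-score part of the score residuals
            res_s[fail] -= ws[fail][:, None] * xbar
            res_s[at_risk] -= (dw / S0) * r_risk[:, None] * (Xs[at_risk] - xbar)
        idx = np.flatnonzero(in_s)
        resid[idx] = (event[in_s] * weight[in_s])[:, None] * Xs + res_s
    return ll, grad, hess, resid


def _fit_weighted_cox(
    frame: pd.DataFrame, covar_cols: list[str], strata: list[str],
    cluster_col: str = "participant_id", tol: float = 1e-9, max_iter: int = 50,
) -> WeightedCoxFit:
    X = frame[covar_cols].to_numpy(dtype=float)
    entry = frame["entry"].to_numpy(dtype=float)
    stop = frame["stop"].to_numpy(dtype=float)
    event = frame["event"].to_numpy(dtype=int)
    weight = frame["weight"].to_numpy(dtype=float)
    if strata:
        strata_codes = pd.factorize(
            pd.Series(list(zip(*(frame[s] for s in strata))))
        )[0]
    else:
        strata_codes = np.zeros(len(frame), dtype=int)
    n, p = X.shape
    beta = np.zeros(p)
    ll_prev = -np.inf
    for it in range(max_iter):
        ll, grad, hess, resid = _loglik_parts(beta, X, entry, stop, event,
                                              weight, strata_codes)
        if not np.isfinite(ll):
            raise CoxConvergenceError("partial likelihood diverged")
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise CoxConvergenceError(f"singular information matrix: {err}")
        # step-halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            ll_new = _loglik_parts(beta + scale * step, X, entry, stop, event,
                                   weight, strata_codes)[0]
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)) and it > 0:
            break
        ll_prev = ll
    else:
        raise CoxConvergenceError(
            f"no convergence in {max_iter} Newton iterations "
            f"(max |grad| = {np.max(np.abs(grad)):.3g})"
        )
    ll, grad, hess, resid = _loglik_parts(beta, X, entry, stop, event,
                                          weight, strata_codes)
    naive = np.linalg.inv(-hess)
    groups = pd.factorize(frame[cluster_col])[0]
    U = np.zeros((groups.max() + 1, p))
    np.add.at(U, groups, resid)
    robust = naive @ (U.T @ U) @ naive
    return WeightedCoxFit(beta, naive, robust, ll, event.sum(), covar_cols)


def _analysis_frame(design: CaseCohortDesign, score: np.ndarray | pd.Series,
                    spec: ModelSpec, covariates: pd.DataFrame | None) -> tuple[pd.DataFrame, list[str]]:
    d = design.data
    score = pd.Series(np.asarray(score, dtype=float).ravel(), index=d.index)
    if len(score) != len(d):
        raise ValueError("score must align with the case-cohort rows")
    sd = score.std(ddof=0)
    if sd == 0:
        raise ValueError("score has zero variance")
    z = (score - score.mean()) / sd

    rows = barlow_weights(design)
    base = pd.DataFrame({"participant_id": d["participant_id"].to_numpy(), "score": z.to_numpy()})
    if covariates is not None and (spec.covariates or spec.strata):
        cov = covariates[covariates["visit"] == "baseline"] if "visit" in covariates else covariates
        cov = cov.set_index("participant_id") if "participant_id" in cov else cov
        cov = cov.loc[base["participant_id"]]
        want = [c for c in spec.covariates if c != "alcohol_sq"]
        missing = [c for c in want + spec.strata if c not in cov.columns]
        if missing:
            raise ValueError(f"covariates missing from cohort table: {missing}")
        block = cov[want].reset_index(drop=True)
        if "alcohol_sq" in spec.covariates:
            block["alcohol_sq"] = block["alcohol"] ** 2
        expanded = build_covariate_design(block)
        for s in spec.strata:
            expanded[s] = cov[s].to_numpy()
        base = pd.concat([base, expanded], axis=1)
        covar_cols = [c for c in expanded.columns if c not in spec.strata]
    else:
        covar_cols = []
    frame = rows.merge(base, on="participant_id", how="left")
    return frame, covar_cols


def fit_case_cohort_cox(
    design: CaseCohortDesign,
    score: np.ndarray | pd.Series,
    spec: ModelSpec | None = None,
    covariates: pd.DataFrame | None = None,
    exposure: str = "",
) -> CoxResult:
    """Fit the Barlow-weighted Cox model for a 1-SD score increase.

    ``score`` must align row-for-row with ``design.data``; it is standardized
    internally so the hazard ratio is per 1 SD on the analysis sample.
    Strata with zero events are dropped with a warning.
    """
    spec = spec or ModelSpec(0, [], [])
    frame, covar_cols = _analysis_frame(design, score, spec, covariates)
    if frame["event"].sum() == 0:
        raise ValueError("no events in the case-cohort sample; cannot fit")
    if spec.strata:
        sizes = frame.groupby(spec.strata, observed=True)["event"].sum()
        empty = sizes[sizes == 0]
        if len(empty):
            warnings.warn(f"dropping {len(empty)} strata with zero events")
            frame = frame.set_index(spec.strata).drop(index=empty.index).reset_index()
    fit = _fit_weighted_cox(frame, ["score"] + covar_cols, spec.strata)
    beta = float(fit.params["score"])
    se = fit.robust_se("score")
    ci = (np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    n_cases = int(design.data["event"].sum())
    n_total = int(design.data["participant_id"].nunique())
    return CoxResult(
        hr_per_sd=float(np.exp(beta)), ci_low=float(ci[0]), ci_high=float(ci[1]),
        p=p, n_cases=n_cases, n_total=n_total,
        model_id=spec.model_id, outcome=design.outcome_name, exposure=exposure,
        log_hr=beta, robust_se=se,
    )


@dataclass
class LRTestResult:
    p: float
    statistic: float
    df: int
    wald_p: dict
    approximate: bool = True  # weighted partial likelihoods are pseudo-likelihoods


def interaction_lr_test(
    design: CaseCohortDesign,
    score: np.ndarray | pd.Series,
    spec: ModelSpec | None = None,
    covariates: pd.DataFrame | None = None,
    interaction_factor: str = "intervention_group",
) -> LRTestResult:
    """Likelihood-ratio test for score x factor product terms.

    Compares the weighted pseudo-log-likelihood of the model with and without
    the score-by-factor interaction columns; the statistic is referred to a
    chi-square with one degree of freedom per product term.  Flagged
    approximate: with Barlow weights this is not a true likelihood ratio, so
    robust Wald p-values per product term are reported alongside.
    """
    spec = spec or ModelSpec(0, [], list(DEFAULT_STRATA))
    if covariates is None:
        raise ValueError("covariate table required (carries the interaction factor)")
    frame, covar_cols = _analysis_frame(design, score, spec, covariates)
    cov = covariates[covariates["visit"] == "baseline"] if "visit" in covariates else covariates
    cov = cov.set_index("participant_id") if "participant_id" in cov else cov
    fac = cov.loc[frame["participant_id"], interaction_factor].astype(str).to_numpy()
    levels = sorted(pd.unique(fac))
    prod_cols = []
    for lv in levels[1:]:
        name = f"score_x_{interaction_factor}_{lv}"
        frame[name] = frame["score"] * (fac == lv)
        prod_cols.append(name)
    if not prod_cols or all(frame[c].abs().max() == 0 for c in prod_cols):
        return LRTestResult(p=1.0, statistic=0.0, df=max(len(prod_cols), 1),
                            wald_p={c: 1.0 for c in prod_cols})

    def _fit(with_products: bool) -> WeightedCoxFit:
        cols = ["score"] + covar_cols + (prod_cols if with_products else [])
        return _fit_weighted_cox(frame, cols, spec.strata)

    full = _fit(True)
    reduced = _fit(False)
    lr = max(2 * (full.log_likelihood - reduced.log_likelihood), 0.0)
    df = len(prod_cols)
    wald = {}
    for c in prod_cols:
        b, s = float(full.params[c]), full.robust_se(c)
        wald[c] = float(2 * stats.norm.sf(abs(b) / s)) if s > 0 else 1.0
    return LRTestResult(p=float(stats.chi2.sf(lr, df)), statistic=lr, df=df, wald_p=wald)


def _nested(specs: list[ModelSpec]) -> bool:
    for a, b in zip(specs, specs[1:]):
        if not set(a.covariates) <= set(b.covariates):
            return False
    return True


def run_model_sequence(
    design: CaseCohortDesign,
    score: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    exposure: str = "total_oo",
    extra_adjustments: list[str] | None = None,
    year1_mode: bool = False,
) -> pd.DataFrame:
    """Fit the nested model sequence; returns a results table (one row per model).

    ``year1_mode`` drops cases whose event occurred within the first year of
    follow-up, mirroring analyses that start from the 1-year visit.
    ``extra_adjustments`` (e.g. coffee and tea intake) are appended to every
    model as a sensitivity analysis.
    """
    specs = specs or default_model_specs(exposure)
    if not _nested(specs):
        raise ValueError("model specs must be nested")
    if year1_mode:
        d = design.data
        keep = ~((d["event"].astype(bool)) & (d["time"] <= 1.0))
        design = CaseCohortDesign(
            d.loc[keep].reset_index(drop=True),
            sampling_fraction=design.sampling_fraction,
            n_full=design.n_full, outcome_name=design.outcome_name,
        )
        score = np.asarray(score, dtype=float)[keep.to_numpy()]
    rows = []
    for spec in specs:
        s = spec
        if extra_adjustments:
            s = ModelSpec(spec.model_id, spec.covariates + list(extra_adjustments),
                          spec.strata)
        res = fit_case_cohort_cox(design, score, s, covariates, exposure=exposure)
        rows.append(res.to_row())
    return pd.DataFrame(rows)
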