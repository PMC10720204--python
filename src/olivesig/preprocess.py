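"""Participant and metabolite quality control and normalization.

The pipeline order mirrors the study design it emulates: metabolite-level QC
(internal standards, drugs, high missingness) precedes the participant-level
>=20%-missing-metabolites rule, and participant FFQ/energy exclusions come
first.  Note the deliberate asymmetry in the missingness thresholds:
participants are excluded at >= 20% missing metabolites, metabolites at
strictly > 20% missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .synthetic_cohort import MetaboliteMatrix

__all__ = [
    "FilterRules",
    "ExclusionLog",
    "filter_participants",
    "filter_metabolites",
    "pooled_reference_standardize",
    "impute_missing",
    "blom_transform",
    "energy_adjust_residual",
]

#: FFQ-derived columns whose absence marks a participant as "missing FFQ"
FFQ_COLUMNS = ("intake_total_oo", "intake_voo", "intake_coo", "energy")


@dataclass
class FilterRules:
    """Exclusion thresholds for participant and metabolite QC."""

    energy_low_female: float = 500.0
    energy_low_male: float = 800.0
    energy_high_female: float = 3500.0
    energy_high_male: float = 4000.0
    participant_missing_metabolite_threshold: float = 0.20  # exclude if >= this
    metabolite_missing_threshold: float = 0.20  # exclude if > this

    def __post_init__(self) -> None:
        if not self.energy_low_female < self.energy_low_male:
            raise ValueError("female lower energy bound must sit below the male bound")
        if not (0 < self.energy_low_female < self.energy_high_female):
            raise ValueError("female energy bounds must be positive and ordered")
        if not (0 < self.energy_low_male < self.energy_high_male):
            raise ValueError("male energy bounds must be positive and ordered")


@dataclass
class ExclusionLog:
    """Ordered record of QC stages: rule applied and ids removed per stage."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, rule: str, removed: list) -> None:
        self.stages.append(
            {"stage": stage, "rule": rule, "ids": list(removed), "n": len(removed)}
        )

    @property
    def total_removed(self) -> int:
        return sum(s["n"] for s in self.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": s["stage"], "rule": s["rule"], "n_removed": s["n"]}
             for s in self.stages]
        )


def filter_participants(
    cohort: pd.DataFrame,
    metabolites: MetaboliteMatrix | pd.DataFrame | None = None,
    rules: FilterRules | None = None,
    ffq_columns: tuple[str, ...] = FFQ_COLUMNS,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the participant exclusion flow.

    In order: (1) missing FFQ data at baseline, (2) implausible energy intake
    by sex-specific bounds (strictly below the low or strictly above the high
    cut), (3) >= 20% missing metabolite values.  ``sex`` is coded 1 = female.
    """
    rules = rules or FilterRules()
    if metabolites is not None:
        met_values = metabolites.values if isinstance(metabolites, MetaboliteMatrix) else metabolites
        if len(met_values) != len(cohort):
            raise ValueError("cohort and metabolite matrix are misaligned")
    log = ExclusionLog()
    df = cohort

    ffq_cols = [c for c in ffq_columns if c in df.columns]
    miss_ffq = df[ffq_cols].isna().any(axis=1)
    log.add("missing_ffq", f"NaN in any of {ffq_cols}", df.loc[miss_ffq, "participant_id"].tolist()
            if "participant_id" in df else df.index[miss_ffq].tolist())
    keep = ~miss_ffq

    if "sex" not in df.columns:
        raise ValueError("sex column required for sex-specific energy bounds")
    female = df["sex"].astype(int) == 1
    low = np.where(female, rules.energy_low_female, rules.energy_low_male)
    high = np.where(female, rules.energy_high_female, rules.energy_high_male)
    energy_out = ((df["energy"] < low) | (df["energy"] > high)) & keep
    log.add(
        "energy_outlier",
        "energy < 500 (F) / 800 (M) or > 3500 (F) / 4000 (M) kcal/day",
        df.loc[energy_out, "participant_id"].tolist() if "participant_id" in df
        else df.index[energy_out].tolist(),
    )
    keep &= ~energy_out

    if metabolites is not None:
        frac_missing = pd.Series(
            np.asarray(met_values.isna().mean(axis=1)), index=df.index
        )
        high_missing = (frac_missing >= rules.participant_missing_metabolite_threshold) & keep
        log.add(
            "high_missing_metabolites",
            f">= {rules.participant_missing_metabolite_threshold:.0%} missing metabolites",
            df.loc[high_missing, "participant_id"].tolist() if "participant_id" in df
            else df.index[high_missing].tolist(),
        )
        keep &= ~high_missing

    return df.loc[keep], log


def filter_metabolites(
    metabolites: MetaboliteMatrix, rules: FilterRules | None = None
) -> tuple[MetaboliteMatrix, ExclusionLog]:
    """Drop internal standards, drug metabolites, and high-missing metabolites.

    A metabolite with exactly 20.0% missing values is retained: the rule is
    strictly greater than the threshold.  Column order of survivors is
    preserved.
    """
    rules = rules or FilterRules()
    ann = metabolites.annotations
    log = ExclusionLog()
    cols = list(metabolites.values.columns)

    is_std = ann.loc[cols, "is_internal_standard"].astype(bool)
    removed = [c for c in cols if is_std[c]]
    log.add("internal_standard", "is_internal_standard flag", removed)
    cols = [c for c in cols if not is_std[c]]

    is_drug = ann.loc[cols, "is_drug"].astype(bool)
    removed = [c for c in cols if is_drug[c]]
    log.add("drug", "is_drug flag", removed)
    cols = [c for c in cols if not is_drug[c]]

    frac = metabolites.values[cols].isna().mean(axis=0)
    removed = [c for c in cols if frac[c] > rules.metabolite_missing_threshold]
    log.add(
        "high_missing",
        f"> {rules.metabolite_missing_threshold:.0%} missing values",
        removed,
    )
    cols = [c for c in cols if frac[c] <= rules.metabolite_missing_threshold]

    out = MetaboliteMatrix(
        metabolites.values[cols],
        metabolites.missing_mask[cols],
        metabolites.annotations.loc[cols],
    )
    return out, log


def pooled_reference_standardize(
    sample_values: np.ndarray | pd.DataFrame,
    sample_positions: np.ndarray,
    reference_values: np.ndarray | pd.DataFrame,
    reference_positions: np.ndarray,
) -> np.ndarray | pd.DataFrame:
    """Nearest-neighbor pooled-reference standardization.

    Each sample value ``v`` becomes ``v / r_nearest * median(all references)``
    per metabolite, where ``r_nearest`` is the pooled-reference measurement
    closest in run order (ties broken toward the earlier run position).  A
    zero nearest reference makes the cell unquantifiable: it is set missing
    (NaN) rather than raising.
    """
    samples = np.asarray(sample_values, dtype=float)
    refs = np.asarray(reference_values, dtype=float)
    spos = np.asarray(sample_positions, dtype=float)
    rpos = np.asarray(reference_positions, dtype=float)
    if refs.ndim == 1:
        refs = refs[:, None] if samples.ndim == 2 else refs.reshape(-1, 1)
    if samples.ndim == 1:
        samples2 = samples[:, None]
    else:
        samples2 = samples
    if refs.shape[0] == 0:
        raise ValueError("at least one pooled reference is required")
    order = np.argsort(rpos, kind="stable")
    rpos_sorted = rpos[order]
    refs_sorted = refs[order]
    # nearest reference in run order; argmin picks the first (earlier) on ties
    dist = np.abs(spos[:, None] - rpos_sorted[None, :])
    nearest = np.argmin(dist, axis=1)
    ref_for_sample = refs_sorted[nearest]  # n_samples x n_metabolites
    med = np.median(refs_sorted, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = samples2 / ref_for_sample * med
    out[ref_for_sample == 0] = np.nan
    if samples.ndim == 1:
        out = out[:, 0]
    if isinstance(sample_values, pd.DataFrame):
        return pd.DataFrame(out, index=sample_values.index, columns=sample_values.columns)
    return out


def impute_missing(
    matrix: MetaboliteMatrix | pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 50,
    max_iter: int = 10,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Iterative random-forest imputation of missing metabolite values.

    missForest-style: columns are initialized at their observed mean and then
    repeatedly re-imputed (in order of increasing missingness) by a random
    forest regression on all other columns, until the relative change of the
    imputed cells falls below ``tol`` or ``max_iter`` sweeps.  Observed
    entries are never touched; imputed values are forest predictions and so
    lie within the observed range of their column.
    """
    values = matrix.values if isinstance(matrix, MetaboliteMatrix) else matrix
    df = values.copy()
    mask = df.isna()
    n_missing = mask.sum(axis=0)
    if (n_missing == len(df)).any():
        bad = n_missing.index[n_missing == len(df)].tolist()
        raise ValueError(f"columns entirely missing, cannot impute: {bad}")
    cols = [c for c in n_missing.sort_values(kind="stable").index if n_missing[c] > 0]
    if not cols:
        return df
    filled = df.fillna(df.mean())
    prev = None
    for it in range(max_iter):
        for j, col in enumerate(cols):
            obs = ~mask[col]
            others = [c for c in df.columns if c != col]
            rf = RandomForestRegressor(
                n_estimators=n_estimators, random_state=seed + it * 1000 + j, n_jobs=1
            )
            rf.fit(filled.loc[obs, others], df.loc[obs, col])
            filled.loc[mask[col], col] = rf.predict(filled.loc[mask[col], others])
        cur = filled.to_numpy()[mask.to_numpy()]
        if prev is not None:
            denom = float(np.sum(cur**2)) or 1.0
            if float(np.sum((cur - prev) ** 2)) / denom < tol:
                break
        prev = cur.copy()
    out = df.where(~mask, filled)
    return out


def blom_transform(x: np.ndarray | pd.Series | pd.DataFrame):
    """Blom's rank-based inverse normal transformation.

    Rank r of n maps to the standard-normal quantile of (r - 3/8)/(n + 1/4);
    ties get the mean of their tied ranks, so the output is order-isomorphic
    to the input and invariant to strictly monotone transformations.
    """
    if isinstance(x, pd.DataFrame):
        return x.apply(lambda col: pd.Series(blom_transform(col.to_numpy()),
                                             index=col.index), axis=0)
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-d vector or a DataFrame of columns")
    if np.isnan(arr).any():
        raise ValueError("missing values must be imputed before the Blom transform")
    if np.unique(arr).size < 2:
        raise ValueError("constant column: Blom transform undefined")
    n = arr.size
    ranks = stats.rankdata(arr, method="average")
    out = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


def energy_adjust_residual(intake, energy):
    """Energy-adjust an intake by the residual method.

    Regresses intake (g/day) on total energy (kcal/day) by least squares and
    returns residuals re-centered at the mean intake, so units and center are
    preserved while the output is exactly uncorrelated with energy.
    Invariant to affine rescaling of the energy units (kcal vs kJ).
    """
    y = np.asarray(intake, dtype=float)
    e = np.asarray(energy, dtype=float)
    if y.shape != e.shape or y.ndim != 1:
        raise ValueError("intake and energy must be 1-d vectors of equal length")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(e) == 0:
        raise ValueError("energy is constant; residual method undefined")
    ec = e - e.mean()
    beta = float(ec @ (y - y.mean())) / float(ec @ ec)
    resid = y - y.mean() - beta * ec
    out = resid + y.mean()
    if isinstance(intake, pd.Series):
        return pd.Series(out, index=intake.index, name=intake.name)
    return out
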