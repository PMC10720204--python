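"""Synthetic cohort generator for olive-oil metabolomics analyses.

The generator emulates the statistical structure of a Mediterranean
nutritional-trial cohort with LC-MS plasma metabolomics: per-participant
covariates, food-frequency-questionnaire (FFQ) olive-oil intakes split into
virgin (VOO) and common/refined (COO) varieties, a metabolite panel with
block-correlated columns and a sparse planted intake signal, a correlated
1-year repeat visit, proportional-hazards survival outcomes, and nested
case-cohort samples.

The key contract is the *planted signal*: for each olive-oil exposure a small
set of "active" metabolites carries a linear relation

    intake = mu + sd * (sqrt(R2) * s + sqrt(1 - R2) * eps)

where ``s`` is the unit-variance weighted combination of the active
metabolites and ``eps`` is independent noise, so the population variance of
intake explained by the metabolome equals ``signal_r2``.  The true active
sets and weights are returned in a truth record so recovery of the signature
can be measured exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "MetaboliteMatrix",
    "CaseCohortDesign",
    "generate_cohort",
    "generate_outcomes",
    "draw_case_cohort",
    "case_cohort_preset",
    "CASE_COHORT_PRESETS",
    "write_simulation",
]

FOOD_GROUPS = {
    # mean, sd in g/day, loosely calibrated to a Spanish high-CVD-risk cohort
    "vegetables": (330.0, 150.0),
    "fruits": (360.0, 195.0),
    "cereals": (230.0, 100.0),
    "nuts": (11.0, 14.0),
    "eggs": (25.0, 15.0),
    "legumes": (20.0, 13.0),
    "fish": (100.0, 52.0),
    "meat": (134.0, 56.0),
    "dairy": (375.0, 220.0),
}

EXPOSURES = ("total_oo", "voo", "coo")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults match the analysis-scale study conditions: ~1,800 participants,
    381 annotated metabolites, 20 active metabolites per oil variety (40 for
    total olive oil, the union), and a planted R^2 of 0.16 so the best
    attainable metabolome-intake correlation is 0.40.
    """

    n_participants: int = 1800
    n_metabolites: int = 381
    n_active_per_exposure: int = 20
    signal_r2: float = 0.16
    visit_correlation: float = 0.8
    missing_rate: float = 0.0
    log_hr_per_sd: float = math.log(0.79)
    subcohort_fraction: float = 0.4
    censoring_rate: float = 0.85
    seed: int = 0
    # metabolite panel correlation structure
    block_size: int = 10
    block_rho: float = 0.3
    # intake calibration (g/day); tertile means of total olive oil land near
    # 22 / 40 / 56 g/day
    voo_mean: float = 21.0
    voo_sd: float = 12.0
    coo_mean: float = 19.0
    coo_sd: float = 11.0
    # missingness mechanism: completely at random by default, optionally
    # missing-at-random keyed to total olive-oil intake tertile
    mar_by_intake: bool = False
    baseline_hazard: float = 0.025

    def __post_init__(self) -> None:
        if not 0 <= self.signal_r2 < 1:
            raise ValueError("signal_r2 must lie in [0, 1)")
        if not 0 <= self.visit_correlation <= 1:
            raise ValueError("visit_correlation must lie in [0, 1]")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must lie in [0, 0.2]")
        if not 0 < self.subcohort_fraction <= 1:
            raise ValueError("subcohort_fraction must lie in (0, 1]")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if self.n_active_per_exposure * 2 > self.n_metabolites:
            raise ValueError(
                "need 2 * n_active_per_exposure <= n_metabolites "
                "(VOO and COO active sets are disjoint)"
            )
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")


@dataclass
class MetaboliteMatrix:
    """Participants x metabolites panel with a missingness mask and annotations.

    ``values`` holds NaN wherever ``missing_mask`` is True.  ``annotations``
    is indexed by metabolite name with boolean ``is_internal_standard`` and
    ``is_drug`` flags plus a free-text ``klass``.
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.missing_mask.columns):
            raise ValueError("values and missing_mask columns differ")
        if not set(self.values.columns) <= set(self.annotations.index):
            missing = set(self.values.columns) - set(self.annotations.index)
            raise ValueError(f"annotations missing for metabolites: {sorted(missing)[:5]}")
        # mask true <=> value absent
        if bool((self.values.isna() != self.missing_mask).any().any()):
            raise ValueError("missing_mask inconsistent with NaN pattern in values")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.values.copy(), self.missing_mask.copy(), self.annotations.copy()
        )


@dataclass
class CaseCohortDesign:
    """A nested case-cohort sample: random subcohort plus all incident cases."""

    data: pd.DataFrame  # participant_id, time, event, in_subcohort
    sampling_fraction: float
    n_full: int
    outcome_name: str = "outcome"

    @property
    def n_cases(self) -> int:
        return int(self.data["event"].sum())

    @property
    def n_subcohort(self) -> int:
        return int(self.data["in_subcohort"].sum())

    @property
    def n_overlap(self) -> int:
        return int((self.data["event"].astype(bool) & self.data["in_subcohort"]).sum())


def _block_correlated_normal(rng: np.random.Generator, n: int, p: int,
                             block_size: int, rho: float) -> np.ndarray:
    """Draw n x p matrix with block-equicorrelated columns (within-block rho)."""
    z = rng.standard_normal((n, p))
    if rho == 0:
        return z
    out = np.empty_like(z)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        g = rng.standard_normal((n, 1))
        out[:, start:stop] = math.sqrt(rho) * g + math.sqrt(1 - rho) * z[:, start:stop]
    return out


def _score_sd(weights: np.ndarray, cols: np.ndarray, block_size: int, rho: float) -> float:
    """Population SD of sum_j w_j m_j under the block-equicorrelation model."""
    var = (1 - rho) * float(np.sum(weights**2))
    blocks = cols // block_size
    for b in np.unique(blocks):
        var += rho * float(np.sum(weights[blocks == b])) ** 2
    return math.sqrt(var)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, MetaboliteMatrix, dict]:
    """Generate the cohort table, metabolite panel, and planted-truth record.

    Returns rows for both visits (baseline and year1), aligned row-for-row
    between the cohort table and the metabolite matrix.  The truth record
    maps each exposure to its active metabolites, weights (for the
    unit-variance planted score), and the planted R^2.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_participants, cfg.n_metabolites
    met_names = [f"met_{j:04d}" for j in range(p)]
    pid = np.array([f"P{i:05d}" for i in range(n)])

    # --- static covariates -------------------------------------------------
    age = np.round(rng.normal(67, 6, n)).clip(55, 80)
    sex = (rng.random(n) < 0.57).astype(int)  # 1 = female
    bmi = rng.normal(30, 3.5, n).clip(20, 45)
    smoking = rng.choice(["never", "former", "current"], n, p=[0.60, 0.24, 0.16])
    education = rng.choice(["primary", "secondary", "college"], n, p=[0.70, 0.20, 0.10])
    pa = rng.lognormal(mean=5.3, sigma=0.6, size=n)  # METs-min/day
    center = rng.choice([f"C{k}" for k in range(1, 6)], n)
    group = rng.choice(
        ["MedDiet+VOO", "MedDiet+nuts", "control"], n, p=[0.345, 0.343, 0.312]
    )
    fam_hist = (rng.random(n) < 0.25).astype(int)
    dyslipidemia = (rng.random(n) < 0.77).astype(int)
    hypertension = (rng.random(n) < 0.87).astype(int)
    dyslip_med = ((dyslipidemia == 1) & (rng.random(n) < 0.5)).astype(int)
    htn_med = ((hypertension == 1) & (rng.random(n) < 0.7)).astype(int)
    # stand-ins for the trial's published propensity scores (a given covariate)
    ps1 = 1 / (1 + np.exp(-(0.02 * (age - 67) - 0.3 * sex + rng.normal(0, 0.5, n))))
    ps2 = 1 / (1 + np.exp(-(0.05 * (bmi - 30) + rng.normal(0, 0.5, n))))
    energy = rng.normal(2280, 540, n).clip(900, 4400)
    alcohol = np.where(rng.random(n) < 0.35, 0.0, rng.lognormal(2.2, 0.9, n)).clip(0, 90)

    foods = {
        name: rng.normal(mu, sd, n).clip(0, None) for name, (mu, sd) in FOOD_GROUPS.items()
    }

    # --- metabolites and planted intake signal -----------------------------
    m0 = _block_correlated_normal(rng, n, p, cfg.block_size, cfg.block_rho)
    # Active metabolites occupy whole correlation blocks (metabolite families
    # such as lipid classes co-vary and carry the dietary signal jointly),
    # with equal-magnitude weights and a common sign per block.  VOO- and
    # COO-active blocks are disjoint so the two planted scores are exactly
    # uncorrelated and the total-olive-oil planted R^2 equals signal_r2 too.
    n_blocks = -(-p // cfg.block_size)
    cols_by_block = [np.arange(b * cfg.block_size, min((b + 1) * cfg.block_size, p))
                     for b in range(n_blocks)]
    k = cfg.n_active_per_exposure
    blocks_per = -(-k // cfg.block_size)
    if 2 * blocks_per > n_blocks:
        raise ValueError("n_active_per_exposure too large for disjoint block pools")
    perm = rng.permutation(n_blocks)

    def _active_from_blocks(block_ids: np.ndarray) -> np.ndarray:
        cols = np.concatenate([cols_by_block[b] for b in block_ids])
        return np.sort(cols[:k])

    active_voo = _active_from_blocks(perm[:blocks_per])
    active_coo = _active_from_blocks(perm[blocks_per: 2 * blocks_per])
    active = np.concatenate([active_voo, active_coo])

    def _block_weights(cols: np.ndarray) -> np.ndarray:
        w = np.empty(len(cols))
        for b in np.unique(cols // cfg.block_size):
            w[cols // cfg.block_size == b] = rng.choice([-1.0, 1.0])
        return w / _score_sd(w, cols, cfg.block_size, cfg.block_rho)

    w_voo = _block_weights(active_voo)
    w_coo = _block_weights(active_coo)

    r = math.sqrt(cfg.signal_r2)
    noise = math.sqrt(1 - cfg.signal_r2)

    def latent(mat: np.ndarray, eps_v: np.ndarray, eps_c: np.ndarray):
        s_v = mat[:, active_voo] @ w_voo
        s_c = mat[:, active_coo] @ w_coo
        u_v = r * s_v + noise * eps_v
        u_c = r * s_c + noise * eps_c
        return u_v, u_c

    eps_v0 = rng.standard_normal(n)
    eps_c0 = rng.standard_normal(n)
    u_v0, u_c0 = latent(m0, eps_v0, eps_c0)
    voo0 = np.clip(cfg.voo_mean + cfg.voo_sd * u_v0, 0, None)
    coo0 = np.clip(cfg.coo_mean + cfg.coo_sd * u_c0, 0, None)

    # --- year-1 visit: AR(1) shrink toward the mean ------------------------
    rho_v = cfg.visit_correlation
    rho_c = math.sqrt(1 - rho_v**2)
    m1 = rho_v * m0 + rho_c * _block_correlated_normal(rng, n, p, cfg.block_size, cfg.block_rho)
    u_v1 = rho_v * u_v0 + rho_c * rng.standard_normal(n)
    u_c1 = rho_v * u_c0 + rho_c * rng.standard_normal(n)
    voo1 = np.clip(cfg.voo_mean + cfg.voo_sd * u_v1, 0, None)
    coo1 = np.clip(cfg.coo_mean + cfg.coo_sd * u_c1, 0, None)

    frames = []
    for visit, voo, coo in (("baseline", voo0, coo0), ("year1", voo1, coo1)):
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "visit": visit,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking": smoking,
            "education": education,
            "physical_activity": pa,
            "center": center,
            "intervention_group": group,
            "ps_1": ps1,
            "ps_2": ps2,
            "family_history_cvd": fam_hist,
            "dyslipidemia": dyslipidemia,
            "hypertension": hypertension,
            "dyslipidemia_med": dyslip_med,
            "hypertension_med": htn_med,
            "energy": energy,
            "intake_voo": voo,
            "intake_coo": coo,
            "intake_total_oo": voo + coo,
            "alcohol": alcohol,
            **foods,
        }))
    cohort = pd.concat(frames, ignore_index=True)

    values = pd.DataFrame(np.vstack([m0, m1]), columns=met_names)
    values.index = pd.MultiIndex.from_arrays(
        [np.concatenate([pid, pid]), ["baseline"] * n + ["year1"] * n],
        names=["participant_id", "visit"],
    )
    cohort.index = values.index

    # --- missingness -------------------------------------------------------
    if cfg.missing_rate > 0:
        if cfg.mar_by_intake:
            tert = pd.qcut(cohort["intake_total_oo"], 3, labels=False).to_numpy()
            rate = cfg.missing_rate * np.array([0.5, 1.0, 1.5])[tert]
            mask = rng.random(values.shape) < rate[:, None]
        else:
            mask = rng.random(values.shape) < cfg.missing_rate
    else:
        mask = np.zeros(values.shape, dtype=bool)
    mask = pd.DataFrame(mask, index=values.index, columns=values.columns)
    values = values.mask(mask)

    annotations = pd.DataFrame(
        {
            "is_internal_standard": False,
            "is_drug": False,
            "klass": "simulated",
        },
        index=pd.Index(met_names, name="metabolite"),
    )

    sd_v, sd_c = cfg.voo_sd, cfg.coo_sd
    tot_norm = math.sqrt(sd_v**2 + sd_c**2)
    truth = {
        "seed": cfg.seed,
        "signal_r2": cfg.signal_r2,
        "exposures": {
            "voo": {
                "metabolites": [met_names[j] for j in active_voo],
                "weights": w_voo.tolist(),
                "r2": cfg.signal_r2,
            },
            "coo": {
                "metabolites": [met_names[j] for j in active_coo],
                "weights": w_coo.tolist(),
                "r2": cfg.signal_r2,
            },
            "total_oo": {
                "metabolites": [met_names[j] for j in np.sort(active)],
                "weights": [
                    float(w)
                    for w in np.concatenate([
                        sd_v * w_voo / tot_norm, sd_c * w_coo / tot_norm
                    ])[np.argsort(np.concatenate([active_voo, active_coo]))]
                ],
                "r2": cfg.signal_r2,
            },
        },
    }
    return cohort, MetaboliteMatrix(values, mask, annotations), truth


def planted_score(metabolites: MetaboliteMatrix | pd.DataFrame, truth: dict,
                  exposure: str = "total_oo") -> np.ndarray:
    """Evaluate the true planted linear combination on a (complete) matrix."""
    values = metabolites.values if isinstance(metabolites, MetaboliteMatrix) else metabolites
    rec = truth["exposures"][exposure]
    return values[rec["metabolites"]].to_numpy(dtype=float) @ np.asarray(rec["weights"])


def generate_outcomes(cohort: pd.DataFrame, score: np.ndarray, config: SimConfig,
                      outcome_name: str = "outcome") -> pd.DataFrame:
    """Draw survival outcomes from a proportional-hazards model on a score.

    Event times are exponential with log-hazard ``log_hr_per_sd`` per SD of
    the (standardized) score; censoring is independent exponential with rate
    calibrated so roughly ``censoring_rate`` of participants are censored.
    Only baseline rows of the cohort are used.
    """
    base = cohort[cohort["visit"] == "baseline"]
    score = np.asarray(score, dtype=float)
    if len(score) != len(base):
        raise ValueError("score must align with baseline participants")
    if not np.all(np.isfinite(score)):
        raise ValueError("score contains non-finite values")
    rng = np.random.default_rng(config.seed + 1_000_003)
    z = (score - score.mean()) / score.std()
    lam = config.baseline_hazard * np.exp(config.log_hr_per_sd * z)
    t_event = rng.exponential(1 / lam)
    c = config.censoring_rate
    if c >= 1:
        time = rng.exponential(1 / config.baseline_hazard, len(base))
        event = np.zeros(len(base), dtype=int)
    else:
        lam_c = config.baseline_hazard * c / (1 - c)
        t_cens = (rng.exponential(1 / lam_c, len(base))
                  if lam_c > 0 else np.full(len(base), np.inf))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-8)
    return pd.DataFrame({
        "participant_id": base["participant_id"].to_numpy(),
        "time": time,
        "event": event,
        "outcome_name": outcome_name,
    })


def draw_case_cohort(outcomes: pd.DataFrame, config: SimConfig | float,
                     seed: int | None = None) -> CaseCohortDesign:
    """Draw a case-cohort sample: a simple random subcohort plus all cases."""
    if isinstance(config, SimConfig):
        fraction = config.subcohort_fraction
        seed = config.seed + 2_000_003 if seed is None else seed
    else:
        fraction = float(config)
        if seed is None:
            raise ValueError("seed required when passing a bare fraction")
    if not 0 < fraction <= 1:
        raise ValueError("subcohort_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(outcomes)
    m = int(round(fraction * n))
    sub_idx = rng.choice(n, size=m, replace=False)
    in_sub = np.zeros(n, dtype=bool)
    in_sub[sub_idx] = True
    keep = in_sub | outcomes["event"].astype(bool).to_numpy()
    data = outcomes.loc[keep, ["participant_id", "time", "event"]].copy()
    data["in_subcohort"] = in_sub[keep]
    name = outcomes["outcome_name"].iloc[0] if "outcome_name" in outcomes else "outcome"
    return CaseCohortDesign(
        data.reset_index(drop=True),
        sampling_fraction=fraction,
        n_full=n,
        outcome_name=str(name),
    )


# Printed case/subcohort/overlap counts of the two published nested samples;
# the underlying sampling fractions were never printed, so the presets force
# the counts by construction.
CASE_COHORT_PRESETS = {
    "PREDIMED-T2D": {"n_cases": 251, "n_subcohort": 694, "n_overlap": 53},
    "PREDIMED-CVD": {"n_cases": 229, "n_subcohort": 788, "n_overlap": 37},
}


def case_cohort_preset(outcomes: pd.DataFrame, preset: str,
                       seed: int = 0) -> CaseCohortDesign:
    """Force the case/subcohort/overlap counts of a published nested sample."""
    spec = CASE_COHORT_PRESETS[preset]
    n_cases, n_sub, n_overlap = spec["n_cases"], spec["n_subcohort"], spec["n_overlap"]
    rng = np.random.default_rng(seed)
    ev = outcomes["event"].astype(bool).to_numpy()
    case_idx = np.flatnonzero(ev)
    noncase_idx = np.flatnonzero(~ev)
    if len(case_idx) < n_cases:
        raise ValueError(f"preset {preset} needs >= {n_cases} cases, found {len(case_idx)}")
    if len(noncase_idx) < n_sub - n_overlap:
        raise ValueError(f"preset {preset} needs >= {n_sub - n_overlap} non-cases")
    cases = rng.choice(case_idx, n_cases, replace=False)
    overlap = rng.choice(cases, n_overlap, replace=False)
    sub_noncases = rng.choice(noncase_idx, n_sub - n_overlap, replace=False)
    keep = np.concatenate([cases, sub_noncases])
    in_sub = np.isin(keep, overlap) | np.isin(keep, sub_noncases)
    data = outcomes.iloc[keep][["participant_id", "time", "event"]].copy()
    data["in_subcohort"] = in_sub
    name = outcomes["outcome_name"].iloc[0] if "outcome_name" in outcomes else "outcome"
    return CaseCohortDesign(
        data.reset_index(drop=True),
        sampling_fraction=n_sub / len(outcomes),
        n_full=len(outcomes),
        outcome_name=str(name),
    )


def write_simulation(outdir: str | Path, config: SimConfig,
                     cohort: pd.DataFrame, metabolites: MetaboliteMatrix,
                     truth: dict, outcomes: pd.DataFrame | None = None) -> None:
    """Write a simulated data set as CSV + truth JSON + config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    metabolites.values.to_csv(outdir / "metabolites.csv")
    metabolites.annotations.to_csv(outdir / "annotations.csv")
    if outcomes is not None:
        outcomes.to_csv(outdir / "outcomes.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
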