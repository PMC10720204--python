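import numpy as np
import pandas as pd
import pytest
from scipy import stats

from olivesig import preprocess as pp
from olivesig.synthetic_cohort import MetaboliteMatrix


def _roster(n, n_ffq_missing=0, n_energy_out=0, n_high_missing=0,
            n_metabolites=20, seed=0):
    """Participant roster with disjoint rule-violating groups."""
    rng = np.random.default_rng(seed)
    sex = rng.integers(0, 2, n)
    energy = rng.uniform(1200, 3200, n)
    cohort = pd.DataFrame({
        "participant_id": [f"P{i:05d}" for i in range(n)],
        "sex": sex,
        "energy": energy,
        "intake_total_oo": rng.uniform(5, 80, n),
        "intake_voo": rng.uniform(0, 40, n),
        "intake_coo": rng.uniform(0, 40, n),
    })
    values = pd.DataFrame(rng.standard_normal((n, n_metabolites)),
                          columns=[f"met_{j}" for j in range(n_metabolites)])
    i = 0
    cohort.loc[i:i + n_ffq_missing - 1, "intake_total_oo"] = np.nan
    i += n_ffq_missing
    for k in range(n_energy_out):
        cohort.loc[i + k, "energy"] = 400 if cohort.loc[i + k, "sex"] == 1 else 4200
    i += n_energy_out
    n_bad_cols = int(np.ceil(0.5 * n_metabolites))
    values.iloc[i:i + n_high_missing, :n_bad_cols] = np.nan
    mask = values.isna()
    ann = pd.DataFrame({"is_internal_standard": False, "is_drug": False,
                        "klass": "x"}, index=values.columns)
    return cohort, MetaboliteMatrix(values, mask, ann)


class TestFilterParticipants:
    def test_published_exclusion_flow_counts(self):
        # 1,882 screened; 11 missing FFQ, 30 energy outliers, 4 with >= 20%
        # missing metabolites -> 1,837 analyzed
        cohort, met = _roster(1882, 11, 30, 4)
        kept, log = pp.filter_participants(cohort, met)
        assert len(kept) == 1837
        assert [s["n"] for s in log.stages] == [11, 30, 4]
        assert log.total_removed == 1882 - 1837

    def test_clean_roster_is_identity(self):
        cohort, met = _roster(50)
        kept, log = pp.filter_participants(cohort, met)
        pd.testing.assert_frame_equal(kept, cohort)
        assert log.total_removed == 0

    def test_idempotent(self):
        cohort, met = _roster(300, 5, 5, 3, seed=2)
        kept, _ = pp.filter_participants(cohort, met)
        met_kept = MetaboliteMatrix(
            met.values.loc[kept.index], met.missing_mask.loc[kept.index],
            met.annotations)
        again, log2 = pp.filter_participants(kept, met_kept)
        assert len(again) == len(kept)
        assert log2.total_removed == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        n = 500
        cohort, met = _roster(n, seed=7)
        # random contamination, possibly overlapping groups
        cohort.loc[rng.choice(n, 20, replace=False), "intake_voo"] = np.nan
        cohort.loc[rng.choice(n, 25, replace=False), "energy"] = rng.choice(
            [300.0, 4500.0], 25)
        rows = rng.choice(n, 10, replace=False)
        vals = met.values.copy()
        vals.iloc[rows, :15] = np.nan
        met = MetaboliteMatrix(vals, vals.isna(), met.annotations)
        kept, _ = pp.filter_participants(cohort, met)

        expected = 0
        for i in range(n):
            row = cohort.iloc[i]
            if pd.isna(row[["intake_total_oo", "intake_voo", "intake_coo",
                            "energy"]]).any():
                continue
            lo, hi = (500, 3500) if row["sex"] == 1 else (800, 4000)
            if row["energy"] < lo or row["energy"] > hi:
                continue
            if met.values.iloc[i].isna().mean() >= 0.20:
                continue
            expected += 1
        assert len(kept) == expected

    def test_missing_sex_column_errors(self):
        cohort, met = _roster(20)
        with pytest.raises(ValueError, match="sex"):
            pp.filter_participants(cohort.drop(columns="sex"), met)


def make_panel(n=50, p=400, n_std=0, n_drug=0, n_high=0, seed=0):
    """Annotated metabolite panel with disjoint flagged/high-missing columns."""
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(rng.standard_normal((n, p)),
                          columns=[f"met_{j:03d}" for j in range(p)])
    cols = list(values.columns)
    std = cols[:n_std]
    drug = cols[n_std:n_std + n_drug]
    high = cols[n_std + n_drug:n_std + n_drug + n_high]
    n_missing = int(np.floor(0.2 * n)) + 1  # strictly > 20%
    for c in high:
        values.loc[values.index[:n_missing], c] = np.nan
    ann = pd.DataFrame({
        "is_internal_standard": [c in std for c in cols],
        "is_drug": [c in drug for c in cols],
        "klass": "x",
    }, index=cols)
    return MetaboliteMatrix(values, values.isna(), ann)


class TestFilterMetabolites:
    def test_published_panel_counts(self):
        # 400 quantified; 3 internal standards + 7 drugs + 9 high-missing
        # removed -> 381 analyzed
        panel = make_panel(n=50, p=400, n_std=3, n_drug=7, n_high=9)
        kept, log = pp.filter_metabolites(panel)
        assert kept.values.shape[1] == 381
        assert [s["n"] for s in log.stages] == [3, 7, 9]

    def test_identity_and_column_order_preserved(self):
        panel = make_panel(p=30)
        kept, log = pp.filter_metabolites(panel)
        assert list(kept.values.columns) == list(panel.values.columns)
        assert log.total_removed == 0

    def test_exactly_twenty_percent_missing_is_retained(self):
        values = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 2)),
                              columns=["a", "b"])
        values.loc[values.index[:2], "a"] = np.nan  # exactly 20%
        ann = pd.DataFrame({"is_internal_standard": False, "is_drug": False,
                            "klass": "x"}, index=values.columns)
        kept, _ = pp.filter_metabolites(MetaboliteMatrix(values, values.isna(), ann))
        assert "a" in kept.values.columns


class TestPooledReferenceStandardize:
    def test_hand_computed_example(self):
        # refs 10 and 20 at run positions 0 and 10, sample 12 at position 2:
        # 12/10 * median([10, 20]) = 12/10 * 15 = 18
        out = pp.pooled_reference_standardize(
            np.array([12.0]), np.array([2]), np.array([10.0, 20.0]),
            np.array([0, 10]))
        assert out[0] == pytest.approx(18.0)

    def test_constant_references_are_identity(self):
        rng = np.random.default_rng(1)
        samples = rng.uniform(1, 5, (8, 3))
        refs = np.full((4, 3), 7.0)
        out = pp.pooled_reference_standardize(
            samples, np.arange(8) + 0.5, refs, np.array([0, 2, 4, 6]))
        np.testing.assert_allclose(out, samples)

    def test_equidistant_tie_uses_earlier_reference(self):
        # sample halfway between refs at positions 0 and 10
        out = pp.pooled_reference_standardize(
            np.array([10.0]), np.array([5]), np.array([10.0, 20.0]),
            np.array([0, 10]))
        assert out[0] == pytest.approx(10.0 / 10.0 * 15.0)

    def test_zero_reference_flags_missing(self):
        out = pp.pooled_reference_standardize(
            np.array([5.0, 5.0]), np.array([0, 9]), np.array([0.0, 10.0]),
            np.array([1, 8]))
        assert np.isnan(out[0])
        assert np.isfinite(out[1])


class TestImputeMissing:
    def test_complete_matrix_unchanged(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((30, 4)))
        out = pp.impute_missing(df, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_observed_cells_bitwise_identical_and_range_respected(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((60, 5)),
                          columns=list("abcde"))
        mask = rng.random(df.shape) < 0.1
        dfm = df.mask(mask)
        out = pp.impute_missing(dfm, seed=1, n_estimators=10)
        obs = ~dfm.isna()
        assert out.where(obs).equals(dfm.where(obs))
        for c in dfm.columns:
            lo, hi = dfm[c].min(), dfm[c].max()
            assert out[c].between(lo, hi).all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((40, 4))).mask(rng.random((40, 4)) < 0.1)
        a = pp.impute_missing(df, seed=9, n_estimators=10)
        b = pp.impute_missing(df, seed=9, n_estimators=10)
        pd.testing.assert_frame_equal(a, b)

    def test_recovers_exact_linear_relation(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 10, 80)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        df.loc[40, "b"] = np.nan
        out = pp.impute_missing(df, seed=2)
        assert out.loc[40, "b"] == pytest.approx(2 * a[40], rel=0.10)

    def test_all_missing_column_errors(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            pp.impute_missing(df)


class TestBlomTransform:
    def test_three_point_example(self):
        out = pp.blom_transform(np.array([5.0, 1.0, 9.0]))
        assert out[0] == pytest.approx(0.0, abs=1e-12)  # middle rank of 3
        assert out[1] == pytest.approx(stats.norm.ppf((1 - 0.375) / 3.25))
        assert out[1] == pytest.approx(-0.869, abs=1e-3)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 5, 100)
        np.testing.assert_allclose(pp.blom_transform(x),
                                   pp.blom_transform(np.exp(x)))
        np.testing.assert_allclose(pp.blom_transform(x),
                                   pp.blom_transform(x ** 3))

    def test_ties_get_midranks(self):
        out = pp.blom_transform(np.array([1.0, 2.0, 2.0, 3.0]))
        assert out[1] == pytest.approx(out[2])
        assert out[1] == pytest.approx(stats.norm.ppf((2.5 - 0.375) / 4.25))

    def test_large_sample_moments_and_normal_score_agreement(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(size=10_000)
        z = pp.blom_transform(x)
        assert abs(z.mean()) < 0.01
        assert abs(z.std() - 1) < 0.01
        exact = stats.norm.ppf((stats.rankdata(x) - 0.375) / (len(x) + 0.25))
        assert np.corrcoef(z, exact)[0, 1] > 0.999

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pp.blom_transform(np.ones(10))


class TestEnergyAdjustResidual:
    def test_orthogonal_energy_returns_input(self):
        intake = np.array([10.0, 20.0, 30.0])
        energy = np.array([2000.0, 2500.0, 2000.0])
        np.testing.assert_allclose(
            pp.energy_adjust_residual(intake, energy), intake, atol=1e-10)

    def test_collinear_intake_collapses_to_mean(self):
        energy = np.array([1800.0, 2200.0, 2600.0, 3000.0])
        intake = 0.01 * energy
        out = pp.energy_adjust_residual(intake, energy)
        np.testing.assert_allclose(out, np.full(4, intake.mean()), atol=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(11)
        intake = rng.uniform(0, 60, 200)
        energy = rng.uniform(1500, 3500, 200)
        out = pp.energy_adjust_residual(intake, energy)
        A = np.column_stack([np.ones(200), energy])
        coef = np.linalg.solve(A.T @ A, A.T @ intake)
        oracle = intake - A @ coef + intake.mean()
        np.testing.assert_allclose(out, oracle, atol=1e-10)
        assert abs(np.corrcoef(out, energy)[0, 1]) < 1e-10

    def test_invariant_to_energy_unit_change(self):
        rng = np.random.default_rng(2)
        intake = rng.uniform(0, 60, 50)
        kcal = rng.uniform(1500, 3500, 50)
        np.testing.assert_allclose(
            pp.energy_adjust_residual(intake, kcal),
            pp.energy_adjust_residual(intake, kcal * 4.184 + 100),
            atol=1e-10)

    def test_constant_energy_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pp.energy_adjust_residual(np.arange(5.0), np.full(5, 2000.0))
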