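"""Thermal-stability scoring: fold changes, scores, z, significance, classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulizer import simulate as sim
from granulizer.tpp import (
    MeltCurveMatrix,
    StabilityModel,
    abundance_score,
    classify,
    compute_fold_changes,
    moderated_significance,
    stability_score,
    z_transform,
)

TEMPS = sim.TPP_TEMPERATURES


def make_matrix(treat, ctrl, temps=TEMPS):
    """Single-protein matrix from explicit intensity rows."""
    inten = np.stack([np.column_stack([ctrl, treat])])
    return MeltCurveMatrix(["P1"], temps, ["DMSO", "treatment"], inten)


class TestFoldChanges:
    def test_identical_conditions_give_zero(self):
        row = np.linspace(10, 1, 10)
        fc = compute_fold_changes(make_matrix(row, row), "treatment")
        assert np.allclose(fc[TEMPS].to_numpy(), 0.0)
        assert fc["n_points"].iloc[0] == 10

    def test_doubling_gives_one(self):
        row = np.linspace(10, 1, 10)
        fc = compute_fold_changes(make_matrix(2 * row, row), "treatment")
        assert np.allclose(fc[TEMPS].to_numpy(), 1.0)

    def test_zero_intensity_becomes_missing(self):
        ctrl = np.linspace(10, 1, 10)
        treat = ctrl.copy()
        treat[3] = 0.0
        with pytest.warns(UserWarning, match="zero intensities"):
            fc = compute_fold_changes(make_matrix(treat, ctrl), "treatment")
        assert np.isnan(fc[TEMPS].to_numpy()[0, 3])
        assert fc["n_points"].iloc[0] == 9

    def test_unknown_condition_raises(self):
        row = np.linspace(10, 1, 10)
        with pytest.raises(KeyError):
            compute_fold_changes(make_matrix(row, row), "nope")

    def test_matches_generator_ground_truth_without_noise(self):
        spec = sim.TppSimSpec(n_proteins=30, n_stabilized=10, delta_tm=2.0,
                              noise_cv=0.0, seed=11)
        matrix, truth = sim.gen_tpp(spec)
        fc = compute_fold_changes(matrix, "treatment")
        for pid in matrix.protein_ids:
            tm, dtm = truth.loc[pid, "tm"], truth.loc[pid, "delta_tm"]
            expected = np.log2(
                sim.melt_fraction(TEMPS, tm + dtm, spec.slope, spec.plateau)
                / sim.melt_fraction(TEMPS, tm, spec.slope, spec.plateau)
            )
            assert np.allclose(fc.loc[pid, TEMPS].to_numpy(dtype=float),
                               expected, atol=1e-12)


class TestScores:
    def test_abundance_is_mean_of_two_lowest(self):
        vals = np.full(10, np.nan)
        vals[:2] = [0.4, 0.6]
        fc = pd.DataFrame([vals], columns=TEMPS, index=["P1"])
        fc["n_points"] = 2
        assert abundance_score(fc).iloc[0] == pytest.approx(0.5)

    def test_abundance_undefined_when_low_temp_missing(self):
        vals = np.ones(10)
        vals[0] = np.nan
        fc = pd.DataFrame([vals], columns=TEMPS, index=["P1"])
        fc["n_points"] = 9
        assert np.isnan(abundance_score(fc).iloc[0])

    def test_pure_abundance_effect_recovered(self):
        # a flat 2x abundance shift with no melting change scores a = 1
        spec = sim.TppSimSpec(n_proteins=20, n_abundance=20, delta_abundance=1.0,
                              noise_cv=0.0, seed=7)
        matrix, _ = sim.gen_tpp(spec)
        fc = compute_fold_changes(matrix, "treatment")
        assert np.allclose(abundance_score(fc), 1.0, atol=1e-12)
        st_ = stability_score(fc, abundance_score(fc))
        assert np.allclose(st_, 0.0, atol=1e-9)

    def test_constant_row_cancels(self):
        fc = pd.DataFrame([np.full(10, 0.7)], columns=TEMPS, index=["P1"])
        fc["n_points"] = 10
        ab = abundance_score(fc)
        assert stability_score(fc, ab).iloc[0] == pytest.approx(0.0)

    def test_direct_sum(self):
        vals = np.array([0, 0, 1, 1, 1, 1, 1, 1, 1, 1], dtype=float)
        fc = pd.DataFrame([vals], columns=TEMPS, index=["P1"])
        fc["n_points"] = 10
        ab = abundance_score(fc)  # 0
        assert ab.iloc[0] == 0.0
        assert stability_score(fc, ab).iloc[0] == pytest.approx(8.0)

    @given(st.floats(-5, 5), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_shift_invariance_and_antisymmetry(self, k, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, 10)
        fc = pd.DataFrame([vals], columns=TEMPS, index=["P1"])
        fc["n_points"] = 10
        ab = abundance_score(fc)
        s0 = stability_score(fc, ab).iloc[0]

        fc_k = pd.DataFrame([vals + k], columns=TEMPS, index=["P1"])
        fc_k["n_points"] = 10
        ab_k = abundance_score(fc_k)
        assert ab_k.iloc[0] == pytest.approx(ab.iloc[0] + k, abs=1e-9)
        assert stability_score(fc_k, ab_k).iloc[0] == pytest.approx(s0, abs=1e-9)

        fc_n = pd.DataFrame([-vals], columns=TEMPS, index=["P1"])
        fc_n["n_points"] = 10
        ab_n = abundance_score(fc_n)
        assert ab_n.iloc[0] == pytest.approx(-ab.iloc[0], abs=1e-12)
        assert stability_score(fc_n, ab_n).iloc[0] == pytest.approx(-s0, abs=1e-9)

    def test_min_points_contract(self):
        vals = np.ones(10)
        vals[5] = np.nan
        fc = pd.DataFrame([vals], columns=TEMPS, index=["P1"])
        fc["n_points"] = 9
        ab = abundance_score(fc)
        assert np.isnan(stability_score(fc, ab, min_points=10).iloc[0])
        assert np.isfinite(stability_score(fc, ab, min_points=9).iloc[0])


class TestZTransform:
    def test_basic(self):
        z = z_transform(pd.Series([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1, 0, 1])

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(0, 1, 500))
        z1 = z_transform(x)
        assert np.allclose(z_transform(z1), z1, atol=1e-12)

    def test_moments(self):
        rng = np.random.default_rng(1)
        z = z_transform(pd.Series(rng.gamma(2, 1, 20000)))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="standard deviation"):
            z_transform(pd.Series([2.0, 2.0, 2.0]))
        with pytest.raises(ValueError, match="two non-missing"):
            z_transform(pd.Series([1.0, np.nan]))

    def test_missing_propagates(self):
        z = z_transform(pd.Series([1.0, np.nan, 3.0]))
        assert np.isnan(z.iloc[1]) and np.isfinite(z.iloc[0])


class TestModeratedSignificance:
    def test_null_calibration(self):
        rng = np.random.default_rng(42)
        z = pd.Series(rng.normal(0, 1, 5000))
        out = moderated_significance(z)
        frac = (out["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_center_gets_p_one(self):
        z = pd.Series(np.concatenate([[0.0], np.linspace(-3, 3, 999)]))
        out = moderated_significance(z)
        assert out["p_value"].iloc[0] > 0.95

    def test_spiked_entries_called(self):
        rng = np.random.default_rng(3)
        z = pd.Series(np.concatenate([rng.normal(0, 1, 950), np.full(50, 6.0)]))
        out = moderated_significance(z)
        assert (out["fdr"].iloc[950:] < 0.05).all()

    def test_refuses_tiny_input(self):
        with pytest.raises(ValueError, match="at least 10"):
            moderated_significance(pd.Series(np.arange(5, dtype=float)))

    def test_local_fdr_variant_runs(self):
        rng = np.random.default_rng(4)
        z = pd.Series(np.concatenate([rng.normal(0, 1, 900), np.full(20, 8.0)]))
        out = moderated_significance(z, fdr_method="local")
        assert out["fdr"].between(0, 1).all()
        assert (out["fdr"].iloc[900:] < 0.05).all()

    def test_weights_widen_null_for_sparse_proteins(self):
        rng = np.random.default_rng(5)
        z = pd.Series(rng.normal(0, 1, 1000))
        z.iloc[0] = 3.0
        w = pd.Series(10.0, index=z.index)
        w.iloc[0] = 5.0  # half the temperatures observed -> less precise
        p_weighted = moderated_significance(z, w)["p_value"].iloc[0]
        p_flat = moderated_significance(z)["p_value"].iloc[0]
        assert p_weighted > p_flat


class TestClassify:
    @pytest.mark.parametrize(
        "z, fdr, expected",
        [
            (0.66, 2.6e-4, "unaffected"),   # significant FDR but |z| <= 1.5
            (3.58, 1.8e-14, "stabilized"),
            (4.75, 7.4e-5, "stabilized"),
            (-2.0, 0.5, "unaffected"),       # fails the FDR arm
            (-2.0, 1e-3, "destabilized"),
            (1.5, 1e-3, "unaffected"),       # strict > on |z|
        ],
    )
    def test_three_way_rule(self, z, fdr, expected):
        out = classify(pd.Series([z]), pd.Series([fdr]))
        assert out.iloc[0] == expected


class TestStabilityModel:
    def test_parameter_recovery_and_ranking(self):
        spec = sim.TppSimSpec(n_proteins=500, n_stabilized=25, delta_tm=2.0,
                              noise_cv=0.05, seed=13)
        matrix, truth = sim.gen_tpp(spec)
        res = StabilityModel(matrix, treatment="treatment").fit()
        stab = truth["class"] == "stabilized"
        scores = res.table["stability_score"]
        assert (scores[stab.to_numpy()] > 0).mean() >= 0.95
        assert scores[stab.to_numpy()].median() > scores[(~stab).to_numpy()].median()
        assert "stabilized" in res.summary()

    def test_null_classification_rate(self):
        spec = sim.TppSimSpec(n_proteins=400, noise_cv=0.05, seed=17)
        matrix, _ = sim.gen_tpp(spec)
        res = StabilityModel(matrix, treatment="treatment").fit()
        frac = (res.table["class"] != "unaffected").mean()
        assert frac <= 0.05

    def test_treatment_equal_control_rejected(self):
        matrix, _ = sim.gen_tpp(sim.TppSimSpec(n_proteins=20, seed=1))
        with pytest.raises(ValueError, match="must differ"):
            compute_fold_changes(matrix, "DMSO", "DMSO")
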