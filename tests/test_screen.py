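"""Plate z-scores, Mahalanobis ranking, drift correction, dose-response fits."""

import numpy as np
import pandas as pd
import pytest

from granulizer import simulate as sim
from granulizer.screen import (
    DoseResponseModel,
    PlateScreenModel,
    control_zscores,
    four_param_logistic,
    mahalanobis_score,
    monotone_dose_check,
    time_drift_normalize,
)


def identity_cov_controls():
    # four control wells whose sample covariance (ddof=1) is exactly I
    s = np.sqrt(3) / 2
    return np.array([[s, s], [s, -s], [-s, s], [-s, -s]])


class TestControlZScores:
    def test_controls_center_exactly(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.normal(5, 2, (40, 4)), columns=list("abcd"))
        roles = pd.Series(["control"] * 16 + ["treatment"] * 24)
        z = control_zscores(feats, roles)
        assert np.allclose(z[roles == "control"].mean(), 0.0, atol=1e-12)
        assert np.allclose(z[roles == "control"].std(ddof=1), 1.0, atol=1e-12)

    def test_two_sigma_shift(self):
        feats = pd.DataFrame({"f": [0.0, 2.0, 1.0, 3.0, 1.5 + 2 * np.std([0, 2, 1, 3], ddof=1)]})
        roles = pd.Series(["control"] * 4 + ["treatment"])
        z = control_zscores(feats, roles)
        assert z["f"].iloc[-1] == pytest.approx(2.0)

    def test_constant_feature_dropped(self):
        feats = pd.DataFrame({"ok": [0.0, 1.0, 2.0], "dead": [5.0, 5.0, 5.0]})
        roles = pd.Series(["control"] * 3)
        with pytest.warns(UserWarning, match="dead"):
            z = control_zscores(feats, roles)
        assert list(z.columns) == ["ok"]

    def test_needs_two_controls(self):
        with pytest.raises(ValueError):
            control_zscores(pd.DataFrame({"f": [1.0, 2.0]}),
                            pd.Series(["control", "treatment"]))


class TestMahalanobis:
    def test_single_feature_reduces_to_abs_z(self):
        ctrl = np.array([[1.0], [-1.0], [0.5], [-0.5]])
        z = np.array([-2.2])
        d = mahalanobis_score(z, ctrl, shrinkage=None)
        sd = np.std(ctrl, ddof=1)
        assert d == pytest.approx(abs(z[0]) / sd)

    def test_identity_covariance_euclidean(self):
        d = mahalanobis_score(np.array([3.0, 4.0]), identity_cov_controls(), shrinkage=None)
        assert d == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_matrix_inverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ctrl = rng.normal(0, 1, (40, 5))
        z = rng.normal(0, 2, 5)
        d = mahalanobis_score(z, ctrl, shrinkage=None)
        S = np.cov(ctrl, rowvar=False)
        oracle = float(np.sqrt(z @ np.linalg.inv(S) @ z))
        assert d == pytest.approx(oracle, rel=1e-10)

    def test_eigenvalue_lower_bound(self):
        rng = np.random.default_rng(6)
        ctrl = rng.normal(0, 1, (60, 5))
        z = rng.normal(0, 2, 5)
        S = np.cov(ctrl, rowvar=False)
        lam_max = np.linalg.eigvalsh(S).max()
        d = mahalanobis_score(z, ctrl, shrinkage=None)
        assert d >= np.abs(z).max() / np.sqrt(lam_max) - 1e-12

    def test_too_few_controls_without_shrinkage(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="shrinkage"):
            mahalanobis_score(np.ones(5), rng.normal(0, 1, (4, 5)), shrinkage=None)
        # shrinkage handles the same instance
        assert mahalanobis_score(np.ones(5), rng.normal(0, 1, (4, 5))) > 0

    def test_feature_rescaling_invariance(self):
        # rescaling a raw feature (controls included) is absorbed by the z-scores
        table, _ = sim.gen_plate(n_wells=96, n_controls=24, n_features=5, seed=9)
        res1 = PlateScreenModel(table).fit()
        scaled = table.copy()
        scaled["feat_2"] = scaled["feat_2"] * 37.5
        res2 = PlateScreenModel(scaled).fit()
        merged = res1.table.merge(res2.table, on="well_id", suffixes=("_1", "_2"))
        assert np.allclose(merged["mahalanobis_1"], merged["mahalanobis_2"], rtol=1e-9)


class TestScreenModel:
    def test_planted_hit_top_ranked(self):
        hits = [(5, np.full(15, 4.0))]
        table, truth = sim.gen_plate(n_wells=384, n_controls=32, n_features=15,
                                     hits=hits, seed=10)
        res = PlateScreenModel(table).fit()
        assert res.table.iloc[0]["well_id"] == "plate_1:W0005"
        assert "Mahalanobis" in res.summary()

    def test_top_hits_excludes_controls(self):
        table, _ = sim.gen_plate(n_wells=96, n_controls=48, n_features=5, seed=11)
        res = PlateScreenModel(table).fit()
        assert (res.top_hits(10)["role"] != "control").all()


class TestTimeDrift:
    def test_equal_controls_identity(self):
        vals = np.array([3.0, 5.0, 7.0])
        out = time_drift_normalize(vals, [0, 1, 2], 0, 2, 100.0, 100.0)
        assert np.allclose(out, vals)

    def test_midpoint_reference_interpolates(self):
        # controls 100 (start) and 50 (end): the midpoint reference is 75,
        # so a midpoint value of 75 is mapped onto the row mean 75
        out = time_drift_normalize(np.array([75.0]), [0.5], 0.0, 1.0, 100.0, 50.0)
        assert out[0] == pytest.approx(75.0)

    def test_linear_ramp_flattened(self):
        ts = np.linspace(0, 1, 11)
        drift = 1.0 - 0.5 * ts          # multiplicative decay over the row
        vals = 100.0 * drift            # constant truth of 100 under the drift
        out = time_drift_normalize(vals, ts, 0, 1, vals[0], vals[-1])
        assert np.allclose(out, out[0], rtol=1e-9)

    def test_subtract_mode(self):
        ts = np.linspace(0, 1, 5)
        vals = 10.0 + 4.0 * ts          # additive drift on constant truth
        out = time_drift_normalize(vals, ts, 0, 1, vals[0], vals[-1], mode="subtract")
        assert np.allclose(out, out[0], rtol=1e-9)


class TestMonotoneCheck:
    def test_strictly_decreasing_true(self):
        conc = np.array([1, 3, 10, 30, 100.0])
        assert monotone_dose_check(conc, np.array([9, 7, 5, 3, 1.0]))
        assert monotone_dose_check(conc, np.array([9, 7, 5, 3, 1.0]),
                                   direction="decreasing")
        assert not monotone_dose_check(conc, np.array([9, 7, 5, 3, 1.0]),
                                       direction="increasing")

    def test_permutation_false(self):
        conc = np.array([1, 3, 10, 30, 100, 300, 1000.0])
        resp = np.array([1, 5, 3, 7, 2, 6, 4.0])  # scrambled: rho = 0.36
        assert not monotone_dose_check(conc, resp)

    def test_constant_false(self):
        conc = np.array([1, 3, 10, 30, 100.0])
        assert not monotone_dose_check(conc, np.full(5, 2.0))


class TestDoseResponse:
    def test_noiseless_roundtrip(self):
        curve, truth = sim.gen_dose_response(ec50=2e-6, slope=1.5, noise_cv=0.0, seed=0)
        fit = DoseResponseModel(curve["concentration"].to_numpy(),
                                curve["response"].to_numpy()).fit()
        assert fit.reliable
        assert fit.ec50 == pytest.approx(truth["ec50"], rel=1e-6)
        assert fit.slope == pytest.approx(truth["slope"], rel=1e-4)
        assert "EC50" in fit.summary()

    def test_flat_response_flagged(self):
        conc = 10.0 ** np.arange(-9, -3, 0.5)
        fit = DoseResponseModel(conc, np.full(len(conc), 2.0)).fit()
        assert not fit.reliable
        assert "flat-response" in fit.flags

    def test_out_of_range_ec50_flagged(self):
        curve, _ = sim.gen_dose_response(
            ec50=1e-1, slope=1.5, noise_cv=0.0,
            concentrations=10.0 ** np.arange(-9, -4, 0.5), seed=1,
        )
        fit = DoseResponseModel(curve["concentration"].to_numpy(),
                                curve["response"].to_numpy()).fit()
        assert not fit.reliable

    def test_predict_matches_forward_model(self):
        curve, truth = sim.gen_dose_response(noise_cv=0.0, seed=2)
        fit = DoseResponseModel(curve["concentration"].to_numpy(),
                                curve["response"].to_numpy()).fit()
        x = np.array([1e-8, 1e-6, 1e-4])
        assert np.allclose(fit.predict(x), four_param_logistic(x, **truth), rtol=1e-4)

    def test_needs_five_concentrations(self):
        with pytest.raises(ValueError):
            DoseResponseModel(np.array([1e-9, 1e-8, 1e-7, 1e-6]), np.ones(4))
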