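"""Fit-quality metrics: MSD, observed~predicted r^2, replicate aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phytosed as ps


class TestMedianSquaredDeviation:
    def test_zero_for_identical_vectors(self):
        assert ps.median_squared_deviation([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_odd_length(self):
        # residuals (1, 2, 3) -> squares (1, 4, 9) -> median 4
        assert ps.median_squared_deviation([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]) == 4.0

    def test_even_length_averages_central_order_statistics(self):
        # residuals (1, 3) -> squares (1, 9) -> (1+9)/2 = 5
        assert ps.median_squared_deviation([1.0, 3.0], [0.0, 0.0]) == 5.0

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ps.ValidityError):
            ps.median_squared_deviation([1.0], [1.0, 2.0])
        with pytest.raises(ps.ValidityError):
            ps.median_squared_deviation([], [])

    @settings(derandomize=True, max_examples=50)
    @given(
        res=st.lists(st.floats(-10, 10), min_size=1, max_size=20),
        k=st.floats(0.1, 10),
    )
    def test_permutation_invariant_and_scale_covariant(self, res, k):
        obs = np.asarray(res)
        pred = np.zeros_like(obs)
        msd = ps.median_squared_deviation(obs, pred)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(obs))
        assert ps.median_squared_deviation(obs[perm], pred[perm]) == msd
        assert ps.median_squared_deviation(k * obs, k * pred) == pytest.approx(
            k**2 * msd, rel=1e-9
        )


class TestObservedPredictedR2:
    def test_perfect_fit(self):
        assert ps.observed_predicted_r2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_zero_slope_gives_zero(self):
        # observed orthogonal to predicted: best-fit line is flat
        assert ps.observed_predicted_r2([1.0, -1.0, -1.0, 1.0], [1.0, 2.0, 3.0, 4.0]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(7)
        pred = rng.uniform(0.01, 0.1, 30)
        obs = 1.3 * pred + rng.normal(0, 0.01, 30)
        # textbook formula: r^2 = cov^2 / (var_x var_y)
        sxy = np.sum((pred - pred.mean()) * (obs - obs.mean()))
        expected = sxy**2 / (np.sum((pred - pred.mean()) ** 2) * np.sum((obs - obs.mean()) ** 2))
        assert ps.observed_predicted_r2(obs, pred) == pytest.approx(expected, rel=1e-10)

    def test_affine_rescaling_of_predictor_leaves_r2(self):
        rng = np.random.default_rng(8)
        pred = rng.uniform(0.01, 0.1, 25)
        obs = pred + rng.normal(0, 0.005, 25)
        r1 = ps.observed_predicted_r2(obs, pred)
        r2 = ps.observed_predicted_r2(obs, 3.0 * pred + 0.7)
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ps.ValidityError, match="constant"):
            ps.observed_predicted_r2([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        with pytest.raises(ps.ValidityError):
            ps.observed_predicted_r2([1.0, 2.0], [1.0, 2.0])


class TestAggregateReplicates:
    def frame(self, values, sid="K1"):
        return pd.DataFrame({"specimen_id": sid, "omega": values})

    def test_mean_mode_with_range(self):
        out = ps.aggregate_replicates(self.frame([1.0, 1.0, 1.0]))
        assert out.loc["K1", "omega"] == 1.0
        assert out.loc["K1", "range"] == 0.0

    def test_median_mode_with_type7_quartiles(self):
        out = ps.aggregate_replicates(self.frame([1.0, 2.0, 3.0, 4.0, 5.0]), statistic="median")
        assert out.loc["K1", "omega"] == 3.0
        assert out.loc["K1", "q25"] == 2.0  # linear-interpolation convention
        assert out.loc["K1", "q75"] == 4.0

    def test_seven_replicates_kept(self):
        out = ps.aggregate_replicates(self.frame(list(range(1, 8))))
        assert out.loc["K1", "n"] == 7

    def test_empty_rejected(self):
        with pytest.raises(ps.ValidityError):
            ps.aggregate_replicates(pd.DataFrame(columns=["specimen_id", "omega"]))


def test_evaluation_report_roundtrip():
    rep = ps.evaluate_predictions([0.01, 0.02, 0.05], [0.012, 0.019, 0.048], group="testing")
    d = rep.to_dict()
    assert d["group"] == "testing"
    assert d["n"] == 3
    assert d["msd_m2_s2"] >= 0
    assert 0 <= d["r_squared"] <= 1
    assert rep.residuals == pytest.approx([-0.002, 0.001, 0.002])
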