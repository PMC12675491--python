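"""GA refitting: reproducibility, monotone history, splits, cross-checks."""

import numpy as np
import pandas as pd
import pytest

import phytosed as ps
from phytosed.fitting import default_bounds, observations_frame

from conftest import settling_campaign

REDUCED = dict(population_size=150, stall_window=150, max_generations=5000, elitism=8)


@pytest.fixture(scope="module")
def noiseless_b():
    cfg, traits, obs = settling_campaign("B", n=20, seed=0, noise_cv=0.0)
    model = ps.SedimentationModel.from_tables(traits, obs, structure="B")
    return model


def test_fit_is_reproducible_under_fixed_seed(noiseless_b):
    r1 = noiseless_b.fit(seed=3, **REDUCED)
    r2 = noiseless_b.fit(seed=3, **REDUCED)
    assert r1.params.equals(r2.params)
    assert r1.mse == r2.mse
    np.testing.assert_array_equal(r1.history, r2.history)


def test_best_objective_history_is_non_increasing(noiseless_b):
    res = noiseless_b.fit(seed=1, **REDUCED)
    assert np.all(np.diff(res.history) <= 0)
    assert res.mse == res.history[-1]


def test_underdetermined_and_empty_observations_rejected():
    cfg, traits, obs = settling_campaign("C", n=3, seed=2, noise_cv=0.0)
    model_data = ps.SedimentationModel.from_tables(traits, obs, structure="C").data
    with pytest.raises(ps.ValidityError, match="underdetermined"):
        ps.fit_model("C", model_data, ps.GAConfig(**REDUCED))
    with pytest.raises(ps.ValidityError):
        ps.fit_model("B", model_data.iloc[:0], ps.GAConfig(**REDUCED))


def test_floating_observations_rejected():
    cfg, traits, obs = settling_campaign("B", n=10, seed=2, noise_cv=0.0)
    data = ps.SedimentationModel.from_tables(traits, obs, structure="B").data.copy()
    data.loc[0, "rho"] = data.loc[0, "rho_sw"] - 1.0
    with pytest.raises(ps.ValidityError, match="non-sinking"):
        ps.fit_model("B", data, ps.GAConfig(**REDUCED))


def test_ga_config_validation():
    with pytest.raises(ps.ValidityError):
        ps.GAConfig(crossover_prob=1.5)
    with pytest.raises(ps.ValidityError):
        ps.GAConfig(population_size=100, elitism=100)
    with pytest.raises(ps.ValidityError):
        ps.GAConfig(max_generations=10, stall_window=100)


def test_default_bounds_bracket_presets_log_symmetrically():
    for structure in ("A", "B", "C"):
        bounds = default_bounds(structure)
        for name, value in ps.preset(structure).as_dict().items():
            lo, hi = bounds[name]
            assert lo < value < hi


def test_ga_agrees_with_differential_evolution(noiseless_b):
    """Independent optimizer cross-check on the same MSE objective."""
    from scipy.optimize import differential_evolution

    data = noiseless_b.data
    from phytosed.models import evaluate_structure

    def mse(log_k):
        w, _, _ = evaluate_structure(
            "B", np.array([10.0 ** log_k[0]]),
            data["d_n"].to_numpy(), data["s_f"].to_numpy(), data["rho"].to_numpy(),
            data["rho_sw"].to_numpy(), data["nu"].to_numpy(), data["g"].to_numpy(),
        )
        return float(np.mean((w - data["omega"].to_numpy()) ** 2))

    de = differential_evolution(mse, [(1.0, 7.0)], seed=0, tol=1e-12)
    ga = noiseless_b.fit(seed=0, **REDUCED)
    assert 10.0 ** de.x[0] == pytest.approx(ga.params["k_drag"], rel=1e-4)


def test_observations_frame_accepts_tuples(median_medium):
    from test_models import make_traits

    t = make_traits(0.02, 0.01, 1104.44)
    df = observations_frame([(t, median_medium, 0.05)])
    assert df.loc[0, "omega"] == 0.05
    assert df.loc[0, "rho_sw"] == median_medium.rho_sw


class TestSplit:
    def frame(self, n):
        return pd.DataFrame(
            {"specimen_id": [f"S{i}" for i in range(n)], "omega": np.arange(n, dtype=float)}
        )

    def test_20_29_partition(self):
        obs = self.frame(49)
        labels = pd.Series(
            ["modeling"] * 20 + ["testing"] * 29, index=[f"S{i}" for i in range(49)]
        )
        modeling, testing = ps.split_modeling_testing(obs, labels)
        assert (len(modeling), len(testing)) == (20, 29)
        assert set(modeling["specimen_id"]).isdisjoint(testing["specimen_id"])

    def test_all_modeling_warns_on_empty_testing(self):
        obs = self.frame(3)
        labels = pd.Series(["modeling"] * 3, index=["S0", "S1", "S2"])
        with pytest.warns(UserWarning, match="empty"):
            ps.split_modeling_testing(obs, labels)

    def test_unknown_label_and_duplicates_rejected(self):
        obs = self.frame(2)
        with pytest.raises(ps.ValidityError, match="unknown split labels"):
            ps.split_modeling_testing(obs, pd.Series(["holdout", "modeling"], index=["S0", "S1"]))
        dup = pd.Series(["modeling", "testing"], index=["S0", "S0"])
        with pytest.raises(ps.ValidityError, match="more than once"):
            ps.split_modeling_testing(self.frame(1), dup)
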