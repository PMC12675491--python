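"""Model/Results front-end for fitting and using the settling models.

:class:`SedimentationModel` holds the observation data and the chosen
model structure; :meth:`~SedimentationModel.fit` runs the genetic
algorithm and returns a :class:`SedimentationResults` carrying the
fitted constants, the objective trajectory, evaluation metrics and a
``summary()`` table.  Prediction, evaluation on held-out data,
simulation of synthetic campaigns and plotting hang off these two
objects; the underlying building blocks remain available as functions
in :mod:`phytosed.models`, :mod:`phytosed.fitting` and
:mod:`phytosed.evaluation`.

Example
-------
>>> from phytosed import SedimentationModel, synthetic
>>> cfg = synthetic.SyntheticConfig(n_specimens=20, seed=7, noise_cv=0.0,
...                                 generating_model=models.MODEL_B)
>>> traits = synthetic.generate_specimens(cfg)
>>> obs = synthetic.generate_observations(traits, cfg)
>>> model = SedimentationModel.from_tables(traits, obs, structure="B")
>>> res = model.fit(seed=1, population_size=200, stall_window=200,
...                 max_generations=20000, elitism=10)
>>> round(res.params["k_drag"] / 4146.337, 3)
1.0
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, aggregate_replicates, evaluate_predictions
from .exceptions import ValidityError
from .fitting import FitResult, GAConfig, fit_model, observations_frame
from .medium import MediumProperties
from .models import ModelSpec, evaluate_structure, preset

__all__ = ["SedimentationModel", "SedimentationResults"]


class SedimentationModel:
    """A settling-velocity model structure bound to observation data.

    Parameters
    ----------
    data : DataFrame
        One row per specimen with columns
        ``d_n, s_f, rho, rho_sw, nu, g, omega`` (SI; ``omega`` is the
        replicate-aggregated observed settling velocity).
    structure : {"A", "B", "C"}
        Which drag closure to fit (see :mod:`phytosed.models`).
    """

    def __init__(self, data: pd.DataFrame, structure: str = "C"):
        self.data = observations_frame(data)
        self.structure = structure
        preset(structure)  # validates the structure name

    @classmethod
    def from_tables(
        cls,
        traits: pd.DataFrame,
        observations: pd.DataFrame,
        structure: str = "C",
        statistic: str = "mean",
    ) -> "SedimentationModel":
        """Build from a trait table and a replicate observation table.

        Replicates are aggregated per specimen (mean by default), merged
        with the derived traits, and floating specimens are dropped.
        """
        obs = observations[~observations["floating"].astype(bool)]
        if obs.empty:
            raise ValidityError("no sinking specimens in the observation table")
        agg = aggregate_replicates(obs, statistic=statistic).reset_index()
        media = obs.groupby("specimen_id")[["rho_sw", "nu", "g"]].mean().reset_index()
        cols = ["specimen_id", "d_n", "s_f", "rho"]
        merged = traits[cols].merge(agg[["specimen_id", "omega"]], on="specimen_id")
        merged = merged.merge(media, on="specimen_id")
        merged = merged[merged["rho"] > merged["rho_sw"]].reset_index(drop=True)
        return cls(merged, structure=structure)

    def predict(self, params, data: pd.DataFrame | None = None) -> np.ndarray:
        """Model velocities for a constant vector; NaN where out of domain."""
        df = self.data if data is None else observations_frame(data)
        omega, _, _ = evaluate_structure(
            self.structure,
            np.asarray(params, dtype=float),
            df["d_n"].to_numpy(),
            df["s_f"].to_numpy(),
            df["rho"].to_numpy(),
            df["rho_sw"].to_numpy(),
            df["nu"].to_numpy(),
            df["g"].to_numpy(),
        )
        return omega

    def fit(self, config: GAConfig | None = None, seed: int | None = None, **ga_kwargs):
        """Fit the constants by GA; keyword arguments override GAConfig fields."""
        if config is None:
            config = GAConfig(seed=seed, **ga_kwargs)
        elif ga_kwargs or seed is not None:
            raise ValidityError("pass either a GAConfig or keyword overrides, not both")
        fit = fit_model(self.structure, self.data, config)
        return SedimentationResults(self, fit)

    def results_from_spec(self, spec: ModelSpec) -> "SedimentationResults":
        """Results object for fixed (e.g. published preset) constants."""
        if spec.structure != self.structure:
            raise ValidityError(
                f"spec structure {spec.structure} does not match model {self.structure}"
            )
        pred = self.predict(np.asarray(spec.constants))
        ok = np.isfinite(pred)
        mse = float(np.mean((pred[ok] - self.data["omega"].to_numpy()[ok]) ** 2))
        fit = FitResult(
            model=spec,
            objective=mse,
            history=np.array([mse]),
            converged=True,
            n_obs=int(ok.sum()),
            generations=0,
            out_of_domain_penalty_hits=int((~ok).sum()),
        )
        return SedimentationResults(self, fit)


class SedimentationResults:
    """Fitted constants plus diagnostics for a :class:`SedimentationModel`."""

    def __init__(self, model: SedimentationModel, fit: FitResult):
        self.model = model
        self.fit_result = fit
        self.spec = fit.model
        self.params = fit.params
        self.mse = fit.objective
        self.history = fit.history
        self.converged = fit.converged
        self.nobs = fit.n_obs
        self._report = self._evaluate(model.data, "fit")

    def _evaluate(self, data: pd.DataFrame, group: str) -> EvaluationReport:
        pred = self.model.predict(self.params.to_numpy(), data)
        ok = np.isfinite(pred)
        return evaluate_predictions(data["omega"].to_numpy()[ok], pred[ok], group=group)

    @property
    def msd(self) -> float:
        """Median squared deviation on the fitting data, m^2 s^-2."""
        return self._report.msd

    @property
    def rsquared(self) -> float | None:
        """r^2 of observed ~ predicted on the fitting data."""
        return self._report.r_squared

    def predict(self, data: pd.DataFrame | None = None) -> np.ndarray:
        return self.model.predict(self.params.to_numpy(), data)

    def evaluate(self, data: pd.DataFrame, group: str = "testing") -> EvaluationReport:
        """Metric report (MSD, MSE, r^2) on held-out observations."""
        return self._evaluate(observations_frame(data), group)

    def prediction_surface(self, medium: MediumProperties, rho, d_n_grid, s_f_grid):
        from .models import prediction_surface

        return prediction_surface(self.spec, medium, rho, d_n_grid, s_f_grid)

    def plot_observed_predicted(self, ax=None):
        """Observed vs predicted scatter with the 1:1 line (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pred = self.predict()
        obs = self.model.data["omega"].to_numpy()
        ax.scatter(pred, obs, s=18)
        lim = [0, max(np.nanmax(pred), obs.max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("predicted $\\omega$ (m s$^{-1}$)")
        ax.set_ylabel("observed $\\omega$ (m s$^{-1}$)")
        ax.set_title(f"Model {self.spec.structure}")
        return ax

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Sedimentation velocity model results",
            "=" * 52,
            f"Structure:            Model {self.spec.structure}",
            f"No. observations:     {self.nobs}",
            f"GA generations:       {self.fit_result.generations}",
            f"Converged (stall):    {self.converged}",
            f"Objective MSE:        {self.mse:.6g} m^2 s^-2",
            f"MSD:                  {self.msd:.6g} m^2 s^-2",
            f"r^2 (obs ~ pred):     "
            + ("n/a" if self.rsquared is None else f"{self.rsquared:.4f}"),
            f"Out-of-domain hits:   {self.fit_result.out_of_domain_penalty_hits}",
            "-" * 52,
            f"{'constant':<12}{'estimate':>18}",
        ]
        for name, value in self.params.items():
            lines.append(f"{name:<12}{value:>18.7g}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<SedimentationResults structure={self.spec.structure} "
            f"mse={self.mse:.3g} nobs={self.nobs}>"
        )
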