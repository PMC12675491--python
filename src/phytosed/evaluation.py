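"""Fit-quality metrics and evaluation reports.

Two headline metrics quantify how well a model predicts observed
settling velocities:

* median squared deviation (MSD): the median of the per-specimen squared
  residuals (observed - predicted)^2, in m^2 s^-2 — robust to the few
  specimens a model gets badly wrong;
* r^2 of the ordinary least-squares line of observed on predicted.

The GA objective is the *mean* squared error, so reports carry both MSE
and MSD.  Replicate velocity measurements are aggregated per specimen
before evaluation (mean with ranges, or median with quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SchemaError, ValidityError

__all__ = [
    "EvaluationReport",
    "median_squared_deviation",
    "mean_squared_error",
    "observed_predicted_r2",
    "aggregate_replicates",
    "evaluate_predictions",
    "dataset_report",
]


def _paired(observed, predicted):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValidityError(
            f"observed and predicted must be 1-d and equal length, got "
            f"{obs.shape} vs {pred.shape}"
        )
    if obs.size == 0:
        raise ValidityError("empty vectors")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValidityError("non-finite values in observed/predicted")
    return obs, pred


def median_squared_deviation(observed, predicted) -> float:
    """Median of squared residuals, m^2 s^-2.

    Even-length inputs use the usual convention: mean of the two central
    order statistics.
    """
    obs, pred = _paired(observed, predicted)
    return float(np.median((obs - pred) ** 2))


def mean_squared_error(observed, predicted) -> float:
    """Mean of squared residuals (the GA objective), m^2 s^-2."""
    obs, pred = _paired(observed, predicted)
    return float(np.mean((obs - pred) ** 2))


def observed_predicted_r2(observed, predicted) -> float:
    """r^2 of the OLS line of observed on predicted velocities."""
    obs, pred = _paired(observed, predicted)
    if obs.size < 3:
        raise ValidityError("need at least 3 points for a linear fit")
    if np.ptp(pred) == 0:
        raise ValidityError("predicted velocities are constant: r^2 undefined")
    res = stats.linregress(pred, obs)
    return float(res.rvalue**2)


def aggregate_replicates(
    replicates: pd.DataFrame,
    statistic: str = "mean",
    id_col: str = "specimen_id",
    value_col: str = "omega",
) -> pd.DataFrame:
    """Aggregate replicate velocities to one value per specimen.

    ``statistic="mean"`` reports the mean with the range (max - min);
    ``"median"`` reports the median with linearly interpolated quartiles
    (type-7 convention).  Returns a frame indexed by specimen with
    columns ``omega``, ``n`` and the dispersion columns.
    """
    if statistic not in ("mean", "median"):
        raise ValidityError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    if replicates.empty:
        raise ValidityError("no replicate rows supplied")
    grouped = replicates.groupby(id_col)[value_col]
    if statistic == "mean":
        out = grouped.agg(omega="mean", n="count")
        out["range"] = grouped.max() - grouped.min()
    else:
        out = grouped.agg(omega="median", n="count")
        out["q25"] = grouped.quantile(0.25)  # type-7 linear interpolation
        out["q75"] = grouped.quantile(0.75)
    return out


@dataclass
class EvaluationReport:
    """Metrics of one observed-vs-predicted comparison."""

    group: str
    msd: float
    mse: float
    r_squared: float | None
    n: int
    residuals: np.ndarray = field(repr=False)
    quartile_convention: str = "linear (type 7)"

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "msd_m2_s2": self.msd,
            "mse_m2_s2": self.mse,
            "r_squared": self.r_squared,
            "n": self.n,
            "quartile_convention": self.quartile_convention,
        }


def evaluate_predictions(observed, predicted, group: str = "") -> EvaluationReport:
    """Assemble the full metric report for one specimen group."""
    obs, pred = _paired(observed, predicted)
    try:
        r2 = observed_predicted_r2(obs, pred)
    except ValidityError:
        r2 = None
    return EvaluationReport(
        group=group,
        msd=median_squared_deviation(obs, pred),
        mse=mean_squared_error(obs, pred),
        r_squared=r2,
        n=obs.size,
        residuals=obs - pred,
    )


def dataset_report(
    traits_path,
    observations_path,
    split_path=None,
    structures=("A", "B", "C"),
    statistic: str = "mean",
) -> dict:
    """Opt-in integration report against a deposited measurement dataset.

    Reads trait and observation tables from disk (the deposited raw data
    are not shipped with the package), predicts settling velocities with
    the shipped preset constants for each requested structure, and
    returns MSD/MSE/r^2 per group.  Out-of-domain specimens (e.g.
    sphere-like plastics under structure C) are excluded per group and
    counted.  This is never run by the default test-suite; it exists so
    the published dataset-level metrics can be recomputed when the data
    are available locally.
    """
    from . import io as _io
    from .fitting import split_modeling_testing
    from .models import evaluate_structure, preset

    traits = _io.read_trait_table(traits_path)
    obs = _io.read_observation_table(observations_path)
    per_specimen = aggregate_replicates(obs, statistic=statistic).reset_index()
    merged = traits.merge(per_specimen, on="specimen_id")
    medium_cols = obs.groupby("specimen_id")[["rho_sw", "nu", "g"]].mean()
    merged = merged.merge(medium_cols, on="specimen_id")
    merged = merged[merged["rho"] > merged["rho_sw"]].reset_index(drop=True)
    if merged.empty:
        raise SchemaError("no sinking specimens after merging traits and observations")

    groups = {"all": merged}
    if split_path is not None:
        split = pd.read_csv(split_path).set_index("specimen_id")["group"]
        modeling, testing = split_modeling_testing(merged, split)
        groups = {"modeling": modeling, "testing": testing}

    report: dict = {"statistic": statistic, "structures": {}}
    for structure in structures:
        spec = preset(structure)
        entry = {}
        for name, frame in groups.items():
            omega, _, ok = evaluate_structure(
                structure,
                np.asarray(spec.constants),
                frame["d_n"].to_numpy(),
                frame["s_f"].to_numpy(),
                frame["rho"].to_numpy(),
                frame["rho_sw"].to_numpy(),
                frame["nu"].to_numpy(),
                frame["g"].to_numpy(),
            )
            sub = frame[ok]
            rep = evaluate_predictions(sub["omega"].to_numpy(), omega[ok], group=name)
            d = rep.to_dict()
            d["n_out_of_domain"] = int((~ok).sum())
            entry[name] = d
        report["structures"][structure] = entry
    return report
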