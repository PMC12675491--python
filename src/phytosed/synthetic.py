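"""Synthetic trait tables and settling observations.

The deposited raw measurements are not required to exercise the
pipeline: this module draws specimen populations with the statistical
structure of the original study and simulates replicate settling
measurements from a chosen generating model.

Study conditions emulated by the defaults
-----------------------------------------
* nominal diameters log-uniform over 0.576-4.844 cm (the measured span);
* shape factors log-uniform over 0.00029-0.0689 (macrophyte span; a
  plastic mode extends the upper end towards 1 for sphere-like objects);
* particle densities lognormal around the study median 1104.44 kg m^-3;
* the medium fixed at the study-median conditions
  (rho_sw = 1009.45 kg m^-3, nu = 1.0915e-6 m^2 s^-1);
* 5 replicate velocity measurements per specimen with multiplicative
  lognormal noise of coefficient of variation 0.1 (replicate spread in
  the measurements scales with velocity, and velocities stay positive).

s_f, d_n and rho are drawn independently; any covariance between traits
in real populations is not emulated.  Morphology routes are assigned
from the drawn shape factor (flattened below s_f = 0.01, branched
above), and the raw route fields (projection area, branch width, axes)
are back-computed so that the derivation routes reproduce the drawn
values exactly — which makes the generator a closed-loop oracle for the
trait module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidityError
from .medium import MediumProperties, STUDY_MEDIAN_MEDIUM
from .models import MODEL_C, ModelSpec, evaluate_structure
from .traits import volume_from_nominal_diameter

__all__ = ["SyntheticConfig", "generate_specimens", "generate_observations"]

_RESAMPLE_CAP = 100


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study population (defaults = study conditions)."""

    n_specimens: int = 49
    seed: int | None = None
    d_n_range: tuple = (0.00576, 0.04844)  # m
    s_f_range: tuple = (0.00029, 0.0689)
    rho_median: float = 1104.44  # kg m^-3
    rho_sigma_log: float = 0.03  # lognormal spread of particle density
    medium: MediumProperties = field(default_factory=lambda: STUDY_MEDIAN_MEDIUM)
    generating_model: ModelSpec = field(default_factory=lambda: MODEL_C)
    noise_cv: float = 0.1
    replicates: int = 5
    plastic_mode: bool = False

    def __post_init__(self) -> None:
        for name in ("d_n_range", "s_f_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValidityError(f"{name} must be positive and ordered, got {(lo, hi)}")
        if self.s_f_range[1] > 1.0:
            raise ValidityError("s_f_range upper bound cannot exceed 1")
        if self.noise_cv < 0:
            raise ValidityError("noise_cv must be non-negative")
        if self.n_specimens < 1 or self.replicates < 1:
            raise ValidityError("n_specimens and replicates must be at least 1")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def _drag_in_domain(config: SyntheticConfig, d_n: float, s_f: float) -> bool:
    # domain of the drag base depends only on (d_n, s_f, nu, g); probe
    # with a surely-sinking density so buoyancy does not interfere
    m = config.medium
    _, _, ok = evaluate_structure(
        config.generating_model.structure,
        np.asarray(config.generating_model.constants),
        np.array([d_n]),
        np.array([s_f]),
        np.array([m.rho_sw * 1.01]),
        m.rho_sw,
        m.nu,
        m.g,
    )
    return bool(ok[0])


def generate_specimens(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a specimen trait table.

    Returns one row per specimen with the raw route fields and the
    derived descriptors (rho, d_n, s_f, morphology route).  Specimens
    whose (d_n, s_f) fall outside the generating model's drag domain are
    resampled (at most 100 attempts each, then an error), so the table
    is always evaluable under ``config.generating_model``; the number of
    resampled draws is recorded in ``df.attrs["n_resampled"]``.
    Reproducible under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sf_hi = 1.0 if config.plastic_mode else config.s_f_range[1]
    sf_lo = config.s_f_range[0]
    rows = []
    n_resampled = 0
    for i in range(config.n_specimens):
        for attempt in range(_RESAMPLE_CAP):
            d_n = float(np.exp(rng.uniform(*np.log(config.d_n_range))))
            s_f = float(np.exp(rng.uniform(np.log(sf_lo), np.log(sf_hi))))
            if _drag_in_domain(config, d_n, s_f):
                break
            n_resampled += 1
        else:
            raise ValidityError(
                f"could not draw an in-domain specimen after {_RESAMPLE_CAP} "
                "attempts; narrow s_f_range or change the generating model"
            )
        rho = float(config.rho_median * np.exp(rng.normal(0.0, config.rho_sigma_log)))
        volume = volume_from_nominal_diameter(d_n)
        wet_weight = rho * volume
        # back-compute route fields from (V, s_f): c = (s_f * sqrt(V))^(2/3)
        c = float((s_f * np.sqrt(volume)) ** (2.0 / 3.0))
        ab = volume / c
        row = {
            "specimen_id": f"SYN{i + 1:03d}",
            "species": "synthetic",
            "volume": volume,
            "wet_weight": wet_weight,
            "rho": rho,
            "d_n": d_n,
            "s_f": s_f,
            "projection_area": np.nan,
            "branch_width": np.nan,
            "axis_a": np.nan,
            "axis_b": np.nan,
            "axis_c": np.nan,
        }
        if config.plastic_mode:
            row["morphology"] = "direct_axes"
            row["axis_a"] = row["axis_b"] = float(np.sqrt(ab))
            row["axis_c"] = c
        elif s_f < 0.01:
            row["morphology"] = "flattened"
            row["projection_area"] = ab
        else:
            row["morphology"] = "cylindrical_or_branched"
            row["branch_width"] = c
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_resampled"] = n_resampled
    return df


def generate_observations(traits: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Simulate replicate settling measurements for a trait table.

    Per sinking specimen, ``config.replicates`` velocities are drawn as
    the generating model's omega times lognormal multiplicative noise
    with mean 1 and coefficient of variation ``config.noise_cv``
    (``noise_cv = 0`` returns the exact model velocities).  Floating
    specimens (rho <= rho_sw) are emitted as a single flagged row with
    no velocity.  Columns: specimen_id, replicate, omega, rho_sw, nu,
    g, floating.
    """
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    m = config.medium
    spec = config.generating_model
    sinking = traits["rho"].to_numpy() > m.rho_sw
    omega_true = np.full(len(traits), np.nan)
    if sinking.any():
        omega, _, ok = evaluate_structure(
            spec.structure,
            np.asarray(spec.constants),
            traits.loc[sinking, "d_n"].to_numpy(),
            traits.loc[sinking, "s_f"].to_numpy(),
            traits.loc[sinking, "rho"].to_numpy(),
            m.rho_sw,
            m.nu,
            m.g,
        )
        if not ok.all():
            bad = traits.loc[sinking].loc[~ok, "specimen_id"].tolist()
            raise ValidityError(
                f"generating model out of domain for specimens {bad}; "
                "regenerate the trait table with this model as generating_model"
            )
        omega_true[sinking] = omega
    if config.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
        mu = -0.5 * sigma**2
    rows = []
    for i, rec in traits.reset_index(drop=True).iterrows():
        if not sinking[i]:
            rows.append(
                {
                    "specimen_id": rec["specimen_id"],
                    "replicate": 0,
                    "omega": np.nan,
                    "rho_sw": m.rho_sw,
                    "nu": m.nu,
                    "g": m.g,
                    "floating": True,
                }
            )
            continue
        if config.noise_cv > 0:
            noise = np.exp(rng.normal(mu, sigma, size=config.replicates))
        else:
            noise = np.ones(config.replicates)
        for r, w in enumerate(omega_true[i] * noise, start=1):
            rows.append(
                {
                    "specimen_id": rec["specimen_id"],
                    "replicate": r,
                    "omega": float(w),
                    "rho_sw": m.rho_sw,
                    "nu": m.nu,
                    "g": m.g,
                    "floating": False,
                }
            )
    return pd.DataFrame(rows)
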