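import math

import numpy as np
import pytest

import phytosed as ps

#: shape-factor span of the negatively buoyant (settling) specimens; the
#: full trait spectrum extends to 0.0689 but only sinking specimens
#: contribute velocity observations
SINKING_SF_RANGE = (0.00029, 0.0278)


@pytest.fixture(scope="session")
def median_medium():
    """Study-median medium: rho_sw = 1009.45 kg/m^3, nu = 1.0915e-6 m^2/s."""
    return ps.STUDY_MEDIAN_MEDIUM


def settling_campaign(structure="B", n=20, seed=0, noise_cv=0.0, replicates=5):
    """Synthetic settling campaign over the sinking-specimen trait range."""
    cfg = ps.SyntheticConfig(
        n_specimens=n,
        seed=seed,
        noise_cv=noise_cv,
        replicates=replicates,
        generating_model=ps.preset(structure),
        s_f_range=SINKING_SF_RANGE,
    )
    traits = ps.generate_specimens(cfg)
    obs = ps.generate_observations(traits, cfg)
    return cfg, traits, obs


def oracle_omega(structure, constants, d_n, s_f, rho, rho_sw, nu, g):
    """Independent scalar re-evaluation of the settling models.

    Written with the math module against the printed formulas, computing
    the square root in the log domain; deliberately shares no code with
    phytosed.models.
    """
    log_num = (
        math.log(4.0 / 3.0)
        + math.log(rho / rho_sw - 1.0)
        + math.log(g)
        + math.log(d_n)
    )
    if structure == "A":
        log_cd = math.log(constants[0]) + math.log(nu) - math.log(d_n) - math.log(g)
    elif structure == "B":
        log_num += (2.0 / 3.0) * math.log(s_f)
        log_cd = (
            math.log(constants[0])
            + math.log(nu)
            - 1.5 * math.log(d_n)
            - 0.5 * math.log(g)
        )
    elif structure == "C":
        k0, k1, k2, k3, p3, k4, p4, po = constants
        lam = nu / (d_n**1.5 * math.sqrt(g))
        base = (
            (k0 + k1 * s_f) * lam
            + k2
            - k3 * math.exp(p3 * math.log(s_f))
            - k4 * math.exp(p4 * math.log(s_f))
        )
        if base <= 0:
            return None
        log_num += (2.0 / 3.0) * math.log(s_f)
        log_cd = po * math.log(base)
    else:
        raise ValueError(structure)
    return math.exp(0.5 * (log_num - log_cd))


def random_in_domain_inputs(rng, n, structure="C"):
    """Random SI inputs inside every model's domain (sinking, base > 0)."""
    rows = []
    while len(rows) < n:
        d_n = float(np.exp(rng.uniform(np.log(0.00576), np.log(0.04844))))
        s_f = float(np.exp(rng.uniform(np.log(0.00029), np.log(0.0689))))
        rho_sw = float(rng.uniform(1000.0, 1030.0))
        rho = rho_sw * float(rng.uniform(1.01, 1.25))
        nu = float(rng.uniform(0.9e-6, 1.5e-6))
        g = 9.81
        if structure == "C":
            if oracle_omega("C", ps.MODEL_C.constants, d_n, s_f, rho, rho_sw, nu, g) is None:
                continue
        rows.append((d_n, s_f, rho, rho_sw, nu, g))
    return rows
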