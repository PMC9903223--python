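"""Shared fixtures: synthetic subjects and a numerical ODE oracle for the
analytic compartment solutions."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import duokin as dk


@pytest.fixture(scope="session")
def schedule():
    return dk.make_frame_schedule()


@pytest.fixture(scope="session")
def clean_subject():
    """One noiseless subject under default study conditions."""
    return dk.generate_subject(dk.CohortConfig(seed=42, noise_scale=0.0), 1)


@pytest.fixture(scope="session")
def noisy_subject():
    """One subject with default frame noise."""
    return dk.generate_subject(dk.CohortConfig(seed=7), 0)


def ode_tissue(params: dk.KineticParameters, inputs, kind: str) -> np.ndarray:
    """Independent oracle: adaptive-step ODE integration of the compartment
    system with piecewise-linear inputs (same input representation as the
    analytic path, so differences measure solution error only)."""
    t = inputs.t_s / 60.0
    cp, cm, wb = inputs.parent_plasma, inputs.metabolite_plasma, inputs.whole_blood
    spec = dk.ModelSpec(kind, {"k4": params.k4} if kind.endswith("_k4fix") else {})
    two_tissue = kind.startswith("2T")
    dual = spec.uses_metabolite_input

    def rhs(tt, y):
        cpv = np.interp(tt, t, cp)
        out = []
        if two_tissue:
            c1, c2 = y[0], y[1]
            out.append(params.K1p * cpv - (params.k2p + params.k3) * c1 + params.k4 * c2)
            out.append(params.k3 * c1 - params.k4 * c2)
        else:
            out.append(params.K1p * cpv - params.k2p * y[0])
        if dual:
            cmv = np.interp(tt, t, cm)
            out.append(params.K1m * cmv - params.k2m * y[-1])
        return out

    n_state = (2 if two_tissue else 1) + (1 if dual else 0)
    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        np.zeros(n_state),
        t_eval=t,
        rtol=1e-10,
        atol=1e-13,
        max_step=2.0 / 60.0,
        method="LSODA",
    )
    tissue = sol.y.sum(axis=0)
    return (1.0 - params.vb) * tissue + params.vb * wb
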