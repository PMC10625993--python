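"""Shared fixtures.

The expensive benchmark runs (bluff-body shedding, 3D pipe) are computed
once per session and shared by the acceptance tests that interrogate
different aspects of the same trajectories.
"""

import numpy as np
import pytest

from tcflow.assembly import State
from tcflow.cases import build_case, load_config, run_square_transient
from tcflow.postprocess import pressure_drop
from tcflow.timeint import solve_steady


@pytest.fixture(scope="session")
def channel_sweep():
    """Steady channel dP/dP_ref for both formulations across dt."""
    out = {}
    for form in ("present", "conventional"):
        for dt in (1e-2, 1e-3, 1e-4):
            cfg = load_config("channel2d", {"formulation": form, "dt": dt})
            s = build_case(cfg)
            st = solve_steady(s.ctx, s.props, s.bcs, s.cfg)
            out[(form, dt)] = pressure_drop(st, s.mesh) / s.reference["dp_ref"]
    return out


def _poiseuille_interpolant(mesh, Q=10.0, R=1.0):
    r2 = mesh.nodes[:, 0] ** 2 + mesh.nodes[:, 1] ** 2
    u = np.zeros((mesh.n_nodes, 3))
    u[:, 2] = (2 * Q / (np.pi * R**2)) * np.maximum(1 - r2 / R**2, 0.0)
    return State(u, np.zeros(mesh.n_nodes), np.zeros_like(u), 0.0)


@pytest.fixture(scope="session")
def pipe_steady():
    """Steady pipe dP/dP_ref at Re=1000, dt=1e-4, for both formulations.

    The Newton solve is warm-started from the analytic Poiseuille
    interpolant; the converged fixed point does not depend on the start.
    """
    out = {}
    for form in ("present", "conventional"):
        cfg = load_config("pipe3d", {"formulation": form, "dt": 1e-4,
                                     "Re": 1000})
        s = build_case(cfg)
        init = _poiseuille_interpolant(s.mesh)
        st = solve_steady(s.ctx, s.props, s.bcs, s.cfg, initial=init,
                          tol_rel=1e-7)
        ref = s.reference["poiseuille"].dP_ref
        out[form] = pressure_drop(st, s.mesh) / ref
    return out


@pytest.fixture(scope="session")
def square_runs():
    """Full desk-scale bluff-body runs: present at two dt values plus the
    conventional formulation at the smaller dt, each integrated to t = 5 s
    from a zero initial state with the start-up protocol of the preset."""
    out = {}
    for key, overrides in {
        "present_4e3": {"dt": 4e-3, "t_end": 5.0},
        "present_6e3": {"dt": 6e-3, "t_end": 5.0},
        "conventional_4e3": {"dt": 4e-3, "t_end": 5.0,
                             "formulation": "conventional"},
    }.items():
        cfg = load_config("square2d", overrides)
        s = build_case(cfg)
        out[key] = run_square_transient(s, cfg)
    return out


@pytest.fixture(scope="session")
def mms_study():
    from tcflow.cases import CaseConfig, run_mms_convergence

    return run_mms_convergence(CaseConfig("mms"))
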