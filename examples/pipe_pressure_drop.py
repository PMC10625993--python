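"""Steady pipe flow at Re = 1000: pressure drop against Hagen-Poiseuille.

Computes the dt-dependent steady solution of both tau formulations at
dt = 1e-4 s on the desk-scale pipe and compares the predicted pressure
drop with the analytic reference dP = 8 mu L Q / (pi R^4).  The Newton
solve is warm-started from the parabolic interpolant; the converged fixed
point does not depend on the start.  Takes a minute or two.
"""

import numpy as np

from tcflow.assembly import State
from tcflow.cases import build_case, load_config
from tcflow.postprocess import pressure_drop
from tcflow.timeint import solve_steady

for form in ("present", "conventional"):
    cfg = load_config("pipe3d", {"formulation": form, "dt": 1e-4,
                                 "Re": 1000})
    setup = build_case(cfg)
    mesh = setup.mesh
    r2 = mesh.nodes[:, 0]**2 + mesh.nodes[:, 1]**2
    u0 = np.zeros((mesh.n_nodes, 3))
    u0[:, 2] = (20.0 / np.pi) * np.maximum(1 - r2, 0.0)
    init = State(u0, np.zeros(mesh.n_nodes), np.zeros_like(u0), 0.0)
    state = solve_steady(setup.ctx, setup.props, setup.bcs, setup.cfg,
                         initial=init, tol_rel=1e-7)
    ref = setup.reference["poiseuille"]
    ratio = pressure_drop(state, mesh) / ref.dP_ref
    print(f"{form:>14}: dP/dP_ref = {ratio:.4f}  (Re = {ref.Re:.0f}, "
          f"{mesh.n_el} tets)")

print("\nAt dt = 1e-4 s the conventional formulation over-predicts the "
      "pressure drop several-fold (grad-div locking as tau -> dt/2); the "
      "present formulation stays within a few percent of the analytical "
      "solution.")
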