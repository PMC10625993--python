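"""Time history of the global flow frequency for a flow reaching steady
state.

omega = ||du/dt|| / ||u|| starts at the 2/dt fallback and decays toward
zero as the channel flow develops — the behavior that makes the present
tau formulation recover the steady advective stabilization regardless of
the time step size.
"""

from tcflow.assembly import State
from tcflow.cases import build_case, load_config
from tcflow.timeint import run_transient

cfg = load_config("channel2d", {"formulation": "present", "dt": 0.05})
setup = build_case(cfg)
state, diags, om = run_transient(State.zero(setup.mesh), setup.cfg,
                                 setup.ctx, setup.props, setup.bcs,
                                 n_steps=100)
print(f"{'t (s)':>8} {'omega (1/s)':>12}")
for _, row in diags.iloc[::10].iterrows():
    print(f"{row['t']:8.2f} {row['omega']:12.4e}")
print("\nomega falls monotonically by orders of magnitude as the flow "
      "approaches steady state; with the conventional formulation the "
      "equivalent parameter would stay pinned at 2/dt = "
      f"{2 / setup.cfg.dt:.0f} 1/s.")
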