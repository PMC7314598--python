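"""Sharp reentry threshold on engineered fibers.

A fiber of ell nodes that is transversely isolated except at its ends
supports a closed activation loop of path length 2 * ell.  After a forced
unidirectional block, the retrograde wave survives iff the loop outlasts
the refractory period: sustained reentry iff 2 * ell > tau.  With tau = 50
the threshold fiber has 26 nodes; the longest non-sustaining fiber (25
nodes, 12.5 mm at 0.5 mm spacing) is the minimal-circuit-length prediction.

Runtime: a few seconds.
"""

from percaf import FiberPlacement, FixtureSpec, SimConfig, make_fixture, run
from percaf.experiments import min_circuit_length_mm

TAU = 50

print(f"tau = {TAU} steps -> minimum reentry-capable fiber "
      f"{min_circuit_length_mm(TAU):.1f} mm")
print(f"{'ell':>4} {'2*ell':>6} {'outcome':>18} {'period':>7}")
for ell in range(22, 31):
    fx = make_fixture(
        FixtureSpec(L_x=80, L_y=12, L_z=4,
                    fibers=(FiberPlacement(x0=20, y=6, z=0, length=ell),))
    )
    sim = SimConfig(T=220, tau=TAU, eps=0.0, delta=0.0, n_steps=6 * 220)
    trace = run(fx.network, sim, block_until=fx.block_until)
    if trace.raw_circuits:
        out, period = "sustained reentry", str(trace.raw_circuits[0].period)
    else:
        out, period = "dies out", "-"
    print(f"{ell:>4} {2 * ell:>6} {out:>18} {period:>7}")
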