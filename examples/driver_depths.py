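"""Transmural depth of reentrant drivers: paroxysmal vs persistent coupling.

Pools reentrant-circuit depths over independent tissues at a paroxysmal
coupling (nu_bar = 0.31: episodes induce and terminate) and a persistent
one (nu_bar = 0.27).  In the inhomogeneous model the endocardial layers are
the most anisotropic, so at paroxysmal coupling drivers concentrate toward
the endocardium; at persistent coupling reentry forms throughout the wall
and the depth distribution flattens.

Runtime: roughly 10 minutes single-CPU.
"""

import numpy as np

from percaf import LatticeSpec, SimConfig
from percaf.experiments import driver_depth_study

spec = LatticeSpec(100, 100, 25)

for label, nu_bar, reps, cycles in (
    ("paroxysmal", 0.31, 16, 100),
    ("persistent", 0.27, 8, 30),
):
    config = SimConfig(T=220, tau=50, eps=0.05, delta=0.05,
                       n_steps=cycles * 220)
    res = driver_depth_study(
        {"mode": "inhomogeneous", "nu_bar": nu_bar},
        replicates=reps, spec=spec, config=config, seed=7,
    )
    hist = res["histogram"]
    print(f"\n{label} (nu_bar = {nu_bar}): {res['n_circuits']} circuits "
          f"from {res['replicates']} tissues")
    print(f"  mean depth {res['mean_depth']:.2f} (uniform would be 12.0), "
          f"modal layer {int(np.argmax(hist))}")
    print(f"  chi-square vs uniform: p = {res['p_uniform']:.3g}")
    print("  depth histogram (endo -> epi):", hist.tolist())
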