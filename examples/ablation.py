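"""Half-depth focal ablation: success depends on the coupling regime.

For each tissue, find the first reentrant circuit, rebuild the identical
structure from its seeds, destroy the tissue over the circuit's footprint
from the endocardium down to half the wall (12 of 25 layers), and replay
the identical conduction-block noise.  The target counts as destroyed if no
circuit re-forms inside the footprint.  At high coupling drivers sit mostly
subendocardially and half-depth lesions usually destroy them; at low
coupling drivers appear at all depths and success drops toward a coin flip.

Runtime: roughly 15-20 minutes single-CPU (dominated by the high-coupling
search for first circuits, which are rare there).
"""

from percaf import LatticeSpec, SimConfig
from percaf.experiments import _seeds, ablation_protocol, success_rates

spec = LatticeSpec(100, 100, 25)

for label, nu_bar, tissues, cap_cycles in (
    ("low coupling (persistent)", 0.27, 15, 50),
    ("high coupling (paroxysmal)", 0.33, 30, 220),
):
    config = SimConfig(T=220, tau=50, eps=0.05, delta=0.05,
                       n_steps=cap_cycles * 220)
    outcomes = ablation_protocol(
        _seeds(11, n=tissues),
        n_targets=1,
        depth=12,
        spec=spec,
        profile_kwargs={"mode": "inhomogeneous", "nu_bar": nu_bar},
        config=config,
        seed=42,
        detect_cap=cap_cycles * 220,
        assess_global=False,
    )
    r = success_rates(outcomes)
    induced = sum(o.had_circuit for o in outcomes)
    print(f"{label}, nu_bar = {nu_bar}: {induced}/{tissues} tissues induced "
          f"a circuit; local success at depth 12: "
          f"{100 * r['local_rate']:.0f}% over {r['n_targets']} targets")
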