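# Methods

`percaf` simulates atrial fibrillation (AF) as an emergent property of a
partially coupled, anisotropic 3D lattice of atrial muscle cells. All data
in this repository are synthetic: every number is produced by the model
itself from explicit seeds. Nothing is fitted to clinical recordings, and
no claim is made beyond the model's own behaviour.

## 1. Tissue model

The tissue is an `L_x × L_y × L_z` lattice of excitable nodes (default
200 × 200 × 25; most studies here use the reduced in-plane size
100 × 100 × 25). The x axis is the longitudinal fiber direction, y wraps
periodically (the atrium as a cylinder), and x and z have open boundaries
(the mitral/tricuspid plane and the endo/epicardial surfaces).

Nodes are joined by bonds drawn independently once per tissue
(`fiber_network.build_network`):

- a +x bond with probability ν∥(z) (longitudinal, within a fiber),
- +y and +z bonds with probability ν⊥(z) (transverse, between fibers);
  the z bond uses the ν⊥ of its lower layer.

The mean coupling per node is ν̄ = (2ν∥ + 4ν⊥)/6 and the fiber-angle
dispersion is Δθ = atan(ν⊥/ν∥). `layer_couplings(ν̄, Δθ)` inverts these
two relations: ν∥ = 3ν̄/(1 + 2 tan Δθ). Parameter sets where the
inversion needs ν∥ > 1 raise `InfeasibleProfileError`.

Two profiles are supported:

- **homogeneous** — one (ν∥, ν⊥) pair for every layer;
- **inhomogeneous** — Δθ varies linearly from 24° at the endocardium
  (z = 0) to 42° at the epicardium (z = L_z − 1) at fixed ν̄ per layer.
  The endocardial layers are therefore the most anisotropic: higher ν∥,
  lower ν⊥, and consequently the highest chance of long, transversely
  isolated fiber segments.

## 2. Excitable dynamics

Each node is resting, excited, or refractory (`dynamics`). A resting node
fires one step after a bond-connected neighbour fires; an excited node is
refractory for exactly τ = 50 steps; the x = 0 plane is paced every
T = 220 steps (refractory sinus nodes are skipped, not queued). One bond
traversal costs one step, so a closed loop of path length p re-excites
itself indefinitely iff p > τ.

Conduction block: a fraction δ = 0.05 of nodes is marked susceptible once
per tissue; each time a susceptible node would fire it instead fails with
probability ε = 0.05, drawn once per node per step. The draw is a
counter-based hash of (dynamics seed, node, step), so the noise stream is a
pure function of position and time: editing the structure (e.g. ablation)
leaves all other draws untouched, and pre/post-lesion runs diverge only
causally. δ = ε = 0.05 follows the established two-dimensional version of
this model class; at δ = 0.01 the high-coupling paroxysmal regime is not
inducible at all on desk-scale lattices (zero circuits across 8 × 100
cycles), so the 2D values are used as the study conditions throughout.

The production path is an event-driven compiled kernel over frontier lists;
a vectorized single-step reference implementation is kept solely as a test
oracle, and the suite asserts bit-for-bit equivalence (including noise) on
random lattices.

## 3. Reentry, detection, and depth

An isolated fiber of ℓ nodes supports a loop of path length 2ℓ around it,
so sustained reentry requires 2ℓ > τ: a sharp threshold at ℓ = 26 for
τ = 50, verified exactly on engineered fixtures. The longest
*non*-sustaining fiber, 25 nodes ≙ 12.5 mm at the 0.5 mm node spacing, is
the model's minimum-circuit-length prediction.

Fixtures initiate reentry with a deterministic unidirectional block: the
first interior node of the fiber refuses excitation until the first paced
wavefront has passed. (A node that *always* fails cannot lie on a
sustaining loop — the loop either includes it and never conducts, or
avoids it and gets no differential delay — so the forced block must be
windowed in time.)

Circuits are found online: a node re-firing with period < T for three
consecutive cycles triggers a walk back along activation parents; closure
into a cycle longer than τ records the loop, and loops sharing nodes are
deduplicated. At study couplings strictly isolated ℓ ≥ 26 fibers are
combinatorially absent (per-node probability ~10⁻¹¹ at ν̄ = 0.33), so real
circuits are tortuous loops threading sparse regions; the **depth** of a
circuit is defined as the z layer of the longest straight x-run in its
loop (ties toward the endocardium), the natural generalization of "the
fiber the loop wraps". In the strongly anisotropic oracle regime (ν∥ = 1)
every detected loop contains the full interior of a structurally censused
isolated segment, tying the dynamic detector to the structural census.

## 4. AF classification

A sinus wavefront excites at most one plane of L_y · L_z nodes per step.
A step is fibrillatory when the excited count exceeded
α · L_y · L_z (α = 1.1) at any point in the trailing window of one pacing
period. Empirically the exceedances in the persistent regime recur with
gaps of exactly T (fibrillatory load stacking on the paced-plane firing),
so the trailing window merges them into one episode; a centered window
would truncate the final window and mislabel persistent runs. Labels:
`sinus` (no fibrillatory step), `persistent` (a single episode reaching
the end of the observation window — a right-censored, finite-horizon
call), `paroxysmal` (anything else).

## 5. Studies

- **Risk curve** (`phase_sweep`): mean AF fraction over independent
  tissues per coupling. Calibrated regimes at 100 × 100 × 25,
  100 cycles: sinus at ν̄ ≥ 0.40; rare, self-terminating episodes at
  0.32–0.33; robust paroxysmal AF at 0.31; near-persistent at 0.30;
  persistent with onset within a few cycles at ≤ 0.28.
- **Driver depth** (`driver_depth_study`): pooled circuit depths with a
  chi-square test against uniformity over layers.
- **Ablation** (`ablation_protocol`): per tissue, find the first circuit
  (early-stopped run), rebuild the identical structure from its seeds,
  remove every bond touching the lesion volume — the circuit's xy
  bounding box (periodic-aware) plus a 2-node margin, from the
  endocardium down to the prescribed depth — and replay the identical
  noise. The target is locally destroyed if no circuit re-forms inside
  the footprint within 20 pacing cycles of the original onset. Remaining
  circuits outside existing lesions become further targets (multiple
  focal ablation); global success is zero AF-classified steps over 50
  cycles after the protocol. Tissues that never harbour a circuit count
  as global successes and are excluded from local rates.

## 6. Randomness and reproducibility

Every experiment seed is expanded with `numpy.random.SeedSequence`
spawn keys into independent structure / block-mask / dynamics seeds, and
each output table row records all three, so any tissue can be replayed
bit-for-bit from its row. The CLI stamps a `manifest.json` (package
version, full configuration echo, file inventory) into every output
directory.

## 7. Numerical choices and limitations

- Problem sizes in the test suite are scaled down to run on one CPU
  within minutes; the acceptance studies use ≥30 tissues per coupling at
  100 × 100 × 25. Statistical assertions use tolerance bands sized by
  the binomial error of the chosen replicate counts.
- The persistent/paroxysmal label is horizon-dependent; "persistent" is
  right-censored at the end of the run.
- The depth histogram at persistent coupling is only approximately
  uniform: the extreme layers (z = 0 and z ≥ 23) are mildly depleted by
  boundary effects, which a high-powered chi-square test can resolve.
- Conduction velocity is one bond per step in all directions; no account
  is taken of curvature, anisotropic velocity, or electrotonic effects.
- δ and ε are taken from the 2D version of the model (see § 2); all regime
  boundaries quoted here are conditional on that choice.
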