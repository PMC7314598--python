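"""Monte-Carlo experiment drivers.

These functions wire the network generator, the automaton, and the circuit
detector into the study designs the model was built for: coupling sweeps of
the time spent in fibrillation, transmural driver-depth statistics, and the
iterative focal-ablation protocol with its global and local success rates.
All randomness is funnelled through ``numpy.random.SeedSequence`` spawned
from a single experiment seed, so every tissue is replayable from its row in
the output table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .detection import CircuitRecord, classify_af, depth_histogram, detect_circuits
from .dynamics import SimConfig, run
from .fiber_network import (
    FiberNetwork,
    LatticeSpec,
    Lesion,
    apply_lesion,
    assign_block_susceptible,
    build_network,
    build_profile,
    percolates,
)

__all__ = [
    "PhasePoint",
    "AblationOutcome",
    "TargetOutcome",
    "phase_sweep",
    "driver_depth_study",
    "ablation_protocol",
    "success_rates",
    "lesion_for_circuit",
    "min_circuit_length_mm",
]

#: Supplementary lattice calibration: one node spacing in millimetres.
NODE_SPACING_MM = 0.5


def min_circuit_length_mm(tau: int = 50, spacing_mm: float = NODE_SPACING_MM) -> float:
    """Shortest reentry-capable isolated fiber, in millimetres.

    A loop around a fiber of ell nodes has path length 2 ell and sustains
    itself only if that exceeds the refractory period, so the minimal fiber
    spans tau / 2 node spacings.
    """
    return 0.5 * tau * spacing_mm


def _seeds(seed: int, *path: int, n: int = 1) -> list[int]:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(path))
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep below 2**31


def _make_tissue(
    spec: LatticeSpec,
    profile_kwargs: dict,
    delta: float,
    structure_seed: int,
    block_seed: int,
) -> FiberNetwork:
    profile = build_profile(spec, **profile_kwargs)
    net = build_network(spec, profile, structure_seed)
    return assign_block_susceptible(net, delta, block_seed)


@dataclass(frozen=True)
class PhasePoint:
    """Aggregate AF burden at one coupling."""

    profile_kwargs: dict
    fractions: tuple[float, ...]
    labels: tuple[str, ...]
    percolating: tuple[bool, ...]

    @property
    def mean_fraction(self) -> float:
        return float(np.mean(self.fractions))

    @property
    def any_percolating(self) -> bool:
        return any(self.percolating)


def phase_sweep(
    points: list[dict],
    replicates: int,
    spec: LatticeSpec,
    config: SimConfig,
    seed: int = 0,
) -> tuple[list[PhasePoint], pd.DataFrame]:
    """Mean time-in-AF over independent tissues at each coupling point.

    ``points`` are keyword dictionaries for :func:`build_profile` (e.g.
    ``{"mode": "inhomogeneous", "nu_bar": 0.33}``).  Returns the aggregated
    phase points and a tidy one-row-per-replicate table.
    """
    if not points:
        raise ValueError("empty coupling grid")
    results = []
    rows = []
    for ip, kwargs in enumerate(points):
        fracs, labels, percs = [], [], []
        for rep in range(replicates):
            s_struct, s_block, s_dyn = _seeds(seed, ip, rep, n=3)
            net = _make_tissue(spec, kwargs, config.delta, s_struct, s_block)
            perc = percolates(net)
            cfg = replace(config, dynamics_seed=s_dyn)
            trace = run(net, cfg)
            ep = classify_af(trace)
            fracs.append(ep.fraction)
            labels.append(ep.label)
            percs.append(perc)
            rows.append(
                dict(
                    point=ip,
                    replicate=rep,
                    structure_seed=s_struct,
                    block_seed=s_block,
                    dynamics_seed=s_dyn,
                    percolates=perc,
                    af_fraction=ep.fraction,
                    label=ep.label,
                    **{k: v for k, v in kwargs.items()},
                )
            )
        results.append(
            PhasePoint(
                profile_kwargs=kwargs,
                fractions=tuple(fracs),
                labels=tuple(labels),
                percolating=tuple(percs),
            )
        )
    return results, pd.DataFrame(rows)


def driver_depth_study(
    profile_kwargs: dict,
    replicates: int,
    spec: LatticeSpec,
    config: SimConfig,
    seed: int = 0,
    min_circuits: int = 0,
) -> dict:
    """Pool reentrant-circuit depths over independent tissues.

    Returns the depth histogram over layers, the mean depth, and a
    chi-square test against a uniform depth distribution.  If
    ``min_circuits`` is positive, extra tissues are simulated (up to 4x the
    requested replicates) until that many circuits are pooled.
    """
    circuits: list[CircuitRecord] = []
    rep = 0
    max_rep = replicates if min_circuits <= 0 else 4 * replicates
    while rep < max_rep and (rep < replicates or len(circuits) < min_circuits):
        s_struct, s_block, s_dyn = _seeds(seed, rep, n=3)
        net = _make_tissue(spec, profile_kwargs, config.delta, s_struct, s_block)
        trace = run(net, replace(config, dynamics_seed=s_dyn))
        circuits.extend(detect_circuits(trace, net))
        rep += 1
    hist = depth_histogram(circuits, spec.L_z)
    n = int(hist.sum())
    out = {
        "histogram": hist,
        "n_circuits": n,
        "replicates": rep,
        "mean_depth": float(np.mean([c.depth for c in circuits])) if n else np.nan,
        "circuits": circuits,
    }
    if n:
        chi2, p = stats.chisquare(hist)
        out["chi2_uniform"] = float(chi2)
        out["p_uniform"] = float(p)
    else:
        out["chi2_uniform"] = np.nan
        out["p_uniform"] = np.nan
    return out


def lesion_for_circuit(
    circuit: CircuitRecord, spec: LatticeSpec, depth: int, margin: int = 2
) -> Lesion:
    """Axis-aligned footprint covering the circuit's loop plus a margin.

    The y extent is the tightest arc on the periodic axis covering all loop
    nodes (the footprint may wrap).  Depth counts layers destroyed from the
    endocardium.
    """
    loop = circuit.loop
    x0 = max(0, int(loop[:, 0].min()) - margin)
    x1 = min(spec.L_x - 1, int(loop[:, 0].max()) + margin)
    ys = np.unique(loop[:, 1])
    L_y = spec.L_y
    if ys.size == L_y:
        y0, y1 = 0, L_y - 1
    else:
        # find the widest empty circular gap; the footprint is its complement
        gaps = np.diff(np.concatenate([ys, [ys[0] + L_y]]))
        k = int(np.argmax(gaps))
        start = int(ys[(k + 1) % ys.size])
        span = L_y - int(gaps[k])  # start..start+span covers all loop ys
        y0e = start - margin
        y1e = start + span + margin
        if y1e - y0e + 1 >= L_y:
            y0, y1 = 0, L_y - 1
        else:
            y0 = y0e % L_y
            y1 = y0 + (y1e - y0e)
    return Lesion(x0=x0, x1=x1, y0=int(y0), y1=int(y1), depth=int(depth))


@dataclass(frozen=True)
class TargetOutcome:
    """One targeted circuit within a tissue's ablation protocol."""

    circuit: CircuitRecord
    lesion: Lesion
    local_success: bool


@dataclass(frozen=True)
class AblationOutcome:
    """Per-tissue result of the iterative focal-ablation protocol."""

    structure_seed: int
    targets: tuple[TargetOutcome, ...]
    global_success: bool | None
    had_circuit: bool
    depth: int

    @property
    def n_targets(self) -> int:
        return len(self.targets)


def _circuit_in_footprint(c: CircuitRecord, lesion: Lesion, L_y: int) -> bool:
    return bool(
        lesion.contains_xy(c.loop[:, 0], c.loop[:, 1], L_y).any()
    )


def ablation_protocol(
    structure_seeds: list[int],
    n_targets: int,
    depth: int,
    spec: LatticeSpec,
    profile_kwargs: dict,
    config: SimConfig,
    seed: int = 0,
    *,
    margin: int = 2,
    detect_cap: int | None = None,
    local_window: int | None = None,
    global_window: int | None = None,
    assess_global: bool = True,
) -> list[AblationOutcome]:
    """Iterative focal ablation of the first ``n_targets`` circuit locations.

    Per tissue: simulate until the first reentrant circuit appears, rebuild
    the identical structure from its seed, destroy the nodes over the
    circuit's footprint down to ``depth`` layers, and re-run with the
    identical conduction-block noise.  The targeted circuit counts as
    locally destroyed if no circuit re-forms inside the lesion footprint
    within ``local_window`` steps of the original onset.  Newly appearing
    circuits outside existing lesions become the next targets, until
    ``n_targets`` locations are ablated or no further circuits appear.
    Global success means the fully lesioned tissue shows zero AF-classified
    steps over ``global_window`` steps.  Tissues in which no circuit ever
    forms are counted as global successes and excluded from local rates.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if not 1 <= depth <= spec.L_z:
        raise ValueError("ablation depth out of range")
    detect_cap = detect_cap if detect_cap is not None else config.n_steps
    local_window = local_window if local_window is not None else 20 * config.T
    global_window = global_window if global_window is not None else 50 * config.T
    outcomes = []
    for it, s_struct in enumerate(structure_seeds):
        s_block, s_dyn = _seeds(seed, it, n=2)
        base = _make_tissue(spec, profile_kwargs, config.delta, s_struct, s_block)

        # find the first circuit (early-stopped run)
        cfg0 = replace(
            config, dynamics_seed=s_dyn, n_steps=detect_cap, stop_at_circuits=1
        )
        trace = run(base, cfg0)
        circuits = sorted(detect_circuits(trace), key=_target_order)
        if not circuits:
            outcomes.append(
                AblationOutcome(
                    structure_seed=int(s_struct),
                    targets=(),
                    global_success=True if assess_global else None,
                    had_circuit=False,
                    depth=depth,
                )
            )
            continue

        net = base
        lesions: list[Lesion] = []
        targets: list[TargetOutcome] = []
        target = circuits[0]
        while target is not None and len(targets) < n_targets:
            lesion = lesion_for_circuit(target, spec, depth, margin=margin)
            net = apply_lesion(net, lesion)
            lesions.append(lesion)
            horizon = min(detect_cap, target.onset + local_window)
            cfg = replace(
                config,
                dynamics_seed=s_dyn,
                n_steps=max(horizon, config.T + 1),
                stop_at_circuits=0,
            )
            trace = run(net, cfg)
            found = sorted(detect_circuits(trace), key=_target_order)
            reformed = any(
                _circuit_in_footprint(c, lesion, spec.L_y)
                and c.onset <= target.onset + local_window
                for c in found
            )
            targets.append(
                TargetOutcome(circuit=target, lesion=lesion, local_success=not reformed)
            )
            # next target: earliest circuit outside all lesioned locations
            target = None
            for c in found:
                if not any(_circuit_in_footprint(c, l, spec.L_y) for l in lesions):
                    target = c
                    break

        global_success = None
        if assess_global:
            cfgg = replace(
                config, dynamics_seed=s_dyn, n_steps=global_window, stop_at_circuits=0
            )
            tr = run(net, cfgg)
            ep = classify_af(tr)
            global_success = ep.fraction == 0.0
        outcomes.append(
            AblationOutcome(
                structure_seed=int(s_struct),
                targets=tuple(targets),
                global_success=global_success,
                had_circuit=True,
                depth=depth,
            )
        )
    return outcomes


def _target_order(c: CircuitRecord):
    return (c.onset, c.core[2], c.core[0], c.core[1])


def success_rates(outcomes: list[AblationOutcome]) -> dict:
    """Global and local ablation success rates from protocol outcomes.

    The global rate is the fraction of tissues whose post-protocol run shows
    no AF (tissues that never harboured a circuit count as successes); the
    local rate is the fraction of targeted circuits destroyed, reported
    overall and per ablation depth, together with the cumulative depth
    distribution of the targeted circuits.
    """
    if not outcomes:
        raise ValueError("no outcomes")
    with_global = [o for o in outcomes if o.global_success is not None]
    global_rate = (
        float(np.mean([o.global_success for o in with_global]))
        if with_global
        else np.nan
    )
    all_targets = [(o.depth, t) for o in outcomes for t in o.targets]
    local_overall = (
        float(np.mean([t.local_success for _, t in all_targets]))
        if all_targets
        else np.nan
    )
    by_depth = {}
    for d in sorted({dd for dd, _ in all_targets}):
        sel = [t.local_success for dd, t in all_targets if dd == d]
        by_depth[d] = (float(np.mean(sel)), len(sel))
    depths = np.array([t.circuit.depth for _, t in all_targets], dtype=int)
    if depths.size:
        L_z = max(int(depths.max()) + 1, max(o.depth for o in outcomes))
        cum = np.cumsum(np.bincount(depths, minlength=L_z)) / depths.size
    else:
        cum = np.array([])
    return {
        "global_rate": global_rate,
        "n_tissues": len(outcomes),
        "local_rate": local_overall,
        "n_targets": len(all_targets),
        "local_rate_by_depth": by_depth,
        "cumulative_depth_distribution": cum,
    }
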