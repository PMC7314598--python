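"""Classification of fibrillatory activity and reentrant-circuit analysis.

A sinus wavefront sweeping the tissue excites at most one front's worth of
nodes per step; sustained excitation far above that level implies multiple
coexisting wavefronts, the signature of fibrillation.  Reentrant circuits
are closed activation loops with period shorter than the pacing interval;
their transmural depth — the layer of the isolated fiber the loop wraps —
is the quantity whose distribution separates paroxysmal from persistent
behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .dynamics import ActivityTrace, SimConfig
from .fiber_network import FiberNetwork, LatticeSpec

__all__ = [
    "AFEpisodes",
    "CircuitRecord",
    "classify_af",
    "detect_circuits",
    "depth_histogram",
    "surface_views",
]


@dataclass(frozen=True)
class AFEpisodes:
    """Fibrillatory intervals of a run.

    intervals are half-open [start, end) step ranges after smoothing;
    fraction is the share of post-burn-in steps classified as AF; label is
    'sinus' (fraction 0), 'persistent' (AF from onset to the end of the
    observation window with no return to sinus rhythm), or 'paroxysmal'.
    """

    intervals: tuple[tuple[int, int], ...]
    fraction: float
    label: str
    n_counted: int

    @property
    def onset(self) -> int | None:
        return self.intervals[0][0] if self.intervals else None


def classify_af(
    trace: ActivityTrace,
    spec: LatticeSpec | None = None,
    config: SimConfig | None = None,
    *,
    alpha: float | None = None,
    window: int | None = None,
) -> AFEpisodes:
    """Classify each step of a trace as sinus or fibrillatory.

    A step is marked fibrillatory when the excited-node count exceeds
    ``alpha * L_y * L_z`` anywhere within the trailing smoothing window of
    ``window`` steps (default: one pacing period) — an episode persists
    until a full pacing cycle passes without excess activity.  Contiguous
    marked steps form episodes; the AF fraction is taken over post-burn-in
    steps.
    """
    spec = spec or trace.spec
    config = config or trace.config
    alpha = config.af_alpha if alpha is None else alpha
    window = window if window is not None else (config.af_window or config.T)
    burn_in = config.burn_in
    counts = trace.counts[: trace.t_end]
    if counts.shape[0] <= burn_in:
        raise ValueError("trace shorter than burn-in")
    threshold = alpha * spec.L_y * spec.L_z
    raw = counts > threshold
    # trailing window: step t is fibrillatory iff an exceedance occurred in
    # (t - window, t]; origin shifts the filter footprint so its right edge
    # sits at t
    af = (
        maximum_filter1d(
            raw.astype(np.uint8),
            size=window,
            mode="constant",
            origin=(window - 1) // 2,
        )
        > 0
    )
    af_counted = af[burn_in:]
    n_counted = af_counted.shape[0]
    fraction = float(af_counted.mean()) if n_counted else 0.0
    # contiguous True runs -> episodes (in absolute step coordinates)
    intervals: list[tuple[int, int]] = []
    padded = np.diff(np.concatenate(([0], af_counted.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    for s, e in zip(starts, ends):
        intervals.append((int(s + burn_in), int(e + burn_in)))
    if fraction == 0.0:
        label = "sinus"
    elif len(intervals) == 1 and intervals[0][1] == burn_in + n_counted:
        label = "persistent"
    else:
        label = "paroxysmal"
    return AFEpisodes(
        intervals=tuple(intervals),
        fraction=fraction,
        label=label,
        n_counted=n_counted,
    )


@dataclass(frozen=True)
class CircuitRecord:
    """A reentrant circuit localized in the tissue.

    core is a representative loop node (minimum activation phase, ties
    broken by lowest (z, x, y)); depth is the layer of the loop's isolated
    longitudinal segment, taken as the z of the longest straight x-run in
    the loop (ties toward the endocardium).
    """

    core: tuple[int, int, int]
    depth: int
    onset: int
    period: int
    loop: np.ndarray  # (n, 3) array of (x, y, z), in reverse activation order

    @property
    def length(self) -> int:
        return self.loop.shape[0]

    def fiber_run(self) -> tuple[int, int, int, int]:
        """(x0, y, z, length) of the longest straight x-run in the loop."""
        return _longest_x_run(self.loop)


def _longest_x_run(coords: np.ndarray) -> tuple[int, int, int, int]:
    """Longest set of loop nodes consecutive in x at constant (y, z)."""
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    c = coords[order]
    best = (int(c[0, 0]), int(c[0, 1]), int(c[0, 2]), 1)
    run_start = 0
    for i in range(1, c.shape[0] + 1):
        end_of_run = (
            i == c.shape[0]
            or c[i, 2] != c[i - 1, 2]
            or c[i, 1] != c[i - 1, 1]
            or c[i, 0] != c[i - 1, 0] + 1
        )
        if end_of_run:
            length = i - run_start
            z, y, x0 = int(c[run_start, 2]), int(c[run_start, 1]), int(c[run_start, 0])
            if length > best[3] or (length == best[3] and z < best[2]):
                best = (x0, y, z, length)
            run_start = i
    return best


def detect_circuits(
    trace: ActivityTrace,
    network: FiberNetwork | None = None,
    config: SimConfig | None = None,
) -> list[CircuitRecord]:
    """Turn the trace's raw activation loops into localized circuit records.

    The kernel records a loop when a node re-fires with period < T for at
    least three consecutive cycles and its activation-parent chain closes
    into a cycle longer than tau; loops sharing nodes are deduplicated at
    recording time.  Here each loop is given a core node and a transmural
    depth.
    """
    spec = trace.spec
    records = []
    for raw in trace.raw_circuits:
        nodes = raw.nodes
        z = nodes % spec.L_z
        r = nodes // spec.L_z
        y = r % spec.L_y
        x = r // spec.L_y
        coords = np.stack([x, y, z], axis=1)
        # loop order is reverse activation: nodes[k] fired at onset - k, so
        # activation phase within the cycle is (onset - k) mod period
        phases = (raw.onset - np.arange(nodes.shape[0])) % raw.period
        min_phase = phases.min()
        cand = coords[phases == min_phase]
        sel = np.lexsort((cand[:, 1], cand[:, 0], cand[:, 2]))[0]
        core = (int(cand[sel, 0]), int(cand[sel, 1]), int(cand[sel, 2]))
        x0, yy, zz, _length = _longest_x_run(coords)
        records.append(
            CircuitRecord(
                core=core,
                depth=int(zz),
                onset=raw.onset,
                period=raw.period,
                loop=coords,
            )
        )
    return records


def depth_histogram(circuits: list[CircuitRecord], L_z: int) -> np.ndarray:
    """Counts of circuit depths per layer z in {0, ..., L_z - 1}."""
    depths = np.array([c.depth for c in circuits], dtype=np.intp)
    if depths.size and (depths.min() < 0 or depths.max() >= L_z):
        raise ValueError("circuit depth outside lattice")
    return np.bincount(depths, minlength=L_z)


def surface_views(
    snapshot: np.ndarray, spec: LatticeSpec, y_section: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Endocardial (z = 0) map, epicardial (z = L_z - 1) map, and a fixed-y
    x-z cross-section of a full-state snapshot."""
    if snapshot.shape != spec.shape:
        raise ValueError("snapshot shape does not match the lattice")
    if not 0 <= y_section < spec.L_y:
        raise ValueError("cross-section index out of bounds")
    endo = snapshot[:, :, 0].copy()
    epi = snapshot[:, :, spec.L_z - 1].copy()
    cross = snapshot[:, y_section, :].copy()
    return endo, epi, cross
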