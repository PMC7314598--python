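"""Three-state excitable dynamics with sinus pacing and conduction block.

Each node is resting, excited, or refractory.  A resting node fires when a
bond-connected neighbour was excited on the previous step, except that
block-susceptible nodes fail to fire with probability ``eps`` (drawn once
per node per step).  An excited node is refractory for exactly ``tau``
subsequent steps.  The sinus node — the whole x = 0 plane — fires every
``T`` steps; refractory sinus nodes are skipped, not queued.  One bond is
one step of conduction time, so a closed loop of path length p re-excites
itself indefinitely iff p > tau.

Two implementations are provided: :func:`run` drives the compiled
event-driven kernel, and :func:`step` is a straightforward vectorized
single-step update on a clock array, used as an independent cross-check of
the kernel on small lattices.  Both consume the same counter-based noise, so
they agree bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .fiber_network import FiberNetwork, LatticeSpec

__all__ = ["SimConfig", "ActivityTrace", "RawCircuit", "init_state", "step", "run"]

RESTING = 0
EXCITED = 1


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    T : sinus pacing period in steps (must exceed tau).
    tau : refractory period in steps.
    eps : probability that a block-susceptible node fails to fire when
        attempted, per step.
    delta : fraction of block-susceptible nodes (used where a network is
        built from this config).
    n_steps : number of synchronous update steps.
    burn_in : steps excluded from episode statistics.
    dynamics_seed : seed of the conduction-block noise stream (independent
        of the structure and block-mask seeds).
    snapshot_times : steps at which to record the full state.
    stop_at_circuits : end the run early once this many reentrant circuits
        have been recorded (0 = never).
    af_alpha, af_window : fibrillation-classification threshold factor and
        smoothing window (see :mod:`percaf.detection`).
    """

    T: int = 220
    tau: int = 50
    eps: float = 0.05
    delta: float = 0.05
    n_steps: int = 22000
    burn_in: int = 0
    dynamics_seed: int = 0
    snapshot_times: tuple[int, ...] = ()
    stop_at_circuits: int = 0
    max_circuits: int = 512
    af_alpha: float = 1.1
    af_window: int | None = None

    def __post_init__(self):
        if not self.T > self.tau > 0:
            raise ValueError("require T > tau > 0")
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError("eps must lie in [0, 1]")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")


@dataclass(frozen=True)
class RawCircuit:
    """A closed activation loop recorded by the kernel (flat node indices)."""

    nodes: np.ndarray
    onset: int
    period: int


@dataclass
class ActivityTrace:
    """Recording of one run.

    counts[t] is the number of nodes excited at step t (zero past t_end if
    the run stopped early).  last_activation holds each node's final
    activation step (a large negative sentinel if never excited), and
    activations the per-node total count.  raw_circuits are the closed
    activation loops found online; snapshots are full state maps
    (0 resting / 1 excited / 2 refractory) at the requested steps.
    """

    spec: LatticeSpec
    config: SimConfig
    counts: np.ndarray
    t_end: int
    last_activation: np.ndarray
    activations: np.ndarray
    raw_circuits: list[RawCircuit]
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.counts.shape[0]


def init_state(spec: LatticeSpec) -> np.ndarray:
    """All-resting clock array (0 = resting, 1 = excited, 2..tau+1 refractory)."""
    return np.zeros(spec.shape, dtype=np.int32)


def step(
    state: np.ndarray,
    network: FiberNetwork,
    t: int,
    config: SimConfig,
    block_until: np.ndarray | None = None,
) -> np.ndarray:
    """Reference synchronous update of the clock array (returns a new array).

    The clock encodes 0 = resting, 1 = excited this step, and c in
    [2, tau+1] = refractory with c-1 steps since excitation.  Conduction
    block uses the same counter-based (seed, node, step) noise as the
    compiled kernel.
    """
    spec = network.spec
    tau = config.tau
    excited = state == EXCITED
    # neighbour-excitation mask via bond shifts
    src = np.zeros(spec.shape, dtype=bool)
    bx, by, bz = network.bond_x, network.bond_y, network.bond_z
    src[1:] |= excited[:-1] & bx[:-1]
    src[:-1] |= excited[1:] & bx[:-1]
    if spec.L_y > 1:
        src |= np.roll(excited & by, 1, axis=1)
        src |= np.roll(excited, -1, axis=1) & by
    src[:, :, 1:] |= excited[:, :, :-1] & bz[:, :, :-1]
    src[:, :, :-1] |= excited[:, :, 1:] & bz[:, :, :-1]
    # excitable now: resting, or refractory period expiring exactly this step
    fire = src & ((state == RESTING) | (state == tau + 1))
    # conduction block, one draw per susceptible node per step
    cand = fire & network.susceptible
    if cand.any() and config.eps > 0.0:
        nodes = np.flatnonzero(cand.ravel())
        u = _kernels.block_noise(config.dynamics_seed, nodes, t)
        blocked = np.zeros(spec.n_nodes, dtype=bool)
        blocked[nodes] = u < config.eps
        fire &= ~blocked.reshape(spec.shape)
    if block_until is not None:
        fire &= ~(t < block_until)
    new = state.copy()
    # refractory bookkeeping: excited -> 2, 2..tau -> +1, tau+1 -> resting
    refr = state >= 1
    new[refr] = state[refr] + 1
    new[state == tau + 1] = RESTING
    new[fire] = EXCITED
    # sinus pacing of resting x = 0 nodes
    if t % config.T == 0:
        pace = new[0] == RESTING
        if block_until is not None:
            pace &= ~(t < block_until[0])
        new[0][pace] = EXCITED
    return new


def run(
    network: FiberNetwork,
    config: SimConfig,
    block_until: np.ndarray | None = None,
) -> ActivityTrace:
    """Run the compiled kernel for ``config.n_steps`` steps.

    Deterministic given (network, config.dynamics_seed, block_until).
    ``block_until`` is an optional per-node step before which the node
    refuses excitation — used by engineered fixtures to force a
    unidirectional conduction block deterministically.
    """
    spec = network.spec
    bx, by, bz = network.flat_bonds()
    susc = np.ascontiguousarray(network.susceptible, dtype=np.uint8).ravel()
    if block_until is None:
        bu = np.zeros(spec.n_nodes, dtype=np.int64)
    else:
        bu = np.ascontiguousarray(block_until, dtype=np.int64).ravel()
        if bu.shape[0] != spec.n_nodes:
            raise ValueError("block_until must cover the lattice")
    snap_times = np.asarray(sorted(config.snapshot_times), dtype=np.int64)
    (
        counts,
        t_end,
        n_circ,
        loops,
        loop_len,
        onsets,
        periods,
        last_act,
        _ready,
        acts,
        snaps,
    ) = _kernels.run_kernel(
        bx,
        by,
        bz,
        susc,
        bu,
        spec.L_x,
        spec.L_y,
        spec.L_z,
        config.T,
        config.tau,
        float(config.eps),
        config.n_steps,
        config.dynamics_seed,
        config.stop_at_circuits,
        snap_times,
        config.max_circuits,
    )
    circuits = [
        RawCircuit(
            nodes=loops[i, : loop_len[i]].copy(),
            onset=int(onsets[i]),
            period=int(periods[i]),
        )
        for i in range(n_circ)
    ]
    snapshots = {
        int(snap_times[i]): snaps[i].reshape(spec.shape).copy()
        for i in range(len(snap_times))
        if snap_times[i] < t_end
    }
    return ActivityTrace(
        spec=spec,
        config=config,
        counts=counts,
        t_end=int(t_end),
        last_activation=last_act.reshape(spec.shape),
        activations=acts.reshape(spec.shape),
        raw_circuits=circuits,
        snapshots=snapshots,
    )
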