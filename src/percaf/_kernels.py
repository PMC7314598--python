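"""Event-driven numba kernels for the excitable-media automaton.

The simulation state is kept in flat C-order arrays indexed by
``n = (x * L_y + y) * L_z + z``.  Only the currently excited frontier is
iterated each step, so quiescent intervals between sinus beats cost almost
nothing.  Conduction-block noise is counter-based (a splitmix64 hash of
(seed, node, step)), which makes every run exactly replayable node-by-node
and step-by-step irrespective of how the network structure changes — the
property the ablation protocol relies on when it re-runs a lesioned copy of
a tissue under identical dynamics noise.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_PHI = U64(0x9E3779B97F4A7C15)
_K2 = U64(0xC2B2AE3D27D4EB4F)
_M1 = U64(0xBF58476D1CE4E5B9)
_M2 = U64(0x94D049BB133111EB)
_INV64 = np.float64(2.0**-64)


@njit(cache=True, inline="always")
def _rand01(seed: np.uint64, n: np.int64, t: np.int64) -> np.float64:
    """splitmix64-style hash of (seed, node, step) mapped to [0, 1)."""
    z = U64(seed) + U64(n) * _PHI + U64(t) * _K2
    z = (z ^ (z >> U64(30))) * _M1
    z = (z ^ (z >> U64(27))) * _M2
    z = z ^ (z >> U64(31))
    return np.float64(z) * _INV64


def block_noise(seed: int, nodes: np.ndarray, t: int) -> np.ndarray:
    """Vectorized numpy twin of the kernel's per-(node, step) noise draw.

    Used by the reference single-step update so that the pure-numpy path and
    the compiled kernel see bit-identical conduction-block decisions.
    """
    with np.errstate(over="ignore"):
        z = U64(seed) + nodes.astype(np.uint64) * _PHI + U64(t) * _K2
        z = (z ^ (z >> U64(30))) * _M1
        z = (z ^ (z >> U64(27))) * _M2
        z = z ^ (z >> U64(31))
    return z.astype(np.float64) * _INV64


@njit(cache=True, inline="always")
def _try_excite(
    m,
    src,
    t,
    T,
    tau,
    eps,
    seed,
    ready,
    last_act,
    parent,
    streak,
    acts,
    susceptible,
    block_until,
    attempt_step,
    attempt_fail,
):
    """Attempt to excite node m from excited neighbour src at step t.

    Returns the re-activation period if m fires now, else 0.  The block draw
    is made once per (node, step) however many neighbours attempt it.
    """
    if last_act[m] == t:
        return 0
    if t < ready[m]:
        return 0
    if t < block_until[m]:
        return 0
    if susceptible[m] != 0:
        if attempt_step[m] != t:
            attempt_step[m] = t
            attempt_fail[m] = 1 if _rand01(seed, m, t) < eps else 0
        if attempt_fail[m] != 0:
            return 0
    p = t - last_act[m]
    last_act[m] = t
    ready[m] = t + tau + 1
    parent[m] = src
    acts[m] += 1
    if 0 < p < T:
        streak[m] += 1
    else:
        streak[m] = 0
    return p


@njit(cache=True)
def run_kernel(
    bond_x,
    bond_y,
    bond_z,
    susceptible,
    block_until,
    L_x,
    L_y,
    L_z,
    T,
    tau,
    eps,
    n_steps,
    seed,
    stop_at_circuits,
    snap_times,
    max_circuits,
):
    """Run the three-state automaton with sinus pacing at x = 0.

    Per step: (1) nodes excited at t-1 excite their resting bond-neighbours
    (block-susceptible nodes fail with probability eps, drawn once per node
    per step); (2) excited nodes enter a refractory period of tau steps;
    (3) at t = 0, T, 2T, ... every resting node in the x = 0 plane fires
    (refractory sinus nodes are skipped, not queued).

    Reentrant circuits are detected online: when a node re-fires with period
    p < T for the third consecutive cycle, the activation-parent chain is
    walked back p hops; if it closes into a cycle through that node, and no
    node of the cycle belongs to an already recorded circuit, the loop is
    recorded (onset step, period, node list) and its nodes are claimed.

    Returns (counts, t_end, n_circuits, loops, loop_len, onsets, periods,
    last_act, ready, acts, snaps).
    """
    N = L_x * L_y * L_z
    plane = L_y * L_z
    ready = np.zeros(N, np.int64)
    last_act = np.full(N, -(1 << 40), np.int64)
    parent = np.full(N, -1, np.int64)
    streak = np.zeros(N, np.int32)
    claimed = np.zeros(N, np.uint8)
    acts = np.zeros(N, np.int64)
    attempt_step = np.full(N, -1, np.int64)
    attempt_fail = np.zeros(N, np.uint8)
    counts = np.zeros(n_steps, np.int64)

    cur = np.empty(N, np.int64)
    nxt = np.empty(N, np.int64)
    cur_n = 0

    loops = np.full((max_circuits, T), -1, np.int64)
    loop_len = np.zeros(max_circuits, np.int64)
    onsets = np.zeros(max_circuits, np.int64)
    periods = np.zeros(max_circuits, np.int64)
    n_circ = 0

    n_snaps = snap_times.shape[0]
    snaps = np.zeros((n_snaps, N), np.int8)
    snap_ptr = 0

    t_end = n_steps
    for t in range(n_steps):
        nn = 0
        # 1) propagation from the step t-1 frontier
        for i in range(cur_n):
            n = cur[i]
            z = n % L_z
            r = n // L_z
            y = r % L_y
            x = r // L_y
            # +x
            if bond_x[n] != 0:
                p = _try_excite(
                    n + plane, n, t, T, tau, eps, seed, ready, last_act, parent,
                    streak, acts, susceptible, block_until, attempt_step, attempt_fail,
                )
                if p != 0:
                    nxt[nn] = n + plane
                    nn += 1
            # -x
            if x > 0 and bond_x[n - plane] != 0:
                p = _try_excite(
                    n - plane, n, t, T, tau, eps, seed, ready, last_act, parent,
                    streak, acts, susceptible, block_until, attempt_step, attempt_fail,
                )
                if p != 0:
                    nxt[nn] = n - plane
                    nn += 1
            if L_y > 1:
                # +y (periodic)
                if bond_y[n] != 0:
                    m = n + L_z if y + 1 < L_y else n - (L_y - 1) * L_z
                    p = _try_excite(
                        m, n, t, T, tau, eps, seed, ready, last_act, parent,
                        streak, acts, susceptible, block_until, attempt_step,
                        attempt_fail,
                    )
                    if p != 0:
                        nxt[nn] = m
                        nn += 1
                # -y (periodic)
                m = n - L_z if y > 0 else n + (L_y - 1) * L_z
                if bond_y[m] != 0:
                    p = _try_excite(
                        m, n, t, T, tau, eps, seed, ready, last_act, parent,
                        streak, acts, susceptible, block_until, attempt_step,
                        attempt_fail,
                    )
                    if p != 0:
                        nxt[nn] = m
                        nn += 1
            # +z
            if bond_z[n] != 0:
                p = _try_excite(
                    n + 1, n, t, T, tau, eps, seed, ready, last_act, parent,
                    streak, acts, susceptible, block_until, attempt_step, attempt_fail,
                )
                if p != 0:
                    nxt[nn] = n + 1
                    nn += 1
            # -z
            if z > 0 and bond_z[n - 1] != 0:
                p = _try_excite(
                    n - 1, n, t, T, tau, eps, seed, ready, last_act, parent,
                    streak, acts, susceptible, block_until, attempt_step, attempt_fail,
                )
                if p != 0:
                    nxt[nn] = n - 1
                    nn += 1
        # 2) circuit detection on the freshly excited nodes: a node that has
        # re-fired with period < T for >= 3 consecutive cycles triggers a
        # backward walk along activation parents; closure into a cycle
        # through the node identifies a reentrant circuit.
        if n_circ < max_circuits:
            for i in range(nn):
                m = nxt[i]
                if streak[m] >= 3 and claimed[m] == 0:
                    cur2 = parent[m]
                    buf = loops[n_circ]
                    buf[0] = m
                    k = 1
                    closed = False
                    while k < T and cur2 >= 0:
                        if cur2 == m:
                            closed = True
                            break
                        buf[k] = cur2
                        cur2 = parent[cur2]
                        k += 1
                    recorded = False
                    if closed and k > tau:
                        ok = True
                        for j in range(k):
                            if claimed[buf[j]] != 0:
                                ok = False
                                break
                        if ok:
                            for j in range(k):
                                claimed[buf[j]] = 1
                            loop_len[n_circ] = k
                            onsets[n_circ] = t
                            periods[n_circ] = k
                            n_circ += 1
                            recorded = True
                            if n_circ >= max_circuits:
                                break
                    if not recorded:
                        for j in range(k):
                            buf[j] = -1
                        # back off before re-walking this node's chain so
                        # driven (non-circuit) nodes stay cheap
                        streak[m] = -16
        # 3) sinus pacing of resting x = 0 nodes
        if t % T == 0:
            for n in range(plane):
                if t >= ready[n] and t >= block_until[n] and last_act[n] != t:
                    p = t - last_act[n]
                    last_act[n] = t
                    ready[n] = t + tau + 1
                    parent[n] = -1
                    acts[n] += 1
                    if 0 < p < T:
                        streak[n] += 1
                    else:
                        streak[n] = 0
                    nxt[nn] = n
                    nn += 1
        counts[t] = nn
        # snapshots of the full state at requested steps
        while snap_ptr < n_snaps and snap_times[snap_ptr] == t:
            for n in range(N):
                if last_act[n] == t:
                    snaps[snap_ptr, n] = 1
                elif t < ready[n]:
                    snaps[snap_ptr, n] = 2
                else:
                    snaps[snap_ptr, n] = 0
            snap_ptr += 1
        cur, nxt = nxt, cur
        cur_n = nn
        if stop_at_circuits > 0 and n_circ >= stop_at_circuits:
            t_end = t + 1
            break
    return (
        counts,
        t_end,
        n_circ,
        loops,
        loop_len,
        onsets,
        periods,
        last_act,
        ready,
        acts,
        snaps,
    )
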