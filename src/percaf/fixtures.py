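"""Deterministic engineered networks for tests and demonstrations.

A fixture embeds one or more isolated longitudinal fibers in an otherwise
fully coupled lattice.  A fiber of ``length`` nodes keeps transverse bonds
only at its two end nodes; the interior is decoupled from the neighbouring
rows, so the shortest closed loop around the fiber (down the fiber and back
through the adjacent row) has path length 2 * length.

Reentry is initiated with a deterministic unidirectional block: the first
interior node of the fiber refuses excitation until the first sinus
wavefront has passed, so the fiber is first excited from its distal end
only.  The retrograde wave then exits at the proximal end and re-excites the
surrounding tissue iff the loop is long enough for it to have recovered —
i.e. iff 2 * length > tau.  (A permanently failing node could not sit on a
sustaining loop, so the forced block is windowed in time rather than a
probability-one block.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiber_network import CouplingProfile, FiberNetwork, LatticeSpec

__all__ = ["FiberPlacement", "FixtureSpec", "Fixture", "make_fixture"]


@dataclass(frozen=True)
class FiberPlacement:
    """An isolated fiber at (x0..x0+length-1, y, z); length >= 3."""

    x0: int
    y: int
    z: int
    length: int

    def nodes(self):
        return [(self.x0 + i, self.y, self.z) for i in range(self.length)]


@dataclass(frozen=True)
class FixtureSpec:
    """A small engineered lattice.

    fibers are the isolated segments to embed; for each fiber with
    ``force_block`` enabled, the first interior node is blocked for all
    steps t < x0 + 2 (exactly long enough to reject the single antegrade
    excitation attempt of the first paced wavefront).  Background coupling
    is full unless overridden.
    """

    L_x: int
    L_y: int
    L_z: int
    fibers: tuple[FiberPlacement, ...] = ()
    force_block: bool = True
    extra_blocks: tuple[tuple[int, int, int, int], ...] = ()  # (x, y, z, until)

    def __post_init__(self):
        seen = set()
        for f in self.fibers:
            if f.length < 3:
                raise ValueError("fiber length must be >= 3")
            if not (0 <= f.x0 and f.x0 + f.length <= self.L_x):
                raise ValueError("fiber exceeds the x extent")
            if not (0 <= f.y < self.L_y and 0 <= f.z < self.L_z):
                raise ValueError("fiber out of bounds")
            for node in f.nodes():
                if node in seen:
                    raise ValueError("fibers overlap")
                seen.add(node)


@dataclass(frozen=True)
class Fixture:
    network: FiberNetwork
    block_until: np.ndarray
    spec: FixtureSpec


def make_fixture(fspec: FixtureSpec) -> Fixture:
    """Build the engineered network and its forced-block schedule."""
    spec = LatticeSpec(fspec.L_x, fspec.L_y, fspec.L_z)
    shape = spec.shape
    bond_x = np.ones(shape, dtype=bool)
    bond_y = np.ones(shape, dtype=bool) if spec.L_y > 1 else np.zeros(shape, bool)
    bond_z = np.ones(shape, dtype=bool)
    bond_x[-1] = False
    bond_z[:, :, -1] = False
    block_until = np.zeros(shape, dtype=np.int64)

    for f in fspec.fibers:
        xs = slice(f.x0 + 1, f.x0 + f.length - 1)  # interior nodes
        y, z = f.y, f.z
        # strip transverse bonds touching the interior
        bond_y[xs, y, z] = False
        bond_y[xs, (y - 1) % spec.L_y, z] = False
        bond_z[xs, y, z] = False
        if z > 0:
            bond_z[xs, y, z - 1] = False
        if fspec.force_block:
            block_until[f.x0 + 1, y, z] = f.x0 + 2
    for (x, y, z, until) in fspec.extra_blocks:
        block_until[x, y, z] = until

    network = FiberNetwork(
        spec=spec,
        profile=CouplingProfile(
            nu_par=np.ones(spec.L_z),
            nu_perp=np.ones(spec.L_z),
            mode="homogeneous",
        ),
        bond_x=bond_x,
        bond_y=bond_y,
        bond_z=bond_z,
        susceptible=np.zeros(shape, dtype=bool),
    )
    return Fixture(network=network, block_until=block_until, spec=fspec)
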