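import numpy as np
import pytest

from percaf import (
    FiberPlacement,
    FixtureSpec,
    LatticeSpec,
    SimConfig,
    build_network,
    build_profile,
    make_fixture,
)


@pytest.fixture(scope="session")
def small_spec():
    return LatticeSpec(20, 10, 5)


@pytest.fixture(scope="session")
def full_network(small_spec):
    """Fully coupled small lattice."""
    profile = build_profile(small_spec, "homogeneous", nu_par=1.0, nu_perp=1.0)
    return build_network(small_spec, profile, structure_seed=0)


def reentry_fixture(length, L_x=80, L_y=12, L_z=4, z=0):
    """Single isolated fiber embedded in a fully coupled lattice."""
    return make_fixture(
        FixtureSpec(
            L_x=L_x,
            L_y=L_y,
            L_z=L_z,
            fibers=(FiberPlacement(x0=20, y=L_y // 2, z=z, length=length),),
        )
    )


@pytest.fixture(scope="session")
def sustained_fixture():
    """Fiber long enough for reentry at tau = 50 (2 * 30 > 50)."""
    return reentry_fixture(30)


@pytest.fixture(scope="session")
def sustained_trace(sustained_fixture):
    from percaf import run

    sim = SimConfig(T=220, tau=50, eps=0.0, delta=0.0, n_steps=20 * 220)
    return run(sustained_fixture.network, sim, block_until=sustained_fixture.block_until)


def bfs_reachable(network, sources):
    """Independent flood fill over the bond graph (python BFS oracle)."""
    L_x, L_y, L_z = network.spec.shape
    bx, by, bz = network.bond_x, network.bond_y, network.bond_z
    seen = set(sources)
    stack = list(sources)
    while stack:
        x, y, z = stack.pop()
        nbrs = []
        if x + 1 < L_x and bx[x, y, z]:
            nbrs.append((x + 1, y, z))
        if x > 0 and bx[x - 1, y, z]:
            nbrs.append((x - 1, y, z))
        if L_y > 1:
            if by[x, y, z]:
                nbrs.append((x, (y + 1) % L_y, z))
            if by[x, (y - 1) % L_y, z]:
                nbrs.append((x, (y - 1) % L_y, z))
        if z + 1 < L_z and bz[x, y, z]:
            nbrs.append((x, y, z + 1))
        if z > 0 and bz[x, y, z - 1]:
            nbrs.append((x, y, z - 1))
        for nb in nbrs:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen
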