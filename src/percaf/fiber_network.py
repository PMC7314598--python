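"""Stochastic anisotropic fiber networks on a 3D lattice.

The tissue is an ``L_x x L_y x L_z`` block of nodes (cells or small groups of
cells) with open boundaries in x (the long axis of conduction) and z (the
transmural axis, z = 0 being the endocardium and z = L_z - 1 the epicardium)
and periodic boundaries in y.  Nodes are coupled to nearest neighbours by
bonds placed independently at random: longitudinal (+x) bonds with
probability nu_par and transverse (+y, +z) bonds with probability nu_perp,
optionally varying with depth z.  Once built, a network is immutable; focal
ablation produces a modified copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LatticeSpec",
    "CouplingProfile",
    "FiberNetwork",
    "Lesion",
    "Segment",
    "StructuralRiskReport",
    "InfeasibleProfileError",
    "layer_couplings",
    "build_profile",
    "build_network",
    "assign_block_susceptible",
    "apply_lesion",
    "percolates",
    "find_isolated_segments",
    "save_network",
    "load_network",
]


class InfeasibleProfileError(ValueError):
    """Raised when (nu_bar, delta_theta) has no valid bond probabilities."""


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice dimensions.

    x is open (sinus node at x = 0), y is periodic, z is open and transmural
    with z = 0 the endocardium.
    """

    L_x: int = 200
    L_y: int = 200
    L_z: int = 25

    def __post_init__(self):
        if min(self.L_x, self.L_y, self.L_z) < 1:
            raise ValueError("all lattice extents must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.L_x, self.L_y, self.L_z)

    @property
    def n_nodes(self) -> int:
        return self.L_x * self.L_y * self.L_z


@dataclass(frozen=True)
class CouplingProfile:
    """Per-layer bond probabilities.

    ``nu_par[z]`` is the probability of a +x bond for nodes in layer z and
    ``nu_perp[z]`` that of a +y bond; +z bonds between layers z and z+1 use
    ``nu_perp[z]`` of the lower layer.  In inhomogeneous mode the mean
    coupling nu_bar = (2 nu_par + 4 nu_perp) / 6 is held fixed while the mean
    fiber angle delta_theta = atan(nu_perp / nu_par) varies linearly from the
    endocardial to the epicardial value.
    """

    nu_par: np.ndarray
    nu_perp: np.ndarray
    mode: str = "homogeneous"
    nu_bar: float | None = None
    theta_endo: float | None = None
    theta_epi: float | None = None

    def __post_init__(self):
        nu_par = np.asarray(self.nu_par, dtype=float)
        nu_perp = np.asarray(self.nu_perp, dtype=float)
        object.__setattr__(self, "nu_par", nu_par)
        object.__setattr__(self, "nu_perp", nu_perp)
        if nu_par.shape != nu_perp.shape or nu_par.ndim != 1:
            raise ValueError("nu_par and nu_perp must be 1D arrays of equal length")
        for arr, name in ((nu_par, "nu_par"), (nu_perp, "nu_perp")):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def mean_coupling(self) -> np.ndarray:
        """Per-layer (2 nu_par + 4 nu_perp) / 6."""
        return (2.0 * self.nu_par + 4.0 * self.nu_perp) / 6.0


def layer_couplings(nu_bar: float, delta_theta_deg: float) -> tuple[float, float]:
    """Solve for (nu_par, nu_perp) given mean coupling and fiber angle.

    The two defining relations are nu_bar = (2 nu_par + 4 nu_perp) / 6 and
    delta_theta = atan(nu_perp / nu_par), giving
    nu_par = 3 nu_bar / (1 + 2 tan(delta_theta)) and
    nu_perp = nu_par * tan(delta_theta).

    Raises
    ------
    InfeasibleProfileError
        If either probability would exceed 1 (e.g. small angles at high
        mean coupling).
    """
    if not 0.0 <= nu_bar <= 1.0:
        raise ValueError("nu_bar must lie in [0, 1]")
    if not 0.0 <= delta_theta_deg <= 90.0:
        raise ValueError("delta_theta must lie in [0, 90] degrees")
    if delta_theta_deg == 90.0:
        nu_par, nu_perp = 0.0, 1.5 * nu_bar
    else:
        t = math.tan(math.radians(delta_theta_deg))
        nu_par = 3.0 * nu_bar / (1.0 + 2.0 * t)
        nu_perp = nu_par * t
    if nu_par > 1.0 + 1e-12 or nu_perp > 1.0 + 1e-12:
        raise InfeasibleProfileError(
            f"nu_bar={nu_bar}, delta_theta={delta_theta_deg} deg requires "
            f"nu_par={nu_par:.4f}, nu_perp={nu_perp:.4f} > 1"
        )
    return min(nu_par, 1.0), min(nu_perp, 1.0)


def build_profile(
    spec: LatticeSpec,
    mode: str = "homogeneous",
    *,
    nu_par: float | None = None,
    nu_perp: float | None = None,
    nu_bar: float | None = None,
    theta_endo: float = 24.0,
    theta_epi: float = 42.0,
) -> CouplingProfile:
    """Build a per-layer coupling profile.

    Homogeneous mode takes explicit (nu_par, nu_perp), constant in depth.
    Inhomogeneous mode takes (nu_bar, theta_endo, theta_epi) and interpolates
    the fiber angle linearly across layers while holding nu_bar fixed in
    every layer: delta_theta(z) = theta_endo + (theta_epi - theta_endo) *
    z / (L_z - 1).
    """
    L_z = spec.L_z
    if mode == "homogeneous":
        if nu_par is None or nu_perp is None:
            raise ValueError("homogeneous mode requires nu_par and nu_perp")
        return CouplingProfile(
            nu_par=np.full(L_z, float(nu_par)),
            nu_perp=np.full(L_z, float(nu_perp)),
            mode="homogeneous",
        )
    if mode == "inhomogeneous":
        if nu_bar is None:
            raise ValueError("inhomogeneous mode requires nu_bar")
        if L_z == 1:
            thetas = np.array([0.5 * (theta_endo + theta_epi)])
        else:
            thetas = theta_endo + (theta_epi - theta_endo) * np.arange(L_z) / (L_z - 1)
        pairs = [layer_couplings(nu_bar, th) for th in thetas]
        return CouplingProfile(
            nu_par=np.array([p[0] for p in pairs]),
            nu_perp=np.array([p[1] for p in pairs]),
            mode="inhomogeneous",
            nu_bar=float(nu_bar),
            theta_endo=float(theta_endo),
            theta_epi=float(theta_epi),
        )
    raise ValueError(f"unknown profile mode {mode!r}")


@dataclass(frozen=True)
class Lesion:
    """An axis-aligned focal-ablation footprint.

    Nodes with x in [x0, x1], y in [y0, y1] (modulo L_y, so the footprint
    may wrap), and z in [0, depth) are destroyed: every bond incident to
    them is removed.  ``depth == L_z`` is a transmural lesion.
    """

    x0: int
    x1: int
    y0: int
    y1: int
    depth: int

    def node_mask(self, spec: LatticeSpec) -> np.ndarray:
        if not (0 <= self.x0 <= self.x1 < spec.L_x):
            raise ValueError("lesion x-extent out of bounds")
        if not 1 <= self.depth <= spec.L_z:
            raise ValueError("lesion depth out of bounds")
        if self.y1 - self.y0 + 1 > spec.L_y or self.y0 < 0:
            raise ValueError("lesion y-extent out of bounds")
        mask = np.zeros(spec.shape, dtype=bool)
        ys = np.arange(self.y0, self.y1 + 1) % spec.L_y
        mask[self.x0 : self.x1 + 1, ys.reshape(1, -1), : self.depth] = True
        return mask

    @property
    def transmural_if(self) -> int:
        return self.depth

    def contains_xy(self, x: np.ndarray, y: np.ndarray, L_y: int) -> np.ndarray:
        """Whether (x, y) columns fall inside the footprint (any depth)."""
        in_x = (x >= self.x0) & (x <= self.x1)
        span = self.y1 - self.y0
        in_y = ((y - self.y0) % L_y) <= span
        return in_x & in_y


@dataclass(frozen=True)
class FiberNetwork:
    """A fixed random fiber network plus its block-susceptible node mask.

    ``bond_x[i, j, k]`` indicates a bond from node (i, j, k) to (i+1, j, k);
    analogously for bond_y (periodic wrap in j) and bond_z.  Bonds at the
    open boundaries (+x at x = L_x - 1, +z at z = L_z - 1) are always absent.
    """

    spec: LatticeSpec
    profile: CouplingProfile
    bond_x: np.ndarray
    bond_y: np.ndarray
    bond_z: np.ndarray
    susceptible: np.ndarray
    structure_seed: int | None = None
    block_seed: int | None = None
    lesions: tuple[Lesion, ...] = field(default=())

    def __post_init__(self):
        for name in ("bond_x", "bond_y", "bond_z", "susceptible"):
            arr = getattr(self, name)
            if arr.shape != self.spec.shape:
                raise ValueError(f"{name} must have shape {self.spec.shape}")
        if self.bond_x[-1].any():
            raise ValueError("+x bonds must be absent at x = L_x - 1")
        if self.bond_z[:, :, -1].any():
            raise ValueError("+z bonds must be absent at z = L_z - 1")

    @property
    def n_nodes(self) -> int:
        return self.spec.n_nodes

    def flat_bonds(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Bond arrays flattened C-order as uint8 (kernel input)."""
        return (
            np.ascontiguousarray(self.bond_x, dtype=np.uint8).ravel(),
            np.ascontiguousarray(self.bond_y, dtype=np.uint8).ravel(),
            np.ascontiguousarray(self.bond_z, dtype=np.uint8).ravel(),
        )


def build_network(
    spec: LatticeSpec, profile: CouplingProfile, structure_seed: int
) -> FiberNetwork:
    """Draw a fiber network: each candidate bond is present independently.

    +x bonds in layer z appear with probability nu_par[z]; +y bonds with
    nu_perp[z]; +z bonds between layers z and z+1 with nu_perp[z] of the
    lower layer.  Deterministic given ``structure_seed``.
    """
    if len(profile.nu_par) != spec.L_z:
        raise ValueError("profile length must equal L_z")
    rng = np.random.default_rng(structure_seed)
    shape = spec.shape
    bond_x = rng.random(shape) < profile.nu_par[None, None, :]
    bond_y = rng.random(shape) < profile.nu_perp[None, None, :]
    bond_z = rng.random(shape) < profile.nu_perp[None, None, :]
    bond_x[-1, :, :] = False
    bond_z[:, :, -1] = False
    if spec.L_y == 1:
        bond_y[:] = False  # a single periodic row has no distinct y-neighbour
    return FiberNetwork(
        spec=spec,
        profile=profile,
        bond_x=bond_x,
        bond_y=bond_y,
        bond_z=bond_z,
        susceptible=np.zeros(shape, dtype=bool),
        structure_seed=int(structure_seed),
    )


def assign_block_susceptible(
    network: FiberNetwork, delta: float, seed: int
) -> FiberNetwork:
    """Mark each node block-susceptible independently with probability delta."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(network.spec.shape) < delta
    return replace(network, susceptible=mask, block_seed=int(seed))


def apply_lesion(network: FiberNetwork, lesion: Lesion) -> FiberNetwork:
    """Destroy the nodes in the lesion volume (returns a modified copy).

    A destroyed node loses every incident bond, so it can neither excite nor
    be excited.  Applying the same lesion twice is a no-op; distinct lesions
    commute.
    """
    mask = lesion.node_mask(network.spec)
    bx = network.bond_x & ~mask
    bx[:-1] &= ~mask[1:]
    by = network.bond_y & ~mask
    by &= ~np.roll(mask, -1, axis=1)
    bz = network.bond_z & ~mask
    bz[:, :, :-1] &= ~mask[:, :, 1:]
    return replace(
        network,
        bond_x=bx,
        bond_y=by,
        bond_z=bz,
        susceptible=network.susceptible & ~mask,
        lesions=network.lesions + (lesion,),
    )


def _adjacency(network: FiberNetwork):
    """Sparse symmetric adjacency of the bond graph (flat C-order indices)."""
    from scipy import sparse

    L_x, L_y, L_z = network.spec.shape
    n = network.n_nodes
    idx = np.arange(n).reshape(network.spec.shape)
    rows, cols = [], []
    bx = network.bond_x[:-1] if L_x > 1 else np.zeros((0, L_y, L_z), bool)
    if L_x > 1:
        r = idx[:-1][bx]
        rows.append(r)
        cols.append(r + L_y * L_z)
    if L_y > 1:
        by = network.bond_y
        r = idx[by]
        rows.append(r)
        cols.append(idx[:, list(range(1, L_y)) + [0], :][by])
    if L_z > 1:
        bz = network.bond_z[:, :, :-1]
        r = idx[:, :, :-1][bz]
        rows.append(r)
        cols.append(r + 1)
    if not rows:
        return sparse.csr_matrix((n, n))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(rows.size, dtype=np.int8)
    adj = sparse.coo_matrix((data, (rows, cols)), shape=(n, n))
    return (adj + adj.T).tocsr()


def percolates(network: FiberNetwork) -> bool:
    """Whether a bond path connects the x = 0 plane to the x = L_x - 1 plane."""
    from scipy.sparse.csgraph import connected_components

    spec = network.spec
    if spec.L_x == 1:
        return True
    adj = _adjacency(network)
    _, labels = connected_components(adj, directed=False)
    labels = labels.reshape(spec.shape)
    return bool(np.isin(labels[0], labels[-1]).any())


@dataclass(frozen=True)
class Segment:
    """A maximal isolated longitudinal run of nodes.

    Nodes (x0..x0+length-1, y, z) are chained by +x bonds; interior nodes
    carry no transverse (y or z) bonds, while both end nodes attach to the
    surrounding tissue through at least one transverse bond.  The segment can
    host reentry when twice its length exceeds the refractory period.
    """

    x0: int
    y: int
    z: int
    length: int

    @property
    def depth(self) -> int:
        return self.z

    def nodes(self) -> list[tuple[int, int, int]]:
        return [(self.x0 + i, self.y, self.z) for i in range(self.length)]


@dataclass(frozen=True)
class StructuralRiskReport:
    percolates: bool
    segments: tuple[Segment, ...]
    tau: int

    @property
    def reentry_capable(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if 2 * s.length > self.tau)

    @property
    def n_reentry_capable(self) -> int:
        return len(self.reentry_capable)


def _transverse_presence(network: FiberNetwork) -> np.ndarray:
    """Whether each node has at least one y or z bond."""
    by = network.bond_y
    bz = network.bond_z
    has = by | np.roll(by, 1, axis=1)
    has = has | bz
    has[:, :, 1:] |= bz[:, :, :-1]
    if network.spec.L_y == 1:
        has = bz.copy()
        has[:, :, 1:] |= bz[:, :, :-1]
    return has


def find_isolated_segments(network: FiberNetwork, tau: int) -> StructuralRiskReport:
    """Census of isolated longitudinal segments (the structural substrate of
    reentry) together with the percolation status of the network.

    A segment is a run of >= 3 nodes chained by +x bonds whose interior
    nodes have no transverse bonds and whose two end nodes each have at
    least one transverse bond (so the run attaches to the bulk at both ends
    and a closed loop around it exists).
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    L_x, L_y, L_z = network.spec.shape
    trans = _transverse_presence(network)
    bx = network.bond_x
    segments = []
    for y in range(L_y):
        for z in range(L_z):
            row_bx = bx[:, y, z]
            row_tr = trans[:, y, z]
            x = 0
            while x < L_x:
                if not row_tr[x]:
                    x += 1
                    continue
                # potential left anchor: extend while chained and interior
                # stays transverse-free
                end = x
                while end < L_x - 1 and row_bx[end] and not row_tr[end + 1]:
                    end += 1
                # the run x..end has interior free of transverse bonds; it is
                # a valid segment if it closed on a transverse-bearing node
                if end > x and end < L_x - 1 and row_bx[end] and row_tr[end + 1]:
                    length = end + 2 - x
                    if length >= 3:
                        segments.append(Segment(x0=x, y=y, z=z, length=length))
                    x = end + 1
                else:
                    x = max(end, x + 1)
    return StructuralRiskReport(
        percolates=percolates(network), segments=tuple(segments), tau=int(tau)
    )


def save_network(network: FiberNetwork, path) -> None:
    """Serialize a network to a compressed .npz container (lossless)."""
    np.savez_compressed(
        path,
        bond_x=network.bond_x,
        bond_y=network.bond_y,
        bond_z=network.bond_z,
        susceptible=network.susceptible,
        nu_par=network.profile.nu_par,
        nu_perp=network.profile.nu_perp,
        mode=np.array(network.profile.mode),
        meta=np.array(
            [
                network.structure_seed if network.structure_seed is not None else -1,
                network.block_seed if network.block_seed is not None else -1,
            ],
            dtype=np.int64,
        ),
        lesions=np.array(
            [[l.x0, l.x1, l.y0, l.y1, l.depth] for l in network.lesions],
            dtype=np.int64,
        ).reshape(-1, 5),
    )


def load_network(path) -> FiberNetwork:
    with np.load(path, allow_pickle=False) as f:
        bond_x = f["bond_x"]
        spec = LatticeSpec(*bond_x.shape)
        profile = CouplingProfile(
            nu_par=f["nu_par"], nu_perp=f["nu_perp"], mode=str(f["mode"])
        )
        meta = f["meta"]
        lesions = tuple(Lesion(*map(int, row)) for row in f["lesions"])
        return FiberNetwork(
            spec=spec,
            profile=profile,
            bond_x=bond_x,
            bond_y=f["bond_y"],
            bond_z=f["bond_z"],
            susceptible=f["susceptible"],
            structure_seed=int(meta[0]) if meta[0] >= 0 else None,
            block_seed=int(meta[1]) if meta[1] >= 0 else None,
            lesions=lesions,
        )
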