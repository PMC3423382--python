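"""Passive dendritic morphologies: SWC I/O, discretization, synthetic trees.

A :class:`CompartmentTree` is a rooted tree of points in the standard SWC
sense (id, type, x, y, z, radius, parent) plus uniform specific electrical
constants.  The root is the soma; when its SWC type code is 1 it is treated
as an isopotential sphere whose membrane area is that of the equivalent
sphere, otherwise it is lumped like any other node.  Each child node owns the
frustum segment joining it to its parent; half of the frustum's lateral
membrane area is lumped onto each endpoint (centered compartmentalization).

Units: coordinates and radii in um, R_a in Ohm*cm, R_m in Ohm*cm^2,
C_m in uF/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CompartmentTree",
    "SwcParseError",
    "TreeStructureError",
    "read_swc",
    "write_swc",
    "discretize",
    "generate_synthetic_tree",
]

UM_TO_CM = 1e-4


class SwcParseError(ValueError):
    """Raised for malformed SWC content; carries the offending line number."""


class TreeStructureError(ValueError):
    """Raised for dangling parents, cycles, or multiple roots."""


@dataclass
class CompartmentTree:
    """Rooted compartmental tree with uniform electrical constants.

    Attributes
    ----------
    ids, parent_ids, type_codes : int arrays (parent_id of the root is -1)
    xyz : (n, 3) float array, um
    radius : (n,) float array, um
    r_a : axial resistivity, Ohm*cm
    r_m : specific membrane resistivity, Ohm*cm^2
    c_m : specific membrane capacitance, uF/cm^2
    """

    ids: np.ndarray
    parent_ids: np.ndarray
    type_codes: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    r_a: float = 70.0
    r_m: float = 10000.0
    c_m: float = 1.0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.parent_ids = np.asarray(self.parent_ids, dtype=int)
        self.type_codes = np.asarray(self.type_codes, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        if len(self.ids) != len(set(self.ids.tolist())):
            raise TreeStructureError("duplicate node ids")
        roots = np.flatnonzero(self.parent_ids < 0)
        if len(roots) != 1:
            raise TreeStructureError(f"expected exactly one root, found {len(roots)}")
        for i, pid in zip(self.ids, self.parent_ids):
            if pid >= 0 and int(pid) not in self._index:
                raise TreeStructureError(f"node {int(i)} has dangling parent {int(pid)}")
            if pid == i:
                raise TreeStructureError(f"node {int(i)} is its own parent")
        # parent-precedes-child ordering guarantees acyclicity
        for k, pid in enumerate(self.parent_ids):
            if pid >= 0 and self._index[int(pid)] >= k:
                raise TreeStructureError(
                    f"node {int(self.ids[k])} appears before its parent {int(pid)}"
                )
        if np.any(self.radius <= 0):
            raise TreeStructureError("all radii must be positive")
        if np.any(self.segment_lengths()[1:] <= 0):
            raise TreeStructureError("all segment lengths must be positive")
        if min(self.r_a, self.r_m, self.c_m) <= 0:
            raise TreeStructureError("electrical constants must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent_ids < 0)[0])

    @property
    def soma_node(self) -> int:
        """Id of the soma (type-1 node if present, else the root)."""
        somatic = np.flatnonzero(self.type_codes == 1)
        return int(self.ids[somatic[0]]) if len(somatic) else int(self.ids[self.root_index])

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def parent_index(self) -> np.ndarray:
        """Positional index of each node's parent (-1 for the root)."""
        out = np.full(self.n_nodes, -1, dtype=int)
        for k, pid in enumerate(self.parent_ids):
            if pid >= 0:
                out[k] = self._index[int(pid)]
        return out

    # -- geometry ----------------------------------------------------------

    def segment_lengths(self) -> np.ndarray:
        """Straight-line length (um) of the segment owned by each node; 0 at root."""
        pidx = self.parent_index()
        out = np.zeros(self.n_nodes)
        child = pidx >= 0
        out[child] = np.linalg.norm(self.xyz[child] - self.xyz[pidx[child]], axis=1)
        return out

    def path_distance(self) -> np.ndarray:
        """Cumulative path length from the root along the tree, um."""
        pidx = self.parent_index()
        seg = self.segment_lengths()
        out = np.zeros(self.n_nodes)
        for k in range(self.n_nodes):  # parents precede children
            if pidx[k] >= 0:
                out[k] = out[pidx[k]] + seg[k]
        return out

    def segment_areas(self) -> np.ndarray:
        """Lateral frustum area pi*(r_parent + r_child)*L (um^2) per node; 0 at root."""
        pidx = self.parent_index()
        seg = self.segment_lengths()
        out = np.zeros(self.n_nodes)
        child = pidx >= 0
        out[child] = math.pi * (self.radius[child] + self.radius[pidx[child]]) * seg[child]
        return out

    def membrane_areas(self) -> np.ndarray:
        """Membrane area (um^2) lumped onto each node.

        Half of every frustum goes to each endpoint; a type-1 root
        additionally contributes its spherical surface.
        """
        pidx = self.parent_index()
        seg_a = self.segment_areas()
        out = np.zeros(self.n_nodes)
        for k in range(self.n_nodes):
            if pidx[k] >= 0:
                out[k] += 0.5 * seg_a[k]
                out[pidx[k]] += 0.5 * seg_a[k]
        r = self.root_index
        if self.type_codes[r] == 1:
            out[r] += 4.0 * math.pi * self.radius[r] ** 2
        return out

    def total_membrane_area(self) -> float:
        return float(self.membrane_areas().sum())

    def axial_conductances(self) -> np.ndarray:
        """Axial conductance (Siemens) of the segment owned by each node; 0 at root."""
        pidx = self.parent_index()
        seg = self.segment_lengths() * UM_TO_CM
        out = np.zeros(self.n_nodes)
        child = pidx >= 0
        r1 = self.radius[child] * UM_TO_CM
        r2 = self.radius[pidx[child]] * UM_TO_CM
        out[child] = math.pi * r1 * r2 / (self.r_a * seg[child])
        return out

    def with_constants(self, r_a=None, r_m=None, c_m=None) -> "CompartmentTree":
        return replace(
            self,
            r_a=self.r_a if r_a is None else r_a,
            r_m=self.r_m if r_m is None else r_m,
            c_m=self.c_m if c_m is None else c_m,
        )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path, r_a: float = 70.0, r_m: float = 10000.0, c_m: float = 1.0) -> CompartmentTree:
    """Parse a standard 7-column SWC file into a :class:`CompartmentTree`."""
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SwcParseError(f"line {lineno}: expected 7 columns, got {len(cols)}")
            try:
                ids.append(int(cols[0]))
                types.append(int(cols[1]))
                xyz.append([float(c) for c in cols[2:5]])
                radii.append(float(cols[5]))
                parents.append(int(cols[6]))
            except ValueError as exc:
                raise SwcParseError(f"line {lineno}: {exc}") from exc
    if not ids:
        raise SwcParseError("empty SWC file")
    return CompartmentTree(
        ids=np.array(ids),
        parent_ids=np.array(parents),
        type_codes=np.array(types),
        xyz=np.array(xyz),
        radius=np.array(radii),
        r_a=r_a,
        r_m=r_m,
        c_m=c_m,
    )


def write_swc(tree: CompartmentTree, path) -> None:
    """Write a tree as standard 7-column SWC (1-based ids preserved)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i, t, (x, y, z), r, p in zip(
            tree.ids, tree.type_codes, tree.xyz, tree.radius, tree.parent_ids
        ):
            fh.write(f"{int(i)} {int(t)} {x:.6f} {y:.6f} {z:.6f} {r:.6f} {int(p)}\n")


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(tree: CompartmentTree, max_segment_length: float) -> CompartmentTree:
    """Split every segment longer than ``max_segment_length`` (um).

    Intermediate nodes interpolate position and radius linearly, which
    preserves topology and total frustum membrane area exactly.
    """
    if max_segment_length <= 0:
        raise ValueError("max_segment_length must be positive")
    pidx = tree.parent_index()
    seg = tree.segment_lengths()

    new_ids, new_types, new_xyz, new_rad, new_par = [], [], [], [], []
    next_id = int(tree.ids.max()) + 1
    # map original positional index -> new id (unchanged: original ids kept)
    for k in range(tree.n_nodes):
        if pidx[k] < 0 or seg[k] <= max_segment_length:
            new_ids.append(int(tree.ids[k]))
            new_types.append(int(tree.type_codes[k]))
            new_xyz.append(tree.xyz[k])
            new_rad.append(float(tree.radius[k]))
            new_par.append(int(tree.parent_ids[k]))
            continue
        n_pieces = int(math.ceil(seg[k] / max_segment_length))
        p = pidx[k]
        prev_id = int(tree.ids[p])
        for j in range(1, n_pieces):
            t = j / n_pieces
            new_ids.append(next_id)
            new_types.append(int(tree.type_codes[k]))
            new_xyz.append((1 - t) * tree.xyz[p] + t * tree.xyz[k])
            new_rad.append((1 - t) * tree.radius[p] + t * tree.radius[k])
            new_par.append(prev_id)
            prev_id = next_id
            next_id += 1
        new_ids.append(int(tree.ids[k]))
        new_types.append(int(tree.type_codes[k]))
        new_xyz.append(tree.xyz[k])
        new_rad.append(float(tree.radius[k]))
        new_par.append(prev_id)
    return CompartmentTree(
        ids=np.array(new_ids),
        parent_ids=np.array(new_par),
        type_codes=np.array(new_types),
        xyz=np.array(new_xyz),
        radius=np.array(new_rad),
        r_a=tree.r_a,
        r_m=tree.r_m,
        c_m=tree.c_m,
    )


# ---------------------------------------------------------------------------
# Synthetic morphologies
# ---------------------------------------------------------------------------

def generate_synthetic_tree(kind: str, parameters: dict | None = None, seed: int = 0) -> CompartmentTree:
    """Deterministic synthetic morphology generator.

    Kinds
    -----
    ``ball_and_stick``
        Spherical soma plus a single unbranched cylinder.  Parameters:
        ``length`` (um, default 1854, the distal extent of a large cat
        motor-neuron dendritic tree), ``radius`` (um, 2.0), ``soma_radius``
        (um, 25.0), ``step`` (um, 20.0).
    ``symmetric_binary``
        Soma plus a symmetric binary tree with Rall 3/2-power tapering at
        branch points.  Parameters: ``levels`` (3), ``branch_length`` (200),
        ``stem_radius`` (3.0), ``soma_radius`` (25.0), ``step`` (20.0).
    ``random_taper``
        Randomly branched, tapering tree drawn from ``numpy`` RNG with the
        given ``seed``.  Parameters: ``n_branches`` (12), ``mean_length``
        (150), ``stem_radius`` (3.0), ``soma_radius`` (25.0), ``step`` (20).
    """
    params = dict(parameters or {})
    if kind == "ball_and_stick":
        return _ball_and_stick(
            length=params.pop("length", 1854.0),
            radius=params.pop("radius", 2.0),
            soma_radius=params.pop("soma_radius", 25.0),
            step=params.pop("step", 20.0),
            **_reject_extras(params, kind),
        )
    if kind == "symmetric_binary":
        return _symmetric_binary(
            levels=params.pop("levels", 3),
            branch_length=params.pop("branch_length", 200.0),
            stem_radius=params.pop("stem_radius", 3.0),
            soma_radius=params.pop("soma_radius", 25.0),
            step=params.pop("step", 20.0),
            **_reject_extras(params, kind),
        )
    if kind == "random_taper":
        return _random_taper(
            n_branches=params.pop("n_branches", 12),
            mean_length=params.pop("mean_length", 150.0),
            stem_radius=params.pop("stem_radius", 3.0),
            soma_radius=params.pop("soma_radius", 25.0),
            step=params.pop("step", 20.0),
            seed=seed,
            **_reject_extras(params, kind),
        )
    raise ValueError(f"unknown synthetic tree kind: {kind!r}")


def _reject_extras(params: dict, kind: str) -> dict:
    if params:
        raise ValueError(f"unknown parameters for {kind}: {sorted(params)}")
    return {}


class _Builder:
    def __init__(self, soma_radius: float):
        self.rows = [(1, 1, 0.0, 0.0, 0.0, soma_radius, -1)]
        self.next_id = 2

    def add(self, parent_id: int, x: float, y: float, z: float, radius: float, type_code: int = 3) -> int:
        nid = self.next_id
        self.rows.append((nid, type_code, x, y, z, radius, parent_id))
        self.next_id += 1
        return nid

    def chain(self, parent_id, p0, p1, radius0, radius1, step) -> int:
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        length = float(np.linalg.norm(p1 - p0))
        n = max(1, int(math.ceil(length / step)))
        pid = parent_id
        for j in range(1, n + 1):
            t = j / n
            q = (1 - t) * p0 + t * p1
            r = (1 - t) * radius0 + t * radius1
            pid = self.add(pid, q[0], q[1], q[2], r)
        return pid

    def build(self) -> CompartmentTree:
        return CompartmentTree(
            ids=np.array([r[0] for r in self.rows]),
            parent_ids=np.array([r[6] for r in self.rows]),
            type_codes=np.array([r[1] for r in self.rows]),
            xyz=np.array([[r[2], r[3], r[4]] for r in self.rows], dtype=float),
            radius=np.array([r[5] for r in self.rows], dtype=float),
        )


def _ball_and_stick(length, radius, soma_radius, step) -> CompartmentTree:
    b = _Builder(soma_radius)
    b.chain(1, (0, 0, 0), (length, 0, 0), radius, radius, step)
    return b.build()


def _symmetric_binary(levels, branch_length, stem_radius, soma_radius, step) -> CompartmentTree:
    b = _Builder(soma_radius)
    # breadth-first growth; children angled +/- 30 deg in the xy plane
    frontier = [(1, np.zeros(3), 0.0, stem_radius)]
    for level in range(levels):
        nxt = []
        n_children = 1 if level == 0 else 2
        for pid, pos, angle, r in frontier:
            child_r = r if level == 0 else r * 2.0 ** (-2.0 / 3.0)
            offs = [0.0] if n_children == 1 else [-math.pi / 6, math.pi / 6]
            for da in offs:
                a = angle + da
                tip = pos + branch_length * np.array([math.cos(a), math.sin(a), 0.0])
                cid = b.chain(pid, pos, tip, r if level == 0 else child_r, child_r, step)
                nxt.append((cid, tip, a, child_r))
        frontier = nxt
    return b.build()


def _random_taper(n_branches, mean_length, stem_radius, soma_radius, step, seed) -> CompartmentTree:
    rng = np.random.default_rng(seed)
    b = _Builder(soma_radius)
    # grow by attaching branches to random existing tips, radius tapering 0.8x
    tips = [(1, np.zeros(3), 0.0, stem_radius)]
    for _ in range(n_branches):
        k = int(rng.integers(len(tips)))
        pid, pos, angle, r = tips[k]
        length = float(rng.uniform(0.5, 1.5) * mean_length)
        a = angle + float(rng.uniform(-math.pi / 3, math.pi / 3))
        tip = pos + length * np.array([math.cos(a), math.sin(a), 0.0])
        child_r = max(0.3, 0.8 * r)
        cid = b.chain(pid, pos, tip, r, child_r, step)
        tips.append((cid, tip, a, child_r))
    return b.build()
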