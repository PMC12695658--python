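"""Branched neuron morphologies and their compartmental discretization.

A :class:`CellMorphology` is the geometric object (branches of 3D points
with radii, e.g. read from an SWC reconstruction); a :class:`CompartmentTree`
is the electrical object: a tree of short cylindrical compartments, each with
a length, radius, axial resistivity and specific capacitance, plus explicit
zero-area *junction nodes* at branch points (voltage is also solved at branch
points, mirroring common practice in compartmental simulators).

Distance convention: ``distance_from_soma`` measures *path length along the
tree* to the compartment midpoint.  Compartments of the designated soma
branch are the origin (distance 0) and dendritic path length accumulates
from the soma's distal attachment point; for trees built without a soma
marker the origin is the proximal end of the root compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MorphologyError",
    "CellMorphology",
    "CompartmentTree",
    "Section",
    "read_swc",
    "write_swc",
    "build_toy_cell",
    "build_cell_from_sections",
    "discretize",
    "distance_from_soma",
    "branch_midpoint_distance",
]

SOMA_TYPE = 1
DEFAULT_RA = 100.0  # Ω·cm
DEFAULT_CM = 1.0  # μF/cm²


class MorphologyError(ValueError):
    """Malformed morphology file or invalid geometry."""


@dataclass
class CellMorphology:
    """Branches of 3D points with per-point radii (μm).

    ``branches[b]`` is an ``(n_b, 4)`` array of ``x, y, z, radius``; a
    non-root branch shares its first point with the end of its parent, so a
    branch with ``n`` points has ``n - 1`` segments of positive length.
    """

    branches: list[np.ndarray]
    parent_branch: list[int]  # -1 for the root branch
    soma_branch: int | None = 0
    point_types: list[np.ndarray] = field(default_factory=list)

    def validate(self) -> None:
        seen_root = False
        for b, (pts, par) in enumerate(zip(self.branches, self.parent_branch)):
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 4:
                raise MorphologyError(f"branch {b}: points must be (n, 4)")
            if np.any(pts[:, 3] <= 0):
                raise MorphologyError(f"branch {b}: non-positive radius")
            if par == -1:
                seen_root = True
            elif not (0 <= par < len(self.branches)) or par == b:
                raise MorphologyError(f"branch {b}: bad parent {par}")
        if not seen_root:
            raise MorphologyError("no root branch")
        # acyclicity / single root: walk every branch up to the root
        for b in range(len(self.branches)):
            hops, cur = 0, b
            while self.parent_branch[cur] != -1:
                cur = self.parent_branch[cur]
                hops += 1
                if hops > len(self.branches):
                    raise MorphologyError("cyclic branch parent relation")

    @property
    def n_branches(self) -> int:
        return len(self.branches)


def _branch_length(points: np.ndarray) -> float:
    d = np.diff(points[:, :3], axis=0)
    return float(np.sum(np.sqrt(np.sum(d * d, axis=1))))


# ---------------------------------------------------------------------------
# SWC I/O (standard 7-column dialect: id type x y z radius parent)
# ---------------------------------------------------------------------------

def read_swc(path) -> CellMorphology:
    """Read a 7-column SWC file into a :class:`CellMorphology`.

    One branch per unbranched path between branch points/tips; non-root
    branches include the branch point itself as their first point. Ids may be
    0- or 1-based; they are normalized internally.
    """
    records: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise MorphologyError(
                    f"{path}:{lineno}: expected 7 columns, got {len(cols)}"
                )
            try:
                pid = int(cols[0])
                ptype = int(cols[1])
                x, y, z, radius = map(float, cols[2:6])
                parent = int(cols[6])
            except ValueError as err:
                raise MorphologyError(f"{path}:{lineno}: {err}") from None
            if pid in records:
                raise MorphologyError(f"{path}:{lineno}: duplicate id {pid}")
            if radius <= 0:
                raise MorphologyError(
                    f"{path}:{lineno}: non-positive radius {radius}"
                )
            if parent != -1 and parent not in records:
                raise MorphologyError(
                    f"{path}:{lineno}: parent {pid} -> {parent} is undefined "
                    "at this point (parents must precede children)"
                )
            if parent == pid:
                raise MorphologyError(f"{path}:{lineno}: self-parent {pid}")
            records[pid] = (ptype, x, y, z, radius, parent)
            order.append(pid)

    roots = [pid for pid in order if records[pid][5] == -1]
    if len(roots) != 1:
        raise MorphologyError(f"{path}: expected 1 root record, got {len(roots)}")
    soma_typed = [pid for pid in order if records[pid][0] == SOMA_TYPE]
    root = soma_typed[0] if soma_typed else roots[0]
    if records[root][5] != -1:
        # soma-typed record that is not the file root: fall back to the root
        root = roots[0]

    children: dict[int, list[int]] = {pid: [] for pid in order}
    for pid in order:
        par = records[pid][5]
        if par != -1:
            children[par].append(pid)

    def point_of(pid):
        t, x, y, z, r, _ = records[pid]
        return (x, y, z, r), t

    branches: list[np.ndarray] = []
    parent_branch: list[int] = []
    point_types: list[np.ndarray] = []
    # stack of (start point id, parent branch index, include_start_as_shared)
    stack = [(root, -1)]
    while stack:
        start, parent_b = stack.pop()
        pts, types = [], []
        if parent_b != -1:
            # shared branch-point geometry from the parent's end
            shared = branches[parent_b][-1]
            pts.append(tuple(shared))
            types.append(point_types[parent_b][-1])
        cur = start
        while True:
            (xyzr, t) = point_of(cur)
            pts.append(xyzr)
            types.append(t)
            kids = children[cur]
            if len(kids) == 1:
                cur = kids[0]
            else:
                break
        b = len(branches)
        branches.append(np.asarray(pts, dtype=float))
        parent_branch.append(parent_b)
        point_types.append(np.asarray(types, dtype=int))
        for kid in reversed(children[cur]):
            stack.append((kid, b))

    soma_b = None
    for b, types in enumerate(point_types):
        if types[0] == SOMA_TYPE and parent_branch[b] == -1:
            soma_b = b
            break
    morph = CellMorphology(branches, parent_branch, soma_branch=soma_b,
                           point_types=point_types)
    morph.validate()
    return morph


def write_swc(morph: CellMorphology, path) -> None:
    """Write a :class:`CellMorphology` as a standard SWC file."""
    morph.validate()
    lines = ["# SWC written by cablegrad (id type x y z radius parent)"]
    next_id = 1
    branch_last_id: dict[int, int] = {}
    # topological order over branches
    pending = [b for b, p in enumerate(morph.parent_branch) if p == -1]
    order: list[int] = []
    children: dict[int, list[int]] = {b: [] for b in range(morph.n_branches)}
    for b, p in enumerate(morph.parent_branch):
        if p != -1:
            children[p].append(b)
    while pending:
        b = pending.pop()
        order.append(b)
        pending.extend(reversed(children[b]))
    for b in order:
        pts = morph.branches[b]
        types = (
            morph.point_types[b]
            if morph.point_types
            else np.full(len(pts), 3, dtype=int)
        )
        start = 0
        if morph.parent_branch[b] == -1:
            parent_id = -1
        else:
            # first point is shared with the parent's last point: skip it
            start = 1
            parent_id = branch_last_id[morph.parent_branch[b]]
        for i in range(start, len(pts)):
            x, y, z, r = pts[i]
            lines.append(
                f"{next_id} {int(types[i])} {x:.9g} {y:.9g} {z:.9g} "
                f"{r:.9g} {parent_id}"
            )
            parent_id = next_id
            next_id += 1
        branch_last_id[b] = parent_id
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# compartment trees
# ---------------------------------------------------------------------------

@dataclass
class CompartmentTree:
    """Tree of cylindrical compartments plus zero-area junction nodes.

    Node arrays are ordered so that ``parent[i] < i`` (root at index 0),
    which is the elimination order used by the tree solver.  Junction nodes
    have zero length/radius/area and carry no membrane.
    """

    length: np.ndarray  # μm, 0 for junctions
    radius: np.ndarray  # μm, 0 for junctions
    ra: np.ndarray  # Ω·cm
    cm: np.ndarray  # μF/cm²
    parent: np.ndarray  # int, -1 for root
    branch_id: np.ndarray  # int, -1 for junctions
    branches: list[list[int]]  # node ids per branch, proximal to distal
    soma_branch: int | None = None
    section_name: dict[str, int] | None = None  # toy cells: name -> branch

    def validate(self) -> None:
        n = len(self.length)
        if not (len(self.radius) == len(self.parent) == n):
            raise MorphologyError("inconsistent node array lengths")
        for i in range(n):
            p = self.parent[i]
            if i == 0:
                if p != -1:
                    raise MorphologyError("node 0 must be the root")
            elif not (0 <= p < i):
                raise MorphologyError(
                    f"node {i}: parent {p} must precede it (tree order)"
                )
        comp = ~self.is_junction
        if np.any(self.length[comp] <= 0) or np.any(self.radius[comp] <= 0):
            raise MorphologyError("compartments need positive length/radius")
        if sum(len(b) for b in self.branches) != int(np.sum(comp)):
            raise MorphologyError("branch lists do not partition compartments")

    @property
    def n_nodes(self) -> int:
        return len(self.length)

    @property
    def is_junction(self) -> np.ndarray:
        return np.asarray(self.branch_id) < 0

    @property
    def n_compartments(self) -> int:
        return int(np.sum(~self.is_junction))

    @property
    def compartment_index(self) -> np.ndarray:
        """Node ids of true compartments, in node order."""
        return np.flatnonzero(~self.is_junction)

    def area(self) -> np.ndarray:
        """Lateral membrane area 2π·a·l per node (μm²); 0 for junctions."""
        return 2.0 * np.pi * self.radius * self.length

    def branch_nodes(self, b: int) -> list[int]:
        return self.branches[b]

    def node_of(self, section: str, pos: float = 0.5) -> int:
        """Node id at relative position ``pos`` along a named toy section."""
        if not self.section_name or section not in self.section_name:
            raise KeyError(f"unknown section {section!r}")
        nodes = self.branches[self.section_name[section]]
        k = min(int(pos * len(nodes)), len(nodes) - 1)
        return nodes[k]


@dataclass
class Section:
    """A straight cable section for programmatic toy morphologies."""

    name: str
    length: float  # μm (total)
    radius: float  # μm
    ncomp: int
    parent: str | None = None  # attaches at the parent's distal end


class _TreeBuilder:
    def __init__(self):
        self.length, self.radius, self.ra, self.cm = [], [], [], []
        self.parent, self.branch_id = [], []
        self.branches: list[list[int]] = []

    def add_node(self, length, radius, ra, cm, parent, branch_id):
        i = len(self.length)
        self.length.append(length)
        self.radius.append(radius)
        self.ra.append(ra)
        self.cm.append(cm)
        self.parent.append(parent)
        self.branch_id.append(branch_id)
        return i

    def add_branch(self, lengths, radii, ra, cm, attach_node):
        b = len(self.branches)
        nodes = []
        parent = attach_node
        for l, r in zip(lengths, radii):
            parent = self.add_node(l, r, ra, cm, parent, b)
            nodes.append(parent)
        self.branches.append(nodes)
        return b

    def add_junction(self, attach_node, ra, cm):
        return self.add_node(0.0, 0.0, ra, cm, attach_node, -1)

    def build(self, soma_branch=None, section_name=None) -> CompartmentTree:
        tree = CompartmentTree(
            length=np.asarray(self.length, dtype=float),
            radius=np.asarray(self.radius, dtype=float),
            ra=np.asarray(self.ra, dtype=float),
            cm=np.asarray(self.cm, dtype=float),
            parent=np.asarray(self.parent, dtype=int),
            branch_id=np.asarray(self.branch_id, dtype=int),
            branches=self.branches,
            soma_branch=soma_branch,
            section_name=section_name,
        )
        tree.validate()
        return tree


def build_cell_from_sections(
    sections: list[Section], ra: float = DEFAULT_RA, cm: float = DEFAULT_CM
) -> CompartmentTree:
    """Assemble sections into a :class:`CompartmentTree`.

    Sections attach at their parent's distal end; a zero-area junction node
    is inserted wherever two or more sections share an attachment point.
    """
    by_name = {s.name: s for s in sections}
    children: dict[str | None, list[Section]] = {}
    for s in sections:
        if s.ncomp < 1:
            raise MorphologyError(f"section {s.name}: ncomp must be >= 1")
        if s.length <= 0 or s.radius <= 0:
            raise MorphologyError(f"section {s.name}: need positive geometry")
        if s.parent is not None and s.parent not in by_name:
            raise MorphologyError(f"section {s.name}: unknown parent")
        children.setdefault(s.parent, []).append(s)
    roots = children.get(None, [])
    if len(roots) != 1:
        raise MorphologyError("exactly one root section required")

    tb = _TreeBuilder()
    section_branch: dict[str, int] = {}
    end_node: dict[str, int] = {}

    def emit(sec: Section, attach: int) -> None:
        lens = np.full(sec.ncomp, sec.length / sec.ncomp)
        b = tb.add_branch(lens, np.full(sec.ncomp, sec.radius), ra, cm, attach)
        section_branch[sec.name] = b
        end_node[sec.name] = tb.branches[b][-1]
        kids = children.get(sec.name, [])
        attach_pt = end_node[sec.name]
        if len(kids) >= 2:
            attach_pt = tb.add_junction(attach_pt, ra, cm)
        for kid in kids:
            emit(kid, attach_pt)

    emit(roots[0], -1)
    soma_b = None
    for name, b in section_branch.items():
        if name.startswith("soma"):
            soma_b = b
            break
    return tb.build(soma_branch=soma_b, section_name=section_branch)


def build_toy_cell(
    kind: str,
    geometry: dict | None = None,
    ncomp: dict | None = None,
    ra: float = DEFAULT_RA,
    cm: float = DEFAULT_CM,
) -> CompartmentTree:
    """Programmatic toy morphologies.

    ``ball_and_stick`` (default): one somatic compartment of radius 10 μm
    plus three neurite compartments of radius 1 μm and length 10 μm each —
    four compartments in total.  ``soma_two_dendrites``: a two-compartment
    soma with two five-compartment dendrites, twelve compartments in total.
    ``geometry``/``ncomp`` override per-section lengths, radii and
    compartment counts.
    """
    geometry = dict(geometry or {})
    ncomp = dict(ncomp or {})

    def g(sec, key, default):
        return geometry.get(sec, {}).get(key, default)

    if kind == "ball_and_stick":
        soma_r = g("soma", "radius", 10.0)
        secs = [
            Section("soma", g("soma", "length", 2 * soma_r), soma_r,
                    ncomp.get("soma", 1)),
            Section("neurite", g("neurite", "length", 30.0),
                    g("neurite", "radius", 1.0), ncomp.get("neurite", 3),
                    parent="soma"),
        ]
    elif kind == "soma_two_dendrites":
        soma_r = g("soma", "radius", 10.0)
        secs = [
            Section("soma", g("soma", "length", 2 * soma_r), soma_r,
                    ncomp.get("soma", 2)),
            Section("dend0", g("dend0", "length", 50.0),
                    g("dend0", "radius", 1.0), ncomp.get("dend0", 5),
                    parent="soma"),
            Section("dend1", g("dend1", "length", 50.0),
                    g("dend1", "radius", 1.0), ncomp.get("dend1", 5),
                    parent="soma"),
        ]
    else:
        raise MorphologyError(f"unknown toy cell kind {kind!r}")
    return build_cell_from_sections(secs, ra=ra, cm=cm)


def discretize(
    morph: CellMorphology,
    ncomp_per_branch: int,
    ra: float = DEFAULT_RA,
    cm: float = DEFAULT_CM,
) -> CompartmentTree:
    """Split each branch into equal-length compartments.

    The compartment radius is the length-weighted mean of the (linearly
    interpolated) point radii it spans; junction nodes are inserted at branch
    points.
    """
    if ncomp_per_branch < 1:
        raise MorphologyError("ncomp_per_branch must be >= 1")
    morph.validate()

    children: dict[int, list[int]] = {b: [] for b in range(morph.n_branches)}
    for b, p in enumerate(morph.parent_branch):
        if p != -1:
            children[p].append(b)

    tb = _TreeBuilder()
    branch_of = {}
    # traverse branches root-first so parents are emitted before children
    order, stack = [], [b for b, p in enumerate(morph.parent_branch) if p == -1]
    while stack:
        b = stack.pop()
        order.append(b)
        stack.extend(reversed(children[b]))

    attach_of: dict[int, int] = {}
    for b in order:
        pts = np.asarray(morph.branches[b], dtype=float)
        seglen = np.sqrt(np.sum(np.diff(pts[:, :3], axis=0) ** 2, axis=1))
        total = float(np.sum(seglen))
        if total <= 0:
            raise MorphologyError(f"branch {b}: zero length")
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        edges = np.linspace(0.0, total, ncomp_per_branch + 1)
        radii = []
        for k in range(ncomp_per_branch):
            radii.append(_mean_radius(arc, pts[:, 3], edges[k], edges[k + 1]))
        attach = attach_of.get(b, -1)
        nb = tb.add_branch(
            np.full(ncomp_per_branch, total / ncomp_per_branch),
            np.asarray(radii), ra, cm, attach,
        )
        branch_of[b] = nb
        attach_pt = tb.branches[nb][-1]
        kids = children[b]
        if len(kids) >= 2:
            attach_pt = tb.add_junction(attach_pt, ra, cm)
        for kid in kids:
            attach_of[kid] = attach_pt

    soma_b = (
        branch_of[morph.soma_branch] if morph.soma_branch is not None else None
    )
    return tb.build(soma_branch=soma_b)


def _mean_radius(arc, radii, s0, s1):
    """Average of the piecewise-linear radius profile over [s0, s1]."""
    # trapezoid integral of interpolated radius, / (s1 - s0)
    xs = np.unique(np.concatenate([[s0, s1], arc[(arc > s0) & (arc < s1)]]))
    rs = np.interp(xs, arc, radii)
    return float(np.trapezoid(rs, xs) / (s1 - s0))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_from_soma(tree: CompartmentTree) -> np.ndarray:
    """Path length (μm) from the soma to each node's midpoint.

    Soma-branch compartments are the origin (distance 0); for trees without a
    soma marker the origin is the root's proximal end.
    """
    n = tree.n_nodes
    dist = np.zeros(n)  # midpoint distances
    dist_end = np.zeros(n)  # distance at the node's distal end
    soma_b = tree.soma_branch
    for i in range(n):
        p = tree.parent[i]
        on_soma = soma_b is not None and tree.branch_id[i] == soma_b
        base = 0.0 if p == -1 else dist_end[p]
        if on_soma:
            dist[i] = 0.0
            dist_end[i] = 0.0
        else:
            dist[i] = base + tree.length[i] / 2.0
            dist_end[i] = base + tree.length[i]
    return dist


def branch_parent(tree: CompartmentTree) -> np.ndarray:
    """Parent branch index per branch (-1 for the root branch).

    Junction nodes are transparent: a branch whose first compartment hangs
    off a junction is parented to the branch feeding that junction.
    """
    out = np.full(len(tree.branches), -1, dtype=int)
    for b, nodes in enumerate(tree.branches):
        p = tree.parent[nodes[0]]
        while p != -1 and tree.branch_id[p] < 0:
            p = tree.parent[p]
        if p != -1:
            out[b] = tree.branch_id[p]
    return out


def branch_midpoint_distance(tree: CompartmentTree) -> np.ndarray:
    """Mean compartment-midpoint distance per branch (μm)."""
    dist = distance_from_soma(tree)
    return np.asarray(
        [float(np.mean(dist[list(nodes)])) for nodes in tree.branches]
    )
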