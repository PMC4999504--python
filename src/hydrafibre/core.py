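"""Domain types, periodic-boundary geometry and atom selections.

Everything downstream (order parameters, clustering, mapping, spectra)
consumes the three containers defined here: :class:`Topology` (chemistry and
connectivity), :class:`Frame` (one stored configuration) and
:class:`Trajectory` (an ordered, uniformly spaced sequence of frames).
Boxes are orthorhombic only; all distances are minimum-image.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .units import element_mass

GROUP_TAGS = ("hydrophobic_tail", "hydrophilic_head", "water", "bead", "other")

#: default residue-name → group_tag mapping, overridable per reader call
DEFAULT_GROUP_MAP = {
    "HOH": "water", "SOL": "water", "TIP3": "water", "TIP": "water",
    "W": "water", "WAT": "water",
    "PLM": "hydrophobic_tail", "PAL": "hydrophobic_tail",
    "C16": "hydrophobic_tail", "TAIL": "hydrophobic_tail",
    "ALA": "hydrophilic_head", "HIS": "hydrophilic_head",
    "HSD": "hydrophilic_head", "HSE": "hydrophilic_head",
    "LEU": "hydrophilic_head", "LYS": "hydrophilic_head",
    "GLY": "hydrophilic_head", "HEAD": "hydrophilic_head",
    "BEAD": "bead", "CG": "bead",
}


class TopologyError(ValueError):
    pass


class SelectionError(ValueError):
    """Raised when a selection expression fails to parse."""


@dataclass
class Atom:
    atom_id: int
    name: str
    element: str
    mass: float
    residue_name: str
    residue_index: int
    molecule_id: int
    group_tag: str = "other"


class Topology:
    """Array-backed atom table plus bond connectivity.

    Atom ids are dense 0-based indices; every atom belongs to exactly one
    molecule.  Parallel numpy arrays keep the per-atom attributes cheap to
    slice in the analysis modules.
    """

    def __init__(self, atoms: Sequence[Atom], bonds: Iterable[tuple] = ()):
        atoms = list(atoms)
        if not atoms:
            raise TopologyError("topology needs at least one atom")
        ids = np.array([a.atom_id for a in atoms])
        if not np.array_equal(ids, np.arange(len(atoms))):
            raise TopologyError("atom_ids must be dense 0..n-1 in order")
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        if np.any(self.masses <= 0):
            raise TopologyError("all masses must be > 0")
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.residue_indices = np.array([a.residue_index for a in atoms], dtype=int)
        self.molecule_ids = np.array([a.molecule_id for a in atoms], dtype=int)
        for a in atoms:
            if a.group_tag not in GROUP_TAGS:
                raise TopologyError(f"unknown group_tag {a.group_tag!r}")
        self.group_tags = np.array([a.group_tag for a in atoms], dtype=object)
        self.bonds = []
        n = len(atoms)
        for i, j in bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise TopologyError(f"bond ({i},{j}) references a missing atom")
            self.bonds.append((int(i), int(j)))
        self._molecule_index: Optional[dict] = None
        self._adjacency: Optional[list] = None

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    def atom(self, i: int) -> Atom:
        return Atom(i, self.names[i], self.elements[i], float(self.masses[i]),
                    self.residue_names[i], int(self.residue_indices[i]),
                    int(self.molecule_ids[i]), self.group_tags[i])

    def molecules(self) -> dict:
        """molecule_id → array of member atom ids (cached)."""
        if self._molecule_index is None:
            order = np.argsort(self.molecule_ids, kind="stable")
            self._molecule_index = {
                int(m): idx for m, idx in zip(
                    *_group_sorted(self.molecule_ids[order], order))
            }
        return self._molecule_index

    def adjacency(self) -> list:
        """Per-atom bonded-neighbour lists (cached)."""
        if self._adjacency is None:
            adj = [[] for _ in range(self.n_atoms)]
            for i, j in self.bonds:
                adj[i].append(j)
                adj[j].append(i)
            self._adjacency = adj
        return self._adjacency


def _group_sorted(sorted_keys, sorted_vals):
    """Split sorted parallel arrays into (unique keys, list of val arrays)."""
    uniq, starts = np.unique(sorted_keys, return_index=True)
    pieces = np.split(sorted_vals, starts[1:])
    return uniq, pieces


@dataclass
class Frame:
    """One stored configuration: time (ps), box edges (Å), coordinates (Å),
    optional velocities (Å/ps)."""

    time: float
    box: np.ndarray
    coordinates: np.ndarray
    velocities: Optional[np.ndarray] = None

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError("box edges must be > 0")
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coordinates.shape:
                raise ValueError("velocities must cover every atom")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


@dataclass
class Trajectory:
    """Ordered frames over one topology with uniform spacing dt (ps)."""

    topology: Topology
    frames: list = field(default_factory=list)

    def __post_init__(self):
        n = self.topology.n_atoms
        times = []
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(f"frame {k}: atom count {fr.n_atoms} != topology {n}")
            times.append(fr.time)
        times = np.asarray(times, dtype=float)
        if len(times) >= 2:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame spacing dt must be uniform")

    @classmethod
    def from_single(cls, topology: Topology, frame: Frame) -> "Trajectory":
        """Wrap one (Topology, Frame) pair as a 1-frame trajectory."""
        return cls(topology, [frame])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return float(self.frames[1].time - self.frames[0].time)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def has_velocities(self) -> bool:
        return all(f.velocities is not None for f in self.frames)


# ---------------------------------------------------------------------------
# Periodic-boundary geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(a, b, box) -> np.ndarray:
    """Minimum-image displacement b − a in an orthorhombic box.

    Each component lies in (−edge/2, +edge/2]; the returned vector is the
    shortest of all periodic images. Broadcasts over leading axes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be > 0")
    d = b - a
    return d - box * np.ceil(d / box - 0.5)


def minimum_image_distance(a, b, box) -> np.ndarray:
    """Minimum-image scalar distance(s) between positions a and b."""
    d = minimum_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_coordinates(coords, box) -> np.ndarray:
    """Wrap coordinates into [0, box) per axis."""
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    return coords - box * np.floor(coords / box)


def pair_distances(points_a, points_b, box, chunk: int = 2048):
    """Dense (len(a), len(b)) matrix of minimum-image distances, chunked to
    bound memory."""
    points_a = np.asarray(points_a, dtype=float)
    points_b = np.asarray(points_b, dtype=float)
    out = np.empty((len(points_a), len(points_b)))
    for s in range(0, len(points_a), chunk):
        blk = points_a[s:s + chunk, None, :] - points_b[None, :, :]
        blk -= box * np.ceil(blk / box - 0.5)
        out[s:s + chunk] = np.sqrt(np.sum(blk * blk, axis=-1))
    return out


def periodic_kdtree(points, box) -> cKDTree:
    """cKDTree over wrapped points with periodic boxsize."""
    pts = wrap_coordinates(points, box)
    # guard against points landing exactly on the upper boundary
    pts = np.where(pts >= box, 0.0, pts)
    return cKDTree(pts, boxsize=np.asarray(box, dtype=float))


def unwrap_group(coords, box, adjacency=None, members=None) -> np.ndarray:
    """Unwrap a connected group of positions across periodic boundaries.

    Starting from the first member, each neighbour is placed at its
    minimum-image position relative to an already-placed atom (breadth-first).
    ``adjacency`` maps local indices to lists of local indices; when omitted a
    chain 0-1-2-… is assumed. Unvisited components are anchored to the
    nearest already-placed atom by minimum image.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if members is None:
        members = list(range(n))
    if adjacency is None:
        adjacency = [[] for _ in range(n)]
        for i in range(n - 1):
            adjacency[i].append(i + 1)
            adjacency[i + 1].append(i)
    out = coords.copy()
    placed = np.zeros(n, dtype=bool)
    from collections import deque

    for root in range(n):
        if placed[root]:
            continue
        if placed.any():
            # anchor disconnected piece to the nearest placed atom
            ref = int(np.flatnonzero(placed)[0])
            out[root] = out[ref] + minimum_image_displacement(
                out[ref], coords[root], box)
        placed[root] = True
        queue = deque([root])
        while queue:
            i = queue.popleft()
            for j in adjacency[i]:
                if not placed[j]:
                    out[j] = out[i] + minimum_image_displacement(
                        out[i], coords[j], box)
                    placed[j] = True
                    queue.append(j)
    return out


def unwrap_molecule(topology: Topology, frame: Frame, atom_ids) -> np.ndarray:
    """Unwrap one molecule's coordinates using its bond connectivity."""
    atom_ids = np.asarray(sorted(atom_ids), dtype=int)
    local = {int(a): k for k, a in enumerate(atom_ids)}
    adj = [[] for _ in range(len(atom_ids))]
    full_adj = topology.adjacency()
    for a in atom_ids:
        for b in full_adj[a]:
            if b in local:
                adj[local[int(a)]].append(local[int(b)])
    return unwrap_group(frame.coordinates[atom_ids], frame.box, adjacency=adj)


# ---------------------------------------------------------------------------
# Selection mini-grammar
# ---------------------------------------------------------------------------
#
#   expr     := or_expr [ "within" NUMBER "of" expr ]
#   or_expr  := and_expr ( "or" and_expr )*
#   and_expr := unary ( "and" unary )*
#   unary    := "not" unary | primary
#   primary  := "(" expr ")" | "all" | "group" TAG | "element" SYM
#             | "resname" NAME | "molid" INT | "name" NAME
#
# "A within d of B" keeps the atoms of A belonging to molecules that have at
# least one A-atom within minimum-image distance d of any atom of B (whole
# molecules enter or leave the shell together).

_TOKEN_RE = re.compile(r"\s*([()]|[^\s()]+)")

_KEYWORDS = {"group", "element", "resname", "molid", "name", "all",
             "and", "or", "not", "within", "of"}


@dataclass
class SelectionSpec:
    """A parsed selection expression, reusable across frames."""

    expression: str

    def __post_init__(self):
        self._ast = _parse_selection(self.expression)

    def evaluate(self, topology: Topology, frame: Frame) -> np.ndarray:
        """Sorted array of atom ids matching the expression in this frame."""
        mask = self._ast.evaluate(topology, frame)
        return np.flatnonzero(mask)


def select(topology: Topology, frame: Frame, spec) -> np.ndarray:
    """Evaluate a SelectionSpec (or expression string) to sorted atom ids."""
    if isinstance(spec, str):
        spec = SelectionSpec(spec)
    return spec.evaluate(topology, frame)


class _Node:
    def evaluate(self, top, frame):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class _Match(_Node):
    kind: str
    value: object

    def evaluate(self, top, frame):
        if self.kind == "all":
            return np.ones(top.n_atoms, dtype=bool)
        if self.kind == "group":
            return top.group_tags == self.value
        if self.kind == "element":
            return np.array([e.upper() == self.value for e in top.elements])
        if self.kind == "resname":
            return np.array([r.upper() == self.value for r in top.residue_names])
        if self.kind == "name":
            return np.array([n.upper() == self.value for n in top.names])
        if self.kind == "molid":
            return top.molecule_ids == self.value
        raise SelectionError(f"unknown match kind {self.kind}")


@dataclass
class _BoolOp(_Node):
    op: str
    args: list

    def evaluate(self, top, frame):
        if self.op == "not":
            return ~self.args[0].evaluate(top, frame)
        masks = [a.evaluate(top, frame) for a in self.args]
        out = masks[0]
        for m in masks[1:]:
            out = (out & m) if self.op == "and" else (out | m)
        return out


@dataclass
class _Within(_Node):
    inner: _Node
    radius: float
    reference: _Node

    def evaluate(self, top, frame):
        mask_a = self.inner.evaluate(top, frame)
        mask_b = self.reference.evaluate(top, frame)
        if not mask_b.any() or not mask_a.any():
            return np.zeros(top.n_atoms, dtype=bool)
        ids_a = np.flatnonzero(mask_a)
        tree = periodic_kdtree(frame.coordinates[mask_b], frame.box)
        pts_a = wrap_coordinates(frame.coordinates[ids_a], frame.box)
        pts_a = np.where(pts_a >= frame.box, 0.0, pts_a)
        dist, _ = tree.query(pts_a, k=1)
        hit_ids = ids_a[dist <= self.radius]
        mols = np.unique(top.molecule_ids[hit_ids])
        return mask_a & np.isin(top.molecule_ids, mols)


def _tokenize(expr: str):
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self, expect=None):
        if self.i >= len(self.tokens):
            raise SelectionError(
                f"unexpected end of selection {self.expr!r}"
                + (f" (expected {expect})" if expect else ""))
        tok, pos = self.tokens[self.i]
        self.i += 1
        if expect is not None and tok != expect:
            raise SelectionError(
                f"expected {expect!r} at position {pos} in {self.expr!r}, got {tok!r}")
        return tok, pos

    def parse(self):
        node = self.parse_expr()
        if self.i < len(self.tokens):
            tok, pos = self.tokens[self.i]
            raise SelectionError(
                f"trailing token {tok!r} at position {pos} in {self.expr!r}")
        return node

    def parse_expr(self):
        node = self.parse_or()
        if self.peek() == "within":
            self.next()
            tok, pos = self.next(expect=None)
            try:
                radius = float(tok)
            except ValueError:
                raise SelectionError(
                    f"expected a distance at position {pos} in {self.expr!r}")
            if radius < 0:
                raise SelectionError("'within' radius must be >= 0")
            self.next(expect="of")
            ref = self.parse_expr()
            node = _Within(node, radius, ref)
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() == "or":
            self.next()
            node = _BoolOp("or", [node, self.parse_and()])
        return node

    def parse_and(self):
        node = self.parse_unary()
        while self.peek() == "and":
            self.next()
            node = _BoolOp("and", [node, self.parse_unary()])
        return node

    def parse_unary(self):
        if self.peek() == "not":
            self.next()
            return _BoolOp("not", [self.parse_unary()])
        return self.parse_primary()

    def parse_primary(self):
        tok, pos = self.next(expect=None)
        if tok == "(":
            node = self.parse_expr()
            self.next(expect=")")
            return node
        if tok == "all":
            return _Match("all", None)
        if tok == "group":
            val, vpos = self.next()
            if val not in GROUP_TAGS:
                raise SelectionError(
                    f"unknown group tag {val!r} at position {vpos}")
            return _Match("group", val)
        if tok == "element":
            val, _ = self.next()
            return _Match("element", val.upper())
        if tok == "resname":
            val, _ = self.next()
            return _Match("resname", val.upper())
        if tok == "name":
            val, _ = self.next()
            return _Match("name", val.upper())
        if tok == "molid":
            val, vpos = self.next()
            try:
                return _Match("molid", int(val))
            except ValueError:
                raise SelectionError(
                    f"molid expects an integer at position {vpos}")
        raise SelectionError(
            f"unexpected token {tok!r} at position {pos} in {self.expr!r}")


def _parse_selection(expr: str) -> _Node:
    if not expr or not expr.strip():
        raise SelectionError("empty selection expression")
    return _Parser(expr).parse()
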