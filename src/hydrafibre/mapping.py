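"""Atomistic ↔ coarse-grained coupling and strategic water reinsertion.

Forward mapping collapses atom groups onto beads at their mass-weighted
centres; back-mapping re-grows atoms from per-bead templates with a random
rigid orientation and an exact centre-of-mass restraint to the bead
position.  Water reinsertion fills geometric regions to prescribed mass
densities by rejection sampling with a hard exclusion radius — the
placement guarantees geometry only (no energetic relaxation), emulating the
stage-3 protocol of keeping inter-fibre water at ~1.1–1.2 g/cc while the
box-mean water density stays at 1 g/cc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (Atom, Frame, SelectionSpec, Topology,
                   minimum_image_displacement, periodic_kdtree, select,
                   wrap_coordinates)
from .units import AMU_TO_G, A3_TO_CC, WATER_MASS_AMU, element_mass

#: MARTINI-convention default: one CG water bead represents 4 molecules
WATER_BEAD_MULTIPLICITY = 4


@dataclass
class CGBead:
    bead_id: int
    bead_type: str
    atom_ids: List[int]
    group_tag: Optional[str] = None


@dataclass
class CGMap:
    """Atom → bead assignment; mapped atoms are partitioned (each atom in at
    most one bead)."""

    beads: List[CGBead]
    water_multiplicity: int = WATER_BEAD_MULTIPLICITY

    def __post_init__(self):
        if self.water_multiplicity < 1:
            raise ValueError("water multiplicity must be >= 1")
        seen = set()
        for b in self.beads:
            if not b.atom_ids:
                raise ValueError(f"bead {b.bead_id} has no member atoms")
            for a in b.atom_ids:
                if a in seen:
                    raise ValueError(f"atom {a} mapped to more than one bead")
                seen.add(a)

    def validate_against(self, topology: Topology):
        for b in self.beads:
            for a in b.atom_ids:
                if not (0 <= a < topology.n_atoms):
                    raise ValueError(
                        f"bead {b.bead_id} references missing atom {a}")


def cgmap_from_name_rows(topology: Topology, rows: Sequence[tuple],
                         water_multiplicity: int = WATER_BEAD_MULTIPLICITY
                         ) -> CGMap:
    """Build a CGMap by applying (bead_type, atom-name list) rows per
    molecule: each molecule contributes one bead per row whose named atoms
    it contains."""
    beads = []
    bid = 0
    for mol, members in sorted(topology.molecules().items()):
        names = {str(topology.names[i]).upper(): int(i) for i in members}
        for bead_type, atom_names in rows:
            ids = [names[n.upper()] for n in atom_names if n.upper() in names]
            if ids:
                beads.append(CGBead(bid, bead_type, ids))
                bid += 1
    return CGMap(beads, water_multiplicity)


def read_cgmap(path, topology: Optional[Topology] = None) -> CGMap:
    """Read the TSV dialect: bead_id <tab> bead_type <tab> comma-separated
    atom ids (integers) or atom names (applied per molecule when a topology
    is given)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated "
                                 "fields")
            rows.append((parts[0], parts[1], parts[2].split(",")))
    try:
        beads = [CGBead(int(bid), btype, [int(a) for a in members])
                 for bid, btype, members in rows]
        return CGMap(beads)
    except ValueError:
        if topology is None:
            raise ValueError(f"{path}: name-based map needs a topology")
        return cgmap_from_name_rows(
            topology, [(btype, members) for _, btype, members in rows])


def write_cgmap(path, cgmap: CGMap):
    with open(path, "w") as fh:
        fh.write("# bead_id\tbead_type\tatom_ids\n")
        for b in cgmap.beads:
            fh.write(f"{b.bead_id}\t{b.bead_type}\t"
                     + ",".join(str(a) for a in b.atom_ids) + "\n")


def _bead_group_tag(bead: CGBead, topology: Topology) -> str:
    if bead.group_tag:
        return bead.group_tag
    tags = set(topology.group_tags[bead.atom_ids])
    return tags.pop() if len(tags) == 1 else "bead"


# ---------------------------------------------------------------------------
# forward / backward mapping
# ---------------------------------------------------------------------------

def forward_map(topology: Topology, frame: Frame, cgmap: CGMap
                ) -> Tuple[Topology, Frame]:
    """Collapse mapped atom groups to beads at their mass-weighted centres.

    Member atoms are unwrapped about the group's first atom before
    averaging so boundary-straddling groups map correctly; a group whose
    unwrapped span exceeds half the box is rejected as ill-defined.
    Bead velocities are the mass-weighted member means when present.
    """
    cgmap.validate_against(topology)
    bead_atoms, coords, vels = [], [], []
    have_vel = frame.velocities is not None
    for k, bead in enumerate(cgmap.beads):
        ids = np.asarray(bead.atom_ids, dtype=int)
        m = topology.masses[ids]
        ref = frame.coordinates[ids[0]]
        disp = minimum_image_displacement(ref, frame.coordinates[ids],
                                          frame.box)
        if np.any(disp.max(axis=0) - disp.min(axis=0)
                  > frame.box / 2.0 + 1e-9):
            raise ValueError(
                f"bead {bead.bead_id}: member atoms span more than half the "
                "box after unwrapping (ill-defined group)")
        com = ref + (m[:, None] * disp).sum(axis=0) / m.sum()
        coords.append(wrap_coordinates(com, frame.box))
        if have_vel:
            vels.append((m[:, None] * frame.velocities[ids]).sum(axis=0)
                        / m.sum())
        mol = int(topology.molecule_ids[ids[0]])
        bead_atoms.append(Atom(k, bead.bead_type, "B", float(m.sum()),
                               bead.bead_type[:4].upper() or "BEAD",
                               k, mol, _bead_group_tag(bead, topology)))
    cg_top = Topology(bead_atoms)
    cg_frame = Frame(time=frame.time, box=frame.box,
                     coordinates=np.array(coords),
                     velocities=np.array(vels) if have_vel else None)
    return cg_top, cg_frame


@dataclass
class BeadTemplate:
    """Internal atomistic geometry of one bead type (coordinates are
    arbitrary-origin; back-mapping recentres exactly)."""

    bead_type: str
    names: List[str]
    elements: List[str]
    coords: np.ndarray
    masses: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.masses is None:
            self.masses = np.array([element_mass(e) for e in self.elements])


def water_template() -> BeadTemplate:
    """Rigid 3-site water (O–H 0.9572 Å, H–O–H 104.52°)."""
    r, half = 0.9572, np.deg2rad(104.52 / 2.0)
    coords = np.array([[0.0, 0.0, 0.0],
                       [r * np.sin(half), r * np.cos(half), 0.0],
                       [-r * np.sin(half), r * np.cos(half), 0.0]])
    return BeadTemplate("W", ["OH2", "H1", "H2"], ["O", "H", "H"], coords)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])


def back_map(cg_frame: Frame, cgmap: CGMap, templates: dict, seed: int = 0,
             jitter_sigma: float = 0.3) -> Tuple[Topology, Frame]:
    """Re-grow atoms from bead positions: template geometry with a random
    rigid rotation plus Gaussian jitter, rigidly shifted so each group's
    mass-weighted centre equals the bead position exactly."""
    rng = np.random.default_rng(seed)
    atoms, coords = [], []
    aid = 0
    for bead in cgmap.beads:
        if bead.bead_type not in templates:
            raise ValueError(f"no template for bead type {bead.bead_type!r}")
        tpl: BeadTemplate = templates[bead.bead_type]
        rot = _random_rotation(rng)
        local = tpl.coords @ rot.T
        if jitter_sigma > 0:
            local = local + rng.normal(0.0, jitter_sigma, size=local.shape)
        m = tpl.masses
        com = (m[:, None] * local).sum(axis=0) / m.sum()
        placed = local - com + cg_frame.coordinates[bead.bead_id]
        for nm, el, xyz in zip(tpl.names, tpl.elements, placed):
            atoms.append(Atom(aid, nm, el, element_mass(el),
                              tpl.bead_type[:4].upper() or "UNK",
                              bead.bead_id, bead.bead_id,
                              "water" if tpl.bead_type.upper().startswith("W")
                              else "other"))
            coords.append(xyz)
            aid += 1
    top = Topology(atoms)
    return top, Frame(time=cg_frame.time, box=cg_frame.box,
                      coordinates=np.array(coords))


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """Geometric region with computable volume.

    Kinds
    -----
    box: the whole box.
    slab: ``{"axis": "x", "lo": , "hi": }``.
    cylinder_shell: ``{"axis": "z", "center": (cx, cy), "r_in": , "r_out": }``.
    inter_fibre: the channel between two parallel (z-aligned) fibres:
        ``{"c1": (x, y), "c2": (x, y), "fibre_radius": , "width": }`` — the
        rectangle running from one fibre surface to the other along the
        centre-to-centre line, ``width`` across, full box height.  Every
        point of it is farther than fibre_radius from both axes.
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    def volume(self, box) -> float:
        box = np.asarray(box, dtype=float)
        p = self.parameters
        if self.kind == "box":
            v = float(np.prod(box))
        elif self.kind == "slab":
            ax = {"x": 0, "y": 1, "z": 2}[p.get("axis", "x")]
            width = p["hi"] - p["lo"]
            other = [box[k] for k in range(3) if k != ax]
            v = width * other[0] * other[1]
        elif self.kind == "cylinder_shell":
            v = np.pi * (p["r_out"] ** 2 - p.get("r_in", 0.0) ** 2) * box[2]
        elif self.kind == "inter_fibre":
            c1 = np.asarray(p["c1"], dtype=float)
            c2 = np.asarray(p["c2"], dtype=float)
            d = np.linalg.norm(c2 - c1)
            length = d - 2.0 * p["fibre_radius"]
            v = length * p["width"] * box[2]
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if v <= 0:
            raise ValueError(f"region {self.kind} has non-positive volume")
        return v

    def contains(self, points, box) -> np.ndarray:
        pts = wrap_coordinates(np.atleast_2d(points), box)
        p = self.parameters
        if self.kind == "box":
            return np.ones(len(pts), dtype=bool)
        if self.kind == "slab":
            ax = {"x": 0, "y": 1, "z": 2}[p.get("axis", "x")]
            return (pts[:, ax] >= p["lo"]) & (pts[:, ax] < p["hi"])
        if self.kind == "cylinder_shell":
            c = np.asarray(p["center"], dtype=float)
            d = pts[:, :2] - c
            d -= box[:2] * np.ceil(d / box[:2] - 0.5)
            r = np.linalg.norm(d, axis=1)
            return (r >= p.get("r_in", 0.0)) & (r < p["r_out"])
        if self.kind == "inter_fibre":
            c1 = np.asarray(p["c1"], dtype=float)
            c2 = np.asarray(p["c2"], dtype=float)
            sep = c2 - c1
            d = np.linalg.norm(sep)
            u = sep / d
            rel = pts[:, :2] - c1
            rel -= box[:2] * np.ceil(rel / box[:2] - 0.5)
            s = rel @ u
            perp = rel - np.outer(s, u)
            return ((s >= p["fibre_radius"]) & (s <= d - p["fibre_radius"])
                    & (np.linalg.norm(perp, axis=1) <= p["width"] / 2.0))
        raise ValueError(f"unknown region kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int, box) -> np.ndarray:
        """n uniform points inside the region."""
        box = np.asarray(box, dtype=float)
        p = self.parameters
        if self.kind == "box":
            return rng.uniform(0, 1, size=(n, 3)) * box
        if self.kind == "slab":
            ax = {"x": 0, "y": 1, "z": 2}[p.get("axis", "x")]
            pts = rng.uniform(0, 1, size=(n, 3)) * box
            pts[:, ax] = rng.uniform(p["lo"], p["hi"], size=n)
            return pts
        if self.kind == "cylinder_shell":
            c = np.asarray(p["center"], dtype=float)
            r2 = rng.uniform(p.get("r_in", 0.0) ** 2, p["r_out"] ** 2, size=n)
            ang = rng.uniform(0, 2 * np.pi, size=n)
            r = np.sqrt(r2)
            return np.stack([c[0] + r * np.cos(ang), c[1] + r * np.sin(ang),
                             rng.uniform(0, box[2], size=n)], axis=1)
        if self.kind == "inter_fibre":
            c1 = np.asarray(p["c1"], dtype=float)
            c2 = np.asarray(p["c2"], dtype=float)
            sep = c2 - c1
            d = np.linalg.norm(sep)
            u = sep / d
            perp = np.array([-u[1], u[0]])
            s = rng.uniform(p["fibre_radius"], d - p["fibre_radius"], size=n)
            t = rng.uniform(-p["width"] / 2.0, p["width"] / 2.0, size=n)
            xy = c1[None, :] + np.outer(s, u) + np.outer(t, perp)
            return np.column_stack([xy, rng.uniform(0, box[2], size=n)])
        raise ValueError(f"unknown region kind {self.kind!r}")


def measure_region_density(topology: Topology, frame: Frame,
                           region: RegionSpec, sel="group water") -> float:
    """Mass density (g/cc) of the selected atoms inside the region."""
    vol = region.volume(frame.box)
    sel = sel if isinstance(sel, SelectionSpec) else SelectionSpec(sel)
    ids = select(topology, frame, sel)
    if len(ids) == 0:
        return 0.0
    inside = region.contains(frame.coordinates[ids], frame.box)
    mass = float(topology.masses[ids][inside].sum())
    return mass * AMU_TO_G / (vol * A3_TO_CC)


# ---------------------------------------------------------------------------
# water reinsertion
# ---------------------------------------------------------------------------

def _water_count(density_g_cc: float, volume_a3: float) -> int:
    return int(np.floor(density_g_cc * volume_a3 * A3_TO_CC
                        / (WATER_MASS_AMU * AMU_TO_G)))


class _CellGrid:
    """Uniform cell grid over the box for O(1) exclusion checks under PBC."""

    def __init__(self, box, cell: float):
        self.box = np.asarray(box, dtype=float)
        self.n = np.maximum(1, np.floor(self.box / cell).astype(int))
        self.size = self.box / self.n
        self.cells = {}

    def _key(self, p):
        return tuple((np.floor(p / self.size).astype(int)) % self.n)

    def add(self, p):
        self.cells.setdefault(self._key(p), []).append(np.asarray(p))

    def any_within(self, p, r) -> bool:
        kx, ky, kz = self._key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = ((kx + dx) % self.n[0], (ky + dy) % self.n[1],
                           (kz + dz) % self.n[2])
                    for q in self.cells.get(key, ()):
                        d = p - q
                        d -= self.box * np.round(d / self.box)
                        if float(d @ d) < r * r:
                            return True
        return False


def reinsert_water(topology: Optional[Topology], frame: Frame,
                   overall_density: float = 1.0,
                   regions: Sequence[Tuple[RegionSpec, float]] = (),
                   exclusion_radius: float = 2.4, seed: int = 0,
                   max_rejections: int = 100000
                   ) -> Tuple[Topology, Frame]:
    """Insert 3-site water molecules to hit region and box-mean densities.

    Region targets are filled first (uniform rejection sampling inside each
    region), then the remainder of the box is filled so that the box-mean
    water density equals ``overall_density``.  No inserted oxygen comes
    within ``exclusion_radius`` of any existing atom or previously placed
    oxygen; molecule counts are target density × volume ÷ molecular mass.
    """
    rng = np.random.default_rng(seed)
    box = frame.box
    tpl = water_template()
    grid = _CellGrid(box, max(exclusion_radius, 1.0))
    existing_coords = frame.coordinates if topology is not None else \
        np.empty((0, 3))
    for p in wrap_coordinates(existing_coords, box):
        grid.add(p)

    n_total = _water_count(overall_density, float(np.prod(box)))
    placements = []   # oxygen positions
    region_specs = list(regions)
    for region, target in region_specs:
        n_region = _water_count(target, region.volume(box))
        _place(rng, grid, region, n_region, box, exclusion_radius,
               placements, max_rejections, forbidden=None)
    n_rest = n_total - len(placements)
    if n_rest > 0:
        whole = RegionSpec("box")
        _place(rng, grid, whole, n_rest, box, exclusion_radius, placements,
               max_rejections, forbidden=[r for r, _ in region_specs])

    # build inserted molecules
    base_atoms = []
    if topology is not None:
        base_atoms = [topology.atom(i) for i in range(topology.n_atoms)]
        mol0 = int(topology.molecule_ids.max()) + 1
        res0 = int(topology.residue_indices.max()) + 1
        bonds = list(topology.bonds)
    else:
        mol0 = res0 = 0
        bonds = []
    atoms = base_atoms
    coords = [frame.coordinates] if topology is not None else []
    aid = len(base_atoms)
    for w, opos in enumerate(placements):
        rot = _random_rotation(rng)
        local = tpl.coords @ rot.T
        placed = local - local[0] + opos      # oxygen at the sampled point
        for nm, el, xyz in zip(tpl.names, tpl.elements, placed):
            atoms.append(Atom(aid, nm, el, element_mass(el), "HOH",
                              res0 + w, mol0 + w, "water"))
            aid += 1
        bonds.append((aid - 3, aid - 2))
        bonds.append((aid - 3, aid - 1))
        coords.append(wrap_coordinates(placed, box))
    new_top = Topology(atoms, bonds)
    new_frame = Frame(time=frame.time, box=box,
                      coordinates=np.vstack(coords))
    return new_top, new_frame


def _place(rng, grid: _CellGrid, region: RegionSpec, n: int, box,
           exclusion: float, placements: list, max_rejections: int,
           forbidden=None):
    rejections = 0
    placed = 0
    while placed < n:
        p = wrap_coordinates(region.sample(rng, 1, box)[0], box)
        bad = grid.any_within(p, exclusion)
        if not bad and forbidden:
            bad = any(r.contains(p[None, :], box)[0] for r in forbidden)
        if bad:
            rejections += 1
            if rejections > max_rejections:
                achieved = (len(placements) * WATER_MASS_AMU * AMU_TO_G
                            / (float(np.prod(box)) * A3_TO_CC))
                raise RuntimeError(
                    f"packing infeasible: {max_rejections} consecutive "
                    f"rejections in region {region.kind!r} after placing "
                    f"{placed}/{n} (achieved box density {achieved:.3f} "
                    "g/cc)")
            continue
        rejections = 0
        grid.add(p)
        placements.append(p)
        placed += 1
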