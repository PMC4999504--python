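"""PA conformation and aggregate census.

End-to-end distances of unwrapped chains, PBC-aware single-linkage
clustering of molecules into aggregates, micelle/fibre classification
(a fibre is an aggregate spanning the periodic box along its principal
axis), fibre linear density and diameter, hexagonal lattice spacing of
fibre centroids, Ramachandran (φ, ψ) analysis with region labels, and
backbone chirality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import (Frame, SelectionSpec, Topology, Trajectory,
                   minimum_image_displacement, periodic_kdtree, select,
                   unwrap_group, unwrap_molecule, wrap_coordinates)

logger = logging.getLogger(__name__)

#: Ramachandran region table, checked in order; first hit wins.
#: The polyproline-II box is centred on (φ, ψ) = (−65°, +145°) with
#: half-width 25° in each angle; the others follow common conventions.
RAMACHANDRAN_REGIONS: List[Tuple[str, Tuple[float, float],
                                 Tuple[float, float]]] = [
    ("P_II", (-90.0, -40.0), (120.0, 170.0)),
    ("beta", (-180.0, -90.0), (90.0, 180.0)),
    ("alpha_R", (-160.0, -20.0), (-120.0, 30.0)),
    ("alpha_L", (20.0, 160.0), (-30.0, 120.0)),
]


# ---------------------------------------------------------------------------
# end-to-end distance
# ---------------------------------------------------------------------------

def end_to_end(traj, endpoint_names: Tuple[str, str]):
    """Per-frame ensemble mean ± SD of the molecule end-to-end distance (Å).

    Endpoints are named atoms present once per molecule; molecules are
    unwrapped through their bond connectivity before measuring, so chains
    crossing the periodic boundary are handled exactly.

    Returns (times, means, sds).
    """
    if isinstance(traj, tuple):
        traj = Trajectory.from_single(*traj)
    top = traj.topology
    name_a, name_b = endpoint_names
    mol_members = top.molecules()
    endpoints = {}
    for mol, members in mol_members.items():
        ia = [i for i in members if str(top.names[i]).upper() == name_a.upper()]
        ib = [i for i in members if str(top.names[i]).upper() == name_b.upper()]
        if not ia or not ib:
            raise ValueError(
                f"molecule {mol} lacks endpoint atom "
                f"{name_a if not ia else name_b!r}")
        endpoints[mol] = (int(ia[0]), int(ib[0]))
    times, means, sds = [], [], []
    for frame in traj.frames:
        dists = []
        for mol, members in mol_members.items():
            coords = unwrap_molecule(top, frame, members)
            local = {int(a): k for k, a in enumerate(sorted(members))}
            ia, ib = endpoints[mol]
            dists.append(np.linalg.norm(coords[local[ib]] - coords[local[ia]]))
        times.append(frame.time)
        means.append(float(np.mean(dists)))
        sds.append(float(np.std(dists)))
    return np.array(times), np.array(means), np.array(sds)


# ---------------------------------------------------------------------------
# clustering and classification
# ---------------------------------------------------------------------------

@dataclass
class ClusterInfo:
    label: int
    molecule_ids: np.ndarray
    size: int                      # aggregation number N_agg
    centroid: Optional[np.ndarray] = None
    axis: Optional[np.ndarray] = None
    radius: float = np.nan         # RMS radial distance of selected beads
    axial_extent: float = np.nan
    kind: str = ""                 # micelle | fibre


@dataclass
class ClusterAssignment:
    """Single-linkage aggregate partition of the selected molecules."""

    molecule_ids: np.ndarray       # all molecules carrying selected beads
    labels: np.ndarray             # per-molecule cluster label (0 = largest)
    clusters: List[ClusterInfo]
    cutoff: float
    selection: str = ""

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters])

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_molecules(topology: Topology, frame: Frame, sel,
                      cutoff: float = 6.0) -> ClusterAssignment:
    """Single-linkage connected components over minimum-image bead contacts.

    Two molecules join one aggregate when any pair of their selected beads
    is within ``cutoff``.  Labels are deterministic: ordered by size
    (descending), ties broken by lowest member molecule_id.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    sel = sel if isinstance(sel, SelectionSpec) else SelectionSpec(sel)
    ids = select(topology, frame, sel)
    if len(ids) == 0:
        raise ValueError(f"selection {sel.expression!r} is empty")
    mols = topology.molecule_ids[ids]
    uniq_mols, mol_index = np.unique(mols, return_inverse=True)
    tree = periodic_kdtree(frame.coordinates[ids], frame.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        mi, mj = mol_index[pairs[:, 0]], mol_index[pairs[:, 1]]
        keep = mi != mj
        graph = coo_matrix(
            (np.ones(keep.sum()), (mi[keep], mj[keep])),
            shape=(len(uniq_mols), len(uniq_mols)))
    else:
        graph = coo_matrix((len(uniq_mols), len(uniq_mols)))
    n_comp, comp = connected_components(graph, directed=False)
    order = sorted(
        range(n_comp),
        key=lambda c: (-np.sum(comp == c), uniq_mols[comp == c].min()))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in comp])
    clusters = []
    for lab in range(n_comp):
        members = uniq_mols[labels == lab]
        clusters.append(ClusterInfo(lab, members, len(members)))
    return ClusterAssignment(uniq_mols, labels, clusters, cutoff,
                             sel.expression)


def _cluster_bead_coords(assignment: ClusterAssignment, topology: Topology,
                         frame: Frame, info: ClusterInfo) -> np.ndarray:
    """Unwrapped coordinates of the cluster's selected beads, connected
    through the same contact graph the clustering used."""
    sel = SelectionSpec(assignment.selection)
    ids = select(topology, frame, sel)
    ids = ids[np.isin(topology.molecule_ids[ids], info.molecule_ids)]
    pts = frame.coordinates[ids]
    tree = periodic_kdtree(pts, frame.box)
    pairs = tree.query_pairs(assignment.cutoff, output_type="ndarray")
    adj = [[] for _ in range(len(pts))]
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)
    return unwrap_group(pts, frame.box, adjacency=adj), ids


def classify_aggregate(assignment: ClusterAssignment, topology: Topology,
                       frame: Frame, label: int,
                       span_fraction: float = 0.9) -> ClusterInfo:
    """Classify one cluster as micelle or fibre and fill its geometry.

    The principal axis is the leading PCA direction of the unwrapped member
    beads; the aggregate is a fibre iff its axial extent reaches
    ``span_fraction`` × the box edge along that axis (periodic-spanning),
    else a micelle.  Radius is the RMS radial bead distance from the axis.
    """
    info = assignment.clusters[label]
    if info.size < 1:
        raise ValueError("empty cluster")
    coords, _ = _cluster_bead_coords(assignment, topology, frame, info)
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    if len(coords) >= 2:
        cov = centred.T @ centred / len(coords)
        w, v = np.linalg.eigh(cov)
        axis = v[:, -1]
    else:
        axis = np.array([0.0, 0.0, 1.0])
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    proj = centred @ axis
    extent = float(proj.max() - proj.min())
    box_edge = float(frame.box[int(np.argmax(np.abs(axis)))])
    radial = centred - np.outer(proj, axis)
    info.centroid = wrap_coordinates(centroid, frame.box)
    info.axis = axis
    info.axial_extent = extent
    info.radius = float(np.sqrt(np.mean(np.sum(radial ** 2, axis=1))))
    info.kind = "fibre" if extent >= span_fraction * box_edge else "micelle"
    return info


def fibre_metrics(assignment: ClusterAssignment, topology: Topology,
                  frame: Frame, label: int) -> Tuple[float, float]:
    """(linear_density in PA/nm, diameter in Å) for a fibre-class cluster.

    Linear density divides the aggregation number by the axial box length;
    the diameter is twice the 95th percentile of member-atom radial
    distances from the fibre axis (all atoms of member molecules, not just
    the clustering beads).
    """
    info = assignment.clusters[label]
    if info.kind != "fibre":
        raise ValueError(f"cluster {label} is {info.kind or 'unclassified'};"
                         " fibre_metrics needs a fibre (classify first)")
    axis = info.axis
    box_edge = float(frame.box[int(np.argmax(np.abs(axis)))])
    linear_density = info.size / (box_edge / 10.0)   # box edge Å → nm
    member_atoms = np.flatnonzero(
        np.isin(topology.molecule_ids, info.molecule_ids))
    d = minimum_image_displacement(info.centroid,
                                   frame.coordinates[member_atoms],
                                   frame.box)
    proj = d @ axis
    radial = np.linalg.norm(d - np.outer(proj, axis), axis=1)
    diameter = 2.0 * float(np.percentile(radial, 95.0))
    return float(linear_density), diameter


def lattice_spacing(centroids, box, axis: Optional[Sequence[float]] = None
                    ) -> Tuple[float, np.ndarray]:
    """Mean nearest-neighbour minimum-image distance between fibre
    centroids, plus the per-fibre coordination count (neighbours within
    1.2 × the minimum spacing).

    When ``axis`` is given (the common fibre direction) the centroids are
    compared in the perpendicular plane, which removes the arbitrary axial
    offset of periodic fibres.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if len(centroids) < 2:
        raise ValueError("need at least 2 fibre centroids")
    box = np.asarray(box, dtype=float)
    n = len(centroids)
    d = np.empty((n, n))
    for i in range(n):
        disp = minimum_image_displacement(centroids[i], centroids, box)
        if axis is not None:
            u = np.asarray(axis, dtype=float)
            u = u / np.linalg.norm(u)
            disp = disp - np.outer(disp @ u, u)
        d[i] = np.linalg.norm(disp, axis=1)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    mean_spacing = float(nn.mean())
    coordination = np.sum(d <= 1.2 * nn.min(), axis=1)
    return mean_spacing, coordination


# ---------------------------------------------------------------------------
# Ramachandran analysis
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (−180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


@dataclass
class RamachandranSet:
    """Per-residue backbone dihedrals with region and chirality labels."""

    molecule_ids: np.ndarray
    residue_indices: np.ndarray
    phi: np.ndarray                # degrees, (−180, 180]
    psi: np.ndarray
    regions: np.ndarray            # P_II | beta | alpha_R | alpha_L | other
    chirality: np.ndarray          # L | D | n/a
    frame_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def region_fraction(self, region: str) -> float:
        return float(np.mean(self.regions == region))


def classify_region(phi: float, psi: float,
                    table=None) -> str:
    table = RAMACHANDRAN_REGIONS if table is None else table
    for name, (plo, phi_hi), (slo, shi) in table:
        if plo <= phi <= phi_hi and slo <= psi <= shi:
            return name
    return "other"


def ramachandran(traj, region_table=None) -> RamachandranSet:
    """Backbone (φ, ψ) for every residue with both flanking peptide bonds.

    φ = dihedral(C_prev, N, Cα, C) and ψ = dihedral(N, Cα, C, N_next),
    using unwrapped molecule coordinates; residues missing a backbone atom
    are skipped with a logged warning.  Chirality is labelled from the
    improper N–Cα–C–Cβ when a Cβ exists.
    """
    if isinstance(traj, tuple):
        traj = Trajectory.from_single(*traj)
    top = traj.topology
    # index backbone atoms per (molecule, residue)
    backbone: Dict[Tuple[int, int], Dict[str, int]] = {}
    for i in range(top.n_atoms):
        nm = str(top.names[i]).upper()
        if nm in ("N", "CA", "C", "CB"):
            key = (int(top.molecule_ids[i]), int(top.residue_indices[i]))
            backbone.setdefault(key, {})[nm] = i
    mols, res, phis, psis, regions, chis, times = ([] for _ in range(7))
    n_skipped = 0
    for frame in traj.frames:
        unwrapped: Dict[int, Tuple[np.ndarray, dict]] = {}
        for (mol, ridx), atoms in sorted(backbone.items()):
            if not all(k in atoms for k in ("N", "CA", "C")):
                n_skipped += 1
                continue
            prev = backbone.get((mol, ridx - 1), {})
            nxt = backbone.get((mol, ridx + 1), {})
            if "C" not in prev or "N" not in nxt:
                continue       # chain termini: φ or ψ undefined
            if mol not in unwrapped:
                members = top.molecules()[mol]
                coords = unwrap_molecule(top, frame, members)
                local = {int(a): k for k, a in enumerate(sorted(members))}
                unwrapped[mol] = (coords, local)
            coords, local = unwrapped[mol]
            pos = lambda a: coords[local[a]]
            phi = dihedral(pos(prev["C"]), pos(atoms["N"]), pos(atoms["CA"]),
                           pos(atoms["C"]))
            psi = dihedral(pos(atoms["N"]), pos(atoms["CA"]), pos(atoms["C"]),
                           pos(nxt["N"]))
            mols.append(mol)
            res.append(ridx)
            phis.append(phi)
            psis.append(psi)
            regions.append(classify_region(phi, psi, region_table))
            if "CB" in atoms:
                chis.append(chirality(pos(atoms["N"]), pos(atoms["CA"]),
                                      pos(atoms["C"]), pos(atoms["CB"])))
            else:
                chis.append("n/a")
            times.append(frame.time)
    if n_skipped:
        logger.warning("ramachandran: skipped %d residues with missing "
                       "backbone atoms", n_skipped)
    return RamachandranSet(np.array(mols), np.array(res), np.array(phis),
                           np.array(psis), np.array(regions, dtype=object),
                           np.array(chis, dtype=object), np.array(times))


def chirality(n, ca, c, cb) -> str:
    """Backbone chirality from the improper dihedral N–Cα–C–Cβ.

    The convention is anchored so ideal L-alanine geometry (improper
    ≈ +120°) gives 'L'; mirror reflection flips the sign and the label.
    """
    ang = dihedral(n, ca, c, cb)
    return "L" if ang > 0 else "D"
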