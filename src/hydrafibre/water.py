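"""Structural metrics of water ordering.

Radial distribution functions, axial density profiles, the Steinhardt Q6
orientational order parameter, the Errington–Debenedetti tetrahedral order
parameter, translational order, geometric hydrogen bonds and cylindrical
radial number distributions around fibre axes.

All distances are minimum-image in orthorhombic boxes.  Order parameters can
be computed on atomistic water oxygens or on coarse-grained water beads; the
neighbour convention used is recorded in every output series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.special import sph_harm_y

from .core import (Frame, SelectionSpec, Topology, Trajectory,
                   minimum_image_displacement, periodic_kdtree, select,
                   wrap_coordinates)
from .units import mass_density_g_cc

logger = logging.getLogger(__name__)


def _as_trajectory(obj, frame=None) -> Trajectory:
    if isinstance(obj, Trajectory):
        return obj
    if isinstance(obj, Topology) and isinstance(frame, Frame):
        return Trajectory.from_single(obj, frame)
    if isinstance(obj, tuple) and len(obj) == 2:
        return Trajectory.from_single(*obj)
    raise TypeError("expected a Trajectory or a (Topology, Frame) pair")


def _spec(sel) -> SelectionSpec:
    return sel if isinstance(sel, SelectionSpec) else SelectionSpec(sel)


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------

@dataclass
class RadialDistribution:
    """Binned pair correlation g(r) with its raw pair counts."""

    bin_edges: np.ndarray
    g: np.ndarray
    pair_counts: np.ndarray
    n_frames: int
    n_a: float
    n_b: float
    rho_b: float           # mean number density of b, Å⁻³
    sel_a: str = ""
    sel_b: str = ""

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def first_peak(self, min_frac: float = 0.5, refine: bool = True) -> float:
        """Position of the first local maximum of g(r) reaching
        ``min_frac`` × max(g), parabolically refined within its bin when
        possible (the threshold suppresses single-count noise bins)."""
        g, r = self.g, self.r
        thresh = min_frac * np.nanmax(g)
        for i in range(1, len(g) - 1):
            if g[i] >= thresh and g[i] >= g[i - 1] and g[i] >= g[i + 1] \
                    and (g[i] > g[i - 1] or g[i] > g[i + 1]):
                if refine:
                    denom = g[i - 1] - 2 * g[i] + g[i + 1]
                    if denom < 0:
                        shift = 0.5 * (g[i - 1] - g[i + 1]) / denom
                        dr = r[1] - r[0]
                        return float(r[i] + np.clip(shift, -0.5, 0.5) * dr)
                return float(r[i])
        raise ValueError("no peak above the threshold found")


def compute_rdf(traj, sel_a, sel_b, r_max: float, dr: float,
                exclude_same_molecule: bool = True) -> RadialDistribution:
    """Pair correlation between two selections.

    Histogram of minimum-image pair distances, normalized per frame by the
    exact spherical-shell volume, the number of reference (a) particles and
    the mean number density of b.  Self pairs are always excluded; pairs
    within one molecule are excluded unless ``exclude_same_molecule=False``.
    """
    traj = _as_trajectory(traj)
    sel_a, sel_b = _spec(sel_a), _spec(sel_b)
    if dr <= 0:
        raise ValueError("dr must be > 0")
    top = traj.topology
    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    if len(edges) < 2:
        raise ValueError("r_max must allow at least one bin")
    counts = np.zeros(len(edges) - 1)
    n_a_tot = n_b_tot = rho_tot = 0.0
    for frame in traj.frames:
        if r_max > np.min(frame.box) / 2.0 + 1e-9:
            raise ValueError(
                f"r_max {r_max} violates the minimum-image bound "
                f"min(box)/2 = {np.min(frame.box) / 2.0:.3f}")
        ids_a = select(top, frame, sel_a)
        ids_b = select(top, frame, sel_b)
        if len(ids_a) == 0:
            raise ValueError(f"selection {sel_a.expression!r} is empty")
        if len(ids_b) == 0:
            raise ValueError(f"selection {sel_b.expression!r} is empty")
        pts_a = frame.coordinates[ids_a]
        tree_b = periodic_kdtree(frame.coordinates[ids_b], frame.box)
        qa = wrap_coordinates(pts_a, frame.box)
        qa = np.where(qa >= frame.box, 0.0, qa)
        neigh = tree_b.query_ball_point(qa, r_max)
        mols_a = top.molecule_ids[ids_a]
        mols_b = top.molecule_ids[ids_b]
        for i, lst in enumerate(neigh):
            if not lst:
                continue
            js = np.asarray(lst)
            keep = ids_b[js] != ids_a[i]
            if exclude_same_molecule:
                keep &= mols_b[js] != mols_a[i]
            js = js[keep]
            if len(js) == 0:
                continue
            d = minimum_image_displacement(
                pts_a[i], frame.coordinates[ids_b[js]], frame.box)
            dist = np.sqrt(np.sum(d * d, axis=1))
            h, _ = np.histogram(dist, bins=edges)
            counts += h
        n_a_tot += len(ids_a)
        n_b_tot += len(ids_b)
        rho_tot += len(ids_b) / frame.volume
    nf = traj.n_frames
    n_a, n_b, rho_b = n_a_tot / nf, n_b_tot / nf, rho_tot / nf
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = counts / (nf * n_a * rho_b * shell)
    return RadialDistribution(edges, g, counts.astype(int), nf, n_a, n_b,
                              rho_b, sel_a.expression, sel_b.expression)


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    axis: str
    bin_centers: np.ndarray
    density: np.ndarray      # g/cc when mass weighted, else Å⁻³
    mass_weighted: bool
    selection: str = ""

    def peak_spacings(self, min_frac: float = 0.5) -> np.ndarray:
        """Distances between successive local maxima above
        min_frac × max(density)."""
        d = self.density
        thresh = min_frac * d.max()
        peaks = [i for i in range(1, len(d) - 1)
                 if d[i] >= thresh and d[i] >= d[i - 1] and d[i] > d[i + 1]]
        return np.diff(self.bin_centers[peaks])


def compute_density_profile(traj, sel, axis: str = "x", dr: float = 1.0,
                            mass_weighted: bool = True) -> DensityProfile:
    """Per-slab density along a box axis, averaged over frames.

    Slab volume is dr × (product of the two orthogonal box edges); mass
    densities are reported in g/cc.
    """
    traj = _as_trajectory(traj)
    sel = _spec(sel)
    if dr <= 0:
        raise ValueError("dr must be > 0")
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    top = traj.topology
    box0 = traj.frames[0].box
    n_bins = max(1, int(np.floor(box0[ax] / dr)))
    edges = np.linspace(0.0, box0[ax], n_bins + 1)
    acc = np.zeros(n_bins)
    for frame in traj.frames:
        ids = select(top, frame, sel)
        if len(ids) == 0:
            raise ValueError(f"selection {sel.expression!r} is empty")
        x = wrap_coordinates(frame.coordinates[ids], frame.box)[:, ax]
        w = top.masses[ids] if mass_weighted else None
        h, _ = np.histogram(x, bins=edges, weights=w)
        other = [frame.box[k] for k in range(3) if k != ax]
        slab_vol = (edges[1] - edges[0]) * other[0] * other[1]
        if mass_weighted:
            acc += np.array([mass_density_g_cc(m, slab_vol) for m in h])
        else:
            acc += h / slab_vol
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(axis, centers, acc / traj.n_frames, mass_weighted,
                          sel.expression)


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------

@dataclass
class OrderParameterSeries:
    kind: str                 # q6 | q_tet | t_trans
    times: np.ndarray
    values: np.ndarray
    selection: str = ""
    convention: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def _neighbour_vectors(points, box, cutoff=None, k_nearest=None):
    """Per-point list of minimum-image neighbour vectors within the
    convention (cutoff radius or k nearest)."""
    n = len(points)
    tree = periodic_kdtree(points, box)
    q = wrap_coordinates(points, box)
    q = np.where(q >= box, 0.0, q)
    vecs = []
    if cutoff is not None:
        lists = tree.query_ball_point(q, cutoff)
        for i, lst in enumerate(lists):
            js = np.asarray([j for j in lst if j != i], dtype=int)
            if len(js) == 0:
                vecs.append(np.empty((0, 3)))
                continue
            vecs.append(minimum_image_displacement(points[i], points[js], box))
    else:
        k = int(k_nearest)
        if n <= k:
            raise ValueError(f"k_nearest={k} needs more than {k} particles")
        _, idx = tree.query(q, k=k + 1)
        for i in range(n):
            js = np.asarray([j for j in idx[i] if j != i][:k], dtype=int)
            vecs.append(minimum_image_displacement(points[i], points[js], box))
    return vecs


def steinhardt_q6_from_vectors(vectors: np.ndarray) -> float:
    """q6 of one particle from its neighbour bond vectors:
    sqrt( 4π/13 Σ_m |⟨Y_6m⟩|² )."""
    v = np.asarray(vectors, dtype=float)
    if len(v) == 0:
        raise ValueError("no neighbour vectors")
    r = np.linalg.norm(v, axis=1)
    theta = np.arccos(np.clip(v[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    total = 0.0
    for m in range(0, 7):
        ylm = sph_harm_y(6, m, theta, phi)
        mean = np.mean(ylm)
        total += (1 if m == 0 else 2) * np.abs(mean) ** 2
    return float(np.sqrt(4.0 * np.pi / 13.0 * total))


def _q6m_means(vectors: np.ndarray) -> np.ndarray:
    """⟨Y_6m⟩ over one particle's neighbours, m = 0..6."""
    v = np.asarray(vectors, dtype=float)
    r = np.linalg.norm(v, axis=1)
    theta = np.arccos(np.clip(v[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    return np.array([np.mean(sph_harm_y(6, m, theta, phi))
                     for m in range(7)])


def compute_q6(traj, sel, neighbours: Optional[dict] = None,
               mode: str = "per_particle") -> OrderParameterSeries:
    """Steinhardt l=6 orientational order of the selected particles.

    ``neighbours`` is ``{"cutoff": r}`` or ``{"k_nearest": k}`` (default
    cutoff 3.5 Å, suited to atomistic water oxygens; use ~6.5 Å for CG
    beads).  ``mode='per_particle'`` averages per-particle q6(i) over the
    selection; ``mode='global'`` accumulates the q_6m over all bonds first
    and takes the invariant of the global average.
    """
    traj = _as_trajectory(traj)
    sel = _spec(sel)
    conv = dict(neighbours or {"cutoff": 3.5})
    cutoff, k_nearest = conv.get("cutoff"), conv.get("k_nearest")
    times, values = [], []
    n_isolated = 0
    for frame in traj.frames:
        ids = select(traj.topology, frame, sel)
        if len(ids) == 0:
            raise ValueError(f"selection {sel.expression!r} is empty")
        pts = frame.coordinates[ids]
        vecs = _neighbour_vectors(pts, frame.box, cutoff=cutoff,
                                  k_nearest=k_nearest)
        if mode == "per_particle":
            qs = []
            for v in vecs:
                if len(v) == 0:
                    n_isolated += 1
                    continue
                qs.append(steinhardt_q6_from_vectors(v))
            if not qs:
                raise ValueError("all selected particles are isolated under "
                                 "the neighbour convention")
            values.append(float(np.mean(qs)))
        elif mode == "global":
            acc = np.zeros(7, dtype=complex)
            n_bonds = 0
            for v in vecs:
                if len(v) == 0:
                    n_isolated += 1
                    continue
                acc += _q6m_means(v) * len(v)
                n_bonds += len(v)
            if n_bonds == 0:
                raise ValueError("no neighbour bonds in selection")
            acc /= n_bonds
            tot = np.abs(acc[0]) ** 2 + 2 * np.sum(np.abs(acc[1:]) ** 2)
            values.append(float(np.sqrt(4 * np.pi / 13.0 * tot)))
        else:
            raise ValueError("mode must be 'per_particle' or 'global'")
        times.append(frame.time)
    if n_isolated:
        logger.info("q6: excluded %d isolated particles", n_isolated)
    conv["mode"] = mode
    return OrderParameterSeries("q6", np.array(times), np.array(values),
                                sel.expression, conv)


def compute_tetrahedral_order(traj, sel, cutoff: Optional[float] = None
                              ) -> OrderParameterSeries:
    """Errington–Debenedetti tetrahedral order parameter.

    q(i) = 1 − (3/8) Σ_{j<k over the 4 nearest neighbours}
    (cos ψ_jk + 1/3)², which is 1 for a perfect tetrahedron and averages 0
    for uniformly random neighbour directions.  Particles with fewer than 4
    neighbours inside ``cutoff`` (when given) are excluded and counted.
    """
    traj = _as_trajectory(traj)
    sel = _spec(sel)
    times, values = [], []
    n_excluded = 0
    for frame in traj.frames:
        ids = select(traj.topology, frame, sel)
        if len(ids) == 0:
            raise ValueError(f"selection {sel.expression!r} is empty")
        pts = frame.coordinates[ids]
        if len(pts) < 5:
            raise ValueError("tetrahedral order needs >= 5 particles")
        vecs = _neighbour_vectors(pts, frame.box, cutoff=None, k_nearest=4)
        qs = []
        for i, v in enumerate(vecs):
            if cutoff is not None:
                keep = np.linalg.norm(v, axis=1) <= cutoff
                v = v[keep]
            if len(v) < 4:
                n_excluded += 1
                continue
            qs.append(tetrahedral_q_from_vectors(v[:4]))
        if not qs:
            raise ValueError("no particle has 4 neighbours inside the cutoff")
        values.append(float(np.mean(qs)))
        times.append(frame.time)
    if n_excluded:
        logger.info("q_tet: excluded %d under-coordinated particles",
                    n_excluded)
    return OrderParameterSeries("q_tet", np.array(times), np.array(values),
                                sel.expression,
                                {"neighbours": "4 nearest", "cutoff": cutoff})


def tetrahedral_q_from_vectors(vectors: np.ndarray) -> float:
    """q for one particle from exactly 4 neighbour vectors."""
    v = np.asarray(vectors, dtype=float)
    if v.shape != (4, 3):
        raise ValueError("need exactly 4 neighbour vectors")
    u = v / np.linalg.norm(v, axis=1)[:, None]
    s = 0.0
    for j in range(3):
        for k in range(j + 1, 4):
            c = float(np.dot(u[j], u[k]))
            s += (c + 1.0 / 3.0) ** 2
    return 1.0 - 3.0 / 8.0 * s


def compute_translational_order(traj, sel, xi_cutoff: float = 2.843,
                                dr: Optional[float] = None
                                ) -> OrderParameterSeries:
    """Translational order t = (1/ξ_c) ∫₀^{ξ_c} |g(ξ) − 1| dξ with
    ξ = r·ρ^{1/3} (density-reduced distance), trapezoidal on the RDF grid.

    One value per trajectory (the RDF is frame-averaged); returned as a
    length-1 series for interface uniformity.
    """
    traj = _as_trajectory(traj)
    sel = _spec(sel)
    frame0 = traj.frames[0]
    ids0 = select(traj.topology, frame0, sel)
    if len(ids0) == 0:
        raise ValueError(f"selection {sel.expression!r} is empty")
    rho = len(ids0) / frame0.volume
    scale = rho ** (1.0 / 3.0)
    r_needed = xi_cutoff / scale
    r_max = np.min(frame0.box) / 2.0 * 0.999
    if r_needed > r_max:
        raise ValueError(
            f"ξ_c={xi_cutoff} needs r up to {r_needed:.2f} Å but the "
            f"minimum-image bound is {r_max:.2f} Å; use a larger box")
    if dr is None:
        dr = r_needed / 200.0
    rdf = compute_rdf(traj, sel, sel, r_max=r_needed, dr=dr)
    xi = rdf.r * scale
    integrand = np.abs(rdf.g - 1.0)
    keep = xi <= xi_cutoff
    t = float(np.trapezoid(integrand[keep], xi[keep]) / xi_cutoff)
    return OrderParameterSeries(
        "t_trans", np.array([frame0.time]), np.array([t]), sel.expression,
        {"xi_cutoff": xi_cutoff, "dr": dr, "rho": rho})


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def find_hbonds(topology: Topology, frame: Frame, donors, acceptors,
                d_cut: float = 3.5, angle_cut: float = 30.0):
    """Geometric hydrogen bonds (donor heavy atom D, bonded H, acceptor A).

    A bond is listed iff the D–A minimum-image distance is ≤ d_cut and the
    H–D–A angle is ≤ angle_cut degrees.  Hydrogens inside the donor
    selection are ignored (only heavy atoms donate); every remaining donor
    must have bonded hydrogens in the topology.
    """
    ids_d = select(topology, frame, _spec(donors))
    ids_a = select(topology, frame, _spec(acceptors))
    ids_d = ids_d[[str(topology.elements[i]).upper() != "H" for i in ids_d]]
    if len(ids_d) == 0 or len(ids_a) == 0:
        raise ValueError("empty donor or acceptor selection")
    adj = topology.adjacency()
    donor_h = {}
    missing = []
    for d in ids_d:
        hs = [j for j in adj[d] if str(topology.elements[j]).upper() == "H"]
        if not hs:
            missing.append(int(d))
        donor_h[int(d)] = hs
    if missing:
        raise ValueError(f"donor atoms without bonded hydrogens: {missing}")
    tree_a = periodic_kdtree(frame.coordinates[ids_a], frame.box)
    qd = wrap_coordinates(frame.coordinates[ids_d], frame.box)
    qd = np.where(qd >= frame.box, 0.0, qd)
    lists = tree_a.query_ball_point(qd, d_cut)
    cos_cut = np.cos(np.deg2rad(angle_cut))
    bonds = []
    for i, lst in enumerate(lists):
        d = int(ids_d[i])
        pd = frame.coordinates[d]
        for j in lst:
            a = int(ids_a[j])
            if a == d:
                continue
            v_da = minimum_image_displacement(pd, frame.coordinates[a],
                                              frame.box)
            for h in donor_h[d]:
                v_dh = minimum_image_displacement(pd, frame.coordinates[h],
                                                  frame.box)
                denom = np.linalg.norm(v_da) * np.linalg.norm(v_dh)
                if denom == 0:
                    continue
                if float(np.dot(v_da, v_dh)) / denom >= cos_cut:
                    bonds.append((d, int(h), a))
    return bonds


# ---------------------------------------------------------------------------
# cylindrical radial number distribution
# ---------------------------------------------------------------------------

@dataclass
class RadialNumberDistribution:
    bin_edges: np.ndarray
    counts: Dict[str, np.ndarray]   # per-species mean counts per annulus

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def radial_number_distribution(traj, axis_point, axis_dir, species: dict,
                               dr: float = 1.0, r_max: Optional[float] = None
                               ) -> RadialNumberDistribution:
    """Counts of each species versus minimum-image distance from a fibre
    axis (cylindrical-radial histogram, frame-averaged).

    ``species`` maps labels to selections; ``axis_dir`` need not be
    normalized but must be nonzero.
    """
    traj = _as_trajectory(traj)
    axis_point = np.asarray(axis_point, dtype=float)
    axis_dir = np.asarray(axis_dir, dtype=float)
    norm = np.linalg.norm(axis_dir)
    if norm == 0:
        raise ValueError("axis direction must be nonzero")
    u = axis_dir / norm
    box0 = traj.frames[0].box
    if r_max is None:
        r_max = float(np.min(box0) / 2.0)
    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    counts = {name: np.zeros(len(edges) - 1) for name in species}
    for frame in traj.frames:
        for name, sel in species.items():
            ids = select(traj.topology, frame, _spec(sel))
            if len(ids) == 0:
                raise ValueError(f"selection for {name!r} is empty")
            d = minimum_image_displacement(axis_point,
                                           frame.coordinates[ids], frame.box)
            radial = d - np.outer(d @ u, u)
            dist = np.linalg.norm(radial, axis=1)
            h, _ = np.histogram(dist, bins=edges)
            counts[name] += h
    for name in counts:
        counts[name] /= traj.n_frames
    return RadialNumberDistribution(edges, counts)
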