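"""Seeded synthetic-trajectory generators.

These generators produce every fixture the analysis stages need without an
MD engine: ideal-gas boxes (null model for g(r)), perfect lattices (order-
parameter oracles), hydration shells with prescribed radii, peptide-
amphiphile (PA) micelles and hexagonal fibre bundles at the architecture
the assembled systems exhibit (300 PAs, 6 fibres, 50 Å centroid spacing,
~11 PA/nm along the axis), harmonic-oscillator velocity trajectories for
spectral checks, and overdamped Langevin samples on analytic 1-D potentials
for umbrella-sampling validation.

Every generator is a pure function of its parameters and seed: the same
inputs give bit-identical output.  Random directions are drawn with the
Marsaglia uniform-sphere method so oracle code can reproduce the streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Atom, Frame, Topology, Trajectory, wrap_coordinates
from .units import C_CM_PER_PS, element_mass

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: PA bead chain: 4 hydrophobic tail beads + 8 hydrophilic head beads.
#: A stand-in for a MARTINI-style mapping of c16-AHL3K3; configurable.
PA_BEADS_DEFAULT = 12
PA_TAIL_BEADS_DEFAULT = 4
BEAD_MASS = 72.0


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic fixture (kind + parameters +
    seed); :func:`generate` dispatches to the matching generator."""

    seed: int
    kind: str
    parameters: dict = field(default_factory=dict)


_GENERATORS = {}


def _register(name):
    def deco(fn):
        _GENERATORS[name] = fn
        return fn
    return deco


def generate(spec: SyntheticSpec):
    if spec.kind not in _GENERATORS:
        raise ValueError(f"unknown generator kind {spec.kind!r}; "
                         f"available: {sorted(_GENERATORS)}")
    return _GENERATORS[spec.kind](seed=spec.seed, **spec.parameters)


def marsaglia_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unit vectors uniform on the sphere (Marsaglia 1972 rejection)."""
    out = np.empty((n, 3))
    got = 0
    while got < n:
        u = rng.uniform(-1, 1, size=(2 * (n - got) + 8, 2))
        s = np.sum(u * u, axis=1)
        ok = s < 1.0
        u, s = u[ok], s[ok]
        take = min(len(s), n - got)
        u, s = u[:take], s[:take]
        root = np.sqrt(1.0 - s)
        out[got:got + take, 0] = 2 * u[:, 0] * root
        out[got:got + take, 1] = 2 * u[:, 1] * root
        out[got:got + take, 2] = 1 - 2 * s
        got += take
    return out


# ---------------------------------------------------------------------------
# simple particle fixtures
# ---------------------------------------------------------------------------

@_register("ideal_gas")
def gen_ideal_gas(n: int, box, n_frames: int = 1, seed: int = 0,
                  dt: float = 1.0) -> Trajectory:
    """Uniform i.i.d. positions each frame: the g(r) ≡ 1 null model."""
    if n < 2:
        raise ValueError("ideal gas needs n >= 2")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    atoms = [Atom(k, "O", "O", element_mass("O"), "HOH", k, k, "water")
             for k in range(n)]
    top = Topology(atoms)
    frames = [Frame(time=i * dt, box=box,
                    coordinates=rng.uniform(0, 1, size=(n, 3)) * box)
              for i in range(n_frames)]
    return Trajectory(top, frames)


@_register("lattice")
def gen_lattice(kind: str, a: float, repeats=(3, 3, 3), seed: int = 0):
    """Perfect periodic lattice: fcc, sc or diamond_ice (diamond cubic,
    the ideal 4-coordinated 'ice-like' network with neighbours at a√3/4)."""
    repeats = np.asarray(repeats, dtype=int).reshape(3)
    if np.any(repeats < 2):
        raise ValueError("need repeats >= 2 per axis")
    if kind == "sc":
        basis = np.array([[0.0, 0.0, 0.0]])
    elif kind == "fcc":
        basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5],
                          [0, 0.5, 0.5]])
    elif kind == "diamond_ice":
        fcc = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5],
                        [0, 0.5, 0.5]])
        basis = np.vstack([fcc, fcc + 0.25])
    else:
        raise ValueError(f"unknown lattice kind {kind!r}")
    cells = np.array(np.meshgrid(*[np.arange(r) for r in repeats],
                                 indexing="ij")).reshape(3, -1).T
    frac = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    coords = frac * a
    box = repeats * a
    atoms = [Atom(k, "O", "O", element_mass("O"), "HOH", k, k, "water")
             for k in range(len(coords))]
    return Topology(atoms), Frame(time=0.0, box=box, coordinates=coords)


@_register("solvation_shell")
def gen_solvation_shell(n_sites: int = 200,
                        shell_radii: Sequence[float] = (2.85, 5.0),
                        shell_counts: Sequence[int] = (4, 12),
                        jitter_sigma: float = 0.05,
                        box=None, seed: int = 3):
    """Hydration-shell fixture: polar sites each dressed with concentric
    water-oxygen shells at prescribed radii (defaults: first shell 2.85 Å,
    second 5.0 Å — the hydrogen-bonding distances the g(r) analyses probe).

    Sites sit on a cubic grid separated by ≥ 2·max(shell_radii) so shells
    never overlap; shell directions are uniform on the sphere and radii get
    Gaussian jitter of width ``jitter_sigma``.
    """
    shell_radii = np.asarray(shell_radii, dtype=float)
    shell_counts = np.asarray(shell_counts, dtype=int)
    if np.any(shell_radii <= 0):
        raise ValueError("shell radii must be > 0")
    spacing = float(2.0 * shell_radii.max() + 2.0)
    per_axis = int(np.ceil(n_sites ** (1.0 / 3.0)))
    if box is None:
        box = np.full(3, per_axis * spacing)
    else:
        box = np.asarray(box, dtype=float)
        if np.any(box < per_axis * spacing):
            raise ValueError(
                f"box {box} too small: sites need spacing {spacing:.2f} Å "
                f"({per_axis} per axis)")
    rng = np.random.default_rng(seed)
    grid = np.array(np.meshgrid(*[np.arange(per_axis)] * 3,
                                indexing="ij")).reshape(3, -1).T
    sites = (grid[:n_sites] + 0.5) * spacing
    atoms, coords = [], []
    aid = 0
    for m, site in enumerate(sites):
        atoms.append(Atom(aid, "N", "N", element_mass("N"), "SIT", m, m,
                          "hydrophilic_head"))
        coords.append(site)
        aid += 1
    mol = len(sites)
    for m, site in enumerate(sites):
        for radius, count in zip(shell_radii, shell_counts):
            if count <= 0:
                continue
            dirs = marsaglia_sphere(rng, int(count))
            radii = np.full(int(count), radius)
            if jitter_sigma > 0:
                radii = radii + rng.normal(0.0, jitter_sigma,
                                           size=int(count))
            for d, r in zip(dirs, radii):
                atoms.append(Atom(aid, "O", "O", element_mass("O"), "HOH",
                                  mol, mol, "water"))
                coords.append(site + d * r)
                aid += 1
                mol += 1
    frame = Frame(time=0.0, box=box,
                  coordinates=wrap_coordinates(np.array(coords), box))
    return Topology(atoms), frame


# ---------------------------------------------------------------------------
# PA aggregates
# ---------------------------------------------------------------------------

def _pa_chain_atoms(atoms, aid, mol, beads_per_pa, n_tail):
    """Append one PA's bead records; returns next atom id."""
    for k in range(beads_per_pa):
        tag = "hydrophobic_tail" if k < n_tail else "hydrophilic_head"
        resname = "TAIL" if k < n_tail else "HEAD"
        atoms.append(Atom(aid, f"B{k+1}", "B", BEAD_MASS, resname, mol, mol,
                          tag))
        aid += 1
    return aid


def _hexagonal_centroids(n_fibres: int, spacing: float):
    """Centroid xy-positions on a triangular (hexagonal-packing) patch and a
    box that keeps all minimum-image nearest-neighbour distances = spacing."""
    s = spacing
    h = s * np.sqrt(3.0) / 2.0
    if n_fibres == 1:
        pts = np.array([[0.0, 0.0]])
        box_xy = np.array([4 * s, 4 * s])
    elif n_fibres == 2:
        pts = np.array([[0.0, 0.0], [s, 0.0]])
        box_xy = np.array([3 * s, 3 * s])
    else:
        # fill staggered rows of 3 (6 fibres = the 2x3 hexagonal patch)
        pts = []
        row = 0
        while len(pts) < n_fibres:
            x0 = (s / 2.0) * (row % 2)
            for c in range(3):
                if len(pts) < n_fibres:
                    pts.append([x0 + c * s, row * h])
            row += 1
        pts = np.array(pts)
        extent = pts.max(axis=0) - pts.min(axis=0)
        box_xy = extent + np.array([s, s])
    # centre the patch in the box
    centre = (pts.max(axis=0) + pts.min(axis=0)) / 2.0
    pts = pts - centre + box_xy / 2.0
    return pts, box_xy


@_register("pa_bundle")
def gen_pa_bundle(n_fibres: int = 6, pas_per_fibre: int = 50,
                  fibre_radius: float = 25.0, centroid_spacing: float = 50.0,
                  box_z: float = 45.5, seed: int = 0,
                  beads_per_pa: int = PA_BEADS_DEFAULT,
                  n_tail: int = PA_TAIL_BEADS_DEFAULT,
                  water_beads: int = 0):
    """Bundle of axis-aligned periodic PA fibres on a hexagonal-packing
    lattice.

    Defaults reproduce the assembled architecture: 6 fibres × 50 PAs =
    300 PAs, 50 Å centroid spacing, box_z 45.5 Å (50 PAs / 4.55 nm ≈ 11 PA
    per nm).  Each PA is a radial 12-bead chain: tail beads within
    0.5·fibre_radius of the fibre axis, head beads further out.  Optional
    ``water_beads`` are placed uniformly outside a 3 Å exclusion of PA beads.
    """
    if centroid_spacing < 2.0 * fibre_radius and n_fibres > 1:
        raise ValueError(
            f"fibres overlap: spacing {centroid_spacing} < 2 x radius "
            f"{fibre_radius}")
    rng = np.random.default_rng(seed)
    centroids_xy, box_xy = _hexagonal_centroids(n_fibres, centroid_spacing)
    box = np.array([box_xy[0], box_xy[1], box_z])
    atoms, coords, bonds = [], [], []
    aid = 0
    for f in range(n_fibres):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        # evenly spaced azimuths sum to zero (centroid exactly on the axis);
        # shuffling decorrelates azimuth from z so the principal axis is z
        azi = rng.permutation(pas_per_fibre)
        for i in range(pas_per_fibre):
            mol = f * pas_per_fibre + i
            theta = phase + 2.0 * np.pi * azi[i] / pas_per_fibre
            z = (i + 0.5) * box_z / pas_per_fibre
            start = aid
            aid = _pa_chain_atoms(atoms, aid, mol, beads_per_pa, n_tail)
            for k in range(beads_per_pa):
                r = (k + 0.5) * fibre_radius / beads_per_pa
                coords.append([centroids_xy[f, 0] + r * np.cos(theta),
                               centroids_xy[f, 1] + r * np.sin(theta),
                               z])
            bonds.extend((start + k, start + k + 1)
                         for k in range(beads_per_pa - 1))
    coords = np.array(coords)
    if water_beads > 0:
        placed = _fill_random(rng, int(water_beads), box, coords,
                              exclusion=3.0)
        mol0 = n_fibres * pas_per_fibre
        for w in range(len(placed)):
            atoms.append(Atom(aid, "W", "W", BEAD_MASS, "W", mol0 + w,
                              mol0 + w, "water"))
            aid += 1
        coords = np.vstack([coords, placed])
    frame = Frame(time=0.0, box=box,
                  coordinates=wrap_coordinates(coords, box))
    return Topology(atoms, bonds), frame


def _fill_random(rng, n, box, existing, exclusion):
    """Uniform points in the box at least ``exclusion`` from existing
    points (grid-accelerated rejection sampling)."""
    from .core import periodic_kdtree, wrap_coordinates as wrapc
    out = []
    tree = periodic_kdtree(existing, box) if len(existing) else None
    tries = 0
    while len(out) < n and tries < 200 * n + 1000:
        p = rng.uniform(0, 1, size=3) * box
        tries += 1
        ok = True
        if tree is not None:
            d, _ = tree.query(np.where(p >= box, 0.0, p))
            ok = d >= exclusion
        if ok and out:
            d = np.linalg.norm(
                (np.array(out) - p + box / 2) % box - box / 2, axis=1)
            ok = np.all(d >= exclusion)
        if ok:
            out.append(p)
    if len(out) < n:
        raise RuntimeError(f"could not place {n} water beads (got {len(out)})")
    return np.array(out)


@_register("micelle")
def gen_micelle(n_pa: int = 50, radius: float = 20.0, seed: int = 0,
                beads_per_pa: int = PA_BEADS_DEFAULT,
                n_tail: int = PA_TAIL_BEADS_DEFAULT, box=None):
    """Spherical micelle: PAs arranged radially on a Fibonacci sphere,
    tails pointing inward, heads on the surface."""
    if box is None:
        box = np.full(3, max(6.0 * radius, 4.0 * radius + 20.0))
    else:
        box = np.asarray(box, dtype=float)
    centre = box / 2.0
    atoms, coords, bonds = [], [], []
    aid = 0
    ks = np.arange(n_pa)
    zdir = 1.0 - 2.0 * (ks + 0.5) / n_pa
    rho = np.sqrt(np.clip(1.0 - zdir ** 2, 0.0, 1.0))
    ang = GOLDEN_ANGLE * ks
    dirs = np.stack([rho * np.cos(ang), rho * np.sin(ang), zdir], axis=1)
    for i in range(n_pa):
        start = aid
        aid = _pa_chain_atoms(atoms, aid, i, beads_per_pa, n_tail)
        for k in range(beads_per_pa):
            r = (k + 0.5) * radius / beads_per_pa
            coords.append(centre + dirs[i] * r)
        bonds.extend((start + k, start + k + 1)
                     for k in range(beads_per_pa - 1))
    frame = Frame(time=0.0, box=box,
                  coordinates=wrap_coordinates(np.array(coords), box))
    return Topology(atoms, bonds), frame


# ---------------------------------------------------------------------------
# velocity trajectories and Langevin sampling
# ---------------------------------------------------------------------------

@_register("harmonic_velocity")
def gen_harmonic_velocity_traj(freq, n_atoms: int = 8, n_steps: int = 4096,
                               dt_fs: float = 1.0, seed: int = 0,
                               amplitude: float = 1.0) -> Trajectory:
    """Velocity trajectory of superposed cosine modes at given wavenumbers.

    Per atom and Cartesian component, v(t) = Σ_m A cos(2π c ν̃_m t + φ),
    with independent uniform random phases; positions are the exact
    integrals of v(t).  The analytic VACF is Σ_m (A²/2) cos(2π c ν̃_m τ)
    (normalized), making this the closed-form oracle for the VACF → VDOS
    pipeline.
    """
    freqs = np.atleast_1d(np.asarray(freq, dtype=float))
    rng = np.random.default_rng(seed)
    dt_ps = dt_fs * 1.0e-3
    t = np.arange(n_steps) * dt_ps
    omega = 2.0 * np.pi * C_CM_PER_PS * freqs  # rad/ps
    box = np.full(3, 1000.0)
    vel = np.zeros((n_steps, n_atoms, 3))
    pos = np.zeros((n_steps, n_atoms, 3))
    for m, w in enumerate(omega):
        phases = rng.uniform(0, 2 * np.pi, size=(n_atoms, 3))
        arg = w * t[:, None, None] + phases[None, :, :]
        vel += amplitude * np.cos(arg)
        if w > 0:
            pos += (amplitude / w) * np.sin(arg)
        else:
            pos += amplitude * np.cos(phases)[None, :, :] * t[:, None, None]
    pos += box / 2.0
    atoms = [Atom(k, "H", "H", element_mass("H"), "HOH", k, k, "water")
             for k in range(n_atoms)]
    top = Topology(atoms)
    frames = [Frame(time=t[i], box=box,
                    coordinates=wrap_coordinates(pos[i], box),
                    velocities=vel[i])
              for i in range(n_steps)]
    return Trajectory(top, frames)


@dataclass
class AnalyticPotential:
    """1-D analytic potential for Langevin/umbrella validation.

    Forms
    -----
    harmonic: U = ½ k (x − x0)²           params: k [kcal/mol/Å²], x0 [Å]
    double_well_quartic: U = h((x/a)²−1)² params: barrier h [kcal/mol], a [Å]
    piecewise_flat_wells: flat plateaus joined by linear ramps
                                          params: edges [Å], values
                                          [kcal/mol], ramp [Å]
    """

    form: str
    parameters: dict = field(default_factory=dict)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        p = self.parameters
        if self.form == "harmonic":
            return 0.5 * p.get("k", 1.0) * (x - p.get("x0", 0.0)) ** 2
        if self.form == "double_well_quartic":
            a = p.get("a", 1.0)
            return p.get("barrier", 1.0) * ((x / a) ** 2 - 1.0) ** 2
        if self.form == "piecewise_flat_wells":
            return self._piecewise(x)[0]
        raise ValueError(f"unknown potential form {self.form!r}")

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        p = self.parameters
        if self.form == "harmonic":
            return p.get("k", 1.0) * (x - p.get("x0", 0.0))
        if self.form == "double_well_quartic":
            a = p.get("a", 1.0)
            h = p.get("barrier", 1.0)
            return h * 4.0 * x / a ** 2 * ((x / a) ** 2 - 1.0)
        if self.form == "piecewise_flat_wells":
            return self._piecewise(x)[1]
        raise ValueError(f"unknown potential form {self.form!r}")

    def _piecewise(self, x):
        """Plateau values joined by linear ramps of width ``ramp`` centred on
        ``edges``; gradient by central difference of the interpolant."""
        p = self.parameters
        edges = np.asarray(p.get("edges", [0.0]), dtype=float)
        values = np.asarray(p.get("values", [0.0, 0.0]), dtype=float)
        if len(values) != len(edges) + 1:
            raise ValueError("need len(values) == len(edges) + 1")
        ramp = float(p.get("ramp", 0.5))
        xs = [edges[0] - ramp / 2.0 - 1e6]
        us = [values[0]]
        for e, v in zip(edges, values[1:]):
            xs.extend([e - ramp / 2.0, e + ramp / 2.0])
            us.extend([us[-1], v])
        xs.append(edges[-1] + ramp / 2.0 + 1e6)
        us.append(values[-1])
        u = np.interp(x, xs, us)
        eps = 1e-6
        g = (np.interp(x + eps, xs, us) - np.interp(x - eps, xs, us)) / (2 * eps)
        return u, g


def langevin_sample(potential: AnalyticPotential, bias=None,
                    kT: float = 0.59616, friction: float = 1.0,
                    dt: float = 0.01, n_steps: int = 10000,
                    x0: Optional[float] = None, seed: int = 0,
                    burn_in: int = 0, stride: int = 1,
                    domain: float = 1.0e3) -> np.ndarray:
    """Overdamped Langevin (Euler–Maruyama) samples of a 1-D coordinate.

    With ``bias=(center, k)`` the sampled potential is U(x) + ½k(x−c)²
    (an umbrella window).  ``stride`` keeps every stride-th step after
    ``burn_in`` discarded steps, for decorrelated samples at fixed output
    length.  Diverging trajectories (|x| > domain) raise, suggesting a
    smaller dt.

    For purely quadratic total potentials the Euler–Maruyama recursion is
    linear and is evaluated with a fast filter; the result is the same
    recursion, not a different sampler.
    """
    rng = np.random.default_rng(seed)
    c, kb = (bias if bias is not None else (0.0, 0.0))
    if x0 is None:
        x0 = c if bias is not None else 0.0
    total = n_steps * stride + burn_in
    sigma = np.sqrt(2.0 * kT * dt / friction)
    noise = rng.standard_normal(total)
    if potential.form == "harmonic":
        # total force is linear: x' = a x + b + σξ — a linear recursion
        k_u = potential.parameters.get("k", 1.0)
        xc = potential.parameters.get("x0", 0.0)
        a = 1.0 - (k_u + kb) * dt / friction
        if abs(a) >= 1.0:
            raise RuntimeError("Euler–Maruyama unstable: (k_total·dt/γ) ≥ 2; "
                               "use a smaller dt")
        b = (k_u * xc + kb * c) * dt / friction
        from scipy.signal import lfilter
        drive = b + sigma * noise
        drive[0] += a * float(x0)
        xs = lfilter([1.0], [1.0, -a], drive)
        if np.max(np.abs(xs)) > domain:
            raise RuntimeError("Langevin trajectory diverged; use a smaller "
                               "dt")
        return xs[burn_in::stride][:n_steps].copy()
    x = float(x0)
    out = np.empty(n_steps)
    grad = potential.gradient
    kept = 0
    for i in range(total):
        g = float(grad(x)) + kb * (x - c)
        x = x - g * dt / friction + sigma * noise[i]
        if abs(x) > domain:
            raise RuntimeError(
                f"Langevin trajectory diverged (|x|={abs(x):.3g} > {domain});"
                " use a smaller dt")
        if i >= burn_in and (i - burn_in) % stride == 0 and kept < n_steps:
            out[kept] = x
            kept += 1
    return out[:kept]


def langevin_walkers(potential: AnalyticPotential, n_walkers: int,
                     kT: float = 0.59616, friction: float = 1.0,
                     dt: float = 0.01, n_steps: int = 1000,
                     x0: float = 0.0, seed: int = 0) -> np.ndarray:
    """(n_steps, n_walkers) matrix of independent overdamped walkers,
    vectorized; used by residence-time oracles."""
    rng = np.random.default_rng(seed)
    x = np.full(n_walkers, float(x0))
    sigma = np.sqrt(2.0 * kT * dt / friction)
    out = np.empty((n_steps, n_walkers))
    for i in range(n_steps):
        grad = potential.gradient(x)
        x = x - grad * dt / friction + sigma * rng.standard_normal(n_walkers)
        out[i] = x
    return out


# ---------------------------------------------------------------------------
# peptide-backbone construction (Ramachandran / chirality fixtures)
# ---------------------------------------------------------------------------

def place_atom(a, b, c, bond: float, angle_deg: float,
               dihedral_deg: float) -> np.ndarray:
    """NeRF placement: new atom D bonded to c with |cd| = bond,
    angle(b,c,d) = angle and dihedral(a,b,c,d) = dihedral."""
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    # sign chosen so dihedral(a, b, c, new) measures back as dihedral_deg
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(dih),
                        -bond * np.sin(ang) * np.sin(dih)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ideal peptide internal coordinates (Engh–Huber-like)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7


def build_backbone(phis, psis, omega: float = 180.0, resname: str = "ALA",
                   with_cb: bool = True, box=None):
    """Construct an ideal peptide backbone with prescribed (φ, ψ).

    ``phis[0]`` and ``psis[-1]`` are undefined for a linear chain and are
    ignored.  Returns (Topology, Frame); atoms are N, CA, C (and CB) per
    residue with peptide bonds in the topology.
    """
    phis = np.asarray(phis, dtype=float)
    psis = np.asarray(psis, dtype=float)
    n_res = len(phis)
    if len(psis) != n_res:
        raise ValueError("phis and psis must have equal length")
    coords = {}
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    coords[(0, "C")] = coords[(0, "CA")] + _B_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res - 1):
        coords[(i + 1, "N")] = place_atom(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _B_C_N, _A_CA_C_N, psis[i])
        coords[(i + 1, "CA")] = place_atom(
            coords[(i, "CA")], coords[(i, "C")], coords[(i + 1, "N")],
            _B_N_CA, _A_C_N_CA, omega)
        coords[(i + 1, "C")] = place_atom(
            coords[(i, "C")], coords[(i + 1, "N")], coords[(i + 1, "CA")],
            _B_CA_C, _A_N_CA_C, phis[i + 1])
    if with_cb:
        for i in range(n_res):
            # L-configuration branch off the backbone plane
            # (improper N-CA-C-CB comes out ≈ +120°, the L anchor)
            coords[(i, "CB")] = place_atom(
                coords[(i, "N")], coords[(i, "C")], coords[(i, "CA")],
                1.53, 110.5, -123.0)
    names = ["N", "CA", "C"] + (["CB"] if with_cb else [])
    atoms, xyz, bonds = [], [], []
    aid = 0
    index = {}
    for i in range(n_res):
        for nm in names:
            el = nm[0]
            atoms.append(Atom(aid, nm, el, element_mass(el), resname, i, 0,
                              "hydrophilic_head"))
            xyz.append(coords[(i, nm)])
            index[(i, nm)] = aid
            aid += 1
    for i in range(n_res):
        bonds.append((index[(i, "N")], index[(i, "CA")]))
        bonds.append((index[(i, "CA")], index[(i, "C")]))
        if with_cb:
            bonds.append((index[(i, "CA")], index[(i, "CB")]))
        if i + 1 < n_res:
            bonds.append((index[(i, "C")], index[(i + 1, "N")]))
    xyz = np.array(xyz)
    if box is None:
        span = xyz.max(axis=0) - xyz.min(axis=0)
        box = span + 100.0
        xyz = xyz - xyz.min(axis=0) + 50.0
    return Topology(atoms, bonds), Frame(time=0.0, box=box, coordinates=xyz)
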