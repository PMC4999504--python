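# Methods

This note documents the models, conventions, numerical choices and
limitations behind each analysis. Units are fixed package-wide: Å, ps, amu,
K, kcal/mol, cm⁻¹; mass densities in g/cc; k_B = 0.0019872041 kcal/mol/K.
All boxes are orthorhombic; triclinic input raises an explicit
unsupported-format error.

## Geometry and selections

Every distance is minimum-image: the displacement b − a is wrapped
component-wise into (−L/2, +L/2], which equals the shortest vector over all
27 periodic images (property-tested against explicit enumeration).
Neighbour searches use periodic k-d trees; coordinates are stored wrapped,
and analyses that need whole molecules (end-to-end distances, cluster
geometry, backbone dihedrals) unwrap on demand through bond connectivity or
the cluster contact graph.

Selections are a small expression grammar over `group` (hydrophobic_tail,
hydrophilic_head, water, bead, other), `element`, `resname`, `name`,
`molid`, `all`, with `and/or/not`, parentheses, and a distance filter
`A within d of B`. `within` keeps the atoms of A belonging to molecules
with at least one A-atom within d of any B atom — whole molecules enter or
leave a hydration shell together, which is the convention wanted for
"water within 5 Å of the PA surface"-style shells. Residue-name → group
mappings are configurable; the defaults tag common water residue names as
water and amino-acid residue names as hydrophilic head groups.

## Synthetic study systems

The generators are pure functions of (parameters, seed); identical inputs
give bit-identical output. Random directions use Marsaglia's uniform-sphere
rejection method so oracle code can reproduce the streams.

- **Ideal gas** — i.i.d. uniform positions; the g(r) ≡ 1 null model.
- **Lattices** — fcc, sc and diamond-cubic ("ice-like") crystals; these
  carry exact coordination geometry (12 neighbours at a/√2, 6 at a, 4 at
  a√3/4 with cos ψ = −1/3) and anchor the order-parameter oracles.
- **Solvation shells** — polar sites on a grid (separation ≥ 2·max radius,
  so shells never overlap), each dressed with water oxygens at prescribed
  radii plus Gaussian radial jitter; defaults 4 waters at 2.85 Å and 12 at
  5.0 Å, the first/second-shell hydrogen-bonding distances the g(r)
  analyses probe. Default 200 sites, jitter 0.05 Å.
- **PA bundle** — each PA is a 12-bead radial chain (4 tail + 8 head
  beads, 72 amu each), a stand-in for a MARTINI-style mapping; tails lie
  within 0.5·fibre_radius of the axis, heads outward. Azimuths are evenly
  spaced (they sum to zero, so the fibre centroid sits exactly on the
  axis) and randomly assigned to z-positions so azimuth and height are
  uncorrelated and the principal axis is the fibre axis. Fibres sit on a
  triangular (hexagonal-packing) patch with equal nearest-neighbour
  spacing under PBC. Defaults reproduce the assembled architecture: 6
  fibres × 50 PAs = 300 PAs, 50 Å spacing, fibre radius 25 Å, box_z
  45.5 Å (50 PAs / 4.55 nm ≈ 11 PA per nm).
- **Micelle** — PAs on a Fibonacci sphere, tails inward; 50 PAs at radius
  20 Å by default (above the N_agg > 40 micellization threshold).
- **Oscillator trajectories** — per atom and component,
  v(t) = Σₘ A cos(2πc ν̃ₘ t + φ) with random phases and exactly integrated
  positions; the VACF is a closed-form cosine, making this the analytic
  oracle for the spectral pipeline.
- **Langevin sampler** — overdamped Euler–Maruyama,
  x' = x − ∇U·dt/γ + √(2k_BT·dt/γ)·ξ, with optional harmonic umbrella
  bias, burn-in and stride (subsampling decorrelates samples at fixed
  output length). For purely quadratic potentials the recursion is linear
  and is evaluated with a fast filter — the same recursion, not a
  different sampler. Analytic potentials: harmonic, quartic double well
  (barrier h at x = 0, minima at ±a), and flat plateaus joined by linear
  ramps. Euler–Maruyama has an O(k·dt/γ) stationary-variance bias; the
  statistical tests choose dt so this bias sits well inside their
  tolerances.

What the generators do **not** emulate: force-field energetics, thermal
disorder beyond simple jitter, realistic hydrogen-bond network topology,
or assembly kinetics. Passing tests therefore demonstrate that the
*analyses* are correct on systems of known structure, not that any MD
observation is reproduced.

## Water structure

- **g(r)**: histogram of minimum-image pair distances, normalized by exact
  shell volumes (4π/3)(r₂³−r₁³), frame count, reference-atom count and the
  mean number density of the partner selection; self pairs always excluded,
  intramolecular pairs excluded by default. r_max is capped at min(box)/2.
  Peak positions are parabolically interpolated; the first-peak finder
  requires a local maximum at ≥ 50 % of the global maximum, which
  suppresses single-count noise bins in sparse histograms.
- **Density profiles**: per-slab mass (g/cc) or number densities along a
  box axis; slab volume dr × the two orthogonal edges.
- **Q₆**: per-particle qₗ₌₆ invariant over minimum-image neighbour
  vectors; neighbour convention (cutoff, default 3.5 Å for atomistic
  oxygens and ~6.5 Å recommended for CG beads, or k-nearest) is recorded
  in every output series. Both per-particle-averaged (default) and
  globally averaged q₆ₘ variants are provided. Isolated particles are
  excluded with a logged count.
- **Tetrahedral order**: the 4 nearest neighbours by minimum-image
  distance; q = 1 for a perfect tetrahedron, E[q] = 0 for uniformly random
  directions, minimum −3 (all neighbours collinear).
- **Translational order**: t = (1/ξ_c)∫₀^{ξ_c}|g(ξ)−1|dξ with
  ξ = r·ρ^{1/3}; default ξ_c = 2.843 (a standard reduced cutoff). The
  required real-space range ξ_c/ρ^{1/3} must fit the minimum-image bound,
  else the call raises with the required box size.
- **Hydrogen bonds**: geometric criterion, D–A ≤ 3.5 Å and H–D–A ≤ 30°
  (configurable; the bibliographic sources for this system state no
  criterion). Hydrogens inside the donor selection are ignored; heavy
  donors must carry bonded hydrogens.
- **Monotonicity check**: ordering metrics (Q₆, t) are verified to decrease
  monotonically with Gaussian positional jitter on an fcc lattice. A
  jittered *crystal* is the right substrate for this property — the
  solvation-shell fixture has uniformly random shell directions, so its Q₆
  is isotropy-limited and insensitive to radial jitter.

## Dynamics and spectra

The VACF C(τ) = ⟨vᵢ(t)·vᵢ(t+τ)⟩ is averaged over selected atoms,
components and all time origins (FFT-based, exact for these averages) and
normalized to C(0) = 1. The VDOS is the one-sided cosine transform of the
windowed VACF on the wavenumber axis ν̃_k = k/(c·N·dt); the grid spacing is
reported as the resolution, and a half-Hann lag window (default) suppresses
truncation lobes. Band metrics (default bands: stretch 2800–3800, bend
1500–1800, libration 300–1100 cm⁻¹) report the parabolically interpolated
peak position, height and trapezoidal integral; the full-axis integral
satisfies the sum rule ∫D(ν)dν = C(0)/(2c) to 1 %. Oscillator fixtures
recover peaks at 400–3400 cm⁻¹ to within one resolution element, and the
ordered-vs-bulk O–H stretch red shift is exercised as a differential check
on synthetic bands (~3390 → ~3340 cm⁻¹): absolute stretch positions depend
on the water model and μs-scale MD and are out of desk-scale reach.

Residence times: molecules inside a per-frame-evaluated region are tracked
by molecule id; S(τ) is the fraction of (molecule, origin) events remaining
continuously inside for τ, tolerating excursions up to `allowed_blip`
frames (default 2; 0 gives the strict intermittency-free definition).
Origins are restricted to the first n − max_lag frames so every lag sees
the same origin set — S is then nonincreasing by construction and exactly 1
for molecules that never leave. τ comes from a least-squares exponential
fit restricted to S ≥ 0.01 (tail noise excluded); a non-decaying curve is
flagged non-identifiable. The estimator is validated against a
sliding-window oracle and a 500-walker free-diffusion escape simulation.

## Assembly census

Aggregates are single-linkage connected components over minimum-image bead
contacts (default cutoffs: 6.0 Å for CG beads, 4.5 Å recommended for
atomistic carbons; always echoed in output). Labels are deterministic:
ordered by size, ties broken by lowest member molecule id. A cluster is a
**fibre** iff its axial extent along the leading PCA axis of the unwrapped
member beads reaches 0.9 × the box edge (periodic-spanning), else a
micelle; this operationalizes the micelle/fibre distinction, which the
source material does not define structurally. Fibre linear density divides
N_agg by the axial box length; the diameter is twice the 95th percentile of
member-atom radial distances. Lattice spacing is the mean nearest-neighbour
minimum-image centroid distance, computed in the plane perpendicular to the
fibre axis when one is supplied (periodic fibres have no well-defined axial
centroid); coordination counts neighbours within 1.2 × the minimum spacing.

Ramachandran: φ = dihedral(C₋₁, N, Cα, C), ψ = dihedral(N, Cα, C, N₊₁),
IUPAC sign convention, degrees in (−180, 180], on unwrapped molecules.
The region table is config-driven and checked in order; the
polyproline-II box is centred on (−65°, +145°) with 25° half-widths, the
β, α_R and α_L boxes follow common conventions. Chirality is the sign of
the improper dihedral N–Cα–C–Cβ, anchored so ideal L-alanine geometry
(≈ +120°) is L; mirror reflection flips the label. The backbone builder
(NeRF internal-coordinate construction with Engh–Huber-like bond geometry)
reproduces prescribed (φ, ψ) to 10⁻⁶ degrees and emits L residues.

## Multiscale coupling

Forward mapping places each bead at the mass-weighted centre of its member
atoms after unwrapping the group about its first atom; groups spanning more
than half the box are rejected as ill-defined. Back-mapping regrows atoms
from per-bead templates with a uniform random rotation (quaternion method)
plus Gaussian jitter (default σ = 0.3 Å), then shifts rigidly so the group
centre of mass equals the bead position exactly — the restraint is an
exact projection, so forward∘back round trips are COM-exact and do not
drift over repeated iterations. Back-mapped chirality is not enforced
(reconstruction from bead centres can invert centres; an optional mirror
fix exists in the chirality utilities). Water beads default to 4 molecules
per bead (MARTINI convention).

Water reinsertion computes molecule counts as ⌊ρ·V/m_w⌋ (18.0154 amu), fills
region targets first and then the rest of the box so the box-mean density
equals the overall target; placement is rejection sampling with a hard
2.4 Å oxygen exclusion against all existing atoms and previously placed
oxygens, accelerated by a periodic cell grid, with a packing-infeasibility
error after 10⁵ consecutive rejections. The "between two fibres" region is
the rectangular channel from one fibre surface to the other along the
centre-to-centre line (width default one fibre radius, full box height);
every point of it is farther than one fibre radius from both axes and its
volume is exact. Placement guarantees geometry only — the subsequent
force-field relaxation of a real multistage protocol is out of scope.

## Free energy

WHAM iterates P(ξ_b) = Σᵢ nᵢhᵢ(b) / Σᵢ nᵢ exp[(fᵢ − Uᵢ(ξ_b))/k_BT] and
fᵢ = −k_BT ln Σ_b P(ξ_b) exp(−Uᵢ(ξ_b)/k_BT) to a tolerance of 10⁻⁸ k_BT
(max 10⁵ iterations), with f₀ = 0 gauge; W = −k_BT ln P shifted to min 0.
Bins default to 100 over the pooled sample range with a 5-count occupancy
floor; adjacent windows must share an occupied bin (a gap is an error
naming the windows), each window needs ≥ 100 samples, and one solve admits
one temperature. Uncertainties, when requested, come from a seeded block
bootstrap (20 blocks per window), warm-started from the converged f.
Validation is entirely against analytic potentials: a harmonic PMF is
recovered to < 0.1 kcal/mol RMS (7 windows, 3×10⁴ strided samples each),
its curvature to 5 %, and a 2 kcal/mol double-well barrier to 15 %.
Duplicating a window doubles its weight in the equations, which shifts W
by an amount bounded by the statistical noise (zero only in the
consistent-histogram limit).

The enthalpy/entropy decomposition uses two PMFs at T₁ < T₂ on one grid:
ΔS = −[W(T₂) − W(T₁)]/(T₂ − T₁), W̄ at T̄ = (T₁+T₂)/2 as the profile mean,
ΔH = W̄ + T̄·ΔS, so W = ΔH + (−T̄ΔS) holds bin-wise exactly. A
temperature-independent profile gives ΔS ≡ 0; a purely entropic spring
W = c·k_B·T·ξ² gives ΔH ≡ 0. No real PA–PA PMF values are asserted — the
reaction coordinate, window layout and well depths of the original
umbrella calculations are not published at desk-reproducible detail.

## Pipeline and determinism

`run_pipeline` executes YAML-configured stages (synth → census → rdf →
order → solvate → density_check) with per-stage seeds derived
deterministically from the global seed; every stage logs parameters,
outputs, seed and wall time to a JSON manifest, and a rerun with the same
config is byte-identical. TSV outputs carry commented parameter-echo
headers. The `hydrafibre` CLI is a thin layer over the library.

## Problem sizes

The shipped study systems are desk-scale by design: 300-PA bundles
(3,600 beads), 10³–10⁴-particle gases and lattices, 10⁴–10⁵ Langevin
samples per umbrella window, 4,096-step oscillator trajectories and
500-walker residence simulations. These sizes give each estimator
statistical room an order of magnitude inside its stated tolerance while
keeping the full suite and the acceptance script in the minutes range.

## Known limitations

- Orthorhombic PBC only; no triclinic cells, PSF/XTC/TRR, or charge/FF
  parameter handling.
- The bead chemistry is a structural stand-in: bead masses, the 12-bead PA
  chain and the CG water multiplicity are conventions, not a parametrized
  force field; the CGMap file interface is the contract for real mappings.
- Absolute vibrational band positions, μs-scale ordering kinetics and
  experimental observables (CD lag times, IR bands, TEM morphology) are
  outside what synthetic fixtures can certify; spectra are validated on
  oscillator closed forms and differential shifts only.
- The micelle/fibre boundary (0.9 × box spanning) and the inter-fibre
  region geometry are this package's operational definitions.
- Rejection-sampled water respects exclusion geometry but is not
  energy-relaxed; inserted configurations are starting points, not
  equilibrium ensembles.
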