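"""Time-correlation analyses: velocity autocorrelation, vibrational density
of states, spectral band metrics and water residence times.

The VDOS is obtained as the cosine transform of the velocity autocorrelation
function (VACF), the same route used for the O–H stretch/bend/libration
bands of hydration water; a red shift of the stretch band diagnoses stronger
hydrogen bonding.  Residence times come from the continuous-survival
probability of molecules inside a region, with a configurable tolerance for
transient recrossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .core import SelectionSpec, Trajectory, select
from .units import C_CM_PER_PS

#: default reporting bands, cm⁻¹ (O–H stretch, H–O–H bend, libration)
BANDS_DEFAULT = {"stretch": (2800.0, 3800.0),
                 "bend": (1500.0, 1800.0),
                 "libration": (300.0, 1100.0)}


@dataclass
class CorrelationSeries:
    """Normalized time correlation: value(0) = 1, lags in ps."""

    lags: np.ndarray
    values: np.ndarray
    n_atoms: int = 0
    n_origins: int = 0
    mass_weighted: bool = False

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0]) if len(self.lags) > 1 else 0.0


@dataclass
class Spectrum:
    wavenumbers: np.ndarray     # cm⁻¹, uniform
    intensity: np.ndarray
    resolution: float           # cm⁻¹ (= grid spacing)
    window: str = "hann"


@dataclass
class SurvivalCurve:
    lags: np.ndarray            # ps
    survival: np.ndarray        # fraction, nonincreasing, survival[0] = 1
    tau: float = np.nan         # ps; NaN/inf when non-identifiable
    fit: dict = field(default_factory=dict)


def compute_vacf(traj: Trajectory, sel="all", max_lag: Optional[float] = None,
                 mass_weighted: bool = False) -> CorrelationSeries:
    """Velocity autocorrelation C(τ) = ⟨v_i(t)·v_i(t+τ)⟩ averaged over the
    selected atoms and all valid time origins, normalized so C(0) = 1.

    Computed with FFTs over the full time axis (all origins), which is exact
    for the stationary averages used here.
    """
    if not traj.has_velocities():
        raise ValueError("trajectory has no velocities; load the velocity "
                         "stream (read_trajectory(..., velocity_paths=...))")
    sel = sel if isinstance(sel, SelectionSpec) else SelectionSpec(sel)
    ids = select(traj.topology, traj.frames[0], sel)
    if len(ids) == 0:
        raise ValueError(f"selection {sel.expression!r} is empty")
    dt = traj.dt
    n = traj.n_frames
    v = np.stack([fr.velocities[ids] for fr in traj.frames])  # (n, m, 3)
    if mass_weighted:
        w = traj.topology.masses[ids]
        v = v * np.sqrt(w)[None, :, None]
    n_lag = n if max_lag is None else min(n, int(round(max_lag / dt)) + 1)
    # FFT autocorrelation per atom/component, summed
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(v, n=nfft, axis=0)
    acf = np.fft.irfft((f * np.conj(f)).real.sum(axis=(1, 2)), n=nfft)[:n_lag]
    counts = np.arange(n, n - n_lag, -1)           # origins per lag
    acf = acf / counts
    c0 = acf[0]
    if c0 == 0:
        raise ValueError("zero velocities: VACF undefined")
    return CorrelationSeries(np.arange(n_lag) * dt, acf / c0,
                             n_atoms=len(ids), n_origins=n,
                             mass_weighted=mass_weighted)


def compute_vdos(vacf: CorrelationSeries, window: str = "hann") -> Spectrum:
    """Vibrational density of states: discrete cosine transform of the
    (windowed) VACF.

    Wavenumber axis ν̃_k = k / (c · T_total) in cm⁻¹ with T_total = N·dt;
    the grid spacing is reported as the spectral resolution.  The half-Hann
    window (default) tapers the lag tail to suppress truncation lobes.
    """
    c = np.asarray(vacf.values, dtype=float)
    n = len(c)
    if n < 2:
        raise ValueError("VACF too short")
    lags = np.asarray(vacf.lags, dtype=float)
    dts = np.diff(lags)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError("non-uniform lag spacing")
    dt = float(dts[0])
    if window == "hann":
        w = np.cos(np.pi * np.arange(n) / (2.0 * (n - 1))) ** 2
    elif window in (None, "none"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    cw = c * w
    # one-sided cosine transform: I_k = dt (c_0 + 2 Σ_{j>=1} c_j cos(2πkj/N))
    spec = np.fft.rfft(cw, n=n)
    intensity = dt * (2.0 * spec.real - cw[0])
    dnu = 1.0 / (C_CM_PER_PS * n * dt)
    wavenumbers = np.arange(len(intensity)) * dnu
    return Spectrum(wavenumbers, intensity, resolution=dnu,
                    window=window or "none")


def band_metrics(spec: Spectrum, band) -> tuple:
    """(peak_position cm⁻¹, peak_intensity, band_integral) inside a
    (lo, hi) wavenumber band; the peak position is parabolically
    interpolated between grid points."""
    lo, hi = band
    mask = (spec.wavenumbers >= lo) & (spec.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"band {band} outside the spectrum range "
                         f"[0, {spec.wavenumbers[-1]:.1f}]")
    nu = spec.wavenumbers[mask]
    y = spec.intensity[mask]
    i = int(np.argmax(y))
    pos, height = float(nu[i]), float(y[i])
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom < 0:
            shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
            pos = float(nu[i] + np.clip(shift, -0.5, 0.5) * spec.resolution)
    integral = float(np.trapezoid(y, nu))
    return pos, height, integral


def spectrum_sum_rule(vacf: CorrelationSeries) -> float:
    """Lag-domain value of the full-axis spectral integral.

    For the one-sided cosine transform used here, ∫₀^{ν_Nyq} D(ν) dν equals
    C(0)/(2c) (the classic VDOS sum rule ∝ ⟨v²⟩); with the normalized VACF
    and any window with w(0) = 1 this is 1/(2c)."""
    return float(vacf.values[0] / (2.0 * C_CM_PER_PS))


# ---------------------------------------------------------------------------
# residence times
# ---------------------------------------------------------------------------

def survival_from_occupancy(inside: np.ndarray, dt: float,
                            allowed_blip: int = 2,
                            min_survival: float = 0.01,
                            max_lag_frames: Optional[int] = None
                            ) -> SurvivalCurve:
    """Continuous-residence survival from a boolean occupancy matrix
    (n_molecules × n_frames).

    S(τ) is the fraction of (molecule, origin) events inside the region that
    remain continuously inside for τ, tolerating excursions of at most
    ``allowed_blip`` frames.  Origins are restricted to the first
    n − max_lag frames so every lag sees the same origin set, which makes
    S nonincreasing by construction and S ≡ 1 for molecules that never
    leave.  τ comes from a least-squares exponential fit restricted to
    S(τ) ≥ ``min_survival``.
    """
    inside = np.asarray(inside, dtype=bool)
    if inside.ndim != 2:
        raise ValueError("occupancy must be (n_molecules, n_frames)")
    n_mol, n_frames = inside.shape
    if not inside.any():
        raise ValueError("region is empty at every origin")
    filled = inside.copy()
    if allowed_blip > 0:
        for row in filled:
            _fill_blips(row, allowed_blip)
    if max_lag_frames is None:
        max_lag_frames = max(1, n_frames // 2)
    max_lag_frames = min(max_lag_frames, n_frames - 1)
    t0_max = n_frames - 1 - max_lag_frames
    # runs of continuous residence, as (start, end) inclusive
    starts, ends = [], []
    for row in filled:
        padded = np.concatenate([[0], row.astype(np.int8), [0]])
        diff = np.diff(padded)
        s = np.flatnonzero(diff == 1)
        e = np.flatnonzero(diff == -1) - 1
        starts.append(s)
        ends.append(e)
    s = np.concatenate(starts)
    e = np.concatenate(ends)
    lags = np.arange(max_lag_frames + 1)
    # origins t0 in [s, min(e - j, t0_max)] survive lag j continuously
    counts = np.maximum(
        np.minimum(e[None, :] - lags[:, None], t0_max) - s[None, :] + 1,
        0).sum(axis=1).astype(float)
    if counts[0] == 0:
        raise ValueError("region is empty at every valid time origin")
    survival = counts / counts[0]
    lags_ps = lags * dt
    curve = SurvivalCurve(lags_ps, survival)
    # exponential fit
    keep = survival >= min_survival
    fit: dict = {"n_points": int(keep.sum())}
    if survival[-1] >= 0.999:
        curve.tau = np.inf
        fit["identifiable"] = False
        fit["reason"] = "no molecule ever leaves the region"
    elif keep.sum() >= 3:
        try:
            popt, pcov = curve_fit(
                lambda t, tau: np.exp(-t / tau), lags_ps[keep],
                survival[keep], p0=[max(lags_ps[keep][-1], dt)],
                maxfev=10000)
            curve.tau = float(popt[0])
            fit["identifiable"] = True
            fit["tau_se"] = float(np.sqrt(pcov[0, 0]))
        except RuntimeError as exc:
            fit["identifiable"] = False
            fit["reason"] = str(exc)
    else:
        fit["identifiable"] = False
        fit["reason"] = "survival decays within fewer than 3 frames"
        curve.tau = float(dt) if survival[1] == 0 else np.nan
    curve.fit = fit
    return curve


def _fill_blips(row: np.ndarray, blip: int) -> None:
    """In place: flip False-runs of length ≤ blip with True on both sides."""
    n = len(row)
    i = 0
    while i < n:
        if not row[i]:
            j = i
            while j < n and not row[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= blip:
                row[i:j] = True
            i = j
        else:
            i += 1


def residence_time(traj: Trajectory, region, allowed_blip: int = 2,
                   min_survival: float = 0.01) -> SurvivalCurve:
    """Survival curve of molecules inside ``region`` (a selection evaluated
    per frame); molecules are tracked by molecule_id."""
    region = region if isinstance(region, SelectionSpec) \
        else SelectionSpec(region)
    top = traj.topology
    per_frame = []
    seen = set()
    for frame in traj.frames:
        ids = select(top, frame, region)
        mols = set(int(m) for m in top.molecule_ids[ids])
        per_frame.append(mols)
        seen |= mols
    if not seen:
        raise ValueError(f"region {region.expression!r} is empty at every "
                         "frame")
    order = sorted(seen)
    row = {m: k for k, m in enumerate(order)}
    inside = np.zeros((len(order), traj.n_frames), dtype=bool)
    for t, mols in enumerate(per_frame):
        for m in mols:
            inside[row[m], t] = True
    return survival_from_occupancy(inside, traj.dt or 1.0,
                                   allowed_blip=allowed_blip,
                                   min_survival=min_survival)
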