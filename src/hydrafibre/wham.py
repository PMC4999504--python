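"""Umbrella-sampling PMF via the weighted histogram analysis method (WHAM)
and two-temperature enthalpy/entropy decomposition.

The self-consistent WHAM equations combine biased window histograms into
the unbiased probability P(ξ) and the potential of mean force
W(ξ) = −k_B T ln P(ξ).  Comparing W at two temperatures gives
ΔS(ξ) = −∂W/∂T by finite difference, and hence the enthalpic and entropic
contributions ΔH and −TΔS that decide whether a contact-pair minimum is
enthalpy- or entropy-stabilized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .units import KB_KCAL


@dataclass
class UmbrellaWindow:
    """Biased samples of the reaction coordinate under the harmonic
    umbrella U_i(ξ) = ½ k (ξ − center)²."""

    center: float              # Å
    k: float                   # kcal/mol/Å²
    samples: np.ndarray        # Å
    temperature: float = 300.0  # K

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.k < 0:
            raise ValueError("spring constant must be >= 0")
        if len(self.samples) < 100:
            raise ValueError(
                f"window at {self.center}: needs >= 100 samples for fitting "
                f"(got {len(self.samples)})")

    def bias(self, xi) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(xi) - self.center) ** 2


@dataclass
class PMFProfile:
    """W(ξ) on a bin grid, min(W) = 0; optional bootstrap uncertainty and
    enthalpy/entropy decomposition arrays on the same grid."""

    bin_centers: np.ndarray
    W: np.ndarray                     # kcal/mol, NaN on unoccupied bins
    temperature: float
    uncertainty: Optional[np.ndarray] = None
    occupancy: Optional[np.ndarray] = None
    delta_h: Optional[np.ndarray] = None
    minus_t_delta_s: Optional[np.ndarray] = None
    free_energies: Optional[np.ndarray] = None   # per-window f_i
    meta: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.W)


def _solve_wham(hist, n_i, bias_bt, f_init, tol, max_iter):
    """Iterate the WHAM self-consistency equations.

    hist: (n_windows, n_bins) counts; bias_bt: (n_windows, n_bins) β·U_i;
    returns (P normalized over bins, f in kT units, n_iterations).
    """
    n_w, n_b = hist.shape
    total = hist.sum(axis=0)
    f = f_init.copy()
    exp_mb = np.exp(-bias_bt)                    # (n_w, n_b)
    for it in range(1, max_iter + 1):
        denom = (n_i[:, None] * np.exp(f)[:, None] * exp_mb).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        norm = p.sum()
        p = p / norm
        z = exp_mb @ p                           # (n_w,)
        f_new = -np.log(z)
        f_new = f_new - f_new[0]                 # gauge: f_0 = 0
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            return p, f, it
    raise RuntimeError(
        f"WHAM did not converge in {max_iter} iterations "
        f"(residual {delta:.3e} kT)")


def wham(windows: Sequence[UmbrellaWindow], bins: Optional[int] = None,
         bin_range: Optional[tuple] = None, tol: float = 1e-8,
         max_iter: int = 100000, occupancy_floor: int = 5,
         n_bootstrap: int = 0, n_blocks: int = 20, seed: int = 0
         ) -> PMFProfile:
    """Self-consistent WHAM estimate of the PMF from umbrella windows.

    All windows must share one temperature.  Bins default to 100 over the
    pooled sample range; bins with fewer than ``occupancy_floor`` total
    counts are masked (NaN in W).  Adjacent windows (by center) must share
    at least one occupied bin.  With ``n_bootstrap`` > 0, a seeded block
    bootstrap (``n_blocks`` blocks per window) gives per-bin uncertainties.
    The converged tolerance ``tol`` is in units of k_BT.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one window")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError(f"windows mix temperatures {sorted(temps)}; "
                         "WHAM requires one temperature per solve")
    temperature = windows[0].temperature
    kt = KB_KCAL * temperature
    all_samples = np.concatenate([w.samples for w in windows])
    if bin_range is None:
        bin_range = (all_samples.min(), all_samples.max())
    if bins is None:
        bins = 100
    edges = np.linspace(bin_range[0], bin_range[1], bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    hist = np.stack([np.histogram(w.samples, bins=edges)[0]
                     for w in windows]).astype(float)
    occupancy = hist.sum(axis=0)
    used = occupancy >= occupancy_floor
    if not used.any():
        raise ValueError("no bin reaches the occupancy floor")

    # overlap check on occupied bins, windows ordered by center
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hist[a] > 0) & (hist[b] > 0)):
            raise ValueError(
                f"windows at {windows[a].center} and {windows[b].center} "
                "share no occupied bin (gap in the umbrella coverage)")

    n_i = hist[:, used].sum(axis=1)
    bias_bt = np.stack([w.bias(centers[used]) for w in windows]) / kt
    f0 = np.zeros(len(windows))
    p_used, f, n_it = _solve_wham(hist[:, used], n_i, bias_bt, f0, tol,
                                  max_iter)
    W = np.full(len(centers), np.nan)
    with np.errstate(divide="ignore"):
        w_used = -kt * np.log(p_used)
    W[used] = w_used - np.nanmin(w_used)

    uncertainty = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.full((n_bootstrap, used.sum()), np.nan)
        for r in range(n_bootstrap):
            hist_r = np.empty_like(hist[:, used])
            for wi, w in enumerate(windows):
                blocks = np.array_split(w.samples, n_blocks)
                pick = rng.integers(0, n_blocks, size=n_blocks)
                res = np.concatenate([blocks[b] for b in pick])
                hist_r[wi] = np.histogram(res, bins=edges)[0][used]
            n_r = hist_r.sum(axis=1)
            try:
                p_r, _, _ = _solve_wham(hist_r, n_r, bias_bt, f.copy(),
                                        max(tol, 1e-7), max_iter)
            except RuntimeError:
                continue
            with np.errstate(divide="ignore"):
                w_r = -kt * np.log(p_r)
            boots[r] = w_r - np.nanmin(w_r)
        unc_used = np.nanstd(boots, axis=0)
        uncertainty = np.full(len(centers), np.nan)
        uncertainty[used] = unc_used

    return PMFProfile(centers, W, temperature, uncertainty=uncertainty,
                      occupancy=occupancy, free_energies=f * kt,
                      meta={"iterations": n_it, "tol": tol,
                            "occupancy_floor": occupancy_floor,
                            "n_windows": len(windows)})


def boltzmann_inversion(samples, temperature: float = 300.0,
                        bins: int = 100) -> PMFProfile:
    """Unbiased single-window limit: W = −k_BT ln(histogram) + const."""
    w = UmbrellaWindow(center=float(np.mean(samples)), k=0.0,
                       samples=samples, temperature=temperature)
    return wham([w], bins=bins)


def read_window_tsv(path) -> UmbrellaWindow:
    """One window per file: a '# center=.. k=.. temperature=..' header line
    followed by one sample per line."""
    meta = {}
    samples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    if "=" in tok:
                        key, val = tok.split("=", 1)
                        meta[key] = float(val)
            else:
                samples.append(float(line))
    for key in ("center", "k"):
        if key not in meta:
            raise ValueError(f"{path}: header lacks {key}=")
    return UmbrellaWindow(meta["center"], meta["k"], np.array(samples),
                          meta.get("temperature", 300.0))


def write_window_tsv(path, window: UmbrellaWindow):
    with open(path, "w") as fh:
        fh.write(f"# center={window.center} k={window.k} "
                 f"temperature={window.temperature}\n")
        for s in window.samples:
            fh.write(f"{s:.8g}\n")


def decompose_pmf(pmf_t1: PMFProfile, pmf_t2: PMFProfile) -> PMFProfile:
    """Enthalpy/entropy decomposition from PMFs at two temperatures.

    ΔS(ξ) = −[W(ξ,T2) − W(ξ,T1)] / (T2 − T1) and
    ΔH(ξ) = W(ξ,T̄) + T̄·ΔS(ξ) with T̄ = (T1+T2)/2 and W(ξ,T̄) the mean of
    the two profiles, so W = ΔH + (−T̄ΔS) holds bin-wise exactly.
    """
    if pmf_t2.temperature <= pmf_t1.temperature:
        raise ValueError("need T2 > T1")
    if len(pmf_t1.bin_centers) != len(pmf_t2.bin_centers) or \
            not np.allclose(pmf_t1.bin_centers, pmf_t2.bin_centers):
        raise ValueError("bin grids differ; recompute on a common grid")
    t1, t2 = pmf_t1.temperature, pmf_t2.temperature
    t_bar = 0.5 * (t1 + t2)
    delta_s = -(pmf_t2.W - pmf_t1.W) / (t2 - t1)
    w_bar = 0.5 * (pmf_t1.W + pmf_t2.W)
    shift = np.nanmin(w_bar)
    w_bar = w_bar - shift
    delta_h = w_bar + t_bar * delta_s
    return PMFProfile(pmf_t1.bin_centers.copy(), w_bar, t_bar,
                      delta_h=delta_h, minus_t_delta_s=-t_bar * delta_s,
                      meta={"T1": t1, "T2": t2})
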