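"""Surrogate IR spectra of the carbonyl-stretch region.

Per-frame CO_D / CO_A stretch frequencies are obtained from an additive
frequency map over the local H-bond environment (water H-bond to the D-ring
carbonyl, His290 H-bond, isomerized-chromophore offset); ensemble spectra
are sums of Lorentzian lines, cluster spectra are combined by population
weights, and intermediate-minus-Pr difference spectra support the rigid
wavenumber shift used when comparing against spectra measured in D2O.

The map values are model conventions chosen for the qualitative sign
structure of the carbonyl bands (water coordination red-shifts CO_D;
isomerization red-shifts it further), not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelError


@dataclass(frozen=True)
class FrequencyMap:
    """Additive map from pocket environment to carbonyl frequencies (cm^-1)."""

    nu0_cod: float = 1720.0
    nu0_coa: float = 1745.0
    shift_isomerized_cod: float = -16.0   # Lumi-R chromophore offset
    shift_water_cod: float = -12.0        # water H-bond to CO_D
    shift_his290_cod: float = -4.0        # His290 H-bond to CO_D
    shift_isomerized_coa: float = -2.0
    linewidth: float = 6.0                # Lorentzian HWHM
    intensity_cod: float = 1.0
    intensity_coa: float = 0.6
    his290_cutoff: float = 3.5            # A, distance criterion for His290

    def __post_init__(self):
        if self.linewidth <= 0:
            raise ModelError("linewidth must be positive")
        if self.nu0_cod <= 0 or self.nu0_coa <= 0:
            raise ModelError("base frequencies must be positive")


@dataclass
class SpectrumGrid:
    """Intensity vs wavenumber on a fixed strictly increasing grid."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ModelError("wavenumber grid must be strictly increasing")
        if self.wavenumber.shape != self.intensity.shape:
            raise ModelError("grid/intensity shape mismatch")


def default_grid(lo: float = 1650.0, hi: float = 1760.0,
                 step: float = 0.5) -> np.ndarray:
    return np.arange(lo, hi + 0.5 * step, step)


def frame_frequencies(frame, fmap: FrequencyMap,
                      isomerized: bool = True) -> tuple:
    """CO_D and CO_A stretch frequencies of one frame (a table row).

    nu = nu0 + sum of the shifts whose environment feature is active.
    """
    for col in ("water_bridge_OD", "OD_His290"):
        if col not in frame:
            raise ModelError(f"frame lacks required indicator column {col!r}")
    nu_d = fmap.nu0_cod
    nu_a = fmap.nu0_coa
    if isomerized:
        nu_d += fmap.shift_isomerized_cod
        nu_a += fmap.shift_isomerized_coa
    if frame["water_bridge_OD"] > 0.5:
        nu_d += fmap.shift_water_cod
    if frame["OD_His290"] < fmap.his290_cutoff:
        nu_d += fmap.shift_his290_cod
    return float(nu_d), float(nu_a)


def _table_frequencies(frames: pd.DataFrame, fmap: FrequencyMap,
                       isomerized: bool) -> tuple:
    nu_d = np.full(len(frames), fmap.nu0_cod)
    nu_a = np.full(len(frames), fmap.nu0_coa)
    if isomerized:
        nu_d += fmap.shift_isomerized_cod
        nu_a += fmap.shift_isomerized_coa
    nu_d = nu_d + fmap.shift_water_cod * (frames["water_bridge_OD"].to_numpy() > 0.5)
    nu_d = nu_d + fmap.shift_his290_cod * (
        frames["OD_His290"].to_numpy(float) < fmap.his290_cutoff)
    return nu_d, nu_a


def ensemble_spectrum(frames: pd.DataFrame, fmap: FrequencyMap = None,
                      grid: np.ndarray = None, isomerized: bool = True,
                      normalize: bool = False) -> SpectrumGrid:
    """Sum of Lorentzian lines (one per frame per carbonyl band).

    The per-frame stick list is retained in the metadata; with ``normalize``
    the peak intensity is scaled to 1.
    """
    if len(frames) == 0:
        raise ModelError("need at least one frame")
    fmap = fmap or FrequencyMap()
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    nu_d, nu_a = _table_frequencies(frames, fmap, isomerized)
    hw2 = fmap.linewidth ** 2
    intensity = np.zeros_like(grid)
    for nus, amp in ((nu_d, fmap.intensity_cod), (nu_a, fmap.intensity_coa)):
        # Lorentzian: amp * hw^2 / ((nu - nu_i)^2 + hw^2), summed over frames
        diff = grid[:, None] - nus[None, :]
        intensity += amp * np.sum(hw2 / (diff * diff + hw2), axis=1)
    intensity /= len(frames)
    sticks = pd.DataFrame({"nu_cod": nu_d, "nu_coa": nu_a})
    meta = {"n_frames": len(frames), "sticks": sticks,
            "normalized": bool(normalize)}
    if normalize:
        peak = intensity.max()
        if peak > 0:
            intensity = intensity / peak
    return SpectrumGrid(wavenumber=grid, intensity=intensity, metadata=meta)


def weighted_average(spectra, weights) -> SpectrumGrid:
    """Pointwise convex combination of spectra on a common grid (weights are
    normalized to sum to one)."""
    spectra = list(spectra)
    w = np.asarray(weights, dtype=float)
    if len(spectra) != len(w):
        raise ModelError("one weight per spectrum required")
    if np.any(w < 0):
        raise ModelError("weights must be non-negative")
    if w.sum() <= 0:
        raise ModelError("weights sum to zero")
    w = w / w.sum()
    grid = spectra[0].wavenumber
    for s in spectra[1:]:
        if s.wavenumber.shape != grid.shape or not np.allclose(s.wavenumber, grid):
            raise ModelError("spectra are on mismatched wavenumber grids")
    intensity = np.zeros_like(grid)
    for s, wi in zip(spectra, w):
        intensity += wi * s.intensity
    return SpectrumGrid(wavenumber=grid.copy(), intensity=intensity,
                        metadata={"weights": w.tolist()})


def normalize_to(spectrum: SpectrumGrid, reference: SpectrumGrid) -> SpectrumGrid:
    """Scale ``spectrum`` by the peak height of ``reference`` (the
    normalize-to-named-spectrum convention for cluster comparisons)."""
    peak = reference.intensity.max()
    if peak <= 0:
        raise ModelError("reference spectrum has a non-positive peak")
    return SpectrumGrid(wavenumber=spectrum.wavenumber.copy(),
                        intensity=spectrum.intensity / peak,
                        metadata=dict(spectrum.metadata, normalized_to_peak=peak))


def difference_spectrum(sample: SpectrumGrid, reference: SpectrumGrid,
                        shift_cm1: float = 0.0) -> SpectrumGrid:
    """Signed (sample - reference) after rigidly shifting the sample by
    ``shift_cm1`` (interpolated back onto the common grid)."""
    grid = sample.wavenumber
    if grid.shape != reference.wavenumber.shape or \
            not np.allclose(grid, reference.wavenumber):
        raise ModelError("sample and reference grids do not match")
    shifted = np.interp(grid, grid + shift_cm1, sample.intensity,
                        left=0.0, right=0.0)
    return SpectrumGrid(wavenumber=grid.copy(),
                        intensity=shifted - reference.intensity,
                        metadata={"shift_cm1": float(shift_cm1)})
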