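"""Ocular-media and reflectance spectra, and visual-pigment templates.

Lens transmission is summarized by T50, the wavelength at which a spectrum
reaches half its maximal transmittance; eyes are UV-transmitting when
T50 < 400 nm and UV-blocking otherwise. Skin reflectance is UV-reflective
when it carries appreciable reflectance below 400 nm. Pigment absorbance
curves use the Govardovskii A1 nomogram, and co-expression of two opsins in
one cone is rendered as a renormalized weighted mixture of templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class SpectraError(ValueError):
    pass


@dataclass(frozen=True)
class Spectrum:
    """Sampled spectrum: strictly increasing wavelengths (nm) and finite values."""

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "transmission"  # transmission | reflectance | absorbance
    note: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.shape != vals.shape or wl.size == 0:
            raise SpectraError("wavelengths/values must be equal-length 1-d arrays")
        if not np.all(np.diff(wl) > 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise SpectraError("non-finite spectrum samples")
        if self.kind in ("transmission", "reflectance") and np.any(vals < 0):
            raise SpectraError(f"negative {self.kind} values")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi


@dataclass(frozen=True)
class T50Result:
    t50_nm: float
    classification: str  # "UV-transmitting" | "UV-blocking"
    note: str = ""


UV_BOUNDARY_NM = 400.0


def _classify_t50(t50: float) -> str:
    # strict inequality for transmitting: exactly 400 nm is UV-blocking
    return "UV-transmitting" if t50 < UV_BOUNDARY_NM else "UV-blocking"


def compute_t50(spectrum: Spectrum) -> T50Result:
    """Wavelength of half-maximal transmittance of a long-pass spectrum.

    The longest-wavelength upward crossing of 0.5 * max is used (ocular media
    are long-pass; noise can create spurious early crossings), with linear
    interpolation between the bracketing samples.
    """
    if not spectrum.covers(300.0, 700.0):
        raise SpectraError("transmission spectrum must cover at least 300-700 nm")
    values = spectrum.values
    vmax = values.max()
    if vmax <= 0:
        raise SpectraError("spectrum never reaches 50% of its maximum")
    threshold = 0.5 * vmax
    if np.isclose(values.max(), values.min()):
        t50 = float(spectrum.wavelengths[0])
        return T50Result(t50, _classify_t50(t50), note="degenerate: flat spectrum")
    below = values[:-1] < threshold
    above = values[1:] >= threshold
    crossings = np.nonzero(below & above)[0]
    if crossings.size == 0:
        t50 = float(spectrum.wavelengths[0])
        return T50Result(
            t50, _classify_t50(t50), note="degenerate: no upward half-maximum crossing"
        )
    i = int(crossings[-1])
    w0, w1 = spectrum.wavelengths[i], spectrum.wavelengths[i + 1]
    v0, v1 = values[i], values[i + 1]
    t50 = float(w0 + (threshold - v0) / (v1 - v0) * (w1 - w0))
    return T50Result(t50, _classify_t50(t50))


def classify_uv_reflectance(
    spectrum: Spectrum,
    band: tuple[float, float] = (300.0, UV_BOUNDARY_NM),
    criterion_fraction: float = 0.2,
) -> bool:
    """True iff peak reflectance inside the UV band is at least
    ``criterion_fraction`` of the spectrum's overall peak."""
    lo, hi = band
    if not spectrum.covers(lo, hi):
        raise SpectraError(f"reflectance spectrum does not cover the {lo}-{hi} nm band")
    in_band = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    overall_peak = spectrum.values.max()
    if overall_peak <= 0:
        return False
    return bool(spectrum.values[in_band].max() >= criterion_fraction * overall_peak)


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra.

    Mismatched grids are linearly resampled onto the first spectrum's grid
    restricted to the wavelength range shared by all replicates (noted in the
    output); no extrapolation is performed.
    """
    if not spectra:
        raise SpectraError("no spectra to average")
    first = spectra[0]
    same_grid = all(
        s.wavelengths.shape == first.wavelengths.shape
        and np.allclose(s.wavelengths, first.wavelengths)
        for s in spectra
    )
    if same_grid:
        grid = first.wavelengths
        note = ""
    else:
        lo = max(s.wavelengths[0] for s in spectra)
        hi = min(s.wavelengths[-1] for s in spectra)
        if lo >= hi:
            raise SpectraError("replicate spectra have no overlapping wavelength range")
        grid = first.wavelengths[(first.wavelengths >= lo) & (first.wavelengths <= hi)]
        note = f"resampled onto common range {lo:g}-{hi:g} nm"
    stacked = np.vstack([np.interp(grid, s.wavelengths, s.values) for s in spectra])
    return Spectrum(grid, stacked.mean(axis=0), kind=first.kind, note=note)


# Govardovskii et al. A1 visual-pigment nomogram constants (alpha band)
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


def pigment_template(lambda_max_nm: float, grid: np.ndarray | None = None) -> Spectrum:
    """Normalized A1 pigment absorbance template (alpha + beta band).

    Valid for lambda_max in [330, 600] nm; the returned curve peaks at 1
    within grid resolution.
    """
    if not 330.0 <= lambda_max_nm <= 600.0:
        raise SpectraError(f"lambda_max {lambda_max_nm} nm outside template domain [330, 600]")
    if grid is None:
        grid = np.arange(300.0, 801.0)
    grid = np.asarray(grid, dtype=float)
    if not (grid[0] <= lambda_max_nm <= grid[-1]):
        raise SpectraError("wavelength grid does not span lambda_max")
    x = lambda_max_nm / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )
    lam_beta = 189.0 + 0.315 * lambda_max_nm
    b_beta = -40.5 + 0.195 * lambda_max_nm
    beta = 0.26 * np.exp(-(((grid - lam_beta) / b_beta) ** 2))
    curve = alpha + beta
    return Spectrum(grid, curve / curve.max(), kind="absorbance")


def coexpression_mixture(curves: Sequence[Spectrum], weights: Sequence[float]) -> Spectrum:
    """Weighted mean of absorbance templates, renormalized to peak 1.

    Models two opsins co-expressed in one cone producing an intermediate
    absorbance; the mixture peak lies between the component peaks.
    """
    if not curves:
        raise SpectraError("empty mixture")
    if len(curves) != len(weights):
        raise SpectraError("need one weight per curve")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise SpectraError("weights must be non-negative with positive sum")
    grid = curves[0].wavelengths
    for c in curves[1:]:
        if c.wavelengths.shape != grid.shape or not np.allclose(c.wavelengths, grid):
            raise SpectraError("mixture components must share a wavelength grid")
    mix = np.zeros_like(grid, dtype=float)
    for curve, weight in zip(curves, w):
        mix += weight * curve.values
    mix /= w.sum()
    return Spectrum(grid, mix / mix.max(), kind="absorbance")


def read_spectrum(path: str | Path, kind: str = "transmission") -> list[Spectrum]:
    """Read two-column (wavelength, value) CSV/TSV; extra columns = replicates."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.shape[1] < 2:
        raise SpectraError(f"{path}: expected wavelength plus at least one value column")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    return [Spectrum(wl, df.iloc[:, j].to_numpy(dtype=float), kind=kind) for j in range(1, df.shape[1])]
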