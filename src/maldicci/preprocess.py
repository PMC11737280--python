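"""Spectral preprocessing: resampling, transform, smoothing, baseline, normalization.

The processing chain turns a raw trace into a normalized fingerprint on a
uniform mass grid: resample -> intensity transform -> Savitzky-Golay
smoothing -> SNIP baseline removal -> total-ion-current normalization, with
an optional dataset-level rigid alignment afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from maldicci.spectra_io import RawSpectrum

logger = logging.getLogger(__name__)

TRANSFORMS = ("sqrt", "log1p", "none")

#: tolerance on the post-normalization intensity sum
NORM_TOL = 1e-9


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum has no signal left to normalize."""


class EmptyCoverageError(ValueError):
    """Raised when a raw spectrum does not overlap the target grid."""


@dataclass(frozen=True)
class ProcessedSpectrum:
    """A spectrum resampled to a uniform mass grid, with processing provenance."""

    grid_mz: np.ndarray
    intensity: np.ndarray
    spectrum_id: str
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid_mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if grid.size != intensity.size:
            raise ValueError("grid and intensity length mismatch")
        if grid.size < 2:
            raise ValueError("grid needs at least two points")
        steps = np.diff(grid)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("grid must be uniform")
        if np.any(intensity < 0) or not np.all(np.isfinite(intensity)):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "grid_mz", grid)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def grid_step(self) -> float:
        return float(self.grid_mz[1] - self.grid_mz[0])

    def with_intensity(self, intensity: np.ndarray, step: str) -> "ProcessedSpectrum":
        return ProcessedSpectrum(
            grid_mz=self.grid_mz,
            intensity=intensity,
            spectrum_id=self.spectrum_id,
            provenance=self.provenance + (step,),
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Defaults follow common MALDI preprocessing practice (sqrt transform,
    order-3 Savitzky-Golay with half-window 10, SNIP with 100 iterations,
    TIC normalization) on a 1 Da grid over the acquisition range.
    """

    transform: str = "sqrt"
    smooth_half_window: int = 10
    baseline_method: str = "SNIP"
    baseline_iterations: int = 100
    grid_step: float = 1.0
    grid_min: float = 2000.0
    grid_max: float = 20000.0
    align: bool = True
    align_tolerance: float = 10.0

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")
        if self.smooth_half_window < 1:
            raise ValueError("smooth_half_window must be >= 1")
        if self.baseline_method != "SNIP":
            raise ValueError("only the SNIP baseline method is supported")
        if self.baseline_iterations < 1:
            raise ValueError("baseline_iterations must be >= 1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not self.grid_min < self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if self.align_tolerance < 0:
            raise ValueError("align_tolerance must be >= 0")


def make_grid(grid_step: float, grid_min: float, grid_max: float) -> np.ndarray:
    n = int(round((grid_max - grid_min) / grid_step)) + 1
    return grid_min + grid_step * np.arange(n)


def resample_uniform(
    raw: RawSpectrum, grid_step: float, grid_min: float, grid_max: float
) -> ProcessedSpectrum:
    """Linearly interpolate a raw spectrum onto a uniform mass grid.

    Grid points outside the raw spectrum's coverage are set to zero.
    """
    if raw.mz[-1] < grid_min or raw.mz[0] > grid_max:
        raise EmptyCoverageError(
            f"{raw.spectrum_id}: raw range [{raw.mz[0]}, {raw.mz[-1]}] does not "
            f"overlap grid [{grid_min}, {grid_max}]"
        )
    grid = make_grid(grid_step, grid_min, grid_max)
    intensity = np.interp(grid, raw.mz, raw.intensity, left=0.0, right=0.0)
    return ProcessedSpectrum(
        grid_mz=grid,
        intensity=intensity,
        spectrum_id=raw.spectrum_id,
        provenance=(f"resample(step={grid_step},min={grid_min},max={grid_max})",),
    )


def transform_intensity(spectrum: ProcessedSpectrum, method: str = "sqrt") -> ProcessedSpectrum:
    """Apply a variance-stabilizing intensity transform (sqrt, log1p or none)."""
    if method not in TRANSFORMS:
        raise ValueError(f"unknown transform {method!r}")
    if np.any(spectrum.intensity < 0):
        raise ValueError("negative intensities cannot be transformed")
    if method == "sqrt":
        out = np.sqrt(spectrum.intensity)
    elif method == "log1p":
        out = np.log1p(spectrum.intensity)
    else:
        out = spectrum.intensity.copy()
    return spectrum.with_intensity(out, f"transform({method})")


def smooth(spectrum: ProcessedSpectrum, half_window: int) -> ProcessedSpectrum:
    """Savitzky-Golay smoothing (order 3) with window 2*half_window+1, clipped at 0."""
    window = 2 * int(half_window) + 1
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if window > spectrum.intensity.size:
        raise ValueError(
            f"smoothing window {window} exceeds spectrum length {spectrum.intensity.size}"
        )
    # order-3 filter; degrades gracefully for windows too small to fit a cubic
    polyorder = min(3, window - 1)
    out = savgol_filter(spectrum.intensity, window_length=window, polyorder=polyorder)
    np.clip(out, 0.0, None, out=out)
    return spectrum.with_intensity(out, f"smooth(half_window={half_window})")


def snip_baseline(intensity: np.ndarray, iterations: int) -> np.ndarray:
    """Estimate a baseline with the SNIP clipping algorithm.

    At iteration k each point is replaced by the minimum of itself and the
    mean of its neighbours k points away; the window grows with k.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    baseline = intensity.astype(float, copy=True)
    n = baseline.size
    for k in range(1, min(iterations, (n - 1) // 2) + 1):
        mean = 0.5 * (baseline[: n - 2 * k] + baseline[2 * k :])
        np.minimum(baseline[k : n - k], mean, out=baseline[k : n - k])
    return baseline


def remove_baseline(spectrum: ProcessedSpectrum, iterations: int) -> ProcessedSpectrum:
    """Subtract a SNIP-estimated baseline; the result is clipped at 0."""
    baseline = snip_baseline(spectrum.intensity, iterations)
    out = spectrum.intensity - baseline
    np.clip(out, 0.0, None, out=out)
    return spectrum.with_intensity(out, f"baseline(SNIP,iterations={iterations})")


def normalize_tic(spectrum: ProcessedSpectrum) -> ProcessedSpectrum:
    """Scale intensities to unit sum (total-ion-current normalization)."""
    total = float(spectrum.intensity.sum())
    if total <= 0:
        raise DegenerateSpectrumError(
            f"{spectrum.spectrum_id}: no positive intensity left to normalize"
        )
    return spectrum.with_intensity(spectrum.intensity / total, "normalize(tic)")


def _shift_intensity(intensity: np.ndarray, shift: int) -> np.ndarray:
    """Shift a trace by `shift` grid points, filling exposed edges with 0."""
    out = np.zeros_like(intensity)
    if shift == 0:
        out[:] = intensity
    elif shift > 0:
        out[shift:] = intensity[:-shift]
    else:
        out[:shift] = intensity[-shift:]
    return out


def align_spectra(
    spectra: Sequence[ProcessedSpectrum], tolerance: float
) -> list[ProcessedSpectrum]:
    """Rigidly align spectra to their intensity-mean reference spectrum.

    For each spectrum the integer grid shift (bounded by
    tolerance/grid_step) maximizing the normalized cross-correlation with
    the mean spectrum is applied.  Shifted spectra are re-normalized so the
    unit-sum invariant survives edge truncation.
    """
    if len(spectra) < 2:
        return list(spectra)
    step = spectra[0].grid_step
    for s in spectra[1:]:
        if s.grid_mz.size != spectra[0].grid_mz.size or not np.allclose(
            s.grid_mz, spectra[0].grid_mz
        ):
            raise ValueError("all spectra must share one grid for alignment")
    max_shift = int(tolerance / step)
    if max_shift < 1:
        return list(spectra)
    reference = np.mean([s.intensity for s in spectra], axis=0)
    ref_norm = float(np.sqrt(np.dot(reference, reference)))
    aligned = []
    for s in spectra:
        x = s.intensity
        x_norm = float(np.sqrt(np.dot(x, x)))
        if ref_norm == 0.0 or x_norm == 0.0:
            aligned.append(s.with_intensity(x.copy(), "align(shift=0)"))
            continue
        best_shift, best_corr = 0, -np.inf
        for shift in range(-max_shift, max_shift + 1):
            corr = float(np.dot(_shift_intensity(x, shift), reference)) / (x_norm * ref_norm)
            if corr > best_corr:
                best_corr, best_shift = corr, shift
        shifted = _shift_intensity(x, best_shift)
        total = shifted.sum()
        if total > 0:
            shifted = shifted / total
        aligned.append(s.with_intensity(shifted, f"align(shift={best_shift})"))
    return aligned


def preprocess_pipeline(raw: RawSpectrum, config: PreprocessConfig) -> ProcessedSpectrum:
    """Run resample -> transform -> smooth -> baseline -> normalize on one spectrum.

    Dataset-level alignment (config.align) is applied separately via
    :func:`preprocess_dataset`.
    """
    spectrum = resample_uniform(raw, config.grid_step, config.grid_min, config.grid_max)
    spectrum = transform_intensity(spectrum, config.transform)
    spectrum = smooth(spectrum, config.smooth_half_window)
    spectrum = remove_baseline(spectrum, config.baseline_iterations)
    spectrum = normalize_tic(spectrum)
    return spectrum


def preprocess_dataset(
    raws: Sequence[RawSpectrum], config: PreprocessConfig
) -> list[ProcessedSpectrum]:
    """Preprocess a batch of spectra, dropping degenerate ones with a logged reason."""
    processed: list[ProcessedSpectrum] = []
    for raw in raws:
        try:
            processed.append(preprocess_pipeline(raw, config))
        except DegenerateSpectrumError as exc:
            logger.warning("excluded spectrum: %s", exc)
    if config.align and len(processed) >= 2:
        processed = align_spectra(processed, config.align_tolerance)
    return processed


__all__ = [
    "ProcessedSpectrum",
    "PreprocessConfig",
    "DegenerateSpectrumError",
    "EmptyCoverageError",
    "make_grid",
    "resample_uniform",
    "transform_intensity",
    "smooth",
    "snip_baseline",
    "remove_baseline",
    "normalize_tic",
    "align_spectra",
    "preprocess_pipeline",
    "preprocess_dataset",
]
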