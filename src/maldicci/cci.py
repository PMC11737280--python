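"""Cross-correlation index (CCI) between processed mass spectra.

The similarity of two spectra is scored per fixed mass interval by the
local maximum of their normalized cross-correlation function over a
symmetric lag window; the CCI is the product of the per-interval local
maxima (0 if any interval lacks a local maximum), reported on the log10
scale in [-inf, 0].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from maldicci.preprocess import ProcessedSpectrum


class GridMismatchError(ValueError):
    """Raised when two spectra are not on the same uniform grid."""


@dataclass(frozen=True)
class IntervalGrid:
    """An exact tiling of [mass_min, mass_max) by half-open windows of equal width."""

    mass_min: float
    mass_max: float
    width: float
    intervals: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class CCIConfig:
    """CCI parameters: interval tiling and the symmetric lag-search window."""

    mass_min: float = 3000.0
    mass_max: float = 12000.0
    width: float = 500.0
    max_lag: int = 20

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        make_interval_grid(self.mass_min, self.mass_max, self.width)  # validates


@dataclass(frozen=True)
class CCIResult:
    """Per-interval local cross-correlation maxima and their product."""

    id_a: str
    id_b: str
    per_interval_max: tuple[Optional[float], ...]
    cci: float
    log10cci: float


def make_interval_grid(mass_min: float, mass_max: float, width: float) -> IntervalGrid:
    """Tile [mass_min, mass_max) with half-open intervals of the given width."""
    if width <= 0:
        raise ValueError("width must be positive")
    if mass_max <= mass_min:
        raise ValueError("mass_max must exceed mass_min")
    count = (mass_max - mass_min) / width
    n = int(round(count))
    if abs(count - n) > 1e-9 or n < 1:
        raise ValueError(
            f"interval width {width} does not divide the range [{mass_min}, {mass_max})"
        )
    edges = mass_min + width * np.arange(n + 1)
    intervals = tuple((float(edges[i]), float(edges[i + 1])) for i in range(n))
    return IntervalGrid(mass_min=mass_min, mass_max=mass_max, width=width, intervals=intervals)


def normalized_xcorr(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized cross-correlation of two segments over lags -max_lag..+max_lag.

    C(tau) = sum_i x[i] * y[i+tau] over the overlapping index range, divided
    by sqrt(sum x^2 * sum y^2) of the full segments (no mean-centering), so
    values are in [0, 1] for non-negative inputs and identical segments give
    C(0) = 1.  If either segment is all-zero the correlation is zero at
    every lag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("segments must be one-dimensional and of equal length")
    n = x.size
    if n < max_lag + 2:
        raise ValueError(f"segment length {n} too short for max_lag {max_lag}")
    denom = float(np.sqrt(np.dot(x, x) * np.dot(y, y)))
    corr = np.zeros(2 * max_lag + 1)
    if denom == 0.0:
        return corr
    for tau in range(0, max_lag + 1):
        corr[max_lag + tau] = np.dot(x[: n - tau], y[tau:])
    for tau in range(1, max_lag + 1):
        corr[max_lag - tau] = np.dot(x[tau:], y[: n - tau])
    corr /= denom
    np.minimum(corr, 1.0, out=corr)  # guard against fp overshoot
    return corr


def local_max(corr: Sequence[float]) -> Optional[float]:
    """Largest interior point strictly greater than both neighbours, or None.

    Monotone or flat sequences have no interior strict peak and yield None.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.size < 3:
        raise ValueError("correlation sequence needs at least 3 lags")
    interior = corr[1:-1]
    is_peak = (interior > corr[:-2]) & (interior > corr[2:])
    if not np.any(is_peak):
        return None
    return float(interior[is_peak].max())


def log10_cci(cci_value: float) -> float:
    """log10 of a CCI value in [0, 1]; 0 maps to -inf, 1 maps to 0."""
    if not 0.0 <= cci_value <= 1.0:
        raise ValueError(f"CCI value {cci_value} outside [0, 1]")
    if cci_value == 0.0:
        return -np.inf
    return float(np.log10(cci_value))


def _segment_slices(grid_mz: np.ndarray, grid: IntervalGrid) -> list[slice]:
    """Index slices of the half-open mass intervals on a uniform grid."""
    slices = []
    for lo, hi in grid.intervals:
        start = int(np.searchsorted(grid_mz, lo - 1e-9, side="left"))
        stop = int(np.searchsorted(grid_mz, hi - 1e-9, side="left"))
        slices.append(slice(start, stop))
    return slices


def _check_same_grid(a: ProcessedSpectrum, b: ProcessedSpectrum) -> None:
    if a.grid_mz.size != b.grid_mz.size or not np.allclose(
        a.grid_mz, b.grid_mz, rtol=0, atol=1e-9
    ):
        raise GridMismatchError(f"{a.spectrum_id} and {b.spectrum_id} are on different grids")


def _check_coverage(spectrum: ProcessedSpectrum, config: CCIConfig) -> None:
    if spectrum.grid_mz[0] > config.mass_min or spectrum.grid_mz[-1] < config.mass_max - spectrum.grid_step:
        raise GridMismatchError(
            f"{spectrum.spectrum_id}: grid does not cover [{config.mass_min}, {config.mass_max})"
        )


def cci(a: ProcessedSpectrum, b: ProcessedSpectrum, config: CCIConfig | None = None) -> CCIResult:
    """Cross-correlation index between two spectra on a shared grid.

    Per interval: normalized cross-correlation then strict local maximum.
    The CCI is the product of per-interval maxima, 0 if any interval has no
    local maximum; the product is accumulated in log space.
    """
    config = config or CCIConfig()
    _check_same_grid(a, b)
    _check_coverage(a, config)
    grid = make_interval_grid(config.mass_min, config.mass_max, config.width)
    slices = _segment_slices(a.grid_mz, grid)

    maxima: list[Optional[float]] = []
    log_sum = 0.0
    for seg in slices:
        x = a.intensity[seg]
        y = b.intensity[seg]
        if x.size < config.max_lag + 2:
            maxima.append(None)
            log_sum = -np.inf
            continue
        peak = local_max(normalized_xcorr(x, y, config.max_lag))
        maxima.append(peak)
        if peak is None or peak <= 0.0:
            log_sum = -np.inf
        else:
            log_sum += np.log10(peak)

    cci_value = 0.0 if log_sum == -np.inf else float(10.0 ** log_sum)
    return CCIResult(
        id_a=a.spectrum_id,
        id_b=b.spectrum_id,
        per_interval_max=tuple(maxima),
        cci=cci_value,
        log10cci=float(log_sum),
    )


def cci_matrix(
    queries: Sequence[ProcessedSpectrum],
    refs: Sequence[ProcessedSpectrum],
    config: CCIConfig | None = None,
) -> np.ndarray:
    """log10(CCI) for every query x reference pair, as an (nq, nr) matrix.

    Block implementation of the same per-interval definition as :func:`cci`
    (per-lag segment dot products via matrix multiplication); results agree
    with the pairwise path to floating-point accuracy.
    """
    config = config or CCIConfig()
    if not queries or not refs:
        return np.zeros((len(queries), len(refs)))
    for s in list(queries) + list(refs):
        _check_same_grid(queries[0], s)
    _check_coverage(queries[0], config)
    grid = make_interval_grid(config.mass_min, config.mass_max, config.width)
    slices = _segment_slices(queries[0].grid_mz, grid)
    max_lag = config.max_lag

    Q = np.stack([s.intensity for s in queries])
    R = np.stack([s.intensity for s in refs])
    nq, nr = Q.shape[0], R.shape[0]
    log_sum = np.zeros((nq, nr))

    for seg in slices:
        x = Q[:, seg]
        y = R[:, seg]
        m = x.shape[1]
        if m < max_lag + 2:
            log_sum[:] = -np.inf
            continue
        sq = np.einsum("ij,ij->i", x, x)
        sr = np.einsum("ij,ij->i", y, y)
        denom = np.sqrt(np.outer(sq, sr))
        corr = np.empty((2 * max_lag + 1, nq, nr))
        for tau in range(0, max_lag + 1):
            corr[max_lag + tau] = x[:, : m - tau] @ y[:, tau:].T
        for tau in range(1, max_lag + 1):
            corr[max_lag - tau] = x[:, tau:] @ y[:, : m - tau].T
        zero = denom == 0.0
        denom[zero] = 1.0
        corr /= denom
        corr[:, zero] = 0.0
        np.minimum(corr, 1.0, out=corr)

        interior = corr[1:-1]
        is_peak = (interior > corr[:-2]) & (interior > corr[2:])
        peaks = np.where(is_peak, interior, -np.inf)
        best = peaks.max(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(best > 0.0, np.log10(np.maximum(best, 1e-300)), -np.inf)
        log_sum += contrib

    return log_sum


__all__ = [
    "IntervalGrid",
    "CCIConfig",
    "CCIResult",
    "GridMismatchError",
    "make_interval_grid",
    "normalized_xcorr",
    "local_max",
    "log10_cci",
    "cci",
    "cci_matrix",
]
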