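"""Spectral pre-processing: anchored global baseline, resampling, replicate averaging.

The instrument workflow re-zeroes every spectrum against the experimental
blank using two signal-free anchor windows (1865-2031 and 3799-3971 cm^-1,
between the fingerprint/carbonyl complex and the CH/OH stretching complex).
We model that step as subtracting the straight line through the per-window
centroids (mean wavenumber, mean absorbance): with the standard two windows
this interpolates both centroids exactly, so the corrected spectrum has zero
mean absorbance in each anchor window, which is the defining property of an
anchored baseline. No normalization is ever applied — the analysis is
quantitative and absorbance is linear in analyte amount.

All downstream analyses (AUC, peak heights, scores) expect baseline-corrected
spectra; averaging of technical replicates is done after correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    GridMismatchError,
    InsufficientAnchorError,
    InsufficientDataError,
    SpectralRangeError,
)
from .spectra_io import Spectrum

__all__ = [
    "AnchorRegions",
    "DEFAULT_ANCHORS",
    "global_baseline_correct",
    "resample_to_grid",
    "average_replicates",
    "replicate_cv",
]


@dataclass(frozen=True)
class AnchorRegions:
    """Signal-free wavenumber windows used to anchor the global baseline."""

    regions: tuple[tuple[float, float], ...] = ((1865.0, 2031.0), (3799.0, 3971.0))

    def __post_init__(self):
        if len(self.regions) < 1:
            raise ConfigurationError("at least one anchor region is required")
        regs = tuple(
            (float(lo), float(hi)) for lo, hi in self.regions
        )
        for lo, hi in regs:
            if not lo < hi:
                raise ConfigurationError(f"anchor region ({lo}, {hi}) has low >= high")
        for (lo1, hi1), (lo2, hi2) in zip(sorted(regs), sorted(regs)[1:]):
            if lo2 < hi1:
                raise ConfigurationError("anchor regions must not overlap")
        object.__setattr__(self, "regions", regs)


DEFAULT_ANCHORS = AnchorRegions()


def _anchor_masks(spectrum: Spectrum, anchors: AnchorRegions) -> list[np.ndarray]:
    w = spectrum.wavenumbers
    masks = []
    for lo, hi in anchors.regions:
        if hi < w[0] or lo > w[-1]:
            raise ConfigurationError(
                f"anchor region ({lo:g}, {hi:g}) lies outside the grid span "
                f"({w[0]:g}, {w[-1]:g})"
            )
        mask = (w >= lo) & (w <= hi)
        if mask.sum() < 2:
            raise InsufficientAnchorError(
                f"anchor region ({lo:g}, {hi:g}) contains {int(mask.sum())} grid "
                "points; need at least 2"
            )
        masks.append(mask)
    return masks


def global_baseline_correct(
    spectrum: Spectrum, anchors: AnchorRegions = DEFAULT_ANCHORS
) -> Spectrum:
    """Subtract the straight baseline anchored in the given windows.

    The line is fitted through the (mean wavenumber, mean absorbance) centroid
    of each anchor window — least squares over centroids when more than two
    windows are configured, ordinary least squares over the window's own
    points when only one window is given. The corrected spectrum is flagged
    ``baseline_corrected``; correcting an already-corrected spectrum warns and
    is a no-op up to floating point (the anchor means are already zero).
    """
    if spectrum.baseline_corrected:
        warnings.warn(
            f"spectrum {spectrum.sample_id!r} is already baseline corrected; "
            "re-correcting is idempotent",
            stacklevel=2,
        )
    masks = _anchor_masks(spectrum, anchors)
    w, a = spectrum.wavenumbers, spectrum.absorbance
    if len(masks) == 1:
        m = masks[0]
        slope, intercept = np.polyfit(w[m], a[m], 1)
    else:
        cw = np.array([w[m].mean() for m in masks])
        ca = np.array([a[m].mean() for m in masks])
        slope, intercept = np.polyfit(cw, ca, 1)
    corrected = a - (intercept + slope * w)
    return spectrum.with_absorbance(corrected, baseline_corrected=True)


def resample_to_grid(spectrum: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate the spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.span
    if grid.min() < lo or grid.max() > hi:
        raise SpectralRangeError(
            f"target grid ({grid.min():g}, {grid.max():g}) exceeds the spectrum "
            f"span ({lo:g}, {hi:g}); refusing to extrapolate"
        )
    values = np.interp(grid, spectrum.wavenumbers, spectrum.absorbance)
    return Spectrum(
        grid, values,
        sample_id=spectrum.sample_id,
        replicate_id=spectrum.replicate_id,
        baseline_corrected=spectrum.baseline_corrected,
    )


def _common_grid(group: Sequence[Spectrum]) -> np.ndarray:
    grid = group[0].wavenumbers
    for s in group[1:]:
        if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
            raise GridMismatchError(
                "replicates are on different wavenumber grids; resample first"
            )
    return grid


def average_replicates(
    group: Sequence[Spectrum],
) -> tuple[Spectrum, np.ndarray]:
    """Pointwise mean spectrum and pointwise SD across technical replicates.

    All replicates must share an identical grid (use :func:`resample_to_grid`
    first). SD uses ddof=1 and is zero for a single replicate.
    """
    group = list(group)
    if not group:
        raise InsufficientDataError("cannot average an empty replicate group")
    grid = _common_grid(group)
    stack = np.vstack([s.absorbance for s in group])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(group) > 1 else np.zeros_like(mean)
    averaged = Spectrum(
        grid, mean,
        sample_id=group[0].sample_id,
        replicate_id="",
        baseline_corrected=all(s.baseline_corrected for s in group),
    )
    return averaged, sd


def replicate_cv(
    group: Sequence[Spectrum], metric: Callable[[Spectrum], float]
) -> float:
    """Coefficient of variation of a derived scalar across unaveraged replicates.

    ``metric`` maps a spectrum to a scalar (an AUC, a LiQ score, ...); the CV
    is SD(ddof=1)/mean of its values over the group. Zero for n=1.
    """
    values = np.array([float(metric(s)) for s in group], dtype=float)
    if values.size < 2:
        return 0.0
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(values.std(ddof=1) / mean)
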