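"""Spectral preprocessing chain for leaf FT-NIR absorbance spectra.

Order of operations: crop to the informative NIR window, Savitzky-Golay
smooth, baseline-correct (rubberband by default), area-normalize each
spectrum to unit trapezoidal integral, then mean-center against a training
mean.  Every step appends a descriptor to the set's processing log.

Centering is fit once on a designated set and captured in a
:class:`CenteringModel` so held-out spectra are centered with the same mean
(queries are never re-centered on their own means).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet

__all__ = [
    "PreprocessConfig",
    "CenteringModel",
    "crop",
    "smooth",
    "baseline_correct",
    "area_normalize",
    "mean_center",
    "apply_centering",
    "preprocess_pipeline",
]

BASELINE_METHODS = ("rubberband", "linear")


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    crop window in cm^-1; smoothing window in points (odd) with its
    polynomial order; baseline method "rubberband" or "linear".
    """

    crop_lo: float = 3800.0
    crop_hi: float = 9000.0
    smooth_window: int = 25
    smooth_polyorder: int = 2
    baseline_method: str = "rubberband"

    def __post_init__(self) -> None:
        if not self.crop_lo < self.crop_hi:
            raise ValueError("crop_lo must be < crop_hi")
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 3")
        if self.smooth_polyorder >= self.smooth_window:
            raise ValueError("smooth_polyorder must be < smooth_window")
        if self.baseline_method not in BASELINE_METHODS:
            raise ValueError(
                f"unknown baseline method {self.baseline_method!r}; "
                f"expected one of {BASELINE_METHODS}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CenteringModel:
    """Mean spectrum of a training set, reapplied to held-out spectra."""

    mean_spectrum: np.ndarray

    def __post_init__(self) -> None:
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float).ravel()


def crop(sset: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep exactly the channels with lo <= wavenumber <= hi (closed interval)."""
    mask = (sset.grid >= lo) & (sset.grid <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"crop [{lo}, {hi}] leaves {int(mask.sum())} channels; at least 3 required"
        )
    return sset.evolve(
        grid=sset.grid[mask],
        absorbance=sset.absorbance[:, mask],
        log_entry={"step": "crop", "lo": float(lo), "hi": float(hi)},
    )


def smooth(sset: SpectraSet, window: int = 25, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay smoothing of each row.

    Edge channels use a polynomial fit over the truncated window
    (scipy's "interp" boundary mode).
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window > sset.n_channels:
        raise ValueError(
            f"smoothing window {window} exceeds channel count {sset.n_channels}"
        )
    smoothed = savgol_filter(sset.absorbance, window, polyorder, axis=1, mode="interp")
    return sset.evolve(
        absorbance=smoothed,
        log_entry={"step": "smooth", "window": int(window), "polyorder": int(polyorder)},
    )


def _lower_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of (x, y), x strictly increasing."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # pop i2 if it lies on or above the chord i1 -> i
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def _rubberband_row(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    idx = _lower_hull(x, y)
    return np.interp(x, x[idx], y[idx])


def baseline_correct(sset: SpectraSet, method: str = "rubberband") -> SpectraSet:
    """Subtract a per-row baseline estimate.

    rubberband: the lower convex hull of the (wavenumber, absorbance)
    points, linearly interpolated between hull vertices — the corrected
    row is >= 0 everywhere and touches 0 at the hull vertices.
    linear: the straight line through the first and last channel.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(
            f"unknown baseline method {method!r}; expected one of {BASELINE_METHODS}"
        )
    x = sset.grid
    out = np.empty_like(sset.absorbance)
    for i, row in enumerate(sset.absorbance):
        if method == "rubberband":
            base = _rubberband_row(x, row)
        else:
            slope = (row[-1] - row[0]) / (x[-1] - x[0])
            base = row[0] + slope * (x - x[0])
        out[i] = row - base
    if method == "rubberband":
        np.maximum(out, 0.0, out=out)  # clamp -0.0 / fp dust at hull vertices
    return sset.evolve(absorbance=out, log_entry={"step": "baseline", "method": method})


def area_normalize(sset: SpectraSet) -> SpectraSet:
    """Divide each row by its trapezoidal integral over the grid."""
    areas = np.trapezoid(sset.absorbance, sset.grid, axis=1)
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        names = [sset.sample_ids[i] for i in bad]
        raise ValueError(f"non-positive spectral area for samples {names}")
    return sset.evolve(
        absorbance=sset.absorbance / areas[:, None],
        log_entry={"step": "area_normalize"},
    )


def mean_center(sset: SpectraSet) -> tuple[SpectraSet, CenteringModel]:
    """Subtract the per-channel mean over rows; return the mean for reuse."""
    if sset.n_samples < 2:
        raise ValueError("mean centering requires at least 2 samples")
    mean = sset.absorbance.mean(axis=0)
    centered = sset.evolve(
        absorbance=sset.absorbance - mean,
        log_entry={"step": "mean_center", "fit": "self"},
    )
    return centered, CenteringModel(mean_spectrum=mean)


def apply_centering(sset: SpectraSet, model: CenteringModel) -> SpectraSet:
    """Center spectra with a previously fitted mean (no refitting)."""
    if model.mean_spectrum.size != sset.n_channels:
        raise ValueError(
            f"centering model has {model.mean_spectrum.size} channels, "
            f"set has {sset.n_channels}"
        )
    return sset.evolve(
        absorbance=sset.absorbance - model.mean_spectrum,
        log_entry={"step": "mean_center", "fit": "model"},
    )


def preprocess_pipeline(
    sset: SpectraSet, cfg: PreprocessConfig | None = None
) -> tuple[SpectraSet, CenteringModel]:
    """crop -> smooth -> baseline -> area-normalize -> mean-center."""
    cfg = cfg or PreprocessConfig()
    out = crop(sset, cfg.crop_lo, cfg.crop_hi)
    out = smooth(out, cfg.smooth_window, cfg.smooth_polyorder)
    out = baseline_correct(out, cfg.baseline_method)
    out = area_normalize(out)
    return mean_center(out)
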