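"""Voxel cleaning for flattened specimen images.

Implements the processing chain applied to each specimen volume before
grid aggregation:

1. low-signal thresholding on the 3D intensity histogram (kernel density
   minimum between the background and tissue modes);
2. flattening to 2D by averaging valid voxels across slices;
3. unconditional removal of a 2-voxel-dilated specimen perimeter;
4. conditional removal, in a 5-voxel band beyond that border, of voxels
   with CNR above 40 % (sparing grid sections that contain substantia
   nigra);
5. per-section outlier rejection by Cook's distance (> 4/n) under an
   intercept-only regression;
6. CNR normalization against the mode of the reference-region (crus
   cerebri) intensities.

CNR is expressed in percent: ``cnr = 100 * (I - mode(I_RR)) / mode(I_RR)``.

Border geometry uses 4-connectivity and city-block (diamond) dilation,
realized as a taxicab distance transform to the low-signal set: the
perimeter is at distance 1, the unconditionally removed border covers
distances 1..3, and the conditional band distances 4..8.  Keying both
border steps on distance to the *low-signal* set (rather than to whatever
was removed before) makes the geometric stages idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.stats import gaussian_kde

from .config import CleaningParams

__all__ = [
    "UnimodalHistogramError",
    "CleanFlatImage",
    "REASON_CODES",
    "mode_of",
    "low_signal_threshold",
    "flatten",
    "classify_low_signal",
    "compute_cnr",
    "remove_edge_artifacts",
    "cooks_distance_constant",
    "cooks_outlier_filter",
]

#: Per-pixel removal reason codes (mutually exclusive; 0 = valid).
REASON_CODES = {
    "valid": 0,
    "outside": 1,        # low-signal, connected to the image border
    "dropout": 2,        # low-signal, inside the specimen
    "border2": 3,        # unconditional 2-voxel-dilated perimeter
    "border5_cnr": 4,    # band voxel with CNR above the edge cutoff
    "cooks_outlier": 5,  # per-section Cook's distance outlier
}
REASON_NAMES = {v: k for k, v in REASON_CODES.items()}


class UnimodalHistogramError(ValueError):
    """The intensity histogram does not show two modes."""


@dataclass
class CleanFlatImage:
    """Flattened 2D image with validity mask and CNR values.

    ``cnr`` (percent) is defined only where ``reasons == 0``;
    ``reference_mode`` is the kernel-density mode of the surviving
    reference-region intensities.
    """

    intensity: np.ndarray
    reasons: np.ndarray
    cnr: np.ndarray | None = None
    reference_mode: float | None = None
    low_signal_threshold: float | None = None

    @property
    def valid(self) -> np.ndarray:
        return self.reasons == REASON_CODES["valid"]

    def removal_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.reasons == code))
                for name, code in REASON_CODES.items()}


# ----------------------------------------------------------------------
# kernel density utilities
# ----------------------------------------------------------------------

def _kde(samples: np.ndarray, bandwidth) -> gaussian_kde:
    try:
        return gaussian_kde(samples, bw_method=bandwidth)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise UnimodalHistogramError(
            f"kernel density estimate failed (degenerate sample): {exc}"
        ) from exc


def _refine_peak(kde: gaussian_kde, grid: np.ndarray, idx: int,
                 sign: float) -> float:
    """Polish a grid extremum of the density by bounded 1D optimization."""
    lo = grid[max(idx - 1, 0)]
    hi = grid[min(idx + 1, len(grid) - 1)]
    if hi <= lo:
        return float(grid[idx])
    res = optimize.minimize_scalar(
        lambda x: sign * kde(np.atleast_1d(x))[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 * max(1.0, abs(hi))},
    )
    return float(res.x)


def mode_of(samples: np.ndarray, bandwidth="silverman",
            grid_points: int = 512) -> float:
    """Mode of a continuous sample: argmax of its Gaussian KDE.

    The density is scanned on a regular grid over the sample range and
    the winning grid point is polished by bounded optimization, so the
    result is accurate well beyond the grid resolution.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("cannot take the mode of an empty sample")
    if np.ptp(samples) == 0:
        return float(samples[0])
    kde = _kde(samples, bandwidth)
    grid = np.linspace(samples.min(), samples.max(), grid_points)
    dens = kde(grid)
    return _refine_peak(kde, grid, int(np.argmax(dens)), sign=-1.0)


def low_signal_threshold(volume: np.ndarray, params: CleaningParams
                         = CleaningParams()) -> float:
    """Intensity threshold separating background from tissue.

    Fits a Gaussian KDE to all voxel intensities and returns the density
    minimum strictly between the two highest modes (ties broken toward
    the lower intensity).  Raises :class:`UnimodalHistogramError` when
    fewer than two modes are found, rather than silently returning an
    extremum.
    """
    x = np.asarray(volume, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty volume")
    if np.ptp(x) == 0:
        raise UnimodalHistogramError("unimodal histogram: constant image")
    kde = _kde(x, params.kde_bandwidth)
    grid = np.linspace(x.min(), x.max(), params.kde_grid_points)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(interior)[0] + 1
    # boundary modes count too (e.g. a background spike at the minimum)
    if dens[0] > dens[1]:
        peaks = np.concatenate(([0], peaks))
    if dens[-1] > dens[-2]:
        peaks = np.concatenate((peaks, [len(dens) - 1]))
    # collapse plateaus: keep the first index of each run
    if peaks.size:
        peaks = peaks[np.concatenate(([True], np.diff(peaks) > 1))]
    if peaks.size < 2:
        raise UnimodalHistogramError(
            f"unimodal histogram: found {peaks.size} mode(s)"
        )
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo_idx, hi_idx = int(top2.min()), int(top2.max())
    if hi_idx - lo_idx < 2:
        raise UnimodalHistogramError("modes not separated by a minimum")
    between = slice(lo_idx + 1, hi_idx)
    min_idx = lo_idx + 1 + int(np.argmin(dens[between]))
    return _refine_peak(kde, grid, min_idx, sign=+1.0)


# ----------------------------------------------------------------------
# flattening and CNR
# ----------------------------------------------------------------------

def flatten(volume: np.ndarray, valid3d: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Average valid voxels across the slice (first) dimension.

    Returns the 2D mean-intensity image (NaN where a pixel column has no
    valid voxel) and the per-pixel count of contributing slices.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.size == 0:
        raise ValueError("empty volume")
    valid3d = np.asarray(valid3d, dtype=bool)
    counts = valid3d.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(valid3d, volume, 0.0).sum(axis=0) / counts
    mean[counts == 0] = np.nan
    return mean, counts


def classify_low_signal(low2d: np.ndarray) -> np.ndarray:
    """Split the low-signal set into 'outside' vs in-specimen 'dropout'.

    Connected components (4-connectivity) of the low-signal mask that
    touch the image border are background; enclosed components are signal
    dropout.
    """
    labels, n = ndimage.label(low2d, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    reasons = np.zeros(low2d.shape, dtype=int)
    if n == 0:
        return reasons
    border_labels = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    border_labels = border_labels[border_labels > 0]
    outside = np.isin(labels, border_labels)
    reasons[low2d & outside] = REASON_CODES["outside"]
    reasons[low2d & ~outside] = REASON_CODES["dropout"]
    return reasons


def compute_cnr(intensity: np.ndarray, valid: np.ndarray,
                reference_mask: np.ndarray,
                params: CleaningParams = CleaningParams()
                ) -> tuple[np.ndarray, float]:
    """CNR (percent) of every valid pixel against the reference mode.

    ``reference_mode`` is the KDE mode of the valid reference-region
    intensities; ``cnr = 100 * (I - mode) / mode``.
    """
    ref = np.asarray(intensity)[np.asarray(reference_mask, bool)
                                & np.asarray(valid, bool)]
    if ref.size == 0:
        raise ValueError("reference region is empty after cleaning")
    mode = mode_of(ref, params.kde_bandwidth, params.kde_grid_points)
    if mode <= 0:
        raise ValueError(f"nonpositive reference mode: {mode}")
    cnr = np.full(intensity.shape, np.nan)
    cnr[valid] = 100.0 * (intensity[valid] - mode) / mode
    return cnr, float(mode)


# ----------------------------------------------------------------------
# edge-artifact removal
# ----------------------------------------------------------------------

def low_signal_distance(reasons: np.ndarray) -> np.ndarray:
    """City-block distance of every pixel to the low-signal set.

    The image frame beyond the array is treated as low-signal as well, so
    specimens touching the border still acquire a perimeter there.
    """
    low = (reasons == REASON_CODES["outside"]) | \
          (reasons == REASON_CODES["dropout"])
    padded = np.pad(~low, 1, constant_values=False)
    d = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return d[1:-1, 1:-1]


def remove_edge_artifacts(
    reasons: np.ndarray,
    cnr: np.ndarray | None,
    sn_mask: np.ndarray,
    params: CleaningParams = CleaningParams(),
    apply_band: bool = True,
) -> np.ndarray:
    """Flag border and edge-artifact pixels; returns the updated reasons.

    Step (a): pixels within ``border_width`` city-block dilations of the
    specimen perimeter (distance 1..border_width+1 from the low-signal
    set) are removed unconditionally.  Step (b): in the band extending
    ``band_width`` voxels beyond that border, pixels with CNR above
    ``edge_cnr_max_pct`` are removed, except inside SN-flagged sections.
    """
    reasons = reasons.copy()
    d = low_signal_distance(reasons)
    currently_valid = reasons == REASON_CODES["valid"]
    border = currently_valid & (d >= 1) & (d <= 1 + params.border_width)
    reasons[border] = REASON_CODES["border2"]
    if apply_band:
        if cnr is None:
            raise ValueError("band removal requires provisional CNR values")
        lo = 2 + params.border_width
        hi = 1 + params.border_width + params.band_width
        band = (reasons == REASON_CODES["valid"]) & (d >= lo) & (d <= hi)
        with np.errstate(invalid="ignore"):
            hot = band & (cnr > params.edge_cnr_max_pct) & ~np.asarray(
                sn_mask, bool)
        reasons[hot] = REASON_CODES["border5_cnr"]
    return reasons


# ----------------------------------------------------------------------
# Cook's-distance outlier rejection
# ----------------------------------------------------------------------

def cooks_distance_constant(values: np.ndarray) -> np.ndarray:
    """Cook's distance of each point under an intercept-only regression.

    With hat values h = 1/n the closed form is
    ``D_i = e_i^2 * h / (p * s^2 * (1 - h)^2)`` with p = 1 and
    ``s^2 = RSS / (n - 1)``.  A zero-variance sample has all D_i = 0.
    """
    y = np.asarray(values, dtype=float).ravel()
    n = y.size
    if n < 2:
        return np.zeros(n)
    e = y - y.mean()
    s2 = np.sum(e ** 2) / (n - 1)
    if s2 == 0:
        return np.zeros(n)
    h = 1.0 / n
    return (e ** 2) * h / (s2 * (1.0 - h) ** 2)


def cooks_outlier_filter(values: np.ndarray, multiplier: float = 4.0
                         ) -> np.ndarray:
    """Keep-mask for a section's CNR values (False = flagged outlier).

    Flags values whose Cook's distance exceeds ``multiplier / n``.
    Sections with fewer than 3 values pass unfiltered with a warning.
    """
    y = np.asarray(values, dtype=float).ravel()
    n = y.size
    if n < 3:
        warnings.warn(
            f"section has only {n} voxel(s); Cook's filter skipped",
            stacklevel=2,
        )
        return np.ones(n, dtype=bool)
    d = cooks_distance_constant(y)
    return d <= multiplier / n
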