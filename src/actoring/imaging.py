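"""Quantification of 2D fluorescence-like intensity images.

Implements the live-cell image pipeline on synthetic TIRF-like images (or
rendered simulation snapshots): background subtraction, cell mask and
centroid, 50 radial line profiles, the intensity-based normalized radial
median, and the center-to-plateau slope of the radial intensity profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

N_RAYS = 50


@dataclass
class IntensityImage:
    data: np.ndarray                 # 2D, nonnegative after background removal
    pixel_size_nm: float
    background: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("intensity image must be 2D")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        if self.background is not None:
            self.data = np.clip(self.data - self.background, 0.0, None)
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite intensities")
        self.data = np.clip(self.data, 0.0, None)


@dataclass
class LineProfileSet:
    centroid: tuple                  # (row, col), pixels
    r: np.ndarray                    # normalized distances 0..1 (n_samples)
    profiles: np.ndarray             # (N_RAYS, n_samples) intensities
    mask: np.ndarray

    def pooled(self):
        """Flattened (r, intensity) sample pairs from all rays."""
        rr = np.tile(self.r, len(self.profiles))
        return rr, self.profiles.ravel()


def mask_and_centroid(image: IntensityImage, threshold: float | None = None,
                      smooth_sigma: float = 2.0):
    """Binary cell mask (largest connected component of the thresholded,
    smoothed image) and its intensity-unweighted centroid.

    The default threshold is Otsu's on the smoothed image; pass an explicit
    minimum-intensity constant to override.
    """
    img = ndimage.gaussian_filter(image.data, smooth_sigma)
    if threshold is None:
        if img.max() <= img.min():
            raise ValueError("flat image: no mask")
        threshold = threshold_otsu(img)
    mask = img > threshold
    if not mask.any():
        raise ValueError("empty mask")
    lab = label(mask)
    largest = max(regionprops(lab), key=lambda r: r.area)
    # fill holes: ring-like cells must yield a filled cell footprint so
    # the centroid lies inside the mask
    mask = ndimage.binary_fill_holes(lab == largest.label)
    centroid = tuple(float(c) for c in np.argwhere(mask).mean(axis=0))
    return mask, centroid


def radial_profiles(image: IntensityImage, mask: np.ndarray, centroid: tuple,
                    n_samples: int = 100) -> LineProfileSet:
    """50 uniformly spaced rays from the centroid to the mask edge.

    Each ray is sampled bilinearly at n_samples points; distances are
    normalized per ray by the centroid-to-mask-edge distance.
    """
    cy, cx = centroid
    iy, ix = int(round(cy)), int(round(cx))
    if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]) or not mask[iy, ix]:
        raise ValueError("centroid outside mask")
    angles = np.arange(N_RAYS) * (2 * np.pi / N_RAYS)
    r_grid = np.linspace(0.0, 1.0, n_samples)
    profiles = np.zeros((N_RAYS, n_samples))
    max_extent = float(np.hypot(*mask.shape))
    for k, a in enumerate(angles):
        dy, dx = np.sin(a), np.cos(a)
        # first mask exit along the ray, at sub-pixel resolution
        ts = np.arange(0.0, max_extent, 0.25)
        ys = cy + ts * dy
        xs = cx + ts * dx
        inside = ((ys >= 0) & (ys <= mask.shape[0] - 1)
                  & (xs >= 0) & (xs <= mask.shape[1] - 1))
        edge_t = ts[-1]
        for t, y, x, ok in zip(ts, ys, xs, inside):
            if not ok or not mask[int(round(y)), int(round(x))]:
                edge_t = t
                break
        if edge_t <= 0:
            continue
        samp_y = cy + r_grid * edge_t * dy
        samp_x = cx + r_grid * edge_t * dx
        profiles[k] = ndimage.map_coordinates(image.data, [samp_y, samp_x],
                                              order=1, mode="nearest")
    return LineProfileSet(centroid=centroid, r=r_grid, profiles=profiles,
                          mask=mask)


def intensity_r_median(profiles: LineProfileSet) -> float:
    """Normalized radius below which half of the total F-actin signal lies.

    Pooled ray samples are weighted by intensity × radius (the annulus-area
    Jacobian that converts equidistant ray samples into a 2D mass
    distribution), and the weighted median of the normalized radius is
    returned. A uniform disk gives 1/sqrt(2).
    """
    r, I = profiles.pooled()
    w = I * r
    total = w.sum()
    if I.sum() <= 0:
        raise ValueError("zero total intensity")
    if total <= 0:
        return 0.0
    order = np.argsort(r)
    cw = np.cumsum(w[order])
    idx = np.searchsorted(cw, 0.5 * total)
    return float(r[order][min(idx, len(r) - 1)])


def plateau_slope(profile_series: np.ndarray, r: np.ndarray,
                  normalize: bool = True,
                  plateau_outer_frac: float = 0.2,
                  lo_frac: float = 0.1, hi_frac: float = 0.9) -> np.ndarray:
    """Center-to-plateau transition slope for a time series of mean radial
    profiles (one row per time point).

    Profiles are bleach-normalized by each frame's mean intensity relative
    to the first frame. The transition region runs from the last radius
    below ``lo_frac`` of the plateau level to the first radius above
    ``hi_frac`` of it (plateau = mean over the outer 20% of radii); its
    least-squares slope is returned per time point (NaN when no plateau
    transition is detectable).
    """
    P = np.atleast_2d(np.asarray(profile_series, dtype=float)).copy()
    r = np.asarray(r, dtype=float)
    if normalize:
        means = P.mean(axis=1)
        if means[0] > 0:
            P = P / (means / means[0])[:, None]
    n_outer = max(1, int(plateau_outer_frac * P.shape[1]))
    slopes = np.full(P.shape[0], np.nan)
    for i, prof in enumerate(P):
        plateau = prof[-n_outer:].mean()
        if plateau <= 0:
            continue
        above = np.nonzero(prof >= hi_frac * plateau)[0]
        if len(above) == 0:
            continue
        i90 = above[0]
        below = np.nonzero(prof[:i90] <= lo_frac * plateau)[0]
        i10 = below[-1] if len(below) else 0
        if i90 - i10 < 2:
            i10 = max(0, i90 - 2)
        seg_r = r[i10:i90 + 1]
        seg_I = prof[i10:i90 + 1]
        if len(seg_r) < 2 or seg_r[-1] == seg_r[0]:
            continue
        slopes[i] = np.polyfit(seg_r, seg_I, 1)[0]
    return slopes
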