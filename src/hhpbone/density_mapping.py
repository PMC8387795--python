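"""Spatial apoptotic-density mapping from two-channel histology images.

The pipeline mirrors a whole-slide TUNEL/DAPI workflow: tiles are merged
into a whole-sample image; nuclei are detected as Laplacian-of-Gaussian
blobs on the DAPI channel and classified TUNEL-positive by mean TUNEL
intensity inside the nucleus disc; positive detections are binned into a
spatial count matrix; the matrix is smoothed with a unit-sum 2-D Gaussian
kernel (reflective boundary, so counts are conserved); the DAPI channel is
Otsu-thresholded into a Boolean trabecular mask (bone matrix binds DAPI
strongly); and the masked, smoothed matrix is the density map. A
center/edge statistic quantifies the radial gradient of apoptotic density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import blob_log

from .exceptions import (
    AlignmentError,
    ConfigError,
    DegenerateImageError,
    LayoutError,
    ZoneError,
)

__all__ = [
    "CellDetections",
    "DensityMatrix",
    "SmoothedDensity",
    "TrabecularMask",
    "DensityMap",
    "CenterEdgeResult",
    "merge_tiles",
    "detect_cells",
    "compute_density_matrix",
    "gaussian_normalize",
    "otsu_threshold",
    "estimate_sample_support",
    "edge_corrected_density",
    "trabecular_mask",
    "combine_map",
    "center_edge_statistic",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CellDetections:
    """Point set of detected nuclei in merged-image coordinates."""

    positions: np.ndarray  # (N, 2) float, (x, y)
    tunel_positive: np.ndarray  # (N,) bool
    dapi_intensity: np.ndarray  # (N,) peak DAPI value
    tunel_intensity: np.ndarray  # (N,) mean TUNEL in nucleus disc
    radii: np.ndarray  # (N,) estimated nucleus radius (px)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_positive(self) -> int:
        return int(np.count_nonzero(self.tunel_positive))


@dataclass
class DensityMatrix:
    """Spatial grid of TUNEL-positive counts (half-open pixel bins)."""

    bin_counts: np.ndarray  # (H, W) int
    bin_size_px: float
    origin: tuple[float, float]  # merged-image pixel of bin (0, 0), (x, y)

    @property
    def total(self) -> int:
        return int(self.bin_counts.sum())


@dataclass
class SmoothedDensity:
    values: np.ndarray  # (H, W) float, >= 0
    sigma_bins: float
    bin_size_px: float
    origin: tuple[float, float]

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class TrabecularMask:
    mask: np.ndarray  # (H, W) bool at image resolution
    threshold: float  # Otsu gray level: mask = dapi > threshold

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class DensityMap:
    """Smoothed density shown only on trabecular bins."""

    map: np.ndarray  # (H, W) float; sentinel on masked-out bins
    bin_mask: np.ndarray  # (H, W) bool at density-grid resolution
    sentinel: float
    bin_size_px: float
    origin: tuple[float, float]
    provenance: dict = dc_field(default_factory=dict)


@dataclass
class CenterEdgeResult:
    center_mean: float
    edge_mean: float
    ratio: float
    radial_profile: np.ndarray  # (n_bins,) mean density vs normalized radius
    radial_bin_edges: np.ndarray  # (n_bins + 1,)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def merge_tiles(
    tiles: list[np.ndarray], layout: tuple[int, int], overlap_px: int = 0
) -> np.ndarray:
    """Compose row-major tiles into one image, averaging overlap strips."""
    rows, cols = layout
    if rows <= 0 or cols <= 0:
        raise LayoutError(f"layout must be positive, got {layout!r}")
    if len(tiles) != rows * cols:
        raise LayoutError(f"{len(tiles)} tiles do not fit a {rows}x{cols} layout")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise LayoutError(f"tiles have mixed shapes: {sorted(shapes)}")
    th, tw = tiles[0].shape
    if overlap_px < 0 or overlap_px >= th or overlap_px >= tw:
        raise LayoutError(f"overlap {overlap_px} incompatible with tile shape {(th, tw)}")
    step_y, step_x = th - overlap_px, tw - overlap_px
    H = th + (rows - 1) * step_y
    W = tw + (cols - 1) * step_x
    acc = np.zeros((H, W))
    wt = np.zeros((H, W))
    for idx, tile in enumerate(tiles):
        r, c = divmod(idx, cols)
        y0, x0 = r * step_y, c * step_x
        acc[y0 : y0 + th, x0 : x0 + tw] += tile
        wt[y0 : y0 + th, x0 : x0 + tw] += 1.0
    return acc / wt


def detect_cells(
    dapi: np.ndarray,
    tunel: np.ndarray,
    min_radius_px: float = 2.0,
    max_radius_px: float = 5.0,
    detect_threshold: float = 0.08,
    tunel_threshold: float = 0.15,
) -> CellDetections:
    """Detect nuclei on DAPI and label them by TUNEL positivity.

    Broad structure (the DAPI-bright trabecular matrix) is first removed
    with a large-sigma Gaussian detrend, then nuclei are found as
    scale-normalized Laplacian-of-Gaussian maxima above
    ``detect_threshold`` within the radius range. A detection is
    TUNEL-positive when the mean TUNEL intensity inside its nucleus disc
    exceeds ``tunel_threshold``.
    """
    dapi = np.asarray(dapi, dtype=float)
    tunel = np.asarray(tunel, dtype=float)
    if dapi.shape != tunel.shape:
        raise ConfigError(f"channel shapes differ: {dapi.shape} vs {tunel.shape}")
    if dapi.size == 0 or dapi.max() == dapi.min():
        return _empty_detections()
    # suppress the broad trabecular plateau so only nucleus-scale blobs remain
    detrended = dapi - gaussian_filter(dapi, sigma=4.0 * max_radius_px)
    blobs = blob_log(
        np.clip(detrended, 0.0, None),
        min_sigma=min_radius_px / math.sqrt(2),
        max_sigma=max_radius_px / math.sqrt(2),
        num_sigma=4,
        threshold=detect_threshold,
    )
    if len(blobs) == 0:
        return _empty_detections()
    ys, xs, sigmas = blobs[:, 0], blobs[:, 1], blobs[:, 2]
    radii = sigmas * math.sqrt(2)
    H, W = dapi.shape
    tunel_means = np.empty(len(blobs))
    dapi_peaks = np.empty(len(blobs))
    for i, (y, x, r) in enumerate(zip(ys, xs, radii)):
        ri = max(1, int(round(r)))
        ylo, yhi = max(0, int(y) - ri), min(H, int(y) + ri + 1)
        xlo, xhi = max(0, int(x) - ri), min(W, int(x) + ri + 1)
        wy, wx = np.mgrid[ylo:yhi, xlo:xhi]
        disc = (wy - y) ** 2 + (wx - x) ** 2 <= r**2
        if not disc.any():
            disc = np.ones_like(wy, dtype=bool)
        tunel_means[i] = tunel[ylo:yhi, xlo:xhi][disc].mean()
        dapi_peaks[i] = dapi[int(round(y)), int(round(x))]
    return CellDetections(
        positions=np.column_stack([xs, ys]),
        tunel_positive=tunel_means > tunel_threshold,
        dapi_intensity=dapi_peaks,
        tunel_intensity=tunel_means,
        radii=radii,
    )


def _empty_detections() -> CellDetections:
    return CellDetections(
        positions=np.empty((0, 2)),
        tunel_positive=np.empty(0, dtype=bool),
        dapi_intensity=np.empty(0),
        tunel_intensity=np.empty(0),
        radii=np.empty(0),
    )


def compute_density_matrix(
    dets: CellDetections,
    bin_size_px: float,
    region: tuple[float, float, float, float],
) -> DensityMatrix:
    """Bin TUNEL-positive detections into a count matrix.

    ``region`` is ``(x0, y0, x1, y1)``; each bin is the half-open square
    ``[x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, ...)`` so every point inside
    the region lands in exactly one bin and totals are conserved.
    """
    if bin_size_px < 1:
        raise ConfigError("bin_size_px must be >= 1")
    x0, y0, x1, y1 = region
    if x1 <= x0 or y1 <= y0:
        raise ConfigError(f"empty region {region!r}")
    nbx = int(math.ceil((x1 - x0) / bin_size_px))
    nby = int(math.ceil((y1 - y0) / bin_size_px))
    counts = np.zeros((nby, nbx), dtype=int)
    pos = dets.positions[dets.tunel_positive]
    if len(pos):
        inside = (
            (pos[:, 0] >= x0) & (pos[:, 0] < x1) & (pos[:, 1] >= y0) & (pos[:, 1] < y1)
        )
        pos = pos[inside]
        ix = np.floor((pos[:, 0] - x0) / bin_size_px).astype(int)
        iy = np.floor((pos[:, 1] - y0) / bin_size_px).astype(int)
        np.add.at(counts, (iy, ix), 1)
    return DensityMatrix(bin_counts=counts, bin_size_px=float(bin_size_px), origin=(x0, y0))


def gaussian_normalize(m: DensityMatrix, sigma_bins: float) -> SmoothedDensity:
    """Smooth the count matrix with a unit-sum 2-D Gaussian kernel.

    The kernel is truncated at 4 sigma and applied with a reflective
    boundary, which conserves the total count exactly. ``sigma_bins = 0``
    returns the counts unchanged.
    """
    if sigma_bins < 0:
        raise ConfigError("sigma_bins must be >= 0")
    counts = m.bin_counts.astype(float)
    if sigma_bins == 0:
        values = counts.copy()
    else:
        values = gaussian_filter(counts, sigma=sigma_bins, mode="reflect", truncate=4.0)
    return SmoothedDensity(
        values=values, sigma_bins=float(sigma_bins), bin_size_px=m.bin_size_px, origin=m.origin
    )


def estimate_sample_support(
    dets: CellDetections,
    grid_shape: tuple[int, int],
    bin_size_px: float,
    origin: tuple[float, float] = (0.0, 0.0),
    coverage_quantile: float = 0.99,
    margin: float = 1.02,
) -> np.ndarray:
    """Boolean bin-level mask of where tissue plausibly exists.

    Bone sections are approximately round, so the support is fitted as a
    circle from *all* detections (both TUNEL labels): center at the
    detection centroid, radius at the ``coverage_quantile`` of
    centroid-to-detection distances times a small ``margin``.
    """
    if len(dets) == 0:
        raise ZoneError("cannot estimate sample support without detections")
    center = dets.positions.mean(axis=0)
    dists = np.hypot(*(dets.positions - center).T)
    radius = float(np.quantile(dists, coverage_quantile)) * margin
    nby, nbx = grid_shape
    x0, y0 = origin
    byy, bxx = np.mgrid[0:nby, 0:nbx]
    bx = x0 + (bxx + 0.5) * bin_size_px
    by = y0 + (byy + 0.5) * bin_size_px
    return np.hypot(bx - center[0], by - center[1]) <= radius


def edge_corrected_density(
    m: DensityMatrix, sigma_bins: float, support: np.ndarray
) -> SmoothedDensity:
    """Boundary-corrected smoothed density (normalized convolution).

    Plain Gaussian smoothing underestimates density near the sample
    boundary because part of the kernel mass falls outside the tissue.
    Dividing the smoothed counts by the identically smoothed support
    indicator renormalizes each bin by the kernel mass that actually lies
    on tissue — the standard edge correction for kernel density estimates.
    The result is a per-bin density *given tissue*, so unlike
    :func:`gaussian_normalize` it does not conserve the raw count total.
    """
    if sigma_bins < 0:
        raise ConfigError("sigma_bins must be >= 0")
    if support.shape != m.bin_counts.shape:
        raise AlignmentError(
            f"support shape {support.shape} != grid {m.bin_counts.shape}"
        )
    counts = m.bin_counts.astype(float)
    sup = support.astype(float)
    if sigma_bins == 0:
        num, den = counts, sup
    else:
        num = gaussian_filter(counts, sigma=sigma_bins, mode="reflect", truncate=4.0)
        den = gaussian_filter(sup, sigma=sigma_bins, mode="reflect", truncate=4.0)
    values = np.where(support, num / np.maximum(den, 1e-12), 0.0)
    return SmoothedDensity(
        values=values,
        sigma_bins=float(sigma_bins),
        bin_size_px=m.bin_size_px,
        origin=m.origin,
    )


def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> float:
    """Gray level maximizing between-class variance (ties -> lower level).

    For integer images the candidate levels are the integer gray values
    spanning the data range (so the result is exact, not bin-quantized);
    float images are histogrammed into ``n_bins`` equal bins and the
    returned level is a bin center. The mask convention is
    ``img > threshold``.
    """
    vals = np.asarray(img).ravel()
    if vals.size == 0:
        raise DegenerateImageError("empty image")
    vmin, vmax = vals.min(), vals.max()
    if vmin == vmax:
        raise DegenerateImageError("constant image cannot be thresholded")
    if np.issubdtype(vals.dtype, np.integer) and int(vmax) - int(vmin) < n_bins:
        levels = np.arange(int(vmin), int(vmax) + 1)
        hist = np.bincount(
            vals.astype(np.int64) - int(vmin), minlength=len(levels)
        ).astype(float)
    else:
        hist, edges = np.histogram(vals, bins=n_bins, range=(float(vmin), float(vmax)))
        hist = hist.astype(float)
        levels = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * levels)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-np.inf)  # last split has empty upper class
    k = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    return float(levels[k])


def trabecular_mask(dapi: np.ndarray, invert: bool = False) -> TrabecularMask:
    """Boolean trabecular image from the DAPI channel via Otsu.

    ``invert=True`` handles inverted-contrast input (trabeculae dark): the
    image is flipped about its midrange before thresholding, so the mask
    complements.
    """
    dapi = np.asarray(dapi, dtype=float)
    work = (dapi.min() + dapi.max()) - dapi if invert else dapi
    thr = otsu_threshold(work)
    return TrabecularMask(mask=work > thr, threshold=float(thr))


def downsample_mask(
    mask: np.ndarray,
    grid_shape: tuple[int, int],
    bin_size_px: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Majority-vote downsampling of a pixel mask onto the density grid.

    A bin is True when at least half of its (in-image) pixels are True.
    """
    nby, nbx = grid_shape
    x0, y0 = origin
    out = np.zeros((nby, nbx), dtype=bool)
    H, W = mask.shape
    s = bin_size_px
    for iy in range(nby):
        ylo = int(math.floor(y0 + iy * s))
        yhi = int(math.ceil(y0 + (iy + 1) * s))
        ylo, yhi = max(0, ylo), min(H, yhi)
        if ylo >= yhi:
            continue
        for ix in range(nbx):
            xlo = int(math.floor(x0 + ix * s))
            xhi = int(math.ceil(x0 + (ix + 1) * s))
            xlo, xhi = max(0, xlo), min(W, xhi)
            if xlo >= xhi:
                continue
            block = mask[ylo:yhi, xlo:xhi]
            out[iy, ix] = block.mean() >= 0.5
    return out


def combine_map(
    sd: SmoothedDensity,
    mask: TrabecularMask | np.ndarray,
    sentinel: float = np.nan,
) -> DensityMap:
    """Mask the smoothed density with the trabecular mask.

    ``mask`` may be a pixel-resolution :class:`TrabecularMask` (downsampled
    to the density grid by majority vote) or an already bin-level boolean
    array matching the grid shape exactly.
    """
    pixel_mask = mask.mask if isinstance(mask, TrabecularMask) else np.asarray(mask)
    if pixel_mask.dtype != bool:
        raise AlignmentError("mask must be boolean")
    if pixel_mask.shape == sd.values.shape:
        bin_mask = pixel_mask
    else:
        x0, y0 = sd.origin
        extent_y = y0 + sd.values.shape[0] * sd.bin_size_px
        extent_x = x0 + sd.values.shape[1] * sd.bin_size_px
        if pixel_mask.shape[0] < extent_y - sd.bin_size_px or pixel_mask.shape[1] < extent_x - sd.bin_size_px:
            raise AlignmentError(
                f"mask shape {pixel_mask.shape} does not cover the density grid"
            )
        bin_mask = downsample_mask(pixel_mask, sd.values.shape, sd.bin_size_px, sd.origin)
    out = np.where(bin_mask, sd.values, sentinel)
    return DensityMap(
        map=out,
        bin_mask=bin_mask,
        sentinel=float(sentinel) if np.isfinite(sentinel) else sentinel,
        bin_size_px=sd.bin_size_px,
        origin=sd.origin,
        provenance={"sigma_bins": sd.sigma_bins},
    )


def center_edge_statistic(
    dmap: DensityMap,
    inner_fraction: float = 0.15,
    outer_fraction: float = 0.92,
    n_profile_bins: int = 10,
) -> CenterEdgeResult:
    """Quantify the center-to-edge gradient of masked-in density.

    The center is the centroid of masked-in bins; radii are normalized by
    the maximum centroid-to-masked-bin distance. ``center_mean`` averages
    bins with normalized radius <= ``inner_fraction``, ``edge_mean`` those
    >= ``outer_fraction``; thin end zones keep the zone means close to the
    underlying center/edge rates for a gradually varying density.
    """
    if not 0.0 < inner_fraction < outer_fraction <= 1.0:
        raise ConfigError("require 0 < inner_fraction < outer_fraction <= 1")
    mask = dmap.bin_mask & np.isfinite(dmap.map)
    if not mask.any():
        raise ZoneError("no masked-in bins")
    iy, ix = np.nonzero(mask)
    vals = dmap.map[iy, ix]
    cy, cx = iy.mean(), ix.mean()
    d = np.hypot(iy - cy, ix - cx)
    dmax = d.max()
    r = d / dmax if dmax > 0 else np.zeros_like(d)
    center_sel = r <= inner_fraction
    edge_sel = r >= outer_fraction
    if not center_sel.any():
        raise ZoneError(f"no masked-in bins with radius <= {inner_fraction}")
    if not edge_sel.any():
        raise ZoneError(f"no masked-in bins with radius >= {outer_fraction}")
    center_mean = float(vals[center_sel].mean())
    edge_mean = float(vals[edge_sel].mean())
    ratio = center_mean / edge_mean if edge_mean != 0 else math.inf
    edges = np.linspace(0.0, 1.0, n_profile_bins + 1)
    profile = np.full(n_profile_bins, np.nan)
    which = np.clip(np.digitize(r, edges) - 1, 0, n_profile_bins - 1)
    for b in range(n_profile_bins):
        sel = which == b
        if sel.any():
            profile[b] = vals[sel].mean()
    return CenterEdgeResult(
        center_mean=center_mean,
        edge_mean=edge_mean,
        ratio=float(ratio),
        radial_profile=profile,
        radial_bin_edges=edges,
    )
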