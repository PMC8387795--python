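"""Synthetic fluorescence-histology scenes and electrophoresis gels.

Every downstream stage of the package (density mapping, gel densitometry,
band ratios) is tested against data produced here, with full ground truth:
nucleus positions and TUNEL labels for histology scenes, and per-lane
fragment masses and band centers for gels.

Histology scenes emulate two-channel cryosection micrographs of trabecular
bone: a DAPI channel carrying both nuclei and the DAPI-bright bone matrix
(whose high DAPI affinity is what makes trabeculae segmentable), and a TUNEL
channel carrying only the apoptotic nuclei. TUNEL-positive cells are drawn
as an inhomogeneous Poisson point process from a radial rate field, so a
center-weighted apoptotic density can be planted and later recovered.

Gels follow the standard log-linear agarose mobility model
``distance(bp) = a - b * log10(bp)``; each discrete fragment mass becomes a
Gaussian band, smears become continuous signal, and a 100-bp ladder lane can
be added for size calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigError, PlacementError

__all__ = [
    "GENE_RULER_100BP",
    "NUCLEOSOMAL_REPEAT_BP",
    "HistologySceneParams",
    "HistologyTruth",
    "FragmentSpec",
    "GelSimParams",
    "GelTruth",
    "GelLaneTruth",
    "generate_radial_density_field",
    "sample_positions_from_rate_field",
    "generate_histology_scene",
    "cut_tiles",
    "simulate_fragments",
    "ladder_lane_spec",
    "render_gel",
]

#: Rung sizes (bp) of a standard 100-bp DNA ladder.
GENE_RULER_100BP: tuple[int, ...] = tuple(range(100, 1100, 100))

#: Internucleosomal cleavage repeat length (bp) characteristic of apoptosis.
NUCLEOSOMAL_REPEAT_BP: int = 180


# ---------------------------------------------------------------------------
# Histology scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HistologySceneParams:
    """Parameters of a synthetic two-channel histology scene.

    ``center_rate`` and ``edge_rate`` are the expected numbers of
    TUNEL-positive cells per rate-field bin (``rate_grid`` bins span the
    merged image) at the sample center and at the sample edge. ``n_cells``
    is the target total nucleus count; TUNEL-positive nuclei are drawn
    first as a Poisson process and TUNEL-negative nuclei fill up the rest.
    """

    image_shape: tuple[int, int] = (256, 256)  # (H, W) of one tile
    tile_grid: tuple[int, int] = (2, 2)  # rows x cols of tiles
    trabecula_fraction: float = 0.4
    nucleus_radius_px: float = 3.0
    n_cells: int = 400
    center_rate: float = 2.0
    edge_rate: float = 0.5
    rate_grid: tuple[int, int] = (16, 16)
    dapi_snr: float = 10.0
    tunel_snr: float = 10.0
    texture_scale_px: float | None = None  # trabecular correlation length; default merged min/32
    matrix_edge_px: float | None = None  # trabecular staining edge softness; default 3x nucleus radius
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("image_shape", "tile_grid", "rate_grid"):
            shape = getattr(self, name)
            if len(shape) != 2 or any(int(s) <= 0 for s in shape):
                raise ConfigError(f"{name} must be two positive integers, got {shape!r}")
        if not 0.0 < self.trabecula_fraction < 1.0:
            raise ConfigError("trabecula_fraction must lie in (0, 1)")
        if self.center_rate < 0 or self.edge_rate < 0:
            raise ConfigError("center_rate and edge_rate must be >= 0")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")
        if self.nucleus_radius_px <= 0:
            raise ConfigError("nucleus_radius_px must be > 0")

    @property
    def merged_shape(self) -> tuple[int, int]:
        return (
            self.tile_grid[0] * self.image_shape[0],
            self.tile_grid[1] * self.image_shape[1],
        )


@dataclass
class HistologyTruth:
    """Ground truth of a generated scene, in merged-image coordinates."""

    positions: np.ndarray  # (N, 2) float, (x, y)
    tunel_positive: np.ndarray  # (N,) bool
    trabecular_mask: np.ndarray  # (H, W) bool, pixel-level
    sample_mask: np.ndarray  # (H, W) bool disc: where tissue exists
    rate_field: np.ndarray  # rate-grid expected TUNEL-positive counts
    merged_dapi: np.ndarray
    merged_tunel: np.ndarray


def generate_radial_density_field(
    shape: tuple[int, int], center_rate: float, edge_rate: float
) -> np.ndarray:
    """Expected-count field decreasing linearly from center to edge.

    The value is ``center_rate`` at the geometric center bin and
    ``edge_rate`` on every boundary bin; in between it interpolates
    linearly in Euclidean distance normalized by the center-to-nearest-edge
    distance (clipped at 1, so corner bins also sit at the edge rate).
    """
    h, w = (int(s) for s in shape)
    if h <= 0 or w <= 0:
        raise ConfigError(f"field shape must be positive, got {shape!r}")
    if center_rate < 0 or edge_rate < 0:
        raise ConfigError("rates must be >= 0")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    r_edge = min(cy, cx)
    if r_edge == 0:  # 1-pixel-wide field: everything is boundary
        r_norm = np.where(r > 0, 1.0, 0.0)
    else:
        r_norm = np.clip(r / r_edge, 0.0, 1.0)
    return edge_rate + (center_rate - edge_rate) * (1.0 - r_norm)


def sample_positions_from_rate_field(
    rate_field: np.ndarray,
    region_shape: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an inhomogeneous Poisson point process over ``region_shape``.

    Each bin of ``rate_field`` covers an equal rectangle of the region;
    the count in a bin is Poisson with the bin's rate and positions are
    uniform within the bin. Returns an (N, 2) array of (x, y) pixel
    coordinates.
    """
    gh, gw = rate_field.shape
    H, W = region_shape
    counts = rng.poisson(rate_field)
    bh, bw = H / gh, W / gw
    xs, ys = [], []
    for iy in range(gh):
        for ix in range(gw):
            n = int(counts[iy, ix])
            if n == 0:
                continue
            xs.append(rng.uniform(ix * bw, (ix + 1) * bw, size=n))
            ys.append(rng.uniform(iy * bh, (iy + 1) * bh, size=n))
    if not xs:
        return np.empty((0, 2))
    return np.column_stack([np.concatenate(xs), np.concatenate(ys)])


def _gaussian_spots(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitude: float,
    radius: float,
) -> np.ndarray:
    """Render Gaussian spots (sigma = radius) at subpixel positions."""
    img = np.zeros(shape)
    if len(positions) == 0:
        return img
    half = int(math.ceil(4 * radius))
    H, W = shape
    for x, y in positions:
        x0, y0 = int(round(x)), int(round(y))
        ylo, yhi = max(0, y0 - half), min(H, y0 + half + 1)
        xlo, xhi = max(0, x0 - half), min(W, x0 + half + 1)
        if ylo >= yhi or xlo >= xhi:
            continue
        yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
        img[ylo:yhi, xlo:xhi] += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * radius**2)
        )
    return img


def generate_histology_scene(
    params: HistologySceneParams,
) -> tuple[list[np.ndarray], list[np.ndarray], HistologyTruth]:
    """Generate TUNEL/DAPI tile lists plus ground truth.

    The sample is a disc centered in the merged frame (sections of bone
    cylinders are roughly round). Trabecular structure is a thresholded
    smoothed random field occupying ``trabecula_fraction`` of the disc.
    TUNEL-positive nuclei follow the radial rate field (restricted to the
    disc); TUNEL-negative nuclei are packed uniformly with a minimum
    separation. Rendering is fully deterministic under a fixed seed.

    Returns ``(tunel_tiles, dapi_tiles, truth)``; tiles are row-major cuts
    of the merged frame with zero overlap.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.merged_shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    # inscribed disc: its boundary coincides with the rate field's
    # normalization radius, so "edge" means the same thing in the
    # generator and in the center/edge statistic
    radius_disc = 0.5 * min(H, W)
    yy, xx = np.mgrid[0:H, 0:W]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_disc**2

    # Trabecular texture: smoothed white noise thresholded at the quantile
    # giving the requested area fraction inside the disc.
    scale = params.texture_scale_px or min(H, W) / 32.0
    texture = gaussian_filter(rng.standard_normal((H, W)), sigma=scale)
    thr = np.quantile(texture[disc], 1.0 - params.trabecula_fraction)
    trab = disc & (texture > thr)

    rate_field = generate_radial_density_field(
        params.rate_grid, params.center_rate, params.edge_rate
    )

    if params.n_cells == 0:
        positions = np.empty((0, 2))
        labels = np.empty(0, dtype=bool)
    else:
        pos_xy = sample_positions_from_rate_field(rate_field, (H, W), rng)
        if len(pos_xy):
            ix = np.clip(pos_xy[:, 0].astype(int), 0, W - 1)
            iy = np.clip(pos_xy[:, 1].astype(int), 0, H - 1)
            pos_xy = pos_xy[disc[iy, ix]]  # tissue exists only in the disc
        n_pos = len(pos_xy)
        n_neg = max(0, params.n_cells - n_pos)
        min_sep = 2.5 * params.nucleus_radius_px
        accepted = list(pos_xy)
        neg = []
        attempts, max_attempts = 0, 200 * max(n_neg, 1)
        while len(neg) < n_neg:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"could not place {n_neg} cells with separation "
                    f"{min_sep:.1f}px inside the sample disc"
                )
            ang = rng.uniform(0, 2 * math.pi)
            rad = radius_disc * math.sqrt(rng.uniform())
            cand = np.array([cx + rad * math.cos(ang), cy + rad * math.sin(ang)])
            if accepted:
                d2 = np.min(np.sum((np.asarray(accepted) - cand) ** 2, axis=1))
                if d2 < min_sep**2:
                    continue
            accepted.append(cand)
            neg.append(cand)
        positions = np.asarray(accepted) if accepted else np.empty((0, 2))
        labels = np.zeros(len(positions), dtype=bool)
        labels[:n_pos] = True

    # Matrix staining has no pixel-sharp edges at 20x: render the
    # trabecular channel with a diffuse boundary (truth mask stays binary).
    edge = params.matrix_edge_px or 3.0 * params.nucleus_radius_px
    soft_trab = gaussian_filter(trab.astype(float), sigma=edge)
    r = params.nucleus_radius_px
    dapi = 0.05 + 0.75 * soft_trab
    dapi += _gaussian_spots((H, W), positions, amplitude=0.45, radius=r)
    tunel = 0.02 + _gaussian_spots((H, W), positions[labels], amplitude=1.0, radius=r)
    if params.dapi_snr > 0 and np.isfinite(params.dapi_snr):
        dapi = dapi + rng.normal(0.0, 0.45 / params.dapi_snr, size=(H, W))
    if params.tunel_snr > 0 and np.isfinite(params.tunel_snr):
        tunel = tunel + rng.normal(0.0, 1.0 / params.tunel_snr, size=(H, W))
    dapi = np.clip(dapi, 0.0, None)
    tunel = np.clip(tunel, 0.0, None)

    truth = HistologyTruth(
        positions=positions,
        tunel_positive=labels,
        trabecular_mask=trab,
        sample_mask=disc,
        rate_field=rate_field,
        merged_dapi=dapi,
        merged_tunel=tunel,
    )
    dapi_tiles = cut_tiles(dapi, params.tile_grid, overlap_px=0)
    tunel_tiles = cut_tiles(tunel, params.tile_grid, overlap_px=0)
    return tunel_tiles, dapi_tiles, truth


def cut_tiles(
    image: np.ndarray, layout: tuple[int, int], overlap_px: int = 0
) -> list[np.ndarray]:
    """Cut ``image`` into a row-major grid of tiles with the given overlap.

    Inverse of :func:`hhpbone.density_mapping.merge_tiles`: adjacent tiles
    share ``overlap_px`` pixels. The image dimensions must be consistent
    with the layout, i.e. ``H = rows*th - (rows-1)*overlap`` for some tile
    height ``th`` (and likewise for width).
    """
    rows, cols = layout
    H, W = image.shape
    th_num = H + (rows - 1) * overlap_px
    tw_num = W + (cols - 1) * overlap_px
    if th_num % rows or tw_num % cols:
        raise ConfigError(
            f"image shape {image.shape} not divisible into {layout} tiles "
            f"with overlap {overlap_px}"
        )
    th, tw = th_num // rows, tw_num // cols
    step_y, step_x = th - overlap_px, tw - overlap_px
    return [
        image[r * step_y : r * step_y + th, c * step_x : c * step_x + tw].copy()
        for r in range(rows)
        for c in range(cols)
    ]


# ---------------------------------------------------------------------------
# Gels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentSpec:
    """Fragment-size distribution of one gel lane.

    ``kind`` is one of ``intact`` (a single large fragment), ``ladder``
    (nucleosomal repeat multiples), ``smear`` (continuous size range) or
    ``explicit`` (a list of (size, mass) pairs). ``mass`` is the lane's
    total loaded mass in arbitrary densitometric units.
    """

    kind: str
    mass: float = 1000.0
    size: float | None = None  # intact
    repeat: int = NUCLEOSOMAL_REPEAT_BP  # ladder
    max_multiple: int = 6  # ladder
    weights: tuple[float, ...] | None = None  # ladder rung weights
    low: float | None = None  # smear
    high: float | None = None  # smear
    pairs: tuple[tuple[float, float], ...] | None = None  # explicit

    def __post_init__(self) -> None:
        if self.kind not in {"intact", "ladder", "smear", "explicit"}:
            raise ConfigError(f"unknown fragment spec kind {self.kind!r}")
        if self.mass < 0:
            raise ConfigError("mass must be >= 0")
        if self.kind == "intact":
            if self.size is None or self.size <= 1000:
                raise ConfigError("intact spec requires a single size > 1000 bp")
        elif self.kind == "ladder":
            if self.repeat <= 0 or self.max_multiple < 1:
                raise ConfigError("ladder spec needs repeat > 0, max_multiple >= 1")
            if self.weights is not None and len(self.weights) != self.max_multiple:
                raise ConfigError("weights must have max_multiple entries")
        elif self.kind == "smear":
            if self.low is None or self.high is None or not 0 < self.low < self.high:
                raise ConfigError("smear spec requires 0 < low < high")
        elif self.kind == "explicit":
            if not self.pairs:
                raise ConfigError("explicit spec requires at least one (size, mass) pair")
            if any(s <= 0 or m < 0 for s, m in self.pairs):
                raise ConfigError("explicit sizes must be > 0 and masses >= 0")

    # -- convenience constructors -------------------------------------
    @classmethod
    def intact_control(cls, size: float = 1500.0, mass: float = 1000.0) -> "FragmentSpec":
        return cls(kind="intact", size=size, mass=mass)

    @classmethod
    def nucleosomal_ladder(
        cls,
        repeat: int = NUCLEOSOMAL_REPEAT_BP,
        max_multiple: int = 6,
        weights: Sequence[float] | None = None,
        mass: float = 1000.0,
    ) -> "FragmentSpec":
        w = tuple(weights) if weights is not None else None
        return cls(kind="ladder", repeat=repeat, max_multiple=max_multiple, weights=w, mass=mass)

    @classmethod
    def smear_range(cls, low: float, high: float, mass: float = 1000.0) -> "FragmentSpec":
        return cls(kind="smear", low=low, high=high, mass=mass)

    @classmethod
    def explicit_bands(cls, pairs: Sequence[tuple[float, float]]) -> "FragmentSpec":
        pairs = tuple((float(s), float(m)) for s, m in pairs)
        return cls(kind="explicit", pairs=pairs, mass=sum(m for _, m in pairs))

    def ladder_weights(self) -> np.ndarray:
        """Normalized rung weights for ladder mode (default: decaying)."""
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
        else:
            w = np.exp(-0.5 * np.arange(self.max_multiple))
        return w / w.sum()

    def mass_by_size(self, n_smear_steps: int = 1024) -> list[tuple[float, float]]:
        """Discretize the spec into (size_bp, mass) quanta for rendering."""
        if self.kind == "intact":
            return [(float(self.size), self.mass)]
        if self.kind == "ladder":
            w = self.ladder_weights()
            return [
                (float(self.repeat * (k + 1)), self.mass * w[k])
                for k in range(self.max_multiple)
            ]
        if self.kind == "explicit":
            return [(s, m) for s, m in self.pairs]
        # smear: uniform mass density in bp, discretized on a fine grid
        edges = np.linspace(self.low, self.high, n_smear_steps + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        return [(float(s), self.mass / n_smear_steps) for s in mids]


def ladder_lane_spec(
    sizes: Sequence[float] = GENE_RULER_100BP, mass_per_rung: float = 100.0
) -> FragmentSpec:
    """Marker lane: one equal-mass band per ladder rung."""
    return FragmentSpec.explicit_bands([(s, mass_per_rung) for s in sizes])


def simulate_fragments(
    spec: FragmentSpec, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` individual fragment sizes (bp) from a lane spec."""
    if spec is None:
        raise ConfigError("fragment spec is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n < 0:
        raise ConfigError("n must be >= 0")
    if spec.kind == "intact":
        return np.full(n, float(spec.size))
    if spec.kind == "ladder":
        mult = rng.choice(np.arange(1, spec.max_multiple + 1), size=n, p=spec.ladder_weights())
        return (spec.repeat * mult).astype(float)
    if spec.kind == "smear":
        return rng.uniform(spec.low, spec.high, size=n)
    sizes = np.array([s for s, _ in spec.pairs])
    masses = np.array([m for _, m in spec.pairs], dtype=float)
    return rng.choice(sizes, size=n, p=masses / masses.sum())


@dataclass(frozen=True)
class GelSimParams:
    """Parameters of a rendered gel image.

    ``migration_coeffs = (a, b)`` define the mobility model
    ``distance_px = a - b*log10(size)`` (strictly decreasing in size for
    b > 0). ``lane_specs`` holds one :class:`FragmentSpec` per lane, left
    to right. Defaults suit a 1.7% agarose DNA gel resolving 100-3000 bp.
    """

    lane_specs: tuple[FragmentSpec, ...]
    ladder_sizes: tuple[float, ...] = GENE_RULER_100BP
    image_height: int = 400
    lane_width_px: int = 24
    lane_gap_px: int = 12
    migration_coeffs: tuple[float, float] = (720.0, 200.0)
    band_sigma_px: float = 2.5
    background_level: float = 0.02
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lane_specs:
            raise ConfigError("at least one lane spec is required")
        if self.migration_coeffs[1] <= 0:
            raise ConfigError("mobility slope b must be > 0 (distance decreasing in bp)")
        if self.band_sigma_px <= 0 or self.image_height <= 0 or self.lane_width_px <= 0:
            raise ConfigError("geometry parameters must be positive")

    @property
    def lane_count(self) -> int:
        return len(self.lane_specs)

    def migration_distance(self, size: float | np.ndarray) -> float | np.ndarray:
        a, b = self.migration_coeffs
        return a - b * np.log10(size)

    def lane_bounds(self, lane: int) -> tuple[int, int]:
        """Half-open column interval of a lane."""
        x0 = self.lane_gap_px + lane * (self.lane_width_px + self.lane_gap_px)
        return x0, x0 + self.lane_width_px

    @property
    def image_width(self) -> int:
        n = self.lane_count
        return self.lane_gap_px + n * (self.lane_width_px + self.lane_gap_px)


@dataclass
class GelLaneTruth:
    """Ground truth of one rendered lane."""

    spec: FragmentSpec
    bands: list[dict]  # size_bp, mass, center_px, clipped
    mass_by_size: list[tuple[float, float]]  # rendering quanta
    clipped: bool = False

    def category_masses(self, bounds: tuple[float, float] = (200.0, 500.0)) -> dict[str, float]:
        """True mass per fragment-size category (middle interval closed)."""
        lo, hi = bounds
        out = {"<200": 0.0, "200-500": 0.0, ">500": 0.0}
        for size, mass in self.mass_by_size:
            if size < lo:
                out["<200"] += mass
            elif size <= hi:
                out["200-500"] += mass
            else:
                out[">500"] += mass
        return out


@dataclass
class GelTruth:
    params: GelSimParams
    lanes: list[GelLaneTruth]

    def lane_bounds(self, lane: int) -> tuple[int, int]:
        return self.params.lane_bounds(lane)


def render_gel(params: GelSimParams) -> tuple[np.ndarray, GelTruth]:
    """Render a gel image (bands bright on dark background) with truth.

    Each mass quantum becomes a discrete Gaussian profile (sigma
    ``band_sigma_px``, normalized to its mass in mean-lane-profile units)
    centered at its model migration distance; additive background and
    Gaussian noise follow. Quanta migrating outside the image raise a
    warning and are flagged ``clipped`` in the truth.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.image_height, params.image_width
    img = np.full((H, W), float(params.background_level))
    rows = np.arange(H)
    lanes: list[GelLaneTruth] = []
    for i, spec in enumerate(params.lane_specs):
        profile = np.zeros(H)
        quanta = spec.mass_by_size()
        bands = []
        lane_clipped = False
        for size, mass in quanta:
            center = float(params.migration_distance(size))
            clipped = not (0.0 <= center <= H - 1)
            kernel = np.exp(-((rows - center) ** 2) / (2.0 * params.band_sigma_px**2))
            ksum = kernel.sum()
            full_sum = params.band_sigma_px * math.sqrt(2 * math.pi)
            if ksum >= 0.99 * full_sum:
                # fully on the image: normalize to exactly `mass`
                profile += mass * kernel / ksum
            elif ksum > 0:
                # partially off the image: deposit only the visible share
                clipped = True
                profile += mass * kernel / full_sum
            else:
                clipped = True
            if clipped:
                lane_clipped = True
            if spec.kind != "smear":
                bands.append(
                    {"size_bp": size, "mass": mass, "center_px": center, "clipped": clipped}
                )
        if lane_clipped:
            warnings.warn(
                f"lane {i}: some fragments migrate outside the image and were clipped",
                stacklevel=2,
            )
        x0, x1 = params.lane_bounds(i)
        img[:, x0:x1] += profile[:, None]
        lanes.append(
            GelLaneTruth(spec=spec, bands=bands, mass_by_size=quanta, clipped=lane_clipped)
        )
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=(H, W))
    img = np.clip(img, 0.0, None)
    return img, GelTruth(params=params, lanes=lanes)
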