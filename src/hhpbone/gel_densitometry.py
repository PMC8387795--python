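"""Lane densitometry, band calling and fragment-size quantification.

Mirrors a standard gel-documentation workflow: a lane's densitogram is the
column-mean of the (bright-band) image over the lane bounds; a rolling
baseline (morphological grey opening) is subtracted; bands are prominence-
filtered peaks whose volume is the summed corrected signal over the band's
support; remaining above-level signal runs are called as smears. A
monotone log-linear fit against a 100-bp ladder maps migration distance to
fragment size, and per-lane volumes are summed into the three fragment
categories <200 bp, 200-500 bp and >500 bp, optionally expressed relative
to an untreated control lane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import binary_closing, gaussian_filter1d, grey_opening

from .exceptions import CalibrationError, ConfigError, PairingError

__all__ = [
    "CATEGORIES",
    "CATEGORY_BOUNDS_BP",
    "LaneProfile",
    "BandCall",
    "LadderCalibration",
    "CategoryQuantification",
    "RelativeQuantification",
    "category_of",
    "extract_lane_profile",
    "estimate_profile_noise",
    "subtract_baseline",
    "detect_bands",
    "detect_smear",
    "calibrate_ladder",
    "categorize_fragments",
    "relative_to_control",
]

#: Fragment-size categories, largest first (the order used in the figures:
#: category 1 = >500 bp, category 2 = 200-500 bp, category 3 = <200 bp).
CATEGORIES: tuple[str, str, str] = (">500", "200-500", "<200")

#: Category boundaries in bp; the middle interval is closed ([200, 500]).
CATEGORY_BOUNDS_BP: tuple[float, float] = (200.0, 500.0)


def category_of(size_bp: float) -> str:
    lo, hi = CATEGORY_BOUNDS_BP
    if size_bp < lo:
        return "<200"
    if size_bp <= hi:
        return "200-500"
    return ">500"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LaneProfile:
    """1-D densitogram of one lane (intensity vs migration distance)."""

    signal: np.ndarray  # background-corrected (or raw) intensity, >= 0
    raw_signal: np.ndarray
    lane_id: str = ""

    def __len__(self) -> int:
        return len(self.signal)


@dataclass
class BandCall:
    """One detected band (or smear) on a lane profile.

    ``extent_px`` is the half-prominence (FWHM-like) extent reported for
    the band; ``support_px`` is the wider half-open interval over which
    ``volume`` integrates the corrected signal (peak bases clipped at
    midpoints to neighbouring bands), so that band + smear volumes add up
    to the whole lane signal.
    """

    center_px: float
    extent_px: tuple[int, int]  # [start, end)
    support_px: tuple[int, int]  # [start, end)
    volume: float
    size_bp: float | None = None
    is_smear: bool = False
    is_wide: bool = False
    #: per-row signal over the support as measured at call time (smears:
    #: the residual after band removal); used for row-wise apportionment
    row_signal: np.ndarray | None = None

    @property
    def width_px(self) -> int:
        return self.extent_px[1] - self.extent_px[0]


@dataclass
class LadderCalibration:
    """Monotone log-linear map between migration distance and size.

    ``distance = intercept - slope * log10(size_bp)`` with slope > 0.
    """

    intercept: float  # a
    slope: float  # b
    rung_table: list[tuple[float, float]]  # (distance_px, size_bp)
    residual: float  # max abs fit residual (px)

    def distance_of(self, size_bp: float | np.ndarray) -> float | np.ndarray:
        return self.intercept - self.slope * np.log10(size_bp)

    def size_of(self, distance_px: float | np.ndarray) -> float | np.ndarray:
        return 10.0 ** ((self.intercept - distance_px) / self.slope)


@dataclass
class CategoryQuantification:
    """Per-lane volume sums and fractions over the three size categories."""

    volumes: dict[str, float]
    fractions: dict[str, float]
    lane_id: str = ""

    @property
    def total(self) -> float:
        return sum(self.volumes.values())


@dataclass
class RelativeQuantification:
    """Treated-vs-control percentages per category (control = 100%)."""

    percentages: dict[str, float]  # NaN where undefined
    undefined: set[str] = dc_field(default_factory=set)
    lane_id: str = ""


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def extract_lane_profile(
    gel: np.ndarray,
    lane_bounds: tuple[int, int],
    lane_id: str = "",
    invert: bool | str = "auto",
    smooth_px: float = 0.0,
) -> LaneProfile:
    """Mean-intensity densitogram over a half-open column interval.

    Quantification happens on the bright-band image. With
    ``invert="auto"`` the polarity is guessed from the background: a
    median above midrange means dark bands on a light background, and the
    image is flipped. ``smooth_px`` applies a 1-D Gaussian to the signal
    (mass-conserving), which suppresses pixel noise on dim lanes; the raw
    profile is always kept unsmoothed.
    """
    gel = np.asarray(gel, dtype=float)
    c0, c1 = lane_bounds
    if not (0 <= c0 < c1 <= gel.shape[1]):
        raise ConfigError(f"lane bounds {lane_bounds!r} outside image width {gel.shape[1]}")
    if invert == "auto":
        invert = bool(np.median(gel) > 0.5 * (gel.min() + gel.max()))
    work = (gel.max() - gel) if invert else gel
    raw = gel[:, c0:c1].mean(axis=1)
    signal_ = work[:, c0:c1].mean(axis=1)
    if smooth_px > 0:
        signal_ = gaussian_filter1d(signal_, smooth_px, mode="nearest")
    return LaneProfile(signal=signal_, raw_signal=raw, lane_id=lane_id)


def estimate_profile_noise(p: LaneProfile, smooth_px: float = 0.0) -> float:
    """Robust noise sigma of the (possibly smoothed) profile.

    Pixel noise is estimated from the *raw* profile via the MAD of first
    differences (immune to sparse bands), then scaled by the variance
    reduction of a 1-D Gaussian smooth of width ``smooth_px``:
    ``sigma_smoothed = sigma_raw / sqrt(2*sqrt(pi)*s)`` for white noise.
    """
    d = np.diff(np.asarray(p.raw_signal, dtype=float))
    if len(d) == 0:
        return 0.0
    sigma_raw = float(1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0))
    if smooth_px > 0:
        sigma_raw /= math.sqrt(2.0 * math.sqrt(math.pi) * smooth_px)
    return sigma_raw


def subtract_baseline(
    p: LaneProfile, window_px: int = 251, presmooth_px: float = 0.0
) -> LaneProfile:
    """Subtract a rolling-minimum (grey-opening) baseline, clipping at 0.

    The opening (minimum filter followed by maximum filter, same window)
    removes every structure narrower than ``window_px`` while leaving
    monotone background ramps in place, so band volumes survive and ramps
    cancel. The window must therefore exceed the widest genuine feature
    (smears included). On noisy profiles a light Gaussian presmooth
    (``presmooth_px`` > 0) of the baseline input keeps the opening from
    tracking noise minima; the baseline is still subtracted from the
    unsmoothed signal so volumes stay unbiased.
    """
    if window_px < 3:
        raise ConfigError("window_px must be >= 3")
    if window_px > len(p.signal):
        raise ConfigError(f"window {window_px} longer than profile ({len(p.signal)})")
    base_input = (
        gaussian_filter1d(p.signal, presmooth_px) if presmooth_px > 0 else p.signal
    )
    # odd-reflection padding continues boundary trends, so the opening
    # tracks a background ramp all the way to the profile ends
    padded = np.pad(base_input, window_px, mode="reflect", reflect_type="odd")
    baseline = grey_opening(padded, size=window_px)[window_px:-window_px]
    corrected = np.clip(p.signal - baseline, 0.0, None)
    return LaneProfile(signal=corrected, raw_signal=p.raw_signal, lane_id=p.lane_id)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Subpixel peak center via a 3-point parabola."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i + np.clip(delta, -0.5, 0.5))


def _local_base(y: np.ndarray, window_px: int) -> np.ndarray:
    """Broad-structure floor under narrow bands: grey opening at band scale.

    Structures narrower than ``window_px`` (bands) are removed; broad
    structure (smears, residual background) survives, so ``y - base``
    isolates the bands' own mass.
    """
    return grey_opening(y, size=window_px, mode="nearest")


def detect_bands(
    p: LaneProfile,
    min_prominence: float,
    min_width_px: float = 2.0,
    max_width_px: float | None = None,
    wide_factor: float = 4.0,
    local_base_window_px: int | None = None,
) -> list[BandCall]:
    """Call one band per prominent peak of the corrected profile.

    The reported extent is the region above half the peak prominence; the
    integration support runs between the peak's bases, clipped at the
    midpoints to neighbouring peaks so no signal is counted twice. Bands
    whose half-prominence extent exceeds ``wide_factor * min_width_px``
    are flagged wide (typically unresolved merged bands). With
    ``max_width_px`` set, peaks broader than that at half prominence are
    not discrete bands at all (e.g. the broad hump of a smear) and are
    left for :func:`detect_smear` to pick up.

    With ``local_base_window_px`` set, detection and volumes use the
    signal above a grey-opening local base of that window, so a band
    riding on a smear is called with its own mass only; pass the same
    window to :func:`detect_smear` so the smear keeps the base mass.
    """
    y = np.asarray(p.signal, dtype=float)
    if len(y) == 0 or y.max() <= 0:
        return []
    if local_base_window_px is not None:
        y = np.clip(y - _local_base(y, local_base_window_px), 0.0, None)
        if y.max() <= 0:
            return []
    peaks, props = sps.find_peaks(y, prominence=min_prominence, width=min_width_px)
    if len(peaks) == 0:
        return []
    widths = sps.peak_widths(y, peaks, rel_height=0.5)
    keep = np.ones(len(peaks), dtype=bool)
    if max_width_px is not None:
        keep = widths[0] <= max_width_px
    peaks_kept = peaks[keep]
    bands: list[BandCall] = []
    lbases = props["left_bases"][keep]
    rbases = props["right_bases"][keep]
    starts_hp = widths[2][keep]
    ends_hp = widths[3][keep]
    widths_hp = widths[0][keep]
    for k, peak in enumerate(peaks_kept):
        start = int(math.floor(starts_hp[k]))
        end = int(math.ceil(ends_hp[k])) + 1
        lo, hi = int(lbases[k]), int(rbases[k]) + 1
        # a band's mass lives within a few FWHM of its center; capping the
        # support there keeps a narrow peak riding on a broad smear from
        # swallowing the smear's signal
        cap = 3.0 * max(widths_hp[k], min_width_px)
        lo = max(lo, int(math.floor(peak - cap)))
        hi = min(hi, int(math.ceil(peak + cap)) + 1)
        if k > 0:
            lo = max(lo, int(round(0.5 * (peaks_kept[k - 1] + peak))))
        if k < len(peaks_kept) - 1:
            hi = min(hi, int(round(0.5 * (peak + peaks_kept[k + 1]))))
        lo, hi = max(0, lo), min(len(y), hi)
        volume = float(y[lo:hi].sum())
        bands.append(
            BandCall(
                center_px=_parabolic_refine(y, int(peak)),
                extent_px=(start, end),
                support_px=(lo, hi),
                volume=volume,
                is_wide=(end - start) > wide_factor * min_width_px,
            )
        )
    return bands


def detect_smear(
    p: LaneProfile,
    bands: list[BandCall],
    smear_min_run_px: int = 20,
    level: float | None = None,
    bridge_px: int = 5,
    mask_smooth_px: float = 4.0,
    local_base_window_px: int | None = None,
) -> list[BandCall]:
    """Append smear calls for long above-level runs outside band signal.

    ``level`` defaults to 5% of the profile maximum. The above-level mask
    is taken on a ``mask_smooth_px``-smoothed copy of the signal (smears
    are broad, so heavy smoothing only stabilizes the mask against noise);
    volumes are still summed from the unsmoothed signal. Gaps up to
    ``bridge_px`` rows are closed before runs are measured.

    Without ``local_base_window_px``, band supports are punched out of
    the mask, so a smear is split around an embedded band and never
    double-counts band signal. With it (matching the window used in
    :func:`detect_bands`), band rows instead contribute the grey-opening
    local base — the smear surface under the band — so a smear overlapping
    a band keeps its own mass, the band keeps only its above-base mass,
    and the totals still add up. Returns the input band list with smear
    calls appended.
    """
    y = np.asarray(p.signal, dtype=float)
    if len(y) == 0 or y.max() <= 0:
        return list(bands)
    if local_base_window_px is not None:
        base = _local_base(y, local_base_window_px)
        y = y.copy()
        for b in bands:
            lo, hi = b.support_px
            y[lo:hi] = base[lo:hi]
    y_mask = gaussian_filter1d(y, mask_smooth_px) if mask_smooth_px > 0 else y
    if level is None:
        level = 0.05 * y_mask.max()
    free = y_mask > level
    if bridge_px > 0:
        free = binary_closing(free, structure=np.ones(bridge_px + 1, dtype=bool))
    if local_base_window_px is None:
        for b in bands:
            lo, hi = b.support_px
            free[lo:hi] = False
    out = list(bands)
    padded = np.concatenate([[False], free, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(padded[:-1] & ~padded[1:])[0]
    for s, e in zip(starts, ends):
        if e - s <= smear_min_run_px:
            continue
        seg = y[s:e]
        if seg.sum() <= 0:
            continue
        center = float(s + np.average(np.arange(e - s), weights=seg))
        out.append(
            BandCall(
                center_px=center,
                extent_px=(int(s), int(e)),
                support_px=(int(s), int(e)),
                volume=float(seg.sum()),
                is_smear=True,
                row_signal=seg.copy(),
            )
        )
    return out


def calibrate_ladder(
    ladder_bands: list[BandCall], rung_sizes: list[float]
) -> LadderCalibration:
    """Least-squares log-linear fit of migration distance vs rung size.

    Bands and rungs are paired top-down: the slowest band (smallest
    migration distance) gets the largest rung. At least 3 rungs are
    required and the pairing must be strictly monotone.
    """
    bands = sorted((b for b in ladder_bands if not b.is_smear), key=lambda b: b.center_px)
    sizes = sorted(rung_sizes, reverse=True)
    if len(sizes) < 3 or len(bands) < 3:
        raise CalibrationError(
            f"need >= 3 matched rungs, got {len(bands)} bands / {len(sizes)} rungs"
        )
    if len(bands) != len(sizes):
        raise PairingError(f"{len(bands)} bands cannot pair with {len(sizes)} rungs")
    centers = np.array([b.center_px for b in bands])
    if np.any(np.diff(centers) <= 0):
        raise PairingError("band centers are not strictly increasing")
    x = np.log10(np.asarray(sizes, dtype=float))
    coef = np.polyfit(x, centers, 1)  # centers ~ coef[0]*x + coef[1]
    slope_b = -coef[0]
    intercept_a = coef[1]
    if slope_b <= 0:
        raise PairingError("fitted mobility is not decreasing in fragment size")
    fitted = intercept_a - slope_b * x
    residual = float(np.max(np.abs(fitted - centers)))
    return LadderCalibration(
        intercept=float(intercept_a),
        slope=float(slope_b),
        rung_table=list(zip(centers.tolist(), [float(s) for s in sizes])),
        residual=residual,
    )


def categorize_fragments(
    bands: list[BandCall],
    cal: LadderCalibration,
    smear_mode: str = "apportion",
    profile: LaneProfile | None = None,
    lane_id: str = "",
) -> CategoryQuantification:
    """Sum band volumes into the <200 / 200-500 / >500 bp categories.

    A discrete band contributes its whole volume to the category of its
    center size. Smears are apportioned by integrating the profile over
    the smear extent row by row through the calibration (``apportion``,
    default), or — in ``compat`` mode — assigned wholesale to the category
    of their largest-size (uppermost) reach, reproducing how single-volume
    smear boxes behave in gel software.
    """
    if smear_mode not in {"apportion", "compat"}:
        raise ConfigError(f"unknown smear_mode {smear_mode!r}")
    volumes = {c: 0.0 for c in CATEGORIES}
    for b in bands:
        if not b.is_smear:
            size = b.size_bp if b.size_bp is not None else float(cal.size_of(b.center_px))
            b.size_bp = size
            volumes[category_of(size)] += b.volume
            continue
        lo, hi = b.extent_px
        if smear_mode == "compat":
            top_size = float(cal.size_of(lo))  # smallest distance = largest size
            b.size_bp = top_size
            volumes[category_of(top_size)] += b.volume
        else:
            if b.row_signal is not None:
                seg = np.asarray(b.row_signal, dtype=float)
            elif profile is not None:
                seg = np.asarray(profile.signal[lo:hi], dtype=float)
            else:
                raise ConfigError("apportion smear mode requires the lane profile")
            rows = np.arange(lo, hi)
            sizes = np.asarray(cal.size_of(rows + 0.5), dtype=float)
            for cat in CATEGORIES:
                sel = np.array([category_of(s) == cat for s in sizes])
                volumes[cat] += float(seg[sel].sum())
            b.size_bp = float(cal.size_of(b.center_px))
    total = sum(volumes.values())
    if total > 0:
        fractions = {c: v / total for c, v in volumes.items()}
    else:
        fractions = {c: 0.0 for c in CATEGORIES}
    return CategoryQuantification(volumes=volumes, fractions=fractions, lane_id=lane_id)


def relative_to_control(
    q_treated: CategoryQuantification, q_control: CategoryQuantification
) -> RelativeQuantification:
    """Per-category treated volume as a percentage of the control lane.

    Categories with zero control volume are flagged undefined (NaN), not
    silently infinite.
    """
    if set(q_treated.volumes) != set(q_control.volumes):
        raise ConfigError("treated and control quantifications use different categories")
    pct: dict[str, float] = {}
    undefined: set[str] = set()
    for cat in q_treated.volumes:
        c = q_control.volumes[cat]
        if c <= 0:
            pct[cat] = math.nan
            undefined.add(cat)
        else:
            pct[cat] = 100.0 * q_treated.volumes[cat] / c
    return RelativeQuantification(percentages=pct, undefined=undefined, lane_id=q_treated.lane_id)
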