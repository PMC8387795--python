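"""Shared plumbing: image/table I/O, run configuration, and the two
end-to-end pipelines (histology density mapping; gel quantification).

Every tunable of every stage lives in :class:`RunConfig`, which
round-trips losslessly through YAML; pipeline outputs are deterministic
functions of (config, seed) and each run writes a sidecar recording the
package version and a hash of the configuration. Nothing written here
embeds timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from matplotlib import colormaps

from . import __version__
from .band_ratios import alpha_chain_ratio, identify_alpha_bands, relative_expression
from .density_mapping import (
    DensityMap,
    center_edge_statistic,
    combine_map,
    compute_density_matrix,
    detect_cells,
    edge_corrected_density,
    estimate_sample_support,
    gaussian_normalize,
    merge_tiles,
    trabecular_mask,
)
from .exceptions import CalibrationError, ChannelMismatchError, ConfigError, HhpboneError
from .gel_densitometry import (
    CATEGORIES,
    calibrate_ladder,
    categorize_fragments,
    detect_bands,
    detect_smear,
    estimate_profile_noise,
    extract_lane_profile,
    relative_to_control,
    subtract_baseline,
)
from .synthetic import (
    GENE_RULER_100BP,
    FragmentSpec,
    GelSimParams,
    HistologySceneParams,
    generate_histology_scene,
    render_gel,
)

logger = logging.getLogger("hhpbone")

__all__ = [
    "LoadedImage",
    "load_image",
    "save_image",
    "HistologyStageConfig",
    "GelStageConfig",
    "RunConfig",
    "auto_lane_bounds",
    "run_histology_pipeline",
    "run_gel_pipeline",
]


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------


@dataclass
class LoadedImage:
    pixels: np.ndarray
    bit_depth: int
    path: str
    looks_inverted: bool  # dark features on light background?


def load_image(path: str | Path, expected_channels: int = 1) -> LoadedImage:
    """Read a TIFF or PNG as grayscale (or per-channel) array.

    Raises :class:`ChannelMismatchError` when e.g. an RGB image arrives
    where a single grayscale channel was expected, and a plain I/O error
    with the format detail for unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    try:
        if suffix in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        elif suffix == ".png":
            arr = iio.imread(path)
        else:
            raise ConfigError(f"unsupported image format {suffix!r} (need TIFF or PNG)")
    except (ConfigError, FileNotFoundError):
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise OSError(f"cannot read {path} as {suffix}: {exc}") from exc
    channels = 1 if arr.ndim == 2 else arr.shape[-1]
    if channels != expected_channels:
        raise ChannelMismatchError(
            f"{path}: expected {expected_channels} channel(s), found {channels}"
        )
    bit_depth = arr.dtype.itemsize * 8 if arr.dtype.kind in "ui" else 0
    vmin, vmax = float(arr.min()), float(arr.max())
    looks_inverted = bool(np.median(arr) > 0.5 * (vmin + vmax))
    return LoadedImage(
        pixels=arr, bit_depth=bit_depth, path=str(path), looks_inverted=looks_inverted
    )


def save_image(path: str | Path, arr: np.ndarray) -> None:
    """Write TIFF (any dtype) or PNG (uint8/uint16; floats are scaled)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
        return
    if suffix == ".png":
        if arr.dtype.kind == "f":
            top = arr.max()
            scaled = arr / top if top > 0 else arr
            arr = (np.clip(scaled, 0, 1) * 65535).astype(np.uint16)
        iio.imwrite(path, arr)
        return
    raise ConfigError(f"unsupported image format {suffix!r}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HistologyStageConfig:
    """Parameters of the histology pipeline (synthetic- or file-driven)."""

    scene: HistologySceneParams | None = None
    tile_manifest: str | None = None  # YAML: layout, overlap_px, dapi/tunel tile paths
    bin_size_px: float = 64.0
    sigma_bins: float = 2.0
    min_radius_px: float = 2.0
    max_radius_px: float = 5.0
    detect_threshold: float = 0.08
    tunel_threshold: float = 0.15
    inner_fraction: float = 0.15
    outer_fraction: float = 0.92
    edge_correction: bool = True
    save_heatmap: bool = True


@dataclass(frozen=True)
class GelStageConfig:
    """Parameters of the gel quantification pipeline."""

    sim: GelSimParams | None = None
    image_path: str | None = None
    lane_bounds: tuple[tuple[int, int], ...] | None = None  # None: auto-detect
    ladder_lane: int = 0
    control_lane: int | None = None
    ladder_sizes: tuple[float, ...] = GENE_RULER_100BP
    baseline_window_px: int = 251
    baseline_presmooth_px: float = 2.0
    profile_smooth_px: float = 1.5
    min_prominence_frac: float = 0.05  # of the lane's corrected maximum
    prominence_noise_mult: float = 4.0  # noise floor: mult * robust profile sigma
    min_width_px: float = 2.0
    max_band_width_px: float = 25.0
    band_local_base_window_px: int = 51
    smear_min_run_px: int = 20
    smear_level_frac: float = 0.05
    smear_level_noise_mult: float = 3.0
    smear_mask_smooth_px: float = 4.0
    smear_mode: str = "apportion"


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters, the seed, and the output directory."""

    seed: int = 0
    out_dir: str = "hhpbone_out"
    log_level: str = "INFO"
    alpha: float = 0.05
    histology: HistologyStageConfig = field(default_factory=HistologyStageConfig)
    gel: GelStageConfig = field(default_factory=GelStageConfig)

    # -- YAML round trip ----------------------------------------------
    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        hist = dict(d.pop("histology", {}))
        gel = dict(d.pop("gel", {}))
        if hist.get("scene") is not None:
            hist["scene"] = HistologySceneParams(**_tupled(hist["scene"], HistologySceneParams))
        if gel.get("sim") is not None:
            sim = dict(gel["sim"])
            sim["lane_specs"] = tuple(
                FragmentSpec(**_tupled(s, FragmentSpec)) for s in sim["lane_specs"]
            )
            gel["sim"] = GelSimParams(**_tupled(sim, GelSimParams, skip={"lane_specs"}))
        if gel.get("lane_bounds") is not None:
            gel["lane_bounds"] = tuple(tuple(b) for b in gel["lane_bounds"])
        gel["ladder_sizes"] = tuple(gel.get("ladder_sizes", GENE_RULER_100BP))
        return cls(
            histology=HistologyStageConfig(**_tupled(hist, HistologyStageConfig, skip={"scene"})),
            gel=GelStageConfig(**{**gel}),
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples to lists so YAML stays readable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        obj = float(obj)
        return None if math.isnan(obj) else obj
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _tupled(d: dict, cls, skip: set[str] = frozenset()) -> dict:
    """Convert YAML lists back to the tuples the dataclasses expect."""
    out = {}
    hints = {f.name: f.type for f in dataclasses.fields(cls)}
    for k, v in d.items():
        if k in skip or k not in hints:
            out[k] = v
            continue
        if isinstance(v, list) and "tuple" in str(hints[k]):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True))


def _heatmap_png(path: Path, values: np.ndarray) -> None:
    """Colormapped PNG of a density grid (NaN bins rendered black)."""
    finite = np.isfinite(values)
    top = values[finite].max() if finite.any() else 1.0
    norm = np.where(finite, values / top if top > 0 else values, 0.0)
    rgba = (colormaps["inferno"](np.clip(norm, 0, 1)) * 255).astype(np.uint8)
    rgba[~finite] = (0, 0, 0, 255)
    iio.imwrite(path, rgba)


def _sidecar(out: Path, config: RunConfig) -> None:
    # the output location is environment, not analysis: normalize it so
    # reruns of the same analysis are byte-identical wherever they land
    recorded = dataclasses.replace(config, out_dir=".")
    _write_json(
        out / "meta.json",
        {"package": "hhpbone", "version": __version__, "config_hash": recorded.content_hash()},
    )
    recorded.to_yaml(out / "config.yaml")


def run_histology_pipeline(config: RunConfig) -> tuple[DensityMap, dict]:
    """Merge -> detect -> bin -> smooth -> mask -> map -> gradient statistic.

    Every intermediate is persisted under ``config.out_dir``. Deterministic
    given (config, seed).
    """
    hc = config.histology
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("histology pipeline -> %s (seed=%d)", out, config.seed)

    try:
        if hc.scene is not None:
            scene = dataclasses.replace(hc.scene, seed=config.seed)
            tunel_tiles, dapi_tiles, _truth = generate_histology_scene(scene)
            layout, overlap = scene.tile_grid, 0
        elif hc.tile_manifest is not None:
            manifest = yaml.safe_load(Path(hc.tile_manifest).read_text())
            layout = tuple(manifest["layout"])
            overlap = int(manifest.get("overlap_px", 0))
            base = Path(hc.tile_manifest).parent
            dapi_tiles = [load_image(base / p).pixels.astype(float) for p in manifest["dapi"]]
            tunel_tiles = [load_image(base / p).pixels.astype(float) for p in manifest["tunel"]]
        else:
            raise ConfigError("histology config needs either a scene or a tile manifest")
        dapi = merge_tiles(dapi_tiles, layout, overlap)
        tunel = merge_tiles(tunel_tiles, layout, overlap)

        dets = detect_cells(
            dapi,
            tunel,
            min_radius_px=hc.min_radius_px,
            max_radius_px=hc.max_radius_px,
            detect_threshold=hc.detect_threshold,
            tunel_threshold=hc.tunel_threshold,
        )
        pd.DataFrame(
            {
                "x": dets.positions[:, 0],
                "y": dets.positions[:, 1],
                "tunel_positive": dets.tunel_positive,
                "tunel_intensity": dets.tunel_intensity,
            }
        ).to_csv(out / "detections.csv", index=False)

        H, W = dapi.shape
        matrix = compute_density_matrix(dets, hc.bin_size_px, region=(0.0, 0.0, float(W), float(H)))
        np.savetxt(out / "density_matrix.csv", matrix.bin_counts, fmt="%d", delimiter=",")
        smoothed = gaussian_normalize(matrix, hc.sigma_bins)
        np.savetxt(out / "smoothed_density.csv", smoothed.values, fmt="%.8g", delimiter=",")
        tmask = trabecular_mask(dapi)
        save_image(out / "trabecular_mask.png", tmask.mask.astype(np.uint8) * 255)
        if hc.edge_correction and len(dets):
            support = estimate_sample_support(
                dets, matrix.bin_counts.shape, matrix.bin_size_px, matrix.origin
            )
            density = edge_corrected_density(matrix, hc.sigma_bins, support)
        else:
            density = smoothed
        dmap = combine_map(density, tmask)
        np.savetxt(out / "density_map.csv", dmap.map, fmt="%.8g", delimiter=",")
        if hc.save_heatmap:
            _heatmap_png(out / "density_map.png", dmap.map)
        stat = center_edge_statistic(
            dmap, inner_fraction=hc.inner_fraction, outer_fraction=hc.outer_fraction
        )
        report = {
            "n_detections": int(len(dets)),
            "n_tunel_positive": dets.n_positive,
            "otsu_threshold": tmask.threshold,
            "center_mean": stat.center_mean,
            "edge_mean": stat.edge_mean,
            "center_edge_ratio": stat.ratio,
            "radial_profile": [None if math.isnan(v) else v for v in stat.radial_profile],
        }
        _write_json(out / "report.json", report)
        _sidecar(out, config)
        return dmap, report
    except HhpboneError as exc:
        raise type(exc)(f"histology pipeline: {exc}") from exc


def auto_lane_bounds(gel: np.ndarray, min_lane_width_px: int = 5) -> list[tuple[int, int]]:
    """Detect lane column intervals by column-sum valley finding.

    Columns whose summed (bright-band) intensity exceeds the midpoint
    between the background floor and the maximum are lane columns;
    contiguous runs wider than ``min_lane_width_px`` become lanes.
    """
    colsum = np.asarray(gel, dtype=float).sum(axis=0)
    lo, hi = colsum.min(), colsum.max()
    if hi <= lo:
        return []
    above = colsum > lo + 0.25 * (hi - lo)
    padded = np.concatenate([[False], above, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(padded[:-1] & ~padded[1:])[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_lane_width_px]


def run_gel_pipeline(config: RunConfig) -> dict:
    """Ladder calibration + per-lane band/smear calling + categorization.

    Returns a dict with the band table, per-lane category quantification
    and relative-to-control percentages; all three are persisted as CSV.
    Lanes without detectable bands are reported empty and the pipeline
    continues.
    """
    gc = config.gel
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("gel pipeline -> %s (seed=%d)", out, config.seed)

    try:
        if gc.sim is not None:
            params = dataclasses.replace(gc.sim, seed=config.seed)
            gel, truth = render_gel(params)
            bounds = [params.lane_bounds(i) for i in range(params.lane_count)]
            save_image(out / "gel.png", gel)
        elif gc.image_path is not None:
            gel = load_image(gc.image_path).pixels.astype(float)
            truth = None
            bounds = list(gc.lane_bounds) if gc.lane_bounds else auto_lane_bounds(gel)
        else:
            raise ConfigError("gel config needs either sim parameters or an image path")
        if gc.ladder_lane >= len(bounds):
            raise CalibrationError(
                f"ladder lane {gc.ladder_lane} missing (found {len(bounds)} lanes)"
            )

        profiles = {}
        for i, b in enumerate(bounds):
            p = extract_lane_profile(
                gel, b, lane_id=f"lane{i}", smooth_px=gc.profile_smooth_px
            )
            profiles[i] = subtract_baseline(
                p, window_px=gc.baseline_window_px, presmooth_px=gc.baseline_presmooth_px
            )

        def _prominence(profile):
            top = profile.signal.max()
            floor = gc.prominence_noise_mult * estimate_profile_noise(
                profile, gc.profile_smooth_px
            )
            return max(gc.min_prominence_frac * top, floor) if top > 0 else 1.0

        ladder_profile = profiles[gc.ladder_lane]
        ladder_bands = detect_bands(
            ladder_profile,
            min_prominence=_prominence(ladder_profile),
            min_width_px=gc.min_width_px,
            max_width_px=gc.max_band_width_px,
            local_base_window_px=gc.band_local_base_window_px,
        )
        cal = calibrate_ladder(ladder_bands, list(gc.ladder_sizes))

        band_rows = []
        quants = {}
        for i, profile in profiles.items():
            if i == gc.ladder_lane:
                continue
            top = profile.signal.max()
            bands = detect_bands(
                profile,
                min_prominence=_prominence(profile),
                min_width_px=gc.min_width_px,
                max_width_px=gc.max_band_width_px,
                local_base_window_px=gc.band_local_base_window_px,
            )
            level = None
            if top > 0:
                mask_sigma = math.hypot(gc.profile_smooth_px, gc.smear_mask_smooth_px)
                level = max(
                    gc.smear_level_frac * top,
                    gc.smear_level_noise_mult
                    * estimate_profile_noise(profile, mask_sigma),
                )
            bands = detect_smear(
                profile,
                bands,
                smear_min_run_px=gc.smear_min_run_px,
                level=level,
                mask_smooth_px=gc.smear_mask_smooth_px,
                local_base_window_px=gc.band_local_base_window_px,
            )
            quants[i] = categorize_fragments(
                bands, cal, smear_mode=gc.smear_mode, profile=profile, lane_id=f"lane{i}"
            )
            for b in bands:
                band_rows.append(
                    {
                        "lane": i,
                        "center_px": b.center_px,
                        "size_bp": b.size_bp,
                        "volume": b.volume,
                        "is_smear": b.is_smear,
                        "extent_start": b.extent_px[0],
                        "extent_end": b.extent_px[1],
                    }
                )
        bands_df = pd.DataFrame(
            band_rows,
            columns=["lane", "center_px", "size_bp", "volume", "is_smear",
                     "extent_start", "extent_end"],
        )
        bands_df.to_csv(out / "bands.csv", index=False)
        cat_df = pd.DataFrame(
            [
                {
                    "lane": i,
                    **{f"volume_{c}": q.volumes[c] for c in CATEGORIES},
                    **{f"fraction_{c}": q.fractions[c] for c in CATEGORIES},
                }
                for i, q in sorted(quants.items())
            ]
        )
        cat_df.to_csv(out / "categories.csv", index=False)

        relatives = {}
        if gc.control_lane is not None and gc.control_lane in quants:
            control = quants[gc.control_lane]
            for i, q in quants.items():
                if i == gc.control_lane:
                    continue
                relatives[i] = relative_to_control(q, control)
            pd.DataFrame(
                [
                    {"lane": i, **{f"pct_{c}": r.percentages[c] for c in CATEGORIES}}
                    for i, r in sorted(relatives.items())
                ]
            ).to_csv(out / "relative.csv", index=False)

        report = {
            "calibration": {
                "intercept": cal.intercept,
                "slope": cal.slope,
                "residual_px": cal.residual,
            },
            "n_lanes": len(bounds),
            "lanes_empty": [i for i, q in quants.items() if q.total == 0],
        }
        _write_json(out / "report.json", report)
        _sidecar(out, config)
        return {
            "bands": bands_df,
            "categories": quants,
            "relative": relatives,
            "calibration": cal,
            "truth": truth,
            "report": report,
        }
    except HhpboneError as exc:
        raise type(exc)(f"gel pipeline: {exc}") from exc


# Re-exported for the CLI's ratio subcommands; keeps one import site.
__all__ += ["relative_expression", "alpha_chain_ratio", "identify_alpha_bands"]
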