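"""Reference synthetic study protocols.

These functions bundle the package's end-to-end workflows into the fixed
study designs used for validation: the collagen-stoichiometry check on a
synthetic SDS-PAGE, and the center/edge gradient-recovery study over a
batch of synthetic histology scenes. They exist so that scripts and tests
exercise exactly the same pipelines with exactly the same designs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np

from .band_ratios import alpha_chain_ratio, identify_alpha_bands
from .gel_densitometry import (
    calibrate_ladder,
    detect_bands,
    extract_lane_profile,
    subtract_baseline,
)
from .io import HistologyStageConfig, RunConfig, run_histology_pipeline
from .synthetic import (
    FragmentSpec,
    GelSimParams,
    HistologySceneParams,
    ladder_lane_spec,
    render_gel,
)

__all__ = [
    "PROTEIN_MARKER_KD",
    "alpha_stoichiometry_ratio",
    "gradient_recovery_study",
]

#: Apparent molecular weights (kD) of a dual-color protein standard.
PROTEIN_MARKER_KD: tuple[float, ...] = (250.0, 150.0, 100.0, 75.0, 50.0, 37.0, 25.0)


def collagen_sds_page_params(seed: int = 0, alpha1_mass: float = 600.0) -> GelSimParams:
    """Synthetic SDS-PAGE: marker lane plus a bone-lysate lane.

    The sample lane carries one high-molecular-weight band and the two
    collagen alpha-chain bands with planted masses in the 2:1
    stoichiometry of collagen type I (alpha-1 twice alpha-2).
    """
    sample = FragmentSpec.explicit_bands(
        [(300.0, 500.0), (130.0, alpha1_mass), (115.0, alpha1_mass / 2.0)]
    )
    return GelSimParams(
        lane_specs=(ladder_lane_spec(PROTEIN_MARKER_KD, mass_per_rung=100.0), sample),
        ladder_sizes=PROTEIN_MARKER_KD,
        migration_coeffs=(780.0, 300.0),
        band_sigma_px=2.5,
        noise_sd=0.0,
        seed=seed,
    )


def alpha_stoichiometry_ratio(seed: int = 0) -> float:
    """Alpha-1/alpha-2 band-volume ratio from the full densitometry path.

    Renders the collagen SDS-PAGE, runs lane extraction, baseline
    subtraction, band detection, marker calibration and alpha-pair
    identification, and returns the measured chain ratio (expected: 2).
    """
    params = collagen_sds_page_params(seed=seed)
    gel, _ = render_gel(params)
    marker = subtract_baseline(extract_lane_profile(gel, params.lane_bounds(0)))
    cal = calibrate_ladder(
        detect_bands(marker, min_prominence=0.1 * marker.signal.max()),
        list(PROTEIN_MARKER_KD),
    )
    sample = subtract_baseline(extract_lane_profile(gel, params.lane_bounds(1)))
    bands = detect_bands(sample, min_prominence=0.05 * sample.signal.max())
    a1, a2 = identify_alpha_bands(bands, max_gap_px=25.0, mw_calibration=cal)
    return alpha_chain_ratio(a1.volume, a2.volume).ratio


def gradient_scene(center_edge_ratio: float, seed: int) -> HistologySceneParams:
    """Standard scene for the gradient-recovery study.

    A 1280x1280 merged field (2x2 tiles) with 2,000 nuclei; the edge rate
    is fixed at 1.2 expected TUNEL-positive cells per 64-px rate bin and
    the center rate scales with the requested ratio.
    """
    edge_rate = 1.2
    return HistologySceneParams(
        image_shape=(640, 640),
        tile_grid=(2, 2),
        n_cells=2000,
        center_rate=edge_rate * center_edge_ratio,
        edge_rate=edge_rate,
        nucleus_radius_px=2.5,
        rate_grid=(20, 20),
        texture_scale_px=16.0,
        seed=seed,
    )


def gradient_stage_config(scene: HistologySceneParams) -> HistologyStageConfig:
    return HistologyStageConfig(
        scene=scene, bin_size_px=16.0, tunel_threshold=0.25, save_heatmap=False
    )


def gradient_recovery_study(
    master_seed: int = 0,
    n_per_ratio: dict[float, int] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Recover planted center/edge ratios over a batch of scenes.

    Runs the full histology pipeline on scenes planted with ratios
    {1, 2, 4} and pools center- and edge-zone means per ratio group (the
    replicate-averaged estimator). Returns per-group pooled ratio
    estimates and the per-scene values.
    """
    if n_per_ratio is None:
        n_per_ratio = {1.0: 4, 2.0: 4, 4.0: 12}
    plan = [r for r, n in n_per_ratio.items() for _ in range(n)]
    seeds = [
        int(s) % (2**31)
        for s in np.random.SeedSequence(master_seed).generate_state(len(plan))
    ]
    per_scene: dict[float, list[dict]] = {r: [] for r in n_per_ratio}

    def run_all(base: Path) -> None:
        for k, (ratio, seed) in enumerate(zip(plan, seeds)):
            scene = gradient_scene(ratio, seed)
            cfg = RunConfig(
                seed=seed,
                out_dir=str(base / f"scene_{k:02d}"),
                histology=gradient_stage_config(scene),
            )
            _, report = run_histology_pipeline(cfg)
            per_scene[ratio].append(report)

    if out_dir is None:
        with TemporaryDirectory() as td:
            run_all(Path(td))
    else:
        run_all(Path(out_dir))

    pooled = {}
    for ratio, reports in per_scene.items():
        c = float(np.mean([r["center_mean"] for r in reports]))
        e = float(np.mean([r["edge_mean"] for r in reports]))
        pooled[ratio] = c / e
    return {
        "pooled_ratio": pooled,
        "per_scene_ratio": {
            r: [rep["center_edge_ratio"] for rep in reps]
            for r, reps in per_scene.items()
        },
    }
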