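import dataclasses
import math

import numpy as np
import pytest

from hhpbone.gel_densitometry import extract_lane_profile
from hhpbone.synthetic import (
    FragmentSpec,
    GelSimParams,
    HistologySceneParams,
    generate_histology_scene,
    ladder_lane_spec,
    render_gel,
)


@pytest.fixture(scope="session")
def small_scene():
    """One 512x512 scene (2x2 tiles of 256) with 200 cells, SNR 10."""
    params = HistologySceneParams(
        image_shape=(256, 256),
        tile_grid=(2, 2),
        n_cells=200,
        center_rate=0.8,
        edge_rate=0.2,
        rate_grid=(16, 16),
        seed=11,
    )
    tunel_tiles, dapi_tiles, truth = generate_histology_scene(params)
    return params, tunel_tiles, dapi_tiles, truth


@pytest.fixture(scope="session")
def dna_gel():
    """Noiseless four-lane DNA gel: ladder, intact, 180-bp ladder, smear."""
    params = GelSimParams(
        lane_specs=(
            ladder_lane_spec(),
            FragmentSpec.intact_control(1500.0),
            FragmentSpec.nucleosomal_ladder(),
            FragmentSpec.smear_range(200.0, 2000.0),
        ),
        seed=5,
    )
    gel, truth = render_gel(params)
    return params, gel, truth


def gel_with_profile_snr(base: GelSimParams, snr: float | None, seed: int):
    """Re-render a gel with image noise set so the weakest lane's peak
    densitogram signal is ``snr`` times the densitogram noise sigma."""
    gel0, _ = render_gel(dataclasses.replace(base, noise_sd=0.0, seed=seed))
    peaks = [
        extract_lane_profile(gel0, base.lane_bounds(i)).signal.max()
        for i in range(base.lane_count)
    ]
    if snr is None:
        return dataclasses.replace(base, noise_sd=0.0, seed=seed)
    noise_img = float(min(peaks)) / snr * math.sqrt(base.lane_width_px)
    return dataclasses.replace(base, noise_sd=noise_img, seed=seed)
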