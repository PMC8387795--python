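# hhpbone

Computational analyses for studying cell death and matrix integrity in
high-hydrostatic-pressure (HHP) treated human trabecular bone. HHP
(here 250–300 MPa for 10–30 min) is a candidate method for devitalizing
bone allografts while preserving the extracellular matrix; the key
questions are *how* the resident cells die (apoptosis vs necrosis),
*where* in the sample they die, and whether structural proteins such as
collagen type I survive. This package implements the downstream image
and signal analyses those questions require, plus synthetic data
generators with full ground truth so every stage is testable without
access to raw microscopy or gel images.

## What it does

**Apoptotic density mapping** (`hhpbone.density_mapping`). From
two-channel fluorescence micrographs — TUNEL marking apoptotic nuclei,
DAPI counterstaining all nuclei *and* the DAPI-avid bone matrix — the
pipeline merges image tiles into a whole-sample image, detects nuclei as
Laplacian-of-Gaussian blobs, classifies them TUNEL-positive by mean
intensity in the nucleus disc, bins the positives into a spatial count
matrix, smooths it with a unit-sum 2-D Gaussian kernel, segments
trabecular bone by Otsu thresholding of the DAPI channel, and masks the
smoothed density onto the trabecular structure. A center/edge statistic
quantifies the radial gradient of apoptotic density:

    ratio = mean density (normalized radius <= 0.15) / mean density (radius >= 0.92)

**Gel densitometry** (`hhpbone.gel_densitometry`). Lane densitograms
are extracted as column means, background-corrected with a grey-opening
rolling baseline, and decomposed into discrete bands (prominence-filtered
peaks) and smears (long above-level runs). Fragment sizes come from a
log-linear mobility fit against a 100-bp ladder,
`distance = a − b·log₁₀(size)`. Per-lane band volumes are summed into
the DNA-fragmentation categories `<200 bp`, `200–500 bp`, `>500 bp`
(oligonucleosomal laddering at ~180 bp multiples indicates apoptosis; a
continuous smear indicates necrosis) and expressed relative to an
untreated control (control = 100%).

**Band ratios** (`hhpbone.band_ratios`). Relative gene expression as
treated/control band volume (absent band = "n.d.", not zero), and the
collagen alpha-1/alpha-2 chain ratio from SDS-PAGE band volumes, whose
stoichiometric expectation for intact collagen type I is 2.

**Statistics** (`hhpbone.stats`). Balanced two-way fixed-effects ANOVA
(treatment protocol × incubation time) with Bonferroni-adjusted
pooled-variance pairwise t tests; significance is inclusive at p ≤ 0.05.

**Synthetic data** (`hhpbone.synthetic`). Histology scenes (disc-shaped
sample, thresholded-random-field trabecular texture, TUNEL-positive
nuclei drawn as an inhomogeneous Poisson process from a radial rate
field) and gel images (Gaussian bands, continuous smears, ladder lanes,
additive noise), both with exact ground truth.

## Worked example

Quantify a synthetic DNA gel with an intact control lane and a lane of
oligonucleosomal (180-bp repeat) fragments:

```python
from hhpbone.synthetic import FragmentSpec, GelSimParams, ladder_lane_spec
from hhpbone.io import RunConfig, GelStageConfig, run_gel_pipeline

sim = GelSimParams(lane_specs=(
    ladder_lane_spec(),                     # 100-bp ladder (lane 0)
    FragmentSpec.intact_control(1500.0),    # untreated control (lane 1)
    FragmentSpec.nucleosomal_ladder(),      # apoptotic DNA (lane 2)
))
cfg = RunConfig(seed=1, out_dir="gel_run",
                gel=GelStageConfig(sim=sim, control_lane=1))
res = run_gel_pipeline(cfg)
for i, q in sorted(res["categories"].items()):
    print("lane", i, {k: round(v, 3) for k, v in q.fractions.items()})
```

prints

```
lane 1 {'>500': 1.0, '200-500': 0.0, '<200': 0.0}
lane 2 {'>500': 0.332, '200-500': 0.252, '<200': 0.416}
```

— the intact control runs entirely above 500 bp while the apoptotic lane
is dominated by sub-200-bp fragments, the classic laddering signature.
The ladder calibration report (`res["calibration"]`) shows the recovered
mobility model (intercept 720.00, slope 200.00, residual 0.08 px), and
`res["relative"]` gives per-category percentages of control; categories
in which the control lane holds no volume are flagged undefined rather
than reported as infinite.

The histology pipeline behaves the same way from a config:

```python
from hhpbone.synthetic import HistologySceneParams
from hhpbone.io import HistologyStageConfig, run_histology_pipeline

scene = HistologySceneParams(image_shape=(512, 512), tile_grid=(2, 2),
                             n_cells=2000, center_rate=4.8, edge_rate=1.2,
                             nucleus_radius_px=2.5, rate_grid=(16, 16),
                             texture_scale_px=16.0)
cfg = RunConfig(seed=1, out_dir="map_run",
                histology=HistologyStageConfig(scene=scene, bin_size_px=16.0,
                                               tunel_threshold=0.25))
dmap, report = run_histology_pipeline(cfg)
print(report["n_tunel_positive"], round(report["center_edge_ratio"], 2))
```

prints `424 2.81`: the scene was planted with a 4:1 center/edge
apoptotic rate gradient and the masked density map recovers a
center-weighted ratio well above 1 (single scenes are noisy; the
replicate-averaged study in `hhpbone.protocols` pools several).

Everything is also reachable from the shell:

```bash
hhpbone synth gel --seed 1 --out-dir gel_data
hhpbone map run --config config.yaml
hhpbone gel quant --config config.yaml
hhpbone ratios alpha --alpha1 200 --alpha2 100
hhpbone stats anova --csv observations.csv
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data assumptions,
parameter defaults and numerical choices in detail.
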