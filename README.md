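# arrayfret

Serial-section array-tomography and sensitized-emission FRET analysis,
with a fully synthetic ground-truth study so every stage is verifiable
without raw microscope data.

The pipeline mirrors how synapse-scale colocalization studies are run on
ribbons of 70 nm resin sections:

1. **synthetic** — renders multi-channel serial-section stacks
   (synaptic / donor / acceptor / raw-FRET channels) with known object
   placements, colocalization labels, bleed-through coefficients, an
   optional amyloid-plaque disk with a distance-density gradient,
   per-section misalignment and Poisson–Gaussian noise.
2. **registration** — rigid-then-affine alignment of consecutive
   sections (phase-correlation seed, Powell refinement), applied
   identically to every channel, with a validity mask for out-of-frame
   pixels.
3. **segmentation** — per-channel local-mean thresholding, 8-connected
   in-plane components linked across consecutive sections into 3D
   objects, a persistence filter (span ≥ 2 sections), and neuropil
   densities per mm³.
4. **colocalization** — object pairing by the ≥ 10 %-of-synapse overlap
   rule, restrictive plaque segmentation, and object densities binned in
   10 µm steps from the plaque edge (far-field reference bin ≥ 50 µm).
5. **fret** — β/γ bleed-through estimation from donor-only /
   acceptor-only control stacks, per-pixel correction
   `Fc = I_DA − β·I_DD − γ·I_AA`, and the percent of FRET-positive
   pixels inside donor ∩ acceptor ∩ synapse object masks.
6. **stats** — standardized effect size, noncentral-t power, the Tukey
   ladder-of-powers transform, receptor occupancy
   `100·(c/Ki)/((c/Ki)+1)`, and a `diagnosis*sex + (1|case/sample)`
   linear mixed model with containment-df F tests and Tukey-adjusted
   cell contrasts.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked
statistics examples, calibration/segmentation/registration/
colocalization recovery, FRET positive-vs-negative-control separation,
mixed-model type-I calibration). Brute-force oracles used by the tests
live in `tests/oracles.py`.

## CLI

```bash
arrayfret simulate --config config.yaml --outdir out/sim
arrayfret align    --indir out/sim/stack --outdir out/aligned --pixel-size 100
arrayfret segment  --indir out/aligned --outdir out/seg --channel synaptic --pixel-size 100
arrayfret coloc    --indir out/aligned --outdir out/coloc --pixel-size 100
arrayfret fret     --indir out/aligned --donor-only out/sim/donor_only \
                   --acceptor-only out/sim/acceptor_only --outdir out/fret --pixel-size 100
arrayfret stats    --table out/run/measurements.csv --measurement fret_positive_pct --outdir out/stats
arrayfret run-all  --config config.yaml --outdir out/run --seed 1
```

A minimal `run-all` config:

```yaml
seed: 1
simulate:
  n_sections: 8
  frame_size: [128, 128]
  geometry: {pixel_size_xy: 100.0, section_thickness: 70.0}
  n_synapses: 40
study:
  cases_per_group: 2
  samples_per_case: 2
  ad_overrides: {frac_coloc: 0.5, fret_efficiency: 0.3}
  control_overrides: {frac_coloc: 0.1, fret_efficiency: 0.0}
segmentation: {local_window: 31, threshold_offset: 1.0}
colocalization: {min_fraction: 0.10}
fret: {threshold: 0.0}
stats: {measurement: percent_coloc_both}
```

Stacks travel as one multi-page 16-bit TIFF per channel (page index =
section index); tables are CSV; configs are YAML; the run manifest
(seed, config hash, results hash) is JSON.

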