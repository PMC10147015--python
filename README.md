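# gliatrace

Single-cell 3D morphometry of Iba1⁺ microglia-like cells (MLCs) in
multichannel confocal z-stacks.

Microglia shift morphology with their functional state: compact
"ameboid" cells (pro-phagocytic, pro-inflammatory) carry few short
processes and occupy a small territory; ramified "surveillance" cells
extend long branching processes over a large territory; "hyper-ramified"
bushy forms mark chronic inflammation.  Quantifying these shifts across
whole imaged populations — rather than eyeballing representative cells —
requires reconstructing every cell in a stack and reducing it to a small
set of morphometric numbers.  `gliatrace` is an open, scriptable,
bit-reproducible pipeline for exactly that workflow, aimed at labs that
image Iba1/DAPI-stained tissue and currently depend on interactive
commercial reconstruction.

## What it computes

For each cell, from a two-channel (Iba1 + DAPI) anisotropic z-stack:

- **soma detection** on a DAPI×Iba1 colocalization channel, with a
  nucleus-in-stack inclusion rule;
- **filament tracing** as intensity-weighted geodesics (edge cost
  ℓ · (ε + 1 − I)^γ) from process-scale seed points to the soma, with
  automated pruning and per-node diameters from the intensity FWHM;
- **total process length** L = Σ‖xᵢ − xⱼ‖ over skeleton edges (µm);
- **Sholl profile** n(r): intersections of the skeleton with concentric
  shells of radius r = k·Δr (Δr = 1 µm default) centered on the soma,
  counted exactly with a half-open crossing rule, and the **Sholl sum**
  Σₖ n(rₖ);
- **convex hull** volume V and area A of the skeleton point set, and the
  territory **sphericity** Ψ = π^⅓(6V)^⅔ / A (Ψ = 1 for a sphere);
- **QC filtering**: cells below the 10th percentile (interpolated order
  statistics) on any of {length, Sholl sum, sphericity, hull volume}
  within their cohort are excluded, as are cells whose nucleus touches
  the axial stack borders;
- **group statistics**: Mann–Whitney U (2 groups) or Kruskal–Wallis with
  Dunn–Bonferroni post hoc over planned comparisons, per-animal
  summaries, and a two-sample Kolmogorov–Smirnov test on pooled Sholl
  intersection-radius distributions.

A built-in synthetic generator renders parametric microglia-like cells
in the four reactivity states into realistic stacks (capsule
rasterization in physical µm, Gaussian PSF, Poisson + Gaussian noise,
16-bit, 101.54 µm / 1440 px / 0.8 µm-section acquisition geometry) with
exact ground-truth skeletons and analytic reference metrics, so the
whole pipeline is validated end to end without any proprietary data.

## Worked example

Simulate one surveillance-state cell, then measure its ground-truth
skeleton:

```bash
gliatrace simulate --preset surveillance --n-cells 1 \
    --field-um 60 --n-slices 30 --seed 42 --out demo/scene
gliatrace measure --swc-dir demo/scene --out demo/metrics
```

`demo/metrics/cell_metrics.csv` then contains (seed 42):

```
cell_id  total_filament_length_um  sholl_sum  hull_volume_um3  sphericity
cell000                    124.14         78          2276.24        0.75
```

— a 124 µm process tree crossing Sholl shells 78 times, claiming a
~2276 µm³ territory of sphericity 0.75: a typical ramified cell.  The
same command measures any SWC skeleton, traced or ground truth.

To run the full image pipeline on a stack (masking → tracing → QC):

```bash
gliatrace trace --input demo/scene/scene.ome.tif --out demo/run
```

and a complete synthetic cohort study — two groups × 3 "animals" × 15
cells each, traced from rendered images and compared statistically:

```bash
gliatrace run-all --groups ameboid:surveillance --n-animals 3 \
    --n-cells 15 --seed 1 --out demo/study
```

With seed 1 this reports 67 of 89 traced cells passing QC and, for the
ameboid versus surveillance groups: median total length 70.0 vs
149.9 µm (Mann–Whitney p = 2.2e-10), Sholl sum 61 vs 93 (p = 1.1e-05),
hull volume 640 vs 2291 µm³ (p = 1.5e-10) and sphericity 0.840 vs 0.792
(p = 4.2e-06) — the compact state is shorter, less branched, smaller in
territory and rounder, each difference highly significant.

The library mirrors the CLI: `rasterize_scene`, `process_stack`,
`measure_cell`, `percentile_filter`, `run_group_study`, etc.; see the
docstrings and `docs/methods.md` for the underlying models and all
tunable parameters.

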