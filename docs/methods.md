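# Methods

`gliatrace` quantifies the 3D morphology of Iba1⁺ microglia-like cells
(MLCs) in two-channel confocal z-stacks, replacing an interactive
commercial reconstruction workflow with a deterministic, scriptable
pipeline.  This note documents the models, parameters and numerical
choices, and what the synthetic validation does and does not show.

## The measurement model

A cell is represented as a *filament graph*: an undirected tree of nodes
with physical coordinates (µm) and radii, rooted at one soma node.  All
geometry is computed in physical micrometres; nothing assumes isotropic
voxels (the target acquisition is strongly anisotropic: 0.0705 µm
lateral pitch versus 0.8 µm optical sections).  Voxel `(k, j, i)` is
identified with its center `((k+0.5)·vz, (j+0.5)·vy, (i+0.5)·vx)`; this
convention is declared once in `image_io` and used everywhere, including
the rasterizer and the tracer, to avoid off-by-half-voxel disagreements.

Per cell, the pipeline reports:

- **Total filament length** — sum of Euclidean edge lengths; the soma
  node itself adds no length.
- **Filament volume** — conical frusta over edges from fitted node
  radii, plus the soma volume imported from the colocalization channel
  (the whole-cell reading of "cell volume"; whether the soma belongs in
  this statistic is a known ambiguity, and the imported-soma flag lets a
  user subtract it).
- **Sholl profile** — intersection counts with concentric shells at
  `k × resolution` (default 1 µm) centered on the soma.  The default
  mode uses 3D spheres; a `projected2d` mode (drop z, concentric
  circles) is available for strict fidelity to the flattened-projection
  description of the analysis.
- **Convex hull volume and area** — exact hull (Qhull) of all skeleton
  node coordinates by default; `tips_only` (leaves + soma) preserves the
  literal "distal tips" construct.  Both are identical for straight
  terminal branches; `all_nodes` is robust for curved ones.
- **Sphericity** — Ψ = π^⅓(6V)^⅔ / A evaluated on the hull volume and
  area, i.e. the roundness of the cell's *territory*, matching the
  attribution of sphericity to convex-hull analysis.

### Sholl counting convention

A crossing is counted where the distance-to-soma along the skeleton
passes a shell level with the half-open rule
(`d_prev < r ≤ d_next` or `d_prev ≥ r > d_next`), so a tip lying exactly
on a shell counts once.  Rather than resampling the polyline and
counting sign changes at finite resolution, the production code counts
crossings *exactly* per straight segment: squared distance along a
segment is a quadratic in the arc parameter, hence quasiconvex, so each
segment crosses each shell at most twice (down–up dips through a shell
count as two transversal crossings; exact tangencies count zero, the
measure-zero limit of the sampling rule).  This is the h→0 limit of the
sampled convention and removes any dependence on a resampling step.  The
independent reference in `synthetic.analytic_metrics` deliberately takes
the other route — dense 0.01 µm resampling — so that the two
implementations can cross-validate; they agree exactly, shell by shell,
on hundreds of random trees.

## Reconstruction pipeline

Stages, in order, all deterministic (ties broken lexicographically on
(z, y, x); no RNG anywhere in reconstruction):

1. **Background subtraction** (optional) — per-slice greyscale opening
   with an elliptical disk of physical radius, subtracted and clipped at
   zero.  Per-slice because a 3D structuring element is ill-posed at
   0.8 µm slicing.
2. **Debris masking** — connected supra-threshold objects are scored by
   volume, mean intensity, mesh-based sphericity and moment-based
   ellipticities; objects passing a stacked conjunctive filter (small,
   bright, round — antibody-deposit-like) are masked.  The mask is
   dilated by `mask_dilation_um` (default 1 µm) so the sub-threshold
   blur halo of each deposit goes with its core, and masked voxels are
   filled with the channel median rather than zero — a hard zero hole
   rings in the blob detector and would *create* spurious seed points.
3. **Colocalization channel** — voxelwise geometric mean of the min-max
   normalized nuclear (DAPI) and membrane (Iba1) channels.  The
   commercial feature this stands in for is not published as a formula;
   the geometric mean is chosen because it is high only where both
   signals are high (soma bodies with confluent intensity), is
   annihilated wherever either channel is at its minimum, and peaks at 1
   where both are maximal.  It is a substitution satisfying the stated
   purpose, not a numerical reconstruction.
4. **Starting points** — scale-normalized negative-LoG blob response at
   σ = starting_diameter/(2√3) on the colocalization channel; local
   maxima above threshold with greedy minimum-separation suppression
   (strongest first).
5. **Nucleus gating** — a starting point survives only if a
   supra-threshold DAPI component overlaps its starting sphere and that
   component touches neither the first nor the last optical section
   (nucleus fully inside the stack).
6. **Seed points** — LoG maxima at the process scale; seeds within
   `remove_seed_radius_factor × starting_radius` of any starting point
   are removed (they sit on the bright soma rim and would spawn
   hair-like false filaments).
7. **Tracing** — "autopath"-style intensity-weighted geodesics.  A
   26-neighborhood graph over voxels above `intensity_floor` carries
   edge weights `physical_length × (ε + 1 − Î)^γ` with ε = 0.01 and
   γ = 4 (Î = mean endpoint intensity, [0, 1] scale).  One multi-source
   Dijkstra from all starting points assigns every seed to its
   cheapest-cost cell — geodesic, not Euclidean, assignment is what
   prevents a seed of one cell being captured by a nearby neighbour —
   and each cell's tree is the union of its seeds' predecessor paths.
   Seeds are consumed farthest-first; a seed already within one seed
   diameter of a traced path, whose candidate path adds less than
   1.5 µm of new territory, is a duplicate strand and spawns nothing.
   γ = 4 (rather than a milder exponent) makes the brightest voxel chain
   strictly cheapest, so geodesics of sibling branches share their
   common prefix instead of splitting early; with γ = 2 the duplicated
   prefixes inflated traced length measurably.
8. **Path refinement** — voxel-grid geodesics zigzag around the true
   centerline and overestimate length by ~10%.  Three corrections, each
   standard in skeleton tracing: Laplacian relaxation of degree-2 chain
   nodes (junctions, tips and soma pinned); re-centering of chain nodes
   onto the intensity ridge (intensity-weighted centroid in the plane
   normal to the local tangent, shift capped at 0.35 µm/iteration);
   chain decimation to ~1 µm node spacing (measures the process at the
   scale the image actually resolves, removing sub-voxel wiggle).
   Finally tips are extended along their terminal direction while the
   interpolated intensity stays above half the tube-interior value,
   pulled back by ~one tube radius because the half-maximum crossing
   marks the blurred *surface* of the end cap, one radius beyond the
   skeletal end point.  Trees are then resampled to ≤ 0.5 µm node
   spacing so that 1 µm Sholl shells see a sub-resolution polyline.
9. **Gap pruning** — an edge whose straight line crosses a contiguous
   below-floor run longer than `max_gap_um` is cut and the component
   not containing the soma is dropped (the guard against geodesic
   "leaps" between cells).
10. **Diameter fitting** — per-node radius from the mean first-crossing
    of 50% of the on-axis intensity along 8 rays normal to the local
    tangent (FWHM convention), clamped to [0.1 µm, starting_radius].
    Fitted radii are PSF-broadened, most strongly along z.
11. **Soma import** — the supra-threshold colocalization component
    containing the soma node supplies the soma volume; the default
    threshold 0.45 approximates the half-maximum surface of the
    colocalization body.  Absent a component, the sphere of the
    starting radius is used and flagged.

### Key tracing parameters

| parameter | default | meaning |
|---|---|---|
| `starting_diameter_um` | 8 | soma scale for detection and seed exclusion; set it to the measured soma diameter |
| `seed_diameter_um` | 1.2 | process scale; also the coverage radius for duplicate suppression |
| `start_threshold`, `seed_threshold` | 0.03, 0.015 | minimum scale-normalized blob response |
| `intensity_floor` | 0.07 | voxels below this never carry a path (background ≈ 0.02 plus noise) |
| `cost_exponent` γ | 4 | contrast of the geodesic cost; higher = stronger ridge-following |
| `max_gap_um` | 5 | longest tolerated below-floor leap |

## QC and statistics

Only cells with a nucleus fully inside the stack enter.  Cells with a
degenerate (planar) hull are excluded.  Then, within a cohort (default:
one model × age cohort pooled across treatment groups, so all groups
share one cutoff and censoring is not differential), a cell is excluded
iff it falls strictly below the 10th percentile — linear interpolation
of order statistics — on *any* of: total length, Sholl sum, sphericity,
hull volume.  This union rule removes 10–40% of cells depending on the
rank correlation of the four metrics; it is the mechanism that discards
cells clipped by the stack borders.

Statistics are nonparametric: Mann–Whitney U for two groups (exact
enumeration when n₁+n₂ ≤ 12 without ties, else normal approximation
with tie and continuity corrections), Kruskal–Wallis (tie-corrected H,
χ² tail) with Dunn post hoc z-tests on pooled tie-corrected ranks for
more, Bonferroni-adjusted by the number of *planned* comparisons (the
study design's 4), not all pairs.  Group Sholl distributions are
compared by a two-sample KS test after expanding each cell's profile
into a multiset of shell radii (radius repeated by intersection count)
and pooling within group; the source protocol names the test but not
the data reduction, and the pooled-radii reduction is one defensible
choice, exposed as such.  Per-animal summaries are plain means plus
cell counts per field.

## The synthetic scene generator

Scenes emulate the target acquisition: 101.54 × 101.54 µm fields at
1440 × 1440 px, 0.8 µm sections, 16-bit with background at 2% of full
scale.  Cells are parametric branching trees (Fibonacci-distributed
primary directions with a random rotation; ~1 µm polyline steps with
Gaussian angular jitter; bifurcation with probability `branch_prob` up
to `max_order`; radius tapering per order) rasterized as exact capsules
(point-to-segment distance in physical µm, voxel value = max over
primitives) plus soma and nucleus spheres, then blurred with a
per-axis Gaussian PSF (default σ = 0.6, 0.15, 0.15 µm in z, y, x),
Poisson noise (default 100 counts per unit intensity) and additive
Gaussian noise (default sd 0.01), quantized to 16 bits.  One seeded
generator per scene with documented stream order (placement, trees in
order, debris, Poisson, Gaussian) makes scenes byte-reproducible.

The four reactivity-state presets (ameboid, transitional, surveillance,
hyper-ramified) are this package's quantitative calibration of a
pictorial taxonomy; only ordinal relations constrain them (mean length
and Sholl sum increase along that order; the ameboid territory is the
smallest; the compact many-stubbed ameboid form has the roundest, hence
most spherical, hull).  The calibration was fixed once from
ground-truth Monte-Carlo, before any tracer-level testing, and the
preset gaps are several standard errors wide at n = 50 cells.

What the generator does **not** emulate: depth-dependent attenuation
and spherical aberration, bleed-through, tissue context (other cell
types, vessels), chromatic shifts, and real microglial fine structure
(varicosities, filopodia).  Passing synthetic validation therefore
shows the *measurement machinery* is correct and the pipeline separates
morphological populations under realistic noise and crowding — not that
the default thresholds are optimal for any particular microscope.

## Validation design and problem sizes

- Sholl: 200 random parametric trees, closed-form counts vs the dense
  0.01 µm oracle, exact integer agreement required.
- Hulls: 100 random point sets (n ≤ 10) vs brute-force supporting-plane
  enumeration within 1e-9, plus closed-form cube and tetrahedron.
- Sphericity: closed forms, plus a 2 µm sphere rasterized at 0.1 µm
  isotropic voxels (Ψ ≥ 0.97; mesh area from a lightly smoothed
  isosurface, with the isoperimetric bound as the area floor so Ψ ≤ 1).
- Tracing recovery: 50 noise-free and 50 noisy+debris single-cell
  scenes of a standard benchmark cell (8 µm segments, two orders,
  tortuosity 0.12) in a 52 µm field chosen so the cell always fits —
  length within 5% (noise-free) / 10% (noisy, debris-masked) and leaf
  count within ±1.  Branches that barely clear the soma-scale seed
  exclusion zone are unresolvable in principle; the benchmark cell
  avoids them so the score reflects the tracer, not the fixture.
- End-to-end: 2 groups × 3 "animals" × 15 cells (ameboid vs
  surveillance) through the full pipeline, Mann–Whitney per metric.
  Scenes use 0.35 µm lateral pitch rather than the full 0.0705 µm to
  keep the study a desk-scale computation; the tracer's accuracy is
  established at finer pitch in the recovery benchmark.

## Known limitations

- Starting and seed diameters are configuration inputs, as in the
  interactive protocol (averaged manual measurements); no automatic
  estimation is attempted.
- The geodesic tracer cannot separate branches running closer than
  about one seed diameter (~1.2 µm) in parallel; such siblings merge.
- Fitted diameters are PSF-broadened (up to ~20% at the default axial
  blur) and are not deconvolved.
- Ellipticity formulas (oblate = 1 − c/b, prolate = 1 − b/a from
  solid-ellipsoid moment scaling) satisfy the verbal definitions
  (sphere → 0, disc → oblate 1, needle → prolate 1) but are not
  guaranteed numerically identical to the commercial implementation.
- Group comparisons here are per-cell; nested (animal-level) dependence
  is summarized but not modelled (no mixed models, by design).
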