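# Methods

This note records the imaging model the package assumes, what the synthetic
phantom generator does and does not emulate, the parameter defaults and why
they were chosen, and the numerical decisions inside the counting algorithm.
It makes no empirical performance claims; every number of that kind is
computed by the test suite or by `scripts/acceptance.py`.

## Imaging model and assumptions

The target modality is block-face cryo-imaging: a specimen is sectioned at
40 µm and the exposed block face is photographed in two fluorescence
channels (red: label; green: autofluorescence) at a pixel size of roughly
10–16 µm (default 15.6 µm). Three consequences drive the design:

1. **A cell is about one pixel.** A 10–15 µm cell under a ~1 px point
   spread function produces a compact blob whose *shape* carries almost no
   information about how many cells it contains. Counting must therefore be
   intensity-based: the package fits superpositions of a calibrated
   single-cell template and selects the number of cells by least-squares
   model selection, rather than trying to resolve individual cells.
2. **Subsurface fluorescence bleeds through.** The block face shows not
   only the surface but also a blurred, attenuated contribution from
   fluorophores below it, which next-image subtraction removes: each slice
   has a blurred, scaled copy of the *next* (deeper) slice subtracted.
3. **Cells split across section boundaries.** A cell whose centre lies
   near the cut plane leaves part of its intensity in one slice and the
   rest in the next. Segmentation is therefore 3D (26-connected), and the
   cell model gives each fitted cell an optional split fraction.

The single-cell image model is a pixel-integrated, isotropic 2D Gaussian:
a cell at continuous position (x_c, y_c) with total intensity I_t
contributes to pixel (i, j) the product of per-axis integrals of a Gaussian
of width σ over the pixel footprint (computed with `erf`). Pixel-integrated
rendering, rather than sampling the Gaussian at pixel centres, is what
makes total intensity nearly invariant to sub-pixel position — the property
the counting method relies on.

## Pipeline

1. **Next-image subtraction** — `I_k ← I_k − a · G(I_{k+1}, s)` with
   attenuation `a` and blur `s`; the deepest slice is left unchanged.
2. **Background removal** — per slice, the background is estimated by
   morphological reconstruction by dilation using a greyscale erosion
   (flat disk, radius 10 px) as the marker, then subtracted and clipped at
   zero. Erosion removes every peak narrower than the disk; reconstruction
   regrows the smooth background underneath the original image.
3. **Ratio threshold** — the processed grey volume keeps red intensity
   only where `I_R > T_RG · I_G` (equivalent to thresholding the R/G ratio
   while remaining defined at `I_G = 0`). Labelled cells have R/G ≈ 8,
   tissue background ≈ 0.4, so `T_RG = 2` separates them with wide margin.
4. **Hysteresis segmentation** — voxels above a high threshold `T_H` seed
   26-connected regions grown over voxels above a low threshold `T_L`.
   `T_H = 0.6 · min_n Cmax(n)` is calibrated from an image of
   well-separated cells in culture (the dimmest cell's peak, with margin);
   `T_L = μ + c·σ` over all voxels of the processed volume (default
   `c = 1.4`).
5. **False-positive rejection** — segmented objects are rejected if their
   volume exceeds `T_V` (autofluorescent anatomy is orders of magnitude
   larger than a cell cluster) or if their intensity-to-volume ratio falls
   outside `[T_RL, T_RH]`. Rejection reasons are recorded.
6. **Calibration** — singleton clusters are selected by a band around the
   dominant mode of the integrated-intensity distribution (see below);
   each is fit with a single pixel-integrated Gaussian and the template
   (σ, I_t) is the mean over converged fits.
7. **Counting** — for each cluster, the initial estimate is
   `N = round(∫C / I_t)` (half-up, floored at 1); candidate counts are
   `N ± max(2, round(0.3·N))`, clipped below at 1. For each candidate `n`,
   `n` template cells are placed and their positions optimised by
   Nelder-Mead on the sum of squared residuals over the cluster patch; the
   candidate with the smallest objective wins (ties prefer fewer cells).
   A result is flagged ambiguous when the runner-up objective is within
   20% (relative) of the winner.
8. **Evaluation** — detected counts are matched to ground truth by
   position; agreement is summarised by a square contingency table over
   cells-per-cluster classes, Fleiss' kappa (two raters: algorithm and
   reference) with its asymptotic standard error, Cohen's kappa for
   comparison, one-vs-rest per-class sensitivity/specificity, and the
   relative total-count error.

## Phantom generator

`generate_phantom` emulates the physical phantoms used to validate this
class of algorithm: fluorescent objects at known positions in a scattering
medium. What it models:

- clusters of 1–5 cells with touching-distance spacing inside a cluster
  and grid-separated cluster sites (so ground-truth clusters are
  unambiguous);
- per-cell total intensity `I_t ~ Normal(mean, CV·mean)` — CV 0.05 for
  microsphere-like objects, 0.15 for labelled cells;
- axial sectioning splits with a spherical-cap geometry: the cell-centre
  depth is uniform within a section, so a cell of radius `r` splits with
  probability `r / T` (section thickness `T`) and the minority fraction of
  its intensity, in (0, 0.5), goes to the adjacent slice;
- subsurface bleed-through built recursively from the deepest slice up
  (`slice_k += bleed · G(slice_{k+1}, blur)`), so matched-parameter
  next-image subtraction inverts it exactly — the generator and the
  preprocessing stage are exact adjoints by construction;
- a smooth background field (shared between channels, red scaled by the
  background R/G ratio), plus additive Gaussian sensor noise, clipped at
  zero.

What it deliberately does **not** model: optical vignetting, depth-varying
attenuation, anisotropic or depth-varying point spread, autofluorescent
anatomy (tested separately by injecting large blobs), registration error
between slices, and photobleaching. `generate_culture_image` produces the
single-slice, singleton-only, bleed-free image used to calibrate `T_H`,
mirroring a dish of cells in culture.

## Parameter defaults

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| `pixel_size_um` | 15.6 | µm | typical block-face pixel size |
| `section_um` | 40 | µm | typical section thickness |
| `sigma_px` | 1.0 | px | one-pixel-scale cell image |
| `intensity_mean` | 1000 | DN | arbitrary digital-number scale |
| `intensity_cv` | 0.15 | — | labelled-cell brightness spread (0.05 for microspheres) |
| `cell_diameter_um` | 12.5 | µm | mid-range 10–15 µm cell (15 µm for microspheres) |
| `background_rg_ratio` | 0.4 | — | tissue R/G ratio |
| `cell_rg_ratio` | 8.0 | — | labelled-cell R/G ratio |
| `bleed_fraction` | 0.17 | — | subsurface bleed ≈ 15–20% |
| `noise_sd` | 3.0 | DN | ≈ 2% of the ~147 DN peak of a 1000 DN cell |
| `ratio_threshold` | 2.0 | — | between 0.4 and 8.0 with margin |
| `erosion_radius_px` | 10 | px | larger than any cluster, smaller than background structure |
| `c` (low threshold) | 1.4 | — | `μ + 1.4σ` keeps the noise floor out of clusters |
| `t_volume` | 500 | voxels | far above any 1–5 cell cluster |
| `d_min` | cell diameter / pixel size | px | minimum centre separation of fitted cells |

## Numerical decisions

- **Optimizer.** Nelder-Mead, iteration cap 10 000, relative
  objective-change tolerance 1e-6 (`fatol = 1e-6 · max(f₀, 1)`,
  `xatol = 1e-4`). The objective is piecewise-smooth (the split fraction is
  clipped and penalties activate at boundaries), so a derivative-free
  simplex is more robust than gradient methods here. Single-cell
  calibration fits use a bounded trust-region least-squares solver instead
  — that problem is smooth and well-conditioned.
- **Constraints as penalties.** Pairwise separation `≥ d_min` (only
  between cells sharing a home slice — cells homed in adjacent 40 µm
  sections are physically separated by more than a cell diameter), split
  fraction in [0, 1], and cell centres inside the fit patch are enforced by
  quadratic penalties with weight `100 · I_t² / d_min²`, scaled so a
  violation of order `d_min` costs far more than any plausible residual
  improvement. The centre-in-patch penalty matters: without it an extra
  model cell can park outside the patch (or route intensity to a
  nonexistent deeper slice) and spuriously lower every candidate objective.
- **Split fraction parameterisation.** Each fitted cell's `z_c` is free
  only when a deeper slice exists inside the patch; otherwise it is frozen
  at 0, so model intensity can never leave the fitted volume.
- **Initial placements.** Candidate cells start at the `n` strongest local
  maxima above 20% of the patch peak (ignoring dim noise maxima), with
  remaining cells jittered around the intensity centroid. The floor is
  required: a corner noise maximum used as a start point can strand a
  model cell where the optimiser cannot recover.
- **Singleton selection for calibration.** The singleton intensity band is
  centred on the dominant mode of the integrated-intensity distribution,
  found by a Gaussian kernel density estimate with bandwidth
  `0.1 · median` — wide enough to smooth noise, narrow enough to keep the
  1-cell and 2-cell modes distinct (generic bandwidth rules merge them on
  small samples). The band is `centre ± n_sd · max(1.4826·MAD, 2% of
  centre)`, capped at `1.45 · centre` so no 2-cell cluster can enter.
- **Split-aware calibration.** A singleton whose cell is sectioned can be
  detected in one slice while part of its intensity lies below threshold
  in the next; fitting the home patch alone would bias `I_t` low by the
  mean split fraction (several percent). Calibration therefore fits the
  home patch jointly with the same window of the next slice, sharing one
  `I_t` and a free split fraction.
- **Culture-image maxima.** When deriving `T_H`, connected components
  smaller than 4 voxels are ignored: on sparse calibration images the
  global `μ + c·σ` threshold sits close to the noise floor and residual
  noise specks would otherwise drag `min Cmax` (and hence `T_H`) down.
- **Rounding.** `N_init` uses round-half-up (`floor(x + 0.5)`); the
  candidate half-width is `max(2, round_half_up(0.3·N))`. Half-up makes
  the estimate monotone in intensity with no even/odd bias.
- **Determinism.** Every stochastic component takes a seed;
  per-cluster RNGs are spawned from one `SeedSequence`, so counting one
  cluster never perturbs another and runs are bit-reproducible.

## Open design decisions

Choices the method description leaves open, resolved as follows:

- **Kappa variant.** Fleiss' formulation with two raters
  (algorithm, reference) is reported, with Cohen's kappa alongside; the
  two differ slightly in their chance-agreement model. The standard error
  uses the large-sample variance of Fleiss' kappa; other SE estimators
  exist and give somewhat different values.
- **Ambiguity flag.** "Two candidate objectives too close to call" is
  operationalised as a relative gap below 20% between the best and
  second-best objective.
- **Candidate-range rounding** (`±30% of N`) uses half-up rounding with a
  floor of ±2, and the range is clipped at 1 cell.
- **Tie-breaking** between equal objectives prefers the smaller cell count
  (parsimony).
- **Matching detections to truth** uses padded bounding-box containment of
  true cell centres (pad 1.5 px, one extra slice allowed for splits);
  unmatched truth rows count as missed, unmatched detections as spurious.

## Limitations

- The counting model assumes all cells share one template (σ, I_t);
  strongly heterogeneous labelling widens the count posterior and raises
  the ambiguity rate.
- Intensity-based counting degrades as the per-cell intensity CV grows:
  with CV 0.15, a 5-cell cluster's intensity distribution overlaps its
  neighbours', bounding achievable per-class sensitivity regardless of the
  optimiser.
- The background estimate from reconstruction-by-dilation rides the local
  noise floor, so `I_Gray` keeps a small positive residual near bright
  objects. Template calibration on singletons detected inside a full
  stack therefore runs a few percent high on `I_t`; the bias largely
  cancels in counting because cluster integrated intensities carry the
  same residual, and calibration on a culture image (where it is smaller)
  recovers the generator parameters within a few percent.
- The phantom's exact adjointness between bleed generation and next-image
  subtraction is optimistic; on real data residual bleed remains and `T_L`
  absorbs it.
- Volumes are processed in memory (desk-scale stacks); whole-animal
  datasets would need tiled streaming.
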