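# Methods

## Problem setting and model

B-mode ultrasound shows lesions as darker, roughly elliptical regions in a
brighter, speckled, inhomogeneous background. The package delineates such a
lesion inside a user-supplied tumor-centered crop (TCI) in three stages:
enhancement, graph-based region merging, and per-image parameter tuning.

**Region merging.** The TCI is a 4-connected pixel graph with absolute
intensity differences as edge weights. Edges are visited in non-descending
weight order; the regions joined by an edge merge when the contrast between
their means does not exceed the smaller of their internal tolerances
`σ(C) + τ(C)` with `τ(C) = (k/|C|)(1 + β/α)`, `β = μ(C)/σ(C)`. The result
is a forest of minimum spanning trees; each tree is a region. The predicate
adapts to local statistics: bright, uniform regions (large β) merge more
readily, large regions less readily. `k` (scale) and `α` (stiffness) shift
this balance and have no universally good values — they are tuned per
image.

**Objective.** The region containing the central TCI pixel is the tumor
candidate. Its score combines
* `V_B` — Σ over adjacent regions of `P(C_i)·(μ_i − μ_ref)²` with
  `P = |C|/|TCI|`: contrast to the surroundings (maximized);
* `V_W` — `arctan(var(C_ref))/P(C_ref)`: non-uniformity, damped by arctan
  so its range is comparable to `P`, and divided by the area fraction so
  that shrinking the region cannot cheat the term (minimized);
* `G_A` — mean Sobel gradient magnitude over the region's inner 4-boundary
  on the enhanced TCI (maximized): pulls the contour onto real edges.

Each term is normalized by its mean over the initial swarm (computed once,
before the first generation) and combined as
`F_O = 0.3·V_B/f_B − 0.3·V_W/f_W + 0.4·G_A/f_A`.

**Search.** Global-best PSO over the box `k ∈ [100, 4000]`,
`α ∈ [0.001, 4]`: 200 particles, ≤200 generations, `c1 = c2 = 0.5`,
inertia decaying linearly 1.0 → 0.2, stopping when the global best is
stable (< 1e−9 in box-normalized coordinates) for 4 consecutive
generations. Tests and the acceptance experiments run a reduced
50-particle / 60-generation swarm; on the phantoms it converges in ~10
generations and recovers analytic optima in 20/20 seeded trials, so the
full-size swarm buys nothing there.

## Design choices where the design was open

* **Uniform initialization** is a deterministic grid (cell centers of an
  `n_k × n_α` lattice; `n_k` is the divisor of `n_p` nearest `√(2·n_p)`,
  giving 20×10 at 200, 10×5 at 50). A deterministic start makes the
  normalization factors a function of the image alone. Seeded random
  initialization is available via `SwarmConfig(init="random")`.
* **Degenerate σ:** for uniform regions `β = μ/σ` is undefined; `β := 0`
  so `τ` reduces to the pure size threshold `k/|C|`. This keeps the
  tolerance finite and lets strong edges between uniform seeds survive.
* **σ is the population standard deviation** — well-defined for
  single-pixel regions.
* **Tie-breaking:** the edge sort is stable with construction order
  (row-major, right edge before down edge), so partitions are
  bit-reproducible.
* **τ grouping:** `τ = (k/|C|)·(1 + β/α)` is the reading under which the
  stated monotonicities hold (τ increases with k, decreases with α).
* **`V_W` grouping:** `arctan(var)/P` rather than `arctan(var)·P`; only
  the divisor form penalizes small reference regions under minimization,
  which is the stated purpose of the `P` factor. The product form is
  selectable (`PipelineConfig(vw_form="multiply")`) for sensitivity
  checks.
* **Boundary handling in PSO:** positions are clamped to the box and the
  clamped component's velocity zeroed; `r1, r2` are drawn per particle,
  per dimension, per generation.
* **Boundary operator:** the region "edge" is the inner 4-boundary
  (member pixels with an outside 4-neighbour; the image border counts as
  outside). Sobel magnitude `√(gx²+gy²)` is computed with replicate
  padding on the enhanced TCI.
* **Morphology:** opening then closing with the 13-cell discrete ellipse
  in a 5×5 box. An added guard keeps only the component containing the
  TCI center (falling back to the largest) in case morphology splits the
  mask; it is on by default and can be disabled.
* **Metrics conventions:** the ray-casting center comes from the truth
  mask and is shared by both contours; rays step 0.25 px (half-step
  offset, round-half-up lookup) and the **outermost** inside→outside
  transition counts, which makes the measure robust to interior holes.
  Rays with zero truth radius are skipped with a warning. FPVF is
  deliberately uncapped and can exceed 100% under gross over-coverage.
* **Preprocessing parameters** (nowhere standardized): bilateral
  `win=9, σ_color=75, σ_space=75`; mean shift `spatial=10, range=20,
  2 pyramid levels`. A grid search over
  `σ_color ∈ {30,75} × spatial ∈ {5,8,10} × range ∈ {20,40,60}` on a
  calibration phantom set (seed 77, easy+medium, disjoint from the
  evaluation suite) selected exactly these values (mean ARE 10.5 on the
  calibration set). All are exposed in `PreprocessConfig`.
* The mean-shift filter is this package's own implementation (per-pixel
  joint spatial-range mode seeking, ≤5 iterations, coarse-to-fine over a
  Gaussian pyramid with the coarse result initializing the finer level);
  the bilateral stage wraps scikit-image, morphology wraps scipy.ndimage.

## The phantom generator

Phantoms emulate the statistical structure the method must cope with: a
darker elliptical or lobulated (5-lobed, sinusoidally modulated radius)
lesion centered in a brighter background, multiplied by mean-1 speckle
with an exponential (squared-Rayleigh-type) heavy tail, blurred by a
Gaussian point-spread stand-in (σ = 1 px), overlaid with a smooth random
intensity-inhomogeneity field, and optionally shadowed by a posterior dark
band. Frames are 128×128 with lesion semi-axes ~20–32 px, so the lesion
fills roughly half the crop — the geometry of a properly taken
tumor-centered ROI. Difficulty tiers fix contrast/speckle at 80/0.1
(easy, ellipse), 50/0.2 (medium, mildly lobulated) and 30/0.3 (hard,
lobulated + shadow). Everything derives from integer seeds and is
byte-reproducible.

What the phantoms do **not** emulate: depth-dependent attenuation and
focusing, anisotropic speckle correlation, tissue texture layering,
refraction edge dropout, and radiologist-drawn (rather than geometric)
truth contours. Passing the phantom experiments therefore demonstrates
correctness and internal consistency of the implementation under
controlled conditions, not clinical-grade accuracy.

## Verification experiments and problem sizes

The acceptance script and test suite run, end to end: oracle equivalence
of the segmenter against a from-scratch brute-force implementation on 50
random images ≤ 10×10 (exact label-map agreement); monotonicity of the
region count in `k` on a fixed 32×32 phantom; hand-computed objective
values (`V_B = 1250` on a two-half instance, `G_A = 1020` at an ideal
0/255 Sobel step, `V_W = 0` for uniform references); PSO inertia endpoints
and quadratic-optimum recovery (20 seeded runs, 50×60 swarm); metric
identities (TPVF+FNVF = 100 exactly; concentric digital disks of radii
10/12 give ARE ≈ 20%); full-pipeline lesion recovery on 20 easy phantoms
(mean TPVF = 100%, mean ARE ≈ 11–13% across suite seeds); and the weight
sensitivity contrast — with weights `(0,1,0)` the uniformity term alone
drives the reference region to swallow the background (mean FPVF ~25×
the balanced default's), reproducing the known failure mode of
uniformity-only optimization. Swarm sizes are reduced to 50 particles /
60 generations for these experiments; convergence diagnostics show the
reduction is inconsequential on phantoms.

## Known limitations

* The enhancement chain systematically dilates the apparent lesion by
  1–3 px: equalization maps most of the blur ramp to lesion-dark values
  and mean shift attaches it to the lesion mode. On phantoms this is the
  dominant error source (the FPVF "halo"); it shrinks relatively as
  lesions grow but never vanishes. Any contour-accuracy-critical use
  should treat the boundary as having a ~2 px outward bias.
* `V_B` can favour reference regions that grow past the lesion when the
  background splits into strongly contrasting zones (e.g. severe
  inhomogeneity after equalization); on small-lesion images this can
  produce gross under-segmentation. The balanced weights and the realistic
  TCI geometry keep this in check, but the failure mode is intrinsic to
  the objective.
* Monotonicity of region count in `k` holds as a strong tendency, not a
  theorem: the greedy merge order can occasionally produce one extra
  region at a larger `k`.
* The per-pixel mean-shift filter is O(pixels × window²) and, with the
  segmentation inner loop, is numba-compiled; the first call in a fresh
  process pays a few seconds of JIT latency.
* Metrics assume a star-shaped truth region with respect to its centroid
  (fallback: nearest foreground pixel); strongly non-star-shaped masks
  make the radial error ill-defined.
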