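# sonoseg

Tumor segmentation for B-mode ultrasound images by minimum-spanning-tree
region merging whose two control parameters are tuned **per image** by
particle swarm optimization (PSO) under a three-term objective combining
region contrast, region uniformity and boundary gradient. The package is
aimed at researchers building ultrasound CAD pipelines who need an
automatic, reproducible lesion delineation step, and it ships a seeded
speckle-phantom generator so the whole pipeline can be exercised and
validated without clinical data.

## Method

The user crops a tumor-centered image (TCI) — a rectangle that fully
contains the lesion, centered on it. The TCI is smoothed by a bilateral
filter, contrast-stretched by classical histogram equalization, and
homogenized by pyramid mean-shift filtering.

The enhanced TCI is segmented as a 4-connected pixel graph: edges (weight
`|I_a − I_b|`) are traversed in non-descending order, and two regions merge
when

    Dif(C1, C2) = |μ(C1) − μ(C2)|  ≤  MInt(C1, C2) = min(σ(C1)+τ(C1), σ(C2)+τ(C2)),
    τ(C) = (k/|C|) · (1 + β/α),     β = μ(C)/σ(C),

so `k` loosens and `α` tightens the merge tolerance. The region containing
the TCI's central pixel (the *reference region*) is the candidate tumor.
Each candidate `(k, α)` is scored by

    F_O = a·V_B/f_B − b·V_W/f_W + c·G_A/f_A,      (a, b, c) = (0.3, 0.3, 0.4),

where `V_B` is the size-weighted squared contrast between the reference
region and its neighbours, `V_W = arctan(var)/P(C_ref)` penalizes
non-uniform (and, through the area fraction `P`, too-small) reference
regions, `G_A` is the mean Sobel magnitude on the region's inner boundary,
and `f_B, f_W, f_A` are the means of the three terms over the initial
swarm. A swarm of `(k, α)` particles (defaults: 200 particles, ≤200
generations, `c1 = c2 = 0.5`, inertia decaying 1.0 → 0.2, `k ∈ [100, 4000]`,
`α ∈ [0.001, 4]`) maximizes `F_O`; the search stops when the global best is
stable for 4 generations. The final mask is the reference region at the
optimum, cleaned by morphological opening and closing with a 5×5 elliptical
kernel.

Segmentations are scored against a truth mask by the averaged radial error
(ARE, over 180 rays from the truth centroid) and the true/false
positive/negative volume fractions (TPVF/FPVF/FNVF, percentages of the
truth area).

## Worked example

```python
from sonoseg import PipelineConfig, phantom_suite, run_pipeline

img, truth, spec = phantom_suite(1, "easy", seed=1)[0]     # 128x128 phantom
cfg = PipelineConfig.from_dict({"pso": {"n_p": 50, "t_max": 60}})
res = run_pipeline(img, truth=truth, config=cfg)
print(res.summary())
```

```
PSO-tuned graph segmentation
==============================================
optimal k                         3958.516
optimal alpha                       0.0633
generations                             10
fitness evaluations                    535
objective F_O                       6.1012
  between-class V_B             17681.7797
  within-class V_W                  9.6572
  boundary gradient G_A           280.3477
norm factors f_B/f_W/f_A       1025.68     12.24     96.16
regions at optimum                      12
mask area (px)                        2623
----------------------------------------------
ARE (%)                              14.14
TPVF (%)                            100.00
FPVF (%)                             29.59
FNVF (%)                              0.00
```

The swarm settled after 10 generations (535 distinct segmentations) on
`(k, α) ≈ (3959, 0.063)`. At that operating point the enhanced TCI splits
into 12 regions; the central one covers the whole lesion (TPVF 100%) with a
thin halo of over-inclusion (FPVF 29.6%, a ~1–2 px rim) and an average
radial contour error of 14.1%. `res.mask`, `res.contour` and
`res.trace.to_dataframe()` expose the mask, the traced contour and the
per-generation optimization record; `res.save(outdir)` writes them to disk.

The same pipeline is scriptable from the shell:

```bash
sonoseg phantom --n 5 --difficulty easy --seed 1 --out phantoms/
sonoseg segment --input phantoms/phantom_000.png \
    --truth phantoms/phantom_000_truth.png --out run0/
sonoseg evaluate --truth phantoms/phantom_000_truth.png --seg run0/mask.png
sonoseg sweep --n 6 --seed 1 --out sweep.csv
```

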