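# Methods

This note records the model, the default parameters, the synthetic
phantom design, and the numerical choices made in the implementation.

## Boundary tracking by dynamic programming

A boundary is modeled as one row per column with the step between
adjacent columns bounded by ±1 (`step_bound=1`). `trace_optimal_path`
minimizes the sum of node costs along the path by a standard column
sweep. Ties are broken deterministically: candidate predecessor offsets
are examined in the order 0, −1, +1 (no change preferred, then upward),
and the terminal column takes the smallest minimizing row. This makes
results bit-reproducible across runs and platforms.

- **RPE**: the minimum-cost path through `max(I) − I`, i.e. the
  brightest coherent band.
- **BM**: per column, the row of maximum absolute axial gradient
  (central differences via `np.gradient`) in the window
  `(rpe, rpe + 8]` below the RPE, median-filtered over 5 columns and
  clamped to lie at or below the RPE. Columns whose window falls outside
  the image take the nearest valid row and are logged.
- Everything strictly above the BM is zeroed before texture analysis so
  retinal layers cannot leak into the class statistics.

## Texture features

An undecimated (à-trous) Haar frame is computed along the axial
direction of each column: low-pass `(a[n] + a[n+s])/2`, high-pass
`(a[n+s] − a[n])/2` with spacing `s = 2^(level−1)` and symmetric bottom
extension. Four levels give four detail subbands plus a final
approximation; the signal always equals the approximation minus the sum
of details, which the tests verify exactly. Each subband is squared and
averaged over a 9×9 window (`scipy.ndimage.uniform_filter`, reflect
mode), yielding a 5-dimensional non-negative energy descriptor per
pixel. Larger detail energies at coarse levels capture the vessel-scale
texture that distinguishes choroid from sclera.

## Mixture model

Three full-covariance Gaussians represent above-BM, choroid, and
below-CSI. The primary fit is supervised moment estimation pooled over
all labeled training pixels: class mean, biased covariance (denominator
N_k), and weight equal to the class pixel fraction. A ridge of
`1e-6 · (trace/n) · I` keeps covariances positive-definite on small
training sets. A standard EM refinement is available; it asserts the
log-likelihood never decreases and rejects component collapse. Posterior
responsibilities are computed in log space with `logsumexp`; pixels
whose density underflows under every component receive a uniform
posterior and are counted in the log.

## Graph-cut labeling

The energy is a Potts model: data term `max(−log(p + ε), 0)` with
`ε` equal to double-precision machine epsilon, and a constant penalty
`r = 4` for every unequal 4-neighbor pair (baseline prototype cut uses
`r = 3`). Minimization uses α-expansion. Each expansion move is an exact
binary min-cut solved with `scipy.sparse.csgraph.maximum_flow`:

- Capacities are scaled by `1e4` and rounded to int64, since the solver
  is integral. The rounding error per edge is below 5·10⁻⁵, negligible
  against the acceptance tolerances.
- The Potts pairwise term is submodular, so every move graph is exact:
  same-label pairs contribute an undirected edge `r`; pairs with two
  different non-α labels contribute `r/2` to each pixel's source
  capacity plus an undirected `r/2` edge; a neighbor fixed at α
  contributes `r` to the other pixel's source capacity.
- The minimum-cut side is recovered by breadth-first search on the
  positive-residual graph; source-side pixels take α.
- Moves are accepted only if the floating-point total energy strictly
  decreases, which guarantees termination and monotone descent.
- For two labels the problem is solved in a single exact cut, so binary
  instances are globally optimal. With three labels α-expansion is an
  approximation; against an exhaustive transfer-matrix oracle on random
  4×4 instances it attains the global optimum in ≥95 of 100 cases and is
  never more than 5% above it.

The CSI is read off as the deepest choroid-labeled pixel per column
(columns with no choroid pixel are linearly interpolated from their
neighbors) and median-filtered over 15 columns. The final CSI is clamped
to lie at or below the BM.

## Synthetic phantoms

Defaults produce 248×384 scans at 7.8 µm axial / 28 µm transversal
resolution — half the clinical 496×768 at 3.9/14 µm, chosen by this
package to keep the 100-image study fast while preserving geometry.
Layers (top to bottom): retina at intensity 60, a 5-row RPE band at 200
with a unique peak of 210 on its centerline (so noiseless tracking
recovers the true RPE exactly), a two-row taper to the choroid so the BM
is the unique axial gradient maximum, choroid at 120 carrying 12 dark
elliptical vessels (contrast 0.35, radii 2–6 px, confined to the
choroid), and sclera at 90. Boundaries are Gaussian-smoothed random
walks. Speckle is multiplicative gamma noise with shape 50 (unit mean),
i.e. a moderately averaged regime; shape `None` gives noiseless images.
Per-image seeds derive from `np.random.SeedSequence(base_seed)` and are
kept below 2³¹.

Realism and limits: the phantom reproduces the properties the pipeline
relies on — a bright RPE, an intensity edge at the BM, a texture (not
intensity-edge) contrast at the CSI — but not retinal layering, vessel
shadowing, depth-dependent signal decay, or motion artifacts. Errors
measured on phantoms therefore characterize the algorithm, not clinical
performance.

## Evaluation protocol

`run_phantom_study` trains on 10 phantoms and tests on 90 held-out ones,
mirroring the 10/90 split of the clinical protocol. Errors are the mean
signed (`pred − ref`) and unsigned column-wise row differences, in
pixels and micrometers; aggregates report mean ± sample standard
deviation (ddof = 1) across images. Baselines (DP search with a 7-pixel
RPE exclusion zone, k-means with depth-ordered relabeling, prototype
graph cut) run on the same BM-zeroed images as the method.

## Known limitations

- α-expansion gives no global-optimality guarantee for K ≥ 3; the bound
  above is empirical on small instances.
- The supervised fit assumes training masks are accurate; label noise
  propagates directly into the class Gaussians.
- Wavelet features are axial-only; transversally oriented texture is
  captured only through the energy window.
- The BM detector assumes the strongest sub-RPE gradient within 8 rows
  is the BM, which can fail under severe RPE atrophy.
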