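# Methods

This note documents the statistical models the package implements, the
defaults it ships with and why, the design choices made where the method was
genuinely open, and what the synthetic tests do and do not demonstrate.

## Superimposition

**Centroid size.** CS = √Σᵢ‖xᵢ − x̄‖², computed on raw coordinates before any
scaling; it is the only size variable used downstream (log-transformed in the
allometry model). Units are whatever the digitization used (micro-CT units);
no conversion is attempted.

**Generalized Procrustes analysis.** Partial Procrustes: each configuration
is centred, scaled to unit centroid size, and rotated to the running
consensus by the proper (det +1) Kabsch rotation; the consensus is the
normalized mean, iterated until its root-mean-square change falls below
1e-10 (cap 100 iterations, error on non-convergence). Reflections are never
introduced implicitly; left elements are made right-equivalent *explicitly*
by negating the first coordinate axis before alignment. The landmark scheme
is treated as side-symmetric, so mirroring requires no relabelling.

**Semilandmark sliding.** Sliding uses the minimized-Procrustes-distance
criterion, not bending energy. Each semilandmark's tangent is the central
difference of its flanking points on the curve (anchors included); the point
moves along the tangent by the least-squares step toward the consensus,
clipped to half the distance to the nearer neighbour so curve ordering can
never invert. Sliding alternates with full GPA re-superimposition (the
consensus evolves); the default is 5 cycles or a change in total Procrustes
distance below 1e-6, whichever comes first. Fixed landmarks never move. The
clipped tangential projection cannot increase a specimen's distance to the
consensus, which gives the monotone-descent property the tests assert.

**Bilateral symmetrization.** For each individual the mirrored left and the
right aligned shapes are Procrustes-averaged (one side rotated onto the
other, arithmetic mean, renormalized); centroid size becomes the mean of the
two side sizes. Individuals represented by one side pass through unchanged
and are flagged — this covers collections where some antimeres are missing
and matches how single, unpaired subfossil elements are handled (left
subfossils are mirrored into the right-equivalent frame). The symmetrized
set is re-superimposed so the stored consensus is its own Procrustes mean.
Sliding is performed before symmetrization; the two orders differ only at
second order in the asymmetry magnitude, and doing it on the full element
set uses all available information for the consensus.

## Morphospace

PCA is the eigendecomposition of the covariance (divisor N−1) of the
vectorized aligned coordinates, computed by SVD. At most min(N−1, 3K−7)
components are kept (superimposition absorbs 7 degrees of freedom in 3D).
Eigenvector signs are fixed so the largest-magnitude loading is positive,
making plots reproducible. Unknown specimens are mirrored if left-sided,
aligned and slid against the **fixed training consensus** — never allowed to
reshape it — then projected by matrix multiplication with the eigenvectors.
Because projected shapes are rescaled to unit centroid size, a synthetic
shape built as mean + t·v re-projects to t exactly only on the direct
(already-aligned) path; through the alignment pipeline the recovery is exact
to O(t²), which is well below measurement noise at realistic scores.

Ancestral states for phylomorphospace plots are maximum-likelihood Brownian
motion estimates, computed exactly as the solution of the sparse linear
system of branch-length-weighted squared-change parsimony; the root estimate
coincides with the GLS phylogenetic mean.

The thin-plate-spline warp uses the 3D kernel U(r) = r with a full affine
part; it interpolates the source landmarks onto the targets exactly and
reproduces affine maps exactly. Only the landmark-level warp field is
produced; surface-mesh rendering is out of scope.

## Hypothesis tests

**Procrustes ANOVA.** A linear model on the vectorized shape coordinates
with sequential (type-I) sums of squares in the order genus → log CS →
genus×log CS. SS are summed squared residual distances; F for each term uses
the full-model residual mean square. Significance is by residual
randomization (RRPP): for each term, residuals of the reduced model (all
preceding terms) are permuted, added back to the reduced fit, and the term's
F recomputed; p = (#{F* ≥ F} + 1)/(n_perm + 1) with the observed arrangement
counted. Size enters as log CS by default (the field-standard allometry
covariate; a raw-CS flag exists). With this single sequential model the
degrees of freedom are 4/1/4 with residual N−10; reported F statistics for
different terms therefore share one residual df, which is the one
arrangement consistent with an all-terms model. Default 1000 permutations.

**Pairwise shape tests.** Statistic = Procrustes distance between two group
mean shapes; null built by permuting the two groups' labels. Raw
(uncorrected) p-values are reported.

**Size ANOVA.** Classical one-way ANOVA on centroid size, with Tukey HSD
post-hoc comparisons via the studentized-range distribution (statsmodels).

**K_mult.** With tree covariance C (shared root-to-MRCA path lengths),
phylogenetic mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y and E = Y − 1a:

K = [tr(EᵀE)/tr(EᵀC⁻¹E)] ÷ [(tr C − n/1ᵀC⁻¹1)/(n − 1)]

The denominator makes E[K] = 1 under Brownian motion; K is invariant to
rescaling all branch lengths. Significance is by permuting the species
values across tips, K ≥ observed, observed included, 1000 iterations by
default. Species values are the within-species means of individual
symmetric-component PC scores (all components, so the trace equals total
shape variance).

## Classification

CVA solves the generalized eigenproblem of the between-group covariance
(divisor G−1) against the pooled within-group covariance W (divisor N−G) on
a reduced set of PC scores. Eigenvectors are W-orthonormal, so the canonical
space is fully whitened: squared Euclidean distance across all canonical
axes equals Mahalanobis D² in the retained-PC space — the identity the tests
verify to 1e-8. Only min(G−1, k) axes carry between-group variance and are
used for ordination plots; all k whitened axes participate in distances.

*PC retention.* Default: the smallest k reaching 90% cumulative variance,
capped at N − G − 1 so W stays invertible; configurable.

*Typicality.* Default chi-square: P(χ²_k ≥ D²), the probability that a true
group member lies at least as far from its group mean. A small-sample F
variant (Hotelling-style, pooled error df) is available by configuration and
converges to the chi-square form as N grows; the choice is recorded in the
report metadata. A typicality call requires p > 0.20 (the reporting
convention for "strong association"); a specimen whose best typicality is
below 0.05 is flagged as having no clear affinity.

*Posteriors.* Equal priors by default (configurable):
P(g|x) = exp(−D²_g/2)/Σ_h exp(−D²_h/2), computed with max subtraction. The
posterior argmax always coincides with the minimum-D² group.

*Cross-validation.* Leave-one-out: group means and pooled W are refitted
without the held-out specimen, which is then assigned by minimum D².

## The synthetic generator

`SimulationConfig` defaults emulate the study design: 13 species in 5 genera
on an ultrametric unit-depth tree, 43 modern individuals with both sides,
11 single-sided subfossils drawn from *Hoplodactylus*. Components, all in
unit-centroid-size shape units:

| parameter | default | meaning |
| --- | --- | --- |
| `bm_rate` | 8.1e-5 | Brownian shape variance per coordinate per unit branch length (among-species divergence) |
| `within_sd` | 0.006 | isotropic individual variation per coordinate |
| `asymmetry_sd` | 0.002 | left–right asymmetry per coordinate (cancels exactly in the symmetric component) |
| `allometry_coefficient` | 0.32 | shape displacement along one fixed direction per unit deviation of log CS from the genus mean |
| genus CS means ± sd | 1690±228.1 (Hoplodactylus), 968±100.9 (Woodworthia), 1198±142.9, 1241±115.6, 1093±104.0 | the modern sample's size structure |
| `fossil_size_scale` | 1.15 | subfossils run larger than the modern sample |

The allometry coefficient was calibrated once, analytically and then
confirmed by replicate simulation, so the fitted allometric fraction of
shape variance is ≈ 0.07 — the regime the analysis is meant to detect; with
the remaining defaults the genus term explains ≈ 0.4 of shape variance and
K_mult on fitted species means lands below 1 (individual noise dilutes the
Brownian structure), qualitatively matching real maxilla data. Every emitted
element is placed in its own random rigid frame at its own centroid size, so
nothing reaches the statistics without passing through superimposition.

What the generator does **not** emulate: spatially correlated landmark error
along real bone surfaces (an optional tangent-directed jitter exists but is
off by default), digitization outliers, missing landmarks, within-species
size–shape covariance beyond the single shared allometric direction, and
real maxilla geometry (the base shape is a deterministic 3D caricature).
Passing tests therefore demonstrate the *machinery* — alignment, descent,
calibration, recovery of injected effects — not that any biological
conclusion would replicate on real scans.

## Numerical choices and degenerate inputs

- GPA convergence 1e-10 RMS consensus change, cap 100 iterations; sliding
  5 cycles, tolerance 1e-6; all recorded in run manifests.
- All-coincident landmarks raise a degenerate-configuration error; exactly
  coincident landmark pairs are rejected at read time.
- Singular TPS systems (coplanar/collinear sources) raise with a hint to
  jitter; the pooled CVA covariance raises with a hint to retain fewer PCs
  when k > N − G.
- Permutation p-values are never 0: the observed arrangement is counted, so
  p ∈ [1/(n_perm+1), 1]; fixed seeds give bit-identical results.
- Ties in permutation statistics are counted as exceedances (≥ with a 1e-12
  slack) to keep the test conservative.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the full chain on the default
43-individual design (sub-second per study), 100 replicate studies for
allometry recovery, 500 Brownian replicates for the K_mult expectation, 500
null datasets (N=20, K=5, 199 permutations) for RRPP type-I calibration, and
n=1000 draws for typicality uniformity — sizes chosen so each property is
measured with standard error well inside its asserted band.

## Known limitations

- Surface (two-tangent-plane) semilandmarks, bending-energy sliding and
  missing-landmark estimation are not implemented.
- The sequential-SS Procrustes ANOVA is one of several df arrangements in
  use; single-term F tests fitted against different reduced models will give
  different residual dfs.
- Typicality probabilities use the full retained-PC dimension as chi-square
  df; with many PCs and few specimens per group they are conservative for
  out-of-sample material (estimation error in W is not propagated).
- The CLI's figure outputs are deliberately minimal; tables are the
  contract.
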