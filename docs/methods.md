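# Methods

`cortexgrad` re-implements, as a tested library, the analysis chain used
to map neurotransmitter-receptor organization across a parcellated
cortex: film densitometry, per-neuron normalization, PCA gradients with
a leave-one-receptor-out dependence statistic, spatially corrected map
correlations, cognitive-network embedding, and a microarray-to-parcel
gene-expression pipeline. Because the real inputs (receptor
autoradiographs, a macaque surface atlas, donor microarray data) are
large external datasets, the package ships a first-class synthetic-data
module that generates structurally faithful inputs with planted ground
truth, and every stage is validated by parameter recovery against that
truth.

## Densitometry

Standards of known radioactivity co-exposed with the tissue sections are
converted to binding-site concentrations by

    C_b = R / (E · B · W_b · S_a) · (K_D + L) / L   [fmol / mg protein]

with counter efficiency `E` (fraction ≤ 1), decay constant `B`
(Ci min⁻¹), protein weight `W_b` (mg), specific activity `S_a`
(Ci mmol⁻¹), dissociation constant `K_D` and incubation concentration
`L` (both nM). The formula is homogeneous of degree 1 in `R` and −1 in
each denominator factor; both identities are tested.

The film response curve gets no parametric form here: a monotone
piecewise-cubic (PCHIP) interpolant through the (gray value, C_b) knots
is exact at every standard and cannot oscillate between them, which is
the standard choice for film response. Standards must be jointly
monotone (either direction); gray values outside the knot range clamp to
the nearest knot with a warning, because film saturates and
extrapolating a saturating response is unphysical.

Laminar profiles are extracted from *rectified* 2-D patches
(depth × tangential): depth bins are equal row bands between the pial
and white-matter rows, averaged over the requested columns. True
curvilinear traversals of folded cortex are out of scope. Area means
average the depth-averaged densities of 3–5 section profiles; the
coefficient of variation uses the sample SD (n−1) because replicate
counts are small. Total binding is treated as specific binding (the
non-specific fraction of the ligands used is a few percent); subtracting
a blank image beforehand is available but off by default.

## Parcel map algebra

Overlap between two labelings of the same mesh is vertex-area-weighted
(not vertex-count-weighted; meshes are irregular): `overlap(s, t)` is
the surface area of `s ∩ t` divided by the area of `s`, so valid rows
sum to one and resampling `out(s) = Σ_t overlap(s, t) · map(t)` conserves
the global area-weighted mean whenever both labelings tile the mesh.
Resampling direction is always explicit; empty source rows are flagged
and propagate as missing.

Per-neuron conversion uses the protein mass fraction of brain tissue
(0.08) and the mg→g factor: `per_neuron = raw · 0.08 · 1000 /
neuron_density`. The constant rescales each area uniformly across
receptors, so z-scored PCA gradients are invariant to it (tested as
global-rescaling invariance of the PC scores).

Areas whose surface is majority (> 0.5) limbic-network are flagged for
downstream exclusion; the threshold is a package choice, as only the
fact of exclusion, not a cutoff, is standard.

## Gradients and the dependence statistic

Receptor columns are z-scored (SD with n−1) so high-density receptors
cannot dominate, and the gradients are the SVD factors of the
normalized matrix `X = U S Vᵀ`, with per-area scores `Z = U S`,
per-receptor loadings `V` and variance fractions `s_k²/Σ s_j²`. All
`m = min(A, R)` components are retained. Because SVD signs are
arbitrary, PC1 is oriented so its loading sum is positive (equivalently,
its scores correlate positively with total normalized density) and each
later PC so that its largest-|loading| receptor loads positively.

The gradient dependence of PC *n* on receptor *r* is computed by
deflating the first n−1 components (`X^(n) = Z_{:,n:} V_{:,n:}ᵀ`),
dropping column *r*, taking the first-PC scores of the reduced matrix
**without re-centering or re-scaling** (the deflated matrix is used as
is), and correlating them with the original `Z_n`:

    g = 1 − ρ²  ∈ [0, 1].

Squaring removes the arbitrary sign. `g ≈ 0` means the gradient
survives the receptor's removal; `g ≈ 1` means its spatial pattern
collapses. The implementation is checked against an independent
eigendecomposition-based oracle to 1e−10 on random matrices, and the
planted fixture verifies that the receptor that dominates the second
planted component is the argmax of `g` for PC2.

## Spatially corrected inference

Parcel maps are spatially smooth, so permutation nulls wildly overstate
significance. Null maps preserving the empirical autocorrelation are
built by variogram matching: permute the source values, smooth with
Gaussian kernels, and refit amplitudes so the surrogate's binned
empirical variogram matches the source's. The family here mixes two
independently permuted, independently smoothed components plus a
white-noise nugget,

    surrogate = √c₁·smooth_{h₁}(perm₁) + √c₂·smooth_{h₂}(perm₂) + √c₀·ε,

with non-negative amplitudes fitted per surrogate by weighted least
squares on the 25-bin empirical variogram (equal-count lag bins over the
lower 75% of pairwise distances; weights ∝ 1/γ² so the small short-lag
bins are matched in relative terms), and the bandwidth pair (from a
log-spaced grid of six values) with the smallest weighted misfit is
kept. A single-kernel surrogate is the special case c₂ = 0; a
white-noise source fits c₁ = c₂ = 0 and stays white. Finished
surrogates are rescaled to the source's exact mean and SD. The
two-kernel mixture exists because a single smoothing width cannot
reproduce a squared-exponential variogram at short and mid lags
simultaneously; `calibration_type_one_rate` measures the resulting
empirical type-I rate of the corrected correlation on independent
smooth-map pairs (correlation length 20 mm, 109 parcels, 500
surrogates), which the acceptance battery requires to lie in
[0.02, 0.10] at α = 0.05 — the naive permutation null on the same
fixtures rejects an order of magnitude more often (tested).

A note on tolerances: the mean surrogate variogram is compared to the
source's *single-realization* empirical variogram, whose per-bin
estimator noise is large — even ensembles drawn from the true
generating covariance deviate substantially per bin. Deviations are
therefore assessed against the variogram sill (≤ 0.2·sill at every
bin), not per-bin relative error.

Distances are Euclidean between parcel centroids — adequate at parcel
resolution on a near-spherical toy cortex; a precomputed geodesic
matrix can be supplied instead. The corrected p-value is the two-tailed
exceedance count with a +1 correction, `p = (1 + #{|r_null| ≥ |r|}) /
(1 + n_surr)`, so it can never be zero; 1,000 surrogates is the
default, 100 the enforced minimum. Bonferroni adjustment multiplies by
the declared family size and clamps at 1.

## Network embedding

Likelihood z-maps are binarized at a strict z > 3.1. The gradient's
vertex map is partitioned into 20 equal-count percentile bins (ties
broken by stable vertex order; bin sizes differ by at most one), and
the Dice coefficient of the mask with each bin yields an embedding
profile. The scalar plot coordinate is the Dice-weighted bin centroid
(`Σ b·Dice_b / Σ Dice_b`), a package decision — the argmax bin is
available as an alternative — and is rescaled linearly to the
gradient's score range for 2-D receptor-space placement. Vertex-level
receptor maps are piecewise-constant paintings of the per-area values.
Network summaries are vertex-area-weighted means (so network means,
weighted by network surface areas, recover the global mean exactly),
with the limbic network excluded by default.

## Gene expression

The microarray-to-parcel pipeline runs in a fixed order: Entrez filter →
sample-to-vertex assignment → z-score across probes within samples →
within-donor similarity filter → 40%-of-areas expression filter →
scaled-robust-sigmoid (SRS) normalization per donor → per-area
expression with nearest-significant-sample fallback → representative
probe per gene. Decisions where the procedure is conventionally
under-specified:

- "Significant expression" is the present/absent call matrix.
- Samples farther than 2 mm from the mesh are dropped; collisions on a
  vertex are resolved in stable (donor, sample) order by moving the
  later sample to the nearest unoccupied vertex.
- The similarity outlier rule is median − 3·scaled-MAD of the
  within-donor similarity distribution (similarity = Pearson r of a
  sample's probe vector with the mean of its donor's other samples);
  donors with fewer than 5 samples are skipped. The rule is
  configurable because only "exceptionally low" similarity is standard.
- The 40% expression filter counts an area as expressing a probe when
  at least one assigned sample has a present call; the denominator is
  the number of areas containing at least one assigned sample, and the
  boundary is inclusive.
- SRS, `y = 1/(1 + exp(−(x − median)/(IQR/1.35)))` min–max rescaled to
  [0, 1], is applied per donor and probe across that donor's samples
  (normalizing away donor scale before samples from all donors are
  pooled into areas). It is invariant to positive affine transforms
  and monotone; both properties are tested.
- Representative probe: 2 probes → higher across-area variance; ≥ 3 →
  highest mean correlation with the others; ties break by probe id;
  all-constant profiles fall back to the variance rule with a warning.

## Synthetic data: what it emulates and what it does not

The toy cortex is an icosphere (radius 30 mm, surface area comparable
to a macaque hemisphere) parcellated by geodesic Voronoi growth from
farthest-point seeds, which guarantees contiguous parcels; a flat grid
mesh is available for fast tests. Seven network labels are grown the
same way. All randomness flows from one integer seed through a
CRC-mixed `SeedSequence` schedule, so every generator is a pure
function of (seed, parameters).

The receptor matrix plants K smooth, mutually orthogonal gradient score
fields (component scales 3.0 and 1.2, so the shared component dominates
as in real data), an all-positive loading vector for component 1, and a
component 2 dominated by the canonical 5-HT1A slot. The z-space matrix
plus Gaussian noise (SD 0.2 by default) is mapped to per-neuron units by
per-receptor location/scale pairs chosen so each receptor spans a
severalfold range while staying positive (extreme excursions are
clipped just inside the positivity bound), and to raw units by the
exact inverse of the per-neuron normalization. Neuron density spans
exactly a 5-fold range with a center-clustered distribution — most
areas share a narrow band while a few extremes reach the cap, as real
cortical neuron counts do — and anticorrelates mildly (coupling 0.3)
with the planted principal gradient, since neuron-dense sensory areas
express fewer receptors per neuron. Because raw = per-neuron × density,
the density factor partially cancels the shared gradient in raw units;
the raw-matrix PC1 therefore correlates moderately (≈ 0.55 on the test
fixture), not near-perfectly, with the per-neuron PC1.

Microarray-like samples sit at jittered mesh vertices with donor
offsets, probe offsets and Gaussian noise (SDs 0.5, 0.5, 0.1) on top of
smooth planted per-gene area maps; present/absent calls are Bernoulli.
Functional z-maps activate a chosen percentile band of a gradient map
(peak z = 6 against sub-threshold background), so the true embedding
position is the band midpoint.

Not emulated: cortical folding, film-exposure physics beyond the
calibration curve, registration errors between native and template
spaces, donor-specific spatial coverage biases, and probe
cross-hybridization. Passing recovery tests therefore demonstrates the
*algorithms* are correct and well-calibrated on data with the study's
statistical structure, not that the pipeline is robust to every
artifact of real acquisitions.

## Problem sizes and numerical choices

Default test/acceptance sizes: 60-area cortex (2,562 vertices) for
recovery, 109 areas for spatial statistics, 20 seeds for recovery
averages, 400 null pairs × 500 surrogates for the calibration check.
Covariance factorizations add escalating jitter (from 1e−10) before
failing; z-scoring rejects constant columns; degenerate reduced
matrices in the dependence statistic raise rather than return NaN; the
dependence correlation is clipped to [−1, 1] against round-off. CoV
summaries skip cells with fewer than two finite replicates and report
the skipped count.

## Known limitations

- Surrogate calibration is mildly conservative (the measured type-I
  rate sits below the nominal α = 0.05); exceedance-count p-values
  with +1 correction add a little more conservatism at small surrogate
  counts.
- The linear back-transform of the synthetic matrix cannot reproduce
  extremely skewed receptors (a 17-fold range implies a lognormal-like
  distribution); planted ranges are severalfold instead.
- Geodesic distances, curvilinear laminar traversals and vertex-level
  surrogates are out of scope.
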