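# Methods

This note documents the models, conventions and numerical choices behind
`fbandnet`, and what the synthetic-data experiments do and do not show.

## Scope and data model

The unit of analysis is a paired cohort: each subject contributes a
baseline and a post-treatment resting-state session, each an ROI
time-series matrix (regions × volumes) with a known TR. Defaults emulate a
small clinical imaging study: 12 subjects, 76 Desikan–Killiany regions,
180 volumes at TR = 2 s. Image-level preprocessing (parcellation,
registration, physiological regression) is out of scope; the pipeline
starts from region-averaged series.

## Motion scrubbing and nuisance regression

A volume is censored when its DVARS-like derivative-RMS value exceeds 8
and/or its framewise displacement exceeds 0.5, together with the volume
immediately before and the two volumes after the offender; windows
truncate at the series boundaries and overlapping windows are unioned.
DVARS is treated in the same raw units as the threshold of 8, without
rescaling; synthetic motion traces are generated in those units.

Order of operations: nuisance regression → wavelet filtering of the full
contiguous series → censored volumes excluded only when correlations are
computed. The undecimated wavelet transform requires contiguous input, so
deleting volumes before filtering is not an option; flagging and late
exclusion keeps the filter valid at the cost of letting censored samples
influence the band decomposition of their neighbors. Nuisance regression
is ordinary least squares against [intercept | nuisance columns]; it is a
projection (idempotent) and residuals are orthogonal to every column.

## Stationary wavelet bands

Each region's series is decomposed with a 4-level stationary (undecimated)
DWT using the orthonormal `db4` filter pair. Level j nominally covers
(f_N/2^j, f_N/2^{j−1}) with f_N = 1/(2·TR); at TR = 2 s this gives
0.125–0.25, 0.0625–0.125, 0.03125–0.0625 and 0.015625–0.03125 Hz.

Implementation: the per-level detail *reconstruction* (not the raw frame
coefficients) is computed directly through its zero-phase transfer
function B_j(ω) = |G(2^{j−1}ω)|²/2 · Π_{l<j} |H(2^{l−1}ω)|²/2 on the FFT
grid, where (H, G) are the DFTs of the scaling/wavelet filters. Because
|H|² + |G|² = 2 for an orthonormal pair, the four detail functions plus
the approximation sum to exactly one: perfect reconstruction holds to
machine precision, and circular convolution makes the transform exactly
shift equivariant. This is numerically identical to `pywt.swt` followed by
a per-level `pywt.iswt` (verified in the test suite) but imposes no
power-of-two length constraint, which matters for 180-volume sessions.

Boundary handling is a config option: `periodic` (default; exact
translation invariance, at the cost of wrapping the series end onto its
start) or `symmetric` (mirror extension to twice the length, then
periodic; still perfectly reconstructing, no wrap-around artifact, but
shift equivariance is only approximate). Downstream connectivity uses the
band-limited reconstruction series, so correlations live on the original
sampling grid.

## Connectivity

Per band and session, connectivity is the Pearson correlation of the
band series over retained volumes (76 × 76, 2850 unique pairs). No Fisher
z-transform is applied anywhere: thresholding and group comparisons
operate on raw r. Zero-variance regions get correlation 0 with a logged
warning rather than NaN — a 0 never survives positive-weight
thresholding, so this keeps the pipeline total without affecting graphs.
At least 8 retained volumes are required; this is an artifact guard, not a
statistical recommendation.

## Graph topology

Binary graphs keep the largest positive correlations at each density of a
uniform grid (default 0.10–0.50, step 0.01; the analysis scripts use step
0.05 to keep their runtime in minutes). The edge-count target is
round-half-away-from-zero of density·2850. Ties at the cutoff are admitted
in lexicographic (i, j) order, which makes edge sets exactly nested across
the grid. Negative correlations are never admitted, so the realized count
can fall short of the target (logged).

Measures and conventions:

* clustering C_i = 2·triangles_i/(k_i(k_i−1)), 0 when k_i < 2;
* characteristic path length is the harmonic version
  L_net = n(n−1)/Σ_{i≠j} d_ij^{−1} with d^{−1} = 0 for disconnected pairs
  (robust to fragmentation; an edgeless graph returns +∞);
* local efficiency is the mean inverse distance among a node's neighbors
  *within the neighbor-induced subgraph* — note that two non-adjacent
  neighbors connected through a third neighbor contribute 1/2, not 0;
* betweenness is normalized by (n−1)(n−2)/2;
* module partitions come from greedy (CNM) modularity maximization,
  computed once per graph and shared by the participation coefficient and
  the within-module degree z-score; the z-score uses the population-SD
  convention, with z = 0 for zero-spread (including singleton) modules;
* participation y_i = 1 − Σ_m (k_i(m)/k_i)², with y_i = 0 for isolated
  nodes.

C_rand and L_rand are means over degree-preserving double-edge-swap
randomizations (default 100 references, 10·|E| accepted swaps each,
seeded). Graphs with no valid swap (e.g. complete) reference themselves,
giving C_norm = L_norm = σ = 1. AUC over a uniform density grid is the
arithmetic mean of the curve.

## Paired inference

The change D of a feature is tested by sign-flip permutation: under
exchangeability of pre/post within subject, each subject's difference is
equally likely to carry either sign. With n subjects the sign space has
2^n points; the test enumerates it exactly whenever 2^n does not exceed
the requested realization count (always at n = 12, where 4096 < 10⁶),
otherwise it draws seeded random assignments. Enumeration is exact and
strictly better than over-sampling a 4096-point space. The p-value is the
tail probability of the permuted mean D′ beyond D *in the direction of
sign(D)*, with the observed assignment in the tail (p is never 0 and is a
multiple of 2^−n when exhaustive; 1/realizations is the resolution when
sampled).

**Calibration caveat.** Choosing the tail from the observed sign makes
this a data-adaptive one-sided test: under the null its p-value is uniform
on (0, 1/2], not (0, 1], so the realized probability of p < α is 2α
(~0.10 at α = 0.05). This is a property of the test definition itself, and
the test suite verifies both the grid-uniformity and the doubled rejection
rate. Consumers who need exact size should double the reported p (or halve
α); the package reports the directional p unchanged because the downstream
tables, thresholds and subnetwork construction are defined on it.
Consequently the BH-FDR subnetworks control the false-discovery rate at
~2α·m₀/m rather than α·m₀/m; in the planted-effect experiments the
realized false-discovery proportion is ≈ 8% at nominal α = 5%.

Effect size is Cohen's d with pooled (n−1)-weighted SD over the two
sessions, signed so that a decrease after treatment is negative. Power is
that of the two-sided one-sample t-test of the changes against μ₀ = 0 at
α = 0.05, from the noncentral-t distribution with noncentrality
√n·mean/SD and n−1 df.

Multiple-testing families follow the design: per band, 76 regions for
nodal metrics and 2850 edges for connectivity (Bonferroni thresholds
0.05/76 ≈ 0.00066 and 0.05/2850 ≈ 1.75 × 10⁻⁵); no pooling across bands.
BH-FDR at α = 0.05 defines the per-band subnetwork of significantly
changed connections, summarized by within-subnetwork nodal degree.

**Granularity interacts with correction.** At n = 12 the smallest exact
p-value is 2^−12 ≈ 2.44 × 10⁻⁴, which lies *above* the edgewise
Bonferroni threshold 1.75 × 10⁻⁵: with exact enumeration no connection
can ever pass edgewise Bonferroni at this sample size (a sampled test can
only appear to, by reporting 0 for any p below its Monte-Carlo
resolution). Similarly, the BH step-up needs p_(k) ≤ k·α/m, so a
subnetwork among 2850 edges is either empty or contains at least
⌈m·2^−12/α⌉ = 14 connections. Both facts are properties of the design,
not of the implementation, and the analysis scripts call them out.

## Clinical regressions

OLS of the clinical change score on a network feature with optional
covariates (age, a single sex indicator, IQ). The partialed slope equals
the Frisch–Waugh residual-on-residual fit (asserted in tests). Subjects
with missing values are dropped listwise; at least 4 complete cases are
required. No multiple-comparison correction is applied — these are
exploratory. A pooled mode stacking both sessions as if independent is
provided, clearly labeled, because that analysis style appears in the
literature; it inflates the false-positive rate and is not endorsed.

## Synthetic cohorts

Each session is a sum of five components: four detail-band processes and
a coarse approximation. Component k starts as iid Gaussian noise, is mixed
across regions by an eigenvalue factor of its target correlation matrix,
and is band-limited with the *same* transfer functions as the analysis —
so planted structure lives exactly in the analyzed bands and parameter
recovery is a true end-to-end test. `noise_sd` scales overall amplitude
only; correlations are set entirely by the per-band target matrices.

Adjacent wavelet bands overlap spectrally (the band-energy mixing matrix
has diagonals ≈ 0.84–0.97), so measured band-j correlations mix the
generating correlations of neighboring bands. The generator inverts this
mixing (the approximation component shares the coarsest band's matrix and
is folded into its column), then projects each compensated matrix to the
nearest valid correlation matrix by eigenvalue clipping if needed.
Measured band correlations therefore match the requested ground truth in
expectation; empirically, planted r = 0.6 at 2000 volumes is recovered
within ±0.05 in every band.

Default conditions: 12 subjects, 76 regions, 180 volumes, TR 2 s, a
6-module template with within-module r = 0.5 and between-module r = 0.1,
noise_sd = 1. The template values are plausible for parcel-averaged BOLD
but are not calibrated to any particular dataset — the study the method
targets does not publish empirical connectivity distributions. Planted
effects must keep the post-session matrices positive semidefinite;
vertex-disjoint within-module edges tolerate |Δr| up to ≈ the smallest
template eigenvalue (0.4–0.5 here), and violations are rejected naming the
offending edge. What passing tests show: the pipeline recovers the
structure this generator plants. What they do not show: robustness to
hemodynamic filtering, 1/f noise spectra, scanner drift, global signal, or
real motion — none of which the generator emulates (motion traces are
schematic spike trains for exercising the scrubbing rule).

Clinical scores are generated as change = intercept + slope·feature +
Gaussian noise around a moderate-to-severe baseline (mean 30, SD 9),
enabling slope-recovery tests of the regression step.

## Problem sizes

The test and analysis runs use deliberately scaled problems chosen to keep
full runs in minutes while preserving every contract: 4–12 subjects,
12–76 regions, 64–2000 volumes, density steps 0.05–0.1 in tests, 8–100
rewired references. The statistical experiments (null calibration,
planted-edge recovery) use 20 cohorts of 12 subjects each, with 2000
volumes for the power experiments.

## Known limitations

* The adaptive-tail permutation p-value is anti-conservative by a factor
  of two at nominal level (see above); it is reported as defined.
* Greedy modularity is one of many community methods; partitions (and
  hence participation/z-score values) are convention-dependent.
* The density-grid step, reference-network count and tie-break rule are
  conventions; results at a single density should not be over-read.
* Scrubbing interacts with filtering only through late exclusion;
  heavily censored sessions (< 8 retained volumes) are rejected rather
  than imputed.
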