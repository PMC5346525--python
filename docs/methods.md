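# Methods

This note documents the models, numerical conventions, and design choices
behind `connectodyn`, and what the synthetic cohort does and does not
emulate.

## Synthetic cohort

The generator produces everything the analysis consumes — ROI time series,
gray-matter volumes with a parcellation, and a cohort table of covariates and
cognitive scores — with the ground truth recorded in a JSON manifest, so
every downstream stage is testable by parameter recovery.

**ROI signals.** Each region's signal is exact fractional Gaussian noise
(fGn) built by circulant embedding (Davies–Harte): the target autocovariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) is embedded in a circulant of
size 2T whose FFT eigenvalues synthesize a Gaussian series with *exactly*
that autocovariance. A non-positive-semidefinite embedding raises rather
than silently approximating (the check is defensive; the fGn embedding is
valid throughout H ∈ (0, 1)). Community structure mixes three independent
fGn streams per region — a subject-global factor g, a block factor f_b, and
an idiosyncratic term e — as x = a·g + b·f_b + c·e with a² = r_between,
a² + b² = r_within, a² + b² + c² = 1, so expected correlations hit the
configured levels exactly (defaults 0.6 within, 0.1 between, six blocks of
15 regions). Hurst truth defaults are 0.19 (patients) versus 0.22
(controls), the study's published group means; those published numbers are
group summaries whose spread mixes subject and estimation variance, so here
they serve as a single per-group truth shared by all regions, and the
subject-level spread of the 90-region average is correspondingly much
tighter than the published SDs. No hemodynamic response, scanner noise, or
motion artifact is modeled: passing recovery tests shows the estimators are
correct on long-memory Gaussian signals, not that they are robust to fMRI
artifacts (that robustness is the job of the out-of-scope preprocessing).

**Gray matter.** Subject volumes are base level 0.55 plus a smooth shared
template fluctuation (Gaussian-filtered white noise, filter width 2 voxels,
SD 0.12), an optional per-parcel group shift (default zero, matching the
study's null global structural findings), and smooth subject noise
(SD 0.05), clipped to [0, 1]. A one-voxel border is background (label 0);
the interior is split into near-equal boxes, one parcel per atlas region.
The study's 12-mm VBM smoothing is emulated by field smoothness, not
replicated. The default 20×24×20 grid yields ~260 cube nodes per subject
(desk scale); the study's ~8,525-node networks are a configuration choice
with quadratic pairwise cost.

**Cognitive scores.** Per-group multivariate normal draws at the study's
published means/SDs for the 11 tests, with a uniform inter-test correlation
(default 0.3), a per-group Bernoulli minority covariate (0.33/0.20) and a
normal distress (CAD) score per group.

**Injected patient effects.** A standard-normal latent u per patient couples
the two modalities: within-block functional correlation becomes
r_w + 0.18·u (clipped), raising functional clustering with u, while the
template fluctuation is scaled by exp(0.8·u), which pushes densities into
clipping and past the cube-inclusion rule and *lowers* structural
clustering with u. The result is a strong negative correlation between
structural and functional global clustering in patients only (about −0.8 at
the defaults) with controls near zero — a deliberately strong coupling
disruption chosen once so that a 30 + 30 cohort detects it with high power;
`fc_coupling = sc_coupling = 0` switches the injection off. Cognitive scores
are independent of u by default, so the composite-versus-PCA correlation has
no injected truth.

**Determinism.** All randomness derives from `numpy` SeedSequences keyed by
(config seed, stream id, subject index); identical (config, seed) reproduce
every output file byte-for-byte, and the manifest embeds the config for
round-trip regeneration.

## Functional connectome

Pearson correlations between region time courses, clipped to ±(1 − 10⁻⁷)
before atanh so duplicated series saturate at z ≈ 8.41 instead of diverging;
constant regions are an error naming the offender. An optional confound
table is residualized out of every region series (OLS with intercept) before
correlation — the hook that carries motion-parameter regression in real
pipelines.

## Structural similarity network

Cubes tile the masked volume on a lattice anchored at the volume origin;
trailing voxels on non-divisible axes are dropped. The 27 values are stored
x-fastest (flat index x + 3y + 9z); the inclusion rule (≥ 14 of 27 voxels
above the 0.1 density threshold) is a majority-gray criterion — the
literature leaves the rule unstated, and majority coverage approximates
"spanning the gray matter" while excluding background. Similarity is the
Pearson correlation of the paired values; the rotation variant maximizes
over all 48 orthogonal cube symmetries and is off by default (the plain
correlation is what the method description states; the rotation
maximization of the originating similarity method is available via config).
Exactly constant cubes have undefined similarity and are dropped with their
count retained. The matrix builder is vectorized ((Z Zᵀ)/27 on standardized
rows) and streams row blocks in the rotation path to bound memory.

## Thresholding and clustering

Edges are ranked by descending positive weight with deterministic
(row, column) tie-breaks; negative weights never enter (correlation-graph
convention). The per-subject connecting density is found by bisection over
the edge count (connectivity is monotone in edges); the cohort-common
minimum connection density is the maximum over subjects, applied per
modality by default (a single common density across modalities is a config
choice — the source leaves this open). Clustering is binary after
thresholding ("actual over possible neighbor connections" is the binary
definition); degree-<2 nodes get 0 so the global mean stays defined over all
nodes.

## Hurst estimation

R/S of a segment is (max − min of the cumulative mean-deviations) divided by
the *population* SD. The expectation used in the bias-corrected regression
is the Anis–Lloyd sum with the Peters finite-sample prefactor,
E[R/S]_n = ((n − ½)/n) · c_n · Σ_{i=1}^{n−1} √((n−i)/i) with
c_n = Γ((n−1)/2)/(√π Γ(n/2)) evaluated through `gammaln` at every n (the
common switch to the asymptotic prefactor above n ≈ 340 exists only to dodge
overflow and introduces a small non-monotone step at the crossover). Two
numerical conventions matter and are deliberate:

1. The Anis–Lloyd sum corresponds to a sample-SD (ddof = 1) denominator;
   because segments here use the population SD, every segment's R/S is
   exactly √(n/(n−1)) times the sample-SD version, and the regression
   multiplies the expectation by that factor. Mismatching the conventions
   leaks a spurious negative slope (white-noise mean Ĥ ≈ 0.47 instead of
   0.49–0.50).
2. Window sizes are divisors d of the base M with
   max(min_window, ⌊√M⌋) ≤ d ≤ M/2 (at least two segments per size;
   min_window defaults to 8). Below ~√M the R/S of a long-memory series is
   dominated by a small-sample transient that the null-anchored expectation
   cannot cancel, which shrinks estimates toward 0.5; long series afford
   discarding those scales. When the √M guard leaves fewer than three sizes
   the bound relaxes back to min_window so study-length series (M = 180,
   sizes 15…90) remain estimable.

The "time series interval" for the divisor-maximizing base is read as
[1, T], ties broken by the largest M (keeps the most data). Segments are
non-overlapping (classical procedure; independence across segments).
Residual behavior worth knowing: R/S estimators retain a shrinkage toward
0.5 away from the null (H = 0.8 at length 4096 recovers ≈ 0.76; the
white-noise null at the study length is centered within ±0.01), and
monotonicity in the true H is preserved. Regions whose estimation fails
(constant signal) carry NaN and are excluded from the subject's global mean
with a logged count.

## Statistics layer

The group GLM is OLS `outcome ~ group + covariates` with the group F from a
full-versus-reduced model comparison, which equals the type-III F for a
single two-level factor under any coding; a constant outcome returns
F = 0, p = 1. FDR is Benjamini–Hochberg step-up. The rank test reports
Mann–Whitney U (pairs with x < y plus half-ties) with a tie-corrected normal
approximation and no continuity correction. Correlation p-values use the
t reference with n − 2 degrees of freedom; correlation differences use the
Fisher z test with variance 1/(n₁−3) + 1/(n₂−3). The structure–function PCA
standardizes the two clustering columns over all participants and
eigendecomposes their 2×2 correlation matrix, orienting the structural
loading positive; the first-component variance is exactly (1 + |r|)/2. The
cognitive composite is the Mahalanobis distance of each patient's score
vector from the *control* mean under the control (unbiased) covariance — so
it measures deviance from controls, not pooled spread — floored at 10⁻¹²
before the natural log (base unstated in the source; natural log chosen).
The default composite uses the four tests that survive FDR under the study
conditions (RAVLT total recall, RAVLT interference, CTMT trial 1, COWA),
configurable. Self-report measures (BRIEF, PRMQ) are modeled with the
distress covariate but excluded from the 10-measure FDR family. For the
structural-clustering-versus-Hurst pair the battery reports Spearman
alongside Pearson (the published p for that pair is consistent with a rank
correlation; the source does not say which was used). Per-region families
(functional clustering, structural clustering, regional Hurst) are
FDR-corrected within family; a parcel with no cubes yields a missing value,
not zero.

## Pipeline

Stages (simulate → fc-build → sc-build → metrics → hurst → stats) are
restartable from cached upstream files; any failure aborts with the stage
name and subject id. The provenance record lists every output file, the
config hash and seed; reruns at a fixed seed reproduce the statistics bundle
byte-for-byte. Gray-matter masks are subject-specific by default (a group
mask is a config choice). The CLI is a thin argparse layer over the same
stage functions.

## Known limitations

- The fGn cohort has no task structure, drift, spikes, or physiological
  noise; preprocessing robustness is untested by design.
- R/S Hurst estimates shrink toward 0.5 away from the null; group *contrasts*
  survive (both groups shrink together), absolute levels should not be
  compared against other estimators.
- The structural generator's coupling mechanism (clipping + inclusion-rule
  attrition) is a convenient monotone handle, not a biophysical model of
  gray-matter covariance change.
- Study-scale structural networks (~8.5k nodes) are supported but quadratic
  in node count; the defaults run a full 60-subject cohort in well under a
  minute per stage on one CPU.
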