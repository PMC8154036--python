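# Methods

This note documents the models and procedures implemented in `faaverse`,
the parameter choices that matter, what the synthetic data do and do not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Spectral pipeline

Referenced continuous data are processed as:

1. **Common-average reference** — per sample, the mean over channels is
   subtracted from every channel (idempotent; any signal common to all
   channels is in its nullspace). Current-source-density and source-space
   data are *consumed* under the `csd` / `src` labels, never computed here.
2. **Rest cropping** — the first 2 s after rest onset are dropped (eye-
   closing artifacts), together with the corresponding 1-s bad-segment mask
   entries. The skip must be a whole number of seconds so mask alignment is
   exact.
3. **Welch PSD** — 2-s windows, 0.5-s step (75 % overlap). A window is
   discarded if *any* of its samples falls inside a rejected 1-s segment
   (the strict reading of mask overlap); remaining tapered periodograms are
   averaged. Output is provably invariant to the content of rejected
   segments. Frequency resolution is 1/win_s = 0.5 Hz.
4. **Band log power** — mean of PSD bins with 8 ≤ f ≤ 13 (edges inclusive),
   then natural log.

Conventions the inference is invariant to, fixed for definiteness and
configurable: Hann taper; one-sided power-per-Hz PSD normalization; natural
log (any base change rescales FAA uniformly and cancels entirely in
z-scored analyses).

## 2. Asymmetry representations

- **Pair FAA**: `values[s, k] = log-power(right_k) − log-power(left_k)` for
  homologous frontal pairs (odd↔even 10-20 labels). Antisymmetric under
  swapping pair roles; invariant to per-subject global power rescaling.
- **Standardized maps**: per subject, z-score of the log-power map over the
  frontal-channels × alpha-bins space (midline channels retained, no
  frequency averaging, no subtraction). Invariant to per-subject affine
  transforms of the log map; sensitive to non-asymmetric effects, which is
  why significant clusters on this representation receive a left/right
  chi-square follow-up. Standardization is applied to *log* power by
  default (consistent with the band pipeline); a switch applies it to
  linear power.

The montage is an idealized spherical 10-20 subset (23 channels,
mirror-symmetric by construction). For montages with non-10-20 labels
(e.g. EGI nets) `layouts.PAIR_ALIASES` is an editable label-correspondence
hook; the synthetic studies all use the built-in montage, so it defaults to
empty.

## 3. Cluster-based permutation engine

Implemented from scratch over arbitrary symmetric adjacency graphs.

- **Adjacency**: channels are neighbours when their 3-D distance is ≤ 1.5 ×
  the median nearest-neighbour distance; channel × frequency lattices are
  the Cartesian product with a path graph over bins; pair spaces inherit
  the left-member geometry; source surrogates use a 4-neighbour lattice.
- **Pointwise statistic**: Welch *t* for plain group contrasts; OLS slope
  *t* (via Frisch–Waugh residualization, vectorized across permutations)
  for linear contrasts and for any contrast with confound control.
- **Entry threshold**: two-sided critical value at α = 0.05. Degrees of
  freedom: n₁+n₂−2 for the Welch map (a common-df threshold; per-node Welch
  df would make the threshold node-dependent), n−p−1 for regression maps.
- **Null**: labels (or predictor values) are permuted between subjects;
  confounds stay attached to their subjects (simple predictor permutation,
  not Freedman–Lane). Each draw contributes its maximum positive and
  minimum negative cluster mass to tail-specific nulls. When the number of
  distinct relabelings is ≤ n_perm (e.g. C(8,4) = 70 for a 4-vs-4 design)
  the engine enumerates them exactly and p-values carry no Monte-Carlo
  error; otherwise p = (1 + b)/(1 + n_perm), which cannot reach zero.
- **Tails**: by default each cluster is compared only with its own tail's
  null and the tail probability is reported as-is — the procedure as
  commonly described and tabulated. Under the null the chance that *some*
  cluster reaches p < α is then close to 2α (two ~α-level tails). For
  strict two-sided familywise control `two_sided_p=True` doubles the tail p
  (capped at 1); by exchangeability the per-tail level is then exactly
  ⌊α/2·(n+1)⌋/(n+1), so the union rate sits just below α. The calibration
  acceptance test runs in this strict mode; a unit test covers the default
  mode's per-tail behaviour.
- **Reporting**: "largest cluster" is by member count (matching
  cluster-size table columns), with the mass-ranked p also reported; rows
  with no clusters print NA.

The chi-square follow-up compares the share of left-side search-space nodes
inside a cluster with the right-side share (Pearson χ², df = 1, no
continuity correction; midline nodes excluded from both margins); a
mirror-symmetric cluster yields χ²(1) = 0, p = 1 identically.

## 4. The multiverse grid

One spec = study × contrast × space × approach × confound flag. Availability
is per study: group contrasts exist only where both groups do, and each
study has its own confound set (gender/age for Studies I and IV;
gender/age/education for II, III, V). With two channel pairs, two channel
spaces plus a source space, and the confound toggle this yields 270 specs,
120 of them channel-pair variants; `availability_from_meta` derives the
table from group structure for user-defined studies. Row-level α is 0.05
with *no* correction across analyses — the meta-level inference is the
binomial significance-count test, partitioned by approach, contrast, or
confound flag, together with a congruence count (significant rows whose
direction is the classical negative FAA; standardized-space effects carry
no direction and never count).

`csd` and `src` are data-selection keys: the runner consumes datasets
tagged with those labels (real CSD or beamformer outputs, or generator
surrogates), keeping the full grid executable without implementing the
transforms. Per-row seeds are derived from the base seed by index, recorded
in the row and the JSON manifest, so any row is reproducible in isolation.

## 5. Aggregation across studies

Because labs differ in equipment and impedance regimes, pooled analyses
z-score FAA within study; a Levene gate (ANOVA on absolute deviations from
group means) is computed and recorded first. z-scoring is *always* applied
— a single reproducible code path rather than gate-conditional behaviour
(`zscore=False` restores manual control); the gate result is reported so
the reader can see whether it mattered. With confound control, each study's
values are first residualized on that study's available confounds (subjects
with missing confounds dropped listwise), then z-scored. Questionnaire
scores are z-scored within study before linear contrasts because studies
use different instruments (BDI-I/BDI-II/PHQ-9). Aggregated group contrasts
use Welch's t on the pooled z-scores (the pooled-vs-Welch choice is
immaterial after within-study standardization; Welch is the default for
consistency with the per-study analyses). The gender × diagnosis (or
× score) interaction is tested by OLS with main effects and the product
term on confound-residualized pooled values.

## 6. Scalar statistics

- Cohen's d uses the pooled SD even alongside Welch's t (the common
  pairing). Under confound control the effect size is the partial
  correlation r = t/√(t²+df).
- BCa intervals: bias correction from the share of bootstrap statistics
  below the point estimate, acceleration from jackknife skewness
  (delegated to scipy's BCa bootstrap); independent resampling for
  two-sample statistics, joint row resampling for correlations and partial
  r. Degenerate bootstrap distributions collapse to a point interval with
  a warning; rank-deficient resamples of a binary predictor (probability
  ~2⁻ⁿ per draw) contribute the observed estimate instead of failing.
- JZS BF01: the g-mixture closed form of the Cauchy-prior marginal
  likelihood, integrated by adaptive quadrature (prior scale r = 0.707);
  the correlation BF01 integrates Hotelling's exact sampling density of r
  against a stretched-beta prior with κ = 1 (uniform). Both are inverted to
  favour the null. Gender is coded 0/1 and education in years in all
  regression designs.
- Binomial meta-test: exact upper tail P(X ≥ k), X ~ Binomial(n, 0.05).

## 7. The synthetic-data generator

What it emulates: five cohorts with the published group designs (29/22,
28/25/23, 27/21/34/9, 22/72/21/2, 24/29) and acquisition parameters
(512/200/250/512/250 Hz; 300/300/180/180/300 s of eyes-closed rest);
questionnaire scores respecting the group definitions (healthy ≤ 5,
subclinical ≥ 10, unclassified 6–9); group-linked confounds (defaults
loosely matching the diagnosed-vs-control age gap in Study I and the lower
education of the diagnosed group in Study V, plus an optional
missing-metadata fraction); i.i.d. Bernoulli bad-segment masks (5 %
default; contiguity is deliberately not modelled — the Welch stage depends
only on the mask); and per-study FAA dispersion (`faa_sd`, defaults 0.30 /
0.50 / 0.35 / 0.45 / 0.60 across the five studies) so the pooling scale
gate is non-trivial. The published record does not characterize per-study
FAA variance; these dispersions are the generator's own choice and are
flagged as such.

Signal model, per subject: unit-variance 1/f^β background per channel
(β = 1 default) plus an amplitude-modulated alpha oscillator per channel —
subject-level peak frequency ~ N(10.5, 0.8²) Hz clipped so ±3 SD stays in
(8, 13), per-channel frequency jitter of SD 0.25 Hz, random phases, slow
(≤ 2 Hz) positive envelopes giving the peak its width, posterior-dominant
amplitude topography, subject amplitude ~ N(2.5, 0.5²). The whole study is
scaled by √power_scale; since FAA is a log-ratio, `power_scale` shifts log
band power but cancels exactly in FAA (scale differences relevant to the
Levene gate are therefore governed by `faa_sd`, not `power_scale`).

**Effect injection.** A per-subject latent a ~ faa_sd·(d·1[diagnosed] +
r·z(score) + √(1−r²)·ε) multiplies right-frontal alpha amplitudes by
exp(+a/4) and left-frontal by exp(−a/4), so the alpha power ratio R/L is
exp(a) and measured FAA tracks a wherever alpha dominates the frontal band
(the defaults give roughly a 8:1 in-band alpha:background ratio frontally).
Attenuation by the background multiplies the group difference and the
between-subject SD equally, so Cohen's d is preserved; the population FAA
contrast equals `asymmetry_effect_d` in expectation, verified by the
parameter-recovery acceptance test. A `symmetric_effect` switch applies
exp(+a/4) bilaterally (midline included) instead, producing group
differences in frontal alpha power without asymmetry — the case the
standardized analysis and the chi-square follow-up exist for.

Two deliberate idealizations, and why: (1) channel oscillators are mutually
incoherent (independent phases, envelopes, and jittered frequencies). A
single coherent alpha source would interfere coherently with the common
average and corrupt or even flip the injected frontal asymmetry; with
incoherent channels the average-reference leakage into any channel's alpha
power is second-order and the injection contract survives re-referencing.
(2) There is no volume-conduction mixing, no ocular/muscular artifact
model, and no head-model forward projection. Consequently, passing tests
demonstrate the *statistical* machinery (calibration, recovery, exactness)
— not robustness to realistic artifact structure or to channel covariance
as found in real EEG.

The `generate_band_power` shortcut draws subjects × channels × bins power
directly from the same spectral model (background density normalized over
0.5–125 Hz, Gaussian alpha bump of SD 0.8 Hz, per-bin log-normal noise of
SD 0.15) under the same injection contract — used where thousands of
replicates are needed. Source surrogates place the latent effect on a 6×5
lattice with an anterior-weighted profile plus vertex noise, standing in
for hemisphere-differenced beamformer output. All generators are
deterministic given the config: streams are keyed by (seed, study_id,
purpose), so studies sharing a seed are still independent.

## 8. Problem sizes in the shipped checks

Chosen as desk-scale defaults: parameter recovery uses 30 subjects/group,
125 Hz, 62 s of rest, 100 replicates; cluster-engine exactness uses 4-vs-4
designs (70 relabelings); type-I calibration uses 12-vs-12 subjects on the
4-pair frontal space, n_perm = 1000, 2000 replicates (replicates beyond the
required 500 sharpen the rate estimate); BCa coverage uses n = 80 per
replicate over 2000 replicates — large enough that BCa's own O(1/n)
small-sample undercoverage (≈ 92.5 % at n = 30 for a normal mean) does not
dominate what is meant to be a check of the implementation. The grid runner
defaults to n_perm = 1000 and n_boot = 1000 per row; published-scale
reruns would raise these (10 000 / 5000) without code changes.

## 9. Known limitations

- CSD and beamformer source localization are out of scope; their grid
  cells run on surrogate (or externally supplied) datasets.
- The generator's latent-FAA model is linear-Gaussian; it cannot express
  alpha-peak shifts with severity, gender-specific FAA effects, or
  artifact-correlated masks.
- Simple predictor permutation under confound control assumes confounds
  are exchangeable with respect to the null of the predictor of interest;
  Freedman–Lane is not implemented.
- Standardized-space analyses lose per-subject mean and scale by
  construction; bilateral effects that are uniform across the analyzed
  band and channels are invisible to them.
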