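# Methods

This note documents the statistical model behind `hrvmefa`, its numerical
choices, the synthetic-data generator that stands in for clinical
recordings, and what the test suite does and does not establish.

## Problem and model

A dynamic exercise protocol yields, per subject, nine consecutive
RR-interval series (epochs): rest, stand, four incremental cycling steps, a
peak, and two recovery phases. From each subject-epoch series twelve
autonomic (ANS) proxies are computed (see below). The resulting panel
`X_ijt` (subject *i*, proxy *j*, epoch *t*) is strongly correlated both
between subjects and within subjects, so the proxies are reduced by a
*two-level* exploratory factor analysis:

- **Between-subject (BS) level.** Subject averages over epochs,
  `X̄_ij = mean_t X_ijt`, give the BS correlation matrix `R_B` (n = 30
  observations). Factors of `R_B` describe stable inter-individual
  autonomic traits over the whole test.
- **Within-subject (WS) level.** Subject-centered values
  `X̃_ijt = X_ijt − X̄_ij` pooled over all n·T rows give the pooled-WS
  correlation matrix `R_W`. Factors of `R_W` describe the dynamics that
  unfold across epochs, net of each subject's overall level.

Each level is factored separately: iterated principal-axis extraction
(SMC start, eigendecomposition of the reduced matrix, communality updates
until the largest change falls below `1e-3`, at most 1000 iterations) and
varimax rotation with Kaiser row normalization (pairwise-angle sweeps; the
closed-form planar angle per factor pair, iterated until no pair moves).
A converged communality above 1 is a Heywood case: the primary fit aborts
with diagnostics, a bootstrap replicate is discarded and counted.
Adequacy is screened with the Kaiser-Meyer-Olkin index (0.6 floor, warning
only). Should a sample correlation matrix fail positive definiteness —
which happens when two proxies are nearly deterministic functions of each
other — its eigenvalues are floored at `1e-3` and the matrix rescaled to
unit diagonal before any inversion-based step (the usual correlation
smoothing).

Factor counts are chosen by a retention rule with three knobs: keep
factors whose reduced-matrix eigenvalue exceeds 0.5 (a retained common
factor should carry at least half a variable's worth of common variance;
the Kaiser-style threshold of 1.0 systematically misses two-indicator
factors, whose reduced eigenvalues sit near 1), then shrink the count
until every rotated factor is interpretable (at least one loading of
magnitude ≥ 0.6) and admissible (non-Heywood). A cumulative-variance floor
(default 50%) is recorded in the rationale but does not veto.

Factors are named from their ≥ 0.6 loadings: a factor marked mostly by
time-based proxies is the **Amplitude** domain; one marked by
{RR_Ro, P0v} only is **Signal Self-Similarity**; {RR_LFnu, RR_HFnu} with
opposite signs is **Oscillatory**; a broader mix of ratio-based markers is
**Frequency**. Factor scores use the Thurstone regression method
(`Z R⁻¹ Λ`) on level-specific standardization, and are re-expressed
through the exact CDF of a Gaussian kernel density estimate fitted to the
scores (Silverman plug-in bandwidth): `indicator = 100 · F̂(score)`. This
"PKDE" step is strictly monotone — ranks are preserved exactly — and maps
every indicator onto [0, 100]. Spacing is *not* preserved (differences
near the center of the distribution stretch, tail differences compress),
so the indicators are process indicators, not measurements.

## The 12 proxies

Time-based (carry a temporal unit): HR (beat/min, from the raw mean RR);
RR_RMS (ms, RMS of the mean-centered tachogram — the printed definition
"root mean square of successive RR intervals" is read as the tachogram's
SD, since a raw RMS of RR values would duplicate HR); RR_TP, RR_LFa,
RR_HFa (ms², autoregressive spectral powers); RMSSD (ms); AC and DC (ms,
phase-rectified signal averaging with acceleration/deceleration anchors,
window ±10 beats, Haar scale 2, anchors excluded when the beat-to-beat
change exceeds 5% of the previous interval).

Ratio-based (normalized): RR_LFnu and RR_HFnu ([0, 100]); RR_Ro ([0, 1],
regularity from the corrected conditional entropy of the 6-level quantized
series — conditional entropy plus a single-occurrence correction term,
minimized over pattern length, normalized by the Shannon entropy);
P0v ([0, 100], share of zero-variation three-beat symbolic patterns after
uniform 6-level quantization over the epoch's own range; bin-edge ties go
to the lower bin).

Spectral analysis is autoregressive on the beat axis: linear detrending,
Yule-Walker/Levinson fits at orders 8-16, Akaike order selection, an
Anderson-style whiteness flag on residual autocorrelations (±1.96/√n
bound; a failure is recorded, not fatal), and pole-residue decomposition
of the spectrum into components. The residue of `S(z)/z` at each pole
inside the unit circle is that component's power; conjugate pairs merge
into one oscillatory component whose frequency is the pole angle in
cycles/beat, converted to Hz via the mean RR. Components with central
frequency in (0.03, 0.15) Hz are LF, in [0.15, 0.40] Hz HF; anything else
contributes to total power only. Normalized units follow the classic
autoregressive-HRV convention `nu = 100 · band / (TP − VLF)`: the
denominator is all component power above 0.03 Hz, *including* supra-HF
components (fast tachograms have beat-axis Nyquist frequencies well above
0.40 Hz). A denominator of LF+HF alone would force
`LFnu + HFnu ≡ 100`, making the two variables exact complements and the
correlation matrices singular; published loading tables for this proxy
set show non-mirror LFnu/HFnu loadings, which is only possible with the
TP−VLF convention.

Undefined proxies (no PRSA anchors, empty bands) are NaN at the vector
level; the panel assembler's missing-policy is `error` by default, with
`impute` (column median) and `drop` (whole subject) as alternatives.

## Inference battery

- **ATS.** Rank-based anova-type statistics for the two-factor
  (group × repeated epoch) design: global mid-ranks, cell relative
  effects, subject-level covariance blocks, Box-approximation numerator
  df. Whole-plot (group) p-values use `F(f̂, f̂₀)` with a Satterthwaite
  denominator df built from the per-group trace terms; epoch and
  interaction effects use `F(f̂, ∞)`. A single-group variant serves the
  consecutive-epoch scans.
- **Two-sample battery** at a fixed epoch or on subject-level scores:
  Bowman-Azzalini permutation test (integrated squared difference of
  kernel density estimates at a common bandwidth — the geometric mean of
  the two plug-in bandwidths), Jonckheere-Terpstra permutation test for
  ordered alternatives (pairwise Mann-Whitney counts; exhaustive
  enumeration when the number of assignments is small), a pooled-resampling
  bootstrap Kolmogorov-Smirnov test (honest under ties), and a studentized
  Wilcoxon rank-sum: the Brunner-Munzel statistic (placement-variance
  studentization, robust to unequal spread) with a permutation null.
  Complete separation (zero placement variance) maps to ±∞, i.e., maximal
  extremity.
- **WSR.** Sign-flip permutation Wilcoxon signed-rank for paired epochs,
  exact for ≤ 12 non-zero pairs.
- Monte-Carlo p-values use the add-one rule `(b + 1)/(B + 1)`; exact
  enumerations report exact tail probabilities. Default resample counts:
  2000 permutations, 1000 bootstrap draws; every result records its seed.
- **FDR.** Benjamini-Hochberg, applied per indicator and per test family
  (across the 8 consecutive pairs, or across the 9 epochs).
- **Sex/age screen.** Median (τ = 0.5) quantile regression of each
  indicator on sex (0 = female, 1 = male), age, and their interaction;
  per-epoch for WS indicators. The screen only reports — indicators are
  never adjusted.
- **Sensitivity grading.** Counts of concordant significant procedures
  map to none/weak/medium/strong. For the single rest-stand contrast the
  count maps directly (all → strong, ≥ half → medium, any → weak); for
  the multi-contrast aspects (exercise pairs, per-epoch group
  comparisons) a contrast qualifies with ≥ 2 significant procedures and
  the level reflects the qualifying share (< 1/3 weak, < 2/3 medium,
  otherwise strong), with per-epoch grading additionally nulled when
  neither overall ATS group nor interaction effect is significant. The
  thresholds live in `SensitivityConfig` because the count-to-level
  convention is descriptive, not canonical.

## Bootstrap

Resampling is by *subject*: a drawn subject contributes all nine epochs,
so the within-subject dependence is never broken. The plan is balanced
within stratum (group): B copies of each stratum's subject list are
shuffled and partitioned into B samples, so each subject appears exactly
B times over the plan and every sample preserves the 15/15 group split.
Replicates rerun the full decomposition-extraction-rotation at the
reference factor counts; Heywood replicates are discarded and counted
(mirroring practice with small-n factor bootstraps), admissible replicates
are aligned to the reference solution by greedy Tucker-congruence matching
with sign flips (threshold 0.7; unmatched replicates are discarded
separately). Intervals are BCa: bias correction from the replicate
fraction below the estimate, acceleration from leave-one-subject-out
jackknife values (or supplied influence values — the infinitesimal
jackknife form); one-sided replicate distributions fall back to the
percentile interval with a warning. Indicator medians (per BS group, per
WS epoch) use percentile intervals from the same replicate stream.

## Synthetic data

No raw recordings from the motivating study are available, so the
generator is the test bed; its defaults are the study conditions.

**Tachogram generator.** Each epoch is mean RR + two narrow-band
beat-domain AR(2) oscillators (poles at radius 0.95, angle
`2π · f_Hz · meanRR/1000`; innovation variance solved from the AR(2)
stationary-variance formula so the oscillator carries the requested band
power) + slow VLF wander (a ~0.015 Hz sinusoid with random amplitude and
phase plus a random linear drift) + white noise. Innovations are
standardized gamma draws (shape 4): real tachograms are time-irreversible
(heart-rate asymmetry), Gaussian AR processes are not, and reversibility
would force AC = −DC exactly. A draw containing a non-positive interval
is rejected wholesale and redrawn (truncation would distort the
spectrum). One global seed expands to per-subject-epoch
`SeedSequence((seed, subject, epoch))` streams, so any subset regenerates
identically.

The default 9-epoch template encodes the protocol's ordinal trends —
spectral power collapsing from thousands of ms² at rest to a few ms² at
peak exercise (epoch 7) with partial recovery, LF share rising through
the early exercise steps and falling into the peak, beat counts summing
to ≈ 1820 per subject (the study protocol reports 1777 ± 280) — with two
group variants: the endurance ("cyclist") template has ~10% longer RR
intervals, doubled amplitudes and an HF-shifted balance relative to the
technical ("shooter") template. Between-subject variance comes from
subject-level factors: an overall power factor (lognormal, σ = 0.45),
band-specific LF/HF factors (σ = 0.35), wander and short-term-noise
factors (σ = 0.5/0.4), and subject-specific oscillator center frequencies
(LF 0.08-0.12 Hz, HF 0.20-0.32 Hz, emulating breathing-rate differences).
Within-subject stochastic variation beyond the template comes from
epoch-level lognormal jitter on band powers (σ = 0.5) and mean RR
(σ = 0.03). These independent subject traits are what keep the proxy
panel's correlations in the realistic 0.7-0.95 range — a single shared
scale factor would drive the amplitude proxies into near-collinearity and
the factoring into permanent Heywood territory.

Spectral fidelity contract: band powers re-estimated by the AR stage stay
within 25% of the requested powers on average over ≥ 50 seeds (tested).

**Latent-panel generator.** Draws panels directly from the two-level
orthogonal factor model
`X_ijt = Λ_B f_i + e_i + Λ_W g_it + ε_it` with standard-normal factors
independent across levels and per-level uniqueness noise; a group shift
displaces the second group's BS factor means. The default structure
mirrors the study's solution: q_B = 2 (amplitude on the eight time-based
variables, negative on HR and AC; frequency on the four ratio-based
variables, negative on RR_HFnu) and q_W = 3 (amplitude;
signal-self-similarity on RR_Ro/P0v; oscillatory on RR_LFnu/−RR_HFnu).
Main loadings are 0.85; the two-indicator WS factors carry 0.95 markers
plus 0.15 cross-loadings — high doublet markers match the published
solution, and a pure doublet would leave its communalities unidentified
(iterated principal-axis estimation then drifts along a ridge into
spurious Heywood flags). All uniquenesses are ≤ 0.4.

**Demographics.** Sex/age covariates are drawn independently of the
physiology (1/3 female share; age ≈ 29 ± 6 years), so the sex/age screen
is exercised under its null.

**What the generator does not emulate.** Ectopy/artifacts and their
editing, respiratory-cardiac coupling and baroreflex dynamics,
non-stationarity within epochs beyond a linear drift and slow wander, and
any true sex/age physiology. Passing tests therefore establish the
*statistical machinery* — decomposition, extraction, calibration,
coverage — under a data-generating process with the study's shape; they
do not validate physiological interpretations on real athletes.

## Problem sizes and defaults used by tests and scripts

The pipeline defaults are 30 subjects × 9 epochs, 300 bootstrap
replicates and 1000 permutations (the analysis drivers raise the
bootstrap to 500). The test suite calibrates each resampling test with
500 null replicates at 400-600 resamples each, checks BCa coverage over
500 simulations at B = 600, and measures latent-structure recovery over
20 seeds; the acceptance script uses 200-replicate calibration snapshots
and 300-simulation coverage. These sizes were chosen to keep Monte-Carlo
standard errors a factor of ~3 below the acceptance bands they inform.

## Known limitations

- The iterated principal-axis + varimax pipeline is sensitive to
  near-collinear variable blocks; the Heywood flag is the honest signal,
  and the bootstrap reports its discard counts rather than smoothing over
  them. Discard rates well above the published study's (12%) occur on
  synthetic panels whose proxies are more collinear than real data.
- The PKDE bandwidth is the Silverman plug-in; only rank preservation and
  the [0, 100] range are contractual. Alternative bandwidths change
  spacing, never ordering.
- The retention rule is a documented reconstruction; with real data the
  factor counts should always be reviewed against the rationale record
  the rule emits.
- Quantile-regression p-values in the sex/age screen are asymptotic
  (kernel-based covariance); at n = 30 they are a screen, not a
  confirmatory test.
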