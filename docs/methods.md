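# Methods

This note documents the models, estimators and design choices behind
`qeegconn`, the assumptions they make, and what the synthetic validation
does and does not demonstrate about real clinical EEG.

## Signal model and preprocessing

A recording is a channels × timepoints matrix in microvolts with a
sampling rate and ordered 10-20 labels. The modern temporal labels
T7/T8/P7/P8 are accepted as synonyms of T3/T4/T5/T6 and normalized to the
older form used throughout. Scalp regions are fixed: frontal
{Fp1, Fp2, F3, Fz, F4, F7, F8}, central {C3, Cz, C4}, temporal
{T3, T4, T5, T6}, parietal {P3, Pz, P4}, occipital {O1, Oz, O2};
hemisphere derives from the label suffix (odd = left, even = right,
z = midline).

Preprocessing is a 50 Hz notch (IIR, quality factor 30) followed by a
0.5–40 Hz Butterworth band-pass of order 4, both applied
forward-and-backward. Zero-phase filtering is non-negotiable here: the
phase-based connectivity metric would otherwise inherit the filter's group
delay as spurious directionality. The same SOS band-pass design is reused
for per-band filtering inside the connectivity estimators, so spectral and
phase analyses see identical band definitions.

Recordings are cut into consecutive non-overlapping 2 s epochs; an epoch
is rejected if any channel exceeds 100 µV peak absolute amplitude. Both
values are configuration keys; 2 s gives a 0.5 Hz spectral grid (so the
1–3 Hz delta band spans five grid points) and the 100 µV bound is a
conventional artifact ceiling for awake scalp EEG. Amplitude rejection is
deliberately simple and deterministic; component-based artifact removal
(ICA) is out of scope and expected to be done upstream when real
recordings are analyzed.

## Spectral markers

Per-channel power spectral densities use Welch's method: Hann windows of
2 s with 50% overlap within each epoch, averaged with equal weight across
epochs (never concatenated). Density scaling is such that the integral of
the PSD over frequency approximates the signal variance.

Band power is the trapezoidal PSD integral over the closed band interval
on the grid; the four bands are delta 1–3, theta 4–7, alpha 8–13 and beta
14–30 Hz. *Total power* for ratio purposes is the sum over these four
bands, not the full 0.5–40 Hz integral: the inter-band gaps (3–4, 7–8,
13–14 Hz) are excluded from every denominator, which is the convention
under which published group percentages sum to ~100. Regional power
integrates over the union of the four bands and sums each region's
channels; regional ratios divide by the five-region total. DTABR is
(P_delta + P_theta) / (P_alpha + P_beta) over all channels; it is
scale-invariant and strictly increasing in delta mass.

Cohort tables report per-subject means by default. Pooled ratios (sum
powers across subjects first) are available behind a flag; the two differ
whenever subjects differ in total power, and which one a published group
percentage reflects is usually unstated.

## Connectivity estimators

All three estimators treat epochs as independent realizations of a
stationary process and never form lags across an epoch boundary. Failed
pairs are reported as missing values (NaN), never as zeros, so group
statistics can exclude them explicitly.

**Pearson r.** Each epoch is band-pass filtered, the product-moment
correlation matrix computed, and matrices averaged over epochs. A
zero-variance channel in any epoch is an error naming the channel.

**Pairwise Granger causality.** For each unordered channel pair a
bivariate VAR is fitted by least squares on the pooled epochs, with the
order p ∈ {1..6} chosen by BIC (ln det Σ̂ + k ln N / N); all candidate
orders are fitted on the common sample that excludes the first
max-order points of each epoch so their criteria are comparable, and only
models with companion spectral radius < 1 are eligible. For each
direction, GC(i→j) = ln(RSS_restricted / RSS_full) for predicting j,
where the restricted regression omits i's lags. Binarization is provided
both ways: an F-test of the p exclusion restrictions at level α (default
0.05), and a fixed threshold on the GC value itself for edge counting.
The value threshold defaults to 0.01: under the null the GC estimate
concentrates near p/N (≈ 10⁻³ at the default problem size of ~3 × 10⁴
pooled samples), while lagged influences of strength ≥ 0.3 produce GC
≥ 0.05, so 0.01 sits an order of magnitude above the null and well below
true effects. Bivariate (not conditional) GC is intentional: it matches
per-pair binarized reporting and keeps the cost of 171 pairs × 6 orders
modest; indirect-path effects are therefore visible in the matrices, as
they are in any pairwise analysis.

**Phase transfer entropy.** Signals are band-pass filtered per band, the
instantaneous phase extracted from the analytic signal, and phases
discretized into equal-width bins. PTE(x→y) is the plug-in transfer
entropy Σ p(y_{t+δ}, y_t, x_t) ln[p(y_{t+δ}|y_t, x_t) / p(y_{t+δ}|y_t)],
a conditional mutual information and hence non-negative. The prediction
delay δ defaults to half the band's mean oscillation period in samples
(e.g. 12 samples for alpha at 250 Hz, minimum 1); the bin count defaults
to ⌈√N_epoch⌉ capped at 64 (23 for 2 s epochs at 250 Hz).

*Epoch combination.* By default the phase histograms are **pooled across
epochs** and one TE is computed per ordered pair from the pooled counts.
The alternative — estimating TE per epoch and averaging — is available
(`PTEParams(epoch_mode="epoch_mean")`) but is not the default for a
quantitative reason: the plug-in TE bias grows with (occupied cells)/M.
At M ≈ 490 samples per epoch and 23 bins the per-epoch bias is ~1.1–1.6
nats, two orders of magnitude above realistic true phase flow, and worse,
the bias depends on each channel's in-band SNR and on inter-channel
correlation, so epoch-mean group contrasts measure bias structure rather
than coupling. Pooling counts over ~60 epochs shrinks the bias ~60-fold
while keeping every lag inside an epoch. Pooled-count PTE recovers
imposed directional phase coupling reliably where the epoch-mean variant
drowns it.

**Edges and hemispheres.** Directed matrices are thresholded (strictly
greater) into edge sets with counts and summed intensities; edges are
partitioned into intra-left, intra-right, cross-hemisphere and
midline-involved (midline takes precedence).

## Group statistics

Connectivity values are bounded or skewed, so contrasts use the
Mann–Whitney U test with midrank ties. The exact two-sided p enumerates
all C(n₁+n₂, n₁) group assignments (permitted up to n₁+n₂ = 20) and
counts |U − n₁n₂/2| at least as extreme; the large-sample route uses the
tie-corrected variance with a 0.5 continuity correction. In exact mode
the reported Z is the normal quantile consistent with the exact p, so
|Z| and p never disagree.

ROC curves sweep the score thresholds; AUC is trapezoidal and equals
U/(n₁n₂) (asserted in tests to 10⁻⁹, ties included). The 95% CI uses the
Hanley–McNeil standard error — adequate for the effect sizes here;
DeLong's method is out of scope. Q-Q diagnostics report paired
standard-normal/sample quantiles at plotting positions (i − ½)/n plus the
squared correlation as a linearity score.

Cohort contrasts default to pooling every finite off-diagonal edge value
across a group's subjects (upper triangle only for undirected metrics).
Pooled edges are not independent — |Z| values in the tens arise from
thousands of correlated edge observations and overstate evidence; the
per-subject-mean mode (one value per subject) is the statistically
conservative alternative and is provided alongside. No multiple-testing
correction is applied by default, matching the reporting style the
pipeline mirrors; a Bonferroni flag exists on the caller's side simply by
adjusting α.

## Synthetic cohorts

Each channel is a sum of band-limited Gaussian components plus white
sensor noise, with directed lagged influences added on top:

* Per band and channel, white noise is band-pass filtered and calibrated
  so that its *measured in-band Welch power* is 1 before weighting —
  calibrating to total variance instead would deflate realized band
  ratios by filter roll-off and window smearing. The component is scaled
  by √(weight) with weights set per band × region.
* Alpha components mix a common shared source with gain g
  (`shared_alpha_gain`), renormalized to unit variance; this produces
  undirected (zero-lag) inter-channel correlation of g²/(1+g²) without
  creating directed ground truth.
* The channel's own signal u_c = band components + white noise
  (noise SD 1 µV). Directed edges then add strength × u_source delayed by
  an integer lag: the process is an explicit structural VAR whose
  innovations are the u's, so analytic Granger values for ground-truth
  edges are computable, and stability is checked at build time via the
  companion spectral radius (feed-forward graphs are trivially stable).

The two profiles mirror the published group contrast. Band proportions
are anchored to the published group means (control
δ/θ/α/β = 13.3/6.9/35.1/7.7% of four-band power; patient
56.0/27.1/14.6/2.3%), giving weight-implied DTABR ≈ 0.47 vs ≈ 4.9.
Regional gains make the control profile frontally weighted and the
patient profile heavily occipital. The control coupling graph is a dense
33-edge acyclic anterior-to-posterior hierarchy (strengths 0.4–0.6, lags
2–7 samples) including six left→right homologous cross-hemisphere links;
the patient graph has three weak posterior edges and no cross-hemisphere
links; shared alpha gain is 0.8 vs 0.2. Graph density matters: directed
group contrasts of pooled edge values are only coupling-driven when a
non-trivial fraction of pairs is actually coupled — with only a handful
of edges the rank statistics are dominated by residual estimator-bias
differences between the groups' SNR profiles.

Cohorts default to 9 control-like and 11 patient-like subjects, 120 s at
250 Hz — sizes chosen to keep the full pipeline (≈ 4 minutes on one CPU)
at desk scale while leaving thousands of pooled edge values per contrast.
Per-subject seeds spawn deterministically from one master seed, and
within-group heterogeneity is ±10% multiplicative jitter on every weight.

The phase-coupled pair for PTE validation integrates two noisy phase
oscillators at the band's center frequency; the second phase is pulled by
κ · ω · sin(θ_x[t−δ] − θ_y[t]) toward the first's delayed phase, with
phase-diffusion SD 0.1 rad/sample. Parameterizing the pull relative to
the natural per-sample increment ω makes κ = 1 a strong, order-unity
coupling and κ = 0 exactly independent oscillators.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that the estimators recover the statistical
structure they target when that structure is present and the model
assumptions hold: spectral weights are recovered within 15%, imposed
lagged influences are detected directionally (and their GC matches the
analytic value), delayed phase coupling orders PTE correctly, null
calibration of the tests is nominal, and the full pipeline reproduces the
direction of every group effect (higher DTABR, delta dominance, reduced
PTE, fewer directed and cross-hemisphere edges in the patient-like
group).

They do not demonstrate performance on real clinical EEG, which differs
in ways the generator deliberately omits: volume conduction and reference
effects (zero-lag mixing that inflates Pearson r and can masquerade as
connectivity), non-stationarity, 1/f background, residual artifacts, and
electrode-quality variation. Two caveats deserve emphasis:

* **Observation noise induces bidirectional Granger flow.** When channels
  are noisy observations of smooth latent components, the lagged copies
  in a coupled channel genuinely improve prediction of the *source* —
  reverse-direction GC is then real information flow, not estimator
  error, and no finite VAR order removes it. This is why the directional
  GC recovery fixture uses white-noise channels (the structural-VAR model
  class), and why binary GC on real band-limited EEG should be read as
  detecting association with a directional bias, not clean causal
  direction.
* **PTE bias tracks SNR.** The plug-in histogram bias differs between
  groups whose in-band SNR differs; with pooled counts it is small but
  not zero. The beta band — where the patient profile has very little
  power — is the weakest contrast in the synthetic cohorts and its
  rank-based direction, while correct at the default seed, has the
  smallest margin across seeds.

## Numerical conventions

Band intervals are closed on the frequency grid; a grid point on a shared
boundary would belong to the lower band (moot for the default integer
bands). GC values are clipped at 0 (log-ratio estimates can round
negative); PTE clipping is counted in the matrix parameters and in
practice never triggers beyond floating-point dust. Degenerate inputs
raise typed errors rather than propagating NaNs: constant channels,
singular pair designs (e.g. duplicated channels), all-identical group
values (flagged Z = 0, p = 1), single-class ROC labels. All output tables
use fixed %.10g float formatting so identical runs are byte-identical;
EDF export quantizes to 16 bits over each channel's observed range.
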