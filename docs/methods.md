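# Methods

This note records the models implemented in `binomatch`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Stimulation protocol

The default `StimulusProtocol` is the standard drifting sinusoidal grating
battery: 12 directions in 30° steps, spatial frequencies
{0.01, 0.02, 0.04, 0.08, 0.16, 0.32} c/deg, 2 Hz temporal frequency, 1.5 s
presentations, five repeats per eye, and two grey blank conditions per eye
per repeat block for the spontaneous-rate estimate. Conditions are randomly
interleaved within each eye. All fields are overridable and validated
(strictly increasing equally spaced directions, positive SFs and duration).

## Response matrices and tuning fits

The spontaneous rate of a unit is its mean rate over *all* blank
presentations (both eyes pooled); each cell of the per-eye response matrix
is the across-repeat mean of spike count / duration minus that rate.
Evoked entries may be negative; they are rectified at zero *only* inside
the index formulas (OSI, DSI, ODI), which keeps those indexes in
[0, 1] / [−1, 1]. Raw (non-subtracted) rates are kept alongside for the
inclusion filter.

The preferred stimulus is the grid argmax of the evoked matrix,
independently per eye; ties break toward the lowest SF, then the lowest
direction, and an all-equal matrix is flagged degenerate. The direction
tuning curve at the preferred SF is fitted as two Gaussians of equal width
σ centred 180° apart with a constant baseline. Numerics:

- bounded trust-region least squares; σ ∈ [5°, 90°], amplitudes ≥ 0,
  baseline free;
- multi-start: one start per sampled direction, with the preferred
  direction constrained within ± one direction step of its start — this
  avoids the local minima of a periodic model while still letting the
  optimizer refine off-grid preferences;
- the best-RSS solution is canonicalized to A1 ≥ A2 (a swap shifts the
  preferred direction by 180°);
- a flat curve (range < 1e−12 Hz) short-circuits to amplitudes 0, baseline
  = mean, degenerate flag; a failed fit falls back to the raw argmax
  direction for downstream metrics.

Index formulas use *measured* per-condition responses by default
(`resp_mode="raw"`); fitted-value mode is available. The orthogonal
response is the mean of both orthogonal directions (pref ± 90°), since an
orientation has two direction representatives; whether to use one or both
is a convention, and the average is the symmetric choice.

ΔO is computed from each eye's fitted preferred direction taken mod 180°,
at each eye's own preferred SF. ODI uses the rectified peak evoked response
per eye; the dominant eye is the one with the larger peak. Inclusion
requires the dominant eye's raw rate at its optimal stimulus to exceed
0.5 Hz (strict). The ISI quality flag marks units with ≥ 0.1 % of spikes at
intervals below 1 ms, evaluated within trials.

CBI per animal is offered in two conventions, because the classical
definition is a convention rather than a formula fixed by the analysis
itself: the default bins unit ODIs into seven equal classes on [−1, 1]
(class 1 most contralateral) and applies
[(n1 − n7) + (2/3)(n2 − n6) + (1/3)(n3 − n5) + N] / (2N); `mean-odi` mode
returns (1 + mean ODI)/2. Both agree at the extremes and at symmetric
populations.

## Cell classification

F1/F0: the preferred-condition response is binned at 100 ms (15 bins over
1.5 s; a trailing partial bin is dropped with a warning), the spontaneous
rate subtracted, and the DFT taken. F0 is the mean; F1 is the one-sided
amplitude 2|X_k|/N at k = round(f_drift × duration) (k = 3 for 2 Hz ×
1.5 s — an integer number of cycles per presentation), so a pure cosine of
amplitude a on mean m gives F1/F0 = a/m and the simple/complex boundary at
1 retains its textbook meaning. The threshold (default 1.0) is a field
convention and is exposed as configuration. Units whose mean response is
not positive get an undefined ratio and are excluded from simple/complex
analysis.

Waveform classification standardizes three shape features (positive-peak
height relative to the trough after trough-depth normalization,
trough-to-peak time, slope 0.5 ms after the trough) to zero mean / unit
variance — the features mix milliseconds with ratios — and clusters them
with 2-means (10 restarts, fixed seed) and average-linkage hierarchical
clustering cut at two. Narrow-spiking is the cluster with the shorter mean
trough-to-peak time; an agreement flag records whether both algorithms
produced the identical partition.

## VEP

P1 is the maximum baseline-corrected deflection in a 50–150 ms
post-reversal window (typical mouse latency range; configurable); baseline
is the pre-reversal mean. Acuity: the amplitude at the highest tested SF
(0.96 c/deg) is subtracted from all points, corrected amplitude is
regressed on log10(SF), and acuity is 10^(x-intercept). The fit uses the
descending limb only — SFs at and above the argmax of corrected
amplitude — because a low-SF roll-off would otherwise flatten the slope
and inflate the estimate; `points="all"` restores the all-points
regression. A non-negative slope raises "no acuity limit detectable".

## Transcriptome statistics

Tests run on log2(x + 1) expression by default. Per gene and group, the
background variance is the mean sample variance over a 101-gene window
centred on the gene in overall mean-expression rank (truncated at the
edges), and the regularized variance is

    s²_reg = (v0·σ²_bg + (n − 1)·s²) / (v0 + n − 2),   v0 = 10.

The statistic combines the two groups Welch-style,
t = (m_B − m_A)/√(s²_reg,A/n_A + s²_reg,B/n_B). Two df conventions are
provided: the default credits the pseudo-observations
(df = n_A + n_B − 2 + 2·v0, matching the behaviour of distributed
implementations of this test and giving an empirical type-I rate near the
nominal 5 % at n = 4 + 4), and a `classic` mode uses n_A + n_B − 2.
`confidence=0` disables regularization entirely, reproducing the ordinary
(Welch-statistic) t-test exactly — the natural meaning of "no
pseudo-observations", and the anchor for the calibration tests.

PPDE fits f(p) = λ + (1 − λ)·Beta(a, b) with a ≤ 1 ≤ b by EM
(deterministic initialization λ = 0.8, a = 0.3, b = 3; weighted beta
M-step by bounded L-BFGS-B; tolerance 1e−8 on the log-likelihood). One
beta component is used: at desk scale a larger mixture is not identifiable,
and the component count is the natural extension point. Because a uniform
sample can be absorbed into the beta component (a = b = 1), the null
weight is bounded from the fitted density at p = 1, π0 = f̂(1), and
PPDE(p) = max(0, 1 − π0/f̂(p)) — the standard identifiability resolution
for p-value mixtures. Consequences: on null data π0 → 1 and all PPDE → 0;
when b > 1 the beta density vanishes at 1 and the bound changes nothing;
and PPDE is always monotone non-increasing in p, so ranking by PPDE equals
ranking by ascending p. EM failure falls back to λ = 1 (all PPDE 0),
flagged. Significance is PPDE > 0.6, and significant genes split into
up/down by the sign of the B − A mean difference.

Fisher enrichment builds the 2×2 table over an *explicit* universe
(expressed vs annotated genes is a study-level choice, so the universe is
a required argument). The two-sided p is computed by exact integer
hypergeometric enumeration — summing all tables with the observed margins
whose probability does not exceed the observed table's, with no
floating-point tie tolerance. The odds ratio is the sample ad/bc; a 0.5
continuity correction is applied, and flagged, only when a cell is zero.
Gene identifiers are opaque strings throughout; no alias mapping.

## Visual cliff

The arena is 50 × 36 cm split into two 25 × 36 cm plates; points on the
dividing line count as shallow (documented tie rule). Occupancy is
time-weighted: each inter-sample interval is assigned to the zone of its
earlier sample. The centre zone — used as an anxiety control — is a
concentric rectangle with half the linear dimensions (25 % of the area) by
default, configurable, since the assay itself does not fix it.
Trajectories longer than 5 minutes are truncated to the trial length.
Out-of-bounds samples are clipped to the walls with a warning.

## Synthetic-data generators

The generators define the conditions under which the pipeline is tested.

*Spiking populations.* Each unit's evoked rate over direction is the same
double-Gaussian form the analysis fits, scaled by a log-Gaussian SF
envelope (width 0.25 decades) around a per-unit preferred SF drawn from
the protocol grid — the analysis only needs an argmax over SF, so no
richer SF model is warranted. Eye gains are set from a true ODI
(clipped normal, mean 0.2 — a contralateral bias) so that the peak-response
ODI equals the drawn value. The ipsi−contra orientation offset is von
Mises on the 180° cycle with concentration κ (default 20, mean true
ΔO ≈ 5°, a well-matched population) or uniform (mean ΔO 45°, fully
unmatched). Peak rates are log-normal (median 10 Hz, σ_log 0.4),
spontaneous rates uniform 0.2–2 Hz, widths uniform 15–35°,
opposite-direction amplitude ratios uniform 0–0.7; none of these
distributions is identified by desk-scale data, so they are configurable
defaults chosen to give realistic selectivity indexes and signal-to-noise
at five repeats. Spikes are piecewise-constant-rate Poisson on 1 ms
sub-bins — exact and sufficient for 100 ms PSTH analysis. Simple cells'
within-trial rate follows a half-rectified sinusoid at the drift frequency,
g(t) ∝ max(0, (1−m) + m·cos 2πft) normalized to unit mean (m = 0.9
default; the pure half-rectified cosine at m = 1 has F1/F0 = π/2);
complex cells are constant within trial. Poisson trains have no refractory
period, so the ISI quality metric correctly reports violations on this
synthetic data — the flag is informational, not an inclusion criterion.
Waveforms are biphasic difference-of-Gaussian templates differing in
trough-to-peak time (0.25 vs 0.55 ms) plus sample noise.

*What passing tests do and do not show.* Recovery on these populations
demonstrates the estimators are consistent and unbiased under the stated
rate model; real recordings add rate nonstationarity, correlated
variability, imperfect sorting and eye-position noise that the generator
deliberately omits, so field performance bounds cannot be read off the
synthetic numbers.

*VEP sessions* draw per-eye amplitudes from max(0, intercept +
slope·log10 SF) plus Gaussian noise, with ipsilateral amplitudes equal to
contralateral divided by the true C/I ratio; optional raw traces embed a
Gaussian P1 deflection at 80 ms.

*Expression matrices* are log-normal with a monotone mean–variance
relationship (noise SD decreasing with expression level), so rank-windowed
background variances are meaningful; target genes are shifted by
−effect·log2 units in the second group; four replicates per group by
default, matching the common developmental design.

*Trajectories* are fixed-step random walks (0.5 cm at 10 Hz → ~5 cm/s,
a realistic exploration speed) whose x-heading points toward the centre of
the shallow or deep half with probability side_bias / 1 − side_bias,
clipped at the walls. side_bias = 0.5 is symmetric; side_bias = 1 is
absorbing at the shallow side. Trials start on the shallow side by
default (as in the assay); symmetric-occupancy checks start at the arena
centre, where the 50 % expectation is exact by symmetry — with a shallow
start, finite 5-minute trials are shallow-biased because the walk mixes
slowly. Between 0.5 and 1 the attractor dynamics saturate quickly, so the
bias parameter should be read as a qualitative preference switch rather
than a calibrated occupancy dial.

## Problem sizes

Recovery checks run at 200 units under the full protocol (five repeats per
eye), null calibration at 10,000 genes with four replicates per group, the
Fisher enumeration sweep over every 2×2 table with total ≤ 60, and
trajectory Monte-Carlo over a few dozen 5-minute trials — sizes chosen to
estimate each quantity with comfortable margin on a single CPU.

## Known limitations

- No spike sorting, receptive-field mapping beyond the grid, or latency
  analysis; positions, sorted spikes and target gene lists are inputs.
- The double-Gaussian fit assumes equal widths for the two direction
  lobes, as the analysis model prescribes.
- One beta component in the PPDE mixture; heavy multi-modal p-value
  distributions would need the configurable component count extended.
- The regularized test's df convention differs across published
  implementations; both are provided and the choice matters at small n.
- Group-comparison inferential statistics (ANOVAs etc.) are out of scope;
  summaries are descriptive, per animal and pooled.
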