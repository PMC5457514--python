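# binomatch

Quantitative analyses for studies of **binocular matching of orientation
preference** in mouse primary visual cortex, with the accompanying VEP,
transcriptome and visual-cliff statistics — implemented as a tested,
reusable Python library that can be exercised end to end on synthetic data
with known ground truth.

## Who this is for

Visual-system physiologists and computational neuroscientists who need the
standard single-unit receptive-field workflow (drifting-grating tuning
curves, eye-specific preferences, ocular dominance), the population-level
VEP measures, the bulk RNA-seq differential-expression statistics used in
developmental comparisons, and visual-cliff behaviour scoring — all in one
place and all testable without animal recordings.

## What it computes

**Single-unit tuning** (`binomatch.tuning`). From a sorted spike table and
trial table under the 12-direction × 6-spatial-frequency × 5-repeat-per-eye
grating protocol: per-eye response matrices (mean evoked rate minus the
spontaneous rate estimated from blank presentations), grid-argmax preferred
stimuli, and a double-Gaussian direction tuning fit at the preferred SF

$$R(\theta) = B + A_1 e^{-d(\theta,\,\theta_p)^2 / 2\sigma^2}
                + A_2 e^{-d(\theta,\,\theta_p+180°)^2 / 2\sigma^2},$$

with wrapped angular distance $d$. Derived metrics:

- $\mathrm{OSI} = (R_\mathrm{pref} - R_\mathrm{ortho}) / (R_\mathrm{pref} + R_\mathrm{ortho})$,
  $\mathrm{DSI} = (R_\mathrm{pref} - R_\mathrm{oppo}) / (R_\mathrm{pref} + R_\mathrm{oppo})$
- tuning width $= \sigma\sqrt{2\ln 2}$ (HWHM of the principal Gaussian)
- **binocular mismatch** $\Delta O \in [0°, 90°]$: unsigned difference of
  the two eyes' preferred orientations on the 180° cycle
- $\mathrm{ODI} = (R_c - R_i)/(R_c + R_i) \in [-1, 1]$ per unit and the
  per-animal contralateral bias index (CBI)
- inclusion (> 0.5 Hz raw peak rate at the dominant eye's optimum) and
  ISI-based cluster-quality flags (< 0.1 % of spikes under 1 ms)

**Cell classification** (`binomatch.classify`). F1/F0 modulation ratio from
a 100-ms PSTH DFT (simple iff F1/F0 > 1), and narrow/broad spiking from
waveform shape by k-means and average-linkage clustering with an agreement
flag.

**VEP** (`binomatch.vep`). P1 peak-to-baseline amplitude and latency,
contralateral/ipsilateral amplitude ratio, and visual acuity by linear
extrapolation of amplitude vs log spatial frequency to zero (0.96 c/deg
baseline subtracted).

**Transcriptome** (`binomatch.transcriptome`). RPKM; Bayesian-regularized
t-test with a 101-gene sliding-window background variance and confidence
v₀ = 10; posterior probability of differential expression (PPDE) from a
uniform+beta p-value mixture, significance at PPDE > 0.6; Fisher exact
gene-set enrichment with odds ratios (exact hypergeometric enumeration);
three-way set intersections.

**Behaviour** (`binomatch.behavior`). Visual-cliff side/centre occupancy
(time-weighted), path length and mean velocity, with 5-minute trial
truncation in the 50 × 36 cm arena.

**Synthetic data** (`binomatch.simulate`). Generators for every input with
recorded ground truth: tuned binocular Poisson spiking populations
(matched or uniformly mismatched eyes), waveform templates, VEP amplitude
curves, two-group expression matrices with designated target genes, and
biased arena random walks.

## Worked example

```bash
python examples/tuning_recovery.py
```

```
units included (> 0.5 Hz peak rate): 40 / 40
median |OPref error| (contra eye):   1.57 deg
mean recovered ΔO:                   5.61 deg
mean true ΔO:                        4.79 deg
mean OSI / DSI (contra):             0.95 / 0.51
```

Forty simulated units with well-matched eyes are pushed through the whole
pipeline: preferred orientations are recovered to within a couple of
degrees, and the recovered population mismatch (mean ΔO ≈ 5.6°) tracks the
generator's truth (4.8°) — the signature of a wild-type-like population.
Regenerating with `mismatch_model="uniform"` drives the recovered mean ΔO
toward 45°, the unmatched (knockout-like) regime. The other scripts in
`examples/` demonstrate cell classification, VEP acuity, differential
expression with enrichment, and visual-cliff scoring the same way.

A thin CLI mirrors the library: `binomatch run --config cfg.yaml`,
plus `simulate`, `tuning`, `classify`, `vep`, `enrich`, `cliff`
subcommands (see `binomatch --help`).

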