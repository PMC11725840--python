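# Methods

## The screen

Each cell is screened in four stages.

1. **Receptive field.** The spike-triggered average (STA) under a binary
   white-noise checkerboard (50 µm checkers, 60 Hz) is computed over 12
   frame lags; the peak lag is located on a 3×3-smoothed deviation map
   (the RF blob spans several checkers, single-pixel noise does not), and
   the peak spatial frame is fitted with a 2-D Gaussian plus offset by
   least squares. RF center = fitted mean; RF size = 2σ with
   σ = √(σₓσᵧ). Cells with fewer than 300 white-noise spikes, a flat STA
   or a divergent fit are excluded as RF-unreliable. Polarity (ON / OFF /
   ON–OFF) compares onset- vs offset-evoked counts of a full-field step
   (ratio threshold 2, configurable); the transience index is
   1 − (mean rate in the late half of the dominant step)/(peak of a
   lightly smoothed PSTH), so a sustained plateau scores 0 and a fast
   decay scores ≈ 1. Conventional direction-selective cells are flagged
   from 8-direction gratings with the resultant-length index (> 0.3, plus
   a permutation test); they are reported, not excluded — the
   extraclassical asymmetry concentrates in non-DS cells as a tendency,
   not a filter.

2. **Geometry.** `Distance_min` is the Euclidean distance from the
   (estimated) RF center to the recording boundary (shapely polygon
   distance). Cells with `Distance_min` < 450 µm are excluded with an
   explicit reason, guaranteeing a ≥ 100 µm annulus of tissue beyond the
   350 µm Central area. Bars are infinite strips perpendicular to their
   motion vector, so circle-crossing times depend only on speed, width
   and radius: the analysis windows are direction-independent and are
   placed per trial at the bar-center/RF-center alignment time. The PRE
   window starts when the leading edge enters the per-cell annulus
   (radius `Distance_min`), not at sweep onset, confining PRE activity to
   tissue-covered retina. The POST window mirrors it; when the annulus is
   wide enough that the bar's leading edge is still inside it after the
   trailing edge clears the Central area (annulus > Central + bar width),
   that leading-edge epoch is excluded from the unmasked POST counts,
   because it coincides with the trailing edge crossing the classical RF.
   The exclusion is dropped in masked-bar analyses, where the mask removes
   the classical-RF response entirely. The identical code path runs in
   µm (retina) or degrees of visual angle (thalamus; Central radius
   11.7°, border exclusion 15°).

3. **Tuning.** Spike counts per direction × repetition use half-open
   windows [start, end). The preferred direction reported everywhere is
   the resultant (vector-sum) angle — continuous, as drawn on polar
   plots; the argmax direction is kept alongside because the motion
   asymmetry index is defined on the argmax/opposite pair,
   mAI = (r_PD − r_ND)/(r_PD + r_ND). NVS is the resultant length
   normalized by the total. The permutation test shuffles direction
   labels across all direction × repetition trials and recomputes the
   resultant length (1000 seeded shuffles,
   p = (1 + #{perm ≥ obs})/(1 + N)); on ideal exchangeable nulls its size
   is exact (verified at 20 000 replicates). A window is asymmetric when
   mAI > 0.3, NVS > 0.15, the PD mean count is ≥ 2 spikes/repetition and
   p < 0.05 — all thresholds live in `RunConfig`.

4. **Baseline and context.** Baseline rate is the mean rate in the final
   1 s of each inter-trial blank. Enhancement/suppression labels compare
   per-repetition PD and ND rates against it with one-sided Wilcoxon
   signed-rank tests.

## The synthetic retina

Cells are inhomogeneous-Poisson units,
`rate = max(0, baseline + center + g_desens · zone − surround)`:

* **Classical center** — Gaussian-weighted stimulus contrast at the RF
  center, passed through a first-order high-pass filter whose time
  constant is the transience parameter (a step input returns
  `exp(−t/τ)`; τ = 1.5 s by default, i.e., sustained on the time scale of
  a bar crossing), polarity-signed, rectified, and scaled by
  `center_gain`.
* **Activation zone** — Gaussian-weighted ON luminance at a point
  `az_offset` from the RF center on the side the preferred motion comes
  from, scaled by `az_gain` and multiplied by `az_ds_gain` (≥ 1) when the
  global motion direction is within ±90° of the zone's angle — the
  "inherent DS component". The zone responds only to wide coherent ON
  stimuli (bars, full-field); checkerboards and gratings do not recruit
  it, consistent with the large-field character of extraclassical
  facilitation and with these cells being non-DS under gratings.
* **Desensitization** — `g = 1 − s·exp(−(t − t_last)/τ_d)` where
  `t_last` is the last time the center drive exceeded half its nominal
  peak; the state persists across trials, so stimulus history matters.
* **Surround** — an optional wider antagonistic Gaussian, off by default:
  the extraclassical approach response has the same ON polarity as the
  center and is modeled as excitation, not as the classical antagonistic
  surround.

Spike times are sampled by thinning against the linear interpolant of a
5 ms rate grid and are reproducible per (seed, protocol, trial, cell).
Inter-trial blanks (2 s) are simulated at the baseline rate and feed the
baseline estimator.

Default cell parameters (all configurable): RF σ 70 µm; baseline
8 spikes/s (sustained ON cells keep a maintained discharge); center gain
60 spikes/s; zone at 600 µm offset, σ 150 µm, gain 24 spikes/s (3× the
baseline — the detection-power operating point); DSGC tuning as a cubed
raised cosine with PD:ND gain 8 (a raised-cosine gain-3 modulation would
leave the resultant index near 0.17, below the 0.3 convention, i.e.,
unflaggable). The standard simulated tissue is a 1.6 mm square, putting
per-cell annuli at ~650–800 µm.

What the generator does **not** emulate: spike-sorting artifacts and unit
contamination, eye/tissue drift, adaptation of the classical center
beyond the single desensitization state, correlated (shared) noise across
cells, curved-retina geometry, and any biophysical circuit (amacrine
pathways exist only as the zone's phenomenological knobs; pharmacology is
a switch that zeroes the zone drive). Passing the validation suite
therefore demonstrates that the analysis recovers the statistical
structure it assumes — not that real recordings satisfy those
assumptions.

## Designed experiments in the validation suite

* **Trial-history (desensitization) split.** Zone probes are grouped by
  the previous trial's bar location (Central / neither-Central-nor-zone),
  and the reported quantity is the ratio of baseline-subtracted
  (evoked) zone responses — which estimates the desensitization gain
  directly. With a single-exponential recovery, "no previous
  stimulation" probes are only meaningful if no Central flash occurred
  for several recovery time constants, so the validation protocol uses a
  designed sequence: runs of ~100 far bars (≈ 6.4·τ_d at τ_d = 40 s,
  inter-trial period 2.5 s) separate probes, half of which are
  immediately preceded by a Central flash. Predicted ratio
  (1 − 0.5·e^{−2/40}) ≈ 0.52 for an injected strength of 0.5; the
  shuffled-history control permutes the previous-trial labels.
* **Masking.** The 700 µm mask strip is centered on the cell under test
  and oriented parallel to the bar. Central suppression and the masked
  PD/ND ratio use evoked rates; the PRE-PD and POST-ND windows both
  capture the leading edge crossing the zone, in opposite directions, so
  with desensitization prevented their ratio estimates `az_ds_gain`. The
  inherent-DS flag is a one-sided Wilcoxon across repetitions; the
  validation experiment uses 20 repetitions per direction, chosen by
  power analysis for a 2× gain at these rates.
* **Circular tests.** All nulls are Monte-Carlo (Rao spacing: uniform
  resampling) or permutation/bootstrap (Kuiper two-sample over the
  circular ECDF difference, rotation-invariant by the max-minus-min
  construction; Fisher's common-median statistic with label permutation;
  percentile-bootstrap CI for the one-sample mean angle). Degrees at the
  API surface, radians internally.

## Numerical choices and degenerate inputs

* Half-open spike windows; a spike exactly at a boundary counts once.
* All-zero direction counts: mAI = 0 and PD undefined (flagged), never an
  exception; identical counts in every trial give permutation p = 1.
* The ±90° inherent-DS cone is boundary-inclusive.
* PSTH-peak estimates are taken from a 5-bin (125 ms) moving average so
  binning ripple does not inflate the transience of sustained cells.
* Full-field clustering z-scores PSTHs, keeps the principal components
  with above-average explained variance (Kaiser-style cut, within a 90%
  envelope — the flat noise tail otherwise dilutes the silhouette used to
  choose k), and agglomerates with Ward linkage; identical PSTHs return a
  degenerate flag rather than an arbitrary split.
* Friedman post hocs use Tukey–Kramer on mean ranks with the studentized
  range distribution.
* Excluded cells always carry a reason string; included + excluded equals
  the input population.

## Problem sizes

The validation suite simulates 500 symmetric cells for detector size,
200 zone cells for power and PD recovery, 40 cells for RF recovery, 20
cells × ~2450 trials for the desensitization split, 100 cells × 2
conditions for masking, 30 cells × 4 speeds, 100 cells per retinal side
for the centripetal-population property, and 1200 replicates per
circular-test size (400 per power); a full pass takes about five minutes
on one CPU.

## Known limitations

* The screen estimates the zone's angle from 8 discrete motion
  directions; tuning width is resolvable only down to the 45° spacing.
* The desensitization model has a single state and exponential recovery;
  multi-time-scale adaptation would bias the split ratio toward 1.
* `Distance_min` uses the polygon boundary only; electrode coverage gaps
  inside the tissue are not modeled.
* The permutation test conditions on the observed counts; with fewer than
  3 repetitions it refuses rather than returning an unstable p.
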