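# Methods

`eegcompare` implements a complete validation analysis for comparing two EEG
recording systems — a dry multipin-electrode cap against a conventional
gel-electrode cap — recorded from the same subjects in paired sessions. The
package covers the preprocessing and multi-criteria data rejection, the
time-, frequency- and spatial-domain comparisons, and a paired-session
simulator that provides a known ground truth, so the entire analysis runs
and is testable with no external data.

## Data model and montages

Both caps are 32-channel 10-10 layouts sharing 29 electrodes; the gel cap
additionally carries M1, POz and a recorded M2 (right mastoid) channel, the
dry cap carries AFz, FT9 and FT10 and is referenced to an external M2
electrode in hardware. Analyses run on the shared 29 channels after
re-referencing the gel data to M2 (subtracting its M2 channel) and dropping
the system-specific electrodes. Electrode positions come from the standard
10-10 sphere, projected azimuthal-equidistantly into the unit head disc
(vertex at the origin, mastoids on the rim).

## Simulator

Per subject and task the generator synthesizes a continuous multichannel
recording at 1024 Hz (μV) with event markers:

* **CHECK** — 300 checkerboard reversals at 0.45 s intervals after a 10 s
  baseline; each reversal evokes an occipital VEP built from two Gaussian
  components (N75 negative, P100 positive, widths 15/16 ms).
* **ASSR** — 75 trials of a 12 s amplitude-modulated tone (40 Hz modulation)
  with 2–3 s jittered intertrial intervals; a fronto-central AEP (N1/P1) in
  the first second of each trial and a 40 Hz sinusoidal steady-state
  component (default scalp peak 0.6 μV) throughout the trial.
* **EOEC** — 60 alternating eyes-open (5 s) / eyes-closed (3 s) segments;
  parieto-occipital alpha (8–12 Hz band-limited noise) whose power is
  multiplied by `alpha_ec_gain` (default 4) during eye closure.

Spatial patterns are fixed Gaussian fields: Oz-centered for the VEP,
Fz/Cz-centered for the AEP and the 40 Hz response, Pz/Oz-centered for alpha,
and a prefrontal field for blinks. Component amplitudes and latencies are
subject-level lognormal/Gaussian latents **shared between a subject's dry and
gel sessions**, so between-system correlation is high by construction — the
property the real validation study exploits. Default scalp-peak amplitudes
(N75 40, P100 44, N1 40, P1 44 μV) were calibrated once so that
grand-average GFPt peaks land in the ≈8–13 μV range typical of these
paradigms; exact matching of any published peak table is not attempted.

Noise is a sum of: 1/f (pink) background (8 μV SD), white sensor noise
(2 μV), band-limited 1–4 Hz noise (4 μV, power doubled for the dry system
via `effect_scale_dry_delta = 2`), a <1 Hz random-walk drift (20 μV dry vs
5 μV gel — the dry low-frequency excess), 50 Hz line noise (5 μV, random
phase per channel), and stereotyped ~400 ms biphasic blinks arriving as a
Poisson process (10/min, 120 μV prefrontal peak). Channels are corrupted
(flat, high-amplitude, or drifting) with probability 0.05 (dry) / 0.02 (gel)
per session; the corrupted list is recorded in the ground truth. The gel M2
channel carries only a ~0.3 μV residual because both systems are
mastoid-referenced at the hardware level; subtracting it during
harmonization is therefore near-identity, and crucially does not inject
extra uncorrelated noise into the gel channels that would mask the
dry-system low-frequency excess.

Randomness: one independent stream per (subject, system, task) plus
subject-level latent streams, all spawned from a single master seed;
identical configuration implies bit-identical output.

What the simulator does **not** emulate: volume conduction (channels share
signal only through the component fields; background noise is spatially
independent), realistic ERP waveform shapes beyond Gaussian bumps,
heteroscedastic impedance drift, movement artifacts, or electrode-skin
physics. Passing tests therefore demonstrate that the *analysis machinery*
is correct and calibrated, not that it would behave identically on real
recordings.

## Preprocessing and rejection cascade

Filtering is zero-phase (forward–backward) Butterworth: 1–48 Hz bandpass
then 48–52 Hz bandstop; "2nd order" refers to the base design, giving an
effective 4th-order magnitude after the two passes. ERP analyses add a
1–30 Hz bandpass; the 40 Hz analysis a 30–48 Hz bandpass.

Rejection runs in three tiers, all using **mean absolute amplitude** (the
signed mean of high-passed EEG is ≈0 and could not express a flat-line
rule), sample SD (n−1), strict `>`, and single-pass statistics that include
the candidate:

1. **Global channels**: mean |x| < 1 μV (flat) or > 50 μV.
2. **Task channels** (task segment = events ± 5 s padding): the amplitude
   rule, or task-mean amplitude > mean + 2·SD over channels, or Hann-windowed
   band power > mean + 2·SD over channels in ≥ 2 of the 5 bands
   (delta 1–4, theta 4–8, alpha 8–14, beta 14–30, gamma 30–48 Hz), with
   task-specific window lengths (VEP 0.5, AEP 0.8, ASSR 11, EOEC 3 s).
3. **Units** (ERP trials; 1 s windows for ASSR/EOEC): per channel across its
   own units, the amplitude rule, or band power in ≥ 2 of 4 bands (ERP),
   gamma only (ASSR), or ≥ 2 of 5 bands (EOEC).

A note on monotonicity: adding a *flat* corrupted channel can never rescue a
rejected one, and absolute-amplitude (tier-1-style) flags survive any
addition; but a single-pass mean + 2·SD threshold is not monotone under
additions that inflate the cross-channel statistics — adding a very loud
channel can un-reject a moderately loud one. This is inherent to the printed
single-pass rule; iterating the statistics would change the published
procedure, so it is documented rather than "fixed".

Percent-rejected accounting uses channel-seconds: a rejected channel
contributes its full task duration, a rejected unit its window length, so
channel- and unit-level rejections combine into one per-channel and
per-subject percentage.

Blink handling delegates the ICA decomposition to FastICA (square,
un-centered sources, so removing all components reconstructs exactly zero)
and implements the three selection criteria: (1) mixing-vector energy
fraction on the frontal electrodes ≥ 0.6 — the frontal set includes the
prefrontal midline sites (Fpz, AFz) where the cap provides them, since blink
fields peak between the eyes; (2) stereotyped large monophasic deflections
in the source at ≥ 1/min; (3) deflections spread over the whole session
(coefficient of variation of per-block counts ≤ 0.5). Criterion 1 is
necessary; among qualifying components the most frontal wins; exactly one
component is removed when found.

## Time domain

Epochs: VEP −0.1–0.4 s, AEP −0.1–0.7 s, half-open sample intervals with
`round((tmax − tmin)·fs)` samples, per-trial baseline subtraction over
[−0.1, 0) s. The global field power GFPt is the spatial standard deviation
(population, 1/n) of the instantaneous potential across channels —
equivalently `sqrt(ΣᵢΣⱼ(Uᵢ−Uⱼ)²/(2n²))`; the pairwise form with a 1/(2n)
normalization sometimes seen in print is dimensionally inconsistent with a
standard deviation and is not used. Between-system agreement is summarized
per subject by the Spearman rank correlation (COR) and the RMSD of the two
GFPt series; component peaks are the GFPt maxima inside search windows
(N75 0.09–0.14, P100 0.13–0.19, N1 0.25–0.36, P1 0.36–0.46 s — positioned
to absorb the fixed presentation delay of the stimulus chain), ties broken
to the earliest sample.

## Frequency domain

PSDs are Hann-tapered Welch estimates in μV²/Hz. The 40 Hz-ASSR analysis
removes seven low-response electrodes (T7, T8, P7, P8, O1, O2, Oz), drops
the first second of each trial (eliminating the AEP), uses 4 s windows with
75% overlap, and evaluates the estimate on an explicit 0.5 Hz frequency
grid — a 4 s window natively yields 0.25 Hz spacing, and the 0.5 Hz analysis
grid (every second bin, exactly what evaluating the Welch estimate at
35:0.5:45 produces) gives the 21-bin strip the SNR bookkeeping assumes. The
SNR is the 40 Hz power divided by the sample SD of the 20 noise bins — all
bins of the 35–45 Hz strip except the signal bin. Standardization z-scores
the PSD per channel across the bins of the analysis range (35–45 Hz for
ASSR, 1–48 Hz for EOEC), making the result invariant to per-channel affine
spectral transforms; subject-level summaries average over channels after
standardization. EOEC uses the EC segments (3 s) and the middle 3 s of EO
segments, 1 s windows with 50% overlap; after window-level rejection each
channel's surviving contiguous runs become its Welch segments, averaged with
equal weights. Band power is the mean PSD over bins whose center lies in
[low, high), the last band closed.

## Spatial domain

Per-electrode quantities (ERP values at the group-level GFPt peak times;
mean standardized alpha power) are interpolated with a biharmonic spline:
Green's function g(r) = r²(ln r − 1) with g(0) = 0 plus an affine term
(a₀ + a₁x + a₂y under the usual orthogonality side conditions). The affine
null-space term is part of the standard thin-plate construction and is what
makes constants and planes exactly reproducible — without it, interpolation
would not commute with a global shift of the electrode values, breaking the
standardized-map contract. Maps live on a 67 × 67 grid over [−1, 1]² masked
to the unit disc, which contains exactly 3,409 in-head pixels (resolution is
a config key; the fast mode uses 21 × 21). Subject maps are standardized
(mean 0, SD 1 over the masked pixels) before testing; missing electrodes
simply drop out of the interpolation.

The between-system test is a paired sign-flip permutation test with
pixel-based max-statistic correction. Exchanging a subject's condition
labels negates its difference map, so the permutation space is the 2ⁿ sign
patterns; all are enumerated for n ≤ 20 (2¹⁵ = 32,768 for the full cohort),
otherwise Monte-Carlo sampling with a seed, always keeping the identity
pattern. Per
pattern the paired t-map t = mean(D)/(SD(D)/√n) is converted pixelwise to Z
using the per-pixel permutation mean/SD (computed in a first pass, so t and
Z maps live on one common scale); the map-wide minimum and maximum Z are
recorded, and the corrected thresholds are the 2.5th percentile of the
minima and the 97.5th percentile of the maxima. A pixel is significant when
its observed Z falls outside the thresholds. The family-wise error of this
construction is verified by simulation (null cohorts, 15 subjects, full
enumeration): the empirical rate sits at or slightly below the nominal 0.05,
as expected for a max-statistic procedure on standardized maps.

Scalar between-system statistics use the two-sided Wilcoxon signed-rank test
(Bonferroni-adjusted α = 0.05/5 = 0.01 over the five EOEC bands) and
Spearman rank correlation pooled over all (subject, electrode) pairs with
pairwise removal of missing entries.

## Problem sizes used by tests and drivers

The full-scale session defaults (1024 Hz, 300/75/60 trials) make a
15-subject cohort expensive to synthesize repeatedly, so the test suite,
the analysis drivers and the acceptance script run the same generative model
at reduced size via `SimConfig.reduced()`: 256 Hz, 60 reversals, 8 × 6 s
ASSR trials, 12 EOEC trials, 2 s baselines (the calibration loops trim the
EOEC task further to 6 trials and 1 s baselines). Effect sizes, noise
levels and all analysis parameters are unchanged; only the amount of data
per session shrinks. Calibration studies use a 20 × 20 head grid. The
choice trades statistical precision per cohort for the ability to run
hundreds of replicate cohorts; the reported detection rates and error rates
are properties of the reduced setting, which the relevant tests state
explicitly.

## Numerical choices and degenerate inputs

* Ties in mean + 2·SD comparisons: strict `>`, so 29 identical channels are
  all kept (SD = 0).
* GFP with fewer than 2 channels, standardization of a constant spectrum,
  SNR with zero noise-band SD, Spearman on a constant series: reported as
  errors or missing values (with a diagnostic), never silently imputed.
* Permutation test with all-zero differences: warns and returns an empty
  significance mask; degenerate pixels (zero permutation SD) get Z = 0.
* EDF writing quantizes to 16 bits over each channel's physical range
  (round-trip error bounded by range/65535); the delimited text format is
  lossless. EDF stores whole 1 s records; the JSON sidecar preserves the
  true sample count for exact cropping on load.
* Channel labels are canonicalized to 10-10 case conventions (`FZ → Fz`,
  `FP1 → Fp1`).

## Known limitations

* The ICA path assumes one dominant blink component; overlapping ocular and
  cardiac sources are not separated.
* Bad channels are removed, not repaired; no interpolation of rejected data.
* The simulator's spatially independent noise makes the electrode-pair
  Spearman correlations lower than those seen on real, volume-conducted
  data; directional comparisons remain meaningful.
* No BrainVision/FIF readers, no streaming, no 3D head geometry, no
  cluster-based correction variants.
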