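# Methods

This package implements the laminar analysis of the visual oddball paradigm
in mouse V1: the comparison of responses to the same grating orientation when
it is contextually *deviant* (rare in an oddball run), *redundant*
(high-probability in an oddball run), or a *control* (equally rare in a
many-standards sequence). The three response surfaces are transmembrane
current (CSD / av-rec), aggregate spiking (MUA), and neural oscillations
(Morlet induced power and inter-electrode phase synchrony), each with its own
statistical treatment. A synthetic forward model with a known injected effect
catalogue provides a recovery oracle for every stage.

## Paradigm and data model

A session is one many-standards control run (8 orientations, each at
~12.5 %) followed by a flip-flop pair of oddball runs (two orthogonal
orientations at ~87.5 % / ~12.5 %, with the roles exchanged in the second
run). Gratings last 500 ms with a ~500 ms inter-stimulus interval; we jitter
the ISI uniformly by ±50 ms (the protocol states only "~500 ms"). Recordings
are 16 contacts at 50 µm pitch, digitized at 10 kHz. Contacts are numbered
1 (most superficial) to 16.

Analysis restricts to one orientation per subject — the one with the
strongest normalized MUA response in the first 100 ms, pooled over contexts
and kept contacts — and holds the trial count constant across the three
contexts by a seeded uniform subsample to the minimum count (random rather
than "first n", to avoid early-session adaptation bias).

## Signal chains

**LFP / CSD.** The wideband signal is low-passed below 110 Hz with a
zero-phase elliptic filter (order 7, 0.01 dB ripple, 60 dB stop), giving
< 0.05 dB deviation below 100 Hz and > 100 dB above 200 Hz after the
forward-backward pass. CSD is the negated second spatial difference,
`CSD_k = −(V_{k−1} − 2V_k + V_{k+1}) / pitch²`, so **sinks are negative**.
The "Gaussian-smoothed with a 5-point Hamming window" instruction is
self-contradictory; we convolve depth with a normalized 5-point Hamming
window and expose a 5-point Gaussian as a config switch. Edge contacts use
Vaknin replication by default (keeping all contacts so the 12-contact layer
window fits); dropping the two edge contacts is a config option. The av-rec
montage averages the CSD across trials per channel, rectifies, then averages
channels within a layer — in that order, which the tests pin against an
explicit-loop oracle.

**MUA.** Band-pass 500–4000 Hz (zero-phase Butterworth), common average
reference computed *after* band-passing and excluding the channel itself
(`ref_i = (Σ_j x_j − x_i)/(n−1)`), full-wave rectification, Gaussian
smoothing in 10-ms windows (read as FWHM; an SD reading is a config switch),
and decimation to 1000 Hz. Smoothing and decimation run as one polyphase
Gaussian-FIR pass: at 10-ms FWHM the Gaussian's attenuation at the 500-Hz
output Nyquist exceeds 250 dB, so the kernel itself is the anti-alias filter;
the kernel radius is rounded to a multiple of the decimation factor so output
samples stay phase-aligned with the input grid. Envelopes are normalized by
one scalar per recording: the SD of the continuous MUA pooled over all
channels and timepoints.

**Layer-4 alignment.** Three criteria are combined by rank-sum: earliest
trial-average MUA peak latency per contact, earliest CSD sink latency, and
proximity to the gamma→alpha/beta spectral dominance crossover (first contact
from the top at which mean 30–80 Hz power falls below mean 8–30 Hz power;
both bands configurable). Contacts whose criterion extremum is below 25 % of
the array maximum are marked uninformative and share a tied worst rank, so a
flat criterion simply abstains. The crossover uses *depth-relative* power —
each frequency divided by its across-contact median — because the absolute
1/f background otherwise dominates both bands and makes the comparison
meaningless. Ties break toward the more superficial contact; disagreements
beyond 3 contacts are logged as warnings. The kept window is 12 contacts
(7 above the alignment contact, 4 below plus itself) partitioned 2/5/2/3
into L1, L2/3, L4, L5 from the top.

**Time–frequency.** Morlet wavelets on 100 frequencies (2–101 Hz, 1-Hz
steps) with cycle counts rising linearly 0.5→20, evaluated on a 4-ms grid
anchored at stimulus onset (so outputs run −248…748 ms inside the −250…750 ms
epoch). Wavelets are normalized to unit response to a unit-amplitude
sinusoid at their centre frequency; power is therefore in relative units,
which cancels in all context contrasts. Epochs are cut 150 ms wider than the
output window so the longest wavelet support fits; output bins whose support
still overruns are flagged. Induced power is the across-trial mean |W|²,
averaged within layers, minus one scalar per (layer, frequency): the mean
power at −200…−50 ms pooled over *all* contexts and trials. Because the
shift is context-shared, context differences are exactly unchanged by it.
The baseline reading "−200–50 ms" is ambiguous; −200 to −50 ms is the
default (it avoids stimulus-onset smearing from the long low-frequency
wavelets), with −200 to +50 ms available in config.

**Inter-electrode synchrony (IES).** For contacts (a, b) and each frequency,
R is the resultant length of `exp(i(φ_a − φ_b))` over trials and the window
timepoints (50–250 ms early, 250–450 ms late). A surrogate R pairs contact
b's phases from the trial two positions ahead (wrapping, so each trial is
used once); IES = R − R_surrogate removes coherence that is merely
stimulus-locked. Raw R ∈ [0, 1]; IES ∈ [−1, 1]. Raw R is symmetric in
(a, b); the one-sided surrogate pairing is not, so a `symmetrize` option
averages the surrogate over both directions when exact symmetry is wanted.
Seed maps average the corrected rows of the L1 seeds (kept contacts 1–2) or
the granular seeds (the two L4 contacts); both the early and the late
window maps are computed, with the cluster statistics run on the early
L1-seeded maps.

## Statistics

* **Windowed contrasts** on av-rec CSD (per layer) and MUA (per layer) use
  contiguous 30-ms bins from 50 to 260 ms. Both contrasts are computed per
  bin: DD (deviant − control) and SSA (redundant − control). MUA tests are
  one-tailed in the hypothesized direction (SSA decrease, DD increase); CSD
  tests are two-tailed, since more or less net transmembrane current is not
  sign-diagnostic. Paired t, df = n−1.
* **ROI ANOVA.** Six time–frequency ROIs (delta/theta 2–7 Hz at 100–150 ms;
  low beta 12–22 Hz at 65–180 ms; high beta 26–35 Hz at 90–120 ms; high
  gamma 68–77 Hz at 110–260 ms; alpha desynchronization 6–12 Hz at
  240–310 ms; late delta/theta 2–7 Hz at 350–560 ms). The high-beta and
  high-gamma bands are printed inconsistently in the source material
  (26–35 vs 26–36; 68–77 vs 67–76); the running-text values are the default
  and the caption values a config option. Each ROI gets a layer × context
  repeated-measures ANOVA (Greenhouse–Geisser corrected via pingouin);
  planned per-layer paired contrasts are reported for all layers but flagged
  as gated unless the interaction is significant. The single a-priori
  prediction — L2/3 delta/theta increase to deviants — is always tested
  ungated. No correction is applied across the six ROIs (matching the
  planned/ROI logic); Holm across ROIs is available as a config extra.
* **Cluster-mass permutation** on subject-wise deviant − control seed-map
  differences (12 contacts × 100 frequencies). Per permutation each
  subject's map is sign-flipped (equivalent to shuffling condition labels
  within subject); the observed mean map is z-scored pointwise against the
  permutation distribution, thresholded at |z| > 1.96 (the threshold is a
  convention, not printed in the protocol; the max-mass correction makes the
  family-wise rate insensitive to it), clustered under 4-neighbourhood
  adjacency per sign (8-neighbourhood in config), and each cluster's mass is
  compared with the permutation distribution of maximum |mass|;
  p = (1 + #{null ≥ |mass|}) / (n_perm + 1), α = 0.025 per tail, 2500
  permutations by default.

## Synthetic forward model

The generator writes, per trial, onto a background of spatially correlated
1/f noise (exponent 1.0, SD 20 µV, Gaussian inter-contact correlation with a
2-contact length — free defaults chosen to mimic the strong neighbour
correlation of laminar LFP):

* **Evoked dipoles**: a zero-sum, zero-first-moment current profile (sink −1
  flanked by +0.5 sources) converted to voltage by double cumulative
  summation along depth (1-D forward model, unit conductivity). With both
  moments zero the voltage is constant outside the dipole support, so the
  second-difference estimator inverts the model exactly — CSD recovery is
  analytically checkable. Default: a granular sink (contact 8) at 50 ms and
  a superficial sink (contact 4) at 85 ms.
* **Ongoing laminar spectra**: band-limited noise whose gamma (30–80 Hz)
  versus alpha/beta (8–30 Hz) amplitude balance crosses over at the granular
  contact (sigmoid profiles), giving the alignment's spectral criterion
  something real to find.
* **Oscillatory bursts**: Hann-windowed sinusoids at the band centre with a
  fresh random phase per trial — *induced*, not evoked, so trial-averaged
  waveforms largely cancel while induced power retains them. A context gain
  multiplies injected *power* (amplitude × √gain), so the induced-power
  difference against control scales linearly in (gain − 1); the property
  test asserts exactly that. Burst durations are set per effect so ≥ 80 % of
  burst energy falls within the stated band ± 2 Hz.
* **Spiking transients**: Poisson-timed biphasic pulses (Gabor at 1.5 kHz,
  σ = 0.25 ms, energy inside 500–4000 Hz) at a 30-Hz baseline rate, with an
  evoked-rate profile per contact: a transient peak whose latency is
  earliest at the granular contacts (45 ms) plus a sustained plateau, and a
  von-Mises-like orientation tuning per subject. MUA context gains multiply
  the evoked-rate increment inside the effect window.
* **Phase coupling**: a narrowband burst shared between L1 seed contacts and
  the deep-L2/3 / dorsal-L4 targets whose phase is copied to the targets
  with probability κ (1.0 in control) scaled by the context gain (0.05 for
  deviants) — so surrogate-corrected synchrony, and nothing else, separates
  the contexts.

The default effect catalogue mirrors the deviance-detection/adaptation
signature: granular MUA adaptation to redundants at 50–80 ms (gain 0.45),
L2/3 MUA deviance detection at 140–230 ms (gain 1.9), L2/3 delta/theta and
high-gamma deviant power increases (gain 2.5), an L1 high-beta deviant
decrease (gain 0.2), and the deviant loss of L1↔deep-L2/3 coupling at
34–41 Hz. The protocol gives no µV effect scale, so amplitudes are in µV
against the 20-µV noise SD and were chosen once so that a 10-subject cohort
recovers all six effects; they are study conditions, not per-run dials.
Cohorts draw per-subject gains log-normally around the catalogue (SD 0.25)
with subject seeds derived from a master seed.

What the generator does **not** emulate: locomotion and pupil-linked state
changes, electrode drift and artifact trials, retinotopy or stimulus motion
structure, laminar differences in noise level, spike waveform diversity, or
any cross-frequency coupling. Passing recovery tests therefore shows the
*analysis chain* is correct and adequately powered under the stated
conditions — not that real V1 data would yield these effect sizes.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 10 subjects with a
128-trial control run and two 88-/64-trial oddball runs (the package default
remains the full 250/150/150 protocol). With 64-trial oddball runs the
matched trial count is 8 per context, inside the 7–12 range the analysis is
designed around. The cluster-test calibration uses 200 null cohorts at 500
permutations. Degenerate inputs are rejected loudly: IES needs ≥ 4 trials
(the 2-ahead surrogate is degenerate below that), the cluster test ≥ 5
subjects and ≥ 100 permutations, CSD ≥ 5 contacts, paired tests ≥ 3
subjects. Zero-variance differences return t = 0, p = 1. Exact ties in
best-orientation selection return the first orientation in sorted order and
set a flag; subjects whose best response stays below 0.5 normalized units
are flagged "no clear response" and excluded from MUA statistics.

## Known limitations

* The 1-D forward model ignores conductivity and radial geometry; CSD units
  are arbitrary (as in the protocol).
* The sign-flip permutation null is conservative when an effect occupies few
  bins, because near-identity sign patterns reproduce much of the observed
  mass; power analyses should treat the cluster test's sensitivity as
  extent-dependent.
* Greenhouse–Geisser epsilons for a two-way within design with > 2 levels
  per factor are approximate (pingouin's estimator); the a-priori contrast
  does not depend on them.
* The wavelet normalization leaves negative-frequency leakage at the lowest
  frequencies (0.5 cycles at 2 Hz), so absolute power there is biased
  upward; context contrasts are unaffected.
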