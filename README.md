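# laminar-oddball

Analysis of laminar electrophysiology from the visual oddball paradigm:
current source density, multiunit activity, Morlet induced power,
surrogate-corrected inter-electrode synchrony, and the accompanying
windowed / ANOVA / cluster-permutation statistics — together with a
synthetic laminar-recording generator whose injected effects make every
stage of the pipeline verifiable.

## Who this is for

Systems neuroscientists working with linear-probe recordings of sensory
cortex who want a tested, scriptable implementation of the
deviance-detection / stimulus-specific-adaptation analysis: comparing
responses to the same stimulus when it is a rare "oddball" (**deviant**),
a high-probability standard (**redundant**), or equally rare in a
many-standards sequence (**control**).

## The analysis in brief

For a 16-contact probe (50 µm pitch, 10 kHz) the pipeline computes, per
subject:

* **CSD**: `CSD_k = −(V_{k−1} − 2V_k + V_{k+1}) / Δz²` on the < 110 Hz LFP
  (sinks negative), depth-smoothed with a 5-point Hamming window, summarized
  per layer as the rectified trial-mean ("av-rec") waveform;
* **MUA**: 500–4000 Hz band-pass, common-average reference excluding the
  channel itself, rectification, 10-ms Gaussian smoothing, 1 kHz envelope,
  normalized by the recording's pooled SD;
* **layer alignment**: granular contact by rank-sum of earliest MUA peak,
  earliest CSD sink, and the gamma→alpha/beta spectral crossover; 12 kept
  contacts partitioned 2/5/2/3 into L1, L2/3, L4, L5;
* **induced power**: 100 Morlet wavelets (2–101 Hz, 0.5→20 cycles) every
  4 ms; across-trial mean |W|² per layer minus a context-shared baseline;
* **IES**: phase-locking factor `R = |⟨e^{i(φ_a−φ_b)}⟩|` per contact pair
  and frequency, minus a 2-trials-ahead surrogate that removes
  stimulus-locked coherence.

Cohort statistics are paired 30-ms-bin contrasts (one-tailed for MUA,
two-tailed for CSD), layer × context repeated-measures ANOVAs on six
time–frequency ROIs with planned contrasts, and a sign-flip cluster-mass
permutation test (max-null corrected, α = 0.025 per tail) on seed-referenced
IES difference maps. `docs/methods.md` documents every convention and
deliberate reading of ambiguous protocol wording.

## Worked example

Generate a synthetic 10-subject cohort with the default injected effect
catalogue, analyze it end-to-end, and print the recovery report:

```python
from laminar_oddball.pipeline import simulate_and_analyze_cohort

stats, subjects = simulate_and_analyze_cohort(n_subjects=10, seed=1)
print(stats.recovery[["effect", "contrast", "statistic", "p", "detected"]])
```

```
                          effect contrast   statistic         p  detected
0                     l4_mua_ssa      SSA   -4.228683  0.001105      True
1                     l23_mua_dd       DD    7.214337  0.000025      True
2                   l23_theta_dd       DD    4.891274  0.000858      True
3               l23_highgamma_dd       DD    6.350749  0.000133      True
4                 l1_highbeta_dd       DD   -4.029871  0.002974      True
5  l1_deep23_lowgamma_decoupling       DD -130.280596  0.002399      True
```

Reading the table: granular-layer MUA is *reduced* to redundants in the
50–80 ms bin (stimulus-specific adaptation, negative one-tailed t), L2/3 MUA
is *enhanced* to deviants at 140–230 ms (deviance detection), deviants raise
L2/3 delta/theta and high-gamma induced power and suppress L1 high-beta
power (paired t on the ROI means), and a significant negative cluster
(cluster mass −130.3, permutation p = 0.0024 < 0.025) marks the loss of
L1 ↔ deep-L2/3 phase synchrony at 34–41 Hz — each matching the sign, layer,
and window/band of the injected ground truth.

The same pipeline runs from the shell on HDF5 containers:

```bash
laminar-oddball synth --subjects 10 --seed 7 --out data/
laminar-oddball analyze --data data/ --out results/ --seed 7
laminar-oddball report --results results/
```

`analyze` writes tidy CSVs (windowed contrasts, ROI values/contrasts, IES
clusters, recovery report), a seed/config manifest, and `report` renders the
three figure analogues plus tables into `results/report.html`.

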