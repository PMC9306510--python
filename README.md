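# psckit

Analysis of spontaneous and miniature postsynaptic currents (PSCs) in
whole-cell voltage-clamp recordings, built for the kind of slice-incubation
experiment where two groups of CA1 pyramidal neurons (vehicle vs. drug
incubation) are compared by synaptic event frequency, amplitude and
kinetics — together with a relative-optical-density (ROD) workflow for
quantifying immunofluorescence in hippocampal subfields.

Because no recordings ship with the package, a synthetic-data generator is a
first-class component: it produces gap-free 10 kHz current traces containing
Poisson trains of biexponential PSCs with two rise-time populations
(perisomatic "fast", ~1 ms 20–80 % rise; dendritic "slow", ~3 ms) over
band-limited noise, with full ground truth, so every stage of the pipeline
is validated against what was actually put in.

## The methods at the core

* **Detection** — sliding-window Pearson correlation of the trace against a
  peak-normalized biexponential template
  g(t) = (e^(−t/τ_d) − e^(−t/τ_r)) / g_max; windows with r > 0.6 mark
  candidate events, whose onsets are then refined on the waveform by
  discrete least-squares kernel alignment. A second pass on the
  event-subtracted residual recovers events masked by larger neighbours.
* **Event QC** — amplitude (|extremum − baseline|), 20–80 % rise time and
  halfwidth with sub-sample interpolation; events are kept only if
  r > 0.6, amplitude > 3 pA, rise < 5 ms and halfwidth > rise time.
* **Fast/slow classification** — for every candidate cutoff τ_c on a 0.1 ms
  grid, the smoothed slow:fast ratio r_s:f(τ_c) = (n(τ>τ_c)+1)/(n(τ≤τ_c)+1)
  is computed per group with its log-scale derivative
  δlog10(r_s:f)/(log10(e)·r_s:f·δτ); the chosen cutoff is the smallest τ_c
  past the initial spike where the two groups' derivatives agree and both
  curves are locally stable — the valley between the rise-time modes.
* **Group statistics** — event counts equalized across cells (first n
  accepted events each), pooled IEI/amplitude/rise ECDFs compared by the
  two-sample Kolmogorov–Smirnov test under the dual criterion p < .01 AND
  D > .05, cell averages by Mann–Whitney U, fast:slow proportions by
  Fisher's exact test.
* **Densitometry** — ROD = log10(256/(255 − grey)) after background
  subtraction, averaged cryotome → vibratome → mouse so the animal is the
  unit of replication, compared by Student's t.

## Worked example

```python
from psckit import (SimulationConfig, CohortScenario, PipelineConfig,
                    ComparisonConfig, run_pipeline)

config = PipelineConfig(
    scenario=CohortScenario(vehicle=SimulationConfig(duration=360.0),
                            n_vehicle=8, n_treated=9, seed=11),
    comparison=ComparisonConfig(n_per_cell=545, seed=11))
report = run_pipeline(config, "results/pipeline")
```

or, as the numbered analysis (`python analysis/01_simulate_cohort.py`, then
`02_run_pipeline.py`, …), which printed:

```
pooled-distribution comparisons (flag: p < .01 and D > .05):
  iei        D = 0.163  p = 7.25e-54 *
  amplitude  D = 0.097  p = 2.32e-19 *
  rise_time  D = 0.080  p = 2.46e-13 *
cell-average comparisons (Mann-Whitney, flag: p < .05):
  amplitude  U = 45.0  p = 0.413
  rise_time  U = 71.0  p = 0.001 *
  frequency  U = 9.0  p = 0.011 *
fast/slow split at 1.4 ms: {'vehicle': {'fast': 2227, 'slow': 2133},
                            'treated': {'fast': 2806, 'slow': 2099}}  Fisher p = 3.78e-09
```

The treated arm was simulated with a 1.38× event-rate multiplier and a
fast-fraction increase (0.60 → 0.70): the pipeline flags exactly those
effects — shorter interevent intervals (IEI), a shifted rise-time
distribution, a higher cell-average frequency, and an increased fast:slow
proportion at the 1.4 ms cutoff — while the cell-average amplitude
comparison, where no effect was simulated at the cell level, stays silent.

The remaining scripts validate each stage against ground truth:
`03_rise_time_cutoff.py` (cutoff curves and selection, 1.5 ms on clean
bimodal samples with modes at 1 and 3 ms), `04_detector_validation.py`
(recall 0.948 / precision 0.950 at SNR ≥ 5, frequency bias −4.7 %),
`05_statistics_calibration.py` (no false K-S flag in 40/40 exchangeable
null runs; IEI flagged in 87 % of effect runs), and `06_densitometry.py`
(the six-subfield ROD table).

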