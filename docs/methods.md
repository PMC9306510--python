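# Methods

## Scope and model

psckit analyses spontaneous/miniature postsynaptic currents (PSCs) in
gap-free whole-cell voltage-clamp recordings and compares two incubation
conditions. All currents are modelled as inward (negative) deflections —
at a holding potential of −70 mV with a high-chloride internal solution
both GABAergic and glutamatergic currents are inward — and all amplitude
analyses use absolute magnitudes.

An event is a scaled biexponential kernel

    g(t) = (exp(−t/τ_d) − exp(−t/τ_r)) / g_max,  t ≥ 0,

peak-normalized so an event of amplitude A deflects the trace by exactly
A pA. The kernel's analytic peak time, 20–80 % rise time and FWHM
(`psckit.kernels`) are computed by closed form or bracketed root finding
(`brentq`, xtol 1e-12); the map from a target 20–80 % rise time to τ_r at
fixed τ_d is strictly monotone and inverted the same way. A rise time is
only realizable up to ≈ 0.39·τ_d; the generator clips rise draws there.

## Synthetic recordings

The generator emulates the statistical structure the analysis assumes,
not the acquisition hardware (no series-resistance, seal-drift or
stimulus artifacts):

* **Onsets** per cell are a homogeneous Poisson process. The cell's rate
  is log-normal around the population mean (default 3.717 events/s, the
  control spontaneous-IPSC cell-average; cell-level CV 0.40, the scale
  implied by the published cell-average SEMs).
* **Rise-time populations**: each event is fast with probability
  `fast_fraction` (default 0.60) or slow otherwise; within-population
  20–80 % rise times are log-normal with means 1 ms / 3 ms and CV 0.20,
  matching the two distribution peaks visible in the source data. Decay
  constant 12 ms for all events.
* **Amplitudes** are log-normal (event-level CV 0.5, cell-level scale CV
  0.3, population mean 11.27 pA). The fast population's mean is 1.5× the
  slow one's (perisomatic events are larger), with the mixture mean held
  at `amplitude_mean`.
* **Noise**: Gaussian white noise of SD `noise_sd` (default 2 pA) passed
  through a 4-pole low-pass Bessel filter at 3 kHz, emulating an
  antialiasing filter before 10 kHz sampling. The post-filter SD follows
  the impulse-response transfer (≈ 0.75 × input SD at the defaults,
  i.e. ≈ 1.5 pA); `filtered_noise_sd` computes it.
* **Conditions**: the treated arm multiplies the event rate (default
  5.143/3.717 ≈ 1.38, the observed spontaneous-IPSC frequency change)
  and raises the fast fraction (default 0.70).

All randomness fans out from one integer seed through
`SeedSequence([seed, stage, crc32(cell_id)])`, so identical
configurations give bit-identical data and any stage can be re-run in
isolation. Recording duration is not fixed by the source experiments;
the demo uses 360 s per cell so that every cell at the control rate
comfortably exceeds the 545 accepted events needed for equalization.

## Detection

Detection follows the correlation-coefficient method: Pearson
correlation of a sliding window against the biexponential template,
evaluated at every sample via FFT cross-correlation and running window
sums; a zero-variance window correlates 0 by convention. Two numerical
choices deviate from the naive reading and are deliberate:

* **Short correlation window (default 10 ms)** rather than the full
  5-decay-constant template length. At spontaneous rates of 3–5 Hz a
  60 ms window contains a second event for ~20 % of events, destroying
  their correlation; a 10 ms window covering the rise and early decay is
  shape-specific yet rarely straddles two events. The full-window
  behaviour remains available (`window_ms=None`).
* **Template constants (default τ_r 3 ms, τ_d 12 ms)**. One template
  must detect both rise-time populations; a sharp template (τ_r ≈ 0.5 ms)
  leaves most slow-rise events below the 0.6 threshold in a short
  window, while τ_r = 3 ms keeps both populations above it.
  `fit_template_from_events` implements the per-recording alternative:
  average detected events and least-squares fit the kernel (falling back
  to the configured default, with a warning, if the fit fails).

Supra-threshold prominent correlation maxima are candidates only —
the correlation peak can trail the true onset by up to ~10 ms when
template and event rises differ. Each candidate is therefore assigned
the largest nearby deflection, a rough onset is extrapolated from the
20–80 % rise chord, and the onset is refined by discrete least-squares
alignment of a small bank of onset-anchored kernels (τ_r 0.7/1.5/3/3.6 ms;
amplitude and offset solved in closed form per shift, so no iterative
optimizer). A candidate is kept only if the correlation within ±1 ms of
its refined onset exceeds the threshold, and detections are deduplicated
within a 2 ms refractory span keeping the higher correlation. Each
filter removes candidates independently, so raising the threshold never
increases the detection count.

A second pass subtracts the fitted events and re-scans the residual,
recovering events masked by a larger neighbour. Residual detections
must clear an amplitude floor (2.5× a robust noise estimate, at least
1 pA — subtraction residue on near-noiseless traces would otherwise
re-detect) and keep a 3 ms berth around existing detections.

Against ground truth (±2 ms onset matching) on cohorts where every event
clears SNR 5, detection achieves recall ≈ 0.95 and precision ≈ 0.95–0.99.
With the default, wider amplitude distribution a tail of events sits at
or below ~2× the noise SD; such events are physically marginal and bound
recall at any threshold.

## Event measurement and filters

Baseline is the median of the 5 ms preceding the onset. The peak is
searched within 12 ms of onset (the kernel peak time for physiological
constants; searching further would jump to neighbouring events) on a
1 ms boxcar-smoothed deviation — the kernel is nearly flat at that
scale, so noise-free attenuation is < 0.2 %, while the upward selection
bias of a raw argmax (~25 % at SNR 5) is suppressed. Kinetic crossings
(20/80 % for rise, 50 % for halfwidth) are first forward crossings on a
lighter 0.3 ms smooth, linearly interpolated between samples, so rise
times are not quantized to the sampling interval. Events whose peak or
half-decay runs off the window are flagged truncated and rejected.

Acceptance requires, in order: correlation > 0.6, amplitude > 3 pA
(amplifier noise floor), 20–80 % rise < 5 ms, halfwidth > rise time.
The first failed criterion is recorded; filtering is idempotent and
order-independent. Noise-free measurements match continuous-kernel root
finding to < 0.01 ms; under the default noise, rise times carry a small
positive bias (~0.1–0.3 ms) from amplitude-level coupling, common to
both arms.

## Fast/slow cutoff selection

For each group, rise times are snapped to the 0.1 ms grid (the sampling
resolution limit) and the ratio r_s:f(τ_c) = (n(τ>τ_c)+1)/(n(τ≤τ_c)+1)
is computed on τ_c = k·0.1 ms. The +1 smoothing keeps the ratio finite;
the curve is non-increasing by construction. The log-scale derivative is
the forward difference of log10 r_s:f divided by log10(e)·r_s:f·δτ (the
printed expression's lone log10 factor is read as the ln→log10
conversion; both readings differ by a positive constant common to the
two groups, so the selected cutoff is unaffected).

The cutoff is the smallest grid point satisfying: (i) both ratios have
fallen below half their maximum (past the initial spike); (ii) the two
derivatives agree — within 10 % relative difference, or, equivalently on
the plotted log scale, with per-bin log-slope differences within the
stability step (in the valley the derivatives are tiny and their
relative difference is pure sampling noise); (iii) both curves are
locally stable, |Δlog10 r_s:f| ≤ 0.02 per 0.1 ms bin. The per-bin step
scales with local density over the smaller class fraction and is sample-
size-free, so this singles out the density valley between the modes.
Log-ratio curves are smoothed with a 0.5 ms moving average before the
comparison. Without the stability condition
(`stability_max_step=None`) the literal two-condition rule is applied.

A selection leaving < 5 % of either group on one side is flagged
low-confidence — the signature of unimodal data, where the search only
settles past the bulk of the sample; the group-comparison pipeline then
falls back to a configured fixed cutoff (default 1.4 ms, the published
class boundary) and records a note. On clean bimodal samples (modes
1/3 ms, n = 2000/group) the selected cutoff lands at 1.4–1.5 ms across
seeds; measured rise times under the default (wide) amplitude
distribution are noisy enough to blur the valley, which the guard
correctly refuses to split.

## Group statistics

Event counts are equalized before pooling: each cell contributes its
first n accepted events (545 for the spontaneous-IPSC design; cells
with fewer are excluded with a notice). A chronological prefix — a
contiguous recording epoch — preserves each cell's interevent-interval
scale; a seeded uniform subsample is also available but stretches every
cell's IEIs to a common mean and thereby erases rate differences from
the pooled IEI distribution.

Pooled IEI, amplitude and rise-time distributions are compared with the
two-sample Kolmogorov–Smirnov test (exact D, asymptotic p) under the
dual significance criterion p < .01 AND D > .05; cell averages
(frequency from full accepted counts over recording duration; amplitude
and rise from the equalized tables) with the two-sided Mann–Whitney U
test (exact for combined n ≤ 12 without ties, tie-corrected normal
approximation otherwise; a fully tied pooled sample returns p = 1); the
fast:slow split with Fisher's exact test, two-sided by
probability-mass summation. No multiple-testing correction is applied,
matching per-comparison reporting. Tests are delegated to scipy; the
test suite checks them against independent oracles (pooled-support ECDF
sweep, full rank-assignment enumeration, binomial-coefficient
hypergeometric enumeration).

Calibration on ground-truth event tables: with homogeneous cells and
exchangeable arms, no K-S flag is raised in 100/100 runs (the D > .05
requirement dominates at pooled n ≈ 4400–4900, where the .05 critical
D corresponds to p ≈ 2e-5). With the generator's cell-level dispersion,
pooled-event ECDF tests treat between-cell heterogeneity as signal and
flag exchangeable arms frequently — the pseudoreplication caveat
inherent to pooled-distribution testing; conclusions should rest on the
cell-average tests whenever cells are heterogeneous. The three
Mann–Whitney tests at α = .05 carry the usual ~14 % familywise rate by
design. Power: the 1.38× rate effect with the fast-fraction increase
flags the IEI K-S comparison in ~85 % of runs at the 8-vs-9-cell design.

## Densitometry

Grey values (8-bit) are background-corrected (background deducted before
conversion, per the stated order of operations; negative corrected
values are rejected unless explicitly clamped) and converted by
ROD = log10(256/(255 − grey)), which saturates at 255 and inverts
exactly as grey = 255 − 256·10^(−ROD). Averaging follows the sampling
hierarchy — cryotome sections → vibratome slice → mouse → group — with
unbalanced designs averaging over available children; n for the SEM and
the t-test is the number of mice. Group comparison uses the two-sided
equal-variance Student's t; degenerate zero-variance inputs resolve to
p = 1 (equal means) or p = 0. Relative percentages are rounded half-up
to integers. (One published percentage, 99 % where the printed means
give 100.9 %, appears to derive from unrounded means and is not
reproduced.)

## Problem sizes

Chosen so the full suite and the acceptance script each run in minutes
on one CPU: detector benchmark 4 cells × 60 s; frequency-recovery bias
50 seeds × 4 cells × 120 s (12 seeds in the test suite); null
calibration 100 runs (40 in the suite), power 25 runs (15); cutoff
recovery n = 2000/group; demo pipeline 8 + 9 cells × 360 s, run twice to
verify byte-identical reports.

## Known limitations

* Events below ~2× the filtered noise SD are not reliably detectable;
  accepted-event frequency underestimates the true rate accordingly
  (−4 to −5 % under benchmark conditions, more with the wide default
  amplitude distribution).
* Rise-time measurement noise at low SNR blurs the fast/slow valley;
  data-driven cutoff selection on measured (rather than true) rise
  times then requires the fixed-cutoff fallback.
* The generator does not model acquisition artifacts (series-resistance
  changes, baseline drift, line noise) or biophysical conductance
  kinetics, so passing benchmarks demonstrate correctness of the
  analysis pipeline under the stated statistical assumptions, not
  robustness to every feature of real recordings.
* Pooled-ECDF tests are anti-conservative under cell heterogeneity (see
  above); no hierarchical (cell-within-animal) model is provided.
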