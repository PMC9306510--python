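"""Synthetic voltage-clamp recordings with ground truth.

Emulates gap-free whole-cell recordings from CA1 pyramidal neurons held at
-70 mV: each cell fires a homogeneous Poisson train of biexponential
postsynaptic currents drawn from two rise-time populations (perisomatic
"fast", ~1 ms 20-80% rise, and dendritic "slow", ~3 ms), superimposed on
band-limited Gaussian noise that mimics an antialiasing Bessel filter in
the acquisition chain.  Cell-to-cell variability in rate and amplitude is
log-normal.  A "treated" arm differs from "vehicle" by a rate multiplier
and an increased fast fraction.  A separate generator produces grey-value
tables for the densitometry workflow.

Every random draw descends from the single configuration seed, so
identical configurations give bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .kernels import biexp_kernel, halfwidth as kernel_halfwidth, tau_rise_for_rise_time
from .trace import Trace

__all__ = [
    "SimulationConfig",
    "GroundTruthEvent",
    "CohortScenario",
    "generate_event_train",
    "render_trace",
    "generate_cohort",
    "generate_grey_values",
    "ground_truth_event_frame",
    "filtered_noise_sd",
    "derive_rng",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Per-cell generator settings.

    Rates and amplitudes are population means; individual cells draw their
    own rate (CV ``rate_dispersion``) and amplitude scale (CV
    ``amplitude_dispersion``) log-normally around them.
    """

    duration: float = 120.0          # s of recording per cell
    sampling_rate: float = 10_000.0  # Hz
    event_rate: float = 3.717        # events/s, population mean
    rate_dispersion: float = 0.40    # CV of the cell-level rate
    amplitude_mean: float = 11.266   # pA, population mean over all events
    amplitude_cv: float = 0.5        # event-level CV within a cell
    amplitude_dispersion: float = 0.3  # CV of the cell-level amplitude scale
    fast_fraction: float = 0.60      # P(event is from the fast population)
    fast_rise_ms: float = 1.0        # mean 20-80% rise, fast population
    slow_rise_ms: float = 3.0        # mean 20-80% rise, slow population
    rise_cv: float = 0.20            # within-population rise-time CV
    fast_amplitude_ratio: float = 1.5  # fast-population mean amp / slow-population
    decay_ms: float = 12.0           # decay time constant of the kernel
    noise_sd: float = 2.0            # pA, white-noise SD before low-pass filtering
    noise_cutoff: float = 3000.0     # Hz, low-pass corner (antialiasing emulation)
    baseline_pA: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.event_rate < 0:
            raise ValueError("event_rate must be non-negative")
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise ValueError("fast_fraction must lie in [0, 1]")
        if not 0 < self.fast_rise_ms < self.slow_rise_ms:
            raise ValueError("need 0 < fast_rise_ms < slow_rise_ms")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_cutoff >= self.sampling_rate / 2:
            raise ValueError("noise_cutoff must be below the Nyquist frequency")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One true synaptic event as placed by the generator."""

    onset: float            # s
    amplitude: float        # pA, positive magnitude
    rise_population: str    # "fast" | "slow"
    rise_ms: float          # target 20-80% rise time of this event's kernel
    tau_rise_ms: float      # kernel rise constant realizing rise_ms
    tau_decay_ms: float


def derive_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator for (seed, stage, cell...) tuples.

    String keys are hashed with CRC-32 so cell identifiers can seed
    sub-streams reproducibly.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


def _lognormal(rng, mean, cv, size=None):
    """Log-normal draws with the requested arithmetic mean and CV."""
    if cv <= 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


# tau_r inversion is a root find; cache per (rise, decay) rounded to 1e-4 ms
_TAU_CACHE: dict[tuple[float, float], float] = {}


def _tau_rise(rise_ms: float, decay_ms: float) -> float:
    key = (round(rise_ms, 4), round(decay_ms, 4))
    if key not in _TAU_CACHE:
        _TAU_CACHE[key] = tau_rise_for_rise_time(key[0], key[1])
    return _TAU_CACHE[key]


def generate_event_train(config: SimulationConfig, cell_id) -> list[GroundTruthEvent]:
    """Draw one cell's ground-truth event list.

    Onsets form a homogeneous Poisson process at the cell's own rate (drawn
    log-normally around ``event_rate``); population labels are Bernoulli in
    ``fast_fraction``; amplitudes are log-normal, with the fast population
    drawn from a higher-amplitude distribution (perisomatic events are both
    fast-rising and large).  Deterministic given ``(config.seed, cell_id)``.
    """
    rng = derive_rng(config.seed, "events", cell_id)
    cell_rate = _lognormal(rng, config.event_rate, config.rate_dispersion) \
        if config.event_rate > 0 else 0.0
    amp_scale = _lognormal(rng, 1.0, config.amplitude_dispersion)
    n = rng.poisson(cell_rate * config.duration)
    if n == 0:
        return []
    onsets = np.sort(rng.uniform(0.0, config.duration, n))
    is_fast = rng.random(n) < config.fast_fraction

    # keep the overall event-amplitude mean at amplitude_mean regardless of
    # the fast/slow mix: slow mean * (1-p + p*ratio) = amplitude_mean
    denom = 1.0 - config.fast_fraction + config.fast_fraction * config.fast_amplitude_ratio
    slow_amp_mean = config.amplitude_mean / denom
    means = np.where(is_fast, slow_amp_mean * config.fast_amplitude_ratio, slow_amp_mean)
    amplitudes = _lognormal(rng, 1.0, config.amplitude_cv, n) * means * amp_scale

    rise_means = np.where(is_fast, config.fast_rise_ms, config.slow_rise_ms)
    rises = _lognormal(rng, 1.0, config.rise_cv, n) * rise_means
    # keep every event's rise realizable for the configured decay constant
    # (the difference-of-exponentials kernel tops out near 0.39 * tau_d)
    rises = np.clip(rises, 0.05, 0.38 * config.decay_ms)
    # quantize so the tau_r root-find cache stays small
    rises = np.round(rises, 2)

    events = []
    for i in range(n):
        pop = "fast" if is_fast[i] else "slow"
        tau_r = _tau_rise(rises[i], config.decay_ms)
        events.append(GroundTruthEvent(
            onset=float(onsets[i]),
            amplitude=float(amplitudes[i]),
            rise_population=pop,
            rise_ms=float(rises[i]),
            tau_rise_ms=tau_r,
            tau_decay_ms=config.decay_ms,
        ))
    return events


def _noise_filter(config: SimulationConfig):
    """4-pole low-pass Bessel at the configured corner frequency."""
    return signal.bessel(4, config.noise_cutoff, fs=config.sampling_rate, norm="mag")


def filtered_noise_sd(config: SimulationConfig) -> float:
    """Standard deviation of the trace noise after the low-pass stage.

    White noise of SD ``noise_sd`` through an LTI filter has output variance
    ``noise_sd**2 * sum(h**2)`` with ``h`` the impulse response.
    """
    if config.noise_sd == 0:
        return 0.0
    b, a = _noise_filter(config)
    impulse = np.zeros(4096)
    impulse[0] = 1.0
    h = signal.lfilter(b, a, impulse)
    return float(config.noise_sd * np.sqrt(np.sum(h * h)))


def render_trace(events, config: SimulationConfig, cell_id="cell",
                 condition: str = "") -> Trace:
    """Render ground-truth events into a sampled current trace.

    trace = baseline - sum_k A_k * g(t - onset_k) + filtered noise, with g
    the peak-normalized biexponential kernel, so each event contributes an
    inward (negative) deflection whose magnitude equals its amplitude.
    """
    n_samples = int(round(config.duration * config.sampling_rate))
    out = np.full(n_samples, config.baseline_pA, dtype=float)
    fs_ms = config.sampling_rate / 1000.0

    for ev in events:
        if not 0.0 <= ev.onset < config.duration:
            raise ValueError(f"event onset {ev.onset} s outside recording")
        i0 = int(round(ev.onset * config.sampling_rate))
        # 8 decay constants captures >99.9% of the kernel
        length = int(round(8.0 * ev.tau_decay_ms * fs_ms))
        i1 = min(i0 + length, n_samples)
        t_ms = np.arange(i1 - i0) / fs_ms
        out[i0:i1] -= ev.amplitude * biexp_kernel(t_ms, ev.tau_rise_ms, ev.tau_decay_ms)

    if config.noise_sd > 0:
        rng = derive_rng(config.seed, "noise", cell_id)
        white = rng.normal(0.0, config.noise_sd, n_samples)
        b, a = _noise_filter(config)
        out += signal.lfilter(b, a, white)

    return Trace(out, config.sampling_rate, trace_id=str(cell_id),
                 condition=condition, meta={"seed": config.seed})


@dataclass(frozen=True)
class CohortScenario:
    """A two-arm (optionally three-arm) incubation experiment.

    The treated arm inherits the vehicle configuration with its event rate
    multiplied by ``rate_multiplier`` (default mirroring the observed
    spontaneous-IPSC frequency change, 5.143/3.717) and its fast fraction
    replaced by ``treated_fast_fraction``.
    """

    vehicle: SimulationConfig = field(default_factory=SimulationConfig)
    n_vehicle: int = 8
    n_treated: int = 9
    rate_multiplier: float = 5.143 / 3.717
    treated_fast_fraction: float = 0.70
    seed: int = 0

    def treated_config(self) -> SimulationConfig:
        return replace(
            self.vehicle,
            event_rate=self.vehicle.event_rate * self.rate_multiplier,
            fast_fraction=self.treated_fast_fraction,
            seed=self.seed + 1,
        )

    def vehicle_config(self) -> SimulationConfig:
        return replace(self.vehicle, seed=self.seed)


def generate_cohort(scenario: CohortScenario, render: bool = True) -> dict:
    """Generate both arms of a scenario.

    Returns ``{condition: {cell_id: {"events": [...], "trace": Trace|None,
    "config": SimulationConfig}}}``.  With ``render=False`` only ground
    truth is produced (used by statistics calibrations that do not need the
    detector).
    """
    if scenario.n_vehicle < 2 or scenario.n_treated < 2:
        raise ValueError("each arm needs at least 2 cells")
    arms = {
        "vehicle": (scenario.vehicle_config(), scenario.n_vehicle),
        "treated": (scenario.treated_config(), scenario.n_treated),
    }
    out: dict = {}
    for condition, (cfg, n_cells) in arms.items():
        cells = {}
        for i in range(n_cells):
            cell_id = f"{condition}_{i:02d}"
            events = generate_event_train(cfg, cell_id)
            trace = render_trace(events, cfg, cell_id, condition) if render else None
            cells[cell_id] = {"events": events, "trace": trace, "config": cfg}
        out[condition] = cells
    return out


def ground_truth_event_frame(cells: dict, condition: str = "",
                             event_class: str = "sIPSC") -> pd.DataFrame:
    """Event-table rows straight from ground truth (detector bypassed).

    Halfwidths are the analytic FWHM of each event's kernel.  Used for
    statistics calibrations where detection fidelity is not under test.
    """
    hw_cache: dict[tuple[float, float], float] = {}
    rows = []
    for cell_id, cell in cells.items():
        for ev in cell["events"]:
            key = (round(ev.tau_rise_ms, 4), ev.tau_decay_ms)
            if key not in hw_cache:
                hw_cache[key] = kernel_halfwidth(key[0], key[1])
            rows.append({
                "cell_id": cell_id,
                "condition": condition,
                "event_class": event_class,
                "onset_s": ev.onset,
                "peak_time_s": np.nan,
                "amplitude_pA": ev.amplitude,
                "rise_ms": ev.rise_ms,
                "halfwidth_ms": hw_cache[key],
                "correlation": 1.0,
                "accepted": True,
                "reject_reason": "",
            })
    return pd.DataFrame(rows)


_ROD_REGIONS = ("DG-ML", "CA1-so", "CA1-sr", "CA1-slm", "CA3-so", "CA3-sr")


def generate_grey_values(region_means: dict, background_mean: float,
                         noise_sd: float, n_mice: int = 4,
                         n_vibratome: int = 3, n_cryotome: int = 2,
                         condition: str = "", seed: int = 0,
                         mouse_sd: float = 0.0) -> pd.DataFrame:
    """Grey-value measurements (0-255 scale) on a mouse/vibratome/cryotome
    hierarchy, one row per (region, cryotome section).

    ``mouse_sd`` adds a mouse-level offset so that between-animal variance
    can exceed section noise, as in real densitometry.
    """
    for name, m in {**region_means, "background": background_mean}.items():
        if not 0.0 <= m < 255.0:
            raise ValueError(f"mean for {name} outside the [0, 255) grey scale")
    rng = derive_rng(seed, "grey", condition)
    rows = []
    for mouse in range(n_mice):
        offsets = {r: rng.normal(0.0, mouse_sd) if mouse_sd > 0 else 0.0
                   for r in region_means}
        for vib in range(n_vibratome):
            for cryo in range(n_cryotome):
                for region, mean in region_means.items():
                    grey = mean + offsets[region] + (
                        rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    bg = background_mean + (
                        rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append({
                        "region": region,
                        "condition": condition,
                        "mouse_id": f"m{mouse}",
                        "vibratome_id": f"m{mouse}_v{vib}",
                        "cryotome_id": f"m{mouse}_v{vib}_c{cryo}",
                        "grey": float(np.clip(grey, 0.0, 255.0)),
                        "background": float(np.clip(bg, 0.0, 255.0)),
                    })
    return pd.DataFrame(rows)
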