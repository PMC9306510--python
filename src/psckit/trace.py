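"""Uniformly sampled current recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """A gap-free single-channel voltage-clamp current recording.

    Attributes
    ----------
    samples : ndarray
        Current in pA.  Synaptic events are inward, i.e. negative
        deflections from baseline (whole-cell at -70 mV with a high-Cl
        internal makes both GABAergic and glutamatergic currents inward).
    sampling_rate : float
        Hz.
    trace_id : str
        Usually the cell identifier.
    condition : str
        Experimental arm label (e.g. "vehicle", "treated").
    """

    samples: np.ndarray
    sampling_rate: float
    trace_id: str = ""
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate
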