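"""Core containers for uniformly sampled electrophysiology signals.

A :class:`Trace` stores one sweep of a whole-cell recording: membrane
voltage in mV (current clamp) or membrane current in pA (voltage clamp),
sampled at a fixed rate.  Time stamps are never stored per sample; they
are reconstructed from ``start_time`` and ``rate``.  A
:class:`PuffProtocol` describes when agonist puffs were delivered within
the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"

#: Units implied by each recording mode.
MODE_UNITS = {CURRENT_CLAMP: "mV", VOLTAGE_CLAMP: "pA"}


@dataclass
class Trace:
    """One uniformly sampled sweep.

    Parameters
    ----------
    samples
        Signal values, mV in current clamp and pA in voltage clamp.
    rate
        Sampling rate in samples per second.
    mode
        ``"current_clamp"`` or ``"voltage_clamp"``; fixes the units.
    start_time
        Time of the first sample in seconds.
    meta
        Free-form metadata (cell id, condition label, seed,
        junction-correction flag, ...).
    """

    samples: np.ndarray
    rate: float
    mode: str
    start_time: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.mode not in MODE_UNITS:
            raise ValueError(
                f"mode must be one of {sorted(MODE_UNITS)}, got {self.mode!r}"
            )

    @property
    def units(self) -> str:
        return MODE_UNITS[self.mode]

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Sweep duration in seconds (n / rate)."""
        return self.n_samples / self.rate

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def times(self) -> np.ndarray:
        """Per-sample time stamps in seconds (reconstructed, not stored)."""
        return self.start_time + np.arange(self.n_samples) / self.rate

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to range)."""
        i = int(round((t - self.start_time) * self.rate))
        return min(max(i, 0), self.n_samples - 1)

    def with_samples(self, samples: np.ndarray, **meta: Any) -> "Trace":
        """Copy of this trace with new samples and optional extra metadata."""
        new = replace(self, samples=np.asarray(samples, dtype=float))
        new.meta = {**self.meta, **meta}
        return new


@dataclass
class PuffProtocol:
    """Timing of agonist puffs within a sweep.

    ``puff_times`` are onset times in seconds, strictly increasing.
    ``concentration`` is the agonist concentration in the puffer pipette
    in µM.  ``frequency`` is the within-train puff rate in Hz, or None
    for isolated puffs separated by ``inter_trial`` seconds.
    """

    puff_times: np.ndarray
    puff_duration: float = 0.010
    concentration: float = 1000.0
    frequency: float | None = None
    inter_trial: float = 60.0

    def __post_init__(self) -> None:
        self.puff_times = np.atleast_1d(np.asarray(self.puff_times, dtype=float))
        if self.puff_times.size == 0:
            raise ValueError("protocol needs at least one puff")
        if np.any(np.diff(self.puff_times) <= 0):
            raise ValueError("puff_times must be strictly increasing")
        if not self.puff_duration > 0:
            raise ValueError("puff_duration must be positive")

    @property
    def n_puffs(self) -> int:
        return int(self.puff_times.size)

    @classmethod
    def single_puff(
        cls, onset: float = 0.2, concentration: float = 1000.0, **kw: Any
    ) -> "PuffProtocol":
        """A single brief puff at ``onset`` seconds."""
        return cls(puff_times=np.array([onset]), concentration=concentration, **kw)

    @classmethod
    def train(
        cls,
        n_puffs: int,
        frequency: float,
        onset: float = 0.2,
        concentration: float = 30.0,
        **kw: Any,
    ) -> "PuffProtocol":
        """A train of ``n_puffs`` puffs at ``frequency`` Hz starting at ``onset``."""
        if n_puffs < 1:
            raise ValueError("n_puffs must be >= 1")
        times = onset + np.arange(n_puffs) / frequency
        return cls(
            puff_times=times, concentration=concentration, frequency=frequency, **kw
        )
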