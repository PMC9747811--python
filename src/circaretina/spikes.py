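"""Spike-train primitives: epoching, PSTHs, ISIs and cumulative cycle distributions.

A sorted unit is a strictly increasing vector of spike times.  All
response analysis happens on the 2 s flash cycle, with phase 0 at the
white-flash onset: phases in ``[0, 1)`` fall in the white half of the
cycle and ``[1, 2)`` in the black half.

The *cumulative cycle distribution* pools spike phases across trials and
treats them as a probability distribution over the cycle.  This
intrinsically normalizes units with respect to their spike count — the
curve is sensitive only to when spikes occur within the cycle, not to how
many there are — which is what makes template matching and clustering of
heterogeneous units possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stimulus import StimulusProtocol

__all__ = [
    "SpikeTrain",
    "RecordingSession",
    "Psth",
    "CumulativeCycleDistribution",
    "CYCLE_DURATION",
    "CDF_GRID",
    "epoch_spikes",
    "pool_phases",
    "psth",
    "cumulative_cycle_distribution",
    "isi_sample",
    "mean_rate",
]

#: Duration of one white+black flash cycle (s).
CYCLE_DURATION = 2.0

#: Fixed 200-point evaluation grid for cumulative cycle distributions:
#: right edges of 10 ms bins spanning the 2 s cycle (matches the PSTH bin).
CDF_GRID = np.arange(1, 201) * 0.01


@dataclass
class SpikeTrain:
    """One sorted unit's spike times (s, from session start)."""

    unit_id: str
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size:
            if self.times[0] < 0:
                raise ValueError(f"unit {self.unit_id}: negative spike time")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError(
                    f"unit {self.unit_id}: spike times must be strictly increasing"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


VALID_ZT = (0, 6, 12, 18)


@dataclass
class RecordingSession:
    """All sorted units of one retina under one protocol presentation."""

    genotype: str  # "Ctrl" | "cKO"
    zt: int
    regime: str  # "mesopic" | "photopic"
    retina_id: str
    protocol: StimulusProtocol
    units: list[SpikeTrain]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zt not in VALID_ZT:
            raise ValueError(f"zt must be one of {VALID_ZT}, got {self.zt}")
        dur = self.protocol.duration
        for u in self.units:
            if u.times.size and u.times[-1] >= dur + 1e-9:
                raise ValueError(
                    f"unit {u.unit_id}: spike at {u.times[-1]:.3f}s beyond "
                    f"protocol duration {dur:.3f}s"
                )

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


@dataclass
class Psth:
    """Trial-averaged firing rate over the 2 s cycle."""

    bin_width: float
    rates: np.ndarray  # spikes/s per bin
    n_trials: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.rates.size) + 0.5) * self.bin_width

    def total_spikes(self) -> float:
        return float(np.sum(self.rates) * self.bin_width * self.n_trials)


@dataclass
class CumulativeCycleDistribution:
    """Empirical CDF of pooled spike phases on the fixed cycle grid."""

    grid: np.ndarray
    values: np.ndarray
    n_spikes: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if np.any(np.diff(v) < -1e-12):
            raise ValueError("cumulative distribution must be non-decreasing")
        if abs(v[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative distribution must end at 1")


def epoch_spikes(
    train: SpikeTrain, protocol: StimulusProtocol, ct: float
) -> list[np.ndarray]:
    """Align spikes to the flash trials of the block at contrast ``ct``.

    Returns one array per trial of spike phases in ``[0, cycle)`` with
    phase 0 at the white-flash onset.
    """
    cycle = protocol.cycle_duration
    out = []
    for onset in protocol.trial_onsets(ct):
        sel = train.times[(train.times >= onset) & (train.times < onset + cycle)]
        out.append(sel - onset)
    return out


def unepoch_spikes(
    phases: Sequence[np.ndarray], protocol: StimulusProtocol, ct: float
) -> np.ndarray:
    """Inverse of :func:`epoch_spikes`: restore in-block absolute spike times."""
    onsets = protocol.trial_onsets(ct)
    if len(onsets) != len(phases):
        raise ValueError("one phase array per trial is required")
    return np.concatenate([np.asarray(p) + t0 for p, t0 in zip(phases, onsets)])


def pool_phases(phases: Sequence[np.ndarray]) -> np.ndarray:
    arrays = [np.asarray(p, float) for p in phases]
    return np.sort(np.concatenate(arrays)) if arrays else np.empty(0)


def psth(
    phases: Sequence[np.ndarray],
    bin_width: float = 0.01,
    cycle_duration: float = CYCLE_DURATION,
) -> Psth:
    """Peri-stimulus time histogram in spikes/s (10 ms bins by default).

    rate(b) = pooled count in bin b / (n_trials * bin_width), so
    sum(rates) * bin_width * n_trials returns the pooled spike count
    exactly.
    """
    n_bins_f = cycle_duration / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9:
        raise ValueError(
            f"bin width {bin_width} must divide the {cycle_duration}s cycle exactly"
        )
    n_trials = len(phases)
    if n_trials == 0:
        raise ValueError("at least one trial is required")
    pooled = pool_phases(phases)
    counts, _ = np.histogram(pooled, bins=n_bins, range=(0.0, cycle_duration))
    return Psth(bin_width, counts / (n_trials * bin_width), n_trials)


def cumulative_cycle_distribution(
    phases: Sequence[np.ndarray] | np.ndarray,
) -> CumulativeCycleDistribution:
    """Empirical CDF of pooled spike phases on the fixed 200-point grid.

    Spikes are pooled across trials first; the value at grid point g is
    the fraction of pooled phases <= g.  Undefined (raises) when the unit
    fired no spike in the cycle windows — callers filter such units out.
    """
    pooled = phases if isinstance(phases, np.ndarray) else pool_phases(phases)
    pooled = np.asarray(pooled, float)
    if pooled.size == 0:
        raise ValueError("cumulative distribution undefined for zero spikes")
    values = np.searchsorted(np.sort(pooled), CDF_GRID, side="right") / pooled.size
    return CumulativeCycleDistribution(CDF_GRID.copy(), values, int(pooled.size))


def isi_sample(
    train: SpikeTrain | np.ndarray, window: tuple[float, float] | None = None
) -> np.ndarray:
    """Inter-spike intervals of the spikes falling in ``window`` (s)."""
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if window is not None:
        t0, t1 = window
        times = times[(times >= t0) & (times < t1)]
    if times.size < 2:
        raise ValueError("at least two spikes are needed for an ISI sample")
    return np.diff(times)


def mean_rate(
    train: SpikeTrain | np.ndarray,
    duration: float | None = None,
    window: tuple[float, float] | None = None,
) -> float:
    """Mean firing rate = spike count / duration (spikes/s)."""
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if window is not None:
        t0, t1 = window
        times = times[(times >= t0) & (times < t1)]
        duration = t1 - t0
    if duration is None or duration <= 0:
        raise ValueError("a positive duration is required")
    return times.size / duration
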