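"""Full-field flash stimulation protocols and Michelson-contrast arithmetic.

The recordings this package analyses present a retina with a static
isoluminant gray screen (to measure spontaneous firing) followed, per
contrast level, by a gray baseline and a train of alternating 1 s white /
1 s black full-field flashes.  Contrast between the bright and dark flash
luminances is expressed on the Michelson convention scaled to 0-100
("CT"), with the white/black pair symmetric around the mean gray.

Luminance is a linear scalar throughout; the luminance regime
(mesopic vs photopic) is carried as metadata only and never enters the
contrast arithmetic.  Time is in seconds from protocol start and every
event occupies the half-open window ``[onset, onset + duration)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "LuminancePair",
    "StimulusEvent",
    "StimulusProtocol",
    "michelson_contrast",
    "contrast_pair",
    "build_flash_protocol",
]

#: Regime mean luminances used by the recordings (cd/m^2); metadata only.
REGIME_LUMINANCE = {"mesopic": 0.092, "photopic": 9.20}

SPONT_GRAY = "spont_gray"
BASELINE_GRAY = "baseline_gray"
FLASH_WHITE = "flash_white"
FLASH_BLACK = "flash_black"


@dataclass(frozen=True)
class LuminancePair:
    """Bright/dark flash luminance pair, ``l_max >= l_min >= 0``."""

    l_max: float
    l_min: float

    def __post_init__(self) -> None:
        if self.l_min < 0 or self.l_max < self.l_min:
            raise ValueError(
                f"require l_max >= l_min >= 0, got ({self.l_max}, {self.l_min})"
            )

    @property
    def mean(self) -> float:
        return 0.5 * (self.l_max + self.l_min)


def michelson_contrast(pair: LuminancePair) -> float:
    """Michelson contrast CT = 100 * (Lmax - Lmin) / (Lmax + Lmin).

    Raises
    ------
    ValueError
        If both luminances are zero (contrast undefined).
    """
    total = pair.l_max + pair.l_min
    if total <= 0:
        raise ValueError("contrast undefined: both luminances are zero")
    return 100.0 * (pair.l_max - pair.l_min) / total


def contrast_pair(mean_gray: float, ct: float) -> LuminancePair:
    """Invert the contrast formula around an isoluminant gray.

    Returns the pair ``(g*(1 + ct/100), g*(1 - ct/100))`` whose Michelson
    contrast is ``ct`` and whose mean is ``mean_gray``.
    """
    if mean_gray <= 0:
        raise ValueError(f"mean_gray must be positive, got {mean_gray}")
    if not 0.0 <= ct <= 100.0:
        raise ValueError(f"contrast must lie in [0, 100], got {ct}")
    return LuminancePair(mean_gray * (1.0 + ct / 100.0), mean_gray * (1.0 - ct / 100.0))


@dataclass(frozen=True)
class StimulusEvent:
    onset: float
    duration: float
    luminance: float
    tag: str

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class StimulusProtocol:
    """Ordered, gap-free schedule of gray and flash events.

    ``contrasts`` records the block presentation order; flash events carry
    the luminances produced by :func:`contrast_pair` at that contrast.
    """

    regime: str
    mean_gray: float
    events: list[StimulusEvent]
    contrasts: list[float]
    n_trials: int
    flash_dur: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = 0.0
        for ev in self.events:
            if ev.duration <= 0:
                raise ValueError("event durations must be positive")
            if ev.onset < prev_end - 1e-12:
                raise ValueError("events overlap or are out of order")
            prev_end = ev.onset + ev.duration

    @property
    def duration(self) -> float:
        return self.events[-1].end if self.events else 0.0

    @property
    def cycle_duration(self) -> float:
        """One white+black flash cycle (s)."""
        return 2.0 * self.flash_dur

    def block_events(self, ct: float) -> list[StimulusEvent]:
        """Flash events of the block at contrast ``ct`` (white and black).

        Blocks are identified positionally: each ``baseline_gray`` event
        opens the next block in ``contrasts`` order, so the lookup is
        well defined even at CT0 where white and black luminances coincide.
        """
        if ct not in self.contrasts:
            raise KeyError(f"no contrast block at CT{ct}; protocol has {self.contrasts}")
        want = self.contrasts.index(ct)
        block = -1
        out = []
        for ev in self.events:
            if ev.tag == BASELINE_GRAY:
                block += 1
            elif ev.tag in (FLASH_WHITE, FLASH_BLACK) and block == want:
                out.append(ev)
        return out

    def trial_onsets(self, ct: float) -> list[float]:
        """Onsets of the white flashes (cycle starts) at contrast ``ct``."""
        return [ev.onset for ev in self.block_events(ct) if ev.tag == FLASH_WHITE]

    def spontaneous_window(self) -> tuple[float, float]:
        for ev in self.events:
            if ev.tag == SPONT_GRAY:
                return (ev.onset, ev.end)
        raise LookupError("protocol has no spontaneous gray segment")

    def block_window(self, ct: float) -> tuple[float, float]:
        """Half-open window spanning the flash train at contrast ``ct``."""
        evs = self.block_events(ct)
        return (evs[0].onset, evs[-1].end)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "regime": self.regime,
                "mean_gray": self.mean_gray,
                "contrasts": self.contrasts,
                "n_trials": self.n_trials,
                "flash_dur": self.flash_dur,
                "meta": self.meta,
                "events": [
                    [ev.onset, ev.duration, ev.luminance, ev.tag] for ev in self.events
                ],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        d = json.loads(text)
        return cls(
            regime=d["regime"],
            mean_gray=d["mean_gray"],
            events=[StimulusEvent(*row) for row in d["events"]],
            contrasts=list(d["contrasts"]),
            n_trials=d["n_trials"],
            flash_dur=d["flash_dur"],
            meta=d.get("meta", {}),
        )

    def trigger_times(self) -> list[float]:
        """Every luminance-change time (one trigger per event onset)."""
        return [ev.onset for ev in self.events]


def build_flash_protocol(
    regime: str = "mesopic",
    mean_gray: float | None = None,
    contrasts: Sequence[float] = (25.0, 50.0, 75.0, 100.0),
    n_trials: int = 20,
    flash_dur: float = 1.0,
    spont_dur: float = 300.0,
    baseline_dur: float = 60.0,
) -> StimulusProtocol:
    """Assemble the standard flash protocol.

    5 min of static mean gray (spontaneous activity), then per contrast a
    60 s gray baseline followed by ``n_trials`` alternating white/black
    flash pairs.  The per-block gray baseline doubles as the inter-block
    gray interval.  Blocks are emitted in the order ``contrasts`` is given
    (ascending CT by default).
    """
    if not contrasts:
        raise ValueError("at least one contrast block is required")
    if min(flash_dur, spont_dur, baseline_dur) <= 0:
        raise ValueError("all durations must be positive")
    if mean_gray is None:
        mean_gray = REGIME_LUMINANCE.get(regime, 0.5)

    events: list[StimulusEvent] = []
    t = 0.0
    events.append(StimulusEvent(t, spont_dur, mean_gray, SPONT_GRAY))
    t += spont_dur
    for ct in contrasts:
        pair = contrast_pair(mean_gray, ct)
        events.append(StimulusEvent(t, baseline_dur, mean_gray, BASELINE_GRAY))
        t += baseline_dur
        for _ in range(n_trials):
            events.append(StimulusEvent(t, flash_dur, pair.l_max, FLASH_WHITE))
            t += flash_dur
            events.append(StimulusEvent(t, flash_dur, pair.l_min, FLASH_BLACK))
            t += flash_dur
    return StimulusProtocol(
        regime=regime,
        mean_gray=mean_gray,
        events=events,
        contrasts=list(contrasts),
        n_trials=n_trials,
        flash_dur=flash_dur,
    )
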