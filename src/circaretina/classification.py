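"""Responsive-unit selection and ON / ON-OFF / OFF polarity calls.

Units pass two gates before being typed: a spontaneous-rate floor
(>= 0.1 spikes/s on the static gray segment) and a responsiveness test
comparing the inter-spike-interval distribution during gray versus during
the maximum-contrast flash train (two-sample Kolmogorov-Smirnov).

Polarity is then assigned by *greedy template matching*: the unit's
cumulative cycle distribution at maximum contrast is compared, in
sup-norm, against a small library of canonical response curves; the
nearest template's class wins in a single pass (no reassignment).  A unit
whose best distance strictly exceeds the rejection threshold theta is
left Not Assigned (NA).  Because the cumulative distribution is a
probability curve, the whole procedure is exactly invariant to spike-count
scaling.

The template library here is this package's own construction (built from
parametric sustained/transient PSTH kernels integrated to CDFs); its
curves and theta are configurable and serialized alongside results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spikes import (
    CDF_GRID,
    CumulativeCycleDistribution,
    RecordingSession,
    SpikeTrain,
    cumulative_cycle_distribution,
    epoch_spikes,
    isi_sample,
    mean_rate,
    pool_phases,
)

__all__ = [
    "ON", "ONOFF", "OFF", "NA",
    "Template", "TemplateLibrary", "PolarityCall",
    "default_templates", "classify_polarity", "classify_curves",
    "rate_floor_filter", "responsiveness_test", "classify_session",
]

ON = "ON"
ONOFF = "ONOFF"
OFF = "OFF"
NA = "NA"

_TAU = 0.08  # transient-burst decay constant (s)


@dataclass(frozen=True)
class Template:
    name: str
    cell_class: str  # ON | ONOFF | OFF
    values: np.ndarray  # CDF values on CDF_GRID


@dataclass
class TemplateLibrary:
    templates: list[Template]
    theta: float = 0.25  # sup-norm rejection threshold
    grid: np.ndarray = field(default_factory=lambda: CDF_GRID.copy())

    def __post_init__(self) -> None:
        classes = {t.cell_class for t in self.templates}
        if not {ON, ONOFF, OFF} <= classes:
            raise ValueError("library needs at least one template per class")

    def matrix(self) -> np.ndarray:
        return np.vstack([t.values for t in self.templates])

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta": self.theta,
                "grid": self.grid.tolist(),
                "templates": [
                    {"name": t.name, "class": t.cell_class, "values": t.values.tolist()}
                    for t in self.templates
                ],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TemplateLibrary":
        d = json.loads(text)
        return cls(
            templates=[
                Template(t["name"], t["class"], np.asarray(t["values"]))
                for t in d["templates"]
            ],
            theta=d["theta"],
            grid=np.asarray(d["grid"]),
        )


@dataclass(frozen=True)
class PolarityCall:
    unit_id: str
    label: str  # ON | ONOFF | OFF | NA
    best_template: str
    distance: float


# --- template construction -----------------------------------------------

def _burst_cdf(t: np.ndarray, onset: float, tau: float = _TAU) -> np.ndarray:
    """CDF of an exponential burst confined to the 1 s half starting at onset."""
    x = np.clip(t - onset, 0.0, 1.0)
    return (1.0 - np.exp(-x / tau)) / (1.0 - np.exp(-1.0 / tau))


def default_templates(theta: float = 0.25) -> TemplateLibrary:
    """Eight canonical cumulative response curves.

    Sustained kernels put uniform spike mass on their preferred half,
    transient kernels an exponential burst (tau = 80 ms) at their
    preferred flash onset; ON-OFF templates mix the two onset bursts.
    """
    t = CDF_GRID
    on_burst = _burst_cdf(t, 0.0)
    off_burst = _burst_cdf(t, 1.0)
    specs = [
        ("on_sustained", ON, np.clip(t, 0.0, 1.0)),
        ("on_transient", ON, on_burst),
        ("on_delayed_sustained", ON, np.clip((t - 0.2) / 0.8, 0.0, 1.0)),
        ("off_sustained", OFF, np.clip(t - 1.0, 0.0, 1.0)),
        ("off_transient", OFF, off_burst),
        ("onoff_symmetric", ONOFF, 0.5 * on_burst + 0.5 * off_burst),
        ("onoff_70_30", ONOFF, 0.7 * on_burst + 0.3 * off_burst),
        ("onoff_30_70", ONOFF, 0.3 * on_burst + 0.7 * off_burst),
    ]
    return TemplateLibrary(
        [Template(name, cls, vals) for name, cls, vals in specs], theta=theta
    )


# --- matching -------------------------------------------------------------

def _on_grid(curve: CumulativeCycleDistribution, grid: np.ndarray) -> np.ndarray:
    if curve.grid.shape == grid.shape and np.allclose(curve.grid, grid):
        return curve.values
    return np.interp(grid, curve.grid, curve.values, left=0.0)


def classify_polarity(
    curve: CumulativeCycleDistribution,
    library: TemplateLibrary,
    unit_id: str = "",
    metric: str = "sup",
) -> PolarityCall:
    """Nearest-template polarity call (greedy, single pass).

    Distance is the sup-norm between CDFs (scale-free on probability
    curves); ``metric="l2"`` uses the RMS distance instead.  Ties go to
    the earlier template in library order; a best distance strictly above
    theta yields NA.
    """
    vals = _on_grid(curve, library.grid)
    diffs = library.matrix() - vals[None, :]
    if metric == "sup":
        d = np.max(np.abs(diffs), axis=1)
    elif metric == "l2":
        d = np.sqrt(np.mean(diffs**2, axis=1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    best = int(np.argmin(d))  # argmin takes the first minimum: library-order ties
    dist = float(d[best])
    tmpl = library.templates[best]
    label = NA if dist > library.theta else tmpl.cell_class
    return PolarityCall(unit_id, label, tmpl.name, dist)


def classify_curves(curves: np.ndarray, library: TemplateLibrary) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized sup-norm matching of many CDF rows; returns (labels, distances)."""
    d = np.max(np.abs(curves[:, None, :] - library.matrix()[None, :, :]), axis=2)
    best = np.argmin(d, axis=1)
    dist = d[np.arange(len(curves)), best]
    classes = np.array([t.cell_class for t in library.templates])
    labels = classes[best].astype(object)
    labels[dist > library.theta] = NA
    return labels, dist


# --- unit selection -------------------------------------------------------

def rate_floor_filter(
    session: RecordingSession, min_rate: float = 0.1
) -> list[SpikeTrain]:
    """Units firing at least ``min_rate`` spikes/s on the spontaneous gray
    segment (inclusive threshold)."""
    window = session.protocol.spontaneous_window()
    return [u for u in session.units if mean_rate(u, window=window) >= min_rate]


def responsiveness_test(
    isi_gray: np.ndarray, isi_flash: np.ndarray, alpha: float = 0.05
) -> tuple[bool, float, float]:
    """Two-sample KS test between gray-screen and flash-train ISI samples.

    Returns ``(keep, D, p)`` with ``keep = (p <= alpha)``: a unit is kept
    only when its firing statistics change significantly under maximum
    contrast stimulation.
    """
    if len(isi_gray) < 2 or len(isi_flash) < 2:
        raise ValueError("need at least two ISIs per sample")
    res = stats.ks_2samp(isi_gray, isi_flash, alternative="two-sided")
    return bool(res.pvalue <= alpha), float(res.statistic), float(res.pvalue)


def classify_session(
    session: RecordingSession,
    library: TemplateLibrary | None = None,
    ct: float = 100.0,
    min_rate: float = 0.1,
    alpha: float = 0.05,
) -> list[dict]:
    """Run the full selection + typing chain on one session.

    Order is enforced: rate floor, then responsiveness (gray vs CT-max
    ISIs), then template matching on the cumulative cycle distribution at
    maximum contrast.  Every unit appears in the output with its drop
    reason or its polarity call.
    """
    if library is None:
        library = default_templates()
    spont = session.protocol.spontaneous_window()
    block = session.protocol.block_window(ct)
    kept = {u.unit_id for u in rate_floor_filter(session, min_rate)}
    rows = []
    for u in session.units:
        row = {
            "unit_id": u.unit_id,
            "retina_id": session.retina_id,
            "genotype": session.genotype,
            "zt": session.zt,
            "regime": session.regime,
            "label": NA,
            "template": "",
            "distance": np.nan,
            "drop_reason": "",
        }
        if u.unit_id not in kept:
            row["drop_reason"] = "rate_floor"
            rows.append(row)
            continue
        g = u.times[(u.times >= spont[0]) & (u.times < spont[1])]
        f = u.times[(u.times >= block[0]) & (u.times < block[1])]
        if g.size < 2 or f.size < 2:
            row["drop_reason"] = "insufficient_isis"
            rows.append(row)
            continue
        keep, _, _ = responsiveness_test(np.diff(g), np.diff(f), alpha)
        if not keep:
            row["drop_reason"] = "unresponsive"
            rows.append(row)
            continue
        phases = pool_phases(epoch_spikes(u, session.protocol, ct))
        if phases.size == 0:
            row["drop_reason"] = "no_cycle_spikes"
            rows.append(row)
            continue
        call = classify_polarity(
            cumulative_cycle_distribution(phases), library, unit_id=u.unit_id
        )
        row.update(label=call.label, template=call.best_template, distance=call.distance)
        rows.append(row)
    return rows
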