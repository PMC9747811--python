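"""Readers and writers for the pipeline's plain-text interchange formats.

Spike input is a two-column table (unit_id, spike_time_s) plus a JSON
session descriptor carrying genotype, ZT, regime, retina id and the
serialized stimulus protocol.  ERG traces travel as (time_s, voltage_uV)
CSV.  Expression tables and all tabular outputs are ordinary CSV handled
directly with pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .erg import ERGTrace
from .spikes import RecordingSession, SpikeTrain
from .stimulus import StimulusProtocol

__all__ = [
    "write_session",
    "read_session",
    "write_erg_trace",
    "read_erg_trace",
]


def write_session(session: RecordingSession, spikes_path, meta_path) -> None:
    """Write a session as a spike table (CSV) and a JSON descriptor."""
    rows = [
        {"unit_id": u.unit_id, "spike_time_s": t}
        for u in session.units
        for t in u.times
    ]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(
        spikes_path, index=False
    )
    meta = {
        "genotype": session.genotype,
        "zt": session.zt,
        "regime": session.regime,
        "retina_id": session.retina_id,
        "unit_ids": [u.unit_id for u in session.units],
        "protocol": json.loads(session.protocol.to_json()),
    }
    Path(meta_path).write_text(json.dumps(meta, sort_keys=True))


def read_session(spikes_path, meta_path) -> RecordingSession:
    """Inverse of :func:`write_session`; empty units are preserved via the
    descriptor's unit list."""
    meta = json.loads(Path(meta_path).read_text())
    table = pd.read_csv(spikes_path)
    by_unit = {
        uid: np.sort(sub["spike_time_s"].to_numpy(float))
        for uid, sub in table.groupby("unit_id")
    }
    units = [
        SpikeTrain(uid, by_unit.get(uid, np.empty(0)))
        for uid in meta["unit_ids"]
    ]
    return RecordingSession(
        genotype=meta["genotype"],
        zt=meta["zt"],
        regime=meta["regime"],
        retina_id=meta["retina_id"],
        protocol=StimulusProtocol.from_json(json.dumps(meta["protocol"])),
        units=units,
    )


def write_erg_trace(trace: ERGTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.times(), "voltage_uV": trace.voltages}
    ).to_csv(path, index=False)


def read_erg_trace(path, pre_trial: float = 0.05, **kwargs) -> ERGTrace:
    """Load a (time_s, voltage_uV) CSV; the sampling rate is inferred from
    the time column, which must be uniform."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time axis must be uniformly sampled")
    return ERGTrace(
        sampling_rate=1.0 / dt[0],
        voltages=df["voltage_uV"].to_numpy(float),
        pre_trial=pre_trial,
        **kwargs,
    )
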