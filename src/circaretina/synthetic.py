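"""Ground-truth generators for every input the pipeline consumes.

Spike trains
    Each unit is an inhomogeneous Poisson process: a homogeneous
    spontaneous baseline over the whole protocol plus, per flash trial,
    an evoked component whose shape depends on the unit's kinetic class
    (sustained = uniform rate over the preferred 1 s half; transient =
    exponential burst at the preferred flash onset; ON-OFF = bursts at
    both onsets).  Evoked strength scales with contrast through a
    Naka-Rushton term cr(CT) = CT/(CT + c50) and with an injectable
    (genotype, ZT) gain factor that serves as recoverable ground truth.
    Both components are drawn exactly (Poisson counts + inverse-CDF
    event times), not via time discretization.

Gene expression
    Cosine-structured relative expression with 24 h period, Gaussian
    replicate noise, and an optional genotype acrophase shift.

ERG waveforms
    A negative a-deflection and positive b-deflection built from
    compactly supported raised-cosine kernels with disjoint supports and
    peak samples on the sampling grid, so the amplitude extractors
    recover the generator parameters exactly at zero noise.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .erg import ERGTrace
from .spikes import RecordingSession, SpikeTrain
from .stimulus import StimulusProtocol, build_flash_protocol

__all__ = [
    "RgcKineticModel",
    "EffectTable",
    "DEFAULT_MODELS",
    "study_effects",
    "contrast_response",
    "simulate_unit",
    "simulate_session",
    "simulate_expression",
    "simulate_erg",
    "default_cohort",
]

CLASS_POLARITY = {
    "ON_sust": "ON",
    "ON_trans": "ON",
    "OFF_sust": "OFF",
    "OFF_trans": "OFF",
    "ONOFF": "ONOFF",
}


@dataclass(frozen=True)
class RgcKineticModel:
    """Generative kinetics of one RGC class.

    ``peak_gain`` is the evoked rate scale (spikes/s) at full drive;
    sustained classes hold it across the preferred half, transient
    classes decay from it with time constant ``decay_tau``.  Defaults
    (baseline 0.5 sp/s; sustained 25, transient 120, ON-OFF burst 100
    sp/s) give realistic mesopic spike counts of roughly 100-400 evoked
    spikes per 20-trial block at full contrast.
    """

    cell_class: str
    baseline_rate: float = 0.5
    peak_gain: float = 25.0
    decay_tau: float = 0.08
    latency: float = 0.0
    contrast_semisaturation: float = 30.0

    def __post_init__(self) -> None:
        if self.cell_class not in CLASS_POLARITY:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.baseline_rate < 0 or self.peak_gain < 0:
            raise ValueError("rates must be non-negative")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")

    @property
    def polarity(self) -> str:
        return CLASS_POLARITY[self.cell_class]


DEFAULT_MODELS: dict[str, RgcKineticModel] = {
    "ON_sust": RgcKineticModel("ON_sust", peak_gain=25.0),
    "ON_trans": RgcKineticModel("ON_trans", peak_gain=120.0),
    "OFF_sust": RgcKineticModel("OFF_sust", peak_gain=25.0),
    "OFF_trans": RgcKineticModel("OFF_trans", peak_gain=120.0),
    "ONOFF": RgcKineticModel("ONOFF", peak_gain=100.0),
}

#: Default per-retina class counts, a scaled-down version of the study's
#: average population (241 ON / 97 OFF / 194 ON-OFF) that keeps the
#: full cohort runnable in minutes on one CPU.
DEFAULT_COUNTS: dict[str, int] = {
    "ON_sust": 25,
    "ON_trans": 25,
    "OFF_sust": 10,
    "OFF_trans": 10,
    "ONOFF": 40,
}


@dataclass
class EffectTable:
    """Injectable ground-truth effects.

    ``peak_gain_factor`` multiplies every unit's evoked gain for a
    (genotype, zt) cell; ``switch_prob`` gives the probability that a
    unit of a class is generated with ON-OFF kinetics instead (modelling
    luminance-dependent polarity switching), keyed by
    (cell_class, genotype, zt, regime).
    """

    peak_gain_factor: dict[tuple[str, int], float] = field(default_factory=dict)
    switch_prob: dict[tuple[str, str, int, str], float] = field(default_factory=dict)

    def gain(self, genotype: str, zt: int) -> float:
        f = self.peak_gain_factor.get((genotype, zt), 1.0)
        if f <= 0:
            raise ValueError("gain factors must be positive")
        return f

    def p_switch(self, cell_class: str, genotype: str, zt: int, regime: str) -> float:
        p = self.switch_prob.get((cell_class, genotype, zt, regime), 0.0)
        if not 0.0 <= p <= 1.0:
            raise ValueError("switch probabilities must lie in [0, 1]")
        return p


def study_effects() -> EffectTable:
    """Default effect table encoding the study's qualitative findings as
    recoverable ground truth: knockout evoked gain x1.5 at ZT18, and an
    elevated OFF->ON-OFF switch probability in the photopic knockout at
    ZT0."""
    return EffectTable(
        peak_gain_factor={("cKO", 18): 1.5},
        switch_prob={
            ("OFF_sust", "cKO", 0, "photopic"): 0.5,
            ("OFF_trans", "cKO", 0, "photopic"): 0.5,
            ("OFF_sust", "Ctrl", 0, "photopic"): 0.2,
            ("OFF_trans", "Ctrl", 0, "photopic"): 0.2,
        },
    )


def contrast_response(ct: float, c50: float = 30.0) -> float:
    """Naka-Rushton contrast drive cr = CT / (CT + c50), in [0, 1)."""
    return ct / (ct + c50)


def _truncated_exp(rng: np.random.Generator, tau: float, n: int, hi: float) -> np.ndarray:
    """Samples from Exp(tau) truncated to [0, hi] by inverse CDF."""
    u = rng.random(n)
    cap = 1.0 - np.exp(-hi / tau)
    return -tau * np.log1p(-u * cap)


def _evoked_per_cycle(model: RgcKineticModel, drive: float) -> tuple[float, float]:
    """Expected evoked counts per cycle at the (ON-half, OFF-half) onsets."""
    g = model.peak_gain * drive
    if model.cell_class == "ON_sust":
        return g * 1.0, 0.0
    if model.cell_class == "OFF_sust":
        return 0.0, g * 1.0
    burst = g * model.decay_tau * (1.0 - np.exp(-1.0 / model.decay_tau))
    if model.cell_class == "ON_trans":
        return burst, 0.0
    if model.cell_class == "OFF_trans":
        return 0.0, burst
    return burst, burst  # ONOFF


def simulate_unit(
    model: RgcKineticModel,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
    gain_factor: float = 1.0,
    refractory: float = 0.0,
) -> np.ndarray:
    """Draw one unit's spike times over the whole protocol.

    The spontaneous baseline is a homogeneous Poisson process over the
    full protocol; evoked spikes are added per flash cycle (exact Poisson
    superposition).  ``refractory`` > 0 applies an absolute dead time by
    thinning (off by default: Poisson suffices for every property the
    pipeline tests).
    """
    dur = protocol.duration
    spikes = [rng.uniform(0.0, dur, rng.poisson(model.baseline_rate * dur))]
    for ct in protocol.contrasts:
        drive = contrast_response(ct, model.contrast_semisaturation) * gain_factor
        mu_on, mu_off = _evoked_per_cycle(model, drive)
        onsets = np.asarray(protocol.trial_onsets(ct))
        half = protocol.flash_dur
        for mu, offset in ((mu_on, 0.0), (mu_off, half)):
            if mu <= 0:
                continue
            counts = rng.poisson(mu, onsets.size)
            total = int(counts.sum())
            if total == 0:
                continue
            if model.cell_class in ("ON_sust", "OFF_sust"):
                rel = rng.uniform(0.0, half, total)
            else:
                rel = _truncated_exp(rng, model.decay_tau, total, half)
            base = np.repeat(onsets + offset + model.latency, counts)
            spikes.append(np.clip(base + rel, 0.0, np.nextafter(dur, 0.0)))
    times = np.unique(np.concatenate(spikes))
    if refractory > 0 and times.size:
        keep = [0]
        for i in range(1, times.size):
            if times[i] - times[keep[-1]] >= refractory:
                keep.append(i)
        times = times[keep]
    return times


def simulate_session(
    counts: dict[str, int] | None = None,
    effects: EffectTable | None = None,
    protocol: StimulusProtocol | None = None,
    genotype: str = "Ctrl",
    zt: int = 0,
    regime: str = "mesopic",
    retina_id: str = "retina0",
    seed: int = 0,
    models: dict[str, RgcKineticModel] | None = None,
) -> tuple[RecordingSession, pd.DataFrame]:
    """Simulate one retina's recording; returns (session, ground truth).

    The ground-truth table has one row per unit with its generative class
    (after any injected polarity switch) and true polarity.
    """
    counts = DEFAULT_COUNTS if counts is None else counts
    effects = effects or EffectTable()
    models = models or DEFAULT_MODELS
    if protocol is None:
        protocol = build_flash_protocol(regime=regime)
    if any(n <= 0 for n in counts.values()):
        raise ValueError("unit counts must be positive")
    rng = np.random.default_rng(seed)
    gain = effects.gain(genotype, zt)
    units, truth = [], []
    i = 0
    for cls in sorted(counts):
        model = models[cls]
        for _ in range(counts[cls]):
            gen_cls = cls
            if rng.random() < effects.p_switch(cls, genotype, zt, regime):
                gen_cls = "ONOFF"
            gen_model = models[gen_cls]
            # switched units keep their own baseline but adopt ON-OFF kinetics
            gen_model = replace(gen_model, baseline_rate=model.baseline_rate)
            times = simulate_unit(gen_model, protocol, rng, gain_factor=gain)
            uid = f"{retina_id}_u{i:04d}"
            units.append(SpikeTrain(uid, times))
            truth.append(
                {
                    "unit_id": uid,
                    "source_class": cls,
                    "generated_class": gen_cls,
                    "true_polarity": CLASS_POLARITY[gen_cls],
                    "gain_factor": gain,
                }
            )
            i += 1
    session = RecordingSession(
        genotype=genotype,
        zt=zt,
        regime=regime,
        retina_id=retina_id,
        protocol=protocol,
        units=units,
        meta={"seed": seed},
    )
    return session, pd.DataFrame(truth)


def simulate_expression(
    gene: str = "Bmal1",
    baseline: float = 1.0,
    amplitude: float = 0.4,
    acrophase: float = 6.0,
    sigma: float = 0.08,
    n_per_zt: int = 6,
    genotype: str = "Ctrl",
    genotype_shift_h: float = 0.0,
    zts: tuple[int, ...] = (0, 6, 12, 18),
    seed: int = 0,
) -> pd.DataFrame:
    """Cosine-structured relative-expression replicates at each ZT.

    value = baseline + amplitude*cos(2*pi*(t - acrophase')/24) + N(0, sigma),
    with acrophase' = acrophase + genotype_shift_h (the injectable phase
    effect; a knockout phase advance is a negative shift).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    phase = acrophase + genotype_shift_h
    rows = []
    for zt in zts:
        mu = baseline + amplitude * np.cos(2.0 * np.pi * (zt - phase) / 24.0)
        vals = mu + rng.normal(0.0, sigma, n_per_zt) if sigma > 0 else np.full(n_per_zt, mu)
        for r, v in enumerate(vals):
            rows.append(
                {
                    "gene": gene,
                    "genotype": genotype,
                    "zt": zt,
                    "replicate": r,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


def expression_to_ct(
    expression: pd.DataFrame, ct_housekeeping: float = 18.0, ct_ref: float = 24.0
) -> pd.DataFrame:
    """Re-express fold values as synthetic (target, housekeeping) Ct pairs
    such that the delta-delta-Ct method recovers them (fold = 2^-ddCt)."""
    df = expression.copy()
    df["ct_housekeeping"] = ct_housekeeping
    df["ct_target"] = ct_housekeeping + (ct_ref - ct_housekeeping) - np.log2(df["value"])
    return df


def _raised_cosine(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Unimodal kernel with compact support [center +- half_width], peak 1."""
    x = (t - center) / half_width
    out = np.zeros_like(t)
    inside = np.abs(x) < 1.0
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * x[inside]))
    return out


def simulate_erg(
    a_amp: float = 150.0,
    b_amp: float = 300.0,
    a_latency: float = 0.015,
    b_latency: float = 0.06,
    noise_sd: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 16300.0,
    pre_trial: float = 0.05,
    duration: float = 0.5,
    baseline_uv: float = 0.0,
    condition: str = "photopic",
) -> ERGTrace:
    """Synthetic flash-ERG trace with known a-/b-wave amplitudes.

    The a-deflection and b-deflection are disjoint raised-cosine kernels
    whose peaks are snapped to the sampling grid; the b kernel's height
    is ``b_amp - a_amp`` so that trough-to-peak extraction returns
    exactly ``b_amp`` (and baseline-to-trough exactly ``a_amp``) at zero
    noise.  Requires ``b_amp >= a_amp >= 0``.
    """
    if a_amp < 0 or b_amp < 0:
        raise ValueError("amplitudes must be non-negative")
    if 0 < b_amp < a_amp:
        raise ValueError("b_amp must be >= a_amp for a trough-to-peak waveform")
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate - pre_trial  # 0 at stimulus onset
    snap = lambda x: round(x * sampling_rate) / sampling_rate

    a_c, b_c = snap(a_latency), snap(b_latency)
    a_w = min(0.010, (b_c - a_c) / 2.0 - 1.0 / sampling_rate)
    b_w = min(0.030, (b_c - a_c) - a_w - 1.0 / sampling_rate)
    v = np.full(n, baseline_uv)
    if a_amp > 0:
        v -= a_amp * _raised_cosine(t, a_c, a_w)
    if b_amp > 0:
        v += (b_amp - a_amp) * _raised_cosine(t, b_c, b_w)
    if noise_sd > 0:
        # band-limited noise (~1 ms correlation), as the recording chain's
        # 0.2-5000 Hz band implies; broadband white noise would bias any
        # extremum-based amplitude reading upward by sigma*sqrt(2 ln n)
        white = np.random.default_rng(seed).normal(0.0, 1.0, n)
        smooth = gaussian_filter1d(white, sigma=0.001 * sampling_rate)
        v = v + noise_sd * smooth / smooth.std()
    return ERGTrace(
        sampling_rate=sampling_rate,
        voltages=v,
        pre_trial=pre_trial,
        condition=condition,
        meta={"true_a": a_amp, "true_b": b_amp},
    )


def default_cohort(
    seed: int = 0,
    n_retinae_per_group: int = 2,
    counts: dict[str, int] | None = None,
    effects: EffectTable | None = None,
    genotypes: tuple[str, ...] = ("Ctrl", "cKO"),
    zts: tuple[int, ...] = (0, 6, 12, 18),
    regimes: tuple[str, ...] = ("mesopic", "photopic"),
    protocol_kwargs: dict | None = None,
) -> tuple[list[RecordingSession], pd.DataFrame]:
    """The study grid: genotype x ZT x regime x retina, deterministic per seed.

    The same retina (same unit identities and generative classes) is
    recorded in both regimes, which is what makes the cross-regime
    polarity-maintenance analysis possible.
    """
    effects = effects if effects is not None else study_effects()
    protocol_kwargs = protocol_kwargs or {}
    protocols = {r: build_flash_protocol(regime=r, **protocol_kwargs) for r in regimes}
    ss = np.random.SeedSequence(seed)
    sessions, truths = [], []
    for g in genotypes:
        for zt in zts:
            for r_idx in range(n_retinae_per_group):
                retina_id = f"{g}_zt{zt}_r{r_idx}"
                child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                for regime in regimes:
                    # same retina, different regime: offset the seed deterministically
                    s = child_seed if regime == "mesopic" else child_seed + 1
                    sess, truth = simulate_session(
                        counts=counts,
                        effects=effects,
                        protocol=protocols[regime],
                        genotype=g,
                        zt=zt,
                        regime=regime,
                        retina_id=retina_id,
                        seed=s,
                    )
                    truth["regime"] = regime
                    truth["retina_id"] = retina_id
                    truth["genotype"] = g
                    truth["zt"] = zt
                    sessions.append(sess)
                    truths.append(truth)
    return sessions, pd.concat(truths, ignore_index=True)
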