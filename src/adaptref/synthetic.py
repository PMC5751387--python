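"""Seeded generators of EEG-like records with known ground truth.

Every stage of the package is exercised on synthetic records with the
statistical structure the filters assume:

* **common-mode interference** — a waveform broadcast to all channels with the
  same phase and per-channel gains (power-line tone, EOG-like blink train,
  slow drift, pink noise);
* **spatially localized narrowband activity** — SSVEP fundamentals plus
  harmonics on occipital channels, or a slow movement-related ramp and a
  mu-band (8-12 Hz) power change on central channels;
* **channel-specific broadband noise** — independent Gaussian (optionally
  1/f-shaped) noise per channel;
* **artifact bursts** — rare high-amplitude events on a single electrode.

Random streams are split per component from the master seed, so adding or
removing a component never perturbs the samples the others draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Record

__all__ = [
    "Component",
    "Burst",
    "SyntheticSpec",
    "gen_record",
    "gen_ssvep",
    "gen_gait_epochs",
    "GaitEpoch",
    "GaitGroundTruth",
]


@dataclass
class Component:
    """One additive signal component.

    ``kind`` is one of ``sine`` (needs ``freq``), ``drift`` (slow random
    walk low-passed below ~0.5 Hz), ``eog_blink`` (raised-cosine pulses of
    200-400 ms at ``rate_hz``), or ``pink_noise``.  ``gains`` maps channel
    label -> gain; a scalar applies to every channel (common mode); channels
    absent from a gain map receive 0 (localized component).
    """

    kind: str
    amplitude: float
    freq: float | None = None
    gains: float | dict[str, float] = 1.0
    phase: float = 0.0
    rate_hz: float = 0.25  # blinks per second for eog_blink

    def gain_vector(self, channels: list[str]) -> np.ndarray:
        if isinstance(self.gains, dict):
            return np.array([float(self.gains.get(c, 0.0)) for c in channels])
        return np.full(len(channels), float(self.gains))


@dataclass
class Burst:
    """A rare high-amplitude artifact on a single electrode."""

    channel: str
    onset_s: float
    duration_s: float
    gain: float  # multiplies the channel's noise sigma


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic multichannel record."""

    channels: list[str]
    fs: float = 250.0
    duration_s: float = 6.0
    components: list[Component] = field(default_factory=list)
    noise_sigma: float | dict[str, float] = 1.0
    bursts: list[Burst] = field(default_factory=list)
    seed: int | None = 0

    def __post_init__(self) -> None:
        for c in self.components:
            if c.amplitude < 0:
                raise ValueError("component amplitudes must be nonnegative")
            if c.kind == "sine":
                if c.freq is None:
                    raise ValueError("sine component needs a frequency")
                if self.fs <= 2 * c.freq:
                    raise ValueError(
                        f"fs={self.fs} too low for a {c.freq} Hz component"
                    )

    def noise_vector(self) -> np.ndarray:
        if isinstance(self.noise_sigma, dict):
            return np.array([float(self.noise_sigma.get(c, 0.0)) for c in self.channels])
        return np.full(len(self.channels), float(self.noise_sigma))


_NOISE_STREAM = 1_000_000
_BURST_STREAM = 1_000_001


def _rng_for(seed, comp_index: int) -> np.random.Generator:
    # per-component stream: reproducible composition
    ss = np.random.SeedSequence(0 if seed is None else seed, spawn_key=(comp_index,))
    return np.random.default_rng(ss)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    X /= np.sqrt(f)
    x = np.fft.irfft(X, n)
    return x / x.std()


def _blink_train(rng: np.random.Generator, n: int, fs: float, rate_hz: float) -> np.ndarray:
    out = np.zeros(n)
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_hz) if rate_hz > 0 else np.inf
        start = int(t * fs)
        if start >= n:
            break
        dur = int(rng.uniform(0.2, 0.4) * fs)  # 200-400 ms raised cosine
        end = min(start + dur, n)
        k = np.arange(end - start)
        out[start:end] += 0.5 * (1 - np.cos(2 * np.pi * k / max(dur - 1, 1)))
    return out


def _pop_wave(rng: np.random.Generator, m: int) -> np.ndarray:
    """Electrode-pop waveform: a sustained unit-scale deflection.

    Sharp raised-cosine edges (2 % of the duration each side) around a hold
    at 1, with a +/-10 % slow wander, mimicking a popped electrode or cable
    tug — a large sustained offset with abrupt onset rather than zero-mean
    scatter.
    """
    if m <= 0:
        return np.zeros(0)
    env = np.ones(m)
    ramp = max(int(0.02 * m), 1)
    k = np.arange(ramp)
    env[:ramp] = 0.5 * (1 - np.cos(np.pi * (k + 1) / ramp))
    env[m - ramp :] = env[:ramp][::-1]
    wander = np.cumsum(rng.standard_normal(m))
    sd = wander.std()
    if sd > 0:
        wander = 0.1 * wander / sd
    return env * (1.0 + wander)


def _component_waveform(c: Component, rng, n: int, fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    if c.kind == "sine":
        return c.amplitude * np.sin(2 * np.pi * c.freq * t + c.phase)
    if c.kind == "pink_noise":
        return c.amplitude * _pink_noise(rng, n)
    if c.kind == "drift":
        # integrated noise low-passed below ~0.5 Hz: EOG-band drift
        walk = np.cumsum(rng.standard_normal(n))
        X = np.fft.rfft(walk)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        X[f > 0.5] = 0.0
        x = np.fft.irfft(X, n)
        sd = x.std()
        return c.amplitude * (x / sd if sd > 0 else x)
    if c.kind == "eog_blink":
        return c.amplitude * _blink_train(rng, n, fs, c.rate_hz)
    raise ValueError(f"unknown component kind {c.kind!r}")


def gen_record(spec: SyntheticSpec) -> tuple[Record, list[dict]]:
    """Render a spec into a record plus a ground-truth component table.

    Deterministic per seed; every component and the noise draw from their own
    substream of the master seed.
    """
    n = int(round(spec.duration_s * spec.fs))
    data = np.zeros((len(spec.channels), n))
    truth: list[dict] = []
    for idx, comp in enumerate(spec.components):
        rng = _rng_for(spec.seed, idx)
        wave = _component_waveform(comp, rng, n, spec.fs)
        g = comp.gain_vector(spec.channels)
        data += g[:, None] * wave[None, :]
        truth.append(
            {"kind": comp.kind, "freq": comp.freq, "amplitude": comp.amplitude,
             "gains": {c: float(gv) for c, gv in zip(spec.channels, g) if gv != 0.0}}
        )
    # noise and bursts draw from fixed stream keys so that adding or
    # removing a component never perturbs their samples
    sig = spec.noise_vector()
    rng = _rng_for(spec.seed, _NOISE_STREAM)
    noise = rng.standard_normal(data.shape) * sig[:, None]
    data += noise
    for b_idx, b in enumerate(spec.bursts):
        rng = _rng_for(spec.seed, _BURST_STREAM + b_idx)
        ci = spec.channels.index(b.channel)
        s0 = int(round(b.onset_s * spec.fs))
        s1 = min(s0 + int(round(b.duration_s * spec.fs)), n)
        sigma = sig[ci] if sig[ci] > 0 else 1.0
        data[ci, s0:s1] += b.gain * sigma * _pop_wave(rng, s1 - s0)
        truth.append(
            {"kind": "burst", "channel": b.channel, "onset_s": b.onset_s,
             "duration_s": b.duration_s, "gain": b.gain,
             "span": (s0, s1)}
        )
    return Record(data, list(spec.channels), spec.fs, {"seed": spec.seed}), truth


# --------------------------------------------------------------------------
# SSVEP-like records
# --------------------------------------------------------------------------

#: the 40-target SSVEP frequency grid: 8-15.8 Hz in 0.2 Hz steps
SSVEP_TARGET_FREQS = tuple(np.round(np.arange(8.0, 15.81, 0.2), 1))

#: occipital gain profile of the SSVEP component: strongest at the occipital
#: pole, decaying toward parietal sites (volume-conduction-like spread)
_SSVEP_GAINS = {
    "Oz": 1.0, "O1": 0.8, "O2": 0.8,
    "POz": 0.5, "PO3": 0.4, "PO4": 0.4, "PO7": 0.35, "PO8": 0.35,
    "P1": 0.2, "P2": 0.2, "P3": 0.15, "P4": 0.15, "Pz": 0.2,
}


def gen_ssvep(
    stim_freq: float,
    channels: list[str] | None = None,
    fs: float = 250.0,
    duration_s: float = 6.0,
    ssvep_amplitude: float = 2.0,
    n_harmonics: int = 3,
    line_freq: float = 50.0,
    line_amplitude: float = 4.0,
    common_pink_amplitude: float = 3.0,
    eog_amplitude: float = 15.0,
    noise_sigma: float = 2.0,
    bursts: list[Burst] | None = None,
    seed: int | None = 0,
) -> tuple[Record, list[dict]]:
    """SSVEP-like record: occipital flicker response + common interference.

    The stimulus component appears at ``stim_freq`` and its harmonics with
    amplitudes decaying as 1/h, spread over the occipito-parietal channels
    with the largest gain at Oz; the power-line tone, an EOG-like blink
    train, and pink noise are common to all channels; independent Gaussian
    noise is per channel.  Defaults emulate a 6 s trial at 250 Hz with
    stimulus amplitudes a few microvolts against a ~2 uV noise floor.
    """
    channels = list(channels or _SSVEP_GAINS)
    comps = [
        Component("sine", line_amplitude, freq=line_freq, gains=1.0),
        Component("pink_noise", common_pink_amplitude, gains=1.0),
        Component("eog_blink", eog_amplitude, gains=0.3, rate_hz=0.2),
    ]
    for h in range(1, n_harmonics + 1):
        f = stim_freq * h
        if f >= fs / 2:
            break
        comps.append(
            Component("sine", ssvep_amplitude / h, freq=f, gains=dict(_SSVEP_GAINS),
                      phase=0.3 * h)
        )
    spec = SyntheticSpec(
        channels=channels, fs=fs, duration_s=duration_s, components=comps,
        noise_sigma=noise_sigma, bursts=list(bursts or []), seed=seed,
    )
    rec, truth = gen_record(spec)
    rec.meta["stim_freq"] = stim_freq
    return rec, truth


# --------------------------------------------------------------------------
# Gait-planning-like epochs
# --------------------------------------------------------------------------

#: gain profile of the movement-related slow ramp over the motor strip
_MRCP_GAINS = {"Cz": 1.0, "CP1": 0.85, "CP2": 0.85, "CPz": 0.8, "C1": 0.7,
               "C2": 0.7, "FCz": 0.5, "CP3": 0.5, "CP4": 0.5, "C3": 0.4,
               "C4": 0.4, "FC1": 0.3, "FC3": 0.2, "FC2": 0.3, "FC4": 0.2,
               "C5": 0.15, "C6": 0.15, "CP5": 0.3, "CP6": 0.3, "Pz": 0.4}

#: gain profile of the mu rhythm (8-12 Hz) over the same strip
_MU_GAINS = _MRCP_GAINS


@dataclass
class GaitEpoch:
    """One labeled epoch: planning (1) or rest (0), with its session."""

    record: Record
    label: int
    session: int


@dataclass
class GaitGroundTruth:
    """Effect sizes planted in a gait-epoch set."""

    mrcp_amplitude: float
    mu_erd: float
    mu_amplitude: float
    noise_sigma: float
    fs: float
    channels: list[str]


def _gait_epoch_spec(
    channels, fs, duration_s, label, mrcp_amplitude, mu_erd, mu_amplitude,
    noise_sigma, eog_amplitude, line_amplitude, seed,
) -> SyntheticSpec:
    comps = [
        Component("sine", line_amplitude, freq=60.0, gains=1.0),
        Component("pink_noise", noise_sigma, gains=1.0),
        Component("eog_blink", eog_amplitude, gains=0.25, rate_hz=0.2),
        Component("drift", 0.5 * eog_amplitude, gains=0.25),
    ]
    mu_amp = mu_amplitude * (1.0 - mu_erd) if label == 1 else mu_amplitude
    if mu_amp > 0:
        comps.append(Component("sine", mu_amp, freq=10.0, gains=dict(_MU_GAINS)))
    spec = SyntheticSpec(
        channels=list(channels), fs=fs, duration_s=duration_s,
        components=comps, noise_sigma=noise_sigma, seed=seed,
    )
    return spec


def gen_gait_epochs(
    channels: list[str],
    fs: float = 400.0,
    n_planning: int = 24,
    n_rest: int = 36,
    n_sessions: int = 6,
    planning_s: float = 1.5,
    rest_s: float = 2.0,
    mrcp_amplitude: float = 8.0,
    mu_erd: float = 0.4,
    mu_amplitude: float = 4.0,
    noise_sigma: float = 6.0,
    eog_amplitude: float = 20.0,
    line_amplitude: float = 4.0,
    seed: int | None = 0,
) -> tuple[list[GaitEpoch], GaitGroundTruth]:
    """Labeled planning/rest epochs emulating a gait-intention protocol.

    Planning epochs (default 1.5 s, 24 repetitions) carry a negative slow
    ramp (movement-related cortical potential) peaking at the epoch end on
    the central channels plus a mu-band (10 Hz) amplitude reduction
    (event-related desynchronization, default 40 %); rest epochs (2.0 s, 36
    repetitions) are stationary.  Both classes share an EOG-like blink
    train, slow drift, a 60 Hz line tone, common pink noise and independent
    channel noise.  Epochs are split round-robin over ``n_sessions``
    sessions (4 planning + 6 rest each with the defaults).

    Set ``mrcp_amplitude=0`` and ``mu_erd=0`` for a null dataset (classes
    identically distributed).

    Returns
    -------
    (epochs, ground_truth)
    """
    if seed is not None and seed < 0:
        raise ValueError("seed must be nonnegative")
    epochs: list[GaitEpoch] = []
    base = 0 if seed is None else int(seed)
    counter = 0
    # every epoch is rendered at a common duration and cropped to its class
    # length, so slow components have identical statistics in both classes
    # and a zero-effect dataset is genuinely null
    render_s = max(planning_s, rest_s)
    for label, count, dur in ((1, n_planning, planning_s), (0, n_rest, rest_s)):
        for i in range(count):
            ep_seed = base * 1_000_003 + counter
            counter += 1
            spec = _gait_epoch_spec(
                channels, fs, render_s, label, mrcp_amplitude, mu_erd,
                mu_amplitude, noise_sigma, eog_amplitude, line_amplitude, ep_seed,
            )
            rec, _ = gen_record(spec)
            n_keep = int(round(dur * fs))
            rec = Record(
                rec.data[:, rec.n_samples - n_keep :], rec.channels, fs, rec.meta
            )
            if label == 1 and mrcp_amplitude > 0:
                # ramped negativity reaching -mrcp_amplitude at movement onset
                n = rec.n_samples
                ramp = -mrcp_amplitude * (np.arange(n) / max(n - 1, 1)) ** 2
                g = np.array([_MRCP_GAINS.get(c, 0.1) for c in channels])
                rec.data += g[:, None] * ramp[None, :]
            session = i % n_sessions
            epochs.append(GaitEpoch(rec, label, session))
    truth = GaitGroundTruth(
        mrcp_amplitude=mrcp_amplitude, mu_erd=mu_erd, mu_amplitude=mu_amplitude,
        noise_sigma=noise_sigma, fs=fs, channels=list(channels),
    )
    return epochs, truth
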