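"""Synthetic event-related EEG cohorts.

Generates multi-subject epoched voltage tensors with the statistical
structure the rest of the pipeline assumes: stimulus-locked ERP deflections
whose amplitudes differ between clinical groups (e.g. diminished late
negative/positive components around 400/600 ms in a dementia group),
band-limited oscillatory activity, and 1/f-shaped broadband background
noise.  Every downstream stage (filtering, trial averaging, visibility-graph
conversion, feature screening, classification) can therefore be exercised
without access to clinical recordings.

The generative model for one trial at one channel is

    x(t) = n_pink(t) + n_white(t)
         + sum_osc A_b sin(2 pi f_b t + phi)
         + sum_erp s A w(t - mu - J)

where ``w`` is a Gaussian-windowed half-sine deflection of width ``sigma``
peaking at latency ``mu``, ``s`` is the per-group amplitude scaling, ``J``
is a trial-level latency jitter shared across channels, and the two noise
terms each carry half the configured noise variance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "ERPComponent",
    "OscComponent",
    "SyntheticConfig",
    "EpochSet",
    "generate_cohort",
    "BAND_CENTERS",
]

#: centre frequency (Hz) used when an oscillatory component names a band
BAND_CENTERS = {
    "delta": 2.5,
    "theta": 6.0,
    "alpha": 10.5,
    "beta": 21.5,
    "gamma": 37.5,
}

#: the 15 recording sites used throughout: midline (Fz, Cz, Pz), lateral
#: frontal/temporal/occipital pairs, plus Broca (Bl/Br), Wernicke (Wl/Wr)
#: and Brodmann-41 (L41/R41) approximations.
DEFAULT_CHANNELS = (
    "Fz", "Cz", "Pz", "F7", "F8", "T5", "T6", "O1", "O2",
    "Bl", "Br", "Wl", "Wr", "L41", "R41",
)

#: word-repetition conditions: All/New/Old x Congruous/Incongruous
DEFAULT_CONDITIONS = ("AN", "NC", "NI", "AO", "OC", "OI")


@dataclass(frozen=True)
class ERPComponent:
    """A stimulus-locked deflection (e.g. an N400- or P600-like component).

    Parameters
    ----------
    latency_s
        Peak latency relative to stimulus onset, seconds.
    width_s
        Half-width of the deflection, seconds; the half-sine support is
        ``[latency - width, latency + width]``.
    amplitude_uv
        Peak amplitude in microvolts; sign encodes polarity.
    group_scale
        Mapping group label -> multiplicative amplitude scaling.  Groups
        absent from the mapping default to 1.0.
    channels, conditions
        Optional subsets the component is confined to (``None`` = all).
    """

    latency_s: float
    width_s: float
    amplitude_uv: float
    group_scale: dict = field(default_factory=dict)
    channels: tuple | None = None
    conditions: tuple | None = None

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian-windowed half-sine centred on latency."""
        u = (t - self.latency_s + self.width_s) / (2.0 * self.width_s)
        half_sine = np.where((u > 0) & (u < 1), np.sin(np.pi * np.clip(u, 0, 1)), 0.0)
        window = np.exp(-0.5 * ((t - self.latency_s) / self.width_s) ** 2)
        return half_sine * window


@dataclass(frozen=True)
class OscComponent:
    """A sinusoidal band component with per-group power scaling.

    ``power_uv2`` is the oscillation power (uV^2); the sinusoid amplitude is
    ``sqrt(2 * power * scale)``.  By default the phase is drawn uniformly
    per trial (induced activity, averages out across trials); with
    ``phase_locked=True`` the phase is zero on every trial (evoked activity
    that survives trial averaging).
    """

    band: str
    power_uv2: float
    group_scale: dict = field(default_factory=dict)
    channels: tuple | None = None
    phase_locked: bool = False

    @property
    def frequency_hz(self) -> float:
        return BAND_CENTERS[self.band]


@dataclass
class SyntheticConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the word-repetition study layout: 250 Hz sampling,
    epochs from -2 s to +2 s around word onset, 15 channels, six word
    conditions and 72 trials per condition (432 trials over six conditions).
    """

    n_subjects_per_group: dict = field(
        default_factory=lambda: {"RNE": 11, "AD": 15, "pAD": 15}
    )
    n_trials: int = 72
    sampling_rate: float = 250.0
    epoch_window: tuple = (-2.0, 2.0)
    channels: tuple = DEFAULT_CHANNELS
    conditions: tuple = DEFAULT_CONDITIONS
    erp_components: tuple = ()
    osc_components: tuple = ()
    noise_sd: float = 10.0
    trial_jitter_sd: float = 0.0
    seed: int = 0

    @property
    def groups(self) -> tuple:
        return tuple(self.n_subjects_per_group)

    @property
    def n_times(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0) * self.sampling_rate))

    @property
    def t0_index(self) -> int:
        return int(round(-self.epoch_window[0] * self.sampling_rate))

    def validate(self) -> None:
        if not self.n_subjects_per_group:
            raise ValueError("at least one group is required")
        for g, n in self.n_subjects_per_group.items():
            if n <= 0:
                raise ValueError(f"non-positive subject count for group {g!r}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        t0, t1 = self.epoch_window
        if not t0 < t1:
            raise ValueError("epoch_window must be increasing")
        if self.noise_sd < 0 or self.trial_jitter_sd < 0:
            raise ValueError("noise_sd and trial_jitter_sd must be non-negative")
        for comp in self.erp_components:
            if not (t0 < comp.latency_s < t1):
                raise ValueError(
                    f"ERP latency {comp.latency_s} s outside epoch window {self.epoch_window}"
                )
            if comp.width_s <= 0:
                raise ValueError("ERP width must be positive")
            for s in comp.group_scale.values():
                if not np.isfinite(s):
                    raise ValueError("non-finite group scaling")
        for comp in self.osc_components:
            if comp.band not in BAND_CENTERS:
                raise ValueError(f"unknown band {comp.band!r}")
            if comp.power_uv2 < 0:
                raise ValueError("oscillation power must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["erp_components"] = [dataclasses.asdict(c) for c in self.erp_components]
        d["osc_components"] = [dataclasses.asdict(c) for c in self.osc_components]
        return d


@dataclass
class EpochSet:
    """Epoched voltage tensor: subject x condition x channel x trial x time (uV)."""

    data: np.ndarray
    sampling_rate: float
    t0_index: int
    subject_groups: list
    channel_names: list
    condition_names: list

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError("data must be 5-D (subject, condition, channel, trial, time)")
        ns, nc, nch, _, nt = self.data.shape
        if ns != len(self.subject_groups):
            raise ValueError("subject_groups length mismatch")
        if nc != len(self.condition_names):
            raise ValueError("condition_names length mismatch")
        if nch != len(self.channel_names):
            raise ValueError("channel_names length mismatch")
        if not 0 <= self.t0_index < nt:
            raise ValueError("t0_index outside the time axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite voltages")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        n = self.data.shape[-1]
        return (np.arange(n) - self.t0_index) / self.sampling_rate

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def save(self, path, config: SyntheticConfig | None = None) -> None:
        """Write the canonical epochs container (HDF5) plus a JSON sidecar."""
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("time", data=self.times)
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["t0_index"] = self.t0_index
            str_dt = h5py.string_dtype()
            f.create_dataset("subjects", data=np.array(self.subject_groups, dtype=str_dt))
            f.create_dataset("channels", data=np.array(self.channel_names, dtype=str_dt))
            f.create_dataset("conditions", data=np.array(self.condition_names, dtype=str_dt))
        if config is not None:
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()].astype(np.float64),
                sampling_rate=float(f.attrs["sampling_rate"]),
                t0_index=int(f.attrs["t0_index"]),
                subject_groups=[s.decode() for s in f["subjects"][()]],
                channel_names=[s.decode() for s in f["channels"][()]],
                condition_names=[s.decode() for s in f["conditions"][()]],
            )


def _pink_noise(rng: np.random.Generator, shape: tuple, n: int) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise along the last axis, unit variance."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def generate_cohort(config: SyntheticConfig) -> EpochSet:
    """Draw a full synthetic cohort; bit-identical for identical config+seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = [g for g, n in config.n_subjects_per_group.items() for _ in range(n)]
    ns = len(groups)
    nc = len(config.conditions)
    nch = len(config.channels)
    ntr = config.n_trials
    nt = config.n_times
    t = (np.arange(nt) - config.t0_index) / config.sampling_rate

    data = np.empty((ns, nc, nch, ntr, nt), dtype=np.float64)
    chan_idx = {ch: i for i, ch in enumerate(config.channels)}

    for s, group in enumerate(groups):
        for c, cond in enumerate(config.conditions):
            # background: pink + white, each with half the noise variance
            sd = config.noise_sd / np.sqrt(2.0)
            block = sd * _pink_noise(rng, (nch, ntr), nt)
            block += sd * rng.standard_normal((nch, ntr, nt))

            for comp in config.osc_components:
                scale = comp.group_scale.get(group, 1.0)
                amp = np.sqrt(2.0 * comp.power_uv2 * max(scale, 0.0))
                chs = (
                    range(nch)
                    if comp.channels is None
                    else [chan_idx[ch] for ch in comp.channels]
                )
                if comp.phase_locked:
                    phase = np.zeros((len(chs), ntr, 1))
                else:
                    phase = rng.uniform(0, 2 * np.pi, (len(chs), ntr, 1))
                wave = amp * np.sin(2 * np.pi * comp.frequency_hz * t + phase)
                for k, ch in enumerate(chs):
                    block[ch] += wave[k]

            # trial-level latency jitter, shared across channels
            jitter = (
                rng.normal(0.0, config.trial_jitter_sd, size=ntr)
                if config.trial_jitter_sd > 0
                else np.zeros(ntr)
            )
            for comp in config.erp_components:
                if comp.conditions is not None and cond not in comp.conditions:
                    continue
                scale = comp.group_scale.get(group, 1.0)
                shifted = ERPComponent(
                    comp.latency_s, comp.width_s, 1.0
                )
                # evaluate the unit waveform at jittered latencies per trial
                wav = np.stack(
                    [
                        dataclasses.replace(shifted, latency_s=comp.latency_s + j).waveform(t)
                        for j in jitter
                    ]
                )  # (ntr, nt)
                wav *= comp.amplitude_uv * scale
                chs = (
                    range(nch)
                    if comp.channels is None
                    else [chan_idx[ch] for ch in comp.channels]
                )
                for ch in chs:
                    block[ch] += wav
            data[s, c] = block

    return EpochSet(
        data=data,
        sampling_rate=config.sampling_rate,
        t0_index=config.t0_index,
        subject_groups=groups,
        channel_names=list(config.channels),
        condition_names=list(config.conditions),
    )
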