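"""Synthetic EEG generator emulating a text-type reading experiment.

The generator reproduces the experimental design of the study it models:
40 participants, 15 trials each of a fixed 10-stimulus pattern (four
originals, one fanfiction, four originals, one badfiction — 150 stimuli,
120/15/15 per participant), a 32-channel 10/10 montage sampled at 500 Hz,
and five binary reading-habit grouping variables with the study's group
sizes.  Known-truth condition and group effects on absolute and relative
band powers are injectable, so every downstream stage has a
parameter-recovery test bed.

Signal model per stimulus segment: one narrowband Gaussian oscillator per
frequency band (band-limited white noise synthesized in the frequency
domain; a pure-tone mode at the band center is available for oracle
tests), superposed on 1/f pink background noise, white sensor noise,
Poisson-scheduled frontal blink transients, and temporal high-frequency
muscle bursts.  Everything is deterministic under a fixed seed; each
participant draws from an independent stream derived from (master seed,
participant index), so adding participants never perturbs earlier ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    GROUP_VARIABLES,
    TEXT_TYPES,
    ContractError,
    EventAnnotation,
    Montage,
    ParticipantMetadata,
    Recording,
    default_montage,
)
from .spectral import BAND_NAMES, BandSpec, default_bands

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "DesignSpec",
    "StimulusSlot",
    "generate_design",
    "synthesize_recording",
    "truth_table",
    "effective_band_powers",
]

#: baseline per-band oscillator power (uV^2), flat across channels; the
#: resulting relative spectrum is alpha-dominant with modest delta/theta,
#: matching an adult eyes-open QEEG profile.
BASE_BAND_POWER_UV2 = {
    "delta": 36.0,
    "theta": 25.0,
    "alpha": 64.0,
    "beta": 9.0,
    "gamma": 2.25,
}

_FRONTAL_WEIGHTS = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.7, "F8": 0.7,
    "F3": 0.4, "F4": 0.4, "Fz": 0.4, "FC1": 0.15, "FC2": 0.15,
}
_TEMPORAL_WEIGHTS = {
    "T7": 1.0, "T8": 1.0, "FT9": 0.8, "FT10": 0.8,
    "TP9": 0.6, "TP10": 0.6, "FC5": 0.2, "FC6": 0.2,
}


@dataclass(frozen=True)
class EffectSpec:
    """A known-truth effect on one band's power.

    ``absolute_scale`` multiplies the band's oscillator power by
    ``magnitude`` wherever the effect applies; ``relative_shift`` adds
    ``magnitude`` to the band's power *fraction* and rescales the other
    bands so total power is conserved.
    """

    target: str  # "text_type" | "group_variable"
    level: str  # e.g. "badfiction" or "non_frequent"
    band: str
    mode: str = "absolute_scale"
    magnitude: float = 1.0
    channel_subset: tuple[str, ...] | str = "all"

    def __post_init__(self) -> None:
        if self.target not in ("text_type", "group_variable"):
            raise ContractError(f"unknown effect target {self.target!r}")
        if self.band not in BAND_NAMES:
            raise ContractError(f"unknown band {self.band!r}")
        if self.mode not in ("absolute_scale", "relative_shift"):
            raise ContractError(f"unknown effect mode {self.mode!r}")
        if self.mode == "absolute_scale" and self.magnitude <= 0:
            raise ContractError("absolute_scale magnitude must be positive")

    def applies_to(self, meta: ParticipantMetadata, text_type: str) -> bool:
        if self.target == "text_type":
            return text_type == self.level
        return any(
            meta.level(var) == self.level
            for var, levels in GROUP_VARIABLES.items()
            if self.level in levels
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Background and artifact amplitudes (all in microvolts RMS)."""

    pink_exponent: float = 1.0
    pink_scale_uv: float = 4.0
    blink_rate_hz: float = 0.2
    blink_amplitude_uv: float = 80.0
    muscle_burst_rate_hz: float = 0.05
    muscle_band_hz: tuple[float, float] = (20.0, 45.0)
    muscle_amplitude_uv: float = 15.0
    sensor_white_uv: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "pink_scale_uv", "blink_rate_hz", "blink_amplitude_uv",
            "muscle_burst_rate_hz", "muscle_amplitude_uv", "sensor_white_uv",
        ):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be nonnegative")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        """All noise and artifact scales zero (oracle tests)."""
        return cls(
            pink_scale_uv=0.0, blink_rate_hz=0.0, blink_amplitude_uv=0.0,
            muscle_burst_rate_hz=0.0, muscle_amplitude_uv=0.0,
            sensor_white_uv=0.0,
        )


def scaled_group_sizes(n_participants: int) -> dict[str, dict[str, int]]:
    """Group sizes preserving the study's proportions at a different N.

    The two strictly binary variables always cover all participants; the
    three variables with a rest category keep their rest share.
    """
    ref = _default_group_sizes()
    out: dict[str, dict[str, int]] = {}
    for var, sizes in ref.items():
        levels = list(sizes)
        if "rest" in GROUP_VARIABLES[var]:
            out[var] = {
                lvl: max(1, int(round(cnt * n_participants / 40)))
                for lvl, cnt in sizes.items()
            }
            total = sum(out[var].values())
            if total > n_participants:  # shrink the larger group
                big = max(out[var], key=out[var].get)
                out[var][big] -= total - n_participants
        else:
            first = max(1, int(round(sizes[levels[0]] * n_participants / 40)))
            first = min(first, n_participants - 1)
            out[var] = {levels[0]: first, levels[1]: n_participants - first}
    return out


def _default_group_sizes() -> dict[str, dict[str, int]]:
    # the study's group Ns; remainders fall into the rest category
    return {
        "reading_frequency": {"frequent": 10, "non_frequent": 10},
        "literary_familiarity": {"buff": 12, "rookie": 14},
        "fantasy_reader": {"fantasy": 26, "non_fantasy": 14},
        "hp_fan": {"fan": 17, "non_fan": 23},
        "badfiction_attitude": {"positive": 9, "negative": 8},
    }


_DEFAULT_PATTERN = (
    "original", "original", "original", "original", "fanfiction",
    "original", "original", "original", "original", "badfiction",
)


@dataclass(frozen=True)
class DesignSpec:
    """Full description of one simulated experiment."""

    n_participants: int = 40
    n_trials: int = 15
    trial_pattern: tuple[str, ...] = _DEFAULT_PATTERN
    stimulus_duration_s: tuple[float, float] = (8.0, 15.0)
    gap_s: float = 0.5
    sampling_rate_hz: float = 500.0
    montage: Montage = field(default_factory=default_montage)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    effects: tuple[EffectSpec, ...] = ()
    group_sizes: dict[str, dict[str, int]] = field(
        default_factory=_default_group_sizes
    )
    oscillator: str = "narrowband"  # or "tone"
    bands: tuple[BandSpec, ...] = field(
        default_factory=lambda: tuple(default_bands())
    )
    base_band_power_uv2: dict[str, float] = field(
        default_factory=lambda: dict(BASE_BAND_POWER_UV2)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for tt in self.trial_pattern:
            if tt not in TEXT_TYPES:
                raise ContractError(f"unknown text type {tt!r} in pattern")
        lo, hi = self.stimulus_duration_s
        if not 0 < lo <= hi:
            raise ContractError("stimulus duration range must be positive")
        for var, sizes in self.group_sizes.items():
            if var not in GROUP_VARIABLES:
                raise ContractError(f"unknown grouping variable {var!r}")
            for lvl in sizes:
                if lvl not in GROUP_VARIABLES[var]:
                    raise ContractError(f"unknown level {lvl!r} for {var!r}")
            if sum(sizes.values()) > self.n_participants:
                raise ContractError(
                    f"group sizes for {var!r} exceed n_participants"
                )
        if self.oscillator not in ("narrowband", "tone"):
            raise ContractError(f"unknown oscillator mode {self.oscillator!r}")


@dataclass(frozen=True)
class StimulusSlot:
    """One scheduled stimulus presentation for one participant."""

    participant_id: str
    stimulus_id: str
    text_type: str
    trial_index: int
    duration_s: float


def _participant_index(participant_id: str) -> int:
    m = re.search(r"(\d+)$", participant_id)
    if m:
        return int(m.group(1))
    import zlib

    return zlib.crc32(participant_id.encode()) % 2**16


def _participant_rng(spec: DesignSpec, participant_id: str, stream: int):
    return np.random.default_rng(
        [spec.seed % 2**31, _participant_index(participant_id), stream]
    )


def generate_design(
    spec: DesignSpec,
) -> list[tuple[ParticipantMetadata, list[StimulusSlot]]]:
    """Assign group labels and per-participant stimulus schedules.

    Group labels are assigned by one seeded shuffle per variable honoring
    ``spec.group_sizes``; participants beyond the listed counts fall into
    the ``rest`` category (or the last listed level for the two strictly
    binary variables).  Each participant's schedule repeats the trial
    pattern ``n_trials`` times with stimulus ids shuffled within text type
    and reading times drawn uniformly from ``stimulus_duration_s``.
    """
    n = spec.n_participants
    ids = [f"P{i:03d}" for i in range(1, n + 1)]

    master = np.random.default_rng([spec.seed % 2**31, 0xD5])
    labels: dict[str, list[str]] = {}
    for var, levels in GROUP_VARIABLES.items():
        sizes = spec.group_sizes.get(var, {})
        order = master.permutation(n)
        fallback = "rest" if "rest" in levels else levels[-1]
        assigned = [fallback] * n
        pos = 0
        for lvl in levels:
            count = sizes.get(lvl, 0)
            for j in order[pos : pos + count]:
                assigned[j] = lvl
            pos += count
        labels[var] = assigned

    pattern = spec.trial_pattern
    counts = {tt: pattern.count(tt) for tt in TEXT_TYPES}
    out = []
    for i, pid in enumerate(ids):
        meta = ParticipantMetadata(
            participant_id=pid,
            **{var: labels[var][i] for var in GROUP_VARIABLES},
        )
        rng = _participant_rng(spec, pid, stream=5)
        # pools of stimulus ids, randomized within text type
        pools = {
            tt: list(
                rng.permutation(
                    [
                        f"{tt[0]}{k:03d}"
                        for k in range(1, counts[tt] * spec.n_trials + 1)
                    ]
                )
            )
            for tt in TEXT_TYPES
            if counts[tt]
        }
        lo, hi = spec.stimulus_duration_s
        schedule = []
        for trial in range(1, spec.n_trials + 1):
            for tt in pattern:
                schedule.append(
                    StimulusSlot(
                        participant_id=pid,
                        stimulus_id=pools[tt].pop(),
                        text_type=tt,
                        trial_index=trial,
                        duration_s=float(rng.uniform(lo, hi)),
                    )
                )
        out.append((meta, schedule))
    return out


def effective_band_powers(
    meta: ParticipantMetadata, text_type: str, spec: DesignSpec
) -> np.ndarray:
    """Ground-truth oscillator power per (channel, band) in uV^2, i.e. the
    baseline powers with every applicable effect applied in order."""
    n_ch = len(spec.montage)
    base = np.array([spec.base_band_power_uv2[b] for b in BAND_NAMES])
    powers = np.tile(base, (n_ch, 1)).astype(np.float64)
    band_index = {b: i for i, b in enumerate(BAND_NAMES)}
    for eff in spec.effects:
        if not eff.applies_to(meta, text_type):
            continue
        if eff.channel_subset == "all":
            ch_idx = np.arange(n_ch)
        else:
            ch_idx = np.array(
                [spec.montage.index(c) for c in eff.channel_subset]
            )
        bi = band_index[eff.band]
        if eff.mode == "absolute_scale":
            powers[ch_idx, bi] *= eff.magnitude
        else:  # relative_shift
            for ci in ch_idx:
                p = powers[ci]
                total = p.sum()
                r = p / total
                r_new = r[bi] + eff.magnitude
                if not 0 < r_new < 1:
                    raise ContractError(
                        "relative_shift pushes band fraction outside (0,1)"
                    )
                scale_others = (1.0 - r_new) / (1.0 - r[bi])
                r = r * scale_others
                r[bi] = r_new
                powers[ci] = r * total
    return powers


def _narrowband_noise(
    rng, n_ch: int, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to (low, high], synthesized
    in the frequency domain (exact band confinement)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs > low) & (freqs <= high)
    if not mask.any():
        raise ContractError(f"band ({low}, {high}] Hz has no DFT bins")
    spec = np.zeros((n_ch, freqs.size), dtype=np.complex128)
    k = int(mask.sum())
    spec[:, mask] = rng.standard_normal((n_ch, k)) + 1j * rng.standard_normal(
        (n_ch, k)
    )
    x = np.fft.irfft(spec, n=n, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def _pink_noise(rng, n_ch: int, n: int, fs: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = np.maximum(freqs[nz], 0.5) ** (-exponent / 2.0)
    spec = amp * (
        rng.standard_normal((n_ch, freqs.size))
        + 1j * rng.standard_normal((n_ch, freqs.size))
    )
    x = np.fft.irfft(spec, n=n, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def _topography(montage: Montage, weights: dict[str, float]) -> np.ndarray:
    return np.array([weights.get(c, 0.05) for c in montage.channel_names])


def synthesize_recording(
    meta: ParticipantMetadata,
    schedule: list[StimulusSlot],
    spec: DesignSpec,
) -> Recording:
    """Render one participant's continuous recording from their schedule."""
    if any(s.participant_id != meta.participant_id for s in schedule):
        raise ContractError("schedule does not belong to this participant")
    fs = spec.sampling_rate_hz
    n_ch = len(spec.montage)
    rng = _participant_rng(spec, meta.participant_id, stream=17)

    lead = int(round(1.0 * fs))
    gap = int(round(spec.gap_s * fs))
    seg_lengths = [int(round(s.duration_s * fs)) for s in schedule]
    total = lead + sum(seg_lengths) + gap * len(schedule)

    data = np.zeros((n_ch, total))
    noise = spec.noise
    if noise.pink_scale_uv > 0:
        data += noise.pink_scale_uv * _pink_noise(
            rng, n_ch, total, fs, noise.pink_exponent
        )
    if noise.sensor_white_uv > 0:
        data += noise.sensor_white_uv * rng.standard_normal((n_ch, total))

    events = []
    pos = lead
    bands = list(spec.bands)
    for slot, n_seg in zip(schedule, seg_lengths):
        powers = effective_band_powers(meta, slot.text_type, spec)
        seg = np.zeros((n_ch, n_seg))
        for bi, band in enumerate(bands):
            amp = np.sqrt(powers[:, bi])[:, None]  # RMS per channel
            if spec.oscillator == "tone":
                phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
                t = np.arange(n_seg) / fs
                seg += amp * np.sqrt(2.0) * np.sin(
                    2 * np.pi * band.center_hz * t[None, :] + phase
                )
            else:
                seg += amp * _narrowband_noise(
                    rng, n_ch, n_seg, fs, band.low_hz, band.high_hz
                )
        data[:, pos : pos + n_seg] += seg
        events.append(
            EventAnnotation(
                onset_s=pos / fs,
                duration_s=n_seg / fs,
                stimulus_id=slot.stimulus_id,
                text_type=slot.text_type,
                trial_index=slot.trial_index,
            )
        )
        pos += n_seg + gap

    duration_s = total / fs
    if noise.blink_rate_hz > 0 and noise.blink_amplitude_uv > 0:
        topo = _topography(spec.montage, _FRONTAL_WEIGHTS)
        n_blinks = rng.poisson(noise.blink_rate_hz * duration_s)
        width = int(round(0.4 * fs))
        t = np.arange(width) / fs
        bump = np.exp(-0.5 * ((t - 0.2) / 0.07) ** 2)  # ~2.3 Hz-wide transient
        for _ in range(n_blinks):
            start = rng.integers(0, max(1, total - width))
            a = noise.blink_amplitude_uv * rng.uniform(0.7, 1.3)
            data[:, start : start + width] += a * topo[:, None] * bump[None, :]
    if noise.muscle_burst_rate_hz > 0 and noise.muscle_amplitude_uv > 0:
        topo = _topography(spec.montage, _TEMPORAL_WEIGHTS)
        n_bursts = rng.poisson(noise.muscle_burst_rate_hz * duration_s)
        width = int(round(0.3 * fs))
        env = np.hanning(width)
        lo, hi = noise.muscle_band_hz
        hi = min(hi, fs / 2 - 1e-6)
        for _ in range(n_bursts):
            start = rng.integers(0, max(1, total - width))
            burst = _narrowband_noise(rng, 1, width, fs, lo, hi)[0] * env
            a = noise.muscle_amplitude_uv * rng.uniform(0.7, 1.3)
            data[:, start : start + width] += a * topo[:, None] * burst[None, :]

    return Recording(
        participant_id=meta.participant_id,
        montage=spec.montage,
        sampling_rate_hz=fs,
        samples=data,
        events=events,
    )


def truth_table(spec: DesignSpec) -> pd.DataFrame:
    """Analytic expected band powers per (participant, text_type, channel,
    band) implied by baseline amplitudes and effects, before noise.

    Columns: ``participant_id, text_type, channel, band, power_uv2,
    rel_power``; relative powers sum to one over the five bands within each
    (participant, text_type, channel) cell.
    """
    rows = []
    for meta, _schedule in generate_design(spec):
        for tt in TEXT_TYPES:
            powers = effective_band_powers(meta, tt, spec)
            rel = powers / powers.sum(axis=1, keepdims=True)
            for ci, ch in enumerate(spec.montage.channel_names):
                for bi, band in enumerate(BAND_NAMES):
                    rows.append(
                        (
                            meta.participant_id, tt, ch, band,
                            powers[ci, bi], rel[ci, bi],
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "text_type", "channel", "band",
            "power_uv2", "rel_power",
        ],
    )


def small_montage(n: int = 8) -> Montage:
    """A reduced montage (subset of the default labels) for fast test beds."""
    subset = ["Fp1", "Fz", "Cz", "Pz", "Oz", "T7", "T8", "P3",
              "P4", "F3", "F4", "O1"][:n]
    return Montage(tuple(subset))
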