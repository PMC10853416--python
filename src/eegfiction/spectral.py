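"""Power spectral density, band powers, relative powers and brain rate.

The spectral pipeline mirrors standard QEEG practice: 1-s Hamming-tapered
windows stepped every 0.5 s, periodogram per window with Welch density
normalization, averaged per stimulus, restricted to the 1..40 Hz grid.
From the averaged PSD we derive

* absolute band power ``P_b`` — the mean per-bin power inside band ``b``,
* relative band power ``R_b`` — the band's share of total summed power
  (guaranteeing ``sum_b R_b = 1`` with unequal band widths), and
* the brain rate ``f_BR = sum_b center(b) * R_b``, a single summary
  frequency weighting each band's center by its relative power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContractError

__all__ = [
    "BAND_NAMES",
    "BandSpec",
    "default_bands",
    "SpectralFeatures",
    "psd_windows",
    "band_powers",
    "brain_rate",
    "features_frame",
    "aggregate",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: conventional QEEG edges within the 0.5-40 Hz passband
_DEFAULT_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}


@dataclass(frozen=True)
class BandSpec:
    """One frequency band: half-open interval ``(low_hz, high_hz]``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.name not in BAND_NAMES:
            raise ContractError(f"unknown band name {self.name!r}")
        if not 0 < self.low_hz < self.high_hz:
            raise ContractError("band edges must satisfy 0 < low < high")

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)

    def bins(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Boolean mask of grid bins inside ``(low, high]``."""
        f = np.asarray(freqs_hz)
        return (f > self.low_hz) & (f <= self.high_hz)


def default_bands() -> list[BandSpec]:
    """The five bands partitioning (0.5, 40] Hz with conventional edges."""
    return [BandSpec(n, *_DEFAULT_EDGES[n]) for n in BAND_NAMES]


def _check_partition(bands: list[BandSpec]) -> None:
    ordered = sorted(bands, key=lambda b: b.low_hz)
    for a, b in zip(ordered, ordered[1:]):
        if abs(a.high_hz - b.low_hz) > 1e-9:
            raise ContractError(
                f"bands {a.name}/{b.name} leave a gap or overlap"
            )


@dataclass
class SpectralFeatures:
    """Per-(stimulus, channel) PSD plus derived band summaries."""

    participant_id: str
    stimulus_id: str
    text_type: str
    channel: str
    freqs_hz: np.ndarray
    psd_abs: np.ndarray  # uV^2/Hz per bin
    band_abs: np.ndarray  # mean per-bin power per band
    band_rel: np.ndarray  # share of total power per band
    brain_rate_hz: float
    n_windows: int = 0
    group_levels: dict = field(default_factory=dict)


def psd_windows(
    windows: np.ndarray,
    sampling_rate_hz: float,
    length_s: float = 1.0,
    f_min_hz: float = 1.0,
    f_max_hz: float = 40.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average Hamming-tapered periodograms over windows of one stimulus.

    Parameters
    ----------
    windows
        Array of shape (n_windows, n_samples) — pre-cut, equal-length
        windows of one channel, in microvolts.

    Returns
    -------
    freqs_hz, psd_abs
        One-sided PSD (uV^2/Hz, Welch density convention: scaled by
        ``1 / (fs * sum(taper^2))`` with off-DC bins doubled) averaged over
        windows and restricted to ``[f_min_hz, f_max_hz]``.  A 1-s window at
        integer rate yields an exact 1 Hz grid.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=np.float64))
    n = windows.shape[1]
    expected = int(round(length_s * sampling_rate_hz))
    if n != expected:
        raise ContractError(
            f"windows have {n} samples, expected {expected} "
            f"({length_s} s at {sampling_rate_hz} Hz)"
        )
    taper = np.hamming(n)
    spec = np.fft.rfft(windows * taper, axis=1)
    scale = 1.0 / (sampling_rate_hz * np.sum(taper**2))
    psd = (np.abs(spec) ** 2) * scale
    psd[:, 1:] *= 2.0
    if n % 2 == 0:
        psd[:, -1] /= 2.0  # Nyquist bin is not mirrored
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    keep = (freqs >= f_min_hz - 1e-9) & (freqs <= f_max_hz + 1e-9)
    return freqs[keep], psd.mean(axis=0)[keep]


def band_powers(
    freqs_hz: np.ndarray,
    psd_abs: np.ndarray,
    bands: list[BandSpec] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute (mean per-bin) and relative (summed-share) band powers.

    ``band_abs[b]`` is the mean of ``psd_abs`` over the bins of band ``b``
    (the convention used for absolute comparisons); ``band_rel[b]`` is the
    summed bin power of the band divided by the total summed power, so the
    relative powers always sum to one even with unequal band widths.
    """
    bands = default_bands() if bands is None else bands
    _check_partition(bands)
    freqs_hz = np.asarray(freqs_hz)
    psd_abs = np.asarray(psd_abs, dtype=np.float64)
    band_abs = np.empty(len(bands))
    band_sum = np.empty(len(bands))
    for i, b in enumerate(bands):
        mask = b.bins(freqs_hz)
        if not mask.any():
            raise ContractError(f"band {b.name} contains no frequency bins")
        band_abs[i] = psd_abs[mask].mean()
        band_sum[i] = psd_abs[mask].sum()
    total = band_sum.sum()
    band_rel = band_sum / total if total > 0 else np.full(len(bands), np.nan)
    return band_abs, band_rel


def brain_rate(band_rel: np.ndarray, bands: list[BandSpec] | None = None) -> float:
    """Relative-power-weighted mean of band center frequencies."""
    bands = default_bands() if bands is None else bands
    band_rel = np.asarray(band_rel, dtype=np.float64)
    if np.any(np.isnan(band_rel)):
        return float("nan")
    if abs(band_rel.sum() - 1.0) > 1e-6:
        raise ContractError("relative band powers must sum to 1")
    centers = np.array([b.center_hz for b in bands])
    return float(np.dot(centers, band_rel))


def extract_features(
    segments,
    bands: list[BandSpec] | None = None,
    group_levels: dict | None = None,
    f_min_hz: float = 1.0,
    f_max_hz: float = 40.0,
) -> list[SpectralFeatures]:
    """Compute :class:`SpectralFeatures` for every (stimulus, channel).

    Accepts the :class:`~eegfiction.preprocess.StimulusSegment` list from
    ``segment_windows``; segments shorter than one window are skipped.
    ``group_levels`` (participant metadata levels) are attached verbatim to
    each feature row.
    """
    bands = default_bands() if bands is None else bands
    out: list[SpectralFeatures] = []
    for seg in segments:
        if seg.n_windows == 0:
            continue
        n_ch = seg.data.shape[0]
        wins = seg.all_windows()  # (n_ch, n_win, L)
        flat = wins.reshape(n_ch * seg.n_windows, seg.window_length)
        taper = np.hamming(seg.window_length)
        spec = np.fft.rfft(flat * taper, axis=1)
        scale = 1.0 / (seg.sampling_rate_hz * np.sum(taper**2))
        psd = (np.abs(spec) ** 2) * scale
        psd[:, 1:] *= 2.0
        if seg.window_length % 2 == 0:
            psd[:, -1] /= 2.0
        allf = np.fft.rfftfreq(seg.window_length, d=1.0 / seg.sampling_rate_hz)
        keep = (allf >= f_min_hz - 1e-9) & (allf <= f_max_hz + 1e-9)
        freqs = allf[keep]
        psd = psd[:, keep].reshape(n_ch, seg.n_windows, -1).mean(axis=1)
        for ci, ch in enumerate(seg.channel_names):
            band_abs, band_rel = band_powers(freqs, psd[ci], bands)
            out.append(
                SpectralFeatures(
                    participant_id=seg.participant_id,
                    stimulus_id=seg.stimulus_id,
                    text_type=seg.text_type,
                    channel=ch,
                    freqs_hz=freqs,
                    psd_abs=psd[ci],
                    band_abs=band_abs,
                    band_rel=band_rel,
                    brain_rate_hz=brain_rate(band_rel, bands),
                    n_windows=seg.n_windows,
                    group_levels=dict(group_levels or {}),
                )
            )
    return out


def features_frame(features: list[SpectralFeatures]) -> pd.DataFrame:
    """Stimulus-level feature rows as a tidy DataFrame (one row per
    (participant, stimulus, channel), band measures as columns)."""
    rows = []
    for f in features:
        row = {
            "participant_id": f.participant_id,
            "stimulus_id": f.stimulus_id,
            "text_type": f.text_type,
            "channel": f.channel,
            "brain_rate": f.brain_rate_hz,
        }
        for i, b in enumerate(BAND_NAMES):
            row[f"abs_{b}"] = f.band_abs[i]
            row[b] = f.band_rel[i]
        row.update(f.group_levels)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate(
    features: list[SpectralFeatures],
    by: str = "text_type",
    level: str = "absolute",
) -> pd.DataFrame:
    """Aggregate features per grouping cell.

    ``level="absolute"`` returns the mean PSD per (channel, frequency bin,
    cell), averaging first within participant and then across participants,
    so participants with unequal stimulus counts carry equal weight.
    ``level="relative"`` keeps stimulus-level rows unaveraged (the unit of
    observation for the two-group cascade).
    """
    if not features:
        raise ContractError("no features to aggregate")
    if level == "relative":
        df = features_frame(features)
        if by != "text_type" and by not in df.columns:
            raise ContractError(f"unknown grouping variable {by!r}")
        return df

    grid = features[0].freqs_hz
    rows = []
    for f in features:
        if by == "text_type":
            cell = f.text_type
        elif by in f.group_levels:
            cell = f.group_levels[by]
        else:
            raise ContractError(f"unknown grouping variable {by!r}")
        for freq, p in zip(grid, f.psd_abs):
            rows.append(
                (f.participant_id, cell, f.channel, freq, p)
            )
    df = pd.DataFrame(
        rows, columns=["participant_id", "cell", "channel", "freq_hz", "psd"]
    )
    within = (
        df.groupby(["participant_id", "cell", "channel", "freq_hz"])["psd"]
        .mean()
        .reset_index()
    )
    out = (
        within.groupby(["cell", "channel", "freq_hz"])["psd"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out
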