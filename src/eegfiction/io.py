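"""Recording data model and readers/writers for EEG containers.

The pipeline's canonical in-memory object is :class:`Recording`: a
channels x time matrix of scalp potentials in microvolts plus an ordered
montage and per-stimulus event annotations.  Three on-disk containers are
supported:

* a native fixture format (JSON sidecar + flat float32 binary) that needs
  no third-party reader,
* BrainVision triplets (``.vhdr``/``.vmrk``/``.eeg``), read through MNE,
* EDF/EDF+ (16-bit), read through MNE and written by a minimal built-in
  writer.

All readers convert to microvolts; all slicing downstream is half-open
``[onset, onset + duration)`` in seconds from recording start.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TEXT_TYPES",
    "DEFAULT_CHANNELS",
    "ContractError",
    "FormatError",
    "Montage",
    "EventAnnotation",
    "Recording",
    "ParticipantMetadata",
    "default_montage",
    "write_native",
    "read_native",
    "write_edf",
    "read_edf",
    "write_brainvision_fixture",
    "read_brainvision",
    "write_features_table",
    "read_features_table",
    "write_metadata_table",
    "read_metadata_table",
]

TEXT_TYPES = ("original", "fanfiction", "badfiction")

#: 32-electrode 10/10 montage used throughout, in acquisition order.
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "FC1", "FC2", "FC5", "FC6", "FT9", "FT10",
    "Cz", "C3", "C4", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6", "TP9", "TP10",
    "Pz", "P3", "P4", "P7", "P8",
    "Oz", "O1", "O2",
]


class ContractError(ValueError):
    """A precondition or invariant of the pipeline's data model is violated."""


class FormatError(ValueError):
    """An on-disk file does not conform to its declared format."""


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels plus reference/ground bookkeeping."""

    channel_names: tuple[str, ...]
    reference_label: str = "FCz"
    ground_label: str = "Fpz"

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        if len(set(names)) != len(names):
            raise ContractError("montage channel names must be unique")

    def __len__(self) -> int:
        return len(self.channel_names)

    def index(self, label: str) -> int:
        try:
            return self.channel_names.index(label)
        except ValueError:
            raise ContractError(f"channel {label!r} not in montage") from None


def default_montage() -> Montage:
    """The study's 32-channel 10/10 montage (reference between Fz and Cz)."""
    return Montage(tuple(DEFAULT_CHANNELS))


@dataclass(frozen=True)
class EventAnnotation:
    """One stimulus presentation: onset/duration in seconds, label, trial."""

    onset_s: float
    duration_s: float
    stimulus_id: str
    text_type: str
    trial_index: int = 1

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ContractError("event onset must be nonnegative")
        if self.duration_s <= 0:
            raise ContractError("event duration must be positive")
        if self.text_type not in TEXT_TYPES:
            raise ContractError(
                f"text_type must be one of {TEXT_TYPES}, got {self.text_type!r}"
            )


@dataclass
class Recording:
    """One participant's continuous multichannel EEG in microvolts."""

    participant_id: str
    montage: Montage
    sampling_rate_hz: float
    samples: np.ndarray  # channels x time, microvolts
    events: list[EventAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ContractError("samples must be a channels x time matrix")
        if self.samples.shape[0] != len(self.montage):
            raise ContractError(
                f"samples has {self.samples.shape[0]} rows but montage has "
                f"{len(self.montage)} channels"
            )
        if self.sampling_rate_hz <= 80.0:
            # 2 x the 40 Hz analysis ceiling
            raise ContractError("sampling rate must exceed 80 Hz")
        self.events = sorted(self.events, key=lambda e: e.onset_s)
        dur = self.duration_s
        for ev in self.events:
            if ev.onset_s + ev.duration_s > dur + 1e-9:
                raise ContractError(
                    f"event {ev.stimulus_id!r} extends past recording end"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        """Channel data resolved by montage label, never raw position."""
        return self.samples[self.montage.index(label)]

    def copy_with(self, samples: np.ndarray, montage: Montage | None = None) -> "Recording":
        return Recording(
            participant_id=self.participant_id,
            montage=montage if montage is not None else self.montage,
            sampling_rate_hz=self.sampling_rate_hz,
            samples=samples,
            events=list(self.events),
        )


_READING_FREQUENCY = ("frequent", "non_frequent", "rest")
_LITERARY_FAMILIARITY = ("buff", "rookie", "rest")
_FANTASY = ("fantasy", "non_fantasy")
_HP_FAN = ("fan", "non_fan")
_BADFICTION_ATTITUDE = ("positive", "negative", "rest")

#: the five grouping variables and their admissible levels; ``rest`` levels
#: are excluded from two-group analysis.
GROUP_VARIABLES = {
    "reading_frequency": _READING_FREQUENCY,
    "literary_familiarity": _LITERARY_FAMILIARITY,
    "fantasy_reader": _FANTASY,
    "hp_fan": _HP_FAN,
    "badfiction_attitude": _BADFICTION_ATTITUDE,
}


@dataclass(frozen=True)
class ParticipantMetadata:
    """Binary reading-habit group labels for one participant."""

    participant_id: str
    reading_frequency: str = "rest"
    literary_familiarity: str = "rest"
    fantasy_reader: str = "non_fantasy"
    hp_fan: str = "non_fan"
    badfiction_attitude: str = "rest"

    def __post_init__(self) -> None:
        for var, levels in GROUP_VARIABLES.items():
            value = getattr(self, var)
            if value not in levels:
                raise ContractError(
                    f"{var} must be one of {levels}, got {value!r}"
                )

    def level(self, variable: str) -> str:
        if variable not in GROUP_VARIABLES:
            raise ContractError(f"unknown grouping variable {variable!r}")
        return getattr(self, variable)


# ---------------------------------------------------------------------------
# native fixture format: <base>.json (montage/rate/events) + <base>.dat
# (float32 little-endian, channel-major)
# ---------------------------------------------------------------------------

def write_native(rec: Recording, base_path: str | Path) -> tuple[Path, Path]:
    base = Path(base_path)
    json_path = base.with_suffix(".json")
    dat_path = base.with_suffix(".dat")
    sidecar = {
        "participant_id": rec.participant_id,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "montage": {
            "channel_names": list(rec.montage.channel_names),
            "reference_label": rec.montage.reference_label,
            "ground_label": rec.montage.ground_label,
        },
        "n_samples": rec.n_samples,
        "events": [
            {
                "onset_s": ev.onset_s,
                "duration_s": ev.duration_s,
                "stimulus_id": ev.stimulus_id,
                "text_type": ev.text_type,
                "trial_index": ev.trial_index,
            }
            for ev in rec.events
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    rec.samples.astype("<f4").tofile(dat_path)
    return json_path, dat_path


def read_native(base_path: str | Path) -> Recording:
    base = Path(base_path)
    json_path = base.with_suffix(".json")
    dat_path = base.with_suffix(".dat")
    if not json_path.exists():
        raise FileNotFoundError(f"missing sidecar file: {json_path}")
    if not dat_path.exists():
        raise FileNotFoundError(f"missing data file: {dat_path}")
    sidecar = json.loads(json_path.read_text())
    montage = Montage(
        tuple(sidecar["montage"]["channel_names"]),
        sidecar["montage"]["reference_label"],
        sidecar["montage"]["ground_label"],
    )
    n_ch, n_samp = len(montage), int(sidecar["n_samples"])
    data = np.fromfile(dat_path, dtype="<f4")
    if data.size != n_ch * n_samp:
        raise FormatError(
            f"{dat_path} holds {data.size} values, expected {n_ch * n_samp}"
        )
    events = [EventAnnotation(**ev) for ev in sidecar["events"]]
    return Recording(
        participant_id=sidecar["participant_id"],
        montage=montage,
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        samples=data.reshape(n_ch, n_samp).astype(np.float64),
        events=events,
    )


# ---------------------------------------------------------------------------
# EDF+ (16-bit) — minimal writer; reading through MNE
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    out = value.encode("ascii")[:width]
    return out + b" " * (width - len(out))


def edf_quantization_step(rec: Recording) -> float:
    """Worst-case per-sample quantization error bound of :func:`write_edf`."""
    phys = max(1e-6, float(np.max(np.abs(rec.samples)))) * (1 + 1e-7)
    return phys / 32767.0


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write an EDF+C file with one annotation channel carrying the events.

    The recording is zero-padded to whole 1-second data records; 16-bit
    quantization uses a symmetric physical range per file (bound given by
    :func:`edf_quantization_step`).  Event labels are encoded as
    ``text_type/stimulus_id/trial_index``.
    """
    path = Path(path)
    fs = rec.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ContractError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = max(1, int(np.ceil(rec.n_samples / fs)))
    n_ch = rec.n_channels

    phys = max(1e-6, float(np.max(np.abs(rec.samples)))) * (1 + 1e-7)
    scaled = np.clip(np.round(rec.samples / phys * 32767.0), -32767, 32767)
    padded = np.zeros((n_ch, n_records * fs), dtype="<i2")
    padded[:, : rec.n_samples] = scaled.astype("<i2")

    # one timestamp TAL per record + all event TALs in record 0
    tals: list[bytes] = []
    for ev in rec.events:
        tals.append(
            b"+%s\x15%s\x14%s\x14\x00"
            % (
                f"{ev.onset_s:.4f}".rstrip("0").rstrip(".").encode(),
                f"{ev.duration_s:.4f}".rstrip("0").rstrip(".").encode(),
                f"{ev.text_type}/{ev.stimulus_id}/{ev.trial_index}".encode(),
            )
        )
    event_blob = b"".join(tals)
    n_annot_samples = max(16, (len(event_blob) + 32) // 2 + 8)

    n_signals = n_ch + 1
    header_bytes = 256 * (1 + n_signals)
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(f"participant {rec.participant_id}", 80))
        fh.write(_edf_field("eegfiction synthetic recording", 80))
        fh.write(_edf_field("01.01.2000", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(header_bytes), 8))
        fh.write(_edf_field("EDF+C", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field("1", 8))
        fh.write(_edf_field(str(n_signals), 4))

        labels = [f"EEG {name}" for name in rec.montage.channel_names]
        labels.append("EDF Annotations")
        for lab in labels:
            fh.write(_edf_field(lab, 16))
        for _ in range(n_signals):
            fh.write(_edf_field("", 80))  # transducer
        for i in range(n_signals):
            fh.write(_edf_field("uV" if i < n_ch else "", 8))
        for i in range(n_signals):
            fh.write(_edf_field(f"{-phys:.6g}" if i < n_ch else "-1", 8))
        for i in range(n_signals):
            fh.write(_edf_field(f"{phys:.6g}" if i < n_ch else "1", 8))
        for _ in range(n_signals):
            fh.write(_edf_field("-32767", 8))
        for _ in range(n_signals):
            fh.write(_edf_field("32767", 8))
        for _ in range(n_signals):
            fh.write(_edf_field("", 80))  # prefiltering
        for i in range(n_signals):
            fh.write(_edf_field(str(fs if i < n_ch else n_annot_samples), 8))
        for _ in range(n_signals):
            fh.write(_edf_field("", 32))

        for rec_i in range(n_records):
            sl = slice(rec_i * fs, (rec_i + 1) * fs)
            for ch in range(n_ch):
                fh.write(padded[ch, sl].tobytes())
            annot = b"+%d\x14\x14\x00" % rec_i
            if rec_i == 0:
                annot += event_blob
            annot += b"\x00" * (2 * n_annot_samples - len(annot))
            fh.write(annot)
    return path


_EVENT_LABEL_RE = re.compile(
    r"^(original|fanfiction|badfiction)/([^/]+)(?:/(\d+))?$"
)


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    EDF+ annotations whose label parses as ``text_type/stimulus_id`` (with an
    optional ``/trial_index``) become :class:`EventAnnotation`; others are
    dropped.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    with open(path, "rb") as fh:
        header = fh.read(256)
    if header[:8] != b"0       ":
        raise FormatError(f"{path} does not start with the EDF version field")
    try:
        header_bytes = int(header[184:192])
        n_records = int(header[236:244])
        n_signals = int(header[252:256])
        with open(path, "rb") as fh:
            sig_header = fh.read(header_bytes)
        spr_field = sig_header[
            256 + n_signals * 216 : 256 + n_signals * 224
        ]
        samples_per_record = sum(
            int(spr_field[i * 8 : (i + 1) * 8]) for i in range(n_signals)
        )
        expected = header_bytes + 2 * n_records * samples_per_record
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path} has a malformed EDF header") from exc
    if path.stat().st_size < expected:
        raise FormatError(
            f"{path} is truncated: {path.stat().st_size} bytes, "
            f"header promises {expected}"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc

    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    samples = raw.get_data() * 1e6  # V -> uV
    events = []
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        m = _EVENT_LABEL_RE.match(desc)
        if m is None:
            continue
        events.append(
            EventAnnotation(
                onset_s=float(onset),
                duration_s=float(duration),
                stimulus_id=m.group(2),
                text_type=m.group(1),
                trial_index=int(m.group(3) or 1),
            )
        )
    return Recording(
        participant_id=path.stem,
        montage=Montage(tuple(names)),
        sampling_rate_hz=float(raw.info["sfreq"]),
        samples=samples,
        events=events,
    )


# ---------------------------------------------------------------------------
# BrainVision triplet — fixture writer + MNE-backed reader
# ---------------------------------------------------------------------------

_STIMULUS_CODES = {"original": 1, "fanfiction": 2, "badfiction": 3}
_CODE_TEXT_TYPES = {v: k for k, v in _STIMULUS_CODES.items()}


def write_brainvision_fixture(rec: Recording, header_path: str | Path) -> Path:
    """Write a minimal BrainVision triplet (IEEE float32, multiplexed).

    Stimulus markers ``S  1``/``S  2``/``S  3`` encode original, fanfiction
    and badfiction; marker size carries the stimulus duration in samples.
    """
    header_path = Path(header_path)
    base = header_path.with_suffix("")
    eeg_path = base.with_suffix(".eeg")
    vmrk_path = base.with_suffix(".vmrk")
    fs = rec.sampling_rate_hz
    interval_us = 1e6 / fs

    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.montage.channel_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    header_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    for k, ev in enumerate(rec.events, start=2):
        pos = int(round(ev.onset_s * fs)) + 1  # 1-based
        size = int(round(ev.duration_s * fs))
        code = _STIMULUS_CODES[ev.text_type]
        mlines.append(f"Mk{k}=Stimulus,S{code:>3d},{pos},{size},0")
    vmrk_path.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.samples.T.astype("<f4").tofile(eeg_path)  # multiplexed = time-major
    return header_path


def read_brainvision(header_path: str | Path) -> Recording:
    """Read a BrainVision triplet; stimulus markers S1/S2/S3 become events."""
    import mne

    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"no such header file: {header_path}")
    text = header_path.read_text(encoding="utf-8", errors="replace")
    for key in ("DataFile", "MarkerFile"):
        m = re.search(rf"^{key}=(.+)$", text, flags=re.MULTILINE)
        if m:
            companion = header_path.parent / m.group(1).strip()
            if not companion.exists():
                raise FileNotFoundError(f"missing companion file: {companion}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_brainvision(
                header_path, preload=True, verbose="error"
            )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(
            f"could not parse {header_path} as BrainVision: {exc}"
        ) from exc

    samples = raw.get_data() * 1e6
    events = []
    counter = 0
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        m = re.search(r"Stimulus/S\s*(\d+)", desc)
        if m is None or int(m.group(1)) not in _CODE_TEXT_TYPES:
            continue
        counter += 1
        events.append(
            EventAnnotation(
                onset_s=float(onset),
                duration_s=float(duration) if duration > 0 else 1.0 / raw.info["sfreq"],
                stimulus_id=f"stim_{counter:04d}",
                text_type=_CODE_TEXT_TYPES[int(m.group(1))],
                trial_index=1,
            )
        )
    return Recording(
        participant_id=header_path.stem,
        montage=Montage(tuple(raw.ch_names)),
        sampling_rate_hz=float(raw.info["sfreq"]),
        samples=samples,
        events=events,
    )


# ---------------------------------------------------------------------------
# feature tables (TSV)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_features_table(features: list, path: str | Path) -> Path:
    """Write per-(stimulus, channel) spectral features as a TSV table.

    One row per feature object; decimal rendering at 10 significant digits,
    which :func:`read_features_table` inverts bit-exactly at that precision.
    All features must share one frequency grid.
    """
    from .spectral import BAND_NAMES

    path = Path(path)
    if features:
        grid = features[0].freqs_hz
        for f in features:
            if len(f.freqs_hz) != len(grid) or not np.allclose(f.freqs_hz, grid):
                raise ContractError("features have heterogeneous frequency grids")
    else:
        grid = np.array([])

    id_cols = ["participant_id", "stimulus_id", "text_type", "channel"]
    psd_cols = [f"psd_{f:g}hz" for f in grid]
    abs_cols = [f"abs_{b}" for b in BAND_NAMES]
    rel_cols = [f"rel_{b}" for b in BAND_NAMES]
    header = id_cols + psd_cols + abs_cols + rel_cols + ["brain_rate_hz"]

    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for f in features:
            row = [f.participant_id, f.stimulus_id, f.text_type, f.channel]
            row += [_FLOAT_FMT % v for v in f.psd_abs]
            row += [_FLOAT_FMT % v for v in f.band_abs]
            row += [_FLOAT_FMT % v for v in f.band_rel]
            row.append(_FLOAT_FMT % f.brain_rate_hz)
            fh.write("\t".join(row) + "\n")
    return path


def read_features_table(path: str | Path) -> list:
    from .spectral import BAND_NAMES, SpectralFeatures

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        psd_cols = [c for c in header if c.startswith("psd_")]
        grid = np.array([float(c[4:-2]) for c in psd_cols])
        n_psd, n_b = len(psd_cols), len(BAND_NAMES)
        out = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            vals = np.array([float(v) for v in parts[4:]])
            out.append(
                SpectralFeatures(
                    participant_id=parts[0],
                    stimulus_id=parts[1],
                    text_type=parts[2],
                    channel=parts[3],
                    freqs_hz=grid,
                    psd_abs=vals[:n_psd],
                    band_abs=vals[n_psd : n_psd + n_b],
                    band_rel=vals[n_psd + n_b : n_psd + 2 * n_b],
                    brain_rate_hz=float(vals[-1]),
                )
            )
    return out


def write_metadata_table(metadata: list[ParticipantMetadata], path: str | Path) -> Path:
    path = Path(path)
    cols = ["participant_id", *GROUP_VARIABLES]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for m in metadata:
            fh.write("\t".join(getattr(m, c) for c in cols) + "\n")
    return path


def read_metadata_table(path: str | Path) -> list[ParticipantMetadata]:
    path = Path(path)
    out = []
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = dict(zip(cols, line.rstrip("\n").split("\t")))
            out.append(ParticipantMetadata(**parts))
    return out
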