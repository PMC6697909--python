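"""Calibrated WAV input/output and breath-phase annotation files.

The recording protocol paces subjects through deep breaths (nominally eight
breaths of 2 s inspiration + 2 s expiration) recorded at two posterior-base
sites, one single-channel recording per site, 16-bit PCM at 44.1 kHz.
Times are seconds (floats), sample indices are 0-based, and all intervals
are half-open ``[start, end)`` so segmentation at phase boundaries is
unambiguous.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile

SITE_LABELS = ("left_posterior_base", "right_posterior_base", "other")

#: columns of the breath-phase annotation CSV
PHASE_COLUMNS = ("recording_id", "breath_index", "kind", "start_s", "end_s")
#: columns of the crackle-event annotation CSV
EVENT_COLUMNS = (
    "recording_id", "breath_index", "onset_s", "relative_onset", "tercile",
    "tcd_ms", "idw_ms", "ldw_ms", "a1", "a2", "a3", "is_fine",
)


class AudioFormatError(ValueError):
    """Raised for unreadable, compressed, or policy-rejected audio files."""


@dataclass
class AudioRecording:
    """Single-channel audio with sampling metadata.

    ``samples`` are dimensionless amplitudes in ``[-1, 1)``; absolute
    calibration (the protocol's 94 dB / 1 kHz reference) is metadata only
    because every downstream feature except the raw deflection amplitudes
    is scale-invariant.
    """

    samples: np.ndarray
    fs: float
    bit_depth: int = 16
    channel_count: int = 1
    site_label: str = "other"
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("AudioRecording holds exactly one channel")
        if self.site_label not in SITE_LABELS:
            raise ValueError(f"unknown site label {self.site_label!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class BreathPhase:
    """One inspiratory or expiratory phase, half-open interval in seconds."""

    kind: str  # "inspiration" | "expiration"
    start_s: float
    end_s: float
    index: int  # 0-based breath number

    def __post_init__(self) -> None:
        if self.kind not in ("inspiration", "expiration"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if not 0.0 <= self.start_s < self.end_s:
            raise ValueError(
                f"need 0 <= start < end, got [{self.start_s}, {self.end_s})")
        if self.index < 0:
            raise ValueError("breath index must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def validate_phases(phases: Sequence[BreathPhase]) -> None:
    """Check time order and non-overlap of a phase sequence."""
    for prev, cur in zip(phases, phases[1:]):
        if cur.start_s < prev.end_s:
            raise ValueError(
                f"phases overlap: [{prev.start_s}, {prev.end_s}) and "
                f"[{cur.start_s}, {cur.end_s})")


def protocol_phases(n_breaths: int = 8, t_insp_s: float = 2.0,
                    t_exp_s: float = 2.0) -> list[BreathPhase]:
    """Breath phases implied by the paced-breathing protocol.

    Alternating inspiration/expiration starting at t = 0; the default
    (8 breaths, 2 s + 2 s) covers the nominal 32 s recording.
    """
    if n_breaths < 1:
        raise ValueError("need at least one breath")
    if t_insp_s <= 0 or t_exp_s <= 0:
        raise ValueError("phase durations must be positive")
    phases = []
    t = 0.0
    for b in range(n_breaths):
        phases.append(BreathPhase("inspiration", t, t + t_insp_s, b))
        t += t_insp_s
        phases.append(BreathPhase("expiration", t, t + t_exp_s, b))
        t += t_exp_s
    return phases


def inspirations(phases: Iterable[BreathPhase]) -> list[BreathPhase]:
    return [p for p in phases if p.kind == "inspiration"]


# ---------------------------------------------------------------------------
# WAV I/O

_INT_SCALES = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31}


def read_wav(path, multichannel: str = "reject",
             site_label: str = "other") -> AudioRecording | list[AudioRecording]:
    """Read a PCM WAV file into an :class:`AudioRecording`.

    Integer PCM is rescaled to ``[-1, 1)``.  ``multichannel`` selects the
    policy for files with more than one channel: ``"reject"`` (default,
    the protocol records one site per file), ``"first_channel"``, or
    ``"split"`` (returns one recording per channel).
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except Exception as exc:  # wavfile raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot read {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"{path} contains no samples")

    if data.dtype in _INT_SCALES:
        bit_depth = data.dtype.itemsize * 8
        floats = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        bit_depth = 8
        floats = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        bit_depth = data.dtype.itemsize * 8
        floats = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported sample format {data.dtype}")

    rid = path.stem

    def mono(x: np.ndarray, suffix: str = "") -> AudioRecording:
        return AudioRecording(x, fs=float(fs), bit_depth=bit_depth,
                              site_label=site_label, recording_id=rid + suffix)

    if floats.ndim == 1:
        return mono(floats)
    n_ch = floats.shape[1]
    if multichannel == "reject":
        raise AudioFormatError(
            f"{path} has {n_ch} channels; policy is 'reject'")
    if multichannel == "first_channel":
        return mono(floats[:, 0])
    if multichannel == "split":
        return [mono(floats[:, c], f"_ch{c}") for c in range(n_ch)]
    raise ValueError(f"unknown multichannel policy {multichannel!r}")


def write_wav(path, recording: AudioRecording, bit_depth: int = 16) -> None:
    """Write a recording as integer PCM WAV (default 16-bit)."""
    if bit_depth != 16:
        raise NotImplementedError("only 16-bit output is supported")
    scaled = np.clip(np.round(recording.samples * 2 ** 15),
                     -(2 ** 15), 2 ** 15 - 1).astype(np.int16)
    wavfile.write(Path(path), int(round(recording.fs)), scaled)


# ---------------------------------------------------------------------------
# Annotation CSVs

def write_annotations(phases: Sequence[BreathPhase], events: Sequence,
                      phases_path, events_path,
                      recording_id: str = "") -> None:
    """Write breath phases and crackle events as two CSV files.

    Times are written with microsecond precision (9 significant decimals)
    so a read/write cycle is lossless at the 1 us level.  ``events`` may be
    any sequence of objects with the :data:`EVENT_COLUMNS` attributes
    (e.g. :class:`crackletrack.crackle_features.CrackleEvent`).
    """
    validate_phases(sorted(phases, key=lambda p: p.start_s))
    with open(phases_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PHASE_COLUMNS)
        for p in phases:
            w.writerow([recording_id, p.index, p.kind,
                        f"{p.start_s:.9f}", f"{p.end_s:.9f}"])
    with open(events_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for e in events:
            w.writerow([
                recording_id, getattr(e, "breath_index", ""),
                f"{e.onset_s:.9f}", f"{e.relative_onset:.9f}", e.tercile,
                f"{e.tcd_ms:.9f}", f"{e.idw_ms:.9f}", f"{e.ldw_ms:.9f}",
                f"{e.a1:.9f}", f"{e.a2:.9f}", f"{e.a3:.9f}",
                int(bool(e.is_fine)),
            ])


def read_phase_annotations(phases_path) -> list[BreathPhase]:
    """Read a breath-phase CSV written by :func:`write_annotations`."""
    phases = []
    with open(phases_path, newline="") as fh:
        for row in csv.DictReader(fh):
            phases.append(BreathPhase(row["kind"], float(row["start_s"]),
                                      float(row["end_s"]),
                                      int(row["breath_index"])))
    validate_phases(sorted(phases, key=lambda p: p.start_s))
    return phases
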