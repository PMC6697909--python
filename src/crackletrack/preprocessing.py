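"""Band limiting and inspiratory-segment extraction.

Breath sounds are analyzed in the 100–2000 Hz band to suppress ambient and
muscle noise.  Filtering is zero-phase (forward-backward Butterworth) so
crackle onset times — the basis of the early/mid/late timing feature — are
not shifted by group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .audio_io import AudioRecording, BreathPhase


@dataclass(frozen=True)
class FilterSettings:
    low_hz: float = 100.0
    high_hz: float = 2000.0
    order: int = 4
    kind: str = "bandpass"

    def validate(self, fs: float) -> None:
        if self.kind != "bandpass":
            raise ValueError("only bandpass filtering is supported")
        if not 0 < self.low_hz < self.high_hz < fs / 2:
            raise ValueError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) "
                f"< Nyquist ({fs / 2})")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def design_sos(settings: FilterSettings, fs: float) -> np.ndarray:
    settings.validate(fs)
    return signal.butter(settings.order, [settings.low_hz, settings.high_hz],
                         btype="bandpass", fs=fs, output="sos")


def bandpass(recording: AudioRecording,
             settings: FilterSettings = FilterSettings()) -> AudioRecording:
    """Zero-phase band limiting; output length equals input length."""
    sos = design_sos(settings, recording.fs)
    filtered = signal.sosfiltfilt(sos, recording.samples)
    return replace(recording, samples=filtered)


def bandpass_array(x: np.ndarray, fs: float,
                   settings: FilterSettings = FilterSettings()) -> np.ndarray:
    """Zero-phase band limiting of a bare sample array."""
    return signal.sosfiltfilt(design_sos(settings, fs), x)


def extract_phase(recording: AudioRecording, phase: BreathPhase) -> np.ndarray:
    """Samples in ``[start_s, end_s)``; length ``round(duration * fs)``."""
    fs = recording.fs
    if phase.end_s > recording.duration_s + 0.5 / fs:
        raise ValueError(
            f"phase ends at {phase.end_s} s but recording lasts "
            f"{recording.duration_s} s")
    start = int(round(phase.start_s * fs))
    length = int(round((phase.end_s - phase.start_s) * fs))
    if length < 1:
        raise ValueError("zero-length phase")
    return recording.samples[start:start + length]
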