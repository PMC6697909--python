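"""Inspiratory power spectrum and percentile frequencies F50/F95/F99.

The percentile frequency Fq is the frequency below which q% of the total
band-limited (100-2000 Hz) signal power is accumulated; F99 tracks the
upper edge of the crackle spectrum and is the headline frequency feature.
Spectra are Welch-averaged modified periodograms (Hann window, default
4096 samples with 50% overlap, ~10.8 Hz resolution at 44.1 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio_io import AudioRecording, BreathPhase, inspirations
from .preprocessing import extract_phase

DEFAULT_BAND = (100.0, 2000.0)


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray   # ascending grid, restricted to the band
    power: np.ndarray      # non-negative, same length
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.shape != self.power.shape:
            raise ValueError("frequency grid and power must align")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def resolution_hz(self) -> float:
        return float(np.median(np.diff(self.freqs_hz)))

    @property
    def total_power(self) -> float:
        return float(self.power.sum())


@dataclass(frozen=True)
class PercentileFrequencies:
    f50_hz: float
    f95_hz: float
    f99_hz: float

    def __post_init__(self) -> None:
        if not self.f50_hz <= self.f95_hz <= self.f99_hz:
            raise ValueError("percentile frequencies must be monotone")


@dataclass(frozen=True)
class SpectralSettings:
    window_len: int = 4096
    overlap: float = 0.5
    band: tuple[float, float] = DEFAULT_BAND


def power_spectrum(segment: np.ndarray, fs: float,
                   settings: SpectralSettings = SpectralSettings()
                   ) -> PowerSpectrum:
    """Welch power spectrum of a segment, truncated to the analysis band."""
    x = np.asarray(segment, dtype=float)
    nper = settings.window_len
    if x.size < nper:
        raise ValueError(
            f"segment ({x.size} samples) shorter than window ({nper})")
    freqs, pxx = signal.welch(x, fs=fs, window="hann", nperseg=nper,
                              noverlap=int(nper * settings.overlap))
    lo, hi = settings.band
    keep = (freqs >= lo) & (freqs <= hi)
    return PowerSpectrum(freqs[keep], pxx[keep], band=settings.band)


def percentile_frequency(spectrum: PowerSpectrum, q: float,
                         interpolate: bool = False) -> float:
    """Smallest grid frequency accumulating >= q of the total bin power.

    The default right-continuous step rule makes the value deterministic
    on discrete spectra; ``interpolate=True`` instead interpolates
    linearly within the bin that crosses the q-quantile.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    total = spectrum.total_power
    if total <= 0:
        raise ValueError("percentile frequency undefined for zero power")
    cum = np.cumsum(spectrum.power)
    target = q * total
    idx = int(np.searchsorted(cum, target - 1e-12 * total))
    idx = min(idx, cum.size - 1)
    if not interpolate or idx == 0:
        return float(spectrum.freqs_hz[idx])
    prev = cum[idx - 1]
    frac = (target - prev) / max(cum[idx] - prev, 1e-300)
    f0, f1 = spectrum.freqs_hz[idx - 1], spectrum.freqs_hz[idx]
    return float(f0 + frac * (f1 - f0))


def percentiles_from_spectrum(spectrum: PowerSpectrum) -> PercentileFrequencies:
    return PercentileFrequencies(
        f50_hz=percentile_frequency(spectrum, 0.50),
        f95_hz=percentile_frequency(spectrum, 0.95),
        f99_hz=percentile_frequency(spectrum, 0.99))


def average_spectra(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Average power across segments on a common grid."""
    if not spectra:
        raise ValueError("no spectra to average")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.freqs_hz.shape != ref.freqs_hz.shape or \
                not np.allclose(s.freqs_hz, ref.freqs_hz):
            raise ValueError("spectra live on different frequency grids")
    mean_power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(ref.freqs_hz.copy(), mean_power, band=ref.band)


def patient_percentiles(recordings: AudioRecording | list[AudioRecording],
                        phases_by_recording: list[BreathPhase] | list[list[BreathPhase]],
                        settings: SpectralSettings = SpectralSettings()
                        ) -> PercentileFrequencies:
    """F50/F95/F99 of one patient.

    Power spectra of every inspiratory segment from every recording site
    are averaged first (the percentiles describe the *total* accumulated
    power), then the percentile frequencies are read off the mean
    spectrum.
    """
    if isinstance(recordings, AudioRecording):
        recordings = [recordings]
        phases_by_recording = [phases_by_recording]  # type: ignore[list-item]
    spectra = []
    for rec, phases in zip(recordings, phases_by_recording):
        for phase in inspirations(phases):
            seg = extract_phase(rec, phase)
            spectra.append(power_spectrum(seg, rec.fs, settings))
    if not spectra:
        raise ValueError("patient has no inspiratory phases")
    return percentiles_from_spectrum(average_spectra(spectra))
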