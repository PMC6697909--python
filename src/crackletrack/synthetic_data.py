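"""Synthetic lung sounds and synthetic patient cohorts.

Two generators make every pipeline stage testable without clinical
recordings:

* **Audio** — breath noise (band-limited, half-sine envelope per phase,
  inspiration louder than expiration) with exponentially damped sinusoid
  crackles inserted at known onsets.  The damped sinusoid
  ``s(t) = A * polarity * sin(2*pi*f0*t) * exp(-t/tau)`` has closed-form
  metrology (IDW = 1/(2 f0), 2CD = 2/f0, zero crossings at k/(2 f0)), so
  detector and waveform measurements can be checked against analytic truth.

* **Cohorts** — per-patient feature tables whose group-wise medians and
  interquartile ranges are calibrated, via quartile-matched lognormals, to
  the published honeycombing (n = 24) vs non-honeycombing (n = 47)
  contrast, with onset terciles drawn from the published category counts.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .audio_io import AudioRecording, BreathPhase, inspirations
from .crackle_features import CrackleEvent, classify_tercile
from .preprocessing import FilterSettings, bandpass_array

Z75 = stats.norm.ppf(0.75)  # standard normal 75th-percentile deviate

SNR_WINDOW_S = 0.020  # noise-power window at crackle onset


# ---------------------------------------------------------------------------
# crackle waveform

@dataclass(frozen=True)
class CrackleSpec:
    """One synthetic crackle: damped sinusoid starting at ``onset_s``."""

    onset_s: float
    f0: float = 400.0        # oscillation frequency, Hz (analysis band)
    tau_s: float = 0.005     # exponential decay constant, s
    amplitude: float = 1.0   # peak scale (relative weight under finite SNR)
    polarity: int = 1

    def __post_init__(self) -> None:
        if not 100 <= self.f0 <= 2000:
            raise ValueError(f"f0 = {self.f0} outside the 100-2000 Hz band")
        if self.tau_s <= 0 or self.amplitude < 0:
            raise ValueError("tau_s must be positive, amplitude non-negative")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")

    @property
    def idw_ms(self) -> float:
        return 1e3 / (2 * self.f0)

    @property
    def tcd_ms(self) -> float:
        return 2e3 / self.f0

    def peak_magnitudes(self, n: int = 3) -> list[float]:
        """Analytic |s| peaks of deflections 1..n (at tan(w t) = w tau)."""
        w = 2 * math.pi * self.f0
        t0 = math.atan(w * self.tau_s) / w
        out = []
        for k in range(n):
            t = t0 + k * math.pi / w
            out.append(self.amplitude * abs(math.sin(w * t))
                       * math.exp(-t / self.tau_s))
        return out


def crackle_waveform(spec: CrackleSpec, fs: float,
                     duration_s: float) -> np.ndarray:
    """Sampled damped-sinusoid crackle of ``round(duration_s * fs)`` samples."""
    if fs < 4 * spec.f0:
        raise ValueError(
            f"fs = {fs} Hz undersamples a {spec.f0} Hz crackle (need >= 4 f0)")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    return (spec.amplitude * spec.polarity
            * np.sin(2 * np.pi * spec.f0 * t) * np.exp(-t / spec.tau_s))


# ---------------------------------------------------------------------------
# breath audio

def synth_breath(fs: float, phases: list[BreathPhase],
                 crackles: list[CrackleSpec], snr_db: float = 20.0,
                 seed: int = 0, site_label: str = "other",
                 recording_id: str = "synthetic",
                 ) -> tuple[AudioRecording, list[CrackleEvent]]:
    """Breath-sound recording with inserted crackles and ground truth.

    Breath noise is white noise band-limited to 100-1000 Hz with a
    half-sine amplitude envelope per phase (expiration at 40% of the
    inspiratory gain).  Every crackle onset must fall inside an
    inspiratory phase.  ``snr_db`` is the mean crackle power over the
    breath-noise power, both measured in a 20 ms window starting at the
    onset; ``snr_db = inf`` disables the noise entirely.  Returns the recording and the analytic
    ground-truth events.
    """
    total_s = max(p.end_s for p in phases)
    n = int(round(total_s * fs))
    insp = inspirations(phases)

    # assign each crackle to its inspiration up front (validation)
    homes: list[BreathPhase] = []
    for c in crackles:
        home = next((p for p in insp if p.start_s <= c.onset_s < p.end_s),
                    None)
        if home is None:
            raise ValueError(
                f"crackle onset {c.onset_s} s outside every inspiration")
        homes.append(home)

    def _unit_window_power(c: CrackleSpec) -> float:
        # mean power of the unit-amplitude crackle over the SNR window
        w = crackle_waveform(
            CrackleSpec(c.onset_s, c.f0, c.tau_s, 1.0, c.polarity),
            fs, SNR_WINDOW_S)
        return float(np.mean(w ** 2))

    noisy = math.isfinite(snr_db)
    if noisy:
        rng = np.random.default_rng(seed)
        noise = bandpass_array(rng.standard_normal(n), fs,
                               FilterSettings(100.0, 1000.0, 4))
        envelope = np.zeros(n)
        for p in phases:
            i0 = int(round(p.start_s * fs))
            i1 = int(round(p.end_s * fs))
            gain = 1.0 if p.kind == "inspiration" else 0.4
            envelope[i0:i1] = gain * np.sin(
                np.pi * np.arange(i1 - i0) / max(i1 - i0, 1))
        noise *= envelope
    else:
        noise = np.zeros(n)

    samples = noise.copy()
    events: list[CrackleEvent] = []
    for c, home in zip(crackles, homes):
        if noisy:
            i0 = int(round(c.onset_s * fs))
            i1 = min(n, i0 + int(round(SNR_WINDOW_S * fs)))
            p_noise = float(np.mean(noise[i0:i1] ** 2)) if i1 > i0 else 0.0
            # SNR = mean crackle power / noise power, both over the 20 ms
            # window starting at the onset
            p_unit = _unit_window_power(c)
            scale = math.sqrt(max(p_noise, 1e-30) * 10 ** (snr_db / 10)
                              / max(p_unit, 1e-30))
        else:
            scale = 1.0
        eff = CrackleSpec(c.onset_s, c.f0, c.tau_s, c.amplitude * scale,
                          c.polarity)
        # support long enough that the truncation step is inaudible
        # (exp(-16) of the peak) and cannot register as a transient
        dur = min(max(16 * c.tau_s, 4 / c.f0), total_s - c.onset_s)
        wave = crackle_waveform(eff, fs, dur)
        i0 = int(round(c.onset_s * fs))
        samples[i0:i0 + wave.size] += wave[:max(0, n - i0)]

        rel = (c.onset_s - home.start_s) / home.duration_s
        a1, a2, a3 = eff.peak_magnitudes(3)
        events.append(CrackleEvent(
            onset_s=c.onset_s, relative_onset=rel,
            tercile=classify_tercile(rel), tcd_ms=c.tcd_ms, idw_ms=c.idw_ms,
            ldw_ms=c.idw_ms, a1=a1, a2=a2, a3=a3, breath_index=home.index))

    peak = float(np.max(np.abs(samples))) if samples.size else 0.0
    if peak > 0:
        samples /= 1.1 * peak  # headroom for 16-bit output
        for e in events:
            e.a1 /= 1.1 * peak
            e.a2 /= 1.1 * peak
            e.a3 /= 1.1 * peak
    rec = AudioRecording(samples, fs=fs, site_label=site_label,
                         recording_id=recording_id)
    return rec, events


# ---------------------------------------------------------------------------
# cohort generation

def quartiles_to_lognormal(median: float, q1: float,
                           q3: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose quartiles equal the given triple.

    mu = ln(median); sigma = ln(q3/q1) / (2 z_0.75).  Raises on
    non-monotone quartiles.
    """
    if not 0 < q1 < median < q3:
        raise ValueError(
            f"need 0 < q1 < median < q3, got ({q1}, {median}, {q3})")
    return math.log(median), math.log(q3 / q1) / (2 * Z75)


def _upper_half_lognormal(median: float, q3: float) -> tuple[float, float]:
    # For printed summaries where rounding collapsed q1 onto the median,
    # calibrate the spread from the upper quartile alone.
    if not 0 < median < q3:
        raise ValueError("need 0 < median < q3")
    return math.log(median), math.log(q3 / median) / Z75


GROUPS = ("honeycombing", "non_honeycombing")

#: published per-group median [q1-q3] summaries used for calibration
_TABLE2 = {
    "count_per_insp": {"honeycombing": (21.5, 14.7, 30.3),
                       "non_honeycombing": (8.0, 3.3, 13.7)},
    "f99_hz": {"honeycombing": (841.0, 782.0, 870.0),
               "non_honeycombing": (689.0, 674.0, 821.0)},
    "f95_hz": {"honeycombing": (527.0, 442.0, 679.0),
               "non_honeycombing": (411.0, 362.0, 457.0)},
    "f50_hz": {"honeycombing": (259.0, 233.0, 289.0),
               "non_honeycombing": (237.0, 220.0, 267.0)},
    "tcd_ms": {"honeycombing": (5.5, 5.4, 6.4),
               "non_honeycombing": (7.0, 5.5, 7.8)},
    "ldw_ms": {"honeycombing": (1.8, 1.5, 2.0),
               "non_honeycombing": (2.0, 2.0, 2.5)},
}

_TABLE1_AGE = {"honeycombing": (77.0, 69.0, 79.0),
               "non_honeycombing": (67.5, 58.2, 74.5)}


def _default_dists() -> dict:
    dists: dict = {}
    for feat, by_group in _TABLE2.items():
        dists[feat] = {}
        for g, (med, q1, q3) in by_group.items():
            if q1 < med:
                dists[feat][g] = quartiles_to_lognormal(med, q1, q3)
            else:  # rounding artifact: q1 == median in the printed table
                dists[feat][g] = _upper_half_lognormal(med, q3)
    return dists


@dataclass
class CohortSpec:
    """Synthetic-cohort parameters, calibrated by default to the published
    group contrast (24 honeycombing vs 47 non-honeycombing patients)."""

    n_honeycombing: int = 24
    n_non_honeycombing: int = 47
    #: feature -> group -> (mu, sigma) of a lognormal
    lognormal_dists: dict = field(default_factory=_default_dists)
    #: group -> (p_early, p_mid, p_late); published counts 20/4/0 and 12/27/8
    tercile_probs: dict = field(default_factory=lambda: {
        "honeycombing": (20 / 24, 4 / 24, 0.0),
        "non_honeycombing": (12 / 47, 27 / 47, 8 / 47)})
    #: group -> (center, scale) of a normal for age, quartile-matched
    age_dists: dict = field(default_factory=lambda: {
        g: (med, (q3 - q1) / (2 * Z75))
        for g, (med, q1, q3) in _TABLE1_AGE.items()})
    #: loading of the latent disease-severity factor on every feature's
    #: Gaussian copula score (signed per feature below); real patients'
    #: feature levels co-move with severity, and without this shared
    #: factor the joint distribution would be unrealistically separable
    severity_loading: float = 0.7
    #: extra shared factor among the three percentile frequencies
    freq_loading: float = 0.51
    #: direction each feature moves with increasing severity
    severity_signs: dict = field(default_factory=lambda: {
        "count_per_insp": 1.0, "f99_hz": 1.0, "f95_hz": 1.0, "f50_hz": 1.0,
        "tcd_ms": -1.0, "ldw_ms": -1.0})
    age_severity_loading: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for g, probs in self.tercile_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"tercile probabilities for {g} must sum to 1")
        for feat, by_group in self.lognormal_dists.items():
            for g, (_, sigma) in by_group.items():
                if sigma <= 0:
                    raise ValueError(f"sigma for {feat}/{g} must be positive")
        if self.severity_loading ** 2 + self.freq_loading ** 2 >= 1:
            raise ValueError("factor loadings must leave residual variance")


def synth_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Draw a per-patient feature table from a :class:`CohortSpec`.

    A latent disease-severity factor loads (with the signs in
    ``severity_signs``) on every continuous feature's copula score, and
    the three percentile frequencies share an extra common factor, so
    features are rank-correlated within patients the way they are across
    real patients; each feature's marginal stays exactly the calibrated
    lognormal.  Onset terciles are drawn from the per-group categorical
    probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sizes = {"honeycombing": spec.n_honeycombing,
             "non_honeycombing": spec.n_non_honeycombing}
    lam_s, lam_f = spec.severity_loading, spec.freq_loading
    pid = 0
    for g in GROUPS:
        n = sizes[g]
        z_sev = rng.standard_normal(n)
        z_freq = rng.standard_normal(n)
        feats = {}
        for feat, by_group in spec.lognormal_dists.items():
            mu, sigma = by_group[g]
            sign = spec.severity_signs.get(feat, 0.0)
            is_freq = feat in ("f50_hz", "f95_hz", "f99_hz")
            lam2 = (lam_s * sign) ** 2 + (lam_f ** 2 if is_freq else 0.0)
            z = (sign * lam_s * z_sev
                 + (lam_f * z_freq if is_freq else 0.0)
                 + math.sqrt(max(1.0 - lam2, 0.0)) * rng.standard_normal(n))
            feats[feat] = np.exp(mu + sigma * z)
        for col in ("f50_hz", "f95_hz", "f99_hz"):
            if col in feats:
                feats[col] = np.clip(feats[col], 101.0, 1999.0)
        terciles = rng.choice(["early", "mid", "late"], size=n,
                              p=spec.tercile_probs[g])
        center, scale = spec.age_dists[g]
        lam_a = spec.age_severity_loading
        ages = center + scale * (lam_a * z_sev
                                 + math.sqrt(1 - lam_a ** 2)
                                 * rng.standard_normal(n))
        for i in range(n):
            row = {"patient_id": f"P{pid:03d}", "group": g,
                   "onset_tercile": terciles[i],
                   "age_y": float(ages[i])}
            row.update({feat: float(v[i]) for feat, v in feats.items()})
            rows.append(row)
            pid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rater fixtures

def synth_ratings(n_items: int, n_raters: int, prevalence: float,
                  agreement_level: float, seed: int = 0) -> pd.DataFrame:
    """Binary ratings (items x raters) with tunable inter-rater agreement.

    Each item has a latent true label ~ Bernoulli(prevalence); each rater
    reports it flipped with probability ``(1 - agreement_level) / 2``, so
    ``agreement_level = 1`` gives identical raters.
    """
    if n_raters < 2:
        raise ValueError("agreement is undefined for a single rater")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0 <= agreement_level <= 1:
        raise ValueError("agreement_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = rng.random(n_items) < prevalence
    p_flip = (1 - agreement_level) / 2
    flips = rng.random((n_items, n_raters)) < p_flip
    ratings = truth[:, None] ^ flips
    return pd.DataFrame(ratings.astype(int),
                        columns=[f"rater_{r}" for r in range(n_raters)])
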