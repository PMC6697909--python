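import math

import numpy as np
import pytest
from scipy import stats

from crackletrack.audio_io import protocol_phases
from crackletrack.synthetic_data import (CohortSpec, CrackleSpec,
                                         crackle_waveform,
                                         quartiles_to_lognormal, synth_breath,
                                         synth_cohort, synth_ratings, Z75)

FS = 44100.0


# ---------------------------------------------------------------------------
# crackle waveform

def test_crackle_zero_crossings_match_analytic():
    spec = CrackleSpec(0.0, 400.0, 0.005)
    w = crackle_waveform(spec, FS, 0.02)
    s = np.sign(w)
    flips = np.nonzero(s[:-1] * s[1:] < 0)[0]
    crossings = [(i + w[i] / (w[i] - w[i + 1])) / FS for i in flips]
    expected = [(k + 1) / (2 * 400.0) for k in range(len(crossings))]
    assert np.allclose(crossings, expected, atol=1 / FS)
    assert spec.idw_ms == pytest.approx(1.25)
    assert spec.tcd_ms == pytest.approx(5.0)


def test_amplitude_ratio_against_dense_grid_oracle():
    spec = CrackleSpec(0.0, 400.0, 0.005)
    # oracle: argmax of |s(t)| on each half-cycle at 1 MHz sampling
    t = np.arange(int(1e6 * 0.01)) / 1e6
    s = np.abs(np.sin(2 * np.pi * 400 * t) * np.exp(-t / 0.005))
    half = 1 / (2 * 400.0)
    peaks = [s[(t >= k * half) & (t < (k + 1) * half)].max()
             for k in range(3)]
    a1, a2, a3 = spec.peak_magnitudes(3)
    assert a2 / a1 == pytest.approx(peaks[1] / peaks[0], abs=1e-3)
    assert a3 / a1 == pytest.approx(peaks[2] / peaks[0], abs=1e-3)
    assert a2 / a1 == pytest.approx(0.78, abs=0.02)


def test_crackle_waveform_edge_cases():
    assert np.all(crackle_waveform(CrackleSpec(0, 400, 0.005, 0.0), FS, 0.01)
                  == 0)
    with pytest.raises(ValueError):
        crackle_waveform(CrackleSpec(0, 1500.0, 0.005), 4000.0, 0.01)
    with pytest.raises(ValueError):
        CrackleSpec(0.0, 50.0, 0.005)  # below analysis band


# ---------------------------------------------------------------------------
# breath synthesis

def test_noise_free_breath_is_silent_outside_crackles():
    phases = protocol_phases(1, 2, 2)
    crackles = [CrackleSpec(t, 400.0, 0.005) for t in (0.5, 1.0, 1.5)]
    rec, truth = synth_breath(FS, phases, crackles, snr_db=float("inf"),
                              seed=0)
    assert len(truth) == 3
    n = rec.samples.size
    mask = np.zeros(n, dtype=bool)
    for c in crackles:
        i0 = int(round(c.onset_s * FS))
        mask[i0:i0 + int(16 * 0.005 * FS) + 1] = True
    assert np.any(rec.samples[mask] != 0)
    assert np.all(rec.samples[~mask] == 0)


def test_breath_ground_truth_and_determinism():
    phases = protocol_phases(2, 2, 2)
    rec0, truth0 = synth_breath(FS, phases, [], snr_db=10.0, seed=3)
    assert truth0 == []
    crackles = [CrackleSpec(0.5, 400.0, 0.005), CrackleSpec(4.5, 600.0, 0.004)]
    rec1, t1 = synth_breath(FS, phases, crackles, snr_db=10.0, seed=3)
    rec2, t2 = synth_breath(FS, phases, crackles, snr_db=10.0, seed=3)
    assert np.array_equal(rec1.samples, rec2.samples)  # bit-identical
    assert t1[0].tercile == "early" and t1[0].breath_index == 0
    assert t1[1].relative_onset == pytest.approx(0.25)
    assert t1[1].breath_index == 1


def test_crackle_outside_inspiration_rejected():
    phases = protocol_phases(1, 2, 2)
    with pytest.raises(ValueError):
        synth_breath(FS, phases, [CrackleSpec(3.0, 400.0, 0.005)])


def test_snr_definition_holds_in_generated_audio():
    # mean crackle power over the 20 ms onset window ~ snr * noise power
    phases = protocol_phases(1, 2, 2)
    spec = CrackleSpec(1.0, 400.0, 0.005)
    noise, _ = synth_breath(FS, phases, [], snr_db=10.0, seed=7)
    mix, _ = synth_breath(FS, phases, [spec], snr_db=10.0, seed=7)
    # both recordings are peak-normalized; recover the relative gain from
    # a crackle-free region, then isolate the crackle in noise units
    far = slice(int(0.3 * FS), int(0.5 * FS))
    alpha = np.median(noise.samples[far] / mix.samples[far])
    crackle = alpha * mix.samples - noise.samples
    i0, i1 = int(1.0 * FS), int(1.02 * FS)
    ratio = np.mean(crackle[i0:i1] ** 2) / np.mean(noise.samples[i0:i1] ** 2)
    assert 10 * np.log10(ratio) == pytest.approx(10.0, abs=1.0)


# ---------------------------------------------------------------------------
# cohort generation

def test_quartiles_to_lognormal_reference_values():
    mu, sigma = quartiles_to_lognormal(8.0, 3.3, 13.7)
    assert mu == pytest.approx(math.log(8.0))
    assert mu == pytest.approx(2.079, abs=1e-3)
    assert sigma == pytest.approx(1.055, abs=1e-3)
    mu2, sigma2 = quartiles_to_lognormal(21.5, 14.7, 30.3)
    assert mu2 == pytest.approx(3.068, abs=1e-3)
    assert sigma2 == pytest.approx(0.536, abs=1e-3)
    # IQR ratio is matched exactly by construction
    assert math.exp(2 * Z75 * sigma) == pytest.approx(13.7 / 3.3)


def test_quartiles_to_lognormal_validation():
    with pytest.raises(ValueError):
        quartiles_to_lognormal(8.0, 8.0, 13.7)  # median == q1
    with pytest.raises(ValueError):
        quartiles_to_lognormal(8.0, 9.0, 13.7)
    with pytest.raises(ValueError):
        quartiles_to_lognormal(-1.0, -2.0, 3.0)


def test_lognormal_monte_carlo_against_quantile_inversion():
    # sample quantiles converge to the analytic lognormal quantiles
    # exp(mu - z75 sigma), exp(mu), exp(mu + z75 sigma)
    mu, sigma = quartiles_to_lognormal(8.0, 3.3, 13.7)
    draws = np.exp(mu + sigma * np.random.default_rng(0).standard_normal(
        100_000))
    q1, med, q3 = np.percentile(draws, [25, 50, 75])
    assert med == pytest.approx(8.0, rel=0.05)
    assert q1 == pytest.approx(math.exp(mu - Z75 * sigma), rel=0.05)
    assert q3 == pytest.approx(math.exp(mu + Z75 * sigma), rel=0.05)


def test_cohort_shape_and_determinism():
    df = synth_cohort(CohortSpec(seed=5))
    assert len(df) == 71
    assert (df["group"] == "honeycombing").sum() == 24
    assert (df["group"] == "non_honeycombing").sum() == 47
    df2 = synth_cohort(CohortSpec(seed=5))
    assert df.equals(df2)
    # honeycombing group never starts late (published count 0)
    assert not (df.loc[df.group == "honeycombing", "onset_tercile"]
                == "late").any()


def test_cohort_marginal_medians_match_calibration():
    spec = CohortSpec(n_honeycombing=20000, n_non_honeycombing=20000, seed=2)
    df = synth_cohort(spec)
    non = df[df.group == "non_honeycombing"]
    hc = df[df.group == "honeycombing"]
    assert non["count_per_insp"].median() == pytest.approx(8.0, rel=0.03)
    assert hc["count_per_insp"].median() == pytest.approx(21.5, rel=0.03)
    assert hc["f99_hz"].median() == pytest.approx(841.0, rel=0.03)
    assert non["tcd_ms"].median() == pytest.approx(7.0, rel=0.03)


def test_cohort_tercile_frequencies_chi2_goodness_of_fit():
    spec = CohortSpec(n_honeycombing=0, n_non_honeycombing=100_000, seed=11)
    df = synth_cohort(spec)
    counts = df["onset_tercile"].value_counts()
    obs = [counts.get(k, 0) for k in ("early", "mid", "late")]
    expected = np.array([12 / 47, 27 / 47, 8 / 47]) * len(df)
    _, p = stats.chisquare(obs, expected)
    assert p > 0.001


def test_cohort_frequencies_rank_correlated():
    df = synth_cohort(CohortSpec(n_honeycombing=0, n_non_honeycombing=5000,
                                 seed=3))
    rho = df[["f50_hz", "f95_hz", "f99_hz"]].corr("spearman")
    assert (rho.to_numpy() > 0.6).all()


def test_cohort_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(tercile_probs={"honeycombing": (0.5, 0.2, 0.2),
                                  "non_honeycombing": (1 / 3,) * 3})
    with pytest.raises(ValueError):
        CohortSpec(severity_loading=0.9, freq_loading=0.6)


# ---------------------------------------------------------------------------
# rater fixtures

def test_ratings_agreement_one_gives_identical_raters():
    df = synth_ratings(50, 3, prevalence=0.3, agreement_level=1.0, seed=0)
    assert df.nunique(axis=1).max() == 1


def test_ratings_validation_and_determinism():
    with pytest.raises(ValueError):
        synth_ratings(10, 1, 0.5, 0.9)
    with pytest.raises(ValueError):
        synth_ratings(10, 2, 1.5, 0.9)
    a = synth_ratings(30, 2, 0.4, 0.8, seed=4)
    b = synth_ratings(30, 2, 0.4, 0.8, seed=4)
    assert a.equals(b)
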