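import numpy as np
import pytest

from crackletrack import CrackleSpec, protocol_phases, synth_breath

FS = 44100.0


@pytest.fixture(scope="session")
def noise_free_recording():
    """One 2 s + 2 s breath with three noise-free 400 Hz crackles."""
    phases = protocol_phases(1, 2.0, 2.0)
    crackles = [CrackleSpec(t, 400.0, 0.005) for t in (0.5, 1.0, 1.5)]
    rec, truth = synth_breath(FS, phases, crackles, snr_db=float("inf"),
                              seed=0)
    return rec, phases, truth


def place_crackles(rng, phases, per_insp, min_sep_s=0.03):
    """Uniform onsets in the central audible span of each inspiration."""
    onsets = []
    for p in phases:
        if p.kind != "inspiration":
            continue
        lo = p.start_s + 0.15 * p.duration_s
        hi = p.start_s + 0.90 * p.duration_s
        ts = np.sort(rng.uniform(lo, hi, per_insp))
        while np.any(np.diff(ts) < min_sep_s):
            ts = np.sort(rng.uniform(lo, hi, per_insp))
        onsets.extend(ts)
    return onsets


@pytest.fixture(scope="session")
def snr10_fixture():
    """Seeded 20-crackle recording at 10 dB SNR with ground-truth onsets."""
    rng = np.random.default_rng(1)
    phases = protocol_phases(4, 2.0, 2.0)
    onsets = place_crackles(rng, phases, per_insp=5)
    crackles = [CrackleSpec(t, float(rng.uniform(300, 700)),
                            float(rng.uniform(0.003, 0.008)))
                for t in onsets]
    rec, truth = synth_breath(FS, phases, crackles, snr_db=10.0, seed=1)
    return rec, phases, np.asarray(onsets)
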