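import numpy as np
import pytest

import ecgid as E
from ecgid.ablation import build_database

FS = 360.0


def gaussian_beat(morph, n=288, fs=FS, centre=None):
    """Clean sum-of-Gaussians beat on an n-sample grid with R at the centre."""
    centre = n // 2 if centre is None else centre
    t = np.arange(n) / fs
    x = np.zeros(n)
    for w in ("P", "Q", "R", "S", "T"):
        c = centre / fs + morph.wave_offsets[w]
        x += morph.wave_amplitudes[w] * np.exp(-0.5 * ((t - c) / morph.wave_widths[w]) ** 2)
    return x


@pytest.fixture(scope="session")
def clean_record():
    """One noise-free record with exact R ground truth."""
    spec = E.CohortSpec(
        n_subjects=2, sessions_per_subject=1, duration=20.0, snr_db=np.inf,
        baseline_amp=0.0, powerline_amp=0.0, seed=3,
    )
    return E.generate_cohort(spec)[0]


@pytest.fixture(scope="session")
def noisy_cohort():
    """10 subjects, 2 sessions, SNR 15 dB with wander and power-line terms."""
    spec = E.CohortSpec(n_subjects=10, sessions_per_subject=2, duration=30.0, snr_db=15.0, seed=2)
    return E.generate_cohort(spec)


@pytest.fixture(scope="session")
def trained_db(noisy_cohort):
    """Session-1 enrollment of the noisy cohort with a trained ML-5 gate."""
    return build_database(noisy_cohort, feature_mode="ml5")


@pytest.fixture(scope="session")
def cohort5():
    """Small 5-subject cohort for gate/oracle equivalence checks."""
    spec = E.CohortSpec(n_subjects=5, sessions_per_subject=2, duration=20.0, snr_db=15.0, seed=6)
    return E.generate_cohort(spec)
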