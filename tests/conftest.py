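import numpy as np
import pytest

from nirsicpp import (
    NoiseConfig,
    SubjectRecord,
    build_paradigm,
    canonical_hrf,
    forward_intensity,
    simulate_subject,
)


@pytest.fixture(scope="session")
def paradigm():
    return build_paradigm()


@pytest.fixture(scope="session")
def hrf():
    return canonical_hrf(1.0)


@pytest.fixture
def clean_subject():
    """Noise-free subject with known per-channel task amplitudes."""
    beta = np.linspace(0.2, 1.1, 10)
    return SubjectRecord("S-clean", "normal", "female", 10.5, 4.0, true_beta=beta)


@pytest.fixture
def clean_recording(clean_subject, paradigm, hrf):
    hemo = simulate_subject(clean_subject, paradigm, NoiseConfig.silent(), hrf=hrf, seed=11)
    return forward_intensity(hemo)


@pytest.fixture
def noisy_recording(paradigm, hrf):
    beta = np.full(10, 0.6)
    sub = SubjectRecord("S-noisy", "ICPP", "male", 11.0, 5.0, lh_iu_l=5.0,
                        fsh_iu_l=4.0, testosterone_nmol_l=12.0, true_beta=beta)
    hemo = simulate_subject(sub, paradigm, NoiseConfig(), hrf=hrf, seed=12)
    return forward_intensity(hemo)


def make_segments(n, n_ch=10, n_t=60, label_fn=lambda i: i % 2, seed=0, class_shift=0.0):
    """Random trial segments, optionally with a class mean shift."""
    from nirsicpp import TrialSegment

    rng = np.random.default_rng(seed)
    segs = []
    for i in range(n):
        lbl = label_fn(i)
        data = rng.normal(0, 1, (n_ch, n_t)) + (class_shift if lbl else -class_shift)
        segs.append(TrialSegment(f"X{i:03d}", i % 2, "HbO", data, lbl, "female"))
    return segs
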