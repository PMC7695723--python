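import numpy as np
import pytest

from dce_response import PhantomSpec, compute_enhancement, generate_dce_exam


def pair_count_auc(scores, labels) -> float:
    """Brute-force AUC: fraction of (positive, negative) pairs ranked
    concordantly, ties counted one half.  Independent of any ranking
    implementation under test."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def noise_free_exam():
    """One noise-free phantom exam: every tissue class has exact kinetics."""
    spec = PhantomSpec(noise_sd=0.0, seed=11)
    series, truth = generate_dce_exam(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def noise_free_maps(noise_free_exam):
    _, series, _ = noise_free_exam
    return compute_enhancement(series)
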