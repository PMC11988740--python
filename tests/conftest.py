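import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def pairwise_auc(pos_scores, neg_scores) -> float:
    """Exhaustive Mann-Whitney concordance: ties credited 0.5.

    Independent oracle for the trapezoidal AUC on small instances.
    """
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
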