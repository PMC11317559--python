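import numpy as np
import pytest

import markovworm as mw


@pytest.fixture(scope="session")
def small_worm():
    """A short default-condition synthetic worm with its ground truth."""
    cfg = mw.SyntheticWormConfig(duration_frames=8_000, seed=42)
    return mw.generate_posture_series(cfg)


@pytest.fixture(scope="session")
def worm_msm(small_worm):
    """Partition + transition model of the small worm (K=8, N=60, tau=8)."""
    series, gt = small_worm
    part = mw.partition(mw.delay_embed(series, 8), 60, seed=0)
    model = mw.estimate_transition_matrix(part.labels, 8, n_states=60, dt=series.dt)
    return part, model, series, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def best_label_match(a: np.ndarray, b: np.ndarray) -> float:
    """Accuracy of a against b maximized over label permutations (small sets)."""
    from itertools import permutations

    states = np.unique(b)
    best = 0.0
    for perm in permutations(states):
        mapped = np.asarray(perm)[np.searchsorted(states, b)]
        best = max(best, float(np.mean(a == mapped)))
    return best
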