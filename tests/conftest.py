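"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: tick
periodicity is scored by exhaustive period/phase enumeration, and AUC by
the exhaustive pairwise rank statistic.
"""

import numpy as np
import pytest

from thyroprep import PhantomSpec, generate_phantom


def brute_force_period(profile: np.ndarray, max_period: int | None = None,
                       dot_height: int = 2) -> int:
    """Best tick period of a 0/1 column profile by exhaustive search.

    For every candidate period p and phase, scores the product of the
    fraction of on-pixels explained by the phase grid (within the dot
    height) and the fraction of grid slots occupied, so degenerate tiny
    periods that trivially explain everything are penalized.
    """
    on = np.flatnonzero(profile)
    if on.size == 0:
        raise ValueError("empty profile")
    h = profile.size
    if max_period is None:
        max_period = h // 3
    best_p, best_score = 2, -1.0
    for p in range(2, max_period + 1):
        for phase in range(p):
            rel = (on - phase) % p
            explained = np.sum(rel < dot_height) / on.size
            slots = len(range(phase, h, p))
            fill = np.sum(rel < dot_height) / max(dot_height * slots, 1)
            score = explained * min(fill, 1.0)
            if score > best_score:
                best_score, best_p = score, p
    return best_p


def brute_force_auc(scores, truth) -> float:
    """P(score+ > score-) + 0.5 P(tie) over all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (pos.size * neg.size)


@pytest.fixture(scope="session")
def default_phantom():
    """One full-size phantom with all three artifact kinds."""
    return generate_phantom(PhantomSpec(), seed=7)


@pytest.fixture(scope="session")
def small_spec():
    """A small phantom spec for fast per-test generation."""
    return PhantomSpec(height=128, width=192, tick_spacing=10,
                       nodule_centre=(64, 70), nodule_axes=(18, 24))
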