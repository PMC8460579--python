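import numpy as np
import pandas as pd
import pytest

from binocsync.simulate import SimConfig, simulate_reading_session


@pytest.fixture(scope="session")
def small_session():
    """A small deterministic simulated session used across test modules."""
    cfg = SimConfig(n_participants=2, n_articles=2, pages_per_article=2, seed=7)
    return simulate_reading_session(cfg)


def random_stream(rng, n, t0=0, max_gap=50, max_dur=200):
    """A sorted, non-overlapping fixation stream of n intervals."""
    starts, ends = [], []
    t = t0 + int(rng.integers(0, max_gap))
    for _ in range(n):
        d = int(rng.integers(1, max_dur))
        starts.append(t)
        ends.append(t + d)
        t += d + int(rng.integers(1, max_gap))
    return np.array(starts), np.array(ends)


def brute_force_matching(ls, le, rs, re):
    """Exhaustive optimal non-crossing matching (oracle for the DP).

    Recursively considers, for each prefix pair, skipping either stream's
    last fixation or pairing the two last ones (if they overlap).  Returns
    the maximal total overlap.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == 0 or j == 0:
            return 0
        w = min(le[i - 1], re[j - 1]) - max(ls[i - 1], rs[j - 1])
        cands = [best(i - 1, j), best(i, j - 1)]
        if w > 0:
            cands.append(best(i - 1, j - 1) + w)
        return max(cands)

    return best(len(ls), len(rs))
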