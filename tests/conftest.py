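import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirscore import SyntheticConfig, generate, score_all

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study: 50 true + 150 false miRNAs, 30 samples, seed 0."""
    return generate(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_scores(default_dataset):
    d = default_dataset
    return score_all(d.mirna_matrix, d.annotation, d.precursor_matrix)


@pytest.fixture()
def tiny_matrix():
    return pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        index=["mir-a", "mir-b"],
        columns=["s1", "s2", "s3"],
    )


def spearman_bruteforce(x, y):
    """Rank-based Spearman via average ranks, independent of scipy."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def mannwhitney_u_bruteforce(x, y):
    """All-pairs U of group x: wins count 1, ties count 1/2."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u
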