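import itertools

import numpy as np
import pytest
from scipy import stats

from sisterdiv import core_io


@pytest.fixture(scope="session")
def table1():
    """The packaged 13-pair galler/non-galler comparison table."""
    return core_io.read_sister_table(core_io.packaged_table1_path())


@pytest.fixture()
def toy_tree():
    """((A:1,B:1):1,C:2); with unit richness."""
    return core_io.richness_tree_from_newick(
        "((A:1,B:1):1,C:2);", {"A": 1, "B": 1, "C": 1})


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)


def oracle_sign_permutation(contrasts):
    """Two-tailed randomization p by explicit iteration over sign tuples."""
    vals = [c for c in contrasts if c != 0]
    obs = abs(sum(vals))
    hits = 0
    for signs in itertools.product((1, -1), repeat=len(vals)):
        s = abs(sum(sg * v for sg, v in zip(signs, vals)))
        if s >= obs - 1e-9 * max(1.0, obs):
            hits += 1
    return hits / 2 ** len(vals)


def oracle_wilcoxon_exact(contrasts, alternative="two-sided"):
    """(W+, p) by explicit 2^m enumeration on tie-averaged ranks."""
    vals = np.asarray([c for c in contrasts if c != 0], dtype=float)
    ranks = stats.rankdata(np.abs(vals))
    w_plus = ranks[vals > 0].sum()
    w_minus = ranks.sum() - w_plus
    dist = []
    for signs in itertools.product((1, 0), repeat=len(vals)):
        dist.append(sum(r for sg, r in zip(signs, ranks) if sg))
    dist = np.asarray(dist)
    tol = 1e-9
    if alternative == "greater":
        p = np.mean(dist >= w_plus - tol)
    else:
        hi, lo = max(w_plus, w_minus), min(w_plus, w_minus)
        p = min(1.0, np.mean(dist >= hi - tol) + np.mean(dist <= lo + tol))
    return float(w_plus), float(p)
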