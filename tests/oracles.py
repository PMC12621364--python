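"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities through different code paths
(scipy log-pmfs, byte-wise diffs) than the implementation under test.
"""

import numpy as np
from scipy import stats


def lrt_oracle(group_a, group_b):
    """Overdispersion-scaled binomial LRT via explicit log-pmf sums."""
    m = np.array([x[0] for x in group_a + group_b], float)
    n = np.array([x[1] for x in group_a + group_b], float)
    grp = np.array([0] * len(group_a) + [1] * len(group_b))
    p_a = m[grp == 0].sum() / n[grp == 0].sum()
    p_b = m[grp == 1].sum() / n[grp == 1].sum()
    p_0 = m.sum() / n.sum()
    p_g = np.where(grp == 0, p_a, p_b)
    deviance = 2 * (
        stats.binom.logpmf(m, n, p_g).sum() - stats.binom.logpmf(m, n, p_0).sum()
    )
    den = n * p_g * (1 - p_g)
    pearson = np.where(den > 0, (m - n * p_g) ** 2 / np.where(den > 0, den, 1), 0).sum()
    phi = pearson / (len(m) - 2)
    if phi > 1:
        deviance = deviance / phi
    return 100 * (p_a - p_b), stats.chi2.sf(max(deviance, 0.0), 1)


def random_count_groups(rng, max_samples=5, max_cov=80):
    k = int(rng.integers(2, max_samples))
    ga = [(int(rng.integers(0, n + 1)), int(n)) for n in rng.integers(1, max_cov, k)]
    gb = [(int(rng.integers(0, n + 1)), int(n)) for n in rng.integers(1, max_cov, k)]
    return ga, gb
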