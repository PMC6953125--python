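"""Brute-force Jonckheere-Terpstra oracle: full label-permutation null.

Independent of the package's convolution-based exact null: enumerates
every distinct assignment of ordered group labels to the observed
values and computes the trend statistic with a quadratic double loop.
"""

import itertools

import numpy as np


def enumerate_jt_pmf(values, sizes):
    values = list(values)
    labels = [g for g, n in enumerate(sizes) for _ in range(n)]

    def u_of(perm):
        u = 0.0
        for i in range(len(values)):
            for j in range(len(values)):
                if perm[i] < perm[j]:
                    if values[i] < values[j]:
                        u += 1.0
                    elif values[i] == values[j]:
                        u += 0.5
        return u

    dist = {}
    for perm in set(itertools.permutations(labels)):
        u = u_of(perm)
        dist[u] = dist.get(u, 0) + 1
    total = sum(dist.values())
    return {u: c / total for u, c in dist.items()}


def oracle_two_sided_p(values, sizes):
    """Two-sided p (twice the smaller tail, capped at 1) from enumeration."""
    from zonepipe.zonation import jt_statistic

    pmf = enumerate_jt_pmf(values, sizes)
    groups = []
    start = 0
    for n in sizes:
        groups.append(np.asarray(values[start:start + n]))
        start += n
    u_obs = jt_statistic(groups)
    lower = sum(c for u, c in pmf.items() if u <= u_obs + 1e-9)
    upper = sum(c for u, c in pmf.items() if u >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))
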