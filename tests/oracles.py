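"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own algorithms: the change-point
oracle is an exhaustive search over all placements of up to two change
points, scored with a plain penalized residual-sum-of-squares rule and a
simple global noise estimate.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np


def rss_table_terms(x: np.ndarray):
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def rss(lo, hi):
        lo = np.asarray(lo)
        hi = np.asarray(hi)
        n = hi - lo
        s = csum[hi] - csum[lo]
        return (csum2[hi] - csum2[lo]) - s ** 2 / n

    return rss


def exhaustive_step_fit(x: np.ndarray, penalty: float = 30.0) -> Tuple[int, ...]:
    """Globally optimal change points (0, 1 or 2) under a penalized RSS.

    Enumerates every admissible placement; k grows while adding one more
    change point reduces the RSS by more than ``penalty`` times a robust
    global noise variance (median |first difference| scaled to SD).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    rss = rss_table_terms(x)
    d = np.abs(np.diff(x))
    sd = 1.4826 * np.median(d) / math.sqrt(2.0)
    var = sd * sd

    best = {0: ((), float(rss(0, n)))}

    ts = np.arange(1, n)
    cost1 = rss(0, ts) + rss(ts, n)
    k1 = int(np.argmin(cost1))
    best[1] = ((int(ts[k1]),), float(cost1[k1]))

    t1g, t2g = np.meshgrid(np.arange(1, n), np.arange(2, n), indexing="ij")
    valid = t1g < t2g
    total = np.where(
        valid,
        rss(0, t1g) + rss(np.where(valid, t1g, 0), np.where(valid, t2g, 1))
        + rss(t2g, n),
        np.inf)
    k2 = np.unravel_index(int(np.argmin(total)), total.shape)
    best[2] = ((int(t1g[k2]), int(t2g[k2])), float(total[k2]))

    k = 0
    while k < 2 and best[k][1] - best[k + 1][1] > penalty * var:
        k += 1
    return best[k][0]


def match_count_hungarian(pos_a: np.ndarray, pos_b: np.ndarray,
                          max_distance: float) -> int:
    """Maximum-cardinality min-cost matching within a distance cutoff."""
    from scipy.optimize import linear_sum_assignment
    if len(pos_a) == 0 or len(pos_b) == 0:
        return 0
    d = np.sqrt(((pos_a[:, None, :] - pos_b[None, :, :]) ** 2).sum(-1))
    big = 1e6
    cost = np.where(d <= max_distance, d, big)
    ri, ci = linear_sum_assignment(cost)
    return int((cost[ri, ci] < big).sum())
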