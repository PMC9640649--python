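"""Independent brute-force oracles used to verify the package's statistics.

These are deliberately separate from the implementation paths they check:
Fisher's exact test by exhaustive hypergeometric enumeration, BH by the
literal step-up definition, and the pooled t-test from the textbook
formula plus the t CDF.
"""

import math

import numpy as np
from scipy import stats


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the same margins.

    p = sum of hypergeometric probabilities of tables whose probability is
    <= that of the observed table (with a small relative tolerance).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x: int) -> float:
        # table [[x, r1-x], [c1-x, r2-(c1-x)]]
        return (
            math.comb(r1, x)
            * math.comb(r2, c1 - x)
            / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def bh_oracle(pvals) -> np.ndarray:
    """Literal step-up definition: q(i) = min_{j>=i} (m * p(j) / j)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = m * p[order] / np.arange(1, m + 1)
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        q[idx] = min(1.0, float(np.min(scaled[rank_pos:])))
    return q


def pooled_t_oracle(x, y) -> tuple[float, float]:
    """Textbook equal-variance two-sample t with the scipy t CDF."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = (
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    )
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * (1 - stats.t.cdf(abs(t), df))
    return t, p


def auc_rank_oracle(y_true, scores) -> float:
    """Mann-Whitney AUC: ties contribute 0.5 per discordant-free pair."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
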