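"""Independent brute-force oracles used across the suite.

Each function recomputes a statistic from first principles (explicit loops,
textbook formulas), deliberately sharing no code with the implementation it
checks.
"""

import numpy as np
from scipy import stats


def welch_oracle(x, y):
    """Textbook Welch t-test, step by step; returns (t, p) for mean(x)-mean(y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx = sum((v - x.mean()) ** 2 for v in x) / (nx - 1)
    vy = sum((v - y.mean()) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def bh_step_up(p, q):
    """Brute-force Benjamini-Hochberg: try every k explicitly."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def mixed_anova_oracle(y, condition):
    """Split-plot two-way ANOVA by explicit group means and nested loops.

    ``y`` is (n_units, n_timepoints); ``condition`` labels units.  Returns a
    dict of (ss, df_num, df_den, F) per effect.
    """
    y = np.asarray(y, float)
    condition = np.asarray(condition)
    conds = list(dict.fromkeys(condition.tolist()))
    g, (n, t) = len(conds), y.shape
    grand = y.mean()

    ss_cond = 0.0
    for c in conds:
        block = y[condition == c]
        ss_cond += block.shape[0] * t * (block.mean() - grand) ** 2
    ss_units = 0.0
    for c in conds:
        block = y[condition == c]
        for u in range(block.shape[0]):
            ss_units += t * (block[u].mean() - block.mean()) ** 2
    ss_time = 0.0
    for j in range(t):
        ss_time += n * (y[:, j].mean() - grand) ** 2
    ss_int = 0.0
    for c in conds:
        block = y[condition == c]
        for j in range(t):
            ss_int += block.shape[0] * (
                block[:, j].mean() - block.mean() - y[:, j].mean() + grand
            ) ** 2
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_units - ss_time - ss_int

    df_cond, df_units = g - 1, n - g
    df_time = t - 1
    df_int = (g - 1) * (t - 1)
    df_err = (n - g) * (t - 1)
    return {
        "condition": (ss_cond, df_cond, df_units,
                      (ss_cond / df_cond) / (ss_units / df_units)),
        "time": (ss_time, df_time, df_err,
                 (ss_time / df_time) / (ss_err / df_err)),
        "interaction": (ss_int, df_int, df_err,
                        (ss_int / df_int) / (ss_err / df_err)),
        "ss_total": ss_total,
    }
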