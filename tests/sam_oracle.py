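"""Independent brute-force oracle for the moderated-difference statistic
and its permutation q / local-FDR estimates.

Plain loops over explicit enumerations; deliberately shares no code with
the package implementation.
"""

import itertools
import math

import numpy as np


def d_statistic(values, mask2, s0):
    """Per-gene (d, s, log2fc) for one labelling, computed longhand."""
    d_out, s_out, fc_out = [], [], []
    idx2 = [j for j, m in enumerate(mask2) if m]
    idx1 = [j for j, m in enumerate(mask2) if not m]
    n1, n2 = len(idx1), len(idx2)
    for row in values:
        x1 = [row[j] for j in idx1]
        x2 = [row[j] for j in idx2]
        m1 = sum(x1) / n1
        m2 = sum(x2) / n2
        ss = sum((v - m1) ** 2 for v in x1) + sum((v - m2) ** 2 for v in x2)
        s = math.sqrt((1 / n1 + 1 / n2) / (n1 + n2 - 2) * ss)
        d_out.append((m2 - m1) / (s + s0))
        s_out.append(s)
        fc_out.append(m2 - m1)
    return np.array(d_out), np.array(s_out), np.array(fc_out)


def exhaustive_null(values, n2, s0):
    """d for every distinct assignment of n2 columns to group 2."""
    n = values.shape[1]
    rows = []
    for combo in itertools.combinations(range(n), n2):
        mask = [j in combo for j in range(n)]
        d, _, _ = d_statistic(values, mask, s0)
        rows.append(d)
    return np.array(rows)


def pi0_estimate(d_obs, d_perm):
    pooled = sorted(d_perm.ravel().tolist())
    q25 = np.percentile(pooled, 25)
    q75 = np.percentile(pooled, 75)
    frac = sum(1 for v in d_obs if q25 <= v <= q75) / len(d_obs)
    return min(1.0, frac / 0.5)


def q_values(d_obs, d_perm, pi0):
    """Tail-area q per gene: median-over-permutations false count at each
    threshold over the observed count, suffix-minimised for monotonicity."""
    scores = np.abs(d_obs)
    perm_scores = np.abs(d_perm)
    thresholds = sorted(set(scores.tolist()))
    raw = {}
    for t in thresholds:
        counts = [sum(1 for v in row if v >= t) for row in perm_scores]
        med = float(np.median(counts))
        rank = sum(1 for v in scores if v >= t)
        raw[t] = pi0 * med / rank
    q = np.empty(len(scores))
    for i, s in enumerate(scores):
        q[i] = min(raw[t] for t in thresholds if t <= s)
    return np.clip(q, 0.0, 1.0)


def local_fdr(d_obs, d_perm, pi0, bandwidth=0.05):
    lo_all = min(d_obs.min(), d_perm.min())
    hi_all = max(d_obs.max(), d_perm.max())
    h = bandwidth * (hi_all - lo_all)
    out = []
    for d in d_obs:
        lo, hi = d - h, d + h
        obs = sum(1 for v in d_obs if lo <= v <= hi)
        counts = [sum(1 for v in row if lo <= v <= hi) for row in d_perm]
        null = float(np.median(counts))
        out.append(min(1.0, max(0.0, pi0 * null / max(obs, 1))))
    return np.array(out)
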