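"""Independent brute-force oracles used to cross-check the implementation.

Every function here is a direct transcription of a textbook formula, written
without reference to the package internals, so tests can compare the two
routes on small instances.
"""

import math

import numpy as np


def welch_t_pvalue(a, b):
    """Welch's two-sided t-test from first principles (t distribution CDF via
    the regularized incomplete beta function through scipy.special only)."""
    from scipy.special import betainc

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    x = df / (df + t * t)
    return t, float(betainc(df / 2.0, 0.5, x))


def student_t_pvalue(a, b):
    """Pooled-variance two-sided Student t."""
    from scipy.special import betainc

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    x = df / (df + t * t)
    return t, float(betainc(df / 2.0, 0.5, x))


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, brute force."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end  # 1-based rank of this p-value
        val = min(prev, p[idx] * n / rank)
        adj[idx] = val
        prev = val
    return adj


def hypergeom_tail(k, N, K, n):
    """P(X >= k) for a hypergeometric draw of n from N with K successes,
    by explicit summation of binomial coefficients."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        )
    return total


def pearson_r_p(x, y):
    """Pearson correlation and two-sided t-based p, from the definition."""
    from scipy.special import betainc

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
    if abs(r) >= 1.0:
        return r, 0.0
    df = n - 2
    t2 = r * r * df / (1 - r * r)
    return r, float(betainc(df / 2.0, 0.5, df / (df + t2)))


def logrank_chi2(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square (1 df) from the standard 2x2 tables at
    each distinct event time."""
    import itertools

    data = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in data if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [(g) for tt, e, g in data if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for g in at_risk if g == 0)
        d = sum(1 for tt, e, g in data if e == 1 and tt == t)
        d1 = sum(1 for tt, e, g in data if e == 1 and tt == t and g == 0)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    from scipy.special import gammaincc

    p = float(gammaincc(0.5, chi2 / 2.0))
    return chi2, p


def ssgsea_running_sum(values, names, member_set, alpha=0.25):
    """ssGSEA enrichment score by explicit running-sum transcription."""
    order = sorted(range(len(values)), key=lambda i: -values[i])
    n = len(values)
    ranks = {idx: n - pos for pos, idx in enumerate(order)}  # highest value -> rank n
    in_set = [names[i] in member_set for i in order]
    w = [abs(ranks[i]) ** alpha for i in order]
    sum_w = sum(wi for wi, h in zip(w, in_set) if h)
    n_out = sum(1 for h in in_set if not h)
    p_in = p_out = 0.0
    es = 0.0
    for wi, h in zip(w, in_set):
        if h:
            p_in += wi / sum_w
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


def gsea_es_leading_edge(stats_sorted_desc, hit_flags, exponent=1.0):
    """Classic GSEA enrichment score and leading-edge positions on an
    already-sorted ranking (descending)."""
    n = len(stats_sorted_desc)
    nh = sum(hit_flags)
    w = [abs(s) ** exponent if h else 0.0 for s, h in zip(stats_sorted_desc, hit_flags)]
    denom = sum(w) or float(nh)
    running = []
    p_hit = p_miss = 0.0
    for wi, h in zip(w, hit_flags):
        if h:
            p_hit += (wi if sum(w) else 1.0) / denom
        else:
            p_miss += 1.0 / (n - nh)
        running.append(p_hit - p_miss)
    i_max = max(range(n), key=lambda i: running[i])
    i_min = min(range(n), key=lambda i: running[i])
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if es >= 0:
        lead = [i for i in range(i_max + 1) if hit_flags[i]]
    else:
        lead = [i for i in range(i_min, n) if hit_flags[i]]
    return es, lead


def rank_sum_z_pvalue(x, y):
    """Wilcoxon rank-sum two-sided p via the tie-corrected normal
    approximation, from the definition."""
    from scipy.special import erfc

    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    n1, n2 = len(x), len(y)
    n = n1 + n2
    r1 = sum(ranks[:n1])
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction
    from collections import Counter

    tie_term = sum(c**3 - c for c in Counter(pooled).values())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 == 0:
        return 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)  # continuity-corrected
    return float(erfc(z / math.sqrt(2)))
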