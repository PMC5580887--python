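"""Independent brute-force implementations used only as test oracles.

Each function re-derives its quantity from the defining formula with plain
loops, sharing no code with the package implementation.
"""

import math

import numpy as np


def brute_variance_partition_fitness(means, error_vars):
    n = len(means)
    grand = sum(means) / n
    sigma_t2 = sum((m - grand) ** 2 for m in means) / n
    sigma_e2 = sum(error_vars) / n
    return sigma_t2, sigma_e2, sigma_t2 - sigma_e2


def brute_variance_partition_increment(groups):
    """groups: list of per-founder lists of population increments (each >= 2)."""
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    grand = sum(all_vals) / n
    sigma_t2 = sum((v - grand) ** 2 for v in all_vals) / n
    sigma_p2 = 0.0
    for g in groups:
        ni = len(g)
        mi = sum(g) / ni
        sigma_p2 += ni / (ni - 1) * sum((v - mi) ** 2 for v in g)
    sigma_p2 /= n
    return sigma_t2, sigma_p2, sigma_t2 - sigma_p2


def brute_weighted_pearson(x, y, w):
    sw = sum(w)
    mx = sum(wi * xi for wi, xi in zip(w, x)) / sw
    my = sum(wi * yi for wi, yi in zip(w, y)) / sw
    cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y)) / sw
    vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x)) / sw
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y)) / sw
    return cov / math.sqrt(vx * vy)


def brute_mutual_information(w_labels, m_column, z_labels=None):
    """Literal evaluation of the (conditional) mutual information in bits."""
    n = len(m_column)
    if z_labels is None:
        z_labels = [0] * n
    total = 0.0
    for zval in sorted(set(z_labels)):
        zidx = [i for i in range(n) if z_labels[i] == zval]
        pz = len(zidx) / n
        inner = 0.0
        for wval in sorted(set(w_labels[i] for i in zidx)):
            widx = [i for i in zidx if w_labels[i] == wval]
            pw = len(widx) / len(zidx)
            for mval in (0, 1):
                p_m_wz = sum(1 for i in widx if m_column[i] == mval) / len(widx)
                p_m_z = sum(1 for i in zidx if m_column[i] == mval) / len(zidx)
                if p_m_wz > 0:
                    inner += pw * p_m_wz * math.log2(p_m_wz / p_m_z)
        total += pz * inner
    return total


def brute_entropy_chain_mi(w_labels, m_column):
    """I(W, m) = H(m) − H(m | W) from entropy definitions."""

    def entropy(vals):
        n = len(vals)
        h = 0.0
        for v in set(vals):
            p = sum(1 for x in vals if x == v) / n
            h -= p * math.log2(p)
        return h

    h_m = entropy(list(m_column))
    h_m_w = 0.0
    n = len(m_column)
    for wval in set(w_labels):
        idx = [i for i in range(n) if w_labels[i] == wval]
        h_m_w += len(idx) / n * entropy([m_column[i] for i in idx])
    return h_m - h_m_w


def lstsq_fit(y, x_columns):
    """Least-squares coefficients and r² via numpy.linalg.lstsq only."""
    x = np.column_stack([np.ones(len(y))] + [np.asarray(c, float) for c in x_columns])
    coef, *_ = np.linalg.lstsq(x, np.asarray(y, float), rcond=None)
    fitted = x @ coef
    y = np.asarray(y, float)
    ss_res = ((y - fitted) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return coef, 1.0 - ss_res / ss_tot


def brute_site_filter_and_call(ref, alt, parental_min=6, err_freq=0.10, err_min=5,
                               call_freq=0.5, call_support=4):
    """Independent loop-based site filtering + calling.

    Returns (surviving site indices, set of (site, population) calls).
    """
    n_sites, n_pops = ref.shape
    survivors = []
    for s in range(n_sites):
        n_majority = 0
        for p in range(n_pops):
            d = ref[s, p] + alt[s, p]
            if d > 0 and alt[s, p] / d > 0.5:
                n_majority += 1
        if n_majority >= parental_min:
            continue
        survivors.append(s)
    final = []
    for s in survivors:
        n_above = 0
        for p in range(n_pops):
            d = ref[s, p] + alt[s, p]
            if d > 0 and alt[s, p] / d > err_freq:
                n_above += 1
        if n_above >= err_min:
            continue
        final.append(s)
    calls = set()
    for s in final:
        for p in range(n_pops):
            d = ref[s, p] + alt[s, p]
            if d > 0 and alt[s, p] / d > call_freq and alt[s, p] >= call_support:
                calls.add((s, p))
    return final, calls
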