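"""Independent brute-force oracles used by the test suite.

Each oracle is written step-by-step from the published definition of the
operation it checks, deliberately avoiding the package's vectorized code
paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def tmm_oracle(counts: np.ndarray, lib_sizes=None, trim_m=0.30, trim_a=0.05):
    """Step-by-step trimmed-mean-of-M-values computation (scalar loops)."""
    counts = np.asarray(counts, dtype=float)
    n_regions, n_samples = counts.shape
    if lib_sizes is None:
        lib_sizes = [sum(counts[i][j] for i in range(n_regions)) for j in range(n_samples)]
    frac = [[counts[i][j] / lib_sizes[j] for j in range(n_samples)] for i in range(n_regions)]

    # reference: sample whose 75th percentile fraction is closest to the mean
    q75 = []
    for j in range(n_samples):
        col = sorted(frac[i][j] for i in range(n_regions))
        q75.append(float(np.percentile(col, 75)))
    mean_q75 = sum(q75) / n_samples
    ref = min(range(n_samples), key=lambda j: abs(q75[j] - mean_q75))

    log_factors = [0.0] * n_samples
    for k in range(n_samples):
        if k == ref:
            continue
        m_vals, a_vals, w_vals = [], [], []
        for i in range(n_regions):
            yk, yr = counts[i][k], counts[i][ref]
            if yk > 0 and yr > 0:
                fk, fr = frac[i][k], frac[i][ref]
                m_vals.append(math.log2(fk / fr))
                a_vals.append(0.5 * math.log2(fk * fr))
                w_vals.append(
                    1.0
                    / (
                        (lib_sizes[k] - yk) / (lib_sizes[k] * yk)
                        + (lib_sizes[ref] - yr) / (lib_sizes[ref] * yr)
                    )
                )
        n = len(m_vals)
        if n == 0:
            continue
        lo_m = int(math.floor(n * trim_m))
        lo_a = int(math.floor(n * trim_a))
        order_m = sorted(range(n), key=lambda i: m_vals[i])
        order_a = sorted(range(n), key=lambda i: a_vals[i])
        rank_m = {idx: r for r, idx in enumerate(order_m)}
        rank_a = {idx: r for r, idx in enumerate(order_a)}
        kept = [
            i
            for i in range(n)
            if lo_m <= rank_m[i] < n - lo_m and lo_a <= rank_a[i] < n - lo_a
        ]
        if len(kept) < 2:
            kept = list(range(n))
        num = sum(w_vals[i] * m_vals[i] for i in kept)
        den = sum(w_vals[i] for i in kept)
        log_factors[k] = num / den

    factors = [2.0**lf for lf in log_factors]
    gm = math.exp(sum(math.log(f) for f in factors) / n_samples)
    return np.array([f / gm for f in factors])


def consensus_oracle(peak_sets, min_support, genome_bp):
    """Per-base coverage counting over a small genome (single chromosome)."""
    cov = np.zeros(genome_bp, dtype=int)
    for peaks in peak_sets:
        seen = np.zeros(genome_bp, dtype=bool)
        for (s, e) in peaks:
            seen[s:e] = True
        cov += seen
    keep = cov >= min_support
    out = []
    i = 0
    while i < genome_bp:
        if keep[i]:
            j = i
            while j + 1 < genome_bp and keep[j + 1]:
                j += 1
            out.append((i, j + 1))
            i = j + 2
        else:
            i += 1
    return out


def intergenic_oracle(gene_spans, tss_list, peaks, chrom_len, window_bp, flank_bp):
    """Per-base exclusion sweep for intergenic window selection (one chrom)."""
    excluded = np.zeros(chrom_len, dtype=bool)
    for (s, e) in gene_spans:
        excluded[s:e] = True
    for tss in tss_list:
        excluded[max(0, tss - flank_bp) : min(chrom_len, tss + flank_bp)] = True
    for (s, e) in peaks:
        excluded[s:e] = True
    kept = []
    for start in range(0, chrom_len - window_bp + 1, window_bp):
        if not excluded[start : start + window_bp].any():
            kept.append((start, start + window_bp))
    return kept


def bh_oracle(p):
    """Literal step-up: q_i = min over rank j >= rank(i) of p_(j)*m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        q[idx] = min(1.0, min(candidates))
    return np.array(q)


def outlier_filter_oracle(columns, k=1.5):
    """Indices kept by the mean ± k*SD rule in every column (inclusive)."""
    n = len(columns[0])
    keep = []
    for i in range(n):
        ok = True
        for col in columns:
            mu = sum(col) / len(col)
            sd = math.sqrt(sum((x - mu) ** 2 for x in col) / (len(col) - 1)) if len(col) > 1 else 0.0
            if not (mu - k * sd <= col[i] <= mu + k * sd):
                ok = False
        if ok:
            keep.append(i)
    return keep


def mannwhitney_exact_oracle(a, b, alternative="two-sided"):
    """Exact Mann-Whitney p by full enumeration of group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    us = [
        u_stat([pooled[i] for i in comb], [pooled[i] for i in range(len(pooled)) if i not in set(comb)])
        for comb in itertools.combinations(range(len(pooled)), n_a)
    ]
    total = len(us)
    if alternative == "less":
        return sum(u <= u_obs for u in us) / total
    if alternative == "greater":
        return sum(u >= u_obs for u in us) / total
    p = 2 * min(
        sum(u <= u_obs for u in us) / total, sum(u >= u_obs for u in us) / total
    )
    return min(1.0, p)
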