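"""Independent oracle implementations shared by the test modules.

Each oracle is a deliberately plain, unoptimized restatement of the rule it
checks, kept separate from the package code paths it validates.
"""

import math

import numpy as np


def enumeration_fisher(a, b, c, d):
    """Pure-combinatorics two-sided Fisher p (point-probability rule)."""
    N, row1, col1 = a + b + c + d, a + b, a + c
    denom = math.comb(N, col1)
    probs = [
        math.comb(row1, x) * math.comb(N - row1, col1 - x) / denom
        for x in range(max(0, col1 - (N - row1)), min(row1, col1) + 1)
    ]
    p_obs = math.comb(row1, a) * math.comb(N - row1, col1 - a) / denom
    return sum(p for p in probs if p <= p_obs * (1 + 1e-7))


def oracle_match(member, centre, max_mm=3, max_over=3):
    """Independent restatement of cluster membership via slice pairs."""
    for shift in range(-len(member) + 1, len(centre)):
        if shift >= 0:
            a = member[: len(centre) - shift]
            b = centre[shift : shift + len(member)]
        else:
            a = member[-shift:][: len(centre)]
            b = centre[: len(member) + shift]
        n = min(len(a), len(b))
        if n <= 0:
            continue
        overhang = (len(member) - n) + (len(centre) - n)
        if overhang > max_over:
            continue
        if sum(x != y for x, y in zip(a[:n], b[:n])) <= max_mm:
            return True
    return False


def oracle_greedy_partition(seq_abundances, max_mm=3, max_over=3):
    """Plain re-implementation of the greedy clustering pass."""
    totals = seq_abundances.sum(axis=1)
    order = sorted(seq_abundances.index, key=lambda s: (-totals[s], s))
    centres, assignment = [], {}
    for seq in order:
        for centre in centres:
            if oracle_match(seq, centre, max_mm, max_over):
                assignment[seq] = centre
                break
        else:
            centres.append(seq)
            assignment[seq] = seq
    return assignment


def oracle_tmm(values, libsizes, trim_m=0.30, trim_a=0.05):
    """Literal, loop-based transcription of the TMM recipe."""
    n_samples = values.shape[1]
    uq = []
    for j in range(n_samples):
        pos = [values[i, j] / libsizes[j] for i in range(values.shape[0])
               if values[i, j] > 0]
        uq.append(np.percentile(pos, 75) if pos else 0.0)
    mean_uq = sum(uq) / n_samples
    r = min(range(n_samples), key=lambda j: (abs(uq[j] - mean_uq), j))

    logf = []
    for s in range(n_samples):
        if s == r:
            logf.append(0.0)
            continue
        idx = [i for i in range(values.shape[0])
               if values[i, s] > 0 and values[i, r] > 0]
        m = [np.log2((values[i, s] / libsizes[s]) / (values[i, r] / libsizes[r]))
             for i in idx]
        a = [0.5 * np.log2((values[i, s] / libsizes[s]) * (values[i, r] / libsizes[r]))
             for i in idx]
        n = len(idx)
        cut_m = int(np.floor(n * trim_m))
        cut_a = int(np.floor(n * trim_a))
        by_m = sorted(range(n), key=lambda i: (m[i], i))
        by_a = sorted(range(n), key=lambda i: (a[i], i))
        keep = set(by_m[cut_m : n - cut_m]) & set(by_a[cut_a : n - cut_a])
        num = den = 0.0
        for i in keep:
            gi = idx[i]
            var = ((libsizes[s] - values[gi, s]) / (libsizes[s] * values[gi, s])
                   + (libsizes[r] - values[gi, r]) / (libsizes[r] * values[gi, r]))
            num += m[i] / var
            den += 1.0 / var
        logf.append(num / den if den > 0 else 0.0)
    centred = [x - sum(logf) / n_samples for x in logf]
    return [2.0 ** x for x in centred], r
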