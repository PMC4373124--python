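"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (literal
double loops, exhaustive enumeration, dense linear solves) so that they
stay independent of the implementation paths they check.
"""

import itertools

import numpy as np


def amova_fst_bruteforce(counts_a, counts_b):
    """Haploid AMOVA F_ST by a literal double loop over individuals.

    delta = 1 for different haplogroups, 0 otherwise; SSDs are computed by
    enumerating all unordered individual pairs.
    """
    ind_a = [k for k, c in enumerate(counts_a) for _ in range(int(c))]
    ind_b = [k for k, c in enumerate(counts_b) for _ in range(int(c))]
    pooled = ind_a + ind_b
    n_a, n_b, n = len(ind_a), len(ind_b), len(pooled)

    def ssd(group):
        total = 0
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                total += int(group[i] != group[j])
        return total / len(group)

    ssd_within = ssd(ind_a) + ssd(ind_b)
    ssd_total = ssd(pooled)
    ssd_among = ssd_total - ssd_within
    msd_among = ssd_among / 1
    msd_within = ssd_within / (n - 2)
    n_c = n - (n_a**2 + n_b**2) / n
    sigma_a = (msd_among - msd_within) / n_c
    sigma_w = msd_within
    if sigma_a + sigma_w == 0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)


def enumerate_optimal_alignments(ref, qry, match=1, mismatch=-1, gap=-2):
    """All optimal global alignments of two short strings (NW with full
    backtracking).  Returns a list of (ref_gapped, qry_gapped) pairs."""
    n, m = len(ref), len(qry)
    score = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == qry[j - 1] else mismatch
            score[i][j] = max(
                score[i - 1][j - 1] + s, score[i - 1][j] + gap, score[i][j - 1] + gap
            )

    results = []

    def backtrack(i, j, r_acc, q_acc):
        if i == 0 and j == 0:
            results.append((r_acc[::-1], q_acc[::-1]))
            return
        s = None
        if i > 0 and j > 0:
            s = match if ref[i - 1] == qry[j - 1] else mismatch
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + s:
            backtrack(i - 1, j - 1, r_acc + ref[i - 1], q_acc + qry[j - 1])
        if i > 0 and score[i][j] == score[i - 1][j] + gap:
            backtrack(i - 1, j, r_acc + ref[i - 1], q_acc + "-")
        if j > 0 and score[i][j] == score[i][j - 1] + gap:
            backtrack(i, j - 1, r_acc + "-", q_acc + qry[j - 1])

    backtrack(n, m, "", "")
    return results


def simplex_grid_minimum(a, b, step=0.001):
    """Exhaustive grid search of ||A x - b||^2 over the probability simplex
    (3 sources).  Returns (x_best, objective)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    assert a.shape[1] == 3
    ticks = int(round(1 / step))
    best_x, best_obj = None, np.inf
    # vectorise over x1 for speed
    for i in range(ticks + 1):
        x1 = i * step
        j = np.arange(ticks - i + 1)
        x2 = j * step
        x3 = 1.0 - x1 - x2
        xs = np.column_stack([np.full_like(x2, x1), x2, x3])
        resid = xs @ a.T - b
        obj = (resid**2).sum(axis=1)
        k = int(obj.argmin())
        if obj[k] < best_obj:
            best_obj = float(obj[k])
            best_x = xs[k]
    return best_x, best_obj


def mwu_exact_pvalue(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(first):
        rest = [pooled[i] for i in range(len(pooled)) if i not in first]
        grp = [pooled[i] for i in first]
        return sum(
            (x > y) + 0.5 * (x == y) for x in grp for y in rest
        )

    u_obs = u_stat(tuple(range(n_a)))
    mean_u = n_a * (len(pooled) - n_a) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(comb) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total
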