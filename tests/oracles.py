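"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: plain loops
written directly from the textbook definitions, so agreement is evidence of
correctness rather than shared bugs.
"""

import math

import numpy as np


def tmm_reference(x: np.ndarray, logratio_trim=0.3, sum_trim=0.05) -> np.ndarray:
    """Trimmed mean of M-values, written as explicit per-sample loops."""
    x = np.asarray(x, dtype=float)
    n_genes, n_samples = x.shape
    lib = x.sum(axis=0)
    # reference column: upper quartile (scaled) closest to the mean upper quartile
    uq = np.array([np.quantile(x[:, j], 0.75) / lib[j] for j in range(n_samples)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for j in range(n_samples):
        m_vals, a_vals, weights = [], [], []
        for g in range(n_genes):
            yo, yr = x[g, j], x[g, ref]
            if yo <= 0 or yr <= 0:
                continue
            po, pr = yo / lib[j], yr / lib[ref]
            m_vals.append(math.log2(po / pr))
            a_vals.append(0.5 * math.log2(po * pr))
            weights.append((lib[j] - yo) / (lib[j] * yo) + (lib[ref] - yr) / (lib[ref] * yr))
        if not m_vals or max(abs(m) for m in m_vals) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m_vals)
        lo_l = math.floor(n * logratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = math.floor(n * sum_trim) + 1
        hi_s = n + 1 - lo_s
        rank_m = _average_ranks(m_vals)
        rank_a = _average_ranks(a_vals)
        num = den = 0.0
        for m, w, rm, ra in zip(m_vals, weights, rank_m, rank_a):
            if lo_l <= rm <= hi_l and lo_s <= ra <= hi_s:
                num += m / w
                den += 1.0 / w
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    factors = np.array(factors)
    log_factors = np.log(factors)
    return factors / np.exp(log_factors.mean())


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def bh_reference(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up written from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def fourway_reference(n6, n12, d_wt, d_homo):
    """Exhaustive rule table for the four-way Venn classification.

    Written as explicit membership-set logic (independent of the package's
    decision cascade).
    """
    calls = {"N6": n6, "N12": n12, "D_WT": d_wt, "D_HOMO": d_homo}
    up = {k for k, v in calls.items() if v == "up"}
    down = {k for k, v in calls.items() if v == "down"}
    if not up and not down:
        return "none", "ns"
    if up and down:
        first = next(c for c in ("N6", "N12", "D_WT", "D_HOMO") if calls[c] != "ns")
        return "mixed", calls[first]
    hits, direction = (up, "up") if up else (down, "down")
    cells = {
        frozenset({"N6", "N12"}): "normal-both-stages",
        frozenset({"N6"}): "normal-6-only",
        frozenset({"N12"}): "normal-12-only",
        frozenset({"D_WT", "D_HOMO"}): "develop-shared",
        frozenset({"D_WT"}): "develop-WT-only",
        frozenset({"D_HOMO"}): "develop-HOMO-only",
    }
    label = cells.get(frozenset(hits), "mixed")
    return label, direction


def clusters_reference(loci, max_gap, min_members):
    """O(n^2) enumeration of maximal co-directional runs.

    For every candidate window [i, j] of the position-sorted loci, check the
    chain conditions pairwise-adjacent and maximality on both sides.
    """
    items = sorted(loci, key=lambda r: (r["chrom"], r["start"], r["end"]))
    n = len(items)

    def chained(i, j):
        for k in range(i, j):
            a, b = items[k], items[k + 1]
            if a["chrom"] != b["chrom"]:
                return False
            if a["direction"] != b["direction"]:
                return False
            if b["start"] - a["end"] > max_gap:
                return False
        return True

    out = []
    for i in range(n):
        for j in range(i, n):
            if not chained(i, j):
                continue
            if i > 0 and chained(i - 1, j):
                continue
            if j < n - 1 and chained(i, j + 1):
                continue
            if j - i + 1 >= min_members:
                out.append([items[k]["name"] for k in range(i, j + 1)])
    return out
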