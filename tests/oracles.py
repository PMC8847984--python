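"""Independent brute-force oracles used by the tests.

These deliberately re-derive results from first principles (exhaustive
enumeration, explicit running sums, simplex grids) so they share no
code path with the implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def mw_enumeration(x, y) -> tuple[float, float]:
    """Exact Mann-Whitney U and two-sided p by exhaustive label arrangement."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)

    def ustat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a > b) + 0.5 * (a == b)
        return u

    u_obs = ustat(x, y)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in chosen]
        us.append(ustat(xs, ys))
    us = np.array(us)
    p = 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return u_obs, min(p, 1.0)


def gsea_es_bruteforce(stats, genes, member_genes, weight: float = 1.0) -> float:
    """Weighted-KS enrichment score by an explicit position-by-position loop."""
    hits = [g in member_genes for g in genes]
    n = len(genes)
    n_hit = sum(hits)
    absw = [abs(s) ** weight for s in stats]
    norm = np.sum(np.array([w for w, h in zip(absw, hits) if h]))
    running = 0.0
    values = []
    for w, h in zip(absw, hits):
        if h:
            running += w / norm
        else:
            running -= 1.0 / (n - n_hit)
        values.append(running)
    values = np.array(values)
    return float(values[int(np.argmax(np.abs(values)))])


def simplex_grid(resolution: float = 0.01):
    """All 3-part fraction vectors on the simplex at the given resolution."""
    steps = int(round(1.0 / resolution))
    for i in range(steps + 1):
        for j in range(steps - i + 1):
            yield np.array([i, j, steps - i - j], dtype=float) / steps


def spearman_midrank(a, b) -> float:
    """Spearman Rs via explicit mid-ranks and the Pearson formula."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(v.size)
        for i, x in enumerate(v):
            out[i] = np.sum(v < x) + 0.5 * (np.sum(v == x) - 1) + 1
        return out

    ra, rb = midranks(a), midranks(b)
    ra, rb = ra - ra.mean(), rb - rb.mean()
    return float(np.sum(ra * rb) / np.sqrt(np.sum(ra**2) * np.sum(rb**2)))
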