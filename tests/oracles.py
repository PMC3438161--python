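"""Brute-force reference implementations used as independent oracles.

Each function here re-derives a pipeline quantity by the most literal
method available (exhaustive scans, enumeration, definitional sums) and is
kept deliberately independent of the package's implementation choices.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_foci(fluor: np.ndarray, pixel_sets: list[set[tuple[int, int]]],
                     threshold: float) -> set[tuple[int, int, int]]:
    """(mask_index, row, col) of the maximal-intensity pixel of every
    connected above-threshold region, via flood fill and row-major argmax."""
    out: set[tuple[int, int, int]] = set()
    for mi, pixset in enumerate(pixel_sets):
        cand = {p for p in pixset if fluor[p] > threshold}
        seen: set[tuple[int, int]] = set()
        for start in sorted(cand):
            if start in seen:
                continue
            region = []
            stack = [start]
            seen.add(start)
            while stack:
                r, c = stack.pop()
                region.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nb = (r + dr, c + dc)
                        if nb in cand and nb not in seen:
                            seen.add(nb)
                            stack.append(nb)
            best = max(region, key=lambda p: (fluor[p], (-p[0], -p[1])))
            # row-major tie-break: smallest (row, col) among maxima
            maxval = fluor[best]
            best = min(p for p in region if fluor[p] == maxval)
            out.add((mi, best[0], best[1]))
    return out


def brute_force_matching(s_prev: list[float], s_cur: list[float],
                         max_step: float) -> set[tuple[int, int]]:
    """Optimal gated bipartite matching by exhaustive enumeration:
    maximise the number of within-gate links, breaking ties by the minimal
    total |Δs| (the objective of penalised optimal assignment)."""
    n, m = len(s_prev), len(s_cur)
    best_links: set[tuple[int, int]] = set()
    best_cost = math.inf
    for k in range(min(n, m), 0, -1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                links = set(zip(rows, cols))
                if any(abs(s_cur[j] - s_prev[i]) > max_step
                       for i, j in links):
                    continue
                cost = sum(abs(s_cur[j] - s_prev[i]) for i, j in links)
                if cost < best_cost:
                    best_cost = cost
                    best_links = links
        if best_links:
            break
    return best_links


def definitional_pearson(x, y) -> float:
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)
                    * sum((b - my) ** 2 for b in y))
    return num / den


def two_pass_sd(values) -> float:
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def exact_rank_sum_p(dev_a, dev_b) -> float:
    """Two-sided exact rank-sum p-value by full enumeration (midranks)."""
    pooled = np.concatenate([dev_a, dev_b])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    n_a = len(dev_a)
    w_obs = ranks[:n_a].sum()
    ws = [sum(ranks[list(c)])
          for c in itertools.combinations(range(len(pooled)), n_a)]
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return float(min(1.0, 2.0 * min(lo, hi)))
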