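"""Independent brute-force reference implementations used only by tests.

Everything here is written against the defining formulas with plain Python
containers (dicts, sets, float sums), deliberately sharing no code with the
package's vectorised implementations.
"""

from __future__ import annotations

import math


def modularity_double_sum(n, edges, assign):
    """Literal ordered-pair double sum Q = (1/2m) ΣΣ (A_ij - k_i k_j / 2m) δ."""
    adj = [[0] * n for _ in range(n)]
    for u, v in edges:
        adj[u][v] = adj[v][u] = 1
    k = [sum(row) for row in adj]
    m2 = float(sum(k))  # 2m
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assign[i] == assign[j]:
                q += adj[i][j] - k[i] * k[j] / m2
    return q / m2


def all_pairs_bfs_floyd(n, edges):
    """All-pairs shortest hop counts by Floyd–Warshall."""
    inf = math.inf
    d = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for u, v in edges:
        d[u][v] = d[v][u] = 1
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == inf:
                continue
            for j in range(n):
                if dik + d[k][j] < d[i][j]:
                    d[i][j] = dik + d[k][j]
    return d


def pim_entries(n, edges, lam):
    """Hand evaluation of overlap x exp(-λ d) on every off-diagonal pair."""
    nbrs = {i: set() for i in range(n)}
    for u, v in edges:
        nbrs[u].add(v)
        nbrs[v].add(u)
    d = all_pairs_bfs_floyd(n, edges)
    out = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ov = len(nbrs[i] & nbrs[j])
            if ov and d[i][j] != math.inf:
                out[(i, j)] = ov * math.exp(-lam * d[i][j])
    return out


def sample_node_bruteforce(n, edges, intensities, v, mu, eps, max_hops,
                           min_keep=1, mode="abs"):
    """Literal hierarchical threshold sampling over explicit pair lists.

    ``intensities`` maps ordered pairs (j, h) with h in Γ(j) to the
    influence value a_jh.  Returns (layers, union, qbars) with sorted
    lists.  Semantics mirror the package's documented contract: threshold
    mean over all frontier→neighbour ordered pairs (zeros included),
    existential retention of unvisited neighbours, per-layer mean
    intensity over the retained layer's incident pairs, early stop on
    layer-to-layer intensity variation below eps (checked from the second
    retained layer), top-``min_keep`` fallback for empty layers.
    """
    nbrs = {i: set() for i in range(n)}
    for a, b in edges:
        nbrs[a].add(b)
        nbrs[b].add(a)
    if not nbrs[v]:
        return [], [], []
    visited = {v}
    frontier = [v]
    layers, qbars = [], []
    prev = None
    for _k in range(1, max_hops + 1):
        pairs = [(j, h) for j in sorted(frontier) for h in sorted(nbrs[j])]
        if not pairs:
            break
        vals = [intensities.get((j, h), 0.0) for j, h in pairs]
        r = mu * (sum(vals) / len(vals))
        tol = 1e-12 * max(1.0, abs(r))
        retained = sorted({h for j, h in pairs
                           if h not in visited
                           and intensities.get((j, h), 0.0) >= r - tol})
        if not retained:
            cands = sorted({h for _, h in pairs if h not in visited})
            if min_keep > 0 and cands:
                best = {
                    h: max(intensities.get((j, h), 0.0)
                           for j in frontier if h in nbrs[j])
                    for h in cands
                }
                cands.sort(key=lambda h: (-best[h], h))
                retained = sorted(cands[:min_keep])
            else:
                break
        layers.append(retained)
        visited.update(retained)
        pairs2 = [(j, h) for j in retained for h in sorted(nbrs[j])]
        qbar = (sum(intensities.get((j, h), 0.0) for j, h in pairs2)
                / len(pairs2)) if pairs2 else 0.0
        qbars.append(qbar)
        if prev is not None:
            delta = qbar - prev
            if mode == "abs":
                delta = abs(delta)
            if delta < eps:
                break
        prev = qbar
        frontier = retained
    union = sorted({u for layer in layers for u in layer})
    return layers, union, qbars


def nmi_from_counts(y, z):
    """Arithmetic-mean NMI from the contingency table, by the definition."""
    n = len(y)
    from collections import Counter

    cy, cz = Counter(y), Counter(z)
    joint = Counter(zip(y, z))
    mi = 0.0
    for (a, b), c in joint.items():
        p = c / n
        mi += p * math.log(p / ((cy[a] / n) * (cz[b] / n)))
    hy = -sum((c / n) * math.log(c / n) for c in cy.values())
    hz = -sum((c / n) * math.log(c / n) for c in cz.values())
    if hy + hz == 0:
        return 1.0
    return 2.0 * mi / (hy + hz)


def ari_from_counts(y, z):
    """Adjusted Rand index from pair counts."""
    from collections import Counter

    def comb2(x):
        return x * (x - 1) / 2.0

    n = len(y)
    cy, cz = Counter(y), Counter(z)
    joint = Counter(zip(y, z))
    sum_ij = sum(comb2(c) for c in joint.values())
    sum_a = sum(comb2(c) for c in cy.values())
    sum_b = sum(comb2(c) for c in cz.values())
    total = comb2(n)
    expected = sum_a * sum_b / total
    mx = 0.5 * (sum_a + sum_b)
    if mx == expected:
        return 0.0
    return (sum_ij - expected) / (mx - expected)


def macro_f1_from_counts(y_true, y_pred):
    """Macro F1 from per-class precision/recall (absent-class F1 = 0)."""
    classes = sorted(set(y_true) | set(y_pred))
    f1s = []
    for c in classes:
        tp = sum(1 for a, b in zip(y_true, y_pred) if a == c and b == c)
        fp = sum(1 for a, b in zip(y_true, y_pred) if a != c and b == c)
        fn = sum(1 for a, b in zip(y_true, y_pred) if a == c and b != c)
        if tp == 0:
            f1s.append(0.0)
            continue
        prec = tp / (tp + fp)
        rec = tp / (tp + fn)
        f1s.append(2 * prec * rec / (prec + rec))
    return sum(f1s) / len(f1s)
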