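"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: betweenness is
computed by explicitly enumerating every geodesic, co-membership by
looping over all herb pairs and prescriptions, and enrichment p-values by
Monte-Carlo draws from the background universe.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_betweenness(graph) -> dict:
    """Normalized betweenness by explicit enumeration of all geodesics.

    For every unordered node pair (s, t) the geodesics are enumerated by
    following BFS-distance-decreasing steps; each interior node of each
    geodesic is credited 1/(#geodesics).  Totals are divided by
    (n-1)(n-2)/2.  Exponential in the worst case — test-scale graphs only.
    """
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    if n < 3:
        return score
    adj = {v: sorted(graph.neighbors(v), key=str) for v in nodes}
    for i, s in enumerate(nodes):
        # BFS distances from s
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        for t in nodes[i + 1:]:
            if t not in dist or t == s:
                continue

            # enumerate every geodesic s -> t explicitly
            paths: list[list] = []

            def extend(path: list) -> None:
                u = path[-1]
                if u == t:
                    paths.append(list(path))
                    return
                for w in adj[u]:
                    if w in dist and dist[w] == dist[u] + 1 and dist[w] <= dist[t]:
                        path.append(w)
                        extend(path)
                        path.pop()

            extend([s])
            if not paths:
                continue
            for p in paths:
                for interior in p[1:-1]:
                    score[interior] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: c / norm for v, c in score.items()}


def brute_comembership(incidence) -> np.ndarray:
    """Pair-count projection by looping over all pairs and prescriptions."""
    v = incidence.values
    n = v.shape[0]
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            count = 0
            for col in range(v.shape[1]):
                if v[i, col] == 1 and v[j, col] == 1:
                    count += 1
            out[i, j] = count
    return out


def permutation_enrich_p(
    N: int, K: int, n: int, k: int, n_draws: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo estimate of P[overlap >= k] plus its standard error.

    Draws ``n`` background elements without replacement and counts how
    often at least ``k`` fall inside a fixed K-element term.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    universe = np.arange(N)
    for _ in range(n_draws):
        sample = rng.choice(universe, size=n, replace=False)
        if (sample < K).sum() >= k:
            hits += 1
    p_hat = hits / n_draws
    se = np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_draws)
    return p_hat, se
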