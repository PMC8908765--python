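"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately takes the dumbest correct route (explicit
loops, exhaustive enumeration, Monte-Carlo simulation) and shares no
code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_bmu(vector, codebook):
    """Exhaustive scan for the closest codebook row (lowest index on ties)."""
    best, bestd = 0, math.inf
    for j in range(len(codebook)):
        d = 0.0
        for f in range(len(vector)):
            d += (vector[f] - codebook[j][f]) ** 2
        d = math.sqrt(d)
        if d < bestd - 1e-15:
            best, bestd = j, d
    return best, bestd


def naive_linkage(dist, method):
    """O(n^3) agglomerative clustering on a distance matrix.

    Returns the merge history as a list of (members_a, members_b, height)
    with members given as frozensets of original indices.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []

    def cluster_dist(a, b):
        vals = [dist[i, j] for i in clusters[a] for j in clusters[b]]
        if method == "complete":
            return max(vals)
        if method == "average":
            return sum(vals) / len(vals)
        raise ValueError(method)

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                d = cluster_dist(keys[ai], keys[bi])
                if best is None or d < best[0] - 1e-12:
                    best = (d, keys[ai], keys[bi])
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return merges


def cophenetic_from_merges(merges, n):
    """Cophenetic distance matrix from a naive merge history."""
    out = np.zeros((n, n))
    for a, b, h in merges:
        for i in a:
            for j in b:
                out[i, j] = out[j, i] = h
    return out


def naive_cut(merges, n, k):
    """Labels from cutting the naive merge history at k clusters."""
    clusters = [frozenset([i]) for i in range(n)]
    for a, b, _ in merges[: n - k]:
        clusters = [c for c in clusters if c != a and c != b] + [a | b]
    labels = np.empty(n, dtype=int)
    for ci, c in enumerate(sorted(clusters, key=min)):
        for i in c:
            labels[i] = ci
    return labels


def naive_silhouette(dist, labels):
    """Silhouette widths by the textbook formula, explicit loops."""
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = sum(dist[i][j] for j in own) / len(own)
        bs = []
        for c in set(labels):
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            bs.append(sum(dist[i][j] for j in members) / len(members))
        b = min(bs)
        denom = max(a, b)
        out[i] = 0.0 if denom == 0 else (b - a) / denom
    return out


def fw_betweenness(nodes, cost):
    """Betweenness by Floyd–Warshall distances plus shortest-path counting.

    ``cost[i][j]`` is the edge cost (inf if absent).  Equal-cost path
    multiplicity is shared fractionally, as in Brandes' algorithm.
    """
    n = len(nodes)
    d = np.array(cost, dtype=float)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    # count shortest paths s->t by DP over the shortest-path DAG
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(d[s])
        sigma[s, s] = 1.0
        for v in order:
            if not np.isfinite(d[s, v]) or v == s:
                continue
            tot = 0.0
            for u in range(n):
                if u != v and np.isfinite(cost[u][v]) and abs(
                    d[s, u] + cost[u][v] - d[s, v]
                ) < 1e-9:
                    tot += sigma[s, u]
            sigma[s, v] = tot
    btw = dict.fromkeys(range(n), 0.0)
    for s in range(n):
        for t in range(n):
            if s == t or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t) or sigma[s, v] == 0 or sigma[v, t] == 0:
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) < 1e-9:
                    btw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return btw


def mc_committor(P, A, B, start, n_walks, rng, max_steps=100000):
    """Monte-Carlo estimate of the probability of hitting A before B."""
    A, B = set(A), set(B)
    hits = 0
    n = P.shape[0]
    cum = np.cumsum(P, axis=1)
    for _ in range(n_walks):
        s = start
        for _ in range(max_steps):
            if s in A:
                hits += 1
                break
            if s in B:
                break
            s = int(np.searchsorted(cum[s], rng.random()))
    return hits / n_walks


def mc_committor_vectorized(P, A, B, start, n_walks, rng, max_steps=100000):
    """Vectorized Monte-Carlo hitting probability (all walks in parallel)."""
    A, B = set(A), set(B)
    cum = np.cumsum(P, axis=1)
    states = np.full(n_walks, start, dtype=np.int64)
    hit_a = np.zeros(n_walks, dtype=bool)
    active = np.ones(n_walks, dtype=bool)
    for s in A:
        hit_a |= states == s
    active &= ~np.isin(states, list(A | B))
    for _ in range(max_steps):
        if not active.any():
            break
        cur = states[active]
        u = rng.random(len(cur))
        rows = cum[cur]
        nxt = (u[:, None] < rows).argmax(axis=1)
        states[active] = nxt
        in_a = np.isin(states, list(A)) & active
        in_b = np.isin(states, list(B)) & active
        hit_a |= in_a
        active &= ~(in_a | in_b)
    return hit_a.sum() / n_walks


def modularity(W, labels):
    """Newman modularity of a partition on a symmetric weight matrix."""
    W = np.asarray(W, dtype=float)
    m2 = W.sum()
    if m2 == 0:
        return 0.0
    k = W.sum(axis=1)
    q = 0.0
    for c in set(labels):
        idx = [i for i, l in enumerate(labels) if l == c]
        q += W[np.ix_(idx, idx)].sum() / m2 - (k[idx].sum() / m2) ** 2
    return q


def best_partition_exhaustive(W):
    """Maximum-modularity partition by scanning every set partition."""
    from sympy.utilities.iterables import multiset_partitions

    n = W.shape[0]
    best_q, best_labels = -np.inf, None
    for part in multiset_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for ci, block in enumerate(part):
            for i in block:
                labels[i] = ci
        q = modularity(W, labels)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    return best_labels, best_q


def tally_transitions(paths, n_states, lag):
    """Sliding-window transition tally, one replica at a time."""
    counts = np.zeros((n_states, n_states))
    for p in paths:
        for t in range(len(p) - lag):
            counts[p[t], p[t + lag]] += 1
    return counts


def power_eigvec_oracle(W):
    """Principal eigenvector of a symmetric matrix via dense eigh."""
    vals, vecs = np.linalg.eigh(W)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    return np.abs(v)
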