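"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions, in the most literal way
possible (python loops, exhaustive enumeration), and never calls into the
package's own computational routines.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def degree_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    return np.array([sum(w[i, j] for j in range(n)) for i in range(n)])


def clustering_oracle(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Onnela clustering by exhaustive triangle enumeration."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n), 0.0
    wh = w / wmax
    c = np.zeros(n)
    for i in range(n):
        neighbors = [j for j in range(n) if w[i, j] > 0]
        k = len(neighbors)
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.combinations(range(n), 2):
            if w[i, j] > 0 and w[j, h] > 0 and w[h, i] > 0:
                total += (wh[i, j] * wh[j, h] * wh[h, i]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1) / 2.0)
    return c, float(np.mean(c))


def floyd_warshall_oracle(w: np.ndarray) -> np.ndarray:
    """Triple-loop all-pairs shortest paths with length = 1/weight."""
    n = w.shape[0]
    d = [[0.0 if i == j else (1.0 / w[i][j] if w[i][j] > 0 else math.inf)
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return np.array(d)


def global_efficiency_oracle(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall_oracle(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i][j]) and d[i][j] > 0:
                total += 1.0 / d[i][j]
    return total / (n * (n - 1))


def local_efficiency_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency_oracle(sub)
    return out


def bh_stepup_oracle(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values from the step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        q[idx] = running_min
    return q


def auc_pair_oracle(scores, labels) -> float:
    """AUC by concordant/discordant pair counting (ties credit 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def _mi_bits(joint: np.ndarray) -> float:
    n = joint.sum()
    px = joint.sum(axis=1) / n
    py = joint.sum(axis=0) / n
    mi = 0.0
    for a in range(joint.shape[0]):
        for b in range(joint.shape[1]):
            pab = joint[a, b] / n
            if pab > 0:
                mi += pab * math.log2(pab / (px[a] * py[b]))
    return mi


def mic_exhaustive_oracle(x, y, alpha: float = 0.6) -> float:
    """MIC by exhaustive enumeration of both axes' partitions.

    Only feasible for tiny n; enumerates every p-by-q grid with
    p * q <= B(n) = max(4, floor(n^alpha)) and every placement of cuts at
    value boundaries on both axes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    B = max(4, int(np.floor(n**alpha)))

    def axis_partitions(vals, n_bins):
        order = np.argsort(vals, kind="stable")
        svals = vals[order]
        bounds = [i for i in range(1, n) if svals[i] != svals[i - 1]]
        for cuts in itertools.combinations(bounds, n_bins - 1):
            edges = [0, *cuts, n]
            labels = np.empty(n, dtype=int)
            for b in range(n_bins):
                labels[order[edges[b]:edges[b + 1]]] = b
            yield labels

    best = 0.0
    for p in range(2, B // 2 + 1):
        for q in range(2, B // p + 1):
            for lx in axis_partitions(x, p):
                for ly in axis_partitions(y, q):
                    joint = np.zeros((p, q))
                    for a, b in zip(lx, ly):
                        joint[a, b] += 1
                    mi = _mi_bits(joint)
                    best = max(best, mi / math.log2(min(p, q)))
    return min(1.0, best)
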