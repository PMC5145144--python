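"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately naive — direct formulas, exhaustive
enumeration, quadrature — and shares no code path with the implementations
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad


def pearson_oracle(x, y) -> float:
    """Product-moment correlation straight from the definition."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def t_sf_oracle(t: float, df: int) -> float:
    """P(T > t) by quadrature of the Student-t density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def dens(u):
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    val, _ = quad(dens, t, np.inf)
    return val


def p_from_r_oracle(r: float, n: int) -> float:
    t = abs(r) * math.sqrt((n - 2) / (1 - r * r))
    return 2 * t_sf_oracle(t, n - 2)


def chi2_2x2_oracle(a, b, c, d) -> tuple[float, float]:
    """(chi2, p) from the closed 2x2 formula and the 1-df tail via erfc."""
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = math.erfc(math.sqrt(chi2 / 2))
    return chi2, p


def hypergeom_tail_oracle(k, m, K, N) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    total = 0
    for i in range(k, min(m, K) + 1):
        total += math.comb(K, i) * math.comb(N - K, m - i)
    return total / math.comb(N, m)


def ari_oracle(labels_a: dict, labels_b: dict) -> float:
    """Adjusted Rand index from the pair-count contingency formula."""
    keys = sorted(labels_a)
    cats_a = sorted({labels_a[k] for k in keys})
    cats_b = sorted({labels_b[k] for k in keys})
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for k in keys:
        table[cats_a.index(labels_a[k]), cats_b.index(labels_b[k])] += 1
    sum_comb = sum(math.comb(int(nij), 2) for nij in table.flat)
    sum_a = sum(math.comb(int(ni), 2) for ni in table.sum(axis=1))
    sum_b = sum(math.comb(int(nj), 2) for nj in table.sum(axis=0))
    n_pairs = math.comb(len(keys), 2)
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if sum_comb == expected else 0.0
    return (sum_comb - expected) / (max_index - expected)


def linkage_oracle(dist_matrix: np.ndarray, method: str):
    """Naive agglomerative clustering by the linkage recurrences.

    Returns the merge list [(leafset_a, leafset_b, height)] in merge order.
    Clusters are frozensets of leaf indices; at each step the pair with the
    smallest inter-cluster distance merges (ties: smallest pair in the scan
    order over current cluster list).
    """
    n = dist_matrix.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    merges = []

    def cluster_dist(A, B):
        ds = [dist_matrix[i, j] for i in A for j in B]
        if method == "single":
            return min(ds)
        if method == "complete":
            return max(ds)
        if method == "average":
            return sum(ds) / len(ds)
        raise ValueError(method)

    while len(clusters) > 1:
        best = None
        for (i, A), (j, B) in itertools.combinations(enumerate(clusters), 2):
            d = cluster_dist(A, B)
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        A, B = clusters[i], clusters[j]
        merges.append((A, B, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(A | B)
    return merges


def subtree_extraction_oracle(
    dendro, bait_names, min_size, max_size, rule, coverage=1.0
):
    """Exhaustively score every admissible subtree of a Dendrogram.

    Walks the linkage matrix independently of the package's extraction code
    and applies the same admissibility predicate (parent merge strictly
    higher) and selection keys.
    """
    n = len(dendro.leaves)
    sets = [frozenset([i]) for i in range(n)]
    heights = [0.0] * n
    parent_h = [math.inf] * (2 * n - 1)
    for row, (a, b, h, _) in enumerate(dendro.Z):
        sets.append(sets[int(a)] | sets[int(b)])
        heights.append(float(h))
        parent_h[int(a)] = float(h)
        parent_h[int(b)] = float(h)
    bait_idx = {i for i, name in enumerate(dendro.leaves) if name in set(bait_names)}
    K = len(bait_idx)
    max_size = n if max_size is None else max_size
    need = math.ceil(coverage * K)
    best_key, best_set = None, None
    for node in range(n, 2 * n - 1):
        tol = 1e-9 * max(1.0, abs(parent_h[node]))
        if not (math.isinf(parent_h[node]) or parent_h[node] - heights[node] > tol):
            continue
        size = len(sets[node])
        if not (min_size <= size <= max_size):
            continue
        k = len(sets[node] & bait_idx)
        if rule == "coverage":
            if k < need:
                continue
            key = (size, heights[node], node)
        else:
            key = (hypergeom_tail_oracle(k, size, K, n), size, heights[node], node)
        if best_key is None or key < best_key:
            best_key, best_set = key, sets[node]
    if best_set is None:
        return None
    return frozenset(dendro.leaves[i] for i in best_set)


def sliding_window_motif_oracle(seq: str, pattern: str, both_strands: bool):
    """All motif occurrences by brute-force window comparison."""
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
        "H": "ACT", "V": "ACG", "N": "ACGTN",
    }
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def matches(window, pat):
        return all(b in iupac[p] for b, p in zip(window, pat))

    w = len(pattern)
    hits = []
    for off in range(len(seq) - w + 1):
        if matches(seq[off : off + w], pattern):
            hits.append((off, "+"))
    if both_strands:
        rc = "".join(comp[b] for b in reversed(seq))
        for off in range(len(rc) - w + 1):
            if matches(rc[off : off + w], pattern):
                hits.append((len(seq) - off - w, "-"))
    return sorted(hits)
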