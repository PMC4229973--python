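"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as a literal, loop-based transcription of the
underlying definitions (exhaustive enumeration, explicit counting) and
shares no code with the package.
"""

from __future__ import annotations

import math
from collections import Counter


# ---------------------------------------------------------------------------
# AODE posterior: literal transcription of the averaged-ODE equation
# ---------------------------------------------------------------------------

def aode_posterior_oracle(train, labels, v, x, k=2):
    """P(+|x) via exhaustive loops over the smoothed count definitions.

    ``train`` is a list of tuples of bin indices (None = unknown), ``v``
    the per-feature bin counts, ``x`` the query tuple.
    """
    n = len(v)

    def F1(c, i, a):
        return sum(1 for t, l in zip(train, labels) if l == c and t[i] == a)

    def F2(c, i, a, j, b):
        return sum(
            1 for t, l in zip(train, labels)
            if l == c and t[i] == a and t[j] == b
        )

    def m(i):
        return sum(1 for t in train if t[i] is not None)

    def mij(i, j):
        return sum(1 for t in train if t[i] is not None and t[j] is not None)

    def p_joint(c, i, a):
        return (F1(c, i, a) + 1) / (m(i) + k * v[i])

    def p_pair(c, i, a, j, b):
        return (F2(c, i, a, j, b) + 1) / (mij(i, j) + k * v[i] * v[j])

    known = [i for i in range(n) if x[i] is not None]
    score = {}
    for c in (0, 1):
        total = 0.0
        for i in known:
            prod = p_joint(c, i, x[i])
            for j in known:
                if j != i:
                    prod *= p_pair(c, i, x[i], j, x[j]) / p_joint(c, i, x[i])
            total += prod
        score[c] = total
    return score[1] / (score[0] + score[1])


# ---------------------------------------------------------------------------
# shortest-path weight by exhaustive simple-path enumeration
# ---------------------------------------------------------------------------

def spw_enumeration_oracle(edges, src, dst):
    """Minimum total weight over all simple paths; None when unreachable.

    ``edges`` is a list of (u, v, w) undirected weighted edges.
    """
    adj = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    if src not in adj or dst not in adj:
        return None
    if src == dst:
        return 0.0
    best = [None]

    def dfs(node, visited, acc):
        if node == dst:
            if best[0] is None or acc < best[0]:
                best[0] = acc
            return
        for nb, w in adj.get(node, ()):
            if nb not in visited:
                dfs(nb, visited | {nb}, acc + w)

    dfs(src, {src}, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# MDL discretization by exhaustive candidate search
# ---------------------------------------------------------------------------

def _entropy(labs):
    n = len(labs)
    if n == 0:
        return 0.0
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(labs).values()
    )


def mdlp_oracle(values, labels):
    """Accepted cut points by scanning every distinct-value midpoint."""
    pairs = sorted(zip(values, labels))
    out = []

    def recurse(chunk):
        n = len(chunk)
        labs = [l for _, l in chunk]
        klass = len(set(labs))
        if n < 2 or klass < 2:
            return
        h = _entropy(labs)
        best = None  # (neg gain placeholder) -> choose max gain, first index
        for idx in range(1, n):
            if chunk[idx][0] == chunk[idx - 1][0]:
                continue
            left = labs[:idx]
            right = labs[idx:]
            gain = h - len(left) / n * _entropy(left) - len(right) / n * _entropy(right)
            if best is None or gain > best[0] + 1e-12:
                best = (gain, idx)
        if best is None:
            return
        gain, idx = best
        left = labs[:idx]
        right = labs[idx:]
        k1, k2 = len(set(left)), len(set(right))
        delta = math.log2(3**klass - 2) - (
            klass * h - k1 * _entropy(left) - k2 * _entropy(right)
        )
        if gain <= (math.log2(n - 1) + delta) / n:
            return
        out.append((chunk[idx - 1][0] + chunk[idx][0]) / 2.0)
        recurse(chunk[:idx])
        recurse(chunk[idx:])

    recurse(pairs)
    return sorted(out)


# ---------------------------------------------------------------------------
# AUC by concordant-pair counting (Mann-Whitney), half credit for ties
# ---------------------------------------------------------------------------

def auc_pair_count_oracle(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# best-template search by exhaustive combination ranking
# ---------------------------------------------------------------------------

def fseq_oracle(hitsA, hitsB, positive_pairs, cutoff=1e2):
    """Rank every hit combination explicitly; hits are plain tuples
    (subject, evalue, positives, qlen, slen)."""
    cands = []
    for sa, ea, pa, qla, sla in hitsA:
        if ea > cutoff:
            continue
        for sb, eb, pb, qlb, slb in hitsB:
            if eb > cutoff:
                continue
            key = tuple(sorted((sa, sb)))
            if key not in positive_pairs:
                continue
            ma = min(max(pa / max(qla, sla), 0.0), 1.0)
            mb = min(max(pb / max(qlb, slb), 0.0), 1.0)
            norm = math.sqrt(ea**2 + eb**2)
            cands.append(((norm, ea, -(ma + mb), sa, sb), (ea, ma, eb, mb)))
    if not cands:
        return (100.0, 0.0, 100.0, 0.0)
    return sorted(cands)[0][1]
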