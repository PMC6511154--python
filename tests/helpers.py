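"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_stem_loop_intervals(seq: str, cls) -> set[tuple[int, int]]:
    """Exhaustive (i, s, l) enumeration of locally maximal stem-loop hits.

    O(n * s * l * s) with naive per-hit mismatch counting; only usable on
    short sequences, which is the point: it shares no code with the scanner.
    """
    seq = seq.upper()
    n = len(seq)

    def mismatches(i, s, l):
        m = 0
        for k in range(s):
            a = seq[i + k]
            b = seq[i + 2 * s + l - 1 - k]
            if a not in _COMP or b not in _COMP or _COMP[b] != a:
                m += 1
        return m

    hits = set()
    for i in range(n):
        for l in range(cls.loop_max + 1):
            for s in range(cls.stem_min, cls.stem_max + 1):
                if i + 2 * s + l > n:
                    break
                if mismatches(i, s, l) <= cls.max_mismatches:
                    hits.add((i, s, l))
    out = set()
    for i, s, l in hits:
        if s + 1 <= cls.stem_max and (i - 1, s + 1, l) in hits:
            continue  # extendable outward at the same center: not maximal
        out.add((i, i + 2 * s + l))
    return out


def brute_auc(labels, scores) -> float:
    """All-pairs Mann-Whitney AUC: P(s+ > s-) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def rank_average(values) -> np.ndarray:
    """Average ranks (1-based) with ties sharing the mean rank."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_spearman(x, y) -> float:
    """Rank both vectors (average ranks) and take the Pearson correlation."""
    rx, ry = rank_average(x), rank_average(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def brute_top_k(densities, k) -> set[int]:
    """Full sort by (density desc, index asc) and take the first k indices."""
    order = sorted(range(len(densities)), key=lambda i: (-densities[i], i))
    return set(order[:k])
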