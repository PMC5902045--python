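"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (pure-Python loops, direct
definitions) and shares no code path with the package internals.
"""

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_window_score(probs, window: str) -> float:
    """Sum of log2 probabilities; N contributes 0."""
    total = 0.0
    for i, ch in enumerate(window):
        if ch == "N":
            continue
        total += math.log2(probs[i]["ACGT".index(ch)])
    return total


def oracle_rll(probs, sequence: str):
    """Exhaustive enumeration of every NN-padded window on both strands.

    Returns (x, rll, offset, strand) under the same tie rule: lowest
    offset first, forward strand preferred at equal offset.
    """
    W = len(probs)
    padded = "NN" + sequence.upper() + "NN"
    s_min = sum(math.log2(min(row)) for row in probs)
    s_max = sum(math.log2(max(row)) for row in probs)
    best = None
    for off in range(len(padded) - W + 1):
        window = padded[off : off + W]
        for strand, win in (("+", window), ("-", revcomp(window))):
            x = oracle_window_score(probs, win)
            if best is None or x > best[0]:
                best = (x, off, strand)
    x, off, strand = best
    rll = 1.0 if s_max == s_min else (x - s_min) / (s_max - s_min)
    rll = min(1.0, max(0.0, rll))
    return x, rll, off, strand


def oracle_auroc(pos, neg) -> float:
    """Direct pairwise U-statistic: wins + half-ties over all pairs."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_affinity_scores(pool, k: int = 8):
    """O(pool^2) substring-count affinity scores (overlapping counts)."""

    def count_in(seq, kmer):
        return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == kmer)

    scores = []
    for hit in pool:
        best = 0
        for i in range(len(hit) - k + 1):
            kmer = hit[i : i + k]
            occ = sum(count_in(other, kmer) for other in pool)
            best = max(best, occ)
        scores.append(best)
    return scores
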