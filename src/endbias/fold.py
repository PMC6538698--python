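"""Base-pair-maximization proxies for RNA self-folding and duplex pairing.

Thermodynamic folding engines report minimum free energies; for ranking
species by structure propensity a monotone stand-in suffices. The proxy
maximizes Watson-Crick + GU base pairs under the classic non-crossing
(Nussinov) recursion with a minimum hairpin loop of 3, and a duplex proxy
maximizes non-crossing antiparallel pairs between two strands. Scores are
pair counts (higher = more structure); an external provider implementing
the same protocol can supply real energies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

#: allowed pairs: Watson-Crick plus the GU wobble (T stands for U)
PAIRABLE = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                      ("G", "T"), ("T", "G")})

MIN_HAIRPIN_LOOP = 3


def pairable(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


@dataclass
class SelfFoldResult:
    """Maximal pairing of a single strand."""

    pairs: int           # number of base pairs (the score)
    pairing: list[tuple[int, int]]  # 0-based (i, j) pairs of one traceback
    free_5p: int         # consecutive unpaired bases from the 5' end
    free_3p: int         # consecutive unpaired bases from the 3' end


class FoldProvider(Protocol):
    """Protocol for pluggable structure-score providers."""

    def self_fold(self, seq: str) -> SelfFoldResult: ...

    def duplex_score(self, a: str, b: str) -> float: ...


def _nussinov_matrix(seq: str, min_loop: int) -> np.ndarray:
    n = len(seq)
    M = np.zeros((n, n), dtype=int)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pairable(seq[i], seq[k]):
                    left = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = M[k + 1, j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            M[i, j] = best
    return M


def _traceback(seq: str, M: np.ndarray, min_loop: int) -> list[tuple[int, int]]:
    # prefer pairing i with the largest admissible k so that terminal bases
    # pair whenever a maximal structure allows it (deterministic)
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(seq) - 1)] if len(seq) > 1 else []
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = M[i, j]
        paired = False
        for k in range(j, i + min_loop, -1):
            if pairable(seq[i], seq[k]):
                left = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = M[k + 1, j] if k + 1 <= j else 0
                if 1 + left + right == target:
                    pairs.append((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return sorted(pairs)


def max_self_pairs(seq: str, min_loop: int = MIN_HAIRPIN_LOOP) -> SelfFoldResult:
    """Maximal non-crossing self-pairing with one deterministic traceback."""
    n = len(seq)
    if n <= min_loop + 1:
        return SelfFoldResult(pairs=0, pairing=[], free_5p=n, free_3p=n)
    M = _nussinov_matrix(seq, min_loop)
    pairing = _traceback(seq, M, min_loop)
    assert len(pairing) == M[0, n - 1]
    if pairing:
        paired_pos = sorted({p for ij in pairing for p in ij})
        free_5p = paired_pos[0]
        free_3p = n - 1 - paired_pos[-1]
    else:
        free_5p = free_3p = n
    return SelfFoldResult(pairs=int(M[0, n - 1]), pairing=pairing,
                          free_5p=free_5p, free_3p=free_3p)


def max_duplex_pairs(a: str, b: str) -> int:
    """Maximal non-crossing antiparallel pairing between two strands.

    Pairs (i, j) with a[i] opposite b[j] must be nested antiparallel:
    i increasing along a means j decreasing along b. Equivalent to a
    longest-common-subsequence recursion between a and reversed b under
    the pairability predicate.
    """
    c = b[::-1]
    n, m = len(a), len(c)
    D = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = max(D[i - 1, j], D[i, j - 1])
            if pairable(a[i - 1], c[j - 1]):
                D[i, j] = max(D[i, j], D[i - 1, j - 1] + 1)
    return int(D[n, m])


class MaxPairingProvider:
    """The built-in pair-count proxy provider."""

    def __init__(self, min_loop: int = MIN_HAIRPIN_LOOP):
        self.min_loop = min_loop

    def self_fold(self, seq: str) -> SelfFoldResult:
        return max_self_pairs(seq, self.min_loop)

    def duplex_score(self, a: str, b: str) -> float:
        return float(max_duplex_pairs(a, b))
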