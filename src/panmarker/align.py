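"""Global pairwise alignment and percent identity.

The identity statistic used throughout the toolkit is computed from an
optimal global (Needleman-Wunsch/Gotoh) alignment under affine gap costs:

* match +1, mismatch -1
* a gap of length g costs ``gap_open + g * gap_extend`` = -4 - 2g

``identity = matches / alignment_length`` where *alignment_length* counts
every alignment column, including gap columns.  Normalising by the full
alignment length (rather than the shorter sequence) penalises length
mismatch, which is what separates genuinely orthologous genes from chance
similarity between unrelated sequences.

The gap costs are deliberately stiff.  With cheap gaps (e.g. open -2,
extend -1) the optimal alignment of two *unrelated* equal-length
sequences chases matches through gaps and its identity converges on
~0.50 — exactly the cross-taxon specificity threshold, leaving no margin
between "absent" and "borderline".  At open -4 / extend -2 the unrelated
background sits near 0.40 while genuinely homologous genes (which
diverge by substitutions far more than by indels) are unaffected, so the
0.50 / 0.90 decision thresholds have headroom on both sides.

Among co-optimal alignments the statistic is made canonical by a
lexicographic objective: maximise score, then matches, then minimise
alignment length.  Both this implementation and the brute-force test
oracle optimise the same triple, so the reported identity is well defined
independent of traceback order.

Degenerate IUPAC symbols are legal input but align like ordinary symbols:
a column is a match only when the two symbols are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
import numpy as np
from numba import njit

__all__ = ["AlignmentScore", "pairwise_identity", "identity_upper_bound"]

MATCH = 1
MISMATCH = -1
GAP_OPEN = -4
GAP_EXTEND = -2

# Packed int64 cell layout: (score + _SOFF) << 26 | matches << 13 | (_LCAP - length).
# Lexicographic max on the packed key == max on (score, matches, -length).
_SOFF = 1 << 17
_LCAP = (1 << 13) - 1
_NEG = np.int64(-(1 << 60))


@dataclass(frozen=True)
class AlignmentScore:
    """Match count, alignment length and fractional identity of one pair."""

    matches: int
    alignment_length: int
    identity: float
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.matches <= self.alignment_length:
            raise ValueError("matches must lie in [0, alignment_length]")


@njit(cache=True)
def _gotoh_packed(a: np.ndarray, b: np.ndarray) -> np.int64:  # pragma: no cover
    la, lb = a.shape[0], b.shape[0]
    one_col = np.int64(1)  # length field decrement per alignment column
    diag_match = (np.int64(MATCH) << 26) + (np.int64(1) << 13) - one_col
    diag_mis = (np.int64(MISMATCH) << 26) - one_col
    open_step = (np.int64(GAP_OPEN + GAP_EXTEND) << 26) - one_col
    ext_step = (np.int64(GAP_EXTEND) << 26) - one_col

    width = lb + 1
    m_prev = np.full(width, _NEG)
    x_prev = np.full(width, _NEG)  # gap in b (consumes a)
    y_prev = np.full(width, _NEG)  # gap in a (consumes b)
    m_cur = np.empty(width, np.int64)
    x_cur = np.empty(width, np.int64)
    y_cur = np.empty(width, np.int64)

    origin = (np.int64(_SOFF) << 26) | np.int64(_LCAP)
    m_prev[0] = origin
    for j in range(1, width):
        y_prev[j] = (origin if j == 1 else y_prev[j - 1]) + (open_step if j == 1 else ext_step)

    for i in range(1, la + 1):
        m_cur[0] = _NEG
        y_cur[0] = _NEG
        best_up = max(m_prev[0], x_prev[0], y_prev[0])
        x_cur[0] = (x_prev[0] + ext_step) if x_prev[0] > max(m_prev[0], y_prev[0]) else (best_up + open_step)
        if i == 1:
            x_cur[0] = origin + open_step
        ai = a[i - 1]
        for j in range(1, width):
            d = max(m_prev[j - 1], x_prev[j - 1], y_prev[j - 1])
            m_cur[j] = d + (diag_match if ai == b[j - 1] else diag_mis)
            # gap in b: move down (consume a[i-1])
            xo = max(m_prev[j], y_prev[j]) + open_step
            xe = x_prev[j] + ext_step
            x_cur[j] = xo if xo > xe else xe
            # gap in a: move right (consume b[j-1])
            yo = max(m_cur[j - 1], x_cur[j - 1]) + open_step
            ye = y_cur[j - 1] + ext_step
            y_cur[j] = yo if yo > ye else ye
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev

    return max(m_prev[lb], x_prev[lb], y_prev[lb])


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@lru_cache(maxsize=1 << 17)
def pairwise_identity(a: str, b: str) -> AlignmentScore:
    """Optimal global alignment identity of two nucleotide sequences.

    Raises ``ValueError`` on an empty sequence or on inputs long enough to
    overflow the packed dynamic-programming cell (sum of lengths > 8000 nt;
    genes, markers and amplicons are all far below this).  Results are
    memoised: marker screening aligns the same representative/gene pairs
    for several target taxa.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if len(a) + len(b) > 8000:
        raise ValueError("sequences too long for the packed alignment kernel")
    key = int(_gotoh_packed(_encode(a), _encode(b)))
    score = (key >> 26) - _SOFF
    matches = (key >> 13) & ((1 << 13) - 1)
    length = _LCAP - (key & ((1 << 13) - 1))
    return AlignmentScore(
        matches=matches,
        alignment_length=length,
        identity=matches / length,
        score=score,
    )


def identity_upper_bound(a: str, b: str) -> float:
    """Cheap provable upper bound on ``pairwise_identity(a, b).identity``.

    Any alignment with m matches, x mismatches and g gap columns satisfies
    ``len(a) + len(b) = 2m + 2x + g`` and ``x + g >= ed`` (the unit-cost
    Levenshtein distance), hence ``m <= (len(a) + len(b) - ed) / 2``; the
    alignment length is at least ``max(len(a), len(b))``.  The bound is
    used to skip full dynamic programming when scanning for best hits: a
    candidate whose bound falls below the running maximum can never win.
    """
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        raise ValueError("identity_upper_bound requires non-empty sequences")
    hi = max(la, lb)
    ratio = min(la, lb) / hi
    if ratio < 0.25:  # already hopeless for any practical threshold
        return ratio
    ed = edlib.align(a.upper(), b.upper(), task="distance")["editDistance"]
    return min(ratio, (la + lb - ed) / (2.0 * hi))
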