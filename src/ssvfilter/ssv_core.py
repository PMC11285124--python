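"""Ungapped-segment dynamic programming engines.

Three routes over the same projected scores:

* :func:`ssv_max_score` — full-precision maximum ungapped diagonal segment
  score, the recurrence M(i,j) = max(0, M(i-1,j-1)) + score(j, codes[i]).
* :func:`ssv_hits_rowmajor` — the 8-bit threshold-hit recurrence with
  reset-on-underflow/overflow cell semantics, evaluated cell by cell in plain
  row-major order. Written as straight loops so it can serve as the reference
  for the vectorized segmented engine.
* :func:`ssv_hits_segmented` — the identical recurrence evaluated in the
  accelerator's order: the padded target is cut into width-n segments, each
  segment sweeps all model positions, and a score queue carries the rightmost
  column of one segment to the leftmost column of the next.

A cell update takes the diagonal predecessor accumulator M in [0, 255], adds
the signed 8-bit emission P: if the sum is negative the accumulator resets to
0; if it reaches 256 the cell is a hit and the accumulator resets to 0;
otherwise the sum is kept. The hardware checks the same two conditions with
an 8-bit adder's carry bit and the emission's sign bit
(:func:`cell_update_adder`), which is equivalent — see the exhaustive test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Set, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .sequence_io import SequenceDB

HIT_THRESHOLD = 256


class GlobalHit(NamedTuple):
    """DP cell (0-based global sequence position, global model position)."""

    seq_pos: int
    model_pos: int


@dataclass
class SegmentConfig:
    """Width of one sequence segment in the segmented evaluation order.

    The hardware instantiates 12,288 cell processing elements; software
    callers may pick any n >= 1.
    """

    n: int = 12288

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("segment width must be >= 1")


def cell_update(m_prev: int, p: int) -> tuple[int, bool]:
    """One reset-rule cell update: (new accumulator, hit flag).

    ``m_prev`` is the diagonal predecessor in [0, 255]; ``p`` is the signed
    8-bit emission score.
    """
    t = m_prev + p
    if t < 0:
        return 0, False
    if t >= HIT_THRESHOLD:
        return 0, True
    return t, False


def cell_update_adder(m_prev: int, p: int) -> tuple[int, bool]:
    """The same update via 8-bit full-adder carry and emission sign bits.

    The emission is taken as its two's-complement byte; the adder produces an
    8-bit sum and a carry. A clear carry with a negative emission means the
    unsigned sum underflowed (reset); a set carry with a positive emission
    means the sum overflowed 256 (hit and reset).
    """
    p_byte = p & 0xFF
    total = (m_prev & 0xFF) + p_byte
    carry = total >= 256
    sum8 = total & 0xFF
    negative = (p_byte & 0x80) != 0
    if negative and not carry:
        return 0, False  # underflow
    if not negative and carry:
        return 0, True  # overflow: threshold passed
    return sum8, False


def _emission_lookup(codes: np.ndarray, scores: np.ndarray) -> None:
    if scores.ndim != 2 or scores.shape[1] != 4:
        raise ValueError("scores must be a (K, 4) matrix over the 4-letter alphabet")
    if codes.size == 0:
        raise ValueError("codes must be non-empty")


def ssv_max_score(codes: np.ndarray, scores: np.ndarray) -> float:
    """Maximum ungapped diagonal segment score, at the scores' precision.

    Equals the maximum, over every diagonal segment of the L x K matrix, of
    the segment's summed emission scores (single cells included, so the
    result is never below the best single selected entry).
    """
    codes = np.asarray(codes)
    scores = np.asarray(scores)
    _emission_lookup(codes, scores)
    return float(ssv_max_scores_batch(codes[np.newaxis, :], scores)[0])


def ssv_max_scores_batch(codes: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Row-wise :func:`ssv_max_score` for a (B, L) batch of code vectors."""
    codes = np.atleast_2d(np.asarray(codes))
    scores = np.asarray(scores, dtype=np.float64)
    B, L = codes.shape
    K = scores.shape[0]
    prev = np.zeros((B, L))
    best = np.full(B, -np.inf)
    for j in range(K):
        emis = scores[j][codes]
        cur = np.empty((B, L))
        cur[:, 0] = emis[:, 0]
        np.maximum(prev[:, :-1], 0.0, out=prev[:, :-1])
        cur[:, 1:] = prev[:, :-1] + emis[:, 1:]
        np.maximum(best, cur.max(axis=1), out=best)
        prev = cur
    return best


def ssv_hits_rowmajor(codes: np.ndarray, scores8: np.ndarray) -> Set[GlobalHit]:
    """All threshold-crossing cells, evaluated in row-major order.

    Reference implementation: plain Python loops, one :func:`cell_update`
    per cell, accumulator bound asserted after every update.
    """
    codes = np.asarray(codes)
    scores8 = np.asarray(scores8)
    _emission_lookup(codes, scores8)
    if scores8.min() < -128 or scores8.max() > 127:
        raise ValueError("scores8 entries must lie in [-128, 127]")
    L = codes.size
    K = scores8.shape[0]
    emis = [[int(scores8[j, c]) for c in range(4)] for j in range(K)]
    hits: set[GlobalHit] = set()
    prev_row = [0] * K  # M(i-1, :)
    for i in range(L):
        c = int(codes[i])
        row = [0] * K
        for j in range(K):
            m_prev = prev_row[j - 1] if j > 0 else 0
            m, hit = cell_update(m_prev, emis[j][c])
            assert 0 <= m <= 255
            if hit:
                hits.add(GlobalHit(i, j))
            row[j] = m
        prev_row = row
    return hits


def ssv_hits_segmented_codes(
    codes: np.ndarray, scores8: np.ndarray, n: int
) -> Set[GlobalHit]:
    """Segmented-order hit evaluation over a raw code vector.

    ``len(codes)`` must be a multiple of ``n``. Produces exactly the
    row-major hit set: the score queue hands the last row of each segment
    column to the first row of the next, so every cell sees the same diagonal
    predecessor in both orders.
    """
    codes = np.asarray(codes)
    scores8 = np.asarray(scores8)
    _emission_lookup(codes, scores8)
    L = codes.size
    if L % n != 0:
        raise ValueError(f"code length {L} is not a multiple of segment width {n}")
    K = scores8.shape[0]
    S = scores8.astype(np.int32)
    hits: set[GlobalHit] = set()
    queue = np.zeros(K, dtype=np.int32)  # last-row M of the previous segment, per column
    pred = np.empty(n, dtype=np.int32)
    for seg in range(L // n):
        base = seg * n
        seg_codes = codes[base : base + n]
        prev_col = np.zeros(n, dtype=np.int32)
        out_queue = np.empty(K, dtype=np.int32)
        for j in range(K):
            pred[0] = queue[j - 1] if (seg > 0 and j > 0) else 0
            pred[1:] = prev_col[:-1]
            t = pred + S[j][seg_codes]
            over = t >= HIT_THRESHOLD
            if over.any():
                for i in np.flatnonzero(over):
                    hits.add(GlobalHit(base + int(i), j))
            prev_col = np.where((t < 0) | over, 0, t)
            out_queue[j] = prev_col[-1]
        queue = out_queue
    return hits


def ssv_hits_segmented(
    db: "SequenceDB", scores8: np.ndarray, cfg: SegmentConfig | None = None
) -> Set[GlobalHit]:
    """Segmented-order hits over a concatenated, padded sequence database."""
    cfg = cfg or SegmentConfig()
    if db.padded_length % cfg.n != 0:
        raise ValueError(
            f"padded length {db.padded_length} is not a multiple of n={cfg.n}"
        )
    return ssv_hits_segmented_codes(db.concatenated, scores8, cfg.n)
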