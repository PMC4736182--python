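"""Ungapped both-strand sequence similarity.

A single scoring engine backs both the division planner (overlap-vs-flank
mispriming risk) and primer selection (candidate-vs-template off-target
risk): the score of a query against a region is the maximum number of
positional base matches over every ungapped alignment of the query with a
full-length window of the region, on either strand. The shorter of the two
strings is slid inside the longer, so the score is symmetric in that sense
and never credits bases that hang off an end.

Higher scores mean a worse (more mispriming-prone) choice. Scores are pure
match counts; callers multiply by their per-base weight.
"""

from __future__ import annotations

import numpy as np

from .sequence import complement, reverse_complement

__all__ = [
    "max_ungapped_matches",
    "offtarget_score",
    "division_score",
    "DivisionScoreTable",
]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def max_ungapped_matches(query: str, region: str, *, exclude_offset: int | None = None) -> int:
    """Best positional match count of ``query`` against windows of ``region``.

    Alignments place the shorter string at every full-window offset of the
    longer. ``exclude_offset`` skips one window start (0-based, on
    ``region``); it is only meaningful when ``query`` fits inside
    ``region`` and is used to mask a primer's intended binding site.
    """
    if not query or not region:
        return 0
    if len(query) > len(region):
        query, region = region, query
        exclude_offset = None
    q = _encode(query)
    r = _encode(region)
    windows = np.lib.stride_tricks.sliding_window_view(r, len(q))
    counts = (windows == q).sum(axis=1)
    if exclude_offset is not None and 0 <= exclude_offset < len(counts):
        counts = counts.copy()
        counts[exclude_offset] = -1
    return int(counts.max())


def offtarget_score(
    query: str,
    region: str,
    *,
    exclude_sense_offset: int | None = None,
) -> int:
    """Both-strand version of :func:`max_ungapped_matches`.

    The reverse-strand contribution scores the reverse complement of the
    query against the sense representation of the region, which counts the
    Watson-Crick pairings the query could form with the region's bottom
    strand. The exclusion applies to the sense strand only (a primer's
    intended site exists on one strand).
    """
    sense = max_ungapped_matches(query, region, exclude_offset=exclude_sense_offset)
    anti = max_ungapped_matches(reverse_complement(query), region)
    return max(sense, anti)


def division_score(overlap: str, left_flank: str, right_flank: str, match_score: float = 1.0) -> float:
    """Mispriming risk of a candidate junction overlap.

    The overlap must prime uniquely at the junction; any similar window in
    either child's non-overlap flank is a competing annealing site. Empty
    flanks contribute nothing.
    """
    best = max(offtarget_score(overlap, left_flank), offtarget_score(overlap, right_flank))
    return best * match_score


class DivisionScoreTable:
    """Vectorized junction scores for every candidate division of one sequence.

    For a sequence S of length L, a candidate is a pair (p, v): p sense
    bases in the left child before the junction, a v-base overlap
    S[p+1..p+v] (1-based), flanks S[1..p] and S[p+v+1..L]. The table
    computes ``division_score`` for all (p, v) with v in [vmin, vmax] using
    running diagonal / anti-diagonal sums of the base-identity matrices, in
    O(vmax * L^2) total — the per-candidate reference costs that much for a
    handful of candidates.

    ``score(p, v)`` is exact: the few edge candidates whose flank is
    shorter than the overlap fall back to the reference scorer.
    """

    def __init__(self, sequence: str, vmin: int, vmax: int, match_score: float = 1.0):
        self.sequence = sequence
        self.vmin = vmin
        self.vmax = vmax
        self.match_score = match_score
        self._tables: dict[int, np.ndarray] = {}
        self._build()

    def _build(self) -> None:
        S = self.sequence
        L = len(S)
        s = _encode(S)
        c = _encode(complement(S))
        M = (s[:, None] == s[None, :]).astype(np.int16)
        A = (s[:, None] == c[None, :]).astype(np.int16)
        T = M.copy()  # T[i, j] = matches of S[i:i+v] vs S[j:j+v]
        U = A.copy()  # U[i, j] = matches of S[i:i+v] vs revcomp window ending at j
        for v in range(1, self.vmax + 1):
            if v >= self.vmin:
                self._tables[v] = self._scores_for_v(T, U, v, L)
            if v < self.vmax and v < L:
                T[: L - v, : L - v] += M[v:, v:]
                U[: L - v, v:] += A[v:, : L - v]

    def _scores_for_v(self, T: np.ndarray, U: np.ndarray, v: int, L: int) -> np.ndarray:
        """Per-p best window score at overlap length v; -1 flags fallback."""
        # valid window starts: j <= L - v for T; window ends j >= v - 1 for U
        nw = L - v + 1
        if nw <= 0:
            return np.full(L, -1, dtype=np.int32)
        Tv = T[:nw, :nw].astype(np.int32)
        Uv = U[:nw, v - 1 :].astype(np.int32)  # column j' = j - (v-1)
        ct = np.maximum.accumulate(Tv, axis=1)
        st = np.maximum.accumulate(Tv[:, ::-1], axis=1)[:, ::-1]
        cu = np.maximum.accumulate(Uv, axis=1)
        su = np.maximum.accumulate(Uv[:, ::-1], axis=1)[:, ::-1]
        out = np.full(L, -1, dtype=np.int32)
        for p in range(1, L - v):
            if p < v or L - p - v < v:
                continue  # flank shorter than overlap: reference fallback
            best = 0
            # sense strand, left flank: windows at o in [0, p-v]
            best = max(best, int(ct[p, p - v]))
            # sense strand, right flank: windows at o in [p+v, L-v]
            if p + v <= L - v:
                best = max(best, int(st[p, p + v]))
            # reverse strand, left flank: window ends j in [v-1, p-1]
            best = max(best, int(cu[p, p - v]))
            # reverse strand, right flank: window ends j in [p+2v-1, L-1]
            if p + 2 * v - 1 <= L - 1:
                best = max(best, int(su[p, p + v]))
            out[p] = best
        return out

    def score(self, p: int, v: int) -> float:
        """Score for candidate (p, v); p is 1-based split position == left flank length."""
        arr = self._tables.get(v)
        cached = int(arr[p]) if arr is not None and 0 <= p < len(arr) else -1
        if cached >= 0:
            return cached * self.match_score
        S = self.sequence
        return division_score(S[p : p + v], S[:p], S[p + v :], self.match_score)
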