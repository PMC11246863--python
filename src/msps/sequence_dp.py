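"""Maximum-scoring segment sets: the MSPS problem on path graphs.

For a sequence of weights ``w_1 .. w_n`` and a startup penalty ``c``, find
disjoint segments maximizing the total of (segment weight sum - c).  This is
the classic linear-time two-state dynamic program: ``M[i, 0]`` / ``M[i, 1]``
is the best score over the prefix ``1..i`` with vertex ``i`` unused / used.

    M[1,0] = 0                      M[1,1] = w_1 - c
    M[i,0] = max(M[i-1,0], M[i-1,1])
    M[i,1] = max(M[i-1,0] + w_i - c, M[i-1,1] + w_i)

A new segment is only ever opened after an unused position: if one segment
ended at ``i-1`` and another started at ``i``, merging them would save one
penalty ``c >= 0``, so the restriction loses nothing.  The answer is
``max(M[n,0], M[n,1])``.
"""

from __future__ import annotations

from typing import Sequence

__all__ = ["SegmentTable", "solve_sequence", "compute_table"]


class SegmentTable:
    """DP table ``M[i, j]`` with traceback choices.

    Indices are 1-based to match the recurrence; intervals reported by
    :func:`solve_sequence` are 0-based half-open.
    """

    def __init__(self, weights: Sequence[float], c: float):
        if len(weights) == 0:
            raise ValueError("weight sequence must be nonempty")
        if c < 0:
            raise ValueError("penalty c must be non-negative")
        n = len(weights)
        self.n = n
        self.c = float(c)
        self.M = [[0.0, 0.0] for _ in range(n + 1)]
        # choice[i][j]: predecessor state j' at i-1 (None at i=1)
        self.choice: list = [[None, None] for _ in range(n + 1)]
        self.M[1][0] = 0.0
        self.M[1][1] = weights[0] - c
        for i in range(2, n + 1):
            w = weights[i - 1]
            prev0, prev1 = self.M[i - 1]
            # ties prefer the predecessor with the vertex unused (j' = 0),
            # which yields minimal coverage among optimal solutions
            if prev0 >= prev1:
                self.M[i][0], self.choice[i][0] = prev0, 0
            else:
                self.M[i][0], self.choice[i][0] = prev1, 1
            start, extend = prev0 + w - c, prev1 + w
            if start >= extend:
                self.M[i][1], self.choice[i][1] = start, 0
            else:
                self.M[i][1], self.choice[i][1] = extend, 1

    @property
    def optimum(self) -> float:
        return max(self.M[self.n][0], self.M[self.n][1])

    def traceback(self) -> list:
        """Selected segments as 0-based half-open ``(start, stop)`` intervals."""
        j = 0 if self.M[self.n][0] >= self.M[self.n][1] else 1
        used = []
        for i in range(self.n, 0, -1):
            used.append(j == 1)
            j = self.choice[i][j] if self.choice[i][j] is not None else 0
        used.reverse()
        intervals = []
        i = 0
        while i < self.n:
            if used[i]:
                j = i
                while j < self.n and used[j]:
                    j += 1
                intervals.append((i, j))
                i = j
            else:
                i += 1
        return intervals


def compute_table(weights: Sequence[float], c: float) -> SegmentTable:
    return SegmentTable(weights, c)


def solve_sequence(weights: Sequence[float], c: float):
    """Optimal segment set for a weight sequence.

    Returns ``(score, intervals)`` where intervals are disjoint 0-based
    half-open ``(start, stop)`` pairs in increasing order whose segment
    scores sum to the optimum.
    """
    table = SegmentTable(weights, c)
    return table.optimum, table.traceback()
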