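"""Greedy subsequence dynamic-time-warping used for gait-cycle matching.

The template is repeatedly aligned to the (1-D, typically decimated)
envelope with open start and end: the dynamic program allows a match to
begin at any column, tracks each path's start column, and reports the
normalized alignment cost of ending the template at every column.  The
best-scoring match is accepted, its span masked, and the program
recomputed locally until no admissible span remains.

The global warping constraint is a window on each match's warped length:
``len in template_len * (1 ± band_frac)``.  Masked columns carry
infinite local cost, so successive matches are disjoint by construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INF = np.inf


@njit(cache=True)
def _dp_region(x, t, masked, D, S, j0, j1):  # pragma: no cover - jit
    """Fill columns [j0, j1) of the accumulated-cost/start matrices.

    D[i, j]: minimal cost of aligning template[0..i] to a signal span
    ending at column j; S[i, j]: start column of that span.  Row 0 starts
    a fresh match at its own column (open start).
    """
    M = t.shape[0]
    for j in range(j0, j1):
        if masked[j]:
            for i in range(M):
                D[i, j] = _INF
                S[i, j] = -1
            continue
        for i in range(M):
            local = (x[j] - t[i]) ** 2
            if i == 0:
                D[0, j] = local
                S[0, j] = j
            else:
                best = _INF
                bs = -1
                if j > 0 and D[i - 1, j - 1] < best:
                    best = D[i - 1, j - 1]
                    bs = S[i - 1, j - 1]
                if D[i - 1, j] < best:
                    best = D[i - 1, j]
                    bs = S[i - 1, j]
                if j > 0 and D[i, j - 1] < best:
                    best = D[i, j - 1]
                    bs = S[i, j - 1]
                if best < _INF:
                    D[i, j] = local + best
                    S[i, j] = bs
                else:
                    D[i, j] = _INF
                    S[i, j] = -1


def greedy_subsequence_matches(
    x: np.ndarray, template: np.ndarray, band_frac: float = 0.25
) -> list[tuple[int, int, float]]:
    """All disjoint template matches in ``x``, greedily by alignment cost.

    Returns ``(start, end, normalized_cost)`` half-open spans sorted by
    start.  Matching stops when every unmasked gap is shorter than half a
    template length (nothing segmentable remains).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    t = np.ascontiguousarray(template, dtype=np.float64)
    N, M = x.shape[0], t.shape[0]
    if N < 2 * M:
        raise ValueError(f"signal ({N}) shorter than 2 template lengths ({2 * M})")
    lo = int(np.floor(M * (1.0 - band_frac)))
    hi = int(np.ceil(M * (1.0 + band_frac)))

    D = np.empty((M, N))
    S = np.empty((M, N), dtype=np.int64)
    masked = np.zeros(N, dtype=np.bool_)
    _dp_region(x, t, masked, D, S, 0, N)

    ends = np.arange(N)
    matches: list[tuple[int, int, float]] = []
    max_iter = N // max(1, lo // 2) + 2
    for _ in range(max_iter):
        starts = S[M - 1]
        lengths = ends - starts + 1
        delta = D[M - 1] / M
        valid = (starts >= 0) & (lengths >= lo) & (lengths <= hi) & np.isfinite(delta)
        if not valid.any():
            break
        j = int(np.argmin(np.where(valid, delta, _INF)))
        a = int(starts[j])
        matches.append((a, j + 1, float(delta[j])))
        masked[a : j + 1] = True
        # Paths ending within ~2*hi after the mask could have crossed it:
        # recompute that region (columns before the mask are unaffected).
        _dp_region(x, t, masked, D, S, a, min(N, j + 1 + 2 * hi))
        # Stop once no unmasked run can hold half a template.
        if _longest_unmasked_run(masked) < max(1, M // 2):
            break
    matches.sort()
    return matches


def _longest_unmasked_run(masked: np.ndarray) -> int:
    padded = np.concatenate(([True], masked, [True]))
    gaps = np.diff(np.flatnonzero(padded)) - 1
    return int(gaps.max()) if gaps.size else 0
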