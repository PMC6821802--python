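"""Banded affine-gap local alignment.

The extension stage of the seed-and-extend classifier and the contig
annotator both use this dynamic-programming core.  Scoring is match +1,
mismatch -1, and affine gaps where a gap of length L costs
``gap_open + (L-1) * gap_extend`` (first gap base -2, each further base -1),
matching the convention of Smith–Waterman as implemented by common local
aligners.  The band is centred on a seed diagonal, so the search is
O(query_length * band_width).
"""

from __future__ import annotations

from dataclasses import dataclass

NEG = -(10 ** 9)


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    identity: float
    aligned_len: int      # alignment columns
    n_matches: int
    q_start: int          # 0-based half-open on the query
    q_end: int
    t_start: int          # 0-based half-open on the target
    t_end: int


def banded_local_align(query: str, target: str, diag: int, band: int = 16,
                       match: int = 1, mismatch: int = -1,
                       gap_open: int = -2, gap_extend: int = -1) -> AlignmentResult | None:
    """Best local alignment whose path stays within ``band`` of ``diag``.

    ``diag`` is the expected offset ``t_pos - q_pos`` from a seed hit.
    Returns None when no positive-scoring alignment exists in the band.
    Ties on the optimal score resolve to the first-ending cell in row-major
    order, which makes results deterministic.
    """
    m, n = len(query), len(target)
    W = 2 * band + 1

    # Three-state affine DP over (row i = query bases consumed, offset d).
    # Cell (i, d) corresponds to target position j = i + diag + d - band.
    M = [[NEG] * W for _ in range(m + 1)]
    Ix = [[NEG] * W for _ in range(m + 1)]   # gap in target (consumes query)
    Iy = [[NEG] * W for _ in range(m + 1)]   # gap in query (consumes target)
    ptrM = [[0] * W for _ in range(m + 1)]   # 0 start, 1 M, 2 Ix, 3 Iy
    ptrX = [[0] * W for _ in range(m + 1)]   # 1 from M, 2 from Ix
    ptrY = [[0] * W for _ in range(m + 1)]

    best = 0
    best_cell = None
    for i in range(1, m + 1):
        qc = query[i - 1]
        Mi, Xi, Yi = M[i], Ix[i], Iy[i]
        Mp, Xp, Yp = M[i - 1], Ix[i - 1], Iy[i - 1]
        pMi, pXi, pYi = ptrM[i], ptrX[i], ptrY[i]
        for d in range(W):
            j = i + diag + d - band
            if j < 1 or j > n:
                continue
            # --- M: consume (q[i-1], t[j-1]) diagonally ---
            pm, px, py = Mp[d], Xp[d], Yp[d]
            b, ptr = 0, 0
            if pm > b:
                b, ptr = pm, 1
            if px > b:
                b, ptr = px, 2
            if py > b:
                b, ptr = py, 3
            s = match if qc == target[j - 1] else mismatch
            Mi[d] = b + s
            pMi[d] = ptr
            # --- Ix: consume q[i-1] against a gap (from row i-1, offset d+1) ---
            if d + 1 < W:
                a1 = Mp[d + 1] + gap_open
                a2 = Xp[d + 1] + gap_extend
                if a1 >= a2:
                    Xi[d], pXi[d] = a1, 1
                else:
                    Xi[d], pXi[d] = a2, 2
            # --- Iy: consume t[j-1] against a gap (same row, offset d-1) ---
            if d >= 1:
                a1 = Mi[d - 1] + gap_open
                a2 = Yi[d - 1] + gap_extend
                if a1 >= a2:
                    Yi[d], pYi[d] = a1, 1
                else:
                    Yi[d], pYi[d] = a2, 2
            if Mi[d] > best:
                best = Mi[d]
                best_cell = (i, d)

    if best_cell is None or best <= 0:
        return None

    # Traceback from the best M cell.
    i, d = best_cell
    q_end = i
    t_end = i + diag + d - band
    matrix = "M"
    n_matches = 0
    cols = 0
    while True:
        if matrix == "M":
            j = i + diag + d - band
            cols += 1
            if query[i - 1] == target[j - 1]:
                n_matches += 1
            ptr = ptrM[i][d]
            i -= 1
            if ptr == 0:
                break
            matrix = ("M", "Ix", "Iy")[ptr - 1]
        elif matrix == "Ix":
            cols += 1
            ptr = ptrX[i][d]
            i -= 1
            d += 1
            matrix = "M" if ptr == 1 else "Ix"
        else:  # Iy
            cols += 1
            ptr = ptrY[i][d]
            d -= 1
            matrix = "M" if ptr == 1 else "Iy"
    q_start = i
    t_start = i + diag + d - band
    return AlignmentResult(
        score=best,
        identity=n_matches / cols,
        aligned_len=cols,
        n_matches=n_matches,
        q_start=q_start, q_end=q_end,
        t_start=t_start, t_end=t_end,
    )
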