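"""Global pairwise alignment and p-distance.

The aligner is a standard Needleman–Wunsch with end-gap penalties, scoring
match +1 / mismatch -1 / gap -2 (linear), and a deterministic traceback that
prefers diagonal, then up (consume x), then left (consume y).  The score
matrix is filled row-wise with a prefix-max trick so each row is a handful of
vectorised numpy operations; for the <=2 kb segments this pipeline aligns
(inter-anchor gaps, insert sequences, CDS + promoter regions) that is fast
enough without a compiled extension.

'N' never matches anything, including another 'N'.
"""

from __future__ import annotations

import numpy as np

MATCH = 1
MISMATCH = -1
GAP = -2

# refuse to allocate absurd DP matrices (the pipeline never needs them)
_MAX_CELLS = 30_000_000

GAP_CHAR = "-"


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    return arr


def nw_matrix(x: str, y: str) -> np.ndarray:
    """Full (len(x)+1, len(y)+1) int32 score matrix."""
    n, m = len(x), len(y)
    if (n + 1) * (m + 1) > _MAX_CELLS:
        raise ValueError(
            f"alignment of {n} x {m} exceeds the supported problem size"
        )
    xa, ya = _encode(x), _encode(y)
    n_code = ord("N")
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = GAP * np.arange(m + 1, dtype=np.int32)
    idx = np.arange(m, dtype=np.int64)
    for i in range(1, n + 1):
        prev = H[i - 1]
        sub = np.where(
            (ya == xa[i - 1]) & (ya != n_code) & (xa[i - 1] != n_code),
            MATCH,
            MISMATCH,
        ).astype(np.int32)
        # candidate without any leftward (gap-in-x) move on this row
        d = np.empty(m + 1, dtype=np.int64)
        d[0] = prev[0] + GAP
        d[1:] = np.maximum(prev[:-1] + sub, prev[1:] + GAP)
        # H[i, j] = max_{j' <= j} d[j'] + GAP * (j - j')
        shifted = d[1:] - GAP * (idx + 1)
        best = np.maximum.accumulate(np.concatenate(([d[0]], shifted)))
        row = best + GAP * np.arange(m + 1, dtype=np.int64)
        H[i] = row.astype(np.int32)
    return H


def nw_transcript(x: str, y: str) -> str:
    """Edit transcript of the optimal global alignment.

    Ops: 'M' match, 'X' mismatch, 'D' consume x only (gap in y),
    'I' consume y only (gap in x).  Traceback preference: diagonal, up, left.
    """
    H = nw_matrix(x, y)
    n_code = ord("N")
    i, j = len(x), len(y)
    ops: list[str] = []
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0:
            a, b = x[i - 1], y[j - 1]
            match = a == b and a != "N" and b != "N"
            s = MATCH if match else MISMATCH
            if h == H[i - 1, j - 1] + s:
                ops.append("M" if match else "X")
                i -= 1
                j -= 1
                continue
        if i > 0 and h == H[i - 1, j] + GAP:
            ops.append("D")
            i -= 1
            continue
        ops.append("I")
        j -= 1
    return "".join(reversed(ops))


def nw_score(x: str, y: str) -> int:
    return int(nw_matrix(x, y)[len(x), len(y)])


def align_pair(seq_x: str, seq_y: str) -> tuple[str, str]:
    """Globally align two sequences; returns the gapped pair of equal length."""
    if not seq_x or not seq_y:
        raise ValueError("align_pair requires non-empty sequences")
    transcript = nw_transcript(seq_x, seq_y)
    ax: list[str] = []
    ay: list[str] = []
    i = j = 0
    for op in transcript:
        if op in "MX":
            ax.append(seq_x[i])
            ay.append(seq_y[j])
            i += 1
            j += 1
        elif op == "D":
            ax.append(seq_x[i])
            ay.append(GAP_CHAR)
            i += 1
        else:
            ax.append(GAP_CHAR)
            ay.append(seq_y[j])
            j += 1
    return "".join(ax), "".join(ay)


def p_distance(aligned_x: str, aligned_y: str) -> float:
    """Proportion of differing sites among gap-free alignment columns.

    Columns containing a gap in either sequence are excluded from both the
    numerator and the denominator.
    """
    if len(aligned_x) != len(aligned_y):
        raise ValueError("aligned sequences must have equal length")
    compared = 0
    mismatches = 0
    for a, b in zip(aligned_x, aligned_y):
        if a == GAP_CHAR or b == GAP_CHAR:
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise ValueError("p-distance undefined: no gap-free columns to compare")
    return mismatches / compared


def percent_identity(seq_x: str, seq_y: str) -> float:
    """Identity over all alignment columns (gap columns count as differences)."""
    ax, ay = align_pair(seq_x, seq_y)
    matches = sum(1 for a, b in zip(ax, ay) if a == b and a != GAP_CHAR)
    return 100.0 * matches / len(ax)
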