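"""Global pairwise alignment and percent identity.

Identity between two proteins is defined as the number of identical aligned
residue pairs divided by the length of the shorter sequence, computed on a
Needleman-Wunsch global alignment (match +2, mismatch -1, gap -2 per residue,
terminal gaps penalized).  Among all score-optimal alignments the one with the
largest number of identical pairs is used, which makes the value well defined;
the dynamic program tracks the (score, identities) pair lexicographically.

The inner loop is numba-compiled when numba is importable and falls back to
pure Python otherwise.
"""

from __future__ import annotations

import numpy as np

DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -1
DEFAULT_GAP = -2


def _nw_kernel_py(a, b, match, mismatch, gap):
    n = a.shape[0]
    m = b.shape[0]
    prev_s = np.empty(m + 1, dtype=np.int64)
    prev_i = np.empty(m + 1, dtype=np.int64)
    prev_c = np.empty(m + 1, dtype=np.int64)
    cur_s = np.empty(m + 1, dtype=np.int64)
    cur_i = np.empty(m + 1, dtype=np.int64)
    cur_c = np.empty(m + 1, dtype=np.int64)
    for j in range(m + 1):
        prev_s[j] = gap * j
        prev_i[j] = 0
        prev_c[j] = 0
    for i in range(1, n + 1):
        cur_s[0] = gap * i
        cur_i[0] = 0
        cur_c[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                ds = prev_s[j - 1] + match
                di = prev_i[j - 1] + 1
            else:
                ds = prev_s[j - 1] + mismatch
                di = prev_i[j - 1]
            dc = prev_c[j - 1] + 1
            bs, bi, bc = ds, di, dc
            us = prev_s[j] + gap
            if us > bs or (us == bs and prev_i[j] > bi):
                bs, bi, bc = us, prev_i[j], prev_c[j]
            ls = cur_s[j - 1] + gap
            if ls > bs or (ls == bs and cur_i[j - 1] > bi):
                bs, bi, bc = ls, cur_i[j - 1], cur_c[j - 1]
            cur_s[j] = bs
            cur_i[j] = bi
            cur_c[j] = bc
        prev_s, cur_s = cur_s, prev_s
        prev_i, cur_i = cur_i, prev_i
        prev_c, cur_c = cur_c, prev_c
    return prev_s[m], prev_i[m], prev_c[m]


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _nw_kernel = njit(cache=True)(_nw_kernel_py)
except ImportError:  # pragma: no cover
    _nw_kernel = _nw_kernel_py


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align_stats(
    a: str,
    b: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> tuple[int, int, int]:
    """Optimal global alignment of ``a`` vs ``b``.

    Returns ``(score, identities, aligned_columns)`` where ``identities`` is
    maximal among score-optimal alignments and ``aligned_columns`` counts the
    residue-residue (non-gap) columns of that alignment.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    s, i, c = _nw_kernel(_encode(a), _encode(b), match, mismatch, gap)
    return int(s), int(i), int(c)


def pairwise_identity(
    a: str,
    b: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> float:
    """Fraction of identical aligned residue pairs over the shorter sequence.

    Symmetric, 1.0 for identical sequences, in [0, 1] always.
    """
    _, ident, _ = align_stats(a, b, match, mismatch, gap)
    return ident / min(len(a), len(b))
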