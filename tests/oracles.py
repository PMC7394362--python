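"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written without importing the corresponding
bismine internals, so that agreement between the two is a real check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import rankdata

MATCH, MISMATCH, GAP = 2, -1, -2


def enumerate_alignment_identity(a: str, b: str) -> tuple[int, int]:
    """(best score, max identities among best) by full path enumeration.

    Exponential in the sequence lengths; use only for very short sequences.
    """
    best = {"score": None, "ident": 0}

    def rec(i: int, j: int, score: int, ident: int) -> None:
        if i == len(a) and j == len(b):
            if (
                best["score"] is None
                or score > best["score"]
                or (score == best["score"] and ident > best["ident"])
            ):
                best["score"], best["ident"] = score, ident
            return
        if i < len(a) and j < len(b):
            eq = a[i] == b[j]
            rec(i + 1, j + 1, score + (MATCH if eq else MISMATCH), ident + eq)
        if i < len(a):
            rec(i + 1, j, score + GAP, ident)
        if j < len(b):
            rec(i, j + 1, score + GAP, ident)

    rec(0, 0, 0, 0)
    return best["score"], best["ident"]


def dp_alignment_identity(a: str, b: str) -> tuple[int, int]:
    """Full-matrix (score, identities) DP over Python tuples."""
    n, m = len(a), len(b)
    H = [[(GAP * (i + j), 0) for j in range(m + 1)] for i in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = (GAP * i, 0)
    for j in range(1, m + 1):
        H[0][j] = (GAP * j, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eq = a[i - 1] == b[j - 1]
            diag = (
                H[i - 1][j - 1][0] + (MATCH if eq else MISMATCH),
                H[i - 1][j - 1][1] + eq,
            )
            up = (H[i - 1][j][0] + GAP, H[i - 1][j][1])
            left = (H[i][j - 1][0] + GAP, H[i][j - 1][1])
            H[i][j] = max(diag, up, left)
    return H[n][m]


def identity_oracle(a: str, b: str) -> float:
    _, ident = dp_alignment_identity(a, b)
    return ident / min(len(a), len(b))


def greedy_cluster_oracle(proteins, threshold: float):
    """Naive re-run of the greedy rule, identity via the tuple DP."""
    ordered = sorted(proteins, key=lambda t: (-len(t[1]), t[0]))
    clusters: list[list] = []  # [centroid_seq, [ids]]
    for pid, seq in ordered:
        for c in clusters:
            if identity_oracle(seq, c[0]) >= threshold:
                c[1].append(pid)
                break
        else:
            clusters.append([seq, [pid]])
    return [frozenset(c[1]) for c in clusters]


def pair_weight_oracle(a, b) -> int:
    return sum(min(x, y) for x, y in zip(a, b))


def count_hits_oracle(records, roster_names) -> dict:
    counts = {g: 0 for g in roster_names}
    for _, row in records.iterrows():
        key = row["sseqid"] if row["sseqid"] in counts else "other"
        counts[key] = counts.get(key, 0) + 1
    return counts


def best_hit_oracle(records):
    """Per-read argmin over (evalue, -bitscore, sseqid) by explicit loops."""
    best = {}
    for _, row in records.iterrows():
        key = row["qseqid"]
        cand = (row["evalue"], -row["bitscore"], row["sseqid"])
        if key not in best or cand < best[key][0]:
            best[key] = (cand, row)
    return {k: v[1]["sseqid"] for k, v in best.items()}


def evalue_filter_oracle(records, cutoff):
    return [i for i, row in records.iterrows() if row["evalue"] <= cutoff]


def anchor_filter_oracle(hits, min_bitscore, max_evalue):
    first = [h for h in hits if h.bitscore > min_bitscore]
    return [h for h in first if h.evalue < max_evalue]


def exact_ranksum_p(a, b) -> float:
    """Two-sided exact permutation p for the rank-sum statistic (midranks).

    Two-sidedness is deviation-based — P(|W - mu| >= |w_obs - mu|) over all
    group assignments — the exact analogue of the two-sided normal test on
    |z|.  For untied symmetric configurations this coincides with doubling
    the smaller tail (e.g. {1,2,3} vs {4,5,6} gives 2/20 = 0.1).
    """
    a = list(a)
    b = list(b)
    pooled = np.asarray(a + b, dtype=float)
    ranks = rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    ws = np.array([ranks[list(c)].sum() for c in combinations(range(len(pooled)), n_a)])
    mu = ws.mean()
    return float(np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12))
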