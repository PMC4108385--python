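"""Independent reference implementations used to check the package.

Everything here is deliberately written from first principles (brute-force
enumeration, memoized recursion) and shares no code with the implementation
under test.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

BLOSUM62 = substitution_matrices.load("BLOSUM62")
NEG_INF = float("-inf")
STOPS = {"TAA", "TAG", "TGA"}


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# Needleman–Wunsch affine-gap score by memoized recursion (Gotoh states).
# Gap of length L costs open + (L-1)*extend.

def nw_affine_score(a: str, b: str, gap_open: float = -10.0, gap_extend: float = -0.5) -> float:
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        # best score of aligning a[:i] with b[:j], ending in the given state
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG_INF
        if state == "M":
            if i == 0 or j == 0:
                return NEG_INF
            sub = float(BLOSUM62[a[i - 1]][b[j - 1]])
            return sub + max(best(i - 1, j - 1, s) for s in "MXY")
        if state == "X":  # a[i-1] aligned to a gap
            if i == 0:
                return NEG_INF
            return max(
                best(i - 1, j, "M") + gap_open,
                best(i - 1, j, "X") + gap_extend,
                best(i - 1, j, "Y") + gap_open,
            )
        # state == "Y": b[j-1] aligned to a gap
        if j == 0:
            return NEG_INF
        return max(
            best(i, j - 1, "M") + gap_open,
            best(i, j - 1, "X") + gap_open,
            best(i, j - 1, "Y") + gap_extend,
        )

    return max(best(n, m, s) for s in "MXY")


# ---------------------------------------------------------------------------
# NG86 site and difference counts by explicit neighbour/pathway enumeration.

def site_counts_oracle(codon: str) -> tuple[float, float]:
    s = n = 0.0
    for pos in range(3):
        outcomes = []
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in STOPS:
                continue
            outcomes.append(aa(mut) == aa(codon))
        if outcomes:
            frac_syn = sum(outcomes) / len(outcomes)
            s += frac_syn
            n += 1.0 - frac_syn
    return s, n


def diff_counts_oracle(ca: str, cb: str) -> tuple[float, float]:
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    path_counts = []
    for order in itertools.permutations(positions):
        cur, syn, non, blocked = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
                break
            if aa(nxt) == aa(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        if not blocked:
            path_counts.append((syn, non))
    assert path_counts, "all pathways blocked (not expected for sense codons)"
    k = len(path_counts)
    return sum(p[0] for p in path_counts) / k, sum(p[1] for p in path_counts) / k


# ---------------------------------------------------------------------------
# Reciprocal best hits by explicit per-gene scan.

def rbh_oracle(hits) -> set[tuple[str, str]]:
    top: dict[tuple[str, str], tuple[float, float]] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        rank = (h.bit_score, h.percent_identity)
        if key not in top or rank > top[key]:
            top[key] = rank
    genes = {q for q, _ in top} | {s for _, s in top}
    best: dict[str, str] = {}
    for g in sorted(genes):
        partners = [(s, r) for (q, s), r in top.items() if q == g]
        if not partners:
            continue
        partners.sort(key=lambda x: (-x[1][0], -x[1][1], x[0]))
        best[g] = partners[0][0]
    out = set()
    for g, partner in best.items():
        if best.get(partner) == g:
            out.add((min(g, partner), max(g, partner)))
    return out


# ---------------------------------------------------------------------------
# Exact two-sided rank-sum p-value by enumerating all group assignments.

def ranksum_exact_p(x: list[float], y: list[float]) -> float:
    import itertools as it

    pooled = sorted(x + y)
    ranks = {}
    for v in set(pooled):
        idx = [i + 1 for i, p in enumerate(pooled) if p == v]
        ranks[v] = sum(idx) / len(idx)
    w_obs = sum(ranks[v] for v in x)
    nx = len(x)
    n = len(pooled)
    values = x + y
    stats_all = []
    for combo in it.combinations(range(n), nx):
        stats_all.append(sum(ranks[values[i]] for i in combo))
    mean_w = sum(stats_all) / len(stats_all)
    extreme = sum(abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9 for w in stats_all)
    return extreme / len(stats_all)
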