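"""Independent brute-force oracles used to check the package's algorithms.

Everything here is deliberately naive (full enumeration, per-base masks,
codon walks) and shares no code with the implementations under test.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _pair_ok(b1: str, b2: str) -> bool:
    return _COMP.get(b1) == b2


def _arms_complementary(s: str, l: int, a: int, g: int) -> bool:
    r = l + a + g
    return all(_pair_ok(s[l + k], s[r + a - 1 - k]) for k in range(a))


def brute_force_dyads(s: str, min_arm=5, max_arm=100, max_spacer=20):
    """Enumerate all (left_start, arm, spacer) triples; keep maximal dyads."""
    s = s.upper()
    n = len(s)
    out = []
    for a in range(min_arm, min(max_arm, n // 2) + 1):
        for g in range(max_spacer + 1):
            span = 2 * a + g
            if span > n:
                break
            for l in range(n - span + 1):
                if not _arms_complementary(s, l, a, g):
                    continue
                # outward extension: arms grow by one base on each end
                if (
                    a + 1 <= max_arm
                    and l - 1 >= 0
                    and l + span < n
                    and _pair_ok(s[l - 1], s[l + span])
                ):
                    continue
                # inward extension: arms absorb the two innermost spacer flanks
                if (
                    g - 2 >= 0
                    and a + 1 <= max_arm
                    and _pair_ok(s[l + a], s[l + a + g - 1])
                ):
                    continue
                out.append((l, a, g))
    out.sort(key=lambda t: (t[0], -t[1], t[2]))
    return out


def mask_density(seq_length: int, dyads, include_spacer: bool = False) -> float:
    covered = np.zeros(seq_length, dtype=bool)
    for l, a, g in dyads:
        if include_spacer:
            covered[l : l + 2 * a + g] = True
        else:
            covered[l : l + a] = True
            covered[l + a + g : l + 2 * a + g] = True
    return covered.sum() / seq_length


# ---------------------------------------------------------------------------
# rank statistics


def kendall_stat(x, y) -> int:
    """C - D by direct pair counting."""
    t = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        t += int(np.sign((x[i] - x[j]) * (y[i] - y[j])))
    return t


def kendall_tau_b(x, y) -> float:
    n = len(x)
    n0 = n * (n - 1) // 2
    t = kendall_stat(x, y)

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return int(sum(c * (c - 1) // 2 for c in counts))

    return t / np.sqrt((n0 - tie_term(x)) * (n0 - tie_term(y)))


def kendall_perm_pvalue(x, y) -> float:
    """Two-sided p by enumerating every permutation of y (tie-free input)."""
    t_obs = abs(kendall_stat(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(kendall_stat(x, perm)) >= t_obs:
            hits += 1
    return hits / total


def mannwhitney_u(a, b) -> float:
    u = 0.0
    for va in a:
        for vb in b:
            u += (va > vb) + 0.5 * (va == vb)
    return u


def ranksum_null_pmf(n_a: int, n_b: int) -> dict[float, float]:
    """Exact null distribution of U_a over all rank splits (no ties)."""
    ranks = list(range(1, n_a + n_b + 1))
    pmf: dict[float, int] = {}
    for combo in itertools.combinations(ranks, n_a):
        rest = [r for r in ranks if r not in combo]
        u = mannwhitney_u(combo, rest)
        pmf[u] = pmf.get(u, 0) + 1
    total = comb(n_a + n_b, n_a)
    return {u: c / total for u, c in pmf.items()}


def ranksum_exact_pvalue(a, b) -> float:
    """Two-sided exact p: 2·min(P(U≤u), P(U≥u)) capped at 1 (tie-free input)."""
    u_obs = mannwhitney_u(a, b)
    pmf = ranksum_null_pmf(len(a), len(b))
    cdf = sum(p for u, p in pmf.items() if u <= u_obs)
    sf = sum(p for u, p in pmf.items() if u >= u_obs)
    return min(1.0, 2.0 * min(cdf, sf))


def holm_stepdown(p_values) -> list[float]:
    """Direct step-down formula: q_(i) = max_{j<=i} min(1, (m-j+1)·p_(j))."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p_values[idx]))
        q[idx] = running
    return q


# ---------------------------------------------------------------------------
# Dollo


def _edges(tree):
    """(branch_id, leafset) for every non-root node of a SpeciesTree."""
    out = []
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        out.append(("|".join(sorted(node.leafset)), frozenset(node.leafset)))
    return out


def dollo_min_events(tree, absent: frozenset) -> set[str]:
    """Smallest Dollo-consistent branch set explaining the absence pattern.

    Searches subsets of branches by increasing size; a subset is consistent
    when every chosen branch's leaves are all absent and their union is
    exactly the absent set.  The minimum is unique for Dollo characters.
    """
    if not absent:
        return set()
    edges = [(bid, ls) for bid, ls in _edges(tree) if ls <= absent]
    for size in range(1, len(edges) + 1):
        found = []
        for combo in itertools.combinations(edges, size):
            union = frozenset().union(*(ls for _, ls in combo))
            if union == absent:
                found.append({bid for bid, _ in combo})
        if found:
            assert len(found) == 1, "minimum Dollo reconstruction must be unique"
            return found[0]
    raise AssertionError("no consistent reconstruction")


def maximal_absent_clades(tree, absent: frozenset) -> set[str]:
    """Branch ids of maximal subtrees whose leaves are all absent."""
    chosen = []
    for bid, ls in _edges(tree):
        if ls <= absent:
            chosen.append((bid, ls))
    return {
        bid
        for bid, ls in chosen
        if not any(ls < other for _, other in chosen)
    }


# ---------------------------------------------------------------------------
# ORFs

_STOPS = {"TAA", "TAG", "TGA"}
_RC = str.maketrans("ACGTN", "TGCAN")

_CODON_TABLE = None


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).translate())


def orf_oracle(seq: str, min_len: int = 75, both_strands: bool = True):
    """Six-frame ATG→stop scan; keeps the 5'-most ATG per (strand, frame, stop).

    Returns tuples (start, end, strand, protein) in forward coordinates,
    sorted by length desc then start.
    """
    s = seq.upper()
    n = len(s)
    results = []
    strands = [("+", s)]
    if both_strands:
        strands.append(("-", s.translate(_RC)[::-1]))
    for strand, work in strands:
        best: dict[tuple, tuple] = {}  # (frame, stop_end) -> (start, end)
        for i in range(n - 2):
            if work[i : i + 3] != "ATG":
                continue
            j = i
            stop_end = None
            while j + 3 <= n:
                if work[j : j + 3] in _STOPS:
                    stop_end = j + 3
                    break
                j += 3
            if stop_end is None:
                continue
            key = (i % 3, stop_end)
            if key not in best or i < best[key][0]:
                best[key] = (i, stop_end)
        for (frame, stop_end), (start, end) in best.items():
            if end - start < min_len:
                continue
            protein = _translate(work[start : end - 3])
            if strand == "+":
                results.append((start, end, "+", protein))
            else:
                results.append((n - end, n - start, "-", protein))
    results.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    return results
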