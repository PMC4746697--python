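"""Independent brute-force oracles used by the test suite.

Each oracle is written from the problem definition, deliberately avoiding
the package's own code paths: a pure-Python Gotoh local aligner, a
longest-path-on-DAG duplex solver (networkx), full enumeration of all
alignments for tiny duplex toys, a naive substring scanner, and an
enumerate-everything phase-run detector.
"""

from __future__ import annotations

import networkx as nx

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}


def pairs_ok(p: str, q: str, allow_gu: bool = True) -> bool:
    return (p, q) in _WC or (allow_gu and (p, q) in _GU)


def gotoh_local_score(
    x: str,
    y: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> int:
    """Optimal local alignment score with affine gaps costing
    ``gap_open + (L - 1) * gap_extend`` for a gap of length L.  Matches are
    literal character equality (N never matches)."""
    n, m = len(x), len(y)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in x (consume y)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in y (consume x)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (x[i - 1] == y[j - 1] and x[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def duplex_dag_score(
    a: str, b: str, lam: float = 1.0, allow_gu: bool = True
) -> float:
    """Best duplex score (pairs − lam·bubble columns) via longest path in the
    alignment DAG — an algorithmic route independent of the package's DP.

    ``a`` runs 5'→3'; ``b`` is the partner window, traversed 3'→5'.
    """
    rb = b[::-1]
    n, m = len(a), len(rb)
    g = nx.DiGraph()
    src, snk = "S", "T"
    for i in range(n + 1):
        for j in range(m + 1):
            node = (i, j)
            g.add_edge(src, node, weight=0.0)
            g.add_edge(node, snk, weight=0.0)
            if i < n and j < m and pairs_ok(a[i], rb[j], allow_gu):
                g.add_edge(node, (i + 1, j + 1), weight=1.0)
            if i < n:
                g.add_edge(node, (i + 1, j), weight=-lam)
            if j < m:
                g.add_edge(node, (i, j + 1), weight=-lam)
    return nx.dag_longest_path_length(g, weight="weight")


def duplex_enumerate_score(
    a: str, b: str, lam: float = 1.0, allow_gu: bool = True
) -> float:
    """Exhaustive enumeration of every monotone alignment of ``a`` against
    ``b`` (3'→5'), scoring pairs − lam·gap columns and keeping the best
    contiguous (local) stretch.  Exponential; use only for toys ≤ 8 nt."""
    rb = b[::-1]
    n, m = len(a), len(rb)
    best = 0.0

    def walk(i: int, j: int, score: float, best_here: float) -> None:
        nonlocal best
        best = max(best, best_here)
        if i == n or j == m:
            return
        if pairs_ok(a[i], rb[j], allow_gu):
            s = score + 1.0
            walk(i + 1, j + 1, s, max(best_here, s))
        walk(i + 1, j, score - lam, best_here)
        walk(i, j + 1, score - lam, best_here)

    # every start cell begins a fresh local alignment
    for i in range(n):
        for j in range(m):
            walk(i, j, 0.0, 0.0)
    return best


def naive_occurrences(read: str, transcript: str) -> list[int]:
    """All 1-based start positions where ``read`` matches exactly."""
    return [
        i + 1
        for i in range(len(transcript) - len(read) + 1)
        if transcript[i : i + len(read)] == read
    ]


def brute_force_phase_runs(
    a_start: int,
    a_end: int,
    b_start: int,
    b_end: int,
    sense_starts: set[int],
    anti_starts: set[int],
    n: int,
    min_duplexes: int = 4,
    min_region_len: int = 81,
) -> set[tuple[int, int, int]]:
    """All maximal phased runs as (register, first_slot_start, n_phases),
    found by checking every (register, start, length) combination.

    ``sense_starts`` are 5′ ends on transcript A, ``anti_starts`` 5′ ends on
    transcript B; evidence and footprint rules follow the 2-nt 3′-overhang
    duplex geometry inside the segment.
    """
    length = a_end - a_start + 1
    if length < min_region_len or length < n + 2:
        return set()

    def evidenced(i: int) -> bool:
        if i in sense_starts and i + n - 1 <= a_end:
            return True
        # antisense partner: B 5' end at sense coordinate i+n-3, footprint
        # (sense coords) [i-2, i+n-3] fully inside the segment
        b5 = b_start + (a_end - (i + n - 3))
        return i - 2 >= a_start and b5 in anti_starts and b5 + n - 1 <= b_end

    runs: set[tuple[int, int, int]] = set()
    for r in range(n):
        slots = list(range(a_start + r, a_end - n + 2, n))
        for t0 in range(len(slots)):
            for t1 in range(t0, len(slots)):
                k = t1 - t0 + 1
                if k < min_duplexes:
                    continue
                if not all(evidenced(slots[t]) for t in range(t0, t1 + 1)):
                    continue
                left_ok = t0 == 0 or not evidenced(slots[t0 - 1])
                right_ok = t1 == len(slots) - 1 or not evidenced(slots[t1 + 1])
                if left_ok and right_ok:
                    runs.add((r, slots[t0], k))
    return runs


def all_kmer_pairs(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}
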