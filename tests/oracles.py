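"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration from the
definition, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices


def brute_force_window_mismatches(residues: str, pattern) -> list[int]:
    """Mismatch count of every window against a compiled pattern, by direct
    character comparison (sequence 'X' fails every non-wildcard element)."""
    m = pattern.length
    counts = []
    for s in range(len(residues) - m + 1):
        mm = 0
        for el, ch in zip(pattern.elements, residues[s:s + m]):
            if el is not None and ch not in el:
                mm += 1
        counts.append(mm)
    return counts


def brute_force_hits(residues: str, pattern, max_mismatches: int) -> list[tuple[int, int]]:
    """[(1-based start, n_mismatches), ...] for windows within the budget."""
    return [
        (s + 1, mm)
        for s, mm in enumerate(brute_force_window_mismatches(residues, pattern))
        if mm <= max_mismatches
    ]


def _alignment_score(cols: list[tuple[str, str]], matrix, gap_open: float, gap_extend: float) -> float:
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in cols:
        if ca == "-":
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += matrix[ca, cb]
            in_gap_a = in_gap_b = False
    return score


def exhaustive_global_score(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0,
    matrix_name: str = "BLOSUM62",
) -> float:
    """Optimal global affine-gap score by enumerating every alignment.

    Feasible only for short sequences (the number of alignments grows as
    the Delannoy numbers).
    """
    matrix = substitution_matrices.load(matrix_name)
    best = [float("-inf")]

    def rec(i: int, j: int, cols: list[tuple[str, str]]) -> None:
        if i == len(a) and j == len(b):
            s = _alignment_score(cols, matrix, gap_open, gap_extend)
            if s > best[0]:
                best[0] = s
            return
        if i < len(a) and j < len(b):
            cols.append((a[i], b[j]))
            rec(i + 1, j + 1, cols)
            cols.pop()
        if i < len(a):
            cols.append((a[i], "-"))
            rec(i + 1, j, cols)
            cols.pop()
        if j < len(b):
            cols.append(("-", b[j]))
            rec(i, j + 1, cols)
            cols.pop()

    rec(0, 0, [])
    return best[0]


def all_splits_of_tree(tree) -> list[frozenset]:
    """Every bipartition of a tree (internal and trivial), one side each."""
    out = [frozenset([t.name]) for t in tree.tips()]
    for node in tree.non_tips(include_self=False):
        out.append(frozenset(t.name for t in node.tips()))
    return out


def brute_force_transfer_distance(light: frozenset, replicate) -> int:
    """Minimum Hamming distance from ``light`` to any replicate bipartition,
    trying both orientations of every split explicitly."""
    all_tips = frozenset(t.name for t in replicate.tips())
    best = None
    for side in all_splits_of_tree(replicate):
        for oriented in (side, all_tips - side):
            d = len(light ^ oriented)
            if best is None or d < best:
                best = d
    return best
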