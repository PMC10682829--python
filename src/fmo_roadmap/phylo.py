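"""Distance trees with classical and transfer-bootstrap branch support.

A deliberately desk-scale inference stack: Poisson-corrected distances
from pairwise-deleted alignment columns, canonical neighbor-joining,
midpoint rooting, Felsenstein site resampling, and branch support both as
the classical bootstrap proportion and as the transfer bootstrap
expectation (TBE).  For a reference branch b with light-side size p, each
replicate tree T* contributes 1 − δ(b, T*)/(p − 1), where the transfer
distance δ is the minimum Hamming distance between the bipartition of b
and any bipartition of T*; TBE is the mean over replicates.  δ = 0 exactly
when the branch occurs in the replicate, so TBE ≥ classical support
branch-wise, and on cherries (p = 2) the two measures coincide.

Trees are :class:`skbio.TreeNode` objects throughout; Newick is written
with 6-decimal branch lengths and ``classical/tbe`` internal labels.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from math import log
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .core_io import GAP, MultipleAlignment

#: Distances are undefined past this observed mismatch fraction.
SATURATION_P = 0.95


class SaturationError(ValueError):
    """Observed divergence too high for a finite Poisson distance."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = self.values
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(d < 0):
            raise ValueError("distance matrix contains negative entries")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)


def poisson_distance(row_a: str, row_b: str) -> float:
    """Poisson-corrected distance −ln(1 − p) between two aligned rows.

    Columns where either row has a gap or an unknown residue are skipped
    (pairwise deletion).  Raises :class:`SaturationError` when the
    mismatch fraction p reaches :data:`SATURATION_P`.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    scored = 0
    mismatches = 0
    for ca, cb in zip(row_a, row_b):
        if ca in (GAP, "X") or cb in (GAP, "X"):
            continue
        scored += 1
        if ca != cb:
            mismatches += 1
    if scored == 0:
        raise ValueError("no scored columns between rows (all gaps/unknowns)")
    p = mismatches / scored
    if p >= SATURATION_P:
        raise SaturationError(
            f"mismatch fraction {p:.3f} ≥ {SATURATION_P}; distance saturated"
        )
    return -log(1.0 - p)


def alignment_distance_matrix(
    msa: MultipleAlignment, saturation: str = "error"
) -> DistanceMatrix:
    """All-pairs Poisson distance matrix from an alignment.

    ``saturation="cap"`` replaces saturated pairs with −ln(1 − 0.95)
    (with a warning) instead of raising, for robustness in pipelines that
    must tolerate arbitrary inputs.
    """
    ids = msa.ids
    n = len(ids)
    d = np.zeros((n, n))
    cap = -log(1.0 - SATURATION_P)
    chars = np.array([np.frombuffer(row.encode("ascii"), dtype=np.uint8)
                      for _, row in msa.rows])
    valid = (chars != ord(GAP)) & (chars != ord("X"))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            scored = int(both.sum())
            if scored == 0:
                raise ValueError(
                    f"no scored columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = int((chars[i][both] != chars[j][both]).sum()) / scored
            if p >= SATURATION_P:
                if saturation != "cap":
                    raise SaturationError(
                        f"mismatch fraction {p:.3f} between {ids[i]!r} and "
                        f"{ids[j]!r} ≥ {SATURATION_P}; distance saturated"
                    )
                warnings.warn(
                    f"distance {ids[i]}–{ids[j]} saturated; capped at {cap:.4f}",
                    stacklevel=2,
                )
                dij = cap
            else:
                dij = -log(1.0 - p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=ids, values=d)


def _clamped(length: float, label: str) -> float:
    if length < 0:
        warnings.warn(
            f"negative NJ branch length {length:.6f} at {label}; clamped to 0",
            stacklevel=3,
        )
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor-joining; returns an unrooted (trifurcating) tree.

    The pair minimising the Q-criterion is joined each round; among ties
    the lexicographically smallest label pair wins.  Negative branch-length
    estimates are clamped to zero with a warning.
    """
    if dm.n < 3:
        raise ValueError(f"neighbor joining needs ≥3 taxa, got {dm.n}")
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    labels = list(dm.labels)
    d = dm.values.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            (min(labels[i], labels[j]), max(labels[i], labels[j]), i, j)
            for i, j in zip(*np.nonzero(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if i < j
        ]
        _, _, i, j = min(candidates)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamped(li, labels[i])
        child_j.length = _clamped(lj, labels[j])
        parent = TreeNode(children=[child_i, child_j])
        new_label = f"({labels[i]},{labels[j]})"

        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.empty(len(keep))
        for idx, k in enumerate(keep):
            d_new[idx] = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d_new
        d[:-1, -1] = d_new
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = _clamped(0.5 * (dab + dac - dbc), labels[0])
    b.length = _clamped(0.5 * (dab + dbc - dac), labels[1])
    c.length = _clamped(0.5 * (dac + dbc - dab), labels[2])
    return TreeNode(children=[a, b, c])


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    lengths = [n.length or 0.0 for n in tree.traverse() if n.parent is not None]
    if not any(l > 0 for l in lengths):
        raise ValueError("cannot midpoint-root a tree whose branch lengths are all zero")
    tips = list(tree.tips())
    if len(tips) == 2:
        half = sum(t.length or 0.0 for t in tips) / 2.0
        a = TreeNode(name=tips[0].name, length=half)
        b = TreeNode(name=tips[1].name, length=half)
        return TreeNode(children=[a, b])
    rooted = tree.copy().root_at_midpoint()
    depths = {t.name: rooted.distance(t) for t in rooted.tips()}
    two = sorted(depths.values())[-2:]
    if len(two) == 2 and abs(two[0] - two[1]) > 1e-9:
        # the two deepest leaves must hang at equal depth from the root
        raise AssertionError("midpoint rooting failed to balance the longest path")
    return rooted


def bootstrap_alignment(
    msa: MultipleAlignment, n_replicates: int, seed: int
) -> list[MultipleAlignment]:
    """Felsenstein bootstrap: resample alignment columns with replacement."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be ≥ 1")
    rng = np.random.default_rng(seed)
    chars = np.array([list(row) for _, row in msa.rows])
    n_cols = msa.n_columns
    out = []
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        resampled = chars[:, idx]
        rows = tuple(
            (rid, "".join(resampled[i])) for i, (rid, _) in enumerate(msa.rows)
        )
        out.append(MultipleAlignment(rows=rows))
    return out


def _canonical_split(side: frozenset, all_tips: frozenset) -> frozenset:
    comp = all_tips - side
    if (len(side), tuple(sorted(side))) <= (len(comp), tuple(sorted(comp))):
        return side
    return comp


def tree_splits(tree: TreeNode, include_trivial: bool = False) -> set[frozenset]:
    """Canonical bipartitions (smaller side) induced by the tree's branches."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= min(len(side), len(all_tips) - len(side)):
            splits.add(_canonical_split(side, all_tips))
    if include_trivial:
        for t in all_tips:
            splits.add(frozenset([t]))
    return splits


@dataclass(frozen=True)
class BranchSupport:
    classical: float
    tbe: float
    p: int


@dataclass(frozen=True)
class SupportValues:
    """Per-branch support keyed by the branch's canonical bipartition."""

    supports: dict[frozenset, BranchSupport]
    n_replicates: int


def _transfer_distance(light: frozenset, replicate_splits: set[frozenset], n: int) -> int:
    """Minimum Hamming distance from ``light`` to any replicate bipartition."""
    p = len(light)
    best = p - 1  # achieved by any trivial split {x} with x in light
    for s in replicate_splits:
        inter = len(light & s)
        d_same = p + len(s) - 2 * inter  # |light Δ s|
        d_flip = n - d_same              # |light Δ complement(s)|
        best = min(best, d_same, d_flip)
        if best == 0:
            break
    return best


def branch_support(ref: TreeNode, replicates: list[TreeNode]) -> SupportValues:
    """Classical and TBE support for every internal branch of ``ref``."""
    if not replicates:
        raise ValueError("at least one replicate tree is required")
    ref_tips = frozenset(t.name for t in ref.tips())
    for k, rep in enumerate(replicates):
        rep_tips = frozenset(t.name for t in rep.tips())
        if rep_tips != ref_tips:
            missing = sorted(ref_tips - rep_tips)
            extra = sorted(rep_tips - ref_tips)
            raise ValueError(
                f"replicate {k} leaf set differs from reference "
                f"(missing {missing}, extra {extra})"
            )
    n = len(ref_tips)
    ref_splits = tree_splits(ref)
    rep_internal = [tree_splits(rep) for rep in replicates]
    rep_all = [tree_splits(rep, include_trivial=True) for rep in replicates]

    supports = {}
    for split in ref_splits:
        p = len(split)
        present = sum(1 for s in rep_internal if split in s)
        scores = [
            1.0 - _transfer_distance(split, splits, n) / (p - 1)
            for splits in rep_all
        ]
        supports[split] = BranchSupport(
            classical=present / len(replicates),
            tbe=float(np.mean(scores)),
            p=p,
        )
    return SupportValues(supports=supports, n_replicates=len(replicates))


def annotate_support(tree: TreeNode, support: SupportValues) -> TreeNode:
    """Label internal nodes of a copy of ``tree`` with ``classical/tbe``."""
    out = tree.copy()
    all_tips = frozenset(t.name for t in out.tips())
    for node in out.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = _canonical_split(side, all_tips)
        if key in support.supports:
            s = support.supports[key]
            node.name = f"{s.classical:.2f}/{s.tbe:.2f}"
    return out


_NEEDS_QUOTE = set(" ()[]{}:;,'\"")


def _fmt_label(name: str | None) -> str:
    if not name:
        return ""
    if any(c in _NEEDS_QUOTE for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        s = _fmt_label(node.name)
    else:
        s = "(" + ",".join(_newick_node(c) for c in node.children) + ")" + _fmt_label(node.name)
    if node.length is not None:
        s += f":{node.length:.6f}"
    return s


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick (6-decimal branch lengths)."""
    s = _newick_node(tree) + ";\n"
    if path is not None:
        Path(path).write_text(s, encoding="utf-8")
    return s


def read_newick(source: str | Path) -> TreeNode:
    """Read Newick from a path or a literal string (underscores preserved)."""
    text = None
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif isinstance(source, str):
        if source.lstrip().startswith("(") or ";" in source:
            text = source
        else:
            text = Path(source).read_text(encoding="utf-8")
    return TreeNode.read(io.StringIO(text), convert_underscores=False)
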