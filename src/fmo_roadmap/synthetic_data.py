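"""Synthetic fixtures with known ground truth.

The generator emulates the statistical structure the rest of the package
assumes, without any database download: a shared random protein scaffold
carries two Rossmann ``GXGXXG`` motifs with the FMO fingerprint inserted
directly after the second one (its natural place in the inter-domain
linker), and each clade diverges from the scaffold before acquiring its
diagnostic active-site residues and clade-typical length (~500/450/420/520
residues for clades I-IV).  BVMO outgroup sequences carry the first BVMO
fingerprint instead of the FMO one; NMO outgroup sequences carry neither.

Everything is a pure function of its seed: reruns are byte-identical.
The sequences are not biological — substitutions are uniform over the 19
alternative residues, there are no indels and no site-rate heterogeneity —
but they give every pipeline stage a known truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np
from skbio import TreeNode

from .core_io import AA20, MultipleAlignment, ProteinSequence
from .fingerprint_engine import vet_family
from .reference_panel import (
    ANCHOR_SITES,
    PanelEntry,
    ReferencePanel,
    default_profiles,
)

_AA = np.frombuffer(AA20.encode(), dtype=np.uint8)
_AA_INDEX = {c: i for i, c in enumerate(AA20)}

SCAFFOLD_LENGTH = 560
#: 1-based inclusive spans of the scaffold motifs.
ROSSMANN1_SPAN = (9, 14)
ROSSMANN2_SPAN = (240, 245)
FINGERPRINT_SPAN = (246, 257)       # FMO fingerprint instance
BVMO_FINGERPRINT_SPAN = (246, 260)  # BVMO fingerprint 1 instance

_ROSSMANN1 = "GAGSAG"
_ROSSMANN2 = "GSGNSG"
_FMO_INSTANCE = "FAGSTVHLMNYK"       # matches FxGxxxHxxx(Y/F)(K/R)
_BVMO1_INSTANCE = "GGAWLLLLFPGSTAD"  # matches GGxWxxxx(F/Y)P(G/M)xxxD

CLADE_LENGTHS = {"I": 500, "II": 450, "III": 420, "IV": 520, "BVMO": 560, "NMO": 450}

#: Clade-specific residues at the anchor-numbered diagnostic sites.
CLADE_DIAGNOSTICS = {
    "I":    {56: "Y", 61: "I", 62: "N", 195: "N", 196: "S", 199: "D", 224: "R", 375: "L"},
    "II":   {56: "Y", 61: "T", 62: "N", 195: "Y", 196: "S", 199: "D", 224: "R", 375: "F"},
    "III":  {56: "Y", 61: "L", 62: "N", 195: "C", 196: "S", 199: "E", 224: "R", 375: "A"},
    "IV":   {56: "Y", 61: "L", 62: "Q", 195: "K", 196: "S", 199: "D", 224: "K", 375: "M"},
    "BVMO": {56: "Y", 61: "L", 62: "D", 195: "D", 196: "S", 199: "D", 224: "R", 375: "L"},
    "NMO":  {56: "Y", 61: "L", 62: "Q", 195: "S", 196: "S", 199: "D", 224: "R", 375: "L"},
}

#: Divergence of each clade consensus from the shared scaffold.
CLADE_DIVERGENCE = {"I": 0.30, "II": 0.30, "III": 0.30, "IV": 0.30, "BVMO": 0.45, "NMO": 0.45}
#: Within-clade divergence of each reference from its clade consensus.
REFERENCE_DIVERGENCE = 0.05

ANCHOR_ID = "AncFMO5_syn"


def _to_codes(residues: str) -> np.ndarray:
    return np.array([_AA_INDEX[c] for c in residues], dtype=np.int64)


def _to_str(codes: np.ndarray) -> str:
    return _AA[codes].tobytes().decode()


def default_protected_sites(length: int) -> frozenset[int]:
    """Diagnostic sites plus motif spans (1-based), clipped to ``length``."""
    sites = set(ANCHOR_SITES.values())
    for lo, hi in (ROSSMANN1_SPAN, ROSSMANN2_SPAN, FINGERPRINT_SPAN):
        sites.update(range(lo, hi + 1))
    return frozenset(p for p in sites if p <= length)


def _protected_mask(length: int, protected_sites: frozenset[int]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for pos in protected_sites:
        mask[pos - 1] = True
    return mask


def _mutate(
    codes: np.ndarray, rate: float, protected: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. substitutions at ``rate`` outside protected sites, uniform
    over the 19 alternative residues."""
    out = codes.copy()
    mask = (rng.random(codes.size) < rate) & ~protected
    shift = rng.integers(1, 20, size=codes.size)
    out[mask] = (codes[mask] + shift[mask]) % 20
    return out


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for one synthetic query set."""

    seed: int
    clade: str
    mutation_rate: float
    length: int | None = None
    protected_sites: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.clade not in CLADE_LENGTHS:
            raise ValueError(f"unknown clade {self.clade!r}")
        if self.length is not None:
            lo, hi = default_profiles()[self.clade].length_range
            if not lo <= self.length <= hi:
                raise ValueError(
                    f"length {self.length} outside clade {self.clade} range ({lo}, {hi})"
                )


def _build_scaffold(rng: np.random.Generator) -> np.ndarray:
    codes = rng.integers(0, 20, size=SCAFFOLD_LENGTH)
    for (lo, _), motif in (
        (ROSSMANN1_SPAN, _ROSSMANN1),
        (ROSSMANN2_SPAN, _ROSSMANN2),
        (FINGERPRINT_SPAN, _FMO_INSTANCE),
    ):
        codes[lo - 1:lo - 1 + len(motif)] = _to_codes(motif)
    return codes


def _apply_clade_identity(codes: np.ndarray, clade: str) -> None:
    for pos, residue in CLADE_DIAGNOSTICS[clade].items():
        if pos <= codes.size:
            codes[pos - 1] = _AA_INDEX[residue]
    if clade == "BVMO":
        lo = BVMO_FINGERPRINT_SPAN[0] - 1
        codes[lo:lo + len(_BVMO1_INSTANCE)] = _to_codes(_BVMO1_INSTANCE)
    elif clade == "NMO":
        # no family fingerprint at all (none is defined for NMOs)
        pass


_INTENDED_VERDICT = {
    "I": "FMO_candidate", "II": "FMO_candidate",
    "III": "FMO_candidate", "IV": "FMO_candidate",
    "BVMO": "BVMO_candidate", "NMO": "none",
}


def _draw_clade_sequence(
    scaffold: np.ndarray,
    clade: str,
    rate: float,
    rng: np.random.Generator,
    base: np.ndarray | None = None,
    replace_fingerprint_span: bool = False,
    max_tries: int = 50,
) -> np.ndarray:
    """Mutated copy of ``base`` (default: scaffold prefix) with the clade's
    diagnostic identity, re-drawn until fingerprint vetting matches the
    clade's intended verdict (random sequence can otherwise create stray
    near-fingerprint windows)."""
    length = CLADE_LENGTHS[clade]
    if base is None:
        base = scaffold[:length]
    protected = _protected_mask(base.size, default_protected_sites(base.size))
    if replace_fingerprint_span or clade == "NMO":
        lo, hi = FINGERPRINT_SPAN
        protected[lo - 1:hi] = False
    for _ in range(max_tries):
        codes = _mutate(base, rate, protected, rng)
        if replace_fingerprint_span:
            # NMO consensus: drop the FMO fingerprint entirely
            lo, hi = FINGERPRINT_SPAN
            codes[lo - 1:hi] = rng.integers(0, 20, size=hi - lo + 1)
        _apply_clade_identity(codes, clade)
        seq = ProteinSequence(id="candidate", residues=_to_str(codes))
        if vet_family(seq).verdict == _INTENDED_VERDICT[clade]:
            return codes
    raise RuntimeError(f"could not draw a clean {clade} sequence in {max_tries} tries")


def _clade_consensuses(seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    scaffold = _build_scaffold(rng)
    return {
        clade: _draw_clade_sequence(
            scaffold,
            clade,
            CLADE_DIVERGENCE[clade],
            rng,
            replace_fingerprint_span=(clade == "NMO"),
        )
        for clade in ("I", "II", "III", "IV", "BVMO", "NMO")
    }


def make_fixture_panel(seed: int = 0) -> ReferencePanel:
    """Deterministic synthetic reference panel.

    One clade-I anchor (the clade I consensus itself, carrying Y/I/N/N/S/D/R
    at anchor sites 56/61/62/195/196/199/224) plus two references per clade
    I-IV and two per outgroup, each drawn at 5% divergence from its clade
    consensus with diagnostic sites and motif spans protected.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    consensuses = _clade_consensuses(seed)

    entries = [
        PanelEntry(
            sequence=ProteinSequence(
                id=ANCHOR_ID,
                residues=_to_str(consensuses["I"]),
                description="clade=I source=synthetic-fixture accession=SYN-ANCHOR",
            ),
            clade="I",
            source="synthetic-fixture",
            accession="SYN-ANCHOR",
        )
    ]
    counter = 1
    for clade in ("I", "II", "III", "IV", "BVMO", "NMO"):
        consensus = consensuses[clade]
        for k in (1, 2):
            codes = _draw_clade_sequence(
                consensus, clade, REFERENCE_DIVERGENCE, rng, base=consensus
            )
            rid = f"clade{clade}_ref{k}" if clade in "I II III IV".split() else f"{clade.lower()}_ref{k}"
            acc = f"SYN-{counter:04d}"
            entries.append(
                PanelEntry(
                    sequence=ProteinSequence(
                        id=rid,
                        residues=_to_str(codes),
                        description=f"clade={clade} source=synthetic-fixture accession={acc}",
                    ),
                    clade=clade,
                    source="synthetic-fixture",
                    accession=acc,
                )
            )
            counter += 1

    return ReferencePanel(
        references=tuple(entries),
        anchor_id=ANCHOR_ID,
        anchor_sites=dict(ANCHOR_SITES),
        profiles=default_profiles(),
    )


def clade_consensus(clade: str, seed: int = 0) -> ProteinSequence:
    """The deterministic consensus sequence of one clade."""
    consensuses = _clade_consensuses(seed)
    return ProteinSequence(id=f"consensus_{clade}", residues=_to_str(consensuses[clade]))


def make_queries(
    spec: GeneratorSpec, n: int, panel_seed: int = 0
) -> list[tuple[ProteinSequence, str]]:
    """``n`` labeled queries: clade consensus plus i.i.d. substitutions.

    Substitutions occur at ``spec.mutation_rate`` outside the protected
    sites (defaults: diagnostic sites plus the fingerprint span) and are
    uniform over the 19 alternative residues.  Returns
    ``[(sequence, true clade), ...]``.
    """
    consensus = _clade_consensuses(panel_seed)[spec.clade]
    if spec.length is not None and spec.length != consensus.size:
        raise ValueError(
            f"queries are drawn from the clade consensus of length {consensus.size}; "
            f"length={spec.length} is not supported"
        )
    protected_sites = (
        spec.protected_sites
        if spec.protected_sites is not None
        else frozenset(
            p for p in set(ANCHOR_SITES.values())
            | set(range(FINGERPRINT_SPAN[0], FINGERPRINT_SPAN[1] + 1))
            if p <= consensus.size
        )
    )
    bad = [p for p in protected_sites if not 1 <= p <= consensus.size]
    if bad:
        raise ValueError(f"protected sites outside [1, {consensus.size}]: {sorted(bad)}")
    protected = _protected_mask(consensus.size, frozenset(protected_sites))
    rng = np.random.default_rng(np.random.SeedSequence([panel_seed, spec.seed, 2]))
    out = []
    for i in range(n):
        codes = _mutate(consensus, spec.mutation_rate, protected, rng)
        seq = ProteinSequence(
            id=f"q{spec.clade}_s{spec.seed}_{i:04d}",
            residues=_to_str(codes),
            description=f"true_clade={spec.clade} rate={spec.mutation_rate}",
        )
        out.append((seq, spec.clade))
    return out


def evolve_alignment(
    tree: TreeNode, n_columns: int, rate_scale: float, seed: int
) -> MultipleAlignment:
    """Evolve a gapless alignment along a rooted tree with branch lengths.

    The root sequence is uniform-random; along each branch every column
    substitutes independently with probability 1 − exp(−length × rate_scale),
    uniformly over the 19 alternative residues.  Rows are returned in tree
    tip order.
    """
    if n_columns < 1:
        raise ValueError("n_columns must be ≥ 1")
    rng = np.random.default_rng(seed)
    none_protected = np.zeros(n_columns, dtype=bool)
    seqs: dict[int, np.ndarray] = {id(tree): rng.integers(0, 20, size=n_columns)}
    for node in tree.preorder(include_self=False):
        length = node.length or 0.0
        p = 1.0 - exp(-length * rate_scale)
        seqs[id(node)] = _mutate(seqs[id(node.parent)], p, none_protected, rng)
    rows = tuple(
        (tip.name, _to_str(seqs[id(tip)])) for tip in tree.tips()
    )
    return MultipleAlignment(rows=rows)
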