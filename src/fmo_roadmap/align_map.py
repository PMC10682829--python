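"""Anchor-referenced residue mapping via global pairwise alignment.

Queries are aligned to the clade-I anchor with a global affine-gap
Needleman-Wunsch (BLOSUM62, gap open 11, gap extend 1 — conventional
protein defaults), and the anchor-numbered diagnostic positions are read
off the alignment columns.  When a trusted multiple alignment containing
the anchor is supplied, the columns come from the MSA instead and no
pairwise alignment is computed.

All user-facing coordinates are 1-based inclusive positions on ungapped
sequences; internal column indices are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .core_io import GAP, MultipleAlignment, ProteinSequence
from .reference_panel import (
    ANCHOR_SITES,
    SCORED_SITES,
    CladeProfile,
    ReferencePanel,
)

#: Weight credited to a sparse (minor) dyad-2 residue: observed in the
#: family but not diagnostic, so it counts as half a match.
MINOR_DYAD2_WEIGHT = 0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored global alignment of two sequences (equal-length gapped rows)."""

    row_a: str
    row_b: str
    score: float
    gap_open: float
    gap_extend: float
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == GAP and cb == GAP:
                raise ValueError("alignment contains an all-gap column")


@dataclass(frozen=True)
class DiagnosticReport:
    """Diagnostic residues of one query in anchor coordinates.

    ``site_residues`` maps each named anchor site to the 1-based query
    position and residue (``None``/'-' when the site falls in a deletion);
    ``per_clade_agreement`` gives (matched weight, number of scored sites)
    against every clade profile.
    """

    query_id: str
    site_residues: dict[str, tuple[int | None, str]]
    per_clade_agreement: dict[str, tuple[float, int]]
    warnings: tuple[str, ...] = ()


def _make_aligner(gap_open: float, gap_extend: float, matrix: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_global(
    a: ProteinSequence,
    b: ProteinSequence,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    matrix: str = "BLOSUM62",
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of ``a`` (row_a) and ``b`` (row_b).

    The first gap residue costs ``gap_open`` and each further one
    ``gap_extend``.  Among co-optimal alignments the aligner's first
    traceback is taken, which is deterministic for fixed inputs.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    aln = aligner.align(a.residues, b.residues)[0]
    return PairwiseAlignment(
        row_a=str(aln[0]),
        row_b=str(aln[1]),
        score=float(aln.score),
        gap_open=gap_open,
        gap_extend=gap_extend,
        matrix_name=matrix,
    )


def map_anchor_sites(
    aln: PairwiseAlignment, sites: dict[str, int]
) -> dict[str, tuple[int | None, str]]:
    """Map anchor-numbered sites through an alignment with the anchor as row_a.

    Returns ``{site name: (query 1-based position or None, residue or '-')}``.
    Site positions must lie in ``[1, ungapped length of row_a]``.
    """
    anchor_len = len(aln.row_a) - aln.row_a.count(GAP)
    for name, pos in sites.items():
        if not 1 <= pos <= anchor_len:
            raise ValueError(
                f"anchor site {name!r} position {pos} outside anchor length {anchor_len}"
            )
    wanted = {pos: name for name, pos in sites.items()}
    out: dict[str, tuple[int | None, str]] = {}
    a_pos = 0
    b_pos = 0
    for ca, cb in zip(aln.row_a, aln.row_b):
        if cb != GAP:
            b_pos += 1
        if ca != GAP:
            a_pos += 1
            if a_pos in wanted:
                name = wanted[a_pos]
                out[name] = (b_pos, cb) if cb != GAP else (None, GAP)
    return out


def score_against_profile(
    site_residues: dict[str, tuple[int | None, str]], profile: CladeProfile
) -> tuple[float, int]:
    """(matched weight, n scored sites) of mapped residues vs one clade profile.

    Scored sites are the dyad, the back-door residue and the nicotinamide
    contacts the profile defines; gapped sites are excluded from the count.
    Minor dyad-2 residues earn :data:`MINOR_DYAD2_WEIGHT`.
    """
    n_match = 0.0
    n_scored = 0
    for site in SCORED_SITES:
        if site not in site_residues:
            continue
        pos, residue = site_residues[site]
        anchor_pos = ANCHOR_SITES[site]
        if site == "dyad1":
            allowed, minor = profile.dyad_site1_allowed, frozenset()
        elif site == "dyad2":
            allowed, minor = profile.dyad_site2_allowed, profile.dyad_site2_minor
        elif site == "backdoor":
            allowed, minor = profile.backdoor_residue, frozenset()
        else:
            if anchor_pos not in profile.nicotinamide_contacts:
                continue  # e.g. Arg224 is not scored for clade IV
            allowed, minor = profile.nicotinamide_contacts[anchor_pos], frozenset()
        if pos is None:
            continue  # deletion: excluded from n_scored
        n_scored += 1
        if residue in allowed:
            n_match += 1.0
        elif residue in minor:
            n_match += MINOR_DYAD2_WEIGHT
    return n_match, n_scored


def _report_from_sites(
    query_id: str,
    site_residues: dict[str, tuple[int | None, str]],
    panel: ReferencePanel,
) -> DiagnosticReport:
    warnings = tuple(
        f"site {name} falls in a deletion relative to the anchor"
        for name, (pos, _) in site_residues.items()
        if pos is None
    )
    agreement = {
        clade: score_against_profile(site_residues, profile)
        for clade, profile in panel.profiles.items()
    }
    return DiagnosticReport(
        query_id=query_id,
        site_residues=site_residues,
        per_clade_agreement=agreement,
        warnings=warnings,
    )


def _msa_site_maps(
    msa: MultipleAlignment, panel: ReferencePanel
) -> dict[str, dict[str, tuple[int | None, str]]]:
    if panel.anchor_id not in msa.ids:
        raise ValueError(f"anchor {panel.anchor_id!r} is not a row of the supplied MSA")
    anchor_row = msa.row(panel.anchor_id)
    wanted = {pos: name for name, pos in panel.anchor_sites.items()}
    site_columns: dict[str, int] = {}
    a_pos = 0
    for col, ch in enumerate(anchor_row):
        if ch != GAP:
            a_pos += 1
            if a_pos in wanted:
                site_columns[wanted[a_pos]] = col
    out = {}
    for rid, row in msa.rows:
        if rid == panel.anchor_id:
            continue
        sites: dict[str, tuple[int | None, str]] = {}
        for name in panel.anchor_sites:
            col = site_columns[name]
            ch = row[col]
            if ch == GAP:
                sites[name] = (None, GAP)
            else:
                sites[name] = (col - row[:col].count(GAP) + 1, ch)
        out[rid] = sites
    return out


def extract_diagnostics(
    queries: Sequence[ProteinSequence] | MultipleAlignment,
    panel: ReferencePanel,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[DiagnosticReport]:
    """Diagnostic reports for queries, via pairwise anchor alignment or an MSA.

    With a plain sequence list each query is globally aligned to the
    anchor; with a :class:`MultipleAlignment` (which must contain the
    anchor as a row) the mapping is read from the MSA columns.
    """
    if isinstance(queries, MultipleAlignment):
        site_maps = _msa_site_maps(queries, panel)
        return [
            _report_from_sites(rid, sites, panel) for rid, sites in site_maps.items()
        ]
    anchor = panel.anchor
    reports = []
    for query in queries:
        aln = align_global(anchor, query, gap_open=gap_open, gap_extend=gap_extend)
        sites = map_anchor_sites(aln, panel.anchor_sites)
        reports.append(_report_from_sites(query.id, sites, panel))
    return reports


def anchor_projection_msa(
    seqs: Sequence[ProteinSequence],
    anchor: ProteinSequence,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MultipleAlignment:
    """Reference-anchored MSA: project every sequence onto anchor columns.

    Each sequence is pairwise-aligned to the anchor and the residue aligned
    to each anchor position becomes that column; insertions relative to the
    anchor are dropped.  Columns = ungapped anchor length.  This is a
    projection, not a progressive MSA: residues are comparable column-wise
    only through the anchor.
    """
    rows = [(anchor.id, anchor.residues)]
    for seq in seqs:
        if seq.id == anchor.id:
            continue
        aln = align_global(anchor, seq, gap_open=gap_open, gap_extend=gap_extend)
        projected = []
        for ca, cb in zip(aln.row_a, aln.row_b):
            if ca != GAP:
                projected.append(cb)
        rows.append((seq.id, "".join(projected)))
    return MultipleAlignment(rows=tuple(rows))
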