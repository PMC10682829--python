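"""PROSITE-style fingerprint motifs and the family vetting rule.

Group B flavoprotein monooxygenases carry short diagnostic sequence
fingerprints: both Rossmann dinucleotide-binding domains show the
glycine-rich ``GXGXXG`` motif, flavin-containing monooxygenases (FMOs)
carry ``FxGxxxHxxx(Y/F)(K/R)`` in the inter-domain linker, and
Baeyer-Villiger monooxygenases (BVMOs) are recognised by
``GGxWxxxx(F/Y)P(G/M)xxxD`` and ``FxGxxxHxxxW(P/D)``.  A candidate is an
FMO when it shows the FMO fingerprint (fully or partially conserved) and
neither BVMO fingerprint; it is a BVMO candidate in the converse case.

Pattern elements are LITERAL (one residue), ANY (wildcard ``x``), or a
CLASS of alternatives ``(A/B)``.  An ``X`` residue in a *sequence* (unknown
amino acid) matches only ANY elements, so low-quality sequence can never
fake a fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core_io import AA20, ProteinSequence

_ALPHA_ORDER = AA20 + "X"
_CODE = {c: i for i, c in enumerate(_ALPHA_ORDER)}
_X_CODE = _CODE["X"]


class PatternError(ValueError):
    """Malformed PROSITE-style pattern string."""


@dataclass(frozen=True)
class MotifPattern:
    """Compiled fingerprint: tuple of allowed-residue sets, ``None`` = wildcard."""

    name: str
    elements: tuple[frozenset | None, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise PatternError(f"pattern {self.name!r} is empty")
        for el in self.elements:
            if el is not None and (not el or not el <= frozenset(AA20)):
                raise PatternError(f"pattern {self.name!r}: bad element {el!r}")

    @property
    def length(self) -> int:
        return len(self.elements)

    @property
    def n_informative(self) -> int:
        """Number of non-wildcard elements."""
        return sum(1 for el in self.elements if el is not None)


@dataclass(frozen=True)
class MotifHit:
    """One window matching a pattern; positions are 1-based inclusive."""

    pattern_name: str
    start: int
    end: int
    matched: str
    n_mismatches: int


FamilyStatus = Literal["full", "partial", "absent"]
Verdict = Literal["FMO_candidate", "BVMO_candidate", "conflict", "none"]


@dataclass(frozen=True)
class FamilyVetting:
    """Outcome of fingerprint vetting for one sequence."""

    fmo_status: FamilyStatus
    bvmo1_status: FamilyStatus
    bvmo2_status: FamilyStatus
    rossmann_count: int
    verdict: Verdict
    warnings: tuple[str, ...] = ()


def compile_pattern(spec: str, name: str | None = None) -> MotifPattern:
    """Compile a PROSITE-style string such as ``"FxGxxxHxxx(Y/F)(K/R)"``.

    Uppercase residue letters are literals, ``x``/``X`` wildcards, and
    ``(A/B/...)`` an alternative class with at least two members.  Raises
    :class:`PatternError` with the character offset on malformed input.
    """
    elements: list[frozenset | None] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch in ("x", "X"):
            elements.append(None)
            i += 1
        elif ch == "(":
            j = spec.find(")", i)
            if j < 0:
                raise PatternError(f"unclosed alternative group at offset {i}")
            body = spec[i + 1:j]
            alts = body.split("/")
            if len(alts) < 2 or any(len(a) != 1 or a not in AA20 for a in alts):
                raise PatternError(f"malformed alternative group {spec[i:j+1]!r} at offset {i}")
            if len(set(alts)) != len(alts):
                raise PatternError(f"duplicate residue in group {spec[i:j+1]!r} at offset {i}")
            elements.append(frozenset(alts))
            i = j + 1
        elif ch in AA20:
            elements.append(frozenset(ch))
            i += 1
        else:
            raise PatternError(f"illegal character {ch!r} at offset {i}")
    return MotifPattern(name=name if name is not None else spec, elements=tuple(elements))


#: Linker fingerprint of flavin-containing monooxygenases.
FMO_FINGERPRINT = compile_pattern("FxGxxxHxxx(Y/F)(K/R)", name="FMO_fingerprint")
#: First Baeyer-Villiger monooxygenase fingerprint.
BVMO_FINGERPRINT_1 = compile_pattern("GGxWxxxx(F/Y)P(G/M)xxxD", name="BVMO_fingerprint_1")
#: Second Baeyer-Villiger monooxygenase fingerprint.
BVMO_FINGERPRINT_2 = compile_pattern("FxGxxxHxxxW(P/D)", name="BVMO_fingerprint_2")
#: Glycine-rich Rossmann dinucleotide-binding motif (one per FAD/NADPH domain).
ROSSMANN_MOTIF = compile_pattern("GXGXXG", name="Rossmann_motif")


def builtin_patterns() -> dict[str, MotifPattern]:
    """The four shipped fingerprints keyed by name."""
    return {
        p.name: p
        for p in (FMO_FINGERPRINT, BVMO_FINGERPRINT_1, BVMO_FINGERPRINT_2, ROSSMANN_MOTIF)
    }


def _mismatch_counts(residues: str, pattern: MotifPattern) -> np.ndarray:
    """Mismatch count for every window start (0-based); empty if seq too short."""
    n, m = len(residues), pattern.length
    if n < m:
        return np.zeros(0, dtype=np.int64)
    codes = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int64)
    for c, i in _CODE.items():
        lut[ord(c)] = i
    codes = lut[codes]
    n_windows = n - m + 1
    counts = np.zeros(n_windows, dtype=np.int64)
    for j, el in enumerate(pattern.elements):
        if el is None:
            continue  # wildcard: everything (including X) matches
        allowed = np.zeros(len(_ALPHA_ORDER), dtype=bool)
        for r in el:
            allowed[_CODE[r]] = True
        # sequence 'X' never satisfies a literal/class element
        allowed[_X_CODE] = False
        counts += ~allowed[codes[j:j + n_windows]]
    return counts


def scan(
    seq: ProteinSequence, pattern: MotifPattern, max_mismatches: int = 0
) -> list[MotifHit]:
    """All windows of ``seq`` matching ``pattern`` with ≤ ``max_mismatches``.

    Overlapping hits are all reported, sorted by start position (1-based).
    Mismatches are counted only at non-wildcard elements; the budget must
    stay below the number of informative elements.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be non-negative")
    if max_mismatches >= pattern.n_informative:
        raise ValueError(
            f"max_mismatches={max_mismatches} must be < the {pattern.n_informative} "
            f"informative elements of pattern {pattern.name!r}"
        )
    counts = _mismatch_counts(seq.residues, pattern)
    hits = []
    for start0 in np.nonzero(counts <= max_mismatches)[0]:
        s = int(start0)
        hits.append(
            MotifHit(
                pattern_name=pattern.name,
                start=s + 1,
                end=s + pattern.length,
                matched=seq.residues[s:s + pattern.length],
                n_mismatches=int(counts[s]),
            )
        )
    return hits


def rossmann_count(seq: ProteinSequence) -> int:
    """Number of non-overlapping exact Rossmann (GXGXXG) hits, greedy left-to-right."""
    count = 0
    next_free = 0
    for hit in scan(seq, ROSSMANN_MOTIF, max_mismatches=0):
        if hit.start > next_free:
            count += 1
            next_free = hit.end
    return count


def _status(
    seq: ProteinSequence, pattern: MotifPattern, partial_max_mismatches: int
) -> FamilyStatus:
    if scan(seq, pattern, max_mismatches=0):
        return "full"
    if partial_max_mismatches > 0 and scan(seq, pattern, partial_max_mismatches):
        return "partial"
    return "absent"


def vet_family(seq: ProteinSequence, partial_max_mismatches: int = 1) -> FamilyVetting:
    """Apply the family vetting rule to one sequence.

    ``full`` means an exact fingerprint hit, ``partial`` a hit with at most
    ``partial_max_mismatches`` mismatches over the informative elements
    (the partially-conserved-fingerprint rule), ``absent`` otherwise.  The
    verdict is FMO_candidate when the FMO fingerprint is present (fully or
    partially) and both BVMO fingerprints are absent; BVMO_candidate when
    the FMO fingerprint is absent and a BVMO fingerprint is fully present;
    conflict when FMO and BVMO evidence co-occur; none otherwise.
    """
    fmo = _status(seq, FMO_FINGERPRINT, partial_max_mismatches)
    bvmo1 = _status(seq, BVMO_FINGERPRINT_1, partial_max_mismatches)
    bvmo2 = _status(seq, BVMO_FINGERPRINT_2, partial_max_mismatches)
    n_ross = rossmann_count(seq)

    if fmo in ("full", "partial") and (bvmo1 == "absent" and bvmo2 == "absent"):
        verdict: Verdict = "FMO_candidate"
    elif fmo in ("full", "partial"):
        verdict = "conflict"
    elif bvmo1 == "full" or bvmo2 == "full":
        verdict = "BVMO_candidate"
    else:
        verdict = "none"

    warns = []
    if verdict in ("FMO_candidate", "BVMO_candidate") and n_ross < 2:
        warns.append(
            f"only {n_ross} Rossmann (GXGXXG) motif(s); two expected for a "
            "two-dinucleotide-binding-domain protein"
        )
    return FamilyVetting(
        fmo_status=fmo,
        bvmo1_status=bvmo1,
        bvmo2_status=bvmo2,
        rossmann_count=n_ross,
        verdict=verdict,
        warnings=tuple(warns),
    )
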