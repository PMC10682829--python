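"""Clade model: reference sequences, anchor numbering, diagnostic profiles.

The FMO family splits into four well-supported clades (I-IV) with BVMOs
and NMOs as external groups.  Each clade carries a diagnostic active-site
signature, expressed in the numbering of the clade-I anchor structure
(positions 56, 61, 62, 195, 196, 199, 224, 375):

======== ========== ========== ============ ======================
site     clades I/II clade III  clade IV     outgroups
======== ========== ========== ============ ======================
dyad-1    T/A/S/V/I  L          L            L/I (BV-active)
dyad-2    N (+T/H/V) N (+T/H/V) Q            NMO Q, BVMO D
back-door N / Y      C          K            not diagnostic
======== ========== ========== ============ ======================

Ser196 and Tyr56 are conserved family-wide; Asp199 is a glutamate in
clade III; Arg224 is absent in clade IV.  Typical lengths are ~500 (I),
~450 (II), ~420 (III) and ~520 (IV) residues; clade III and the NMOs lack
the C-terminal domain, and some clade III members carry an N-terminal
NTF2-like extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from .core_io import AA20, ProteinSequence, read_fasta, write_fasta

CLADES = ("I", "II", "III", "IV", "BVMO", "NMO")
FMO_CLADES = ("I", "II", "III", "IV")

#: Diagnostic sites in anchor numbering, in increasing anchor position.
ANCHOR_SITES = {
    "tyr56": 56,
    "dyad1": 61,
    "dyad2": 62,
    "backdoor": 195,
    "ser196": 196,
    "asp199": 199,
    "arg224": 224,
    "gatekeeper": 375,
}

#: Sites scored against clade profiles (the gatekeeper is reported only:
#: its identity is clade-variable).
SCORED_SITES = ("tyr56", "dyad1", "dyad2", "backdoor", "ser196", "asp199", "arg224")

_FULL20 = frozenset(AA20)


class PanelError(ValueError):
    """Invalid reference panel data."""


@dataclass(frozen=True)
class CladeProfile:
    """Expected diagnostic residues and architecture for one clade."""

    clade: str
    dyad_site1_allowed: frozenset
    dyad_site2_allowed: frozenset
    dyad_site2_minor: frozenset
    backdoor_residue: frozenset
    nicotinamide_contacts: dict[int, frozenset]
    length_range: tuple[int, int]
    has_c_terminal_domain: bool
    gatekeeper_note: str = ""

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise PanelError(f"unknown clade label {self.clade!r}")
        for name, s in (
            ("dyad_site1_allowed", self.dyad_site1_allowed),
            ("dyad_site2_allowed", self.dyad_site2_allowed),
            ("backdoor_residue", self.backdoor_residue),
        ):
            if not s or not s <= _FULL20:
                raise PanelError(f"clade {self.clade}: {name} must be a non-empty residue set")
        for pos, s in self.nicotinamide_contacts.items():
            if not s or not s <= _FULL20:
                raise PanelError(f"clade {self.clade}: contact {pos} has an invalid residue set")
        lo, hi = self.length_range
        if not lo < hi:
            raise PanelError(f"clade {self.clade}: length_range min must be < max")


def default_profiles() -> dict[str, CladeProfile]:
    """Built-in diagnostic profiles for clades I-IV, BVMO and NMO.

    FMO-clade residue sets transcribe the published active-site survey;
    the outgroup back-door and NMO dyad-1 sets are deliberately the full
    alphabet (not diagnostic) and outgroup length ranges are soft package
    defaults.
    """
    tasvi = frozenset("TASVI")
    minor = frozenset("THV")
    return {
        "I": CladeProfile(
            clade="I",
            dyad_site1_allowed=tasvi,
            dyad_site2_allowed=frozenset("N"),
            dyad_site2_minor=minor,
            backdoor_residue=frozenset("N"),
            nicotinamide_contacts={
                56: frozenset("Y"), 196: frozenset("S"),
                199: frozenset("D"), 224: frozenset("R"),
            },
            length_range=(460, 560),
            has_c_terminal_domain=True,
            gatekeeper_note="Leu375 gatekeeper at the loop apex in one clade I structure",
        ),
        "II": CladeProfile(
            clade="II",
            dyad_site1_allowed=tasvi,
            dyad_site2_allowed=frozenset("N"),
            dyad_site2_minor=minor,
            backdoor_residue=frozenset("Y"),
            nicotinamide_contacts={
                56: frozenset("Y"), 196: frozenset("S"),
                199: frozenset("D"), 224: frozenset("R"),
            },
            length_range=(410, 490),
            has_c_terminal_domain=True,
            gatekeeper_note="W324 blockade residue stacks against the C-terminal helix",
        ),
        "III": CladeProfile(
            clade="III",
            dyad_site1_allowed=frozenset("L"),
            dyad_site2_allowed=frozenset("N"),
            dyad_site2_minor=minor,
            backdoor_residue=frozenset("C"),
            nicotinamide_contacts={
                56: frozenset("Y"), 196: frozenset("S"),
                199: frozenset("E"), 224: frozenset("R"),
            },
            length_range=(380, 460),
            has_c_terminal_domain=False,
            gatekeeper_note="short C-terminus; some members carry an NTF2-like N-extension",
        ),
        "IV": CladeProfile(
            clade="IV",
            dyad_site1_allowed=frozenset("L"),
            dyad_site2_allowed=frozenset("Q"),
            dyad_site2_minor=frozenset(),
            backdoor_residue=frozenset("K"),
            nicotinamide_contacts={
                56: frozenset("Y"), 196: frozenset("S"), 199: frozenset("D"),
            },
            length_range=(480, 560),
            has_c_terminal_domain=True,
            gatekeeper_note="Arg224 contact absent; Lys218 extends into the substrate site",
        ),
        "BVMO": CladeProfile(
            clade="BVMO",
            dyad_site1_allowed=frozenset("LI"),
            dyad_site2_allowed=frozenset("D"),
            dyad_site2_minor=frozenset(),
            backdoor_residue=_FULL20,
            nicotinamide_contacts={},
            length_range=(500, 620),
            has_c_terminal_domain=True,
            gatekeeper_note="longer NADPH-binding insertion (~120 residues)",
        ),
        "NMO": CladeProfile(
            clade="NMO",
            dyad_site1_allowed=_FULL20,
            dyad_site2_allowed=frozenset("Q"),
            dyad_site2_minor=frozenset(),
            backdoor_residue=_FULL20,
            nicotinamide_contacts={},
            length_range=(400, 500),
            has_c_terminal_domain=False,
            gatekeeper_note="stretched NADPH-binding domain forms an open substrate groove",
        ),
    }


@dataclass(frozen=True)
class PanelEntry:
    """One labeled reference sequence."""

    sequence: ProteinSequence
    clade: str
    source: str = ""
    accession: str = ""


@dataclass
class ReferencePanel:
    """Labeled references plus anchor numbering and clade profiles."""

    references: tuple[PanelEntry, ...]
    anchor_id: str
    anchor_sites: dict[str, int]
    profiles: dict[str, CladeProfile]
    _ref_dm_cache: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [e.sequence.id for e in self.references]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate reference ids in panel")
        if self.anchor_id not in ids:
            raise PanelError(f"anchor id {self.anchor_id!r} not among references")
        anchor_len = len(self.anchor.residues)
        for name, pos in self.anchor_sites.items():
            if not 1 <= pos <= anchor_len:
                raise PanelError(
                    f"anchor site {name!r} position {pos} outside anchor length {anchor_len}"
                )
        for entry in self.references:
            if entry.clade not in CLADES:
                raise PanelError(f"unknown clade label {entry.clade!r} for {entry.sequence.id!r}")
            if entry.clade not in self.profiles:
                raise PanelError(f"no profile for clade {entry.clade!r}")
        for clade in FMO_CLADES:
            n = sum(1 for e in self.references if e.clade == clade)
            if n < 2:
                raise PanelError(f"clade {clade} has {n} reference(s); at least 2 required")

    @property
    def anchor(self) -> ProteinSequence:
        return next(e.sequence for e in self.references if e.sequence.id == self.anchor_id)

    def entries_for(self, clade: str) -> list[PanelEntry]:
        return [e for e in self.references if e.clade == clade]

    @property
    def clades_present(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.references:
            if e.clade not in seen:
                seen.append(e.clade)
        return tuple(seen)

    def save(self, directory: str | Path) -> None:
        """Write the panel directory: panel.fasta, profiles.tsv, anchors.tsv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        seqs = [
            replace(
                e.sequence,
                description=f"clade={e.clade} source={e.source or 'NA'} "
                            f"accession={e.accession or 'NA'}",
            )
            for e in self.references
        ]
        write_fasta(seqs, directory / "panel.fasta")
        with open(directory / "anchors.tsv", "w", encoding="utf-8") as fh:
            fh.write("# site\tanchor_position ('anchor' row names the numbering reference)\n")
            fh.write(f"anchor\t{self.anchor_id}\n")
            for name, pos in self.anchor_sites.items():
                fh.write(f"{name}\t{pos}\n")
        with open(directory / "profiles.tsv", "w", encoding="utf-8") as fh:
            fh.write("# clade\tfield\tvalue\n")
            for clade, p in self.profiles.items():
                fh.write(f"{clade}\tdyad_site1_allowed\t{''.join(sorted(p.dyad_site1_allowed))}\n")
                fh.write(f"{clade}\tdyad_site2_allowed\t{''.join(sorted(p.dyad_site2_allowed))}\n")
                fh.write(f"{clade}\tdyad_site2_minor\t{''.join(sorted(p.dyad_site2_minor)) or '.'}\n")
                fh.write(f"{clade}\tbackdoor_residue\t{''.join(sorted(p.backdoor_residue))}\n")
                for pos, allowed in sorted(p.nicotinamide_contacts.items()):
                    fh.write(f"{clade}\tcontact_{pos}\t{''.join(sorted(allowed))}\n")
                fh.write(f"{clade}\tlength_range\t{p.length_range[0]}-{p.length_range[1]}\n")
                fh.write(f"{clade}\thas_c_terminal_domain\t{int(p.has_c_terminal_domain)}\n")
                fh.write(f"{clade}\tgatekeeper_note\t{p.gatekeeper_note or '.'}\n")


def _parse_header_fields(description: str) -> dict[str, str]:
    out = {}
    for token in description.split():
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def _read_tsv(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _load_panel_dir(directory: Path) -> ReferencePanel:
    fasta = directory / "panel.fasta"
    anchors = directory / "anchors.tsv"
    profiles_tsv = directory / "profiles.tsv"
    for p in (fasta, anchors, profiles_tsv):
        if not p.exists():
            raise PanelError(f"panel file missing: {p}")

    entries = []
    for seq in read_fasta(fasta):
        meta = _parse_header_fields(seq.description)
        if "clade" not in meta:
            raise PanelError(f"reference {seq.id!r} has no clade= field in its header")
        entries.append(
            PanelEntry(
                sequence=seq,
                clade=meta["clade"],
                source=meta.get("source", ""),
                accession=meta.get("accession", ""),
            )
        )

    anchor_id = None
    anchor_sites: dict[str, int] = {}
    for row in _read_tsv(anchors):
        if len(row) != 2:
            raise PanelError(f"anchors.tsv: expected 2 columns, got {row!r}")
        if row[0] == "anchor":
            anchor_id = row[1]
        else:
            anchor_sites[row[0]] = int(row[1])
    if anchor_id is None:
        raise PanelError("anchors.tsv does not name the anchor sequence")

    raw: dict[str, dict[str, str]] = {}
    for row in _read_tsv(profiles_tsv):
        if len(row) != 3:
            raise PanelError(f"profiles.tsv: expected 3 columns, got {row!r}")
        raw.setdefault(row[0], {})[row[1]] = row[2]

    profiles = {}
    for clade, fields in raw.items():
        try:
            lo, hi = fields["length_range"].split("-")
            contacts = {
                int(k.removeprefix("contact_")): frozenset(v)
                for k, v in fields.items()
                if k.startswith("contact_")
            }
            minor = fields.get("dyad_site2_minor", ".")
            note = fields.get("gatekeeper_note", ".")
            profiles[clade] = CladeProfile(
                clade=clade,
                dyad_site1_allowed=frozenset(fields["dyad_site1_allowed"]),
                dyad_site2_allowed=frozenset(fields["dyad_site2_allowed"]),
                dyad_site2_minor=frozenset() if minor == "." else frozenset(minor),
                backdoor_residue=frozenset(fields["backdoor_residue"]),
                nicotinamide_contacts=contacts,
                length_range=(int(lo), int(hi)),
                has_c_terminal_domain=bool(int(fields["has_c_terminal_domain"])),
                gatekeeper_note="" if note == "." else note,
            )
        except KeyError as exc:
            raise PanelError(f"profiles.tsv: clade {clade} is missing field {exc}") from exc
    return ReferencePanel(
        references=tuple(entries),
        anchor_id=anchor_id,
        anchor_sites=anchor_sites,
        profiles=profiles,
    )


def load_reference_panel(path_or_tag: str | Path = "fixture", seed: int = 0) -> ReferencePanel:
    """Load a panel directory, or the built-in synthetic fixture panel.

    The tag ``"fixture"`` builds the deterministic synthetic panel shipped
    with the package (no download needed); any other value is treated as a
    directory containing ``panel.fasta``, ``profiles.tsv`` and
    ``anchors.tsv``.
    """
    if path_or_tag == "fixture":
        from .synthetic_data import make_fixture_panel

        return make_fixture_panel(seed=seed)
    return _load_panel_dir(Path(path_or_tag))
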