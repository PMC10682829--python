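# fmo-roadmap

Sequence-based vetting, diagnostics and clade classification for
flavin-containing monooxygenases (FMOs) and their Group B relatives.

FMOs are one-component flavoenzymes with a paired Rossmann fold (one
dinucleotide-binding domain each for FAD and NADPH) that oxygenate
nucleophilic N/S centres through a C4a-(hydro)peroxyflavin. Their family
tree splits into four well-supported clades (I–IV) with the
Baeyer-Villiger monooxygenases (BVMOs) and N-hydroxylating
monooxygenases (NMOs) as external groups, and the clades differ in
diagnostic active-site residues, typical length and domain architecture —
not in host taxonomy. `fmo-roadmap` turns that roadmap into a
reproducible pipeline for anyone who has a candidate protein sequence
and wants to know: *is this an FMO, and if so which clade?*

The pipeline has four stages, usable separately as a library or together
from the shell:

1. **Fingerprint vetting** (`vet`). Candidates are screened with the
   family fingerprints, compiled from PROSITE-style strings:
   the FMO linker motif `FxGxxxHxxx(Y/F)(K/R)`, the BVMO fingerprints
   `GGxWxxxx(F/Y)P(G/M)xxxD` and `FxGxxxHxxxW(P/D)`, and the Rossmann
   motif `GXGXXG` (expected twice). A *full* hit is exact; a *partial*
   hit tolerates a configurable number of mismatches at informative
   positions (default 1). FMO and BVMO evidence together yields
   `conflict`, never a silent call.
2. **Diagnostic residues** (`diagnose`). Each query is globally aligned
   (BLOSUM62, affine gaps 11/1) to a clade-I anchor sequence, and the
   anchor-numbered active-site positions are read off the columns: the
   flavin dyad (sites 61/62), the nicotinamide "back-door" residue
   (195, asparagine/tyrosine/cysteine/lysine for clades I–IV), the
   conserved Tyr56/Ser196 pair, Asp199 (Glu in clade III) and Arg224
   (absent in clade IV). Agreement with each clade profile is counted,
   with sparse dyad-2 variants (T/H/V) scored as half-matches.
3. **Tree** (`tree`). Poisson-corrected distances (pairwise deletion)
   feed canonical neighbor-joining; the tree is midpoint rooted and
   every internal branch gets classical bootstrap support *and* the
   transfer bootstrap expectation, TBE = mean over replicates of
   1 − δ/(p−1), where δ is the minimum Hamming transfer distance of the
   branch's bipartition into the replicate and p its light-side size.
4. **Classification** (`classify`). A weighted vote — placement by mean
   distance to each clade's references (0.5), diagnostic-site agreement
   (0.3), length-range membership (0.1) and fingerprint conservation
   (0.1) — picks the clade; calls whose top two scores sit within a
   margin (default 0.15) are reported `ambiguous` rather than forced.
   BVMO-vetted sequences stay `outgroup`, and NMO is only ever attached
   as a caveat because no NMO fingerprint exists.

Because the published reference enzymes live in external databases, the
package ships a deterministic **synthetic panel**: a shared scaffold
with the fingerprints and the clade-diagnostic residues written in at
known anchor coordinates, plus generators for mutated query sets and
alignments evolved along known trees, so every stage is testable offline
against known truth.

## Worked example

```bash
fmo-roadmap simulate queries --clade IV --rate 0.1 --n 4 --seed 42 --out queries.fasta
fmo-roadmap classify --in queries.fasta --out classify.tsv
cat classify.tsv
```

```
query_id        family  clade   confidence      top_evidence
qIV_s42_0000    FMO     IV      0.9332  placement
qIV_s42_0001    FMO     IV      0.9370  placement
qIV_s42_0002    FMO     IV      0.9264  placement
qIV_s42_0003    FMO     IV      0.9264  placement
```

All four queries — clade IV consensus with 10% random substitutions —
come back as clade IV FMOs. The confidence is the weighted agreement of
the evidence with the winning clade (1.0 would mean zero distance to the
clade references, perfect diagnostic agreement, in-range length and a
full fingerprint). The full pipeline writes every intermediate artifact
plus a run log and census:

```bash
fmo-roadmap run --in queries.fasta --out run1 --bootstrap 25 --seed 1
fmo-roadmap summarize run1
```

```
{
  "ambiguous_count": 0,
  "clade_counts": { "IV": 4 },
  "family_counts": { "FMO": 4 },
  "mean_confidence": 0.93075,
  "n_queries": 4
}
```

`run1/` then contains `vetting.tsv`, `diagnostics.tsv`, `tree.nwk`
(with `classical/TBE` labels on internal branches), `classify.tsv`,
`report.json` and `run.log`; rerunning with the same seed reproduces the
TSV/Newick artifacts byte for byte.

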