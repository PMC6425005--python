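# prospect

Discovery of proneuropeptides (pNPs) and peptide prohormones in predicted
proteomes.

Neuropeptides and peptide hormones are synthesized as large inactive
precursors that share a small set of structural hallmarks: an N-terminal
signal peptide, one or more bioactive peptide segments flanked by mono- or
dibasic cleavage sites recognised by prohormone convertases, and the
absence of a folded protein domain.  Because related precursors from
different phyla often share almost no overall sequence similarity, family
assignment works best through all-vs-all similarity clustering rather than
conventional phylogenetics.  `prospect` packages this whole workflow — the
kind of in-silico survey used to chart neuropeptide complements across
molluscan and lophotrochozoan taxa — as a tested, reusable Python library
with a thin CLI, exercisable end-to-end on synthetic secretomes with exact
ground truth.

## What it computes

1. **Signal-peptide gate** — a von-Heijne-style heuristic (small residues at
   the −3/−1 cleavage positions, Kyte–Doolittle hydrophobic h-region) with
   score cut-offs *u* = 0.45 (plain) and *U* = 0.50 (transmembrane-like), or
   an importer for external predictor tables.  Survivors are truncated to
   their mature sequence.
2. **Cleavage-motif scan** — the ten convertase site patterns
   `(R|K)*GKR(R|K)*`, `(R|K)*GRK(R|K)*`, `(R|K)*GRR(R|K)*`, `(R|K)*GKK(R|K)*`,
   `(R|K)*KR(R|K)*`, `(R|K)*RK(R|K)*`, `(R|K)*RR(R|K)*`, `(R|K)*KK(R|K)*`,
   `(R|K)*GR(R|K)*`, `(R|K)*GK(R|K)*`, resolved leftmost-longest and
   non-overlapping; candidates lacking any motif are discarded.
3. **Folded-domain exclusion** — hmmsearch-style domain hits at
   E ≤ 1e−10 remove a candidate unless the accession is allowlisted
   (e.g. `PF01581`, the FMRFamide-related-peptide model, which would
   otherwise discard true precursors).
4. **Redundancy collapse** — CD-HIT-style greedy clustering at 0.95
   identity (identical aligned positions / shorter sequence length).
5. **Reference screen** — survivors must hit a curated precursor reference
   set at a loose E ≤ 1e−03.
6. **Cluster map** — exact affine-gap Smith–Waterman (BLOSUM62, gaps 11/1)
   over all pairs; Karlin–Altschul statistics
   `E = K·m·n·exp(−λS)` (λ = 0.267, K = 0.041), `P = 1 − exp(−E)`; edges at
   P ≤ 1e−06; a 20,000-round force-directed 2-D layout; seed-and-grow
   convex clustering; isolated clusters of fewer than 3 sequences without a
   registered conserved motif are pruned.
7. **Maturation** — peptides excised between sites; C-terminal
   α-amidation annotated when a glycine donor precedes the basic residues
   (motif-leading G, or a stripped segment-terminal G); N-terminal Gln
   marks pyroglutamate.
8. **Phyletic classification** — each family's origin is the last common
   ancestor of the taxa it occurs in, on a configurable backbone
   (Eumetazoa ⊃ Bilateria ⊃ Protostomia ⊃ Lophotrochozoa ⊃ Mollusca ⊃
   {Conchifera, Aculifera} ⊃ class-level taxa); per-taxon minimum
   complements are the column sums of the family-by-taxon presence matrix.

A synthetic-data module plants precursors with these exact hallmarks among
decoys that each fail one specific gate, with truth tables, so the whole
cascade is testable without any downloads.

## Worked example

```python
from prospect import excise_peptides, scan_cleavage_sites

mature = "FMRFGKRFMRFGKRQRPWGKR"
sites = scan_cleavage_sites(mature)
for p in excise_peptides(mature, sites):
    print(p.sequence, p.span, p.amidated, p.pyroglutamate)
```

prints

```
FMRF (0, 4) True False
FMRF (7, 11) True False
QRPW (14, 18) True True
```

Three `GKR` sites cut the region into three peptides.  Each site's leading
glycine is an amide donor, so all three products are C-terminally amidated
(`FMRF` + amide is the classic FMRFamide); the last peptide's N-terminal
glutamine is flagged for pyroglutamate formation.  Running the cascade on a
synthetic proteome (`python examples/01_screen_a_proteome.py`) prints the
per-stage survivor counts and, against the generator's truth,
`recall = 1.00` and `precision = 1.00`.

More narrative examples live in `examples/` (screening, maturation,
cluster maps, phyletic classification).  The same functionality is exposed
as a CLI: `prospect simulate | screen | cluster | mature | classify | run`.

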