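# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `prospect`.  It is written for users who need to know what
the pipeline assumes before trusting its calls on real data.

## The precursor model

A proneuropeptide or peptide prohormone is modelled as

    signal peptide | [peptide segment | cleavage site]+ | spacer

The pipeline never tries to recognise bioactivity directly; it recognises
the *hallmarks* of precursor architecture and removes everything that a
hallmark excludes.  Every stage is a predicate on one record, so the
cascade's survivor set is independent of filter order (the redundancy
collapse, which is not a per-record predicate, runs at its configured
position; the default order is signal → domains → motifs → redundancy →
reference).

### Signal-peptide gate

The built-in heuristic follows the classic (−3,−1) rule: a candidate
cleavage position `c ∈ [8, 40]` is eligible when the residues at `c−3` and
`c−1` are small (`A G S C T V`) and the mean Kyte–Doolittle hydropathy of
the h-window `[max(2, c−13), c−5)` is at least 1.5.  The score is a
logistic transform (slope 2.0) of the best window mean minus 1.5, compared
against `u = 0.45` for plain N-termini and `U = 0.50` for
transmembrane-like ones (mean hydropathy of the first 40 residues ≥ 2.0) —
a hydrophobic start can mimic a membrane anchor, so it is held to a higher
bar.  The transform's slope is arbitrary (any monotone map works); fixing
it makes tests exact.  The heuristic is a deliberately simple stand-in for
neural-network predictors: its purpose is a deterministic, offline-testable
gate with the same decision semantics, not state-of-the-art accuracy.  When
a dedicated external predictor has been run, its annotation table can be
imported instead (`import_signal_predictions`), preserving fidelity;
positive calls below the cut-off are demoted with a warning.

Sequences without an initial methionine (mid-transcript fragments) are not
pre-filtered; they simply face the same gate.

### Cleavage-motif scan

The ten site patterns (`(R|K)*` flanks around cores `GKR GRK GRR GKK KR RK
RR KK GR GK`) are matched left-to-right, longest match first at each
position, ties to the lowest pattern index, never overlapping.  Overlap
resolution is not biologically canonical — convertase competition in vivo
is unresolved — but a deterministic rule is required for exact tests; this
one is validated against an all-substrings brute-force oracle.  The discard
rule is literal: one motif suffices (`min_sites = 1`); a stricter reading
(`min_sites = 2`) is a config switch.

### Folded-domain exclusion and allowlist

Domain hits (HMMER `--domtblout` or the package's own TSV sidecar) at
independent E ≤ 1e−10 remove a record.  The allowlist (default `PF01581`)
exists because some genuine precursor families have their own profile
models; without the exemption the filter silently deletes exactly the
sequences being sought.  Accession version suffixes are stripped before
comparison.

### Redundancy collapse

Greedy incremental clustering in decreasing length order (ties by id):
each record joins the first representative at identity ≥ 0.95, where
identity = identical aligned positions of the optimal local alignment
divided by the shorter sequence's length.  This reproduces the decision
semantics of CD-HIT's default behaviour without its word-filter shortcuts,
which only matter at database scale.

### Reference screen

A candidate survives if its best local alignment against the curated
precursor reference reaches E ≤ 1e−03 — deliberately loose, because the
screen's job is to discard unrelated secreted proteins, not to call
orthology.

## Similarity engine

Alignment is exact affine-gap Smith–Waterman under BLOSUM62 with NCBI gap
costs (a length-k gap costs 11 + k), implemented as a dynamic program
(numba-accelerated when available; a pure-Python path gives identical
results).  Traceback prefers diagonal moves, then gaps in the subject,
then the query, making spans deterministic.  Scores convert to E-values
with the published gapped BLOSUM62/11/1 Karlin–Altschul constants
λ = 0.267, K = 0.041, and P = 1 − exp(−E).  Profile-iterative search
(psi-blast-style) is out of scope: profiles need a database-scale sequence
background; precomputed tabular output can be imported instead, and the
clustering layer is agnostic to hit provenance.

## Cluster map

Edges connect pairs with P ≤ 1e−06.  Attraction weights are
`min(1, −log10(P)/100)`.  The layout runs directly in 2-D (the collapse
from 3-D in interactive tools is purely visual): coordinates start uniform
in [−1,1]² from the seed; each round applies edge attraction
`a(i,j)·(x_j − x_i)`, pairwise repulsion `0.05·(x_i − x_k)/‖x_i − x_k‖²`,
and a per-round displacement cap of 0.1.  The force constants are
conventional, not fitted; all downstream calls use graph topology only, so
coordinates affect visualisation alone.

Convex clustering is a documented substitute for unpublished tool
defaults: seeds in decreasing degree order; a cluster repeatedly absorbs
the qualifying unassigned node with the most edges into the current
members (qualifying: linked to ≥ 50 % of them), breaking ties by triangle
support — the number of neighbours shared with the cluster's current
neighbourhood — then node order.  Densest-first growth with structural
tie-breaking prevents a weakly linked bystander from slipping in while the
cluster is still small; on random graphs with exactly symmetric ties the
final index tie-break is necessarily arbitrary.  Clusters that stay
singletons are reported "unassigned".  Pruning removes isolated clusters
smaller than 3 unless a conserved motif has been registered for them; the
outgroup rule drops any node outside the focus taxa with no edge into
them (applied before size pruning by default; both orders are valid and
configurable).

## Maturation chemistry

Amidation bookkeeping: motif-leading glycines (cores `GKR GRK GRR GKK GR
GK`) amidate the preceding segment without altering it; for glycine-less
cores (`KR RK RR KK`) a segment-terminal glycine is the donor and is
stripped from the reported peptide.  Peptides are reported post-strip with
the flag, so the audit trail (segments + stripped donors + site cores)
reconstructs the mature sequence exactly.  A leading glutamine flags
pyroglutamate.  The minimum reported peptide length defaults to 3 —
no canonical minimum exists; it is configurable.  Consensus strings use an
80 % majority per column, bracketing up to 4 residues otherwise ('X'
beyond), dropping majority-gap columns; conserved-residue counts require
the residue in ≥ `min_fraction` of non-gap entries with non-gap coverage of
at least half the rows.  These thresholds make motif notation
deterministic where interactive motif-discovery tools were historically
used.

## Phyletic classification

The default clade tree follows the Conchifera/Aculifera hypothesis inside
the standard metazoan backbone and ships as an editable nested mapping
(YAML), exportable as newick.  A family's origin is the lowest named clade
ancestral to every terminal taxon it occurs in; presence requires a single
member sequence (minimum-complement semantics — absence of evidence is not
loss).  Complement counts are column sums of the boolean family-by-taxon
matrix.

## Synthetic benchmark

The generator emulates precursor architecture exactly: a synthetic signal
(`MK` + leucine h-core + `QAHA` c-region, built so the (−3,−1) rule is
satisfied only at the true boundary), then `[peptide(+donor G) + site
core] × n_copies`, then a spacer drawn from an alphabet (`N Q E D H P W
Y`) that can create neither cleavage motifs nor competing hydrophobic
windows.  Every planted precursor is post-verified at generation: the
built-in predictor must recover the exact boundary, the scanner exactly
`n_copies` sites, excision exactly `n_copies` peptide copies.  Decoy
classes fail exactly one gate by construction (charged N-terminus / planted
domain hit at E = 1e−20 / basic-residue-free body).

The standard benchmark plants 150 precursors as 30 families × 5 members —
shared peptide and cleavage pattern, member-specific copy number (2–5),
signal length (12–30), spacers, and taxon — among 617 decoys per class
(1,851 total).  Family structure matters: singleton families would all be
pruned by the minimum-cluster-size rule, leaving clustering and
classification untested.  The reference set carries one representative per
family with redrawn spacers, so the reference screen tests similarity, not
identity.  Recall counts a planted precursor as recovered if it or its
redundancy representative survives the cascade; precision is the planted
fraction of reported candidates.

What the benchmark does *not* emulate: evolutionary divergence between
family members (members share their peptide verbatim), compositional bias,
fragmentary transcripts, alternative splicing, or false cleavage context.
Passing it therefore demonstrates that the machinery is correct and
self-consistent — off-by-one-free coordinates, faithful thresholds, exact
bookkeeping — not that the heuristics would match a neural-network signal
predictor or database-scale profile search on real transcriptomes.  On
real data the two import paths (external signal predictions, precomputed
similarity tables) are the recommended configuration.

A known, realistic artefact: distinct families that share a cleavage
pattern can acquire weak cross-family edges, because a local alignment can
chain the short identical site cores across tandem repeats.  Repetitive
precursors genuinely form over-connected regions in similarity maps — the
classic reason the central repetitive cluster of such maps is re-clustered
separately — and the benchmark reproduces it in miniature (28–30 clusters
recovered from 30 planted families depending on seed, with recall and
precision unaffected).

## Problem sizes and determinism

Default test and acceptance runs use the 2,001-record benchmark,
1,000-sequence scanner oracles, 200-pair aligner oracles, exhaustive
convex-clustering enumeration to 5 nodes plus 300 random 6–7-node graphs,
and a 45-node planted 3-block layout graph — sizes chosen so the full suite
runs in a couple of minutes on a single CPU while still exercising every
code path at meaningful scale.  All stochastic components consume explicit
seeds; reruns are bit-identical apart from wall-clock timings in reports.
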