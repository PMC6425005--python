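"""Synthetic proteomes with planted precursors and decoys.

Every pipeline stage is testable offline against ground truth: planted
precursors carry all hallmarks of a bona fide proneuropeptide (synthetic
signal peptide built to pass the built-in predictor, tandem peptide copies
flanked by convertase cleavage motifs, no folded domain), while each decoy
class is constructed to fail exactly one gate:

* ``decoy_no_signal`` — acidic/charged N-terminus (no eligible cleavage
  position exists), but carries cleavage motifs;
* ``decoy_folded_domain`` — valid signal and motifs, plus an emitted domain
  hit at e=1e-20 to the synthetic accession PFTEST01;
* ``decoy_no_repeats`` — valid signal, zero cleavage motifs (verified by
  scanning at generation time).

A planted precursor's mature region is ``[peptide(+donor G) + site core] x
n_copies + trailing spacer``: the first peptide copy starts immediately
after the signal cleavage site and every copy is flanked by cleavage motifs,
so scanning yields exactly ``n_copies`` sites and excision returns exactly
``n_copies`` amidated copies of the planted peptide.  Spacer and peptide
alphabets exclude residues that could create unintended motifs or signal
anchors, keeping the truth tables exact.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigError
from .io import DomainHit, ProteinRecord, write_domain_table, write_fasta
from .maturation import excise_peptides
from .phylo import CladeTree
from .screen import _CORES, scan_cleavage_sites
from .signals import predict_signal

#: trailing-spacer alphabet: no basics (K,R), no G, no small residues, no
#: strongly hydrophobic residues (cannot outscore the planted signal window)
SPACER_ALPHABET = "NQEDHPWY"
#: peptide alphabet for randomly drawn families: additionally G-free so any
#: core works and no donor ambiguity arises
PEPTIDE_ALPHABET = "ADEFHILMNPQSTVWY"
#: N-terminal alphabet of the signal-less decoys: charged/polar, no small
#: residues anywhere an eligible (-3,-1) pair could form
ACIDIC_ALPHABET = "DENQHWYP"

DECOY_KINDS = ("decoy_no_signal", "decoy_folded_domain", "decoy_no_repeats")
DECOY_DOMAIN_ACCESSION = "PFTEST01"


@dataclass(frozen=True)
class PrecursorSpec:
    """Blueprint of one planted precursor."""

    n_copies: int
    peptide: str
    site_pattern_id: int  # 0-9
    signal_length: int = 18  # in [12, 30]
    spacer_length_range: tuple[int, int] = (4, 12)
    taxon: str = "Gastropoda"
    amidation: bool = True  # G-less cores get a planted donor G when True

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ConfigError("n_copies must be positive")
        if not 0 <= self.site_pattern_id <= 9:
            raise ConfigError("site_pattern_id must be in 0..9")
        if not 12 <= self.signal_length <= 30:
            raise ConfigError("signal_length must be in [12, 30]")
        core = _CORES[self.site_pattern_id]
        validate_peptide(self.peptide, core, self.amidation)


def validate_peptide(peptide: str, core: str, amidation: bool) -> None:
    """Reject peptides that would create or distort cleavage motifs."""
    if len(peptide) < 3:
        raise ConfigError("peptide must be at least 3 residues")
    if core in peptide:
        raise ConfigError(f"peptide {peptide!r} contains the site core {core!r}")
    if peptide[0] in "RK" or peptide[-1] in "RK":
        raise ConfigError(f"peptide {peptide!r} starts/ends with a basic residue")
    for a, b in zip(peptide, peptide[1:]):
        if a in "RK" and b in "RK":
            raise ConfigError(f"peptide {peptide!r} contains a basic-residue pair")
        if a == "G" and b in "RK":
            raise ConfigError(f"peptide {peptide!r} contains G followed by a basic residue")
    g_less = not core.startswith("G")
    if g_less and not amidation and peptide.endswith("G"):
        raise ConfigError(
            f"peptide {peptide!r} ends in G before a G-less core without amidation"
        )


def make_signal(signal_length: int) -> str:
    """Synthetic signal peptide: n-region MK, leucine h-core, and a QAHA
    c-region whose alanines satisfy the (-3,-1) small-residue rule only at
    the intended boundary (Q and H are not small, so neighbouring positions
    are ineligible and the predicted cleavage lands exactly after the final
    residue)."""
    return "M" + "K" + "L" * (signal_length - 6) + "QAHA"


@dataclass
class TruthRow:
    """Ground truth for one generated record."""

    record_id: str
    cls: str  # precursor | decoy_no_signal | decoy_folded_domain | decoy_no_repeats
    taxon: str
    family_id: str = ""
    peptide: str = ""
    n_copies: int = 0
    signal_end: int = 0  # 0-based index of the first mature residue (0 = none)
    site_spans: tuple[tuple[int, int], ...] = ()  # on the mature sequence


def _spacer(rng: random.Random, length_range: tuple[int, int]) -> str:
    n = rng.randint(length_range[0], length_range[1])
    return "".join(rng.choice(SPACER_ALPHABET) for _ in range(n))


def generate_precursor(
    spec: PrecursorSpec,
    rng: random.Random,
    record_id: str = "precursor",
    family_id: str = "",
) -> tuple[ProteinRecord, TruthRow]:
    """Build one planted precursor and its truth row (deterministic given the
    generator state).  The generated record is post-verified: scanning its
    mature region must yield exactly ``n_copies`` sites and excision exactly
    ``n_copies`` copies of the planted peptide."""
    core = _CORES[spec.site_pattern_id]
    donor = "G" if (spec.amidation and not core.startswith("G")) else ""
    signal = make_signal(spec.signal_length)
    unit = spec.peptide + donor + core
    mature = unit * spec.n_copies + _spacer(rng, spec.spacer_length_range)
    seq = signal + mature

    sites = scan_cleavage_sites(mature)
    if len(sites) != spec.n_copies:
        raise ConfigError(
            f"spec for {record_id}: expected {spec.n_copies} cleavage sites, "
            f"scan found {len(sites)}"
        )
    peptides = excise_peptides(mature, sites, min_len=1)
    copies = [p for p in peptides if p.sequence == spec.peptide]
    if len(copies) != spec.n_copies:
        raise ConfigError(
            f"spec for {record_id}: excision recovered {len(copies)} peptide "
            f"copies, expected {spec.n_copies}"
        )
    record = ProteinRecord(id=record_id, sequence=seq, taxon=spec.taxon)
    pred = predict_signal(record)
    if not pred.has_signal or pred.cleavage_index != spec.signal_length:
        raise ConfigError(
            f"spec for {record_id}: built-in predictor places the cleavage at "
            f"{pred.cleavage_index}, expected {spec.signal_length}"
        )
    truth = TruthRow(
        record_id=record_id,
        cls="precursor",
        taxon=spec.taxon,
        family_id=family_id,
        peptide=spec.peptide,
        n_copies=spec.n_copies,
        signal_end=spec.signal_length,
        site_spans=tuple(s.span for s in sites),
    )
    return record, truth


def random_peptide(rng: random.Random, min_len: int = 8, max_len: int = 15) -> str:
    """Random family peptide over the motif-safe alphabet (never ends in G —
    the alphabet is G-free)."""
    n = rng.randint(min_len, max_len)
    return "".join(rng.choice(PEPTIDE_ALPHABET) for _ in range(n))


def random_spec(rng: random.Random, taxon: str = "Gastropoda") -> PrecursorSpec:
    return PrecursorSpec(
        n_copies=rng.randint(2, 5),
        peptide=random_peptide(rng),
        site_pattern_id=rng.randrange(10),
        signal_length=rng.randint(12, 30),
        spacer_length_range=(4, 12),
        taxon=taxon,
        amidation=bool(rng.getrandbits(1)),
    )


def generate_decoys(
    kind: str,
    n: int,
    rng: random.Random,
    id_prefix: str = "",
    taxa: Sequence[str] = ("Gastropoda",),
) -> tuple[list[ProteinRecord], list[DomainHit], list[TruthRow]]:
    """Generate ``n`` decoys of one class, each failing exactly its gate."""
    if kind not in DECOY_KINDS:
        raise ConfigError(f"unknown decoy kind {kind!r}")
    records: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    truths: list[TruthRow] = []
    for k in range(n):
        taxon = rng.choice(list(taxa))
        rid = f"{id_prefix}{kind}_{k}|{taxon}"
        if kind == "decoy_no_signal":
            head = "M" + "".join(rng.choice(ACIDIC_ALPHABET) for _ in range(44))
            spec = random_spec(rng, taxon)
            core = _CORES[spec.site_pattern_id]
            donor = "G" if (spec.amidation and not core.startswith("G")) else ""
            body = (spec.peptide + donor + core) * spec.n_copies + _spacer(rng, (4, 12))
            seq = head + body
        elif kind == "decoy_folded_domain":
            spec = random_spec(rng, taxon)
            rec, _ = generate_precursor(spec, rng, record_id=rid)
            seq = rec.sequence
            hits.append(
                DomainHit(
                    record_id=rid,
                    domain_accession=DECOY_DOMAIN_ACCESSION,
                    domain_name="synthetic_fold",
                    evalue=1e-20,
                    env_start=spec.signal_length,
                    env_end=len(seq),
                )
            )
        else:  # decoy_no_repeats
            signal = make_signal(rng.randint(12, 30))
            body = "".join(
                rng.choice(PEPTIDE_ALPHABET + "G") for _ in range(rng.randint(40, 120))
            )
            # G-free tail guard is unnecessary: motifs need K/R, absent here
            seq = signal + body
            assert not scan_cleavage_sites(body), "decoy_no_repeats grew a motif"
        records.append(ProteinRecord(id=rid, sequence=seq, taxon=taxon))
        truths.append(TruthRow(record_id=rid, cls=kind, taxon=taxon))
    return records, hits, truths


@dataclass
class Benchmark:
    """In-memory benchmark bundle (also writable as plain-text files)."""

    proteome: list[ProteinRecord]
    domain_hits: list[DomainHit]
    reference: list[ProteinRecord]
    truth: list[TruthRow]

    @property
    def planted_ids(self) -> set[str]:
        return {t.record_id for t in self.truth if t.cls == "precursor"}


def generate_benchmark(
    n_pos: int = 150,
    n_neg_per_kind: int = 617,
    seed: int = 42,
    members_per_family: int = 5,
    out_dir: str | Path | None = None,
) -> Benchmark:
    """Build the standard benchmark: planted precursor families among decoys.

    Precursors are grouped into families of ``members_per_family`` members
    sharing one peptide and cleavage pattern but differing in copy number,
    signal and spacer, each member carried by a different terminal taxon —
    so redundancy collapse, clustering, and phyletic classification are all
    exercised.  The reference set holds one representative per family with
    redrawn spacers (screening tests similarity, not identity).  Fully
    reproducible from ``seed``; with ``out_dir`` the proteome FASTA, a
    HMMER-style domain table, the reference FASTA and a truth TSV are
    written.
    """
    rng = random.Random(seed)
    leaves = CladeTree.default().leaves
    proteome: list[ProteinRecord] = []
    truth: list[TruthRow] = []
    reference: list[ProteinRecord] = []
    domain_hits: list[DomainHit] = []

    n_families = (n_pos + members_per_family - 1) // members_per_family if n_pos else 0
    made = 0
    for f in range(n_families):
        peptide = random_peptide(rng)
        pattern_id = rng.randrange(10)
        amidation = bool(rng.getrandbits(1))
        breadth = rng.randint(2, min(members_per_family, len(leaves)))
        family_taxa = rng.sample(leaves, breadth)
        for m in range(members_per_family):
            if made >= n_pos:
                break
            taxon = family_taxa[m % len(family_taxa)]
            spec = PrecursorSpec(
                n_copies=rng.randint(2, 5),
                peptide=peptide,
                site_pattern_id=pattern_id,
                signal_length=rng.randint(12, 30),
                taxon=taxon,
                amidation=amidation,
            )
            rid = f"fam{f}_m{m}|{taxon}"
            rec, row = generate_precursor(spec, rng, record_id=rid, family_id=f"fam{f}")
            proteome.append(rec)
            truth.append(row)
            made += 1
        core = _CORES[pattern_id]
        donor = "G" if (amidation and not core.startswith("G")) else ""
        ref_seq = (peptide + donor + core) * rng.randint(2, 5) + _spacer(rng, (6, 14))
        reference.append(ProteinRecord(id=f"ref_fam{f}", sequence=ref_seq, taxon="reference"))

    for kind in DECOY_KINDS:
        recs, hits, rows = generate_decoys(kind, n_neg_per_kind, rng, taxa=leaves)
        proteome.extend(recs)
        domain_hits.extend(hits)
        truth.extend(rows)

    bench = Benchmark(
        proteome=proteome, domain_hits=domain_hits, reference=reference, truth=truth
    )
    if out_dir is not None:
        write_benchmark(bench, out_dir)
    return bench


def write_benchmark(bench: Benchmark, out_dir: str | Path) -> dict[str, Path]:
    """Write the benchmark as plain-text files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": out / "proteome.fasta",
        "domains": out / "domains.domtbl",
        "reference": out / "reference.fasta",
        "truth": out / "truth.tsv",
    }
    write_fasta(bench.proteome, paths["proteome"])
    write_domtblout(bench.domain_hits, paths["domains"])
    write_fasta(bench.reference, paths["reference"])
    write_truth(bench.truth, paths["truth"])
    return paths


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in HMMER3 --domtblout column layout (1-based envelopes)."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  acc\n")
        for h in hits:
            fh.write(
                f"{h.record_id} - 0 {h.domain_name} {h.domain_accession} 0 "
                f"{h.evalue:g} 0.0 0.0 1 1 {h.evalue:g} {h.evalue:g} 0.0 0.0 "
                f"0 0 0 0 {h.env_start + 1} {h.env_end} 0.00\n"
            )


def write_truth(rows: Iterable[TruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "record_id\tclass\ttaxon\tfamily_id\tpeptide\tn_copies\t"
            "signal_end\tsite_spans\n"
        )
        for r in rows:
            spans = ";".join(f"{a}-{b}" for a, b in r.site_spans)
            fh.write(
                f"{r.record_id}\t{r.cls}\t{r.taxon}\t{r.family_id}\t{r.peptide}\t"
                f"{r.n_copies}\t{r.signal_end}\t{spans}\n"
            )


def read_truth(path: str | Path) -> list[TruthRow]:
    rows: list[TruthRow] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            spans = tuple(
                tuple(int(x) for x in part.split("-"))
                for part in cols[7].split(";")
                if part
            )
            rows.append(
                TruthRow(
                    record_id=cols[0],
                    cls=cols[1],
                    taxon=cols[2],
                    family_id=cols[3],
                    peptide=cols[4],
                    n_copies=int(cols[5]),
                    signal_end=int(cols[6]),
                    site_spans=spans,  # type: ignore[arg-type]
                )
            )
    return rows
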