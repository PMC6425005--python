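"""Readers and writers for every external format the pipeline touches.

All internal coordinates are 0-based half-open; 1-based inclusive coordinates
of BLAST tabular and HMMER domain tables are converted at this boundary.
Round-trips through each reader/writer pair are exact for identifiers and
sequences and agree to 1e-6 for real-valued fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .errors import FormatError, StateError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = AMINO_ACIDS | {"X"}


def default_taxon_convention(header_id: str) -> str:
    """Taxon = suffix after the last '|' of the id token, else 'unknown'."""
    if "|" in header_id:
        return header_id.rsplit("|", 1)[1] or "unknown"
    return "unknown"


@dataclass
class ProteinRecord:
    """One protein sequence with identity and taxon provenance.

    The unit flowing through every pipeline stage.  ``sequence`` is uppercase
    over the 20 standard amino acids plus X; ``taxon`` should match a leaf of
    the clade configuration for classification stages.
    """

    id: str
    sequence: str
    taxon: str = "unknown"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise StateError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.sequence:
            raise StateError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise StateError(
                f"record {self.id!r} has illegal residue {self.sequence[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DomainHit:
    """One folded-domain match (hmmsearch-style) on a protein."""

    record_id: str
    domain_accession: str
    domain_name: str
    evalue: float
    env_start: int  # 0-based
    env_end: int  # half-open

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise StateError(f"negative e-value {self.evalue} for {self.record_id}")
        if self.env_start >= self.env_end:
            raise StateError(
                f"empty envelope [{self.env_start},{self.env_end}) for {self.record_id}"
            )


@dataclass
class SimilarityHit:
    """One pairwise local-alignment hit (BLAST outfmt-6 column set)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int  # 0-based half-open spans
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise StateError(f"negative e-value on hit {self.query_id}->{self.subject_id}")
        if self.alignment_length < 1:
            raise StateError(f"alignment length < 1 on hit {self.query_id}->{self.subject_id}")

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def subject_span(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)

    @property
    def pvalue(self) -> float:
        """P = 1 - exp(-E), the standard Karlin-Altschul conversion."""
        return -math.expm1(-self.evalue)


def read_fasta(
    path: str | Path,
    taxon_convention: Callable[[str], str] = default_taxon_convention,
) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id; the taxon is
    derived from the id via ``taxon_convention``.  Sequences are uppercased and
    a single trailing '*' stop character (TransDecoder-style) is stripped.
    Malformed input raises :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FormatError(f"{path}:{header_line}: entry {header!r} has no sequence")
        for i, c in enumerate(seq):
            if c not in ALLOWED_RESIDUES:
                raise FormatError(
                    f"{path}: record {header!r}: illegal residue {c!r} at position {i}"
                )
        rid = header
        if rid in seen:
            raise FormatError(f"{path}:{header_line}: duplicate record id {rid!r}")
        seen.add(rid)
        tok = header.split()[0] if header.split() else ""
        desc = header[len(tok):].strip()
        records.append(
            ProteinRecord(id=tok, sequence=seq, taxon=taxon_convention(tok), description=desc)
        )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].strip()
                if not head:
                    raise FormatError(f"{path}:{lineno}: FASTA header with no id")
                header = head
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence data before any header")
                chunks.append(line.strip())
        flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as 60-column-wrapped FASTA, in input order."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# --- domain-hit tables -------------------------------------------------------

#: column indices in HMMER3 domtblout: target(0) taccn(1) tlen(2) query(3)
#: qaccn(4) qlen(5) full-E(6) ... c-Evalue(11) i-Evalue(12) ... env_from(19) env_to(20)
_DOMTBL_MIN_COLS = 21


def parse_domain_table(path: str | Path, dialect: str = "hmmer-domtbl") -> list[DomainHit]:
    """Parse a folded-domain hit table.

    ``hmmer-domtbl``: HMMER3 ``--domtblout`` layout from searching Pfam
    profiles against the proteome; the per-domain *independent* E-value column
    is used.  ``simple-tsv``: the package's own sidecar layout
    (record_id, accession, name, evalue, env_start, env_end; 0-based half-open).
    Comment lines (leading '#') are skipped; any other line either parses or
    raises :class:`FormatError` with its line number.
    """
    if dialect not in ("hmmer-domtbl", "simple-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            try:
                if dialect == "hmmer-domtbl":
                    if len(cols) < _DOMTBL_MIN_COLS:
                        raise ValueError(
                            f"expected >= {_DOMTBL_MIN_COLS} columns, got {len(cols)}"
                        )
                    hits.append(
                        DomainHit(
                            record_id=cols[0],
                            domain_accession=cols[4],
                            domain_name=cols[3],
                            evalue=float(cols[12]),
                            env_start=int(cols[19]) - 1,
                            env_end=int(cols[20]),
                        )
                    )
                else:
                    if len(cols) != 6:
                        raise ValueError(f"expected 6 columns, got {len(cols)}")
                    hits.append(
                        DomainHit(
                            record_id=cols[0],
                            domain_accession=cols[1],
                            domain_name=cols[2],
                            evalue=float(cols[3]),
                            env_start=int(cols[4]),
                            env_end=int(cols[5]),
                        )
                    )
            except (ValueError, StateError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the ``simple-tsv`` dialect (round-trips with the parser)."""
    with open(path, "w") as fh:
        fh.write("# record_id\taccession\tname\tevalue\tenv_start\tenv_end\n")
        for h in hits:
            fh.write(
                f"{h.record_id}\t{h.domain_accession}\t{h.domain_name}\t"
                f"{h.evalue:.6g}\t{h.env_start}\t{h.env_end}\n"
            )


# --- similarity tables -------------------------------------------------------


def parse_similarity_table(path: str | Path) -> list[SimilarityHit]:
    """Parse 12-column BLAST tabular (outfmt 6).

    1-based inclusive coordinates are converted to 0-based half-open spans.
    """
    path = Path(path)
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                hits.append(
                    SimilarityHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=float(cols[2]),
                        alignment_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        query_start=int(cols[6]) - 1,
                        query_end=int(cols[7]),
                        subject_start=int(cols[8]) - 1,
                        subject_end=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except (ValueError, StateError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_similarity_table(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular (outfmt 6, 1-based inclusive)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.query_start + 1}\t{h.query_end}\t{h.subject_start + 1}\t"
                f"{h.subject_end}\t{h.evalue:.6g}\t{h.bitscore:.6g}\n"
            )


# --- CLANS-style cluster files ----------------------------------------------


def write_cluster_file(
    graph,
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write a :class:`~prospect.clustermap.ClusterGraph` as a CLANS-style file.

    Layout: a parameter header, a ``<seq>`` block of FASTA entries in node
    insertion order, a ``<pos>`` block of per-node 2-D coordinates, and an
    ``<hsp>`` block of ``i j:pvalue`` edges.  Parseable by
    :func:`read_cluster_file`.
    """
    if graph.coords is None and len(graph.nodes) > 0:
        raise StateError("graph has no layout coordinates; run the layout first")
    sequences = sequences or {}
    with open(path, "w") as fh:
        fh.write(f"sequences={len(graph.nodes)}\n")
        fh.write("<param>\n")
        fh.write("colors=taxon\n")
        fh.write("</param>\n")
        fh.write("<seq>\n")
        for rid, taxon in graph.nodes:
            fh.write(f">{rid}|{taxon}\n{sequences.get(rid, 'X')}\n")
        fh.write("</seq>\n")
        fh.write("<pos>\n")
        for i in range(len(graph.nodes)):
            x, y = graph.coords[i]
            fh.write(f"{i} {x:.6f} {y:.6f}\n")
        fh.write("</pos>\n")
        fh.write("<hsp>\n")
        for i, j, p in graph.edges:
            fh.write(f"{i} {j}:{p:.6e}\n")
        fh.write("</hsp>\n")


def read_cluster_file(path: str | Path):
    """Companion reader for :func:`write_cluster_file` (round-trip exact)."""
    from .clustermap import ClusterGraph  # local import: avoid cycle

    import numpy as np

    path = Path(path)
    nodes: list[tuple[str, str]] = []
    coords: list[tuple[float, float]] = []
    edges: list[tuple[int, int, float]] = []
    block = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("<") and line.endswith(">"):
                block = None if line.startswith("</") else line[1:-1]
                continue
            if block == "seq":
                if line.startswith(">"):
                    head = line[1:]
                    if "|" in head:
                        rid, taxon = head.rsplit("|", 1)
                    else:
                        rid, taxon = head, "unknown"
                    nodes.append((rid, taxon))
                continue
            if block == "pos":
                cols = line.split()
                if len(cols) != 3:
                    raise FormatError(f"{path}:{lineno}: bad <pos> line")
                coords.append((float(cols[1]), float(cols[2])))
                continue
            if block == "hsp":
                try:
                    ij, p = line.split(":")
                    i, j = ij.split()
                    edges.append((int(i), int(j), float(p)))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad <hsp> line") from exc
                continue
    graph = ClusterGraph(nodes=nodes, edges=edges)
    if coords:
        if len(coords) != len(nodes):
            raise FormatError(f"{path}: {len(coords)} positions for {len(nodes)} sequences")
        graph.coords = np.asarray(coords, dtype=float)
    return graph
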