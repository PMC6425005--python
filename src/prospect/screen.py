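"""The candidate-selection cascade for precursor discovery.

A mature (signal-stripped) protein is a credible proneuropeptide or
prohormone precursor when it (i) carries repetitive mono-/dibasic
prohormone-convertase cleavage motifs, (ii) lacks known folded protein
domains, and (iii) shows similarity to a curated reference set of precursors.
This module implements those three predicates plus a CD-HIT-style greedy
redundancy collapse, each as a separate operation so the cascade order is
configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import blosum62, estimate_evalue, sw_align
from .errors import ConfigError, StateError
from .io import DomainHit, ProteinRecord, SimilarityHit

#: The ten prohormone-convertase cleavage-site patterns, in canonical order.
#: Basic-residue runs may flank a core that is a mono- or dibasic site,
#: optionally preceded by a glycine (the amide donor for the upstream peptide).
CLEAVAGE_PATTERNS: tuple[str, ...] = (
    "(R|K)*GKR(R|K)*",
    "(R|K)*GRK(R|K)*",
    "(R|K)*GRR(R|K)*",
    "(R|K)*GKK(R|K)*",
    "(R|K)*KR(R|K)*",
    "(R|K)*RK(R|K)*",
    "(R|K)*RR(R|K)*",
    "(R|K)*KK(R|K)*",
    "(R|K)*GR(R|K)*",
    "(R|K)*GK(R|K)*",
)

_CORES: tuple[str, ...] = ("GKR", "GRK", "GRR", "GKK", "KR", "RK", "RR", "KK", "GR", "GK")
_BASIC = frozenset("RK")


def cleavage_patterns() -> tuple[str, ...]:
    """The ten cleavage-site regular expressions, in canonical order."""
    return CLEAVAGE_PATTERNS


@dataclass(frozen=True)
class CleavageSite:
    """One matched cleavage motif occurrence within a mature sequence."""

    start: int
    end: int  # half-open
    core: str  # full matched motif text
    pattern_id: int  # 0-9, index into cleavage_patterns()
    g_donor: bool  # motif begins with G => amide donor for the upstream peptide

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _longest_match_at(seq: str, pos: int) -> tuple[int, int] | None:
    """Longest full match of any pattern anchored at ``pos``.

    A match is (basic run)(core)(basic run).  Returns (end, pattern_id) of
    the longest match, ties broken by lowest pattern id, or None.
    """
    n = len(seq)
    # length of the basic run starting at pos
    run = 0
    while pos + run < n and seq[pos + run] in _BASIC:
        run += 1
    best_end = -1
    best_pid = -1
    for pid, core in enumerate(_CORES):
        lc = len(core)
        # the core may start after 0..run leading basic residues
        for lead in range(run + 1):
            s = pos + lead
            if seq[s : s + lc] != core:
                continue
            e = s + lc
            while e < n and seq[e] in _BASIC:
                e += 1
            # patterns are tried in ascending pid order, so on equal length
            # the lowest pattern id wins automatically
            if e > best_end:
                best_end, best_pid = e, pid
    return (best_end, best_pid) if best_end >= 0 else None


def scan_cleavage_sites(sequence: str) -> list[CleavageSite]:
    """Scan a mature sequence left to right for cleavage motifs.

    At each position the longest match over the ten patterns wins (ties by
    lowest pattern id); matches never overlap; the scan resumes after each
    match.  Returned sites are sorted by start.
    """
    sites: list[CleavageSite] = []
    pos = 0
    n = len(sequence)
    while pos < n:
        if sequence[pos] not in ("R", "K", "G"):
            pos += 1
            continue
        m = _longest_match_at(sequence, pos)
        if m is None:
            pos += 1
            continue
        end, pid = m
        core = sequence[pos:end]
        sites.append(
            CleavageSite(start=pos, end=end, core=core, pattern_id=pid, g_donor=core[0] == "G")
        )
        pos = end
    return sites


def has_repetitive_sites(sites: Sequence[CleavageSite], min_sites: int = 1) -> bool:
    """True when the sequence carries at least ``min_sites`` cleavage motifs.

    The default 1 reflects the literal discard rule "lacking any repetitive
    motif"; raise ``min_sites`` for a stricter reading.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be positive")
    return len(sites) >= min_sites


def filter_by_repetitive_sites(
    records: Iterable[ProteinRecord], min_sites: int = 1
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Split records into (kept, removed-with-reason) on the motif predicate."""
    kept: list[ProteinRecord] = []
    removed: list[tuple[ProteinRecord, str]] = []
    for rec in records:
        n = len(scan_cleavage_sites(rec.sequence))
        if n >= min_sites:
            kept.append(rec)
        else:
            removed.append((rec, f"{n} cleavage motif(s), fewer than {min_sites}"))
    return kept, removed


def strip_accession_version(accession: str) -> str:
    return accession.rsplit(".", 1)[0] if "." in accession else accession


def filter_by_domains(
    records: Iterable[ProteinRecord],
    hits: Iterable[DomainHit],
    max_evalue: float = 1e-10,
    allowlist: Iterable[str] = (),
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Remove records with a confident folded-domain match.

    A record is removed iff it has at least one hit with
    ``evalue <= max_evalue`` whose version-stripped accession is not in the
    allowlist.  The allowlist exists because some genuine precursor families
    carry their own profile models (e.g. the FMRFamide-related-peptide model
    PF01581) and would otherwise be discarded as folded proteins.
    """
    allow = {strip_accession_version(a) for a in allowlist}
    by_record: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_record.setdefault(h.record_id, []).append(h)
    kept: list[ProteinRecord] = []
    removed: list[tuple[ProteinRecord, str]] = []
    for rec in records:
        offending = None
        for h in by_record.get(rec.id, ()):
            if h.evalue <= max_evalue and strip_accession_version(h.domain_accession) not in allow:
                offending = h
                break
        if offending is None:
            kept.append(rec)
        else:
            removed.append(
                (rec, f"folded domain {offending.domain_accession} at e={offending.evalue:g}")
            )
    return kept, removed


@dataclass
class RedundancyClusters:
    """Outcome of the greedy identity collapse."""

    representatives: list[str]
    membership: dict[str, str]  # member id -> representative id

    def representative_of(self, record_id: str) -> str:
        return self.membership[record_id]


def pairwise_identity(a: str, b: str, matrix: np.ndarray | None = None) -> float:
    """Identity of the optimal local alignment, over the shorter sequence."""
    res = sw_align(a, b, matrix)
    return res.n_identical / min(len(a), len(b))


def remove_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.95,
    matrix: np.ndarray | None = None,
) -> RedundancyClusters:
    """CD-HIT-style greedy incremental clustering.

    Records are visited by decreasing length (ties: id ascending); each joins
    the first existing representative with identity >= threshold (identical
    aligned positions in the local alignment divided by the shorter sequence
    length), else founds a new cluster.
    """
    if not 0 < identity_threshold <= 1:
        raise ConfigError(f"identity threshold must be in (0,1], got {identity_threshold}")
    sub = blosum62() if matrix is None else matrix
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[ProteinRecord] = []
    membership: dict[str, str] = {}
    for rec in order:
        assigned = False
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence, sub) >= identity_threshold:
                membership[rec.id] = rep.id
                assigned = True
                break
        if not assigned:
            reps.append(rec)
            membership[rec.id] = rec.id
    return RedundancyClusters(representatives=[r.id for r in reps], membership=membership)


def screen_against_reference(
    records: Sequence[ProteinRecord],
    reference: Sequence[ProteinRecord] | None,
    max_evalue: float = 1e-03,
    hit_table: Iterable[SimilarityHit] | None = None,
    matrix: np.ndarray | None = None,
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Keep records with at least one reference hit at ``evalue <= max_evalue``.

    Either an in-process similarity search against ``reference`` is run with
    the package aligner, or a precomputed ``hit_table`` (e.g. imported BLAST
    tabular) is consulted instead.
    """
    kept: list[ProteinRecord] = []
    removed: list[tuple[ProteinRecord, str]] = []
    if hit_table is not None:
        good = {h.query_id for h in hit_table if h.evalue <= max_evalue}
        for rec in records:
            if rec.id in good:
                kept.append(rec)
            else:
                removed.append((rec, f"no reference hit at e<={max_evalue:g}"))
        return kept, removed

    if not reference:
        raise ConfigError("reference precursor set is empty")
    sub = blosum62() if matrix is None else matrix
    for rec in records:
        best = float("inf")
        for ref in reference:
            res = sw_align(rec.sequence, ref.sequence, sub)
            if res.score <= 0:
                continue
            e = estimate_evalue(res.score, len(rec.sequence), len(ref.sequence))
            if e < best:
                best = e
            if best <= max_evalue:
                break
        if best <= max_evalue:
            kept.append(rec)
        else:
            removed.append((rec, f"best reference e-value {best:g} > {max_evalue:g}"))
    return kept, removed
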