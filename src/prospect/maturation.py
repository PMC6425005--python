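"""Excision and annotation of mature bioactive peptides.

A precursor's mature region is cut at its convertase cleavage sites into
candidate peptides.  Two post-translational modifications are annotated:

* C-terminal alpha-amidation — a glycine immediately preceding the basic
  cleavage residues is oxidised to an amide by peptidylglycine
  alpha-amidating monooxygenase.  The donor glycine is either the leading G
  of the following motif (GKR, GRK, ..., GR, GK) or, for G-less motifs
  (KR/RK/RR/KK), a terminal G of the peptide segment itself, which is then
  stripped from the reported peptide.
* N-terminal pyroglutamination — an N-terminal glutamine cyclises to
  pyroglutamate.

Alignment-summary helpers (consensus strings in ``GN[QHR]QN`` style and
conserved-residue column counts) support family descriptions.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .errors import StateError
from .screen import CleavageSite


@dataclass
class MaturePeptide:
    """One excised bioactive peptide with modification flags."""

    parent_id: str
    start: int  # span on the mature precursor, half-open, pre-strip
    end: int
    sequence: str  # after donor-glycine removal
    amidated: bool
    pyroglutamate: bool

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def excise_peptides(
    mature_seq: str,
    sites: Sequence[CleavageSite],
    min_len: int = 3,
    parent_id: str = "",
) -> list[MaturePeptide]:
    """Cut the mature sequence at its cleavage sites into peptides.

    Segments are the maximal intervals between consecutive site spans plus
    the leading and trailing segments.  A segment is amidated when the
    following site's motif starts with G (the donor), or when the segment
    itself ends in G immediately before a G-less motif — in which case the
    trailing donor G is stripped from the reported peptide.  A leading Q
    marks pyroglutamate.  Segments shorter than ``min_len`` after processing
    (or empty) are discarded.
    """
    prev_end = 0
    for s in sites:
        if s.start < prev_end:
            raise StateError("cleavage sites overlap or are unsorted")
        if mature_seq[s.start : s.end] != s.core:
            raise StateError(f"site core {s.core!r} does not match sequence at {s.start}")
        prev_end = s.end

    bounds: list[tuple[int, int, CleavageSite | None]] = []
    pos = 0
    for s in sites:
        bounds.append((pos, s.start, s))
        pos = s.end
    bounds.append((pos, len(mature_seq), None))

    peptides: list[MaturePeptide] = []
    for start, end, next_site in bounds:
        segment = mature_seq[start:end]
        if not segment:
            continue
        amidated = False
        if next_site is not None:
            if next_site.g_donor:
                amidated = True
            elif segment.endswith("G"):
                amidated = True
                segment = segment[:-1]
        if not segment or len(segment) < min_len:
            continue
        peptides.append(
            MaturePeptide(
                parent_id=parent_id,
                start=start,
                end=end,
                sequence=segment,
                amidated=amidated,
                pyroglutamate=segment.startswith("Q"),
            )
        )
    return peptides


def count_motif_repeats(mature_seq: str, motif: str) -> int:
    """Count non-overlapping, left-to-right matches of ``motif`` (a regular
    expression) — the peptide-copy statistic behind repeat-number
    comparisons across species."""
    try:
        pattern = re.compile(motif)
    except re.error as exc:
        raise ValueError(f"invalid motif pattern {motif!r}: {exc}") from exc
    count = 0
    pos = 0
    while pos <= len(mature_seq):
        m = pattern.search(mature_seq, pos)
        if m is None:
            break
        count += 1
        pos = m.end() if m.end() > m.start() else pos + 1
    return count


def _check_alignment(aligned: Sequence[str]) -> None:
    if len(aligned) < 2:
        raise ValueError("alignment needs at least 2 rows")
    width = len(aligned[0])
    if any(len(row) != width for row in aligned):
        raise ValueError("alignment rows have unequal lengths")


def consensus_from_alignment(aligned: Sequence[str], majority: float = 0.8) -> str:
    """Bracketed consensus of a gapped alignment.

    Per column: a residue present in >= 80% of rows is emitted verbatim;
    otherwise up to four distinct non-gap residues are emitted bracketed,
    ordered by frequency then first occurrence; more diverse columns emit
    'X'.  Columns that are majority-gap are dropped.  The notation matches
    conventional family consensus strings such as GN[QHR]QN.
    """
    _check_alignment(aligned)
    n = len(aligned)
    out: list[str] = []
    for col in range(len(aligned[0])):
        column = [row[col] for row in aligned]
        gaps = column.count("-")
        if gaps > n / 2:
            continue
        residues = [c for c in column if c != "-"]
        counts = Counter(residues)
        top, top_n = counts.most_common(1)[0]
        if top_n >= majority * n:
            out.append(top)
            continue
        distinct = sorted(
            counts, key=lambda c: (-counts[c], next(i for i, x in enumerate(column) if x == c))
        )
        if len(distinct) <= 4:
            out.append("[" + "".join(distinct) + "]")
        else:
            out.append("X")
    return "".join(out)


def conserved_residue_columns(
    aligned: Sequence[str], residue: str, min_fraction: float = 1.0
) -> int:
    """Number of alignment columns conserved for ``residue``.

    A column counts when the residue's frequency among non-gap entries is at
    least ``min_fraction`` and non-gap entries cover at least half the rows —
    the statistic behind counts like "ten conserved cysteines".
    """
    if len(residue) != 1:
        raise ValueError("residue must be a single letter")
    _check_alignment(aligned)
    n = len(aligned)
    count = 0
    for col in range(len(aligned[0])):
        column = [row[col] for row in aligned]
        nongap = [c for c in column if c != "-"]
        if len(nongap) < n / 2 or not nongap:
            continue
        if nongap.count(residue) / len(nongap) >= min_fraction:
            count += 1
    return count


def reconstruct(
    mature_seq_peptides: Sequence[MaturePeptide], sites: Sequence[CleavageSite], length: int
) -> str:
    """Re-interleave peptides (with stripped donor glycines restored) and
    site cores into the original mature sequence — the auditing inverse of
    :func:`excise_peptides` for full-coverage excisions."""
    chars = [""] * length
    for s in sites:
        chars[s.start] = s.core
        for k in range(s.start + 1, s.end):
            chars[k] = ""
    for p in mature_seq_peptides:
        seq = p.sequence
        if p.end - p.start == len(seq) + 1:  # stripped donor G
            seq = seq + "G"
        chars[p.start] = seq
        for k in range(p.start + 1, p.end):
            chars[k] = ""
    return "".join(chars)
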