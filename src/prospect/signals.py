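"""Signal-peptide gating and secretome construction.

Candidate precursors must carry an N-terminal signal peptide directing them
into the secretory pathway.  The gate can run in two modes:

* a built-in von-Heijne-style heuristic (`predict_signal`): the (-3,-1) rule
  (small residues at the two positions flanking the cleavage site) combined
  with a hydrophobic h-region requirement scored by mean Kyte-Doolittle
  hydropathy, with separate score cut-offs for plain (0.45) and
  transmembrane-like (0.50) N-termini;
* an importer for external predictor output (`import_signal_predictions`),
  preserving fidelity when a dedicated tool has been run upstream.

Retained records are truncated to their mature sequence (signal removed) by
`make_secretome`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigError, FormatError, StateError
from .io import ProteinRecord

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

#: Small residues accepted at the -3 and -1 positions of the cleavage site.
SMALL_RESIDUES = set("AGSCTV")

MIN_CLEAVAGE = 8
MAX_CLEAVAGE = 40
HYDROPATHY_FLOOR = 1.5  # minimum mean h-region hydropathy for an eligible site
TM_HYDROPATHY = 2.0  # N-terminal mean hydropathy above which a record is tm-like
LOGISTIC_SLOPE = 2.0


@dataclass(frozen=True)
class SignalParams:
    """Cut-offs of the signal gate.

    ``u`` applies to plain-network records, ``U`` to transmembrane-like ones
    (a hydrophobic first 40 residues can mimic a membrane anchor, so a higher
    bar is applied there).
    """

    u: float = 0.45
    U: float = 0.50

    def __post_init__(self) -> None:
        if not (0 <= self.u <= 1 and 0 <= self.U <= 1):
            raise ConfigError(f"thresholds must lie in [0,1], got u={self.u}, U={self.U}")


@dataclass
class SignalPrediction:
    """Presence/position/score of an N-terminal signal peptide for one record."""

    record_id: str
    has_signal: bool
    cleavage_index: int | None  # 0-based index of the first mature residue
    score: float
    network: str  # "plain" | "tm-like"


def _mean_hydropathy(seq: str, start: int, end: int) -> float:
    window = seq[start:end]
    if not window:
        return float("-inf")
    return sum(KYTE_DOOLITTLE.get(c, 0.0) for c in window) / len(window)


def predict_signal(record: ProteinRecord, params: SignalParams = SignalParams()) -> SignalPrediction:
    """Built-in heuristic signal-peptide call.

    Scans candidate cleavage positions ``c`` in [8, 40] (bounded by the
    sequence length).  A position is eligible when the residues at ``c-3`` and
    ``c-1`` are small ({A,G,S,C,T,V}) and the mean Kyte-Doolittle hydropathy of
    the h-window ``[max(2, c-13), c-5)`` is at least 1.5.  The score is a
    logistic transform (slope 2.0) of the best eligible window's mean
    hydropathy minus 1.5; records whose first 40 residues average >= 2.0
    hydropathy are classed tm-like and held to the higher cut-off.
    Sequences shorter than 10 residues return a negative call with score 0.
    """
    seq = record.sequence
    network = "tm-like" if _mean_hydropathy(seq, 0, 40) >= TM_HYDROPATHY else "plain"
    if len(seq) < 10:
        return SignalPrediction(record.id, False, None, 0.0, network)

    best_c = None
    best_h = float("-inf")
    for c in range(MIN_CLEAVAGE, min(MAX_CLEAVAGE, len(seq) - 1) + 1):
        if seq[c - 3] not in SMALL_RESIDUES or seq[c - 1] not in SMALL_RESIDUES:
            continue
        h = _mean_hydropathy(seq, max(2, c - 13), c - 5)
        if h < HYDROPATHY_FLOOR:
            continue
        if h > best_h:
            best_h, best_c = h, c

    if best_c is None:
        return SignalPrediction(record.id, False, None, 0.0, network)

    score = 1.0 / (1.0 + math.exp(-LOGISTIC_SLOPE * (best_h - HYDROPATHY_FLOOR)))
    threshold = params.U if network == "tm-like" else params.u
    has_signal = score >= threshold
    return SignalPrediction(record.id, has_signal, best_c if has_signal else None, score, network)


def import_signal_predictions(
    path: str | Path, params: SignalParams = SignalParams()
) -> dict[str, SignalPrediction]:
    """Import external predictor output.

    Tab-separated columns: record_id, YES/NO, 1-based position of the last
    signal residue, score.  The 1-based last signal residue equals the 0-based
    index of the first mature residue, so it is taken as ``cleavage_index``
    directly.  YES rows whose score falls below the plain-network cut-off are
    demoted to negative calls (with a warning recorded on stderr by callers).
    """
    import sys

    path = Path(path)
    out: dict[str, SignalPrediction] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            rid, flag, pos_s, score_s = cols
            if rid in out:
                raise FormatError(f"{path}:{lineno}: duplicate record id {rid!r}")
            try:
                pos = int(pos_s)
                score = float(score_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if flag not in ("YES", "NO"):
                raise FormatError(f"{path}:{lineno}: flag must be YES or NO, got {flag!r}")
            has_signal = flag == "YES"
            if has_signal and score < params.u:
                print(
                    f"warning: {rid}: YES call with score {score} below cut-off "
                    f"{params.u}; rejected",
                    file=sys.stderr,
                )
                has_signal = False
            out[rid] = SignalPrediction(
                record_id=rid,
                has_signal=has_signal,
                cleavage_index=pos if has_signal else None,
                score=score,
                network="plain",
            )
    return out


def write_signal_predictions(
    predictions: Iterable[SignalPrediction], path: str | Path
) -> None:
    """Write predictions in the importer's table layout."""
    with open(path, "w") as fh:
        for p in predictions:
            flag = "YES" if p.has_signal else "NO"
            pos = p.cleavage_index if p.cleavage_index is not None else 0
            fh.write(f"{p.record_id}\t{flag}\t{pos}\t{p.score:.4f}\n")


def make_secretome(
    records: Iterable[ProteinRecord],
    predictions: Mapping[str, SignalPrediction],
) -> list[ProteinRecord]:
    """Keep signal-positive records and strip their signal peptides.

    Records lacking a positive prediction are discarded; retained records have
    their sequence replaced by the mature region ``sequence[cleavage_index:]``
    with ids unchanged.
    """
    out: list[ProteinRecord] = []
    for rec in records:
        if rec.id not in predictions:
            raise StateError(f"no signal prediction for record {rec.id!r}")
        pred = predictions[rec.id]
        if not pred.has_signal:
            continue
        ci = pred.cleavage_index
        if ci is None or ci >= len(rec.sequence):
            raise StateError(
                f"record {rec.id!r}: cleavage index {ci} outside sequence of "
                f"length {len(rec.sequence)}"
            )
        out.append(
            ProteinRecord(
                id=rec.id,
                sequence=rec.sequence[ci:],
                taxon=rec.taxon,
                description=rec.description,
            )
        )
    return out
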