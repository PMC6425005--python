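"""End-to-end orchestration of the discovery cascade.

Stages, in default order: signal gate -> folded-domain exclusion ->
cleavage-motif filter -> redundancy collapse -> reference similarity screen
-> all-vs-all similarity -> graph / layout / convex clusters -> pruning ->
peptide excision and annotation -> phyletic classification.  Every stage
logs its input/output counts and removal reasons; the report is fully
reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import align, clustermap, maturation, phylo, screen, signals
from .errors import ConfigError
from .io import DomainHit, ProteinRecord, SimilarityHit
from .simulate import TruthRow


@dataclass
class PipelineConfig:
    """All tunable parameters of the cascade, with the canonical defaults."""

    u_threshold: float = 0.45
    U_threshold: float = 0.50
    domain_max_evalue: float = 1e-10
    identity_threshold: float = 0.95
    reference_max_evalue: float = 1e-03
    cluster_p_cut: float = 1e-06
    layout_rounds: int = 20000
    min_cluster_size: int = 3
    min_sites: int = 1
    min_peptide_len: int = 3
    seed: int = 0
    focus_taxa: tuple[str, ...] = ()
    allowlist: tuple[str, ...] = ("PF01581",)
    motif_filter_first: bool = False  # run motif gate before domain exclusion

    def __post_init__(self) -> None:
        for name in ("domain_max_evalue", "reference_max_evalue", "cluster_p_cut"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("u_threshold", "U_threshold", "identity_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.layout_rounds < 1:
            raise ConfigError("layout_rounds must be >= 1")
        if self.min_sites < 1 or self.min_cluster_size < 1 or self.min_peptide_len < 0:
            raise ConfigError("size/count parameters must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("focus_taxa", "allowlist"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class StageLog:
    stage: str
    n_in: int
    n_out: int
    seconds: float
    detail: str = ""


@dataclass
class PipelineReport:
    """Machine-readable outcome of one pipeline run."""

    stages: list[StageLog] = field(default_factory=list)
    audit: list[tuple[str, str, str]] = field(default_factory=list)  # id, stage, reason
    candidates: list[str] = field(default_factory=list)  # surviving representative ids
    membership: dict[str, str] = field(default_factory=dict)  # id -> representative
    families: list[dict] = field(default_factory=list)
    peptides: list[dict] = field(default_factory=list)
    recall: float | None = None
    precision: float | None = None

    def stage_counts(self) -> list[tuple[str, int, int]]:
        return [(s.stage, s.n_in, s.n_out) for s in self.stages]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "stages": [asdict(s) for s in self.stages],
            "audit": self.audit,
            "candidates": self.candidates,
            "membership": self.membership,
            "families": self.families,
            "peptides": self.peptides,
            "recall": self.recall,
            "precision": self.precision,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _log(report: PipelineReport, stage: str, n_in: int, n_out: int, t0: float,
         detail: str = "", verbose: bool = True) -> None:
    entry = StageLog(stage, n_in, n_out, round(time.perf_counter() - t0, 3), detail)
    report.stages.append(entry)
    if verbose:
        print(f"[{stage}] {n_in} -> {n_out} ({entry.seconds}s) {detail}", file=sys.stderr)


def run_pipeline(
    config: PipelineConfig,
    proteome: Sequence[ProteinRecord],
    domain_hits: Iterable[DomainHit] = (),
    reference: Sequence[ProteinRecord] = (),
    signal_predictions: Mapping[str, signals.SignalPrediction] | None = None,
    reference_hit_table: Iterable[SimilarityHit] | None = None,
    truth: Sequence[TruthRow] | None = None,
    clade_tree: phylo.CladeTree | None = None,
    verbose: bool = True,
) -> PipelineReport:
    """Execute the full cascade and return the report.

    With ``truth`` supplied, recall is the fraction of planted precursors
    recovered (directly or via their redundancy representative) and
    precision the fraction of reported candidates that are planted.
    An empty proteome yields a valid all-zero report.
    """
    report = PipelineReport()
    tree = clade_tree or phylo.CladeTree.default()
    records = list(proteome)

    # --- signal gate ---------------------------------------------------------
    t0 = time.perf_counter()
    params = signals.SignalParams(u=config.u_threshold, U=config.U_threshold)
    preds = dict(signal_predictions) if signal_predictions is not None else {
        r.id: signals.predict_signal(r, params) for r in records
    }
    secretome = signals.make_secretome(records, preds)
    kept_ids = {r.id for r in secretome}
    for r in records:
        if r.id not in kept_ids:
            report.audit.append((r.id, "signal", "no signal peptide cleavage site"))
    _log(report, "signal", len(records), len(secretome), t0, verbose=verbose)

    # --- folded-domain exclusion and cleavage-motif filter -------------------
    def domain_stage(recs):
        t = time.perf_counter()
        kept, removed = screen.filter_by_domains(
            recs, domain_hits, config.domain_max_evalue, config.allowlist
        )
        for rec, reason in removed:
            report.audit.append((rec.id, "domains", reason))
        _log(report, "domains", len(recs), len(kept), t, verbose=verbose)
        return kept

    def motif_stage(recs):
        t = time.perf_counter()
        kept, removed = screen.filter_by_repetitive_sites(recs, config.min_sites)
        for rec, reason in removed:
            report.audit.append((rec.id, "motifs", reason))
        _log(report, "motifs", len(recs), len(kept), t, verbose=verbose)
        return kept

    if config.motif_filter_first:
        current = domain_stage(motif_stage(secretome))
    else:
        current = motif_stage(domain_stage(secretome))

    # --- redundancy collapse -------------------------------------------------
    t0 = time.perf_counter()
    clusters = screen.remove_redundancy(current, config.identity_threshold)
    rep_ids = set(clusters.representatives)
    reps = [r for r in current if r.id in rep_ids]
    report.membership = dict(clusters.membership)
    for r in current:
        if r.id not in rep_ids:
            report.audit.append(
                (r.id, "redundancy", f"collapsed into {clusters.membership[r.id]}")
            )
    _log(report, "redundancy", len(current), len(reps), t0, verbose=verbose)

    # --- reference similarity screen -----------------------------------------
    t0 = time.perf_counter()
    if reference or reference_hit_table is not None:
        kept, removed = screen.screen_against_reference(
            reps, reference, config.reference_max_evalue, hit_table=reference_hit_table
        )
        for rec, reason in removed:
            report.audit.append((rec.id, "reference", reason))
    else:
        kept = reps
    _log(report, "reference", len(reps), len(kept), t0, verbose=verbose)
    report.candidates = [r.id for r in kept]

    counts = [s.n_out for s in report.stages]
    assert all(a >= b for a, b in zip(counts, counts[1:])), "cascade counts increased"

    # --- benchmark metrics ---------------------------------------------------
    if truth is not None:
        planted = {t.record_id for t in truth if t.cls == "precursor"}
        reported = set(report.candidates)
        recovered = {
            rid for rid in planted
            if report.membership.get(rid, rid) in reported
        }
        report.recall = len(recovered) / len(planted) if planted else 1.0
        report.precision = (
            len(reported & planted) / len(reported) if reported else 1.0
        )

    # --- clustering ----------------------------------------------------------
    t0 = time.perf_counter()
    taxa = {r.id: r.taxon for r in kept}
    graph = clustermap.ClusterGraph(nodes=[(r.id, r.taxon) for r in kept], edges=[])
    if len(kept) >= 2:
        hits = align.all_vs_all(
            [(r.id, r.sequence) for r in kept], max_p=config.cluster_p_cut
        )
        graph = clustermap.build_graph(
            hits, p_cut=config.cluster_p_cut, taxa=taxa,
            include_ids=[r.id for r in kept],
        )
    if config.focus_taxa:
        graph = clustermap.drop_unconnected_to_focus(graph, config.focus_taxa)
    if graph.n_nodes:
        clustermap.run_layout(graph, rounds=config.layout_rounds, seed=config.seed)
        clustermap.convex_clusters(graph)
        graph, pruned = clustermap.prune_clusters(graph, config.min_cluster_size)
        for rid in pruned:
            report.audit.append((rid, "cluster_prune", "isolated cluster below minimum size"))
    _log(report, "cluster", len(kept), graph.n_nodes, t0, verbose=verbose)

    # --- maturation ----------------------------------------------------------
    t0 = time.perf_counter()
    by_id = {r.id: r for r in kept}
    for rid, _ in graph.nodes:
        rec = by_id[rid]
        sites = screen.scan_cleavage_sites(rec.sequence)
        for pep in maturation.excise_peptides(
            rec.sequence, sites, min_len=config.min_peptide_len, parent_id=rid
        ):
            report.peptides.append(
                {
                    "parent": rid,
                    "start": pep.start,
                    "end": pep.end,
                    "sequence": pep.sequence,
                    "amidated": pep.amidated,
                    "pyroglutamate": pep.pyroglutamate,
                }
            )
    _log(report, "maturation", graph.n_nodes, len(report.peptides), t0, verbose=verbose)

    # --- phyletic classification ---------------------------------------------
    t0 = time.perf_counter()
    leaves = set(tree.leaves)
    cluster_members: dict[str, list[int]] = {}
    for i, label in graph.cluster_of.items():
        if label != clustermap.UNASSIGNED:
            cluster_members.setdefault(label, []).append(i)
    families: list[phylo.FamilyAssignment] = []
    for label in sorted(cluster_members):
        idxs = cluster_members[label]
        members = [graph.nodes[i][0] for i in idxs]
        taxa_present = {graph.nodes[i][1] for i in idxs} & leaves
        fam = phylo.FamilyAssignment(
            family_id=label, members=members, taxa_present=taxa_present
        )
        if taxa_present:
            fam.classify(tree)
        families.append(fam)
        report.families.append(
            {
                "family_id": label,
                "size": len(members),
                "members": members,
                "taxa": sorted(taxa_present),
                "origin": fam.origin,
            }
        )
    _log(report, "classify", len(cluster_members), len(families), t0, verbose=verbose)
    return report
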