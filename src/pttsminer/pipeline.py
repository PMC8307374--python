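"""End-to-end orchestration: mine -> classify -> evolve, with audit logs.

The mining stage chains motif scanning, domain calling, architecture
classification, the candidate length filter, and identity dereplication,
recording per-stage counts (input >= architecture-pass >= filter-pass >=
representatives).  Classification assigns every candidate a subfamily,
clade, and predicted cyclization type against a labeled reference set.
The evolution stage tallies gene counts per lineage and reconstructs
gain/loss history on a species tree.  All stages are deterministic:
re-running with the same inputs reproduces byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from . import architecture as arch
from . import evolution, trees
from .align import AlignmentParams, dereplicate
from .architecture import (ArchitectureLabel, DomainCallParams, LengthWindow,
                           PttsCandidate)
from .io import ProteinRecord, TaxonomyTable, write_tsv
from .motifs import scan_all
from .trees import CladeAssignment, ReferenceSet

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Bundled thresholds for a pipeline run."""

    length_window: LengthWindow = field(default_factory=LengthWindow)
    domain_params: DomainCallParams = field(default_factory=DomainCallParams)
    alignment_params: AlignmentParams = field(default_factory=AlignmentParams)
    derep_threshold: float = 80.0
    k_nearest: int = 3
    rooting_mode: str = "midpoint"
    outgroup_label: str | None = None
    seed: int = 0


@dataclass
class MineResult:
    """Mining outcome plus the per-stage audit counts."""

    labels: dict[str, ArchitectureLabel]
    candidates: list[PttsCandidate]  # architecture-pass, pre-filter
    filtered: list[PttsCandidate]  # length-filter pass
    representatives: list[ProteinRecord]
    cluster_map: dict[str, str]
    stage_counts: dict[str, int]


def run_mine(
    records: list[ProteinRecord],
    config: PipelineConfig | None = None,
    external_domains: dict | None = None,
) -> MineResult:
    """Run the candidate-selection stages over a proteome.

    With ``external_domains`` (record id -> list of DomainCall, e.g. from
    a profile-HMM search) the motif-anchored domain caller is bypassed
    for the records listed there.
    """
    if config is None:
        config = PipelineConfig()
    labels: dict[str, ArchitectureLabel] = {}
    candidates: list[PttsCandidate] = []
    for rec in records:
        hits = scan_all(rec)
        if external_domains is not None and rec.id in external_domains:
            calls = external_domains[rec.id]
        else:
            calls = arch.call_domains(rec, hits, config.domain_params)
        label = arch.classify_architecture(rec, calls, hits["CLASSII_DXDD"])
        labels[rec.id] = label
        if label is ArchitectureLabel.PTTS:
            candidates.append(arch.make_candidate(rec, calls))
        logger.debug("record %s: label=%s", rec.id, label.value)

    filtered = arch.filter_candidates(list(candidates), config.length_window)
    if len(filtered) >= 1:
        reps, cluster_map = dereplicate(
            [c.record for c in filtered], config.derep_threshold,
            config.alignment_params)
    else:
        reps, cluster_map = [], {}
    for cand in filtered:
        cand.cluster_id = cluster_map.get(cand.record.id)

    counts = {
        "input": len(records),
        "architecture_pass": len(candidates),
        "filter_pass": len(filtered),
        "representatives": len(reps),
    }
    logger.info("mine: %s", counts)
    return MineResult(labels=labels, candidates=candidates, filtered=filtered,
                      representatives=reps, cluster_map=cluster_map,
                      stage_counts=counts)


def run_classify(
    queries: list[ProteinRecord],
    references: ReferenceSet,
    config: PipelineConfig | None = None,
    build_tree: bool = False,
) -> tuple[list[CladeAssignment], dendropy.Tree | None]:
    """Assign every query a subfamily/clade/cyclization prediction.

    Optionally also builds the joint neighbor-joining tree over queries
    plus references (rooted per config) for inspection.
    """
    if config is None:
        config = PipelineConfig()
    if not queries:
        return [], None
    assignments = [
        trees.assign_subfamily(q, references, k=config.k_nearest,
                               params=config.alignment_params)
        for q in queries
    ]
    joint_tree = None
    if build_tree:
        from .align import pairwise_matrix
        pool = list(queries) + [r for r, _ in references.references]
        if references.outgroup is not None:
            pool.append(references.outgroup)
        dm = pairwise_matrix(pool, config.alignment_params)
        joint_tree = trees.neighbor_joining(dm)
        if config.rooting_mode == "outgroup" and references.outgroup is not None:
            joint_tree = trees.root_tree(joint_tree, "outgroup",
                                         references.outgroup.id)
        else:
            joint_tree = trees.root_tree(joint_tree, "midpoint")
    logger.info("classify: %d queries assigned", len(assignments))
    return assignments, joint_tree


@dataclass
class EvolutionResult:
    lineage_table: pd.DataFrame
    presence: evolution.PresenceMatrix
    dollo: evolution.DolloResult | None
    scenarios: pd.DataFrame | None


def run_evolution(
    gene_table: pd.DataFrame,
    taxonomy: TaxonomyTable,
    species_tree: dendropy.Tree | None = None,
    rank: int = 0,
    alt_gain_nodes: list | None = None,
) -> EvolutionResult:
    """Lineage tallies plus (when a species tree is given) Dollo
    reconstruction and optional alternative-gain scenario comparison."""
    table = evolution.lineage_counts(gene_table, taxonomy, rank=rank)
    presence = evolution.PresenceMatrix.from_gene_table(gene_table, taxonomy)
    dollo = None
    scenarios = None
    if species_tree is not None:
        if any(presence.presence.values()):
            dollo = evolution.dollo_reconstruct(species_tree, presence.presence)
            if alt_gain_nodes:
                scenarios = evolution.compare_scenarios(
                    species_tree, presence.presence, alt_gain_nodes)
        else:
            logger.info("evolution: no species carries the gene; "
                        "skipping reconstruction")
    logger.info("evolution: %d lineages tallied", len(table))
    return EvolutionResult(lineage_table=table, presence=presence,
                           dollo=dollo, scenarios=scenarios)


def write_mine_report(result: MineResult, records: list[ProteinRecord],
                      outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "candidates.tsv"
    rows = arch.candidate_report_rows(records, result.labels, result.filtered)
    write_tsv(rows, ["record_id", "label", "ts_start", "ts_end", "pt_start",
                     "pt_end", "length", "flags"], path)
    write_tsv(sorted(result.stage_counts.items()), ["stage", "count"],
              outdir / "stage_counts.tsv")
    return path


def write_classify_report(assignments: list[CladeAssignment],
                          outdir: str | Path,
                          joint_tree: dendropy.Tree | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "assignments.tsv"
    write_tsv(trees.assignment_report_rows(assignments),
              ["query_id", "subfamily", "clade", "cyclization_type",
               "cyclization_mode", "support", "tie_flag"], path)
    if joint_tree is not None:
        from .io import write_newick
        (outdir / "classification_tree.nwk").write_text(
            write_newick(joint_tree) + "\n")
    return path
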