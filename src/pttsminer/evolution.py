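"""Gene-family presence/absence across lineages and Dollo gain/loss inference.

The distribution of a gene family over a species tree is explained under
Dollo parsimony: the gene is gained exactly once (at the most recent
common ancestor of all species carrying it) and may subsequently be lost
any number of times; the inferred losses are the minimal set of branches
explaining every absence.  A scenario comparator makes the alternative
explanation computable as well: for any other candidate gain placement it
counts the losses required plus the present species outside the gain
subtree, which must then be explained by transfer (e.g. horizontal gene
transfer) rather than descent.

Species tree nodes are identified by the frozenset of leaf labels below
them, which is stable across traversal orders and serializations.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from .io import TaxonomyTable

NodeId = frozenset


def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def node_id(node: dendropy.Node) -> NodeId:
    """Canonical node identifier: frozenset of descendant leaf labels."""
    return frozenset(_leaf_label(l) for l in node.leaf_iter())


@dataclass(frozen=True)
class PresenceMatrix:
    """Per-species gene counts and presence flags, with lineage annotation."""

    species: tuple[str, ...]
    counts: tuple[int, ...]
    taxonomy: TaxonomyTable | None = None

    def __post_init__(self) -> None:
        if len(self.species) != len(self.counts):
            raise ValueError("species and counts must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("gene counts must be non-negative")

    @property
    def presence(self) -> dict[str, bool]:
        return {s: c >= 1 for s, c in zip(self.species, self.counts)}

    @classmethod
    def from_gene_table(
        cls, gene_table: pd.DataFrame, taxonomy: TaxonomyTable
    ) -> "PresenceMatrix":
        """Tally genes per species; species absent from the gene table get
        count 0.  Gene-table rows naming unknown species are an error."""
        counts = {s: 0 for s in taxonomy.species}
        for sp in gene_table["species_id"]:
            if sp not in counts:
                raise KeyError(f"gene table names unknown species {sp!r}")
            counts[sp] += 1
        species = tuple(taxonomy.species)
        return cls(species=species,
                   counts=tuple(counts[s] for s in species),
                   taxonomy=taxonomy)


def lineage_counts(
    gene_table: pd.DataFrame,
    taxonomy: TaxonomyTable,
    rank: int = 0,
) -> pd.DataFrame:
    """Tally genes and species per lineage at a taxonomy rank.

    ``rank`` indexes the lineage path (0 = highest rank, e.g. phylum).
    Lineages with zero genes are still listed.  Columns: lineage,
    n_genes, n_species_with_gene, n_species_total.
    """
    lineage_of: dict[str, str] = {}
    for species, path in taxonomy.rows:
        lineage_of[species] = path[rank] if rank < len(path) else path[-1]

    gene_species = list(gene_table["species_id"])
    for sp in gene_species:
        if sp not in lineage_of:
            raise KeyError(f"gene table names unknown species {sp!r}")

    lineages = sorted(set(lineage_of.values()))
    per_species = {s: 0 for s in lineage_of}
    for sp in gene_species:
        per_species[sp] += 1

    rows = []
    for lin in lineages:
        members = [s for s in lineage_of if lineage_of[s] == lin]
        n_genes = sum(per_species[s] for s in members)
        n_with = sum(1 for s in members if per_species[s] >= 1)
        rows.append((lin, n_genes, n_with, len(members)))
    return pd.DataFrame(
        rows, columns=["lineage", "n_genes", "n_species_with_gene",
                       "n_species_total"]
    )


@dataclass(frozen=True)
class DolloResult:
    """Single-gain reconstruction: the gain node, the minimal loss-branch
    set (each branch identified by the node below it), and the implied
    presence state at every node of the tree."""

    gain: NodeId
    losses: frozenset  # of NodeId
    states: dict  # NodeId -> bool

    @property
    def n_losses(self) -> int:
        return len(self.losses)


def _presence_for_leaves(tree: dendropy.Tree, presence: dict) -> dict:
    # reconstruction is defined on rooted trees; Newick input is treated
    # as rooted at its outermost grouping
    tree.is_rooted = True
    leaves = {_leaf_label(l) for l in tree.leaf_node_iter()}
    missing = leaves - set(presence)
    if missing:
        raise ValueError(f"presence undefined for leaves: {sorted(missing)}")
    return {lab: bool(presence[lab]) for lab in leaves}


def dollo_reconstruct(species_tree: dendropy.Tree, presence: dict) -> DolloResult:
    """Infer the single gain and the minimal losses explaining a
    presence/absence pattern.

    The gain is placed at the MRCA of all present leaves.  Below it, each
    maximal subtree containing no present leaf contributes exactly one
    loss on its root branch; this loss set is minimal for the single-gain
    constraint, because distinct maximal absent subtrees cannot share a
    loss and each must contain at least one.  Deterministic and invariant
    to leaf order.
    """
    presence = _presence_for_leaves(species_tree, presence)
    present_leaves = [lab for lab, p in presence.items() if p]
    if not present_leaves:
        raise ValueError("at least one species must carry the gene")

    taxa = [t for t in species_tree.taxon_namespace if t.label in present_leaves]
    if len(present_leaves) == 1:
        gain_node = species_tree.find_node_with_taxon_label(present_leaves[0])
    else:
        gain_node = species_tree.mrca(taxa=taxa)

    # has_present per node, postorder, restricted to the gain subtree
    has_present: dict[int, bool] = {}
    for node in gain_node.postorder_iter():
        if node.is_leaf():
            has_present[id(node)] = presence[_leaf_label(node)]
        else:
            has_present[id(node)] = any(
                has_present[id(c)] for c in node.child_nodes())

    losses = set()
    states: dict[NodeId, bool] = {}
    for node in species_tree.preorder_node_iter():
        states[node_id(node)] = False
    for node in gain_node.preorder_iter():
        if node is gain_node:
            states[node_id(node)] = True
            continue
        parent_present = states[node_id(node.parent_node)]
        if not parent_present:
            states[node_id(node)] = False
            continue
        if has_present[id(node)]:
            states[node_id(node)] = True
        else:
            losses.add(node_id(node))
            states[node_id(node)] = False
    return DolloResult(gain=node_id(gain_node), losses=frozenset(losses),
                       states=states)


def _resolve_node(tree: dendropy.Tree, node_ref) -> dendropy.Node:
    """Find a node by internal-node label, leaf label, or leaf-label set."""
    if isinstance(node_ref, dendropy.Node):
        return node_ref
    if isinstance(node_ref, str):
        for node in tree.preorder_node_iter():
            if node.label == node_ref or (node.taxon is not None
                                          and node.taxon.label == node_ref):
                return node
        raise ValueError(f"no node labeled {node_ref!r}")
    want = frozenset(node_ref)
    for node in tree.preorder_node_iter():
        if node_id(node) == want:
            return node
    raise ValueError(f"no node with leaf set {sorted(want)}")


def compare_scenarios(
    species_tree: dendropy.Tree,
    presence: dict,
    alt_gain_nodes: list,
) -> pd.DataFrame:
    """Loss/transfer accounting for alternative gain placements.

    For each candidate gain node: present leaves outside its subtree are
    transfer events (acquisition not explained by descent); within the
    subtree, losses are counted as in :func:`dollo_reconstruct` using the
    in-subtree presences only.  Columns: gain, n_losses, n_transfers.
    """
    presence = _presence_for_leaves(species_tree, presence)
    rows = []
    for node_ref in alt_gain_nodes:
        gain_node = _resolve_node(species_tree, node_ref)
        inside = {_leaf_label(l) for l in gain_node.leaf_iter()}
        transfers = sorted(
            lab for lab, p in presence.items() if p and lab not in inside)
        inside_presence = {lab: presence[lab] for lab in inside}
        if any(inside_presence.values()):
            # count losses for a gain fixed at this node (not at the MRCA)
            has_present: dict[int, bool] = {}
            for node in gain_node.postorder_iter():
                if node.is_leaf():
                    has_present[id(node)] = inside_presence[_leaf_label(node)]
                else:
                    has_present[id(node)] = any(
                        has_present[id(c)] for c in node.child_nodes())
            n_losses = 0
            for node in gain_node.preorder_iter():
                if node is gain_node:
                    continue
                parent_has = has_present[id(node.parent_node)]
                if parent_has and not has_present[id(node)]:
                    n_losses += 1
        else:
            n_losses = 0
        label = (node_ref if isinstance(node_ref, str)
                 else ",".join(sorted(node_id(gain_node))))
        rows.append((label, n_losses, len(transfers)))
    return pd.DataFrame(rows, columns=["gain", "n_losses", "n_transfers"])


def annotate_states(tree: dendropy.Tree, result: DolloResult) -> dendropy.Tree:
    """Clone the tree with internal-node labels showing inferred
    presence (1) / absence (0), for annotated Newick export."""
    annotated = tree.clone(depth=1)
    for node in annotated.preorder_node_iter():
        state = "1" if result.states.get(node_id(node), False) else "0"
        if node.is_leaf():
            continue
        node.label = f"{node.label}|{state}" if node.label else state
    return annotated
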