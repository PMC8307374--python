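"""Distance-based phylogeny and phylogeny-anchored functional classification.

Trees are built by neighbor joining from a pairwise distance matrix and
rooted either on a designated outgroup or at the midpoint of the longest
leaf-to-leaf path.  Functional classification exploits the bifurcation of
the PTTS family: subfamilies A, E and F form Clade I, whose members
catalyze type A (C1-IV-V) cyclization, and subfamilies B, C and D form
Clade II, whose members catalyze type B (C1-III-IV) cyclization.  A query
is assigned a subfamily by its nearest labeled references (k-nearest
majority by default, or by smallest enclosing clade when an externally
built tree is supplied), and its clade and cyclization type follow
deterministically from the subfamily.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np

from .align import AlignmentParams, DistanceMatrix, global_align_identity
from .io import ProteinRecord

logger = logging.getLogger(__name__)

SUBFAMILIES = ("A", "B", "C", "D", "E", "F")

#: Subfamily -> clade: A/E/F form Clade I, B/C/D form Clade II.
SUBFAMILY_CLADE = {"A": "I", "E": "I", "F": "I", "B": "II", "C": "II", "D": "II"}

#: Clade -> cyclization mode: Clade I enzymes use type A (C1-IV-V)
#: initial cyclization, Clade II enzymes type B (C1-III-IV).
CLADE_CYCLIZATION_MODE = {"I": "C1-IV-V", "II": "C1-III-IV"}
CLADE_TYPE_LETTER = {"I": "A", "II": "B"}


def clade_of(subfamily: str) -> str:
    """Clade (I or II) of a subfamily; total on A-F, error otherwise."""
    try:
        return SUBFAMILY_CLADE[subfamily]
    except KeyError:
        raise ValueError(f"unknown subfamily {subfamily!r}") from None


def cyclization_type_of(clade: str) -> str:
    """Cyclization mode of a clade: I -> C1-IV-V (type A), II -> C1-III-IV
    (type B)."""
    try:
        return CLADE_CYCLIZATION_MODE[clade]
    except KeyError:
        raise ValueError(f"unknown clade {clade!r}") from None


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining agglomeration over a distance matrix.

    At each step the pair minimizing the Q criterion is joined (ties are
    broken by matrix position, so the result is deterministic).  Negative
    intermediate branch lengths are clamped to 0 with the deficit moved
    to the sister branch so the joined pair's path length is preserved;
    each clamp is logged.  The returned tree is unrooted with a
    trifurcating seed node.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace([str(lab) for lab in dm.labels])
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=tns.get_taxon(str(lab)))
        nodes.append(node)
    D = dm.values.astype(float).copy()
    active = list(range(n))

    def clamp_pair(li: float, lj: float, d: float) -> tuple[float, float]:
        if li < 0:
            logger.debug("clamping negative branch length %.6g to 0", li)
            return 0.0, d
        if lj < 0:
            logger.debug("clamping negative branch length %.6g to 0", lj)
            return d, 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic argmin: first (i, j) in row-major order
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = d_ij - li
        li, lj = clamp_pair(li, lj, d_ij)
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            parent.add_child(child)
            child.edge.length = length
        # distances from the new node to every other active node
        new_row = 0.5 * (D[i, :] + D[j, :] - d_ij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # final trifurcation
    i, j, k = active
    d_ij, d_ik, d_jk = D[i, j], D[i, k], D[j, k]
    li = 0.5 * (d_ij + d_ik - d_jk)
    lj = 0.5 * (d_ij + d_jk - d_ik)
    lk = 0.5 * (d_ik + d_jk - d_ij)
    center = dendropy.Node()
    for child, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        if length < 0:
            logger.debug("clamping negative terminal branch length %.6g to 0", length)
            length = 0.0
        center.add_child(child)
        child.edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def root_tree(
    tree: dendropy.Tree,
    mode: str = "midpoint",
    outgroup_label: str | None = None,
) -> dendropy.Tree:
    """Root a tree on the outgroup edge or at the midpoint.

    Outgroup mode places the root halfway along the edge leading to the
    outgroup leaf; midpoint mode uses the midpoint of the longest
    leaf-to-leaf path.  The input tree is not modified.
    """
    if mode not in ("outgroup", "midpoint"):
        raise ValueError(f"unknown rooting mode {mode!r}")
    rooted = tree.clone(depth=1)
    if mode == "outgroup":
        if outgroup_label is None:
            raise ValueError("outgroup mode requires outgroup_label")
        node = rooted.find_node_with_taxon_label(outgroup_label)
        if node is None:
            raise ValueError(f"outgroup {outgroup_label!r} not found in tree")
        edge = node.edge
        if edge.length is None:
            edge.length = 0.0
        half = edge.length / 2.0
        rooted.reroot_at_edge(edge, length1=half, length2=half,
                              update_bipartitions=False)
    else:
        _reroot_at_midpoint(rooted)
    rooted.is_rooted = True
    return rooted


def _reroot_at_midpoint(tree: dendropy.Tree) -> None:
    """Root at the midpoint of the longest leaf-to-leaf path (in place).

    Implemented explicitly (rather than via dendropy's helper) so the
    edge case where the midpoint falls exactly on an internal node is
    handled by rooting at that node instead of splitting an edge.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    best = None
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            d = pdm.distance(taxa[i], taxa[j])
            if best is None or d > best[0] + 1e-12:
                best = (d, taxa[i], taxa[j])
    total, ta, tb = best
    na = tree.find_node_with_taxon_label(ta.label)
    nb = tree.find_node_with_taxon_label(tb.label)
    ancestors_a = []
    node = na
    while node is not None:
        ancestors_a.append(node)
        node = node.parent_node
    ids_a = {id(n) for n in ancestors_a}
    node = nb
    while id(node) not in ids_a:
        node = node.parent_node
    mrca = node
    # path edges from na to nb, tagged with the end reached first
    path: list[tuple[dendropy.Node, str]] = []
    node = na
    while node is not mrca:
        path.append((node, "child_first"))
        node = node.parent_node
    down = []
    node = nb
    while node is not mrca:
        down.append((node, "parent_first"))
        node = node.parent_node
    path.extend(reversed(down))

    half = total / 2.0
    acc = 0.0
    for node, direction in path:
        elen = node.edge.length or 0.0
        if acc + elen >= half - 1e-12:
            offset = half - acc  # distance walked into this edge
            from_child = offset if direction == "child_first" else elen - offset
            if abs(from_child) < 1e-12:
                tree.reroot_at_node(node, update_bipartitions=False)
            elif abs(from_child - elen) < 1e-12 and node.parent_node is not None:
                tree.reroot_at_node(node.parent_node, update_bipartitions=False)
            else:
                tree.reroot_at_edge(node.edge, length1=elen - from_child,
                                    length2=from_child,
                                    update_bipartitions=False)
            return
        acc += elen
    raise RuntimeError("midpoint not found on the longest path")


@dataclass(frozen=True)
class ReferenceSet:
    """Characterized PTTSs with known subfamily labels (A-F), plus an
    optional outgroup sequence used only for tree rooting."""

    references: tuple[tuple[ProteinRecord, str], ...]
    outgroup: ProteinRecord | None = None

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("reference set must not be empty")
        for _, subfam in self.references:
            if subfam not in SUBFAMILIES:
                raise ValueError(f"invalid subfamily label {subfam!r}")

    @property
    def subfamilies(self) -> set[str]:
        return {s for _, s in self.references}

    def label_of(self, record_id: str) -> str:
        for rec, subfam in self.references:
            if rec.id == record_id:
                return subfam
        raise KeyError(record_id)


@dataclass(frozen=True)
class CladeAssignment:
    """A query's inferred subfamily, clade, and predicted cyclization.

    ``support`` is the fraction of the k nearest references agreeing with
    the chosen subfamily; ``tie_flag`` marks decisions that rested on a
    deterministic tie-break.
    """

    query_id: str
    subfamily: str
    clade: str
    cyclization_type: str  # "A" or "B"
    cyclization_mode: str  # "C1-IV-V" or "C1-III-IV"
    support: float
    tie_flag: bool = False

    def __post_init__(self) -> None:
        if SUBFAMILY_CLADE[self.subfamily] != self.clade:
            raise ValueError("clade inconsistent with subfamily")
        if CLADE_TYPE_LETTER[self.clade] != self.cyclization_type:
            raise ValueError("cyclization type inconsistent with clade")
        if CLADE_CYCLIZATION_MODE[self.clade] != self.cyclization_mode:
            raise ValueError("cyclization mode inconsistent with clade")


def _assignment(query_id: str, subfamily: str, support: float,
                tie_flag: bool) -> CladeAssignment:
    clade = clade_of(subfamily)
    return CladeAssignment(
        query_id=query_id,
        subfamily=subfamily,
        clade=clade,
        cyclization_type=CLADE_TYPE_LETTER[clade],
        cyclization_mode=CLADE_CYCLIZATION_MODE[clade],
        support=support,
        tie_flag=tie_flag,
    )


def assign_subfamily(
    query: ProteinRecord,
    references: ReferenceSet,
    k: int = 3,
    params: AlignmentParams | None = None,
) -> CladeAssignment:
    """k-nearest-reference subfamily assignment.

    Distances (1 - identity/100) are computed from the query to every
    reference; the majority subfamily among the k nearest wins, with a
    majority tie resolved by the single nearest reference and exact
    distance ties resolved by ascending reference id.  Ties are flagged.
    """
    if len(references.subfamilies) < 2:
        raise ValueError("references must span at least 2 subfamilies")
    scored = []
    for rec, subfam in references.references:
        d = 1.0 - global_align_identity(query, rec, params) / 100.0
        scored.append((d, rec.id, subfam))
    scored.sort()
    # an exact sequence match overrides voting: the query IS that reference
    if scored[0][0] < 1e-12:
        zero_labels = sorted({s for d, _, s in scored if d < 1e-12})
        return _assignment(query.id, scored[0][2], 1.0,
                           tie_flag=len(zero_labels) > 1)
    top = scored[: min(k, len(scored))]
    votes = Counter(s for _, _, s in top)
    best_count = max(votes.values())
    winners = sorted(s for s, c in votes.items() if c == best_count)
    majority_tie = len(winners) > 1
    if majority_tie:
        subfamily = top[0][2]  # single nearest decides
    else:
        subfamily = winners[0]
    # distance tie at the very top between different subfamilies
    d0 = scored[0][0]
    top_labels = {s for d, _, s in scored if abs(d - d0) < 1e-12}
    distance_tie = len(top_labels) > 1
    support = votes[subfamily] / len(top)
    if majority_tie or distance_tie:
        support = 1.0 if k == 1 or len(top) == 1 else support
    return _assignment(query.id, subfamily, support, majority_tie or distance_tie)


def assign_subfamily_by_tree(
    tree: dendropy.Tree,
    query_label: str,
    reference_labels: dict[str, str],
) -> CladeAssignment:
    """Assign a subfamily from an externally built (e.g. ML) tree.

    Walks rootward from the query leaf to the smallest clade containing
    at least one labeled reference; the majority subfamily among the
    references in that clade wins (ties by alphabetical subfamily,
    flagged).  ``reference_labels`` maps leaf label -> subfamily.
    """
    node = tree.find_node_with_taxon_label(query_label)
    if node is None:
        raise ValueError(f"query {query_label!r} not found in tree")
    current = node.parent_node
    while current is not None:
        labels = []
        for leaf in current.leaf_iter():
            lab = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if lab in reference_labels:
                labels.append(reference_labels[lab])
        if labels:
            votes = Counter(labels)
            best = max(votes.values())
            winners = sorted(s for s, c in votes.items() if c == best)
            subfamily = winners[0]
            return _assignment(
                query_label, subfamily, votes[subfamily] / len(labels),
                tie_flag=len(winners) > 1,
            )
        current = current.parent_node
    raise ValueError("tree contains no labeled reference leaves")


def assignment_report_rows(assignments: list[CladeAssignment]) -> list[tuple]:
    """Rows (query_id, subfamily, clade, cyclization_type,
    cyclization_mode, support, tie_flag) for the assignment TSV."""
    return [
        (a.query_id, a.subfamily, a.clade, a.cyclization_type,
         a.cyclization_mode, f"{a.support:.3f}", int(a.tie_flag))
        for a in assignments
    ]
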