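"""Synthetic fungal proteomes with known ground truth.

Every pipeline stage is exercised against generated data in which the
answer is planted: chimeric PTTS sequences carry a class I TS motif pair
(DDXXD/E then (N/H)DXX(S/T)XXXE) upstream of two trans-PT DDXXD/N motifs
at recorded positions inside a ~700 aa sequence; decoys realize the
negative architectures (TS-only, PT-only, class II DXDD enzymes,
wrong-order chimeras, length outliers, motif-free random proteins);
subfamily radiations mutate six independent ancestors at a configurable
per-site rate with motif residues frozen; and species scenarios plant a
single gene gain and a set of loss branches on a random species tree.

Random filler is drawn uniformly from the 20 standard residues and
rejection-checked so that no accidental motif arises: a generated
sequence is accepted only if its motif-hit positions coincide exactly
with those of a skeleton in which all filler is replaced by glycine
(glycine can never complete a motif anchor, so the skeleton's hits are
exactly the planted ones).  Generation is fully deterministic given
(seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import dendropy
import numpy as np

from .io import AMINO_ACIDS, ProteinRecord, parse_newick
from .motifs import builtin_patterns, scan

DECOY_KINDS = ("TS_only", "PT_only", "classII_TS", "wrong_order",
               "length_outlier", "random")

#: Fixed subfamily guide tree: A/E/F form Clade I, B/C/D Clade II.
DEFAULT_SUBFAMILY_TREE = "(((A,E),F),((B,C),D));"

_EXPECTED_LABEL = {
    "TS_only": "TS_only",
    "PT_only": "PT_only",
    "classII_TS": "classII_TS",
    "wrong_order": "wrong_order_chimera",
    "length_outlier": "PTTS",
    "random": "none",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all generators.

    PTTS lengths are uniform over [650, 750] aa (the family's typical
    ~700 aa size); ``motif_offsets`` may pin the four anchor starts
    (DDXXD/E, triad, first and second DDXXD/N) to fixed positions, e.g.
    (95, 230, 487, 614) for a template mimicking a characterized
    sesterterpene synthase; ``mutation_rate`` is the per-site
    substitution probability used for subfamily radiations.
    """

    seed: int
    n_ptts: int = 40
    n_decoys_per_kind: int = 10
    ptts_length_range: tuple[int, int] = (650, 750)
    motif_offsets: tuple[int, int, int, int] | None = None
    mutation_rate: float = 0.05
    n_descendants_per_subfamily: int = 20
    subfamily_tree: str = DEFAULT_SUBFAMILY_TREE

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation rate must be in [0, 1)")
        lo, hi = self.ptts_length_range
        if lo > hi or lo < 60:
            raise ValueError("invalid PTTS length range")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one generated record."""

    record_id: str
    label: str  # expected architecture label
    ts_dde_start: int | None = None
    ts_triad_start: int | None = None
    pt_first_start: int | None = None
    pt_second_start: int | None = None
    subfamily: str | None = None
    cluster_seed: str | None = None
    species: str | None = None

    @property
    def motif_intervals(self) -> list[tuple[int, int]]:
        out = []
        for start, width in ((self.ts_dde_start, 5), (self.ts_triad_start, 9),
                             (self.pt_first_start, 5), (self.pt_second_start, 5)):
            if start is not None:
                out.append((start, start + width - 1))
        return out


def _rand_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n)) if n else ""


def _dde_instance(rng) -> str:
    return "DD" + _rand_residues(rng, 2) + rng.choice(["D", "E"])


def _triad_instance(rng) -> str:
    return (rng.choice(["N", "H"]) + "D" + _rand_residues(rng, 2)
            + rng.choice(["S", "T"]) + _rand_residues(rng, 3) + "E")


def _pt_instance(rng) -> str:
    return "DD" + _rand_residues(rng, 2) + rng.choice(["D", "N"])


def _dxdd_instance(rng) -> str:
    return "D" + _rand_residues(rng, 1) + "DD"


def _hit_positions(seq: str) -> set[tuple[str, int]]:
    out = set()
    for pat in builtin_patterns():
        for h in scan(seq, pat):
            out.add((pat.name, h.start))
    return out


def _assemble(length: int, planted: list[tuple[int, str]],
              rng: np.random.Generator, max_tries: int = 1000) -> str:
    """Place planted instances at their 1-based starts inside random filler,
    rejecting fillers that create motif hits beyond the skeleton's."""
    planted = sorted(planted)
    for prev, nxt in zip(planted, planted[1:]):
        if prev[0] + len(prev[1]) > nxt[0]:
            raise ValueError("planted motifs overlap; infeasible offsets")
    if planted and planted[-1][0] + len(planted[-1][1]) - 1 > length:
        raise ValueError("planted motifs do not fit in requested length")

    skeleton = ["G"] * length
    for start, ins in planted:
        skeleton[start - 1 : start - 1 + len(ins)] = list(ins)
    expected = _hit_positions("".join(skeleton))

    filler_idx = [i for i in range(length)]
    for start, ins in planted:
        for i in range(start - 1, start - 1 + len(ins)):
            filler_idx.remove(i)
    for _ in range(max_tries):
        seq = skeleton[:]
        fill = rng.choice(list(AMINO_ACIDS), size=len(filler_idx))
        for i, ch in zip(filler_idx, fill):
            seq[i] = ch
        s = "".join(seq)
        if _hit_positions(s) == expected:
            return s
    raise RuntimeError("could not place motifs without accidental matches")


def _sample_positions(rng, compact: bool = False) -> tuple[int, int, int, int]:
    """Random anchor starts (dde, triad, pt1, pt2) honoring domain geometry."""
    if compact:
        dde = int(rng.integers(10, 31))
        triad = dde + int(rng.integers(50, 81))
        pt1 = triad + 9 + int(rng.integers(50, 81))
        pt2 = pt1 + int(rng.integers(25, 41))
    else:
        dde = int(rng.integers(30, 101))
        triad = dde + int(rng.integers(80, 151))
        pt1 = triad + 9 + int(rng.integers(80, 181))
        pt2 = pt1 + int(rng.integers(40, 101))
    return dde, triad, pt1, pt2


def generate_ptts(
    config: SimConfig,
    rng: np.random.Generator,
    rec_id: str = "ptts1",
    subfamily: str | None = None,
) -> tuple[ProteinRecord, TruthRow]:
    """One chimeric PTTS with recorded motif anchor positions."""
    lo, hi = config.ptts_length_range
    if config.motif_offsets is not None:
        dde, triad, pt1, pt2 = config.motif_offsets
        length = int(rng.integers(lo, hi + 1))
        if pt2 + 4 > length or not (dde < triad and triad + 9 <= pt1 < pt2):
            raise ValueError("motif offsets infeasible for configured length")
    else:
        dde, triad, pt1, pt2 = _sample_positions(rng)
        length = int(rng.integers(max(lo, pt2 + 24), hi + 1))
    planted = [
        (dde, _dde_instance(rng)),
        (triad, _triad_instance(rng)),
        (pt1, _pt_instance(rng)),
        (pt2, _pt_instance(rng)),
    ]
    seq = _assemble(length, planted, rng)
    record = ProteinRecord(id=rec_id, sequence=seq)
    truth = TruthRow(record_id=rec_id, label="PTTS",
                     ts_dde_start=dde, ts_triad_start=triad,
                     pt_first_start=pt1, pt_second_start=pt2,
                     subfamily=subfamily, cluster_seed=rec_id)
    return record, truth


def generate_decoy(
    kind: str,
    config: SimConfig,
    rng: np.random.Generator,
    rec_id: str = "decoy1",
) -> tuple[ProteinRecord, TruthRow]:
    """One negative-control record of the requested kind."""
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}")
    lo, hi = config.ptts_length_range
    positions: dict[str, int | None] = dict(
        ts_dde_start=None, ts_triad_start=None,
        pt_first_start=None, pt_second_start=None)

    if kind == "length_outlier":
        # a valid PTTS whose length falls outside the candidate window
        if rng.random() < 0.5:
            dde, triad, pt1, pt2 = _sample_positions(rng, compact=True)
            length = int(rng.integers(max(300, pt2 + 14), 460))
        else:
            dde, triad, pt1, pt2 = _sample_positions(rng)
            length = int(rng.integers(1150, 1400))
        planted = [(dde, _dde_instance(rng)), (triad, _triad_instance(rng)),
                   (pt1, _pt_instance(rng)), (pt2, _pt_instance(rng))]
        positions.update(ts_dde_start=dde, ts_triad_start=triad,
                         pt_first_start=pt1, pt_second_start=pt2)
    elif kind == "wrong_order":
        # PT pair first, then the TS pair; the blocks are separated beyond
        # the domain span so a PT motif that happens to end in D cannot
        # pair with the downstream TS triad and flip the interpretation
        pt1_w = int(rng.integers(20, 41))
        pt2_w = pt1_w + int(rng.integers(40, 61))
        dde_w = pt2_w + 5 + int(rng.integers(330, 361))
        triad_w = dde_w + int(rng.integers(80, 121))
        length = int(rng.integers(max(lo, triad_w + 29), hi + 31))
        planted = [(pt1_w, _pt_instance(rng)), (pt2_w, _pt_instance(rng)),
                   (dde_w, _dde_instance(rng)), (triad_w, _triad_instance(rng))]
        positions.update(ts_dde_start=dde_w, ts_triad_start=triad_w,
                         pt_first_start=pt1_w, pt_second_start=pt2_w)
    elif kind == "TS_only":
        dde, triad, _, _ = _sample_positions(rng)
        length = int(rng.integers(max(lo, triad + 29), hi + 1))
        planted = [(dde, _dde_instance(rng)), (triad, _triad_instance(rng))]
        positions.update(ts_dde_start=dde, ts_triad_start=triad)
    elif kind == "PT_only":
        pt1 = int(rng.integers(30, 301))
        pt2 = pt1 + int(rng.integers(40, 101))
        length = int(rng.integers(max(lo, pt2 + 24), hi + 1))
        planted = [(pt1, _pt_instance(rng)), (pt2, _pt_instance(rng))]
        positions.update(pt_first_start=pt1, pt_second_start=pt2)
    elif kind == "classII_TS":
        pos = int(rng.integers(50, 401))
        length = int(rng.integers(lo, hi + 1))
        planted = [(pos, _dxdd_instance(rng))]
    else:  # random: no planted motifs at all
        length = int(rng.integers(lo, hi + 1))
        planted = []

    seq = _assemble(length, planted, rng)
    record = ProteinRecord(id=rec_id, sequence=seq)
    truth = TruthRow(record_id=rec_id, label=_EXPECTED_LABEL[kind], **positions)
    return record, truth


def generate_proteome(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ProteinRecord], list[TruthRow]]:
    """A mixed cohort: ``n_ptts`` planted PTTSs plus ``n_decoys_per_kind``
    decoys of every kind, in deterministic order."""
    if rng is None:
        rng = config.rng()
    records, truths = [], []
    for i in range(config.n_ptts):
        rec, tr = generate_ptts(config, rng, rec_id=f"ptts{i + 1:03d}")
        records.append(rec)
        truths.append(tr)
    for kind in DECOY_KINDS:
        for i in range(config.n_decoys_per_kind):
            rec, tr = generate_decoy(kind, config, rng,
                                     rec_id=f"{kind}{i + 1:03d}")
            records.append(rec)
            truths.append(tr)
    return records, truths


def _mutate_preserving_motifs(
    seq: str,
    frozen: list[tuple[int, int]],
    rate: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> str:
    """Per-site substitution at ``rate`` outside the frozen (1-based,
    closed) intervals, rejecting mutants that gain or lose motif hits."""
    frozen_idx = set()
    for start, end in frozen:
        frozen_idx.update(range(start - 1, end))
    baseline = _hit_positions(seq)
    alphabet = list(AMINO_ACIDS)
    for _ in range(max_tries):
        chars = list(seq)
        draws = rng.random(len(chars))
        for i, p in enumerate(draws):
            if i in frozen_idx or p >= rate:
                continue
            choices = [a for a in alphabet if a != chars[i]]
            chars[i] = choices[int(rng.integers(0, len(choices)))]
        mutant = "".join(chars)
        if _hit_positions(mutant) == baseline:
            return mutant
        if rate == 0.0:
            return mutant
    raise RuntimeError("could not mutate without disturbing motif content")


def radiate_subfamilies(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ProteinRecord], list[TruthRow]]:
    """Six-subfamily radiation with known labels.

    One random ancestor PTTS per subfamily (A-F); each descendant is an
    independently mutated copy of its ancestor at ``mutation_rate`` per
    site with all planted motif residues frozen, so every descendant
    retains the chimeric architecture and classification tests isolate
    phylogenetic signal.
    """
    if rng is None:
        rng = config.rng()
    subfams = sorted(set(l for l in parse_newick(config.subfamily_tree).taxon_namespace
                         .labels()))
    records, truths = [], []
    for subfam in subfams:
        anc, anc_truth = generate_ptts(
            config, rng, rec_id=f"{subfam}_anc", subfamily=subfam)
        records.append(anc)
        truths.append(anc_truth)
        for i in range(config.n_descendants_per_subfamily):
            mut = _mutate_preserving_motifs(
                anc.sequence, anc_truth.motif_intervals,
                config.mutation_rate, rng)
            rid = f"{subfam}_d{i + 1:02d}"
            records.append(ProteinRecord(id=rid, sequence=mut))
            truths.append(replace(anc_truth, record_id=rid,
                                  cluster_seed=anc.id))
    return records, truths


def generate_similarity_clusters(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_seeds: int = 10,
    members_per_seed: int = 4,
    member_rate: float = 0.03,
) -> tuple[list[ProteinRecord], list[TruthRow]]:
    """Dereplication fixture: ``n_seeds`` unrelated seed PTTSs, each with
    high-identity mutant members (default ~97% identical)."""
    if rng is None:
        rng = config.rng()
    records, truths = [], []
    for s in range(n_seeds):
        seed_rec, seed_truth = generate_ptts(
            config, rng, rec_id=f"seed{s + 1:02d}")
        records.append(seed_rec)
        truths.append(seed_truth)
        for m in range(members_per_seed):
            mut = _mutate_preserving_motifs(
                seed_rec.sequence, seed_truth.motif_intervals, member_rate, rng)
            # members are slightly truncated so the seed is always longest
            # and therefore becomes the cluster representative
            mut = mut[: len(mut) - (m + 1)]
            rid = f"seed{s + 1:02d}_m{m + 1}"
            records.append(ProteinRecord(id=rid, sequence=mut))
            truths.append(replace(seed_truth, record_id=rid,
                                  cluster_seed=seed_rec.id))
    return records, truths


@dataclass(frozen=True)
class SpeciesScenario:
    """A planted gain/loss scenario on a random species tree."""

    tree: dendropy.Tree
    presence: dict
    gain: frozenset
    losses: frozenset  # of frozensets (leaf sets below each lost branch)


def _random_rooted_tree(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    labels = [f"s{i + 1}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = round(float(rng.uniform(0.1, 1.0)), 6)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def _leafset(node: dendropy.Node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def _count_maximal_absent(gain: dendropy.Node, present: set) -> int:
    has: dict[int, bool] = {}
    for node in gain.postorder_iter():
        if node.is_leaf():
            has[id(node)] = node.taxon.label in present
        else:
            has[id(node)] = any(has[id(c)] for c in node.child_nodes())
    n = 0
    for node in gain.preorder_iter():
        if node is gain:
            continue
        if has[id(node.parent_node)] and not has[id(node)]:
            n += 1
    return n


def generate_species_scenario(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_leaves: int = 10,
    max_losses: int = 3,
) -> SpeciesScenario:
    """Plant a gain node and non-nested loss branches on a random tree.

    Losses are only planted where they remain individually identifiable:
    each loss keeps its parent's subtree non-empty of carriers and keeps
    the gain node equal to the carriers' MRCA, so the planted loss count
    equals the minimal loss count for the planted gain.
    """
    if n_leaves < 4:
        raise ValueError("species scenario needs at least 4 leaves")
    if rng is None:
        rng = config.rng()
    tree = _random_rooted_tree(rng, n_leaves)
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    gain = internals[int(rng.integers(0, len(internals)))]
    present = set(_leafset(gain))

    loss_nodes: list[dendropy.Node] = []
    candidates = [n for n in gain.preorder_iter() if n is not gain]
    order = list(rng.permutation(len(candidates)))
    target = int(rng.integers(0, max_losses + 1))
    for idx in order:
        if len(loss_nodes) >= target:
            break
        cand = candidates[idx]
        cand_leaves = _leafset(cand)
        existing = set().union(*(_leafset(n) for n in loss_nodes)) if loss_nodes else set()
        if cand_leaves & existing:
            continue  # nested or overlapping with an existing loss
        trial_present = present - cand_leaves
        if not trial_present:
            continue
        # gain must stay the MRCA of the carriers
        taxa = [t for t in tree.taxon_namespace if t.label in trial_present]
        mrca = (tree.find_node_with_taxon_label(next(iter(trial_present)))
                if len(trial_present) == 1 else tree.mrca(taxa=taxa))
        if mrca is not gain:
            continue
        # every planted loss must stay individually identifiable
        if _count_maximal_absent(gain, trial_present) != len(loss_nodes) + 1:
            continue
        loss_nodes.append(cand)
        present = trial_present

    presence = {leaf.taxon.label: (leaf.taxon.label in present)
                for leaf in tree.leaf_node_iter()}
    return SpeciesScenario(
        tree=tree,
        presence=presence,
        gain=_leafset(gain),
        losses=frozenset(_leafset(n) for n in loss_nodes),
    )
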