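# Methods

This note records the models implemented in `pttsminer`, the parameter
choices that matter, and what the synthetic benchmarks do and do not
establish about behavior on real proteomes.

## Motif model and domain calling

Chimeric PTTS detection in the literature rests on profile-HMM
co-occurrence: a protein carrying both a terpene-synthase C-terminal
domain and a polyprenyl-synthetase domain. This package's built-in path
instead anchors domain calls on the degenerate catalytic motifs
themselves, so that mining runs with no external databases:

| pattern | motif | role |
|---|---|---|
| `DDxx[DE]` | DDXXD/E | class I TS metal binding |
| `[NH]Dxx[ST]xxxE` | (N/H)DXX(S/T)XXXE ("NSE/DTE") | class I TS triad |
| `DxDD` | DXDD | class II TS general acid (annotation only) |
| `DDxx[DN]` | DDXXD/N | trans-PT chain elongation (two required) |

Pattern semantics: `x` is a wildcard and matches the ambiguity code X;
exact and class positions do not match X, because an ambiguous residue
cannot certify a required aspartate. The scanner tests every window and
reports all overlapping hits; downstream callers select from the full
hit list. The triad is encoded in its explicit nine-residue form; the
stricter NSE/DTE spellings are not separately enforced.

A TS call pairs the leftmost DDXXD/E hit with the leftmost downstream
triad hit within `max_domain_span` (default 400 aa, the upper end of
class I TS domain sizes). A PT call takes the two most widely separated
DDXXD/N hits that fit within the span and are at least
`min_motif_separation` (default 20 aa) apart — widest-pair selection is
deterministic and independent of input order, and matters because
DDXXD/E and DDXXD/N overlap as patterns: a motif ending in D satisfies
both. For the same reason, aspartate-rich hits inside an already-called
TS interval are excluded from PT pairing; otherwise the TS metal-binding
motif would masquerade as the first PT motif.

Architecture labels are exclusive: PTTS requires the TS interval
strictly before the PT interval; the reverse order is a wrong-order
chimera; overlapping intervals are labeled `none` and flagged, since an
ambiguous architecture should not pass silently. DXDD only annotates a
record as a class II TS when no class I calls exist — it never vetoes a
record that independently satisfies the chimera criterion.

For users with profile-HMM results in hand, externally produced domain
intervals can be supplied as a TSV and bypass motif-anchored calling
entirely.

Candidates are filtered to a closed length window, default [500, 1100]
aa. This operationalizes the family's typical ~700 aa size while
tolerating terminal extensions and modest misannotation.

## Alignment, identity, and dereplication

Percent identity is computed from one optimal global alignment with
affine gaps (match 1, mismatch 0, gap open 10, gap extend 0.5; a gap of
length L costs open + (L−1)·extend). The denominator is the full
alignment length including gap columns: this penalizes length mismatch
and, with the argument pair ordered canonically before aligning, makes
the measure exactly symmetric. Alignment is delegated to Biopython's
`PairwiseAligner`; the test suite checks it against brute-force
enumeration of all alignments on short sequences. Identity-based scoring
is the simplest reproducible choice for a redundancy threshold whose
original metric is unspecified; a substitution-matrix mode (e.g.
BLOSUM62) is configurable but not default, and published pairwise
identity figures obtained with other aligners are not expected to
reproduce exactly under the defaults.

Dereplication is greedy: records are visited by descending length (ties
by ascending id), each joins the first representative it reaches at ≥
the threshold (default 80%), otherwise it founds a cluster. The ordering
makes the outcome independent of input order; the invariants (no two
representatives ≥ threshold, every member ≥ threshold to its
representative) are enforced by tests.

## Phylogeny and functional classification

The built-in tree path is neighbor joining over alignment distances
(d = 1 − identity/100). NJ is authored in-package: Q-criterion
agglomeration with deterministic tie-breaks, negative intermediate
branch lengths clamped to zero with the deficit moved to the sister
branch so the joined pair's path length is preserved (each clamp is
logged). It is cross-checked in the tests against an independent
implementation and recovers generating topologies exactly from additive
matrices. Maximum-likelihood inference is deliberately out of scope —
the clade structure being queried is deep and well separated, and an
externally computed ML tree can be imported for clade-based assignment
(smallest clade containing the query and a labeled reference). Midpoint
rooting is implemented explicitly so the edge case where the midpoint
falls exactly on an internal node roots at that node rather than
corrupting the topology.

Subfamily assignment is k-nearest-reference majority vote (k = 3).
Majority ties fall back to the single nearest reference; exact distance
ties break by ascending reference id; every tie is flagged in the
report. A query at distance zero from a reference short-circuits voting
and is assigned that reference's subfamily with support 1.0 — an exact
sequence match is stronger evidence than any vote. The subfamily → clade
→ cyclization maps (A/E/F → I → type A "C1-IV-V"; B/C/D → II → type B
"C1-III-IV") are total functions, and assignments violating them cannot
be constructed. Subfamily labels are taken as given reference metadata;
the six-way partition is not re-derived de novo.

## Gene-family evolution

Presence/absence of the family across species is explained under Dollo
parsimony: one gain, placed at the MRCA of all carriers, plus losses.
Losses are the roots of maximal carrier-free subtrees below the gain;
this set is minimal under the single-gain constraint because distinct
maximal absent subtrees cannot share a loss and each needs one. The test
suite verifies minimality against exhaustive subset search on trees up
to 12 leaves. Gene counts are reduced to presence/absence for
reconstruction; duplication is reported only as per-species counts.
Tree nodes are identified by their descendant leaf sets, which is stable
across traversal orders and serializations.

The scenario comparator makes alternative origins computable: for any
candidate gain node it reports the losses required within the subtree
and counts carriers outside it as transfer events. This turns a verbal
argument — family-wide origin with subsequent losses versus a later
origin plus horizontal transfer — into two comparable event counts. No
probabilistic reconciliation is attempted.

## Mass arithmetic

Monoisotopic masses use pinned principal-isotope constants (C = 12
exactly, H = 1.00782503, O = 15.99491462, N, S) and the neutral-molecule
convention — no electron-mass subtraction for [M]+ — which reproduces
conventionally printed "calculated" values (C25H40 → 340.3130 at four
decimals). Nominal masses sum integer mass numbers. The diagnostic ion
table (272, 290, 340, 358) is matched at ±0.5 m/z by default.

## Synthetic data: what it emulates and what it does not

The generator plants the statistical structure the pipeline assumes:
chimeras of 650–750 aa with the four anchor motifs in the canonical
order and spacing; decoys realizing each negative architecture (TS-only,
PT-only, class II, wrong-order, length outlier, motif-free); subfamily
radiations (six independent random ancestors, descendants mutated per
site at a configurable rate, default 0.05, with motif residues frozen);
and species trees with planted gain/loss scenarios constrained so each
planted loss remains individually identifiable. Filler residues are
uniform over the 20 standard amino acids; a frequency-table option
exists for stress tests but composition realism is not load-bearing
because motif placement is explicit. Every generated sequence is
rejection-checked against a glycine-skeleton scan so no accidental motif
arises, and generation is byte-deterministic given (seed, config).

Consequently, green benchmarks establish correctness of the logic —
architecture rules, clustering invariants, tree recovery, minimality —
under the stated geometry. They do not establish sensitivity on real
proteomes, where motifs decay, domains vary in span beyond the defaults,
and gene models are incomplete; the wrong-order decoy, in particular, is
planted with its PT block more than one domain-span away from the TS
triad because a PT motif ending in D genuinely satisfies the TS
DDXXD/E pattern and a closer arrangement is intrinsically ambiguous.
For real use, the external-domain hook (profile-HMM intervals) and the
ML-tree import are the recommended high-fidelity paths.

## Problem sizes and numerical conventions

All sequence coordinates are 1-based with closed intervals. Residues
other than the 20 standard letters plus X are rejected, not coerced.
The reproduction script and acceptance-level tests use: 1,000 random
sequences for the scanner oracle; 40 random pairs (lengths to 12, one
side short enough for exact enumeration) for the alignment oracle; 100
seeded 8-taxon additive matrices for NJ recovery; a 100-protein cohort
(40 chimeras, 60 decoys) for architecture precision/recall; a
six-subfamily radiation with 20 descendants each (half held out) for
classification accuracy; 10 seed clusters of 5 for dereplication; and
50 random trees up to 12 leaves for Dollo minimality. The full suite
runs in a few minutes on one CPU.
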