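"""Global-alignment identity, distance matrices, and dereplication.

Percent identity between two proteins is computed from one optimal global
(Needleman–Wunsch) alignment with affine gap costs, as the fraction of
alignment columns (gaps included) that are identical matches.  Using the
full alignment length as the denominator penalizes length mismatch and
makes the measure symmetric.  Candidate sets are dereplicated greedily so
that no two retained representatives reach the identity threshold
(default 80%) — the same redundancy criterion used when assembling
non-redundant PTTS candidate sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io import ProteinRecord


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for global alignment (arbitrary score units).

    Gap of length L costs ``gap_open + (L - 1) * gap_extend``; both
    penalties are non-negative.  The default identity scoring (match 1,
    mismatch 0) is the simplest reproducible choice; a substitution
    matrix by name (e.g. ``"BLOSUM62"``) may be supplied instead, in
    which case match/mismatch scores are ignored.
    """

    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    substitution_matrix: str | None = None

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner(mode="global")
        if self.substitution_matrix is not None:
            aligner.substitution_matrix = substitution_matrices.load(
                self.substitution_matrix)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


def global_align_identity(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    params: AlignmentParams | None = None,
) -> float:
    """Percent identity in [0, 100] from an optimal global alignment.

    identity = 100 x (identical matched columns) / (alignment columns,
    gaps included).  The argument pair is ordered canonically before
    aligning so the result is exactly symmetric.  Empty sequences are an
    error.
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    if params is None:
        params = AlignmentParams()
    # canonical order => identity(a, b) == identity(b, a) bit-for-bit
    if sb < sa:
        sa, sb = sb, sa
    aligner = params.make_aligner()
    aln = aligner.align(sa, sb)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def alignment_score(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Optimal global alignment score under ``params``."""
    if params is None:
        params = AlignmentParams()
    return float(params.make_aligner().score(a, b))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix in [0, 1] with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def pairwise_matrix(
    records: list[ProteinRecord],
    params: AlignmentParams | None = None,
) -> DistanceMatrix:
    """Distance matrix over all unordered pairs, d = 1 - identity/100."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_align_identity(records[i], records[j], params)
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return DistanceMatrix(labels=tuple(ids), values=d)


def dereplicate(
    records: list[ProteinRecord],
    threshold: float = 80.0,
    params: AlignmentParams | None = None,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Greedy identity clustering at ``threshold`` percent.

    Records are visited by descending length (ties by ascending id, so
    the outcome is independent of input order).  Each record joins the
    first existing representative it reaches at >= threshold identity,
    otherwise it founds a new cluster.  Returns the representatives in
    creation order and a member -> representative id map (representatives
    map to themselves).  Any two representatives are < threshold
    identical, and every member is >= threshold identical to its
    representative.
    """
    if not (0.0 < threshold <= 100.0):
        raise ValueError("threshold must be in (0, 100]")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[ProteinRecord] = []
    assignment: dict[str, str] = {}
    for rec in ordered:
        home = None
        for rep in reps:
            if global_align_identity(rec, rep, params) >= threshold:
                home = rep
                break
        if home is None:
            reps.append(rec)
            assignment[rec.id] = rec.id
        else:
            assignment[rec.id] = home.id
    return reps, assignment
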