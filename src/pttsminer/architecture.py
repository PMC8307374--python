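"""Domain calling and chimeric-architecture classification.

A chimeric PTTS carries an N-terminal class I TS domain followed by a
C-terminal trans-PT domain.  Domains are called from motif evidence: a TS
call needs one DDXXD/E hit followed by one (N/H)DXX(S/T)XXXE hit within a
bounded span, a PT call needs two DDXXD/N hits with a minimum separation.
An optional hook accepts externally produced domain intervals (e.g. from a
profile-HMM search) in a simple TSV, bypassing motif-anchored calling.

Because the DDXXD/E and DDXXD/N patterns overlap (a motif ending in D
satisfies both), PT calling ignores aspartate-rich hits that fall inside
an already-called TS interval; otherwise the TS metal-binding motif would
masquerade as the first PT motif.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

from .io import ProteinRecord
from .motifs import MotifHit, scan_all


class ArchitectureLabel(str, enum.Enum):
    PTTS = "PTTS"
    TS_ONLY = "TS_only"
    PT_ONLY = "PT_only"
    CLASSII_TS = "classII_TS"
    WRONG_ORDER_CHIMERA = "wrong_order_chimera"
    NONE = "none"


@dataclass(frozen=True)
class DomainCall:
    """An inferred TS or PT domain: a 1-based closed interval spanning its
    supporting motif hits."""

    kind: str  # "TS" or "PT"
    start: int
    end: int
    supporting_hits: tuple[MotifHit, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("TS", "PT"):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid domain interval")
        for h in self.supporting_hits:
            if h.start < self.start or h.end > self.end:
                raise ValueError("interval must span all supporting hits")

    def overlaps(self, other: "DomainCall") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class DomainCallParams:
    """Tunable geometry for motif-anchored domain calling.

    ``max_domain_span`` bounds the width (in residues) of a single called
    domain; ``min_motif_separation`` is the minimum distance between the
    start positions of the two PT aspartate-rich motifs.  Defaults reflect
    typical class I TS and trans-PT domain sizes.
    """

    max_domain_span: int = 400
    min_motif_separation: int = 20


@dataclass
class PttsCandidate:
    """A record that passed the architecture stage, with audit flags."""

    record: ProteinRecord
    ts_call: DomainCall
    pt_call: DomainCall
    length_pass: bool = True
    motif_pass: bool = True
    cluster_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.record)

    def __post_init__(self) -> None:
        if not self.ts_call.end < self.pt_call.start:
            raise ValueError("TS interval must strictly precede PT interval")


def call_domains(
    record: ProteinRecord,
    hits: dict[str, list[MotifHit]] | None = None,
    params: DomainCallParams | None = None,
) -> list[DomainCall]:
    """Call TS and PT domains for one record from motif hits.

    The TS call pairs the leftmost DDXXD/E hit with the leftmost
    downstream triad hit within ``max_domain_span``.  The PT call uses the
    two most widely separated DDXXD/N hits that fit within the span, are
    separated by at least ``min_motif_separation``, and do not fall inside
    the TS interval.  Absence of calls is a valid outcome, not an error.
    """
    if hits is None:
        hits = scan_all(record)
    if params is None:
        params = DomainCallParams()
    calls: list[DomainCall] = []

    ts_call = None
    dde_hits = hits.get("TS_DDXXDE", [])
    triad_hits = hits.get("TS_NSE_DTE", [])
    for dde in dde_hits:
        for triad in triad_hits:
            if triad.start <= dde.start:
                continue
            span = triad.end - dde.start + 1
            if span <= params.max_domain_span:
                ts_call = DomainCall(
                    kind="TS", start=dde.start, end=triad.end,
                    supporting_hits=(dde, triad),
                )
                break
        if ts_call is not None:
            break
    if ts_call is not None:
        calls.append(ts_call)

    pt_hits = hits.get("PT_DDXXDN", [])
    if ts_call is not None:
        pt_hits = [h for h in pt_hits
                   if h.end < ts_call.start or h.start > ts_call.end]
    best: tuple[int, int, int] | None = None  # (-width, start index) for det. choice
    best_pair: tuple[MotifHit, MotifHit] | None = None
    for i in range(len(pt_hits)):
        for j in range(i + 1, len(pt_hits)):
            a, b = pt_hits[i], pt_hits[j]
            width = b.end - a.start + 1
            sep = b.start - a.start
            if width > params.max_domain_span or sep < params.min_motif_separation:
                continue
            key = (-width, a.start, b.start)
            if best is None or key < best:
                best = key
                best_pair = (a, b)
    if best_pair is not None:
        calls.append(DomainCall(
            kind="PT", start=best_pair[0].start, end=best_pair[1].end,
            supporting_hits=best_pair,
        ))
    return calls


def classify_architecture(
    record: ProteinRecord,
    calls: list[DomainCall] | None = None,
    classii_hits: list[MotifHit] | None = None,
    params: DomainCallParams | None = None,
) -> ArchitectureLabel:
    """Assign one architecture label per record.

    PTTS requires a TS call entirely upstream of a PT call; the reverse
    order is a wrong-order chimera; single calls give TS_only / PT_only; a
    DXDD hit with no class I calls marks a class II TS; overlapping TS/PT
    intervals are labeled ``none`` (ambiguous architecture must not pass
    silently).  DXDD only annotates — it never excludes a record that
    independently satisfies the PTTS criterion.
    """
    if calls is None or classii_hits is None:
        all_hits = scan_all(record)
        if calls is None:
            calls = call_domains(record, all_hits, params)
        if classii_hits is None:
            classii_hits = all_hits["CLASSII_DXDD"]
    ts = next((c for c in calls if c.kind == "TS"), None)
    pt = next((c for c in calls if c.kind == "PT"), None)
    if ts is not None and pt is not None:
        if ts.overlaps(pt):
            return ArchitectureLabel.NONE
        if ts.end < pt.start:
            return ArchitectureLabel.PTTS
        return ArchitectureLabel.WRONG_ORDER_CHIMERA
    if ts is not None:
        return ArchitectureLabel.TS_ONLY
    if pt is not None:
        return ArchitectureLabel.PT_ONLY
    if classii_hits:
        return ArchitectureLabel.CLASSII_TS
    return ArchitectureLabel.NONE


@dataclass
class LengthWindow:
    """Closed residue-length interval for candidate filtering.

    The default [500, 1100] operationalizes the ``~700 aa`` size of known
    chimeric PTTSs while tolerating terminal extensions.
    """

    min_length: int = 500
    max_length: int = 1100

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("length window min must not exceed max")

    def __contains__(self, length: int) -> bool:
        return self.min_length <= length <= self.max_length


def make_candidate(record: ProteinRecord, calls: list[DomainCall]) -> PttsCandidate:
    ts = next(c for c in calls if c.kind == "TS")
    pt = next(c for c in calls if c.kind == "PT")
    return PttsCandidate(record=record, ts_call=ts, pt_call=pt)


def filter_candidates(
    candidates: list[PttsCandidate],
    length_window: LengthWindow | None = None,
) -> list[PttsCandidate]:
    """Keep candidates whose length falls inside the (closed) window.

    Every candidate's ``length_pass`` flag is set for audit, including the
    rejected ones.
    """
    if length_window is None:
        length_window = LengthWindow()
    kept: list[PttsCandidate] = []
    for cand in candidates:
        cand.length_pass = cand.length in length_window
        if cand.length_pass:
            kept.append(cand)
    return kept


def read_external_domains(path: str | Path) -> dict[str, list[DomainCall]]:
    """Load externally produced domain intervals (TSV: record_id,
    domain_name, start, end), bypassing motif-anchored calling.

    ``domain_name`` must be TS or PT; intervals are 1-based closed.
    External calls carry no supporting motif hits.
    """
    out: dict[str, list[DomainCall]] = {}
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            rid, kind, start, end = parts
            out.setdefault(rid, []).append(
                DomainCall(kind=kind, start=int(start), end=int(end),
                           supporting_hits=())
            )
    return out


def candidate_report_rows(
    records: list[ProteinRecord],
    labels: dict[str, ArchitectureLabel],
    candidates: list[PttsCandidate],
) -> list[tuple]:
    """Rows (record_id, label, ts_start, ts_end, pt_start, pt_end, length,
    flags) for the candidate TSV report."""
    by_id = {c.record.id: c for c in candidates}
    rows = []
    for rec in records:
        cand = by_id.get(rec.id)
        flags = []
        if cand is not None:
            flags.append("length_pass" if cand.length_pass else "length_fail")
            if cand.cluster_id is not None:
                flags.append(f"cluster={cand.cluster_id}")
        rows.append((
            rec.id,
            labels[rec.id].value,
            cand.ts_call.start if cand else "",
            cand.ts_call.end if cand else "",
            cand.pt_call.start if cand else "",
            cand.pt_call.end if cand else "",
            len(rec),
            ";".join(flags),
        ))
    return rows
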