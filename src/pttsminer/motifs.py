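"""Degenerate Asp-rich motif patterns and the scanner that finds them.

Class I terpene synthase (TS) domains carry a DDXXD/E metal-binding motif
and an (N/H)DXX(S/T)XXXE triad ("NSE/DTE"); class II TSs instead carry the
general-acid motif DXDD; trans-prenyltransferase (PT) domains carry two
aspartate-rich DDXXD/N motifs.  These four patterns anchor every
architecture decision downstream, so the scanner is deliberately exact:
every window is tested, all (possibly overlapping) hits are reported, and
hit coordinates are 1-based.

Pattern grammar: uppercase letters are exact residues, ``x`` (either case)
is a wildcard, and ``[...]`` is a residue class, e.g. ``"DDxx[DE]"``.
A wildcard matches any residue including the ambiguity code X; exact and
class tokens do not match X, because an ambiguous residue cannot certify a
required aspartate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import AMINO_ACIDS, ProteinRecord

WILDCARD = "*"  # internal token marker


class PatternSyntaxError(ValueError):
    """Raised when a motif pattern string cannot be parsed."""


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif: an ordered list of position tokens.

    Each token is a frozenset of allowed residues, or the ``WILDCARD``
    marker which additionally admits X.
    """

    name: str
    tokens: tuple

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("pattern must have at least one token")
        for tok in self.tokens:
            if tok is WILDCARD:
                continue
            if not tok or not tok.issubset(set(AMINO_ACIDS)):
                raise ValueError(f"invalid residue class in pattern {self.name!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    def matches(self, window: str) -> bool:
        """True if ``window`` (same length as the pattern) satisfies every token."""
        if len(window) != len(self.tokens):
            return False
        for ch, tok in zip(window, self.tokens):
            if tok is WILDCARD:
                continue
            if ch not in tok:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    """A single pattern match: 1-based ``start`` and the matched substring."""

    pattern_name: str
    start: int
    matched: str

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + len(self.matched) - 1


def parse_pattern(text: str, name: str | None = None) -> MotifPattern:
    """Parse a pattern string such as ``"DDxx[DE]"`` or ``"[NH]Dxx[ST]xxxE"``."""
    if not text:
        raise PatternSyntaxError("empty pattern")
    tokens: list = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in ("x", "X"):
            tokens.append(WILDCARD)
            i += 1
        elif ch == "[":
            j = text.find("]", i + 1)
            if j == -1:
                raise PatternSyntaxError(f"unclosed '[' at offset {i} in {text!r}")
            members = text[i + 1 : j]
            if not members:
                raise PatternSyntaxError(f"empty residue class at offset {i} in {text!r}")
            bad = [c for c in members if c not in AMINO_ACIDS]
            if bad:
                raise PatternSyntaxError(f"illegal residue {bad[0]!r} in class in {text!r}")
            tokens.append(frozenset(members))
            i = j + 1
        elif ch in AMINO_ACIDS:
            tokens.append(frozenset(ch))
            i += 1
        else:
            raise PatternSyntaxError(f"illegal character {ch!r} at offset {i} in {text!r}")
    return MotifPattern(name=name if name is not None else text, tokens=tuple(tokens))


#: Canonical pattern strings for the four anchoring motifs.
BUILTIN_PATTERN_STRINGS = {
    "TS_DDXXDE": "DDxx[DE]",
    "TS_NSE_DTE": "[NH]Dxx[ST]xxxE",
    "CLASSII_DXDD": "DxDD",
    "PT_DDXXDN": "DDxx[DN]",
}


def builtin_patterns() -> list[MotifPattern]:
    """The four built-in motif patterns, in a fixed order:

    - ``TS_DDXXDE``: class I TS metal-binding motif DDXXD/E
    - ``TS_NSE_DTE``: class I TS triad (N/H)DXX(S/T)XXXE
    - ``CLASSII_DXDD``: class II TS general-acid motif DXDD
    - ``PT_DDXXDN``: trans-PT aspartate-rich motif DDXXD/N
    """
    return [parse_pattern(s, name=n) for n, s in BUILTIN_PATTERN_STRINGS.items()]


def builtin_pattern(name: str) -> MotifPattern:
    return parse_pattern(BUILTIN_PATTERN_STRINGS[name], name=name)


def scan(record: ProteinRecord | str, pattern: MotifPattern) -> list[MotifHit]:
    """All matches of ``pattern`` in the sequence, ascending by start.

    Overlapping hits are all reported.  A pattern longer than the
    sequence yields an empty list.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    m = len(pattern)
    hits: list[MotifHit] = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if pattern.matches(window):
            hits.append(MotifHit(pattern_name=pattern.name, start=i + 1, matched=window))
    return hits


def scan_all(record: ProteinRecord | str) -> dict[str, list[MotifHit]]:
    """Scan with every built-in pattern; mapping pattern name -> hits."""
    return {p.name: scan(record, p) for p in builtin_patterns()}


def hits_to_rows(record_id: str, hits: list[MotifHit]) -> list[tuple]:
    """Rows (record_id, pattern, start, matched) for TSV export."""
    return [(record_id, h.pattern_name, h.start, h.matched) for h in hits]
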