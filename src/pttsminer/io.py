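"""Reading and writing of the plain-text formats used across the pipeline.

Protein sequences travel as FASTA, species lineages as a TSV taxonomy
table, and trees as Newick.  All sequence positions downstream of this
module are 1-based and intervals are closed, matching the residue
numbering convention used when motif coordinates are reported (e.g. a
DDYYD motif "at 95" occupies residues 95..99).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

#: The 20 standard amino acids plus X for an ambiguous residue.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the sequence contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence.

    Sequences are uppercased on construction and may contain only the 20
    standard residues plus ``X``; anything else is rejected rather than
    coerced so that motif matching stays unambiguous.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be a non-empty string")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        for pos, ch in enumerate(seq, start=1):
            if ch not in VALID_RESIDUES:
                raise FastaFormatError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyTable:
    """Species lineages: for each species id an ordered path of rank names,
    e.g. ``("Ascomycota", "Pezizomycotina", "Dothideomycetes")``.
    """

    rows: tuple[tuple[str, tuple[str, ...]], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for species, lineage in self.rows:
            if species in seen:
                raise ValueError(f"duplicate species id {species!r} in taxonomy")
            if not lineage:
                raise ValueError(f"species {species!r}: lineage path must be non-empty")
            seen.add(species)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.rows)

    def lineage_of(self, species: str) -> tuple[str, ...]:
        for s, lineage in self.rows:
            if s == species:
                return lineage
        raise KeyError(f"unknown species {species!r}")

    def __contains__(self, species: str) -> bool:
        return any(s == species for s, _ in self.rows)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Record order is preserved; wrapped sequence lines are joined.  An
    empty file yields an empty list with a warning.  Duplicate ids and
    illegal residues raise :class:`FastaFormatError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), description=desc))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with sequence lines wrapped at ``width``.

    Round-trips losslessly through :func:`read_fasta`.
    """
    if width < 1:
        raise ValueError("line width must be >= 1")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV with header ``species_id<TAB>lineage``; lineage
    ranks are separated by ``>`` (surrounding whitespace ignored)."""
    path = Path(path)
    rows: list[tuple[str, tuple[str, ...]]] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            return TaxonomyTable()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            species = parts[0].strip()
            lineage = tuple(tok.strip() for tok in parts[1].split(">") if tok.strip())
            rows.append((species, lineage))
    return TaxonomyTable(rows=tuple(rows))


def write_taxonomy(table: TaxonomyTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("species_id\tlineage\n")
        for species, lineage in table.rows:
            fh.write(f"{species}\t{' > '.join(lineage)}\n")


class NewickParseError(ValueError):
    """Raised for malformed Newick input."""


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Leaf labels become taxa; internal-node labels and branch lengths are
    preserved.  Malformed input raises :class:`NewickParseError`.
    """
    # dendropy silently tolerates a missing final ')' in some cases, so do a
    # cheap balance check first to guarantee the contract.
    depth = 0
    for off, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at offset {off}")
    if depth != 0:
        raise NewickParseError(f"unbalanced parentheses ({depth} unclosed '(')")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a one-line Newick string (branch lengths kept)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    """Labels of all leaves, in tree traversal order."""
    out = []
    for leaf in tree.leaf_node_iter():
        out.append(leaf.taxon.label if leaf.taxon is not None else leaf.label)
    return out


def write_tsv(rows: Sequence[Sequence], header: Sequence[str], path: str | Path) -> None:
    """Write rows as a plain TSV with a header line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
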