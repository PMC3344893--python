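"""Sequence, alignment and tree I/O plus the coordinate conventions used package-wide.

All sequence data is held internally in the DNA alphabet (IUPAC degeneracy
codes allowed); RNA input is converted U→T on load and rendered back as RNA
on output when the record was RNA-flagged.  Promoter coordinates relative to
a transcription start site (TSS) follow the genetics convention with no
position 0: ..., -2, -1, +1, +2, ...  All internal sequence indices are
1-based closed; conversion to 0-based half-open happens only at BED export.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import dendropy
from Bio import AlignIO, SeqIO

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "SeqRecord",
    "Alignment",
    "TssInterval",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "revcomp",
    "interval_length",
    "to_bed_interval",
]

#: IUPAC nucleotide degeneracy codes mapped to their base sets (DNA alphabet).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

GAP = "-"

PathLike = Union[str, Path]
Source = Union[PathLike, TextIO]


def _as_handle(source: Source) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return open(source)  # noqa: SIM115 - caller-scope lifetime is fine here


@dataclass
class SeqRecord:
    """A single named sequence (one species or one element consensus).

    ``residues`` is always uppercase DNA (U converted to T); ``kind`` records
    whether the original input was RNA so it can be rendered back.
    """

    id: str
    residues: str
    kind: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if self.kind not in ("dna", "rna"):
            raise ValueError(f"kind must be 'dna' or 'rna', got {self.kind!r}")
        seq = self.residues.upper()
        if "U" in seq:
            self.kind = "rna"
            seq = seq.replace("U", "T")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        self.residues = seq

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def display_residues(self) -> str:
        """Residues in the original alphabet (RNA records rendered with U)."""
        if self.kind == "rna":
            return self.residues.replace("T", "U")
        return self.residues


@dataclass
class Alignment:
    """A multiple alignment as an ordered list of (id, gapped residues) rows."""

    rows: list[tuple[str, str]]
    reference_id: str = ""

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment requires at least one row")
        self.rows = [(rid, seq.upper().replace("U", "T")) for rid, seq in self.rows]
        length = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != length:
                raise ValueError(
                    f"alignment row {rid!r} has length {len(seq)}, expected {length}"
                )
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate row ids in alignment: {dup}")
        if not self.reference_id:
            self.reference_id = self.rows[0][0]
        if self.reference_id not in ids:
            raise ValueError(f"reference id {self.reference_id!r} not among rows")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return seq
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")


@dataclass(frozen=True)
class TssInterval:
    """Closed interval in TSS-relative coordinates; position 0 does not exist."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start == 0 or self.end == 0:
            raise ValueError("TSS-relative coordinates have no position 0")
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start:+d} must not follow end {self.end:+d}"
            )


def read_fasta(source: Source) -> list[SeqRecord]:
    """Parse FASTA into records, normalising case and flagging RNA input.

    Raises ``ValueError`` on empty input or duplicate ids (naming the id).
    """
    handle = _as_handle(source)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in FASTA input: {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, residues=str(rec.seq), description=desc))
    if not records:
        raise ValueError("no sequences found in FASTA input")
    return records


def write_fasta(records: Iterable[SeqRecord], dest: Source, width: int = 70) -> None:
    handle = dest if hasattr(dest, "write") else open(dest, "w")
    own = not hasattr(dest, "write")
    try:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            handle.write(header + "\n")
            seq = rec.display_residues
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


def read_alignment(source: Source, format: str = "afa", reference_id: str = "") -> Alignment:
    """Read an aligned FASTA (``afa``) or Clustal alignment.

    The first row is the default coordinate reference.  Ragged rows raise a
    ``ValueError`` naming the offending id.
    """
    if format not in ("afa", "clustal"):
        raise ValueError(f"unknown alignment format {format!r}")
    handle = _as_handle(source)
    if format == "afa":
        rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
        if not rows:
            raise ValueError("no sequences found in alignment input")
        length = len(rows[0][1])
        for rid, seq in rows:
            if len(seq) != length:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has length {len(seq)}, expected {length}"
                )
    else:
        try:
            aln = AlignIO.read(handle, "clustal")
        except ValueError as exc:
            raise ValueError(f"could not parse Clustal alignment: {exc}") from exc
        rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
    return Alignment(rows=rows, reference_id=reference_id)


def write_alignment(alignment: Alignment, dest: Source) -> None:
    handle = dest if hasattr(dest, "write") else open(dest, "w")
    own = not hasattr(dest, "write")
    try:
        for rid, seq in alignment.rows:
            handle.write(f">{rid}\n{seq}\n")
    finally:
        if own:
            handle.close()


def read_newick(source: Union[str, Path, TextIO]) -> dendropy.Tree:
    """Parse a rooted Newick tree; leaf labels must be unique.

    Accepts a Newick string, a path, or a handle.  Raises ``ValueError`` on
    malformed input (e.g. unbalanced parentheses).
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        text = source
        if "(" not in text and Path(text).exists():
            text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse error types
        raise ValueError(f"could not parse Newick tree: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels in tree: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def revcomp(residues: str) -> str:
    """Reverse complement over the full IUPAC alphabet (DNA or RNA).

    A string containing U (and no T) is treated as RNA and complemented in
    RNA space, so ``revcomp`` is an involution on both alphabets.
    """
    s = residues.upper()
    rna = "U" in s
    if rna:
        if "T" in s:
            raise ValueError("sequence mixes T and U")
        s = s.replace("U", "T")
    out = []
    for ch in reversed(s):
        try:
            out.append(IUPAC_COMPLEMENT[ch])
        except KeyError:
            raise ValueError(f"non-IUPAC character in sequence: {ch!r}") from None
    res = "".join(out)
    return res.replace("T", "U") if rna else res


def interval_length(iv: TssInterval) -> int:
    """Number of positions in a closed TSS-relative interval (no position 0).

    Spanning the TSS, ``(-197, +107)`` covers 197 upstream plus 107 downstream
    positions = 304 bp; a same-sign interval is the ordinary closed count.
    """
    if iv.start < 0 < iv.end:
        return -iv.start + iv.end
    return iv.end - iv.start + 1


def to_bed_interval(start_1based_closed: int, end: int) -> tuple[int, int]:
    """Convert a 1-based closed interval to BED (0-based half-open)."""
    if start_1based_closed < 1:
        raise ValueError("1-based start must be >= 1")
    if end < start_1based_closed:
        raise ValueError("end precedes start")
    return start_1based_closed - 1, end
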