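"""Readers/writers for the external formats the pipeline touches, plus shared records.

Conventions
-----------
* All coordinates are 1-based inclusive.
* DNA alphabet is ``{A, C, G, T, N}``; lowercase input is uppercased, ``U`` and
  anything else is rejected.  ``N`` is legal input everywhere and is treated as
  missing data by every distance computation downstream.
* TSV files are tab-separated with no quoting; lines starting with ``#`` are
  comments.  Every writer terminates its file with a newline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence with an optional genome-of-origin label."""

    id: str
    residues: str
    genome_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r}: illegal characters {sorted(bad)!r} "
                f"(alphabet is A/C/G/T/N; gaps belong in aligned FASTA)"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int, suffix: str = "") -> "NucSequence":
        """Extract ``[start, end]`` (1-based inclusive) as a new record."""
        if not (1 <= start <= end <= len(self.residues)):
            raise ValueError(
                f"{self.id}: slice {start}..{end} out of bounds 1..{len(self.residues)}"
            )
        return NucSequence(self.id + suffix, self.residues[start - 1 : end],
                           self.genome_label)


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple alignment: ordered ``(id, gapped residues)`` rows."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        rows = tuple((rid, res.upper()) for rid, res in self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise FormatError("alignment has no rows")
        lengths = {len(res) for _, res in rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [rid for rid, _ in rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate alignment ids: {dupes}")
        for rid, res in rows:
            bad = set(res) - DNA_ALPHABET - {GAP}
            if bad:
                raise FormatError(f"row {rid!r}: illegal characters {sorted(bad)!r}")
            if not res.replace(GAP, ""):
                raise FormatError(f"row {rid!r} is all gaps")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def degapped(self, row_id: str) -> NucSequence:
        for rid, res in self.rows:
            if rid == row_id:
                return NucSequence(rid, res.replace(GAP, ""))
        raise KeyError(row_id)


# Enumerated category paths for Table-1-style TE accounting.
CATEGORIES = (
    "class I / LTR / gypsy",
    "class I / LTR / copia",
    "class I / LTR / unknown",
    "class I / non-LTR",
    "class II / CACTA",
    "MITE",
    "tandem_repeat",
    "gene",
    "unassigned",
)


@dataclass(frozen=True)
class AnnotationRecord:
    """One row of a TE/repeat/gene accounting table."""

    name: str
    category: str
    copy_number: int
    length_bp: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise FormatError(
                f"{self.name}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.copy_number < 1:
            raise FormatError(f"{self.name}: copy_number must be positive")
        if self.length_bp < 0:
            raise FormatError(f"{self.name}: negative length")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with an intronless CDS spanning ``start..end`` (1-based inclusive)."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(f"{self.name}: invalid span {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.name}: strand must be + or -")

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read ungapped FASTA; rejects gaps, duplicate ids and illegal characters."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    out: list[NucSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if GAP in residues:
            raise FormatError(
                f"{path}: record {rec.id!r} contains gaps; use read_aligned_fasta"
            )
        try:
            out.append(NucSequence(rec.id, residues))
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fasta(seqs: Iterable[NucSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_aligned_fasta(path: str | Path) -> Alignment:
    """Read gapped FASTA as an alignment; ragged rows are a shape error."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    rows = tuple((rec.id, str(rec.seq)) for rec in records)
    lengths = {len(res) for _, res in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    try:
        return Alignment(rows)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_aligned_fasta(aln: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, res in aln.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(res), width):
                fh.write(res[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def _tsv_rows(path: str | Path) -> Iterable[list[str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


def read_genome_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``id<TAB>genome_label``; conflicting duplicates are errors."""
    labels: dict[str, str] = {}
    for fields in _tsv_rows(path):
        if len(fields) != 2:
            raise FormatError(f"{path}: expected 2 columns, got {len(fields)}: {fields}")
        rid, lab = fields
        if rid in labels and labels[rid] != lab:
            raise FormatError(
                f"{path}: id {rid!r} mapped to both {labels[rid]!r} and {lab!r}"
            )
        labels[rid] = lab
    return labels


def write_genome_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid in labels:
            fh.write(f"{rid}\t{labels[rid]}\n")


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    """TSV ``name<TAB>category<TAB>copies<TAB>length_bp``."""
    out = []
    for fields in _tsv_rows(path):
        if len(fields) != 4:
            raise FormatError(f"{path}: expected 4 columns, got {fields}")
        name, category, copies, length = fields
        out.append(AnnotationRecord(name, category, int(copies), int(length)))
    return out


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """TSV ``name<TAB>start<TAB>end<TAB>strand``."""
    out = []
    for fields in _tsv_rows(path):
        if len(fields) != 4:
            raise FormatError(f"{path}: expected 4 columns, got {fields}")
        name, start, end, strand = fields
        out.append(GeneRecord(name, int(start), int(end), strand))
    return out


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree) -> str:
    """Serialise a phylo.Tree deterministically.

    Branch lengths to six decimals; integer bootstrap supports as internal node
    labels; children ordered lexicographically by the smallest tip label in each
    subtree, so the same tree always yields the same string.
    """

    def min_tip(node) -> str:
        if node.is_tip():
            return node.name
        return min(min_tip(c) for c in node.children)

    def render(node, with_length: bool) -> str:
        if node.is_tip():
            s = node.name
        else:
            kids = sorted(node.children, key=min_tip)
            s = "(" + ",".join(render(c, True) for c in kids) + ")"
            if node.support is not None:
                s += str(int(round(node.support)))
        if with_length:
            s += f":{node.length:.6f}"
        return s

    return render(tree.root, False) + ";"


def write_newick_file(tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")
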