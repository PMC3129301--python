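"""Sequence-composition accounting for a large genomic clone (BAC scale).

Aggregates a TE/repeat/gene annotation table into per-category copy numbers,
base-pair totals and percentage fractions of the clone; computes gene-island
geometry and gene density; derives protein lengths from intronless CDS spans;
and runs an in-silico PCR check for ISBP-style junction markers.

Percentages are rounded half-up to one decimal so that printed report tables
are stable across platforms (banker's rounding would flip .x5 cases).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .io_formats import AnnotationRecord, GeneRecord, NucSequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"),
                                           rounding=ROUND_HALF_UP))


def revcomp(s: str) -> str:
    return s.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CategoryTotal:
    copies: int
    length_bp: int
    fraction_pct: float


@dataclass(frozen=True)
class CompositionReport:
    """Per-category and rolled-up accounting of one clone sequence."""

    total_len: int
    per_category: dict[str, CategoryTotal]
    rollups: dict[str, CategoryTotal]

    def fraction(self, rollup: str) -> float:
        return self.rollups[rollup].fraction_pct


#: rollup name -> predicate on category path
_ROLLUPS: dict[str, callable] = {
    "class I": lambda c: c.startswith("class I /"),
    "LTR retrotransposons": lambda c: c.startswith("class I / LTR"),
    "gypsy": lambda c: c == "class I / LTR / gypsy",
    "copia": lambda c: c == "class I / LTR / copia",
    "unknown LTR": lambda c: c == "class I / LTR / unknown",
    "non-LTR": lambda c: c == "class I / non-LTR",
    "class II": lambda c: c.startswith("class II /"),
    "MITE": lambda c: c == "MITE",
    "tandem repeats": lambda c: c == "tandem_repeat",
    "genes": lambda c: c == "gene",
    "TE total": lambda c: c.startswith("class I /")
    or c.startswith("class II /") or c == "MITE",
}


def composition_report(records: Sequence[AnnotationRecord],
                       total_len: int) -> CompositionReport:
    """Sum copies and lengths per category/rollup; fractions are % of ``total_len``."""
    if total_len <= 0:
        raise ValueError("total_len must be positive")
    assigned = sum(r.length_bp for r in records)
    if assigned > total_len:
        raise ValueError(
            f"assigned length {assigned} bp exceeds clone length {total_len} bp"
        )

    def total(rs: Iterable[AnnotationRecord]) -> CategoryTotal:
        rs = list(rs)
        bp = sum(r.length_bp for r in rs)
        return CategoryTotal(
            copies=sum(r.copy_number for r in rs),
            length_bp=bp,
            fraction_pct=_round_half_up(100.0 * bp / total_len),
        )

    categories = sorted({r.category for r in records})
    per_category = {c: total(r for r in records if r.category == c)
                    for c in categories}
    rollups = {name: total(r for r in records if pred(r.category))
               for name, pred in _ROLLUPS.items()}
    unassigned = total_len - assigned
    rollups["unassigned"] = CategoryTotal(
        copies=0, length_bp=unassigned,
        fraction_pct=_round_half_up(100.0 * unassigned / total_len),
    )
    return CompositionReport(total_len, per_category, rollups)


def fraction_within(records: Sequence[AnnotationRecord], name_prefix: str,
                    rollup_bp: int) -> float:
    """Percentage that records whose name starts with ``name_prefix`` contribute
    to a rollup total (e.g. one family's share of all LTR retrotransposons)."""
    if rollup_bp <= 0:
        raise ValueError("rollup total must be positive")
    fam = sum(r.length_bp for r in records if r.name.startswith(name_prefix))
    return _round_half_up(100.0 * fam / rollup_bp)


@dataclass(frozen=True)
class GeneIsland:
    offset_5prime: int
    span: int
    n_genes: int


def gene_island(genes: Sequence[GeneRecord]) -> GeneIsland:
    """Island geometry: offset = first gene start; span = last end - first start.

    The span is a coordinate difference (not an inclusive length), matching the
    usual "island of X bp located Y bp from the 5' end" arithmetic.
    """
    if not genes:
        raise ValueError("need at least one gene")
    first = min(g.start for g in genes)
    last = max(g.end for g in genes)
    return GeneIsland(offset_5prime=first, span=last - first, n_genes=len(genes))


def gene_density(total_len: int, n_genes: int) -> int:
    """One gene per this many kb, rounded to the nearest integer."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    return int(_round_half_up(total_len / n_genes / 1000.0, digits=0))


def protein_length_from_cds(g: GeneRecord) -> int:
    """Residue count of the protein encoded by an intronless CDS ``start..end``
    that includes the terminal stop codon."""
    span = g.span_bp
    if span % 3 != 0:
        raise ValueError(f"{g.name}: CDS span {span} bp is not a codon multiple")
    return span // 3 - 1


def _clean_primer(p: str) -> str:
    p = "".join(p.split()).replace("-", "").upper()
    if len(p) < 15:
        raise ValueError(f"primer too short after cleanup: {p!r} ({len(p)} nt)")
    if set(p) - set("ACGT"):
        raise ValueError(f"primer {p!r} has non-ACGT characters")
    return p


def insilico_pcr(template: NucSequence, fwd: str, rev: str,
                 max_product: int = 5000) -> list[int]:
    """Exact-match in-silico PCR: product lengths for every fwd site paired with
    every downstream reverse-complemented rev site, up to ``max_product`` bp.

    Primers may be written with hyphens/whitespace ("ccaga-taccc-..." style);
    matching is case-insensitive and exact (no mismatches).
    """
    fwd = _clean_primer(fwd)
    rev_site = revcomp(_clean_primer(rev))
    seq = template.residues
    fwd_starts = _find_all(seq, fwd)          # 0-based
    rev_ends = [p + len(rev_site) for p in _find_all(seq, rev_site)]  # 0-based excl
    products = []
    for fs in fwd_starts:
        for re_ in rev_ends:
            length = re_ - fs  # == 1-based end - 1-based start + 1
            if len(fwd) <= length <= max_product and re_ - len(rev_site) >= fs:
                products.append(length)
    return sorted(products)


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out
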