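#!/usr/bin/env python
"""Composition accounting of the 113.6-kb wheat BAC clone annotation.

Aggregates the bundled element/gene tables into category fractions, the
gene-island geometry, gene density and CDS-derived protein lengths, and prints
the headline numbers; the full rollup table goes to results/composition.tsv.
"""

from importlib import resources
from pathlib import Path

from retroclock import (
    composition_report,
    fraction_within,
    gene_density,
    gene_island,
    protein_length_from_cds,
)
from retroclock.io_formats import read_annotation_table, read_gene_table

BAC_LEN = 113_605

data = resources.files("retroclock") / "data"
with resources.as_file(data / "bac_2383A24_elements.tsv") as p:
    records = read_annotation_table(p)
with resources.as_file(data / "bac_2383A24_genes.tsv") as p:
    genes = read_gene_table(p)

rep = composition_report(records, BAC_LEN)
Path("results").mkdir(exist_ok=True)
with open("results/composition.tsv", "w") as fh:
    fh.write(f"# clone length {BAC_LEN} bp\n")
    fh.write("# rollup\tcopies\tlength_bp\tfraction_pct\n")
    for name, tot in rep.rollups.items():
        fh.write(f"{name}\t{tot.copies}\t{tot.length_bp}\t{tot.fraction_pct}\n")

ltr_bp = rep.rollups["LTR retrotransposons"].length_bp
isl = gene_island(genes)
print(f"clone length {BAC_LEN} bp")
print(f"class I retrotransposons: {rep.fraction('class I')}% "
      f"(LTR retrotransposons {rep.fraction('LTR retrotransposons')}%, "
      f"gypsy {rep.fraction('gypsy')}%, copia {rep.fraction('copia')}%)")
print(f"Fatima family share of LTR retrotransposons: "
      f"{fraction_within(records, 'RLG_Fatima', ltr_bp)}%")
print(f"TE total {rep.fraction('TE total')}% (bp-based); "
      f"unassigned {rep.fraction('unassigned')}%")
print(f"tandem repeats (Spelt1): {rep.fraction('tandem repeats')}% "
      f"({rep.rollups['tandem repeats'].length_bp} bp)")
print(f"gene island: {isl.n_genes} genes, span {isl.span} bp, "
      f"{isl.offset_5prime} bp from the 5' end")
print(f"gene density: one gene per {gene_density(BAC_LEN, len(genes))} kb")
print("protein lengths: " + ", ".join(
    f"{g.name}={protein_length_from_cds(g)} aa" for g in genes))
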