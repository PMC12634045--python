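"""Score codon consequences and residue-class significance of A-to-I edits.

Loads the bundled catalog of conserved-residue missense edits from larval
motoneurons and re-derives each row's amino-acid change from its codon,
flagging substitutions that cross residue classes (positive/negative/
hydrophobic/polar/phospho/structural).
"""

from scedit import GeneModel, classify_significance, codon_effect, load_conserved_missense

catalog = load_conserved_missense()
print(f"catalog rows: {len(catalog)}")

n_significant = 0
for row in catalog.itertuples(index=False):
    (idx,) = [i for i in range(3) if row.original_codon[i] != row.edited_codon[i]]
    gene = GeneModel(gene_id=row.gene, chrom="t", strand="+", utr5=(),
                     cds=((1, 6),), utr3=(), cds_sequence=row.original_codon + "TAA")
    eff = codon_effect(gene, idx + 1, row.edited_codon[idx])
    n_significant += eff.significant

print(f"significant missense changes: {n_significant}")
print(f"conserved through mammals: {(catalog['conservation'] == 'Mammals').sum()}")
print(f"not previously annotated:  {(catalog['previously_annotated'] == 'No').sum()}")

example = catalog.iloc[0]
print(f"\nexample: {example.gene} {example.position}: "
      f"{example.original_codon}->{example.edited_codon} "
      f"({example.original_aa}>{example.edited_aa}), "
      f"significant={classify_significance(example.original_aa, example.edited_aa)}")
# a phospho-class serine becoming a structural glycine is the archetypal
# disruptive edit in this catalog
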