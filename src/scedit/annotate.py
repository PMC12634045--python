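"""Strand correction, edit classification, region/codon consequence calling.

A-to-I editing deaminates adenosine on the transcript's sense strand; reads
are aligned to the plus strand of the genome, so an edit in a minus-strand
gene surfaces as a T-to-C genomic mismatch.  Everything downstream of calling
therefore works on sense-corrected bases: minus-strand changes are listed as
their complement.
"""

from __future__ import annotations

from typing import Mapping

from Bio.Seq import Seq

from .io import EditSite, CodonEffect, GeneModel, ValidationError

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: residue classes used to score whether a missense change is disruptive:
#: substitutions *between* classes are significant, within a class are not.
RESIDUE_CLASSES: Mapping[str, frozenset] = {
    "positive": frozenset("RK"),
    "negative": frozenset("DE"),
    "hydrophobic": frozenset("AVILMFYW"),
    "polar": frozenset("NQ"),
    "phospho": frozenset("ST"),
    "structural": frozenset("CGPH"),
}

_STANDARD_TABLE = 1  # standard nuclear genetic code


def residue_class(aa: str, scheme: Mapping[str, frozenset] = RESIDUE_CLASSES) -> str:
    for name, members in scheme.items():
        if aa in members:
            return name
    raise ValidationError(f"unknown residue {aa!r}")


def orient_to_sense(ref_base: str, alt_base: str, strand: str) -> tuple[str, str]:
    """Map plus-strand observed bases onto the gene's sense strand.

    Plus strand is the identity; minus strand complements each base (the
    coordinate is unchanged, so no reversal is involved).
    """
    for b in (ref_base, alt_base):
        if b not in _COMPLEMENT:
            raise ValidationError(f"invalid base {b!r}")
    if strand == "+":
        return ref_base, alt_base
    if strand == "-":
        return _COMPLEMENT[ref_base], _COMPLEMENT[alt_base]
    raise ValidationError(f"invalid strand {strand!r}")


def classify_edit_type(sense_ref: str, sense_alt: str) -> str:
    """Canonical A>G (ADAR) vs the noncanonical classes on sense bases."""
    pair = (sense_ref, sense_alt)
    if pair == ("A", "G"):
        return "canonical_AtoG"
    if pair == ("C", "T"):
        return "noncanonical_CtoT"
    if pair == ("G", "A"):
        return "noncanonical_GtoA"
    return "noncanonical_other"


def assign_region(pos: int, gene: GeneModel) -> str:
    """5UTR / CDS / 3UTR membership of an exonic position.

    The utr5/utr3 fields already carry 5'/3' identity in sense terms, so
    membership lookup needs no strand flip here; strand matters when the
    intervals are built (a minus-strand gene's 5'UTR has the highest genomic
    coordinates).
    """
    for region, ivs in (("5UTR", gene.utr5), ("CDS", gene.cds), ("3UTR", gene.utr3)):
        if any(s <= pos <= e for s, e in ivs):
            return region
    raise ValidationError(f"{gene.gene_id}: position {pos} is not exonic")


def cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the sense-oriented CDS."""
    plus_offset = 0
    for s, e in gene.cds:
        if s <= pos <= e:
            plus_offset += pos - s
            break
        plus_offset += e - s + 1
    else:
        raise ValidationError(f"{gene.gene_id}: position {pos} not in CDS")
    if gene.strand == "+":
        return plus_offset
    return len(gene.cds_sequence) - 1 - plus_offset


def transcript_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of an exonic position along the transcript (5'->3')."""
    exons = gene.exons
    plus_offset = 0
    for s, e in exons:
        if s <= pos <= e:
            plus_offset += pos - s
            break
        plus_offset += e - s + 1
    else:
        raise ValidationError(f"{gene.gene_id}: position {pos} not exonic")
    if gene.strand == "+":
        return plus_offset
    total = sum(e - s + 1 for s, e in exons)
    return total - 1 - plus_offset


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=_STANDARD_TABLE))


def codon_effect(gene: GeneModel, pos: int, sense_alt: str) -> CodonEffect:
    """Consequence of substituting ``sense_alt`` at a CDS position.

    Each edit is evaluated as a single substitution against the reference
    CDS; edits sharing a codon are scored independently (see
    :func:`combined_codon_effects` for the joint variants).
    """
    off = cds_offset(gene, pos)
    seq = gene.cds_sequence
    codon_start = (off // 3) * 3
    original = seq[codon_start : codon_start + 3]
    within = off % 3
    edited = original[:within] + sense_alt + original[within + 1 :]
    if edited == original:
        raise ValidationError(f"{gene.gene_id}:{pos} substitution does not change the codon")
    original_aa = translate_codon(original)
    edited_aa = translate_codon(edited)
    if original_aa == edited_aa:
        effect = "silent"
    elif original_aa == "*":
        effect = "stop_loss"
    elif edited_aa == "*":
        effect = "stop_gain"
    else:
        effect = "missense"
    significant = False
    if effect == "missense":
        significant = classify_significance(original_aa, edited_aa)
    elif effect == "stop_loss":
        significant = True  # read-through always alters the protein C-terminus
    return CodonEffect(
        original_codon=original,
        edited_codon=edited,
        original_aa=original_aa,
        edited_aa=edited_aa,
        effect=effect,
        significant=significant,
    )


def combined_codon_effects(gene: GeneModel, edits: list[tuple[int, str]]) -> dict:
    """Joint codon variants when several edited positions share one codon.

    Adjacent edited adenosines (as in the complexin N130 codon) can occur on
    the same molecule; with no read-level phasing available the output is
    count-free: every combination of the single edits is enumerated and the
    resulting codon/amino acid reported.
    """
    by_codon: dict[int, list[tuple[int, str]]] = {}
    for pos, alt in edits:
        off = cds_offset(gene, pos)
        by_codon.setdefault(off // 3, []).append((off % 3, alt))
    out = {}
    for codon_idx, subs in by_codon.items():
        original = gene.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3]
        variants = {}
        for mask in range(1, 2 ** len(subs)):
            codon = list(original)
            for bit, (within, alt) in enumerate(subs):
                if mask >> bit & 1:
                    codon[within] = alt
            var = "".join(codon)
            variants[var] = translate_codon(var)
        out[codon_idx] = {"original": original, "original_aa": translate_codon(original), "variants": variants}
    return out


def classify_significance(
    original_aa: str, edited_aa: str, scheme: Mapping[str, frozenset] = RESIDUE_CLASSES
) -> bool:
    """True iff the substitution crosses between residue classes."""
    return residue_class(original_aa, scheme) != residue_class(edited_aa, scheme)


def annotate_conservation(original_aa: str, orthologue_residues: Mapping[str, tuple[str, str]]) -> str:
    """Conservation label from an orthologue-residue table.

    ``orthologue_residues`` maps taxon -> (group, residue) with group in
    {insect, mammal}.  The unedited residue is conserved in mammals if every
    mammalian entry matches it (mammal label takes precedence), in insects if
    every insect entry matches; otherwise 'none'.
    """
    if not orthologue_residues:
        return "none"
    mammals = [r for g, r in orthologue_residues.values() if g == "mammal"]
    insects = [r for g, r in orthologue_residues.values() if g == "insect"]
    if mammals and all(r == original_aa for r in mammals):
        return "mammals"
    if insects and all(r == original_aa for r in insects):
        return "insects"
    return "none"


def annotate_sites(
    sites: list[EditSite],
    gene_models: Mapping[str, GeneModel],
) -> list[dict]:
    """Per-site functional annotation rows (codon consequence for CDS sites)."""
    rows = []
    for s in sites:
        gene = gene_models[s.gene_id]
        row = {
            "chrom": s.chrom,
            "pos": s.pos,
            "gene_id": s.gene_id,
            "region": s.region,
            "edit_class": s.edit_class,
            "sense_change": f"{s.sense_ref}>{s.sense_alt}",
        }
        if s.region == "CDS":
            eff = codon_effect(gene, s.pos, s.sense_alt)
            row.update(
                original_codon=eff.original_codon,
                edited_codon=eff.edited_codon,
                original_aa=eff.original_aa,
                edited_aa=eff.edited_aa,
                effect=eff.effect,
                significant=eff.significant,
            )
        rows.append(row)
    return rows
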