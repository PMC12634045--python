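"""Domain types and readers/writers for the formats the pipeline touches.

Coordinates are 1-based with inclusive interval ends throughout, matching the
``chrom:start-end`` style used in genome browsers and the FlyBase annotation
this layout mirrors.  Only a narrow VCF dialect is consumed: CHROM/POS/REF/ALT/
QUAL and the per-sample AD (allele depth) field; everything else is ignored and
never required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
CELL_TYPES = ("Ib", "Is", "muscle", "other")

#: genomic interval, 1-based inclusive
Interval = tuple[int, int]


class ValidationError(ValueError):
    """A record violated a domain invariant."""


class ParseError(ValueError):
    """A file could not be interpreted in the expected dialect."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with 5'UTR/CDS/3'UTR intervals and its CDS sequence.

    ``cds_sequence`` is given in sense (mRNA) orientation: for minus-strand
    genes it is the reverse complement of the plus-strand reference slice.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    utr5: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    utr3: tuple[Interval, ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        for name in ("utr5", "cds", "utr3"):
            ivs = getattr(self, name)
            for (s, e) in ivs:
                if s > e:
                    raise ValidationError(f"{self.gene_id}: {name} interval {s}-{e} has start > end")
            for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
                if s1 <= e0:
                    raise ValidationError(f"{self.gene_id}: {name} intervals overlap or are unsorted")
        cds_len = sum(e - s + 1 for s, e in self.cds)
        if len(self.cds_sequence) != cds_len:
            raise ValidationError(
                f"{self.gene_id}: cds_sequence length {len(self.cds_sequence)} != CDS span {cds_len}"
            )
        if cds_len % 3 != 0:
            raise ValidationError(f"{self.gene_id}: CDS length {cds_len} is not a multiple of 3")

    @property
    def exons(self) -> tuple[Interval, ...]:
        """All exonic intervals (UTRs + CDS) sorted by genomic coordinate."""
        return tuple(sorted(self.utr5 + self.cds + self.utr3))

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    @property
    def span(self) -> Interval:
        ex = self.exons
        return (ex[0][0], ex[-1][1])


@dataclass(frozen=True)
class VariantObservation:
    """One cell's ALT/REF read counts at one genomic site (plus-strand bases)."""

    sample_id: str
    cell_type: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    ref_count: int
    alt_count: int
    qual: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValidationError(f"{self.chrom}:{self.pos} REF equals ALT ({self.ref_base})")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(f"{self.chrom}:{self.pos} negative read count")
        if self.cell_type not in CELL_TYPES:
            raise ValidationError(f"unknown cell type {self.cell_type!r}")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass
class ParentalSnpSet:
    """Genomic variation of one parental line: SNPs, indels and gDNA pileups."""

    line_id: str
    snps: set = field(default_factory=set)  # {(chrom, pos, alt_base)}
    indels: set = field(default_factory=set)  # {(chrom, pos)}
    gdna_pileups: dict = field(default_factory=dict)  # (chrom,pos) -> (ref_match, mismatch)

    @property
    def snp_positions(self) -> set:
        return {(c, p) for c, p, _ in self.snps}


EDIT_CLASSES = ("canonical_AtoG", "noncanonical_CtoT", "noncanonical_GtoA", "noncanonical_other")
REGIONS = ("5UTR", "CDS", "3UTR")


@dataclass
class EditSite:
    """A strand-corrected, annotated edit locus with per-cell editing rates.

    One EditSite is emitted per (locus, gene) pairing: a site inside exons of
    two overlapping genes yields two EditSite records sharing coordinates, so
    strand correction and region assignment stay unambiguous per gene.
    ``gene_ids`` lists every gene whose exon contains the locus; ``gene_ids[0]``
    is the gene this record is annotated against.
    """

    chrom: str
    pos: int
    gene_ids: list
    region: str
    genomic_ref: str
    genomic_alt: str
    sense_ref: str
    sense_alt: str
    edit_class: str
    per_cell_rates: dict = field(default_factory=dict)  # sample_id -> rate
    cell_types: dict = field(default_factory=dict)  # sample_id -> cell_type
    mean_rate_by_type: dict = field(default_factory=dict)
    previously_annotated: bool = False
    gdna_purity: float | None = None  # None = no gDNA coverage ("unknown", retained)

    def __post_init__(self) -> None:
        for sid, r in self.per_cell_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"{self.chrom}:{self.pos} rate {r} for {sid} outside [0,1]")
        if self.region not in REGIONS:
            raise ValidationError(f"{self.chrom}:{self.pos} bad region {self.region!r}")
        if self.edit_class not in EDIT_CLASSES:
            raise ValidationError(f"{self.chrom}:{self.pos} bad edit class {self.edit_class!r}")

    @property
    def n_cells_detected(self) -> int:
        return len(self.per_cell_rates)

    @property
    def gene_id(self) -> str:
        return self.gene_ids[0]

    @property
    def key(self):
        """Identity used when matching sites across catalogs/datasets."""
        return (self.chrom, self.pos, self.sense_ref, self.sense_alt)

    @property
    def mean_rate(self) -> float:
        """Mean editing rate over the cells contributing the edit."""
        return sum(self.per_cell_rates.values()) / len(self.per_cell_rates)


EFFECTS = ("silent", "missense", "stop_gain", "stop_loss")


@dataclass(frozen=True)
class CodonEffect:
    """Consequence of a single-base substitution inside a codon."""

    original_codon: str
    edited_codon: str
    original_aa: str
    edited_aa: str
    effect: str
    significant: bool = False

    def __post_init__(self) -> None:
        diffs = sum(a != b for a, b in zip(self.original_codon, self.edited_codon))
        if diffs != 1:
            raise ValidationError(
                f"codons {self.original_codon}->{self.edited_codon} differ at {diffs} positions"
            )
        if (self.effect == "silent") != (self.original_aa == self.edited_aa):
            raise ValidationError("effect 'silent' iff amino acid unchanged")
        if self.significant and self.effect not in ("missense", "stop_loss"):
            raise ValidationError("only missense/stop_loss changes can be significant")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_GENE_MODEL_COLUMNS = ["gene_id", "feature", "chrom", "strand", "start", "end"]
_FEATURE_FIELD = {"five_prime_UTR": "utr5", "CDS": "cds", "three_prime_UTR": "utr3"}


def read_fasta(path) -> dict:
    """Reference sequences as a name -> uppercase string mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_models(path, reference: Mapping[str, str] | str | Path) -> list[GeneModel]:
    """Read the flat TSV gene-model dialect plus a reference FASTA.

    The table carries one row per feature interval with columns
    gene_id / feature (five_prime_UTR, CDS, three_prime_UTR) / chrom / strand /
    start / end.  CDS sequence is extracted from the reference and
    reverse-complemented into sense orientation for minus-strand genes.
    """
    if not isinstance(reference, Mapping):
        reference = read_fasta(reference)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(_GENE_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing gene-model columns {sorted(missing)}")
    models = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        chroms = grp["chrom"].unique()
        strands = grp["strand"].unique()
        if len(chroms) != 1 or len(strands) != 1:
            raise ParseError(f"{gene_id}: inconsistent chrom/strand across feature rows")
        chrom, strand = chroms[0], strands[0]
        fields: dict = {"utr5": [], "cds": [], "utr3": []}
        for row in grp.itertuples(index=False):
            if row.feature not in _FEATURE_FIELD:
                raise ParseError(f"{gene_id}: unknown feature {row.feature!r}")
            start, end = int(row.start), int(row.end)
            if start > end:
                raise ParseError(f"{gene_id}: interval {start}-{end} has start > end")
            fields[_FEATURE_FIELD[row.feature]].append((start, end))
        for k in fields:
            fields[k] = tuple(sorted(fields[k]))
        if chrom not in reference:
            raise ParseError(f"{gene_id}: chrom {chrom!r} not in reference")
        seq = reference[chrom]
        cds_plus = "".join(seq[s - 1 : e] for s, e in fields["cds"])
        cds_sense = str(Seq(cds_plus).reverse_complement()) if strand == "-" else cds_plus
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                utr5=fields["utr5"],
                cds=fields["cds"],
                utr3=fields["utr3"],
                cds_sequence=cds_sense,
            )
        )
    return models


def _cell_type_of(sample_id: str, sample_types: Mapping[str, str] | None) -> str:
    if sample_types and sample_id in sample_types:
        return sample_types[sample_id]
    prefix = sample_id.split("_", 1)[0]
    return prefix if prefix in CELL_TYPES else "other"


def read_variant_table(path, sample_types: Mapping[str, str] | None = None) -> list[VariantObservation]:
    """Read per-cell variant observations from a VCF subset or a flat TSV.

    VCF: one observation per (sample, ALT); multi-allelic records split per
    the AD convention (AD = ref depth followed by one depth per ALT).  Samples
    lacking the AD field raise; REF==ALT records are logged and skipped.
    TSV: columns sample_id, cell_type, chrom, pos, ref, alt, ref_count,
    alt_count[, qual].

    Cell types default to the sample-id prefix before the first underscore
    ("Ib_007" -> Ib); a ``sample_types`` mapping overrides that convention.
    """
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt", ".csv"):
        return _read_variant_tsv(path)
    out: list[VariantObservation] = []
    with pysam.VariantFile(str(path)) as vcf:
        if "AD" not in vcf.header.formats:
            raise ParseError(f"{path}: VCF lacks the per-sample AD format field")
        for rec in vcf:
            alts = rec.alts or ()
            qual = float(rec.qual) if rec.qual is not None else 0.0
            for sample, call in rec.samples.items():
                ad = call.get("AD")
                if ad is None or all(v is None for v in ad):
                    continue
                ref_count = int(ad[0] or 0)
                for i, alt in enumerate(alts):
                    alt_count = int(ad[i + 1] or 0) if len(ad) > i + 1 else 0
                    if alt_count == 0:
                        continue
                    if alt == rec.ref:
                        logger.warning("%s:%s REF==ALT record skipped", rec.chrom, rec.pos)
                        continue
                    if rec.ref not in VALID_BASES or alt not in VALID_BASES:
                        logger.warning("%s:%s ambiguous base dropped (%s>%s)", rec.chrom, rec.pos, rec.ref, alt)
                        continue
                    out.append(
                        VariantObservation(
                            sample_id=sample,
                            cell_type=_cell_type_of(sample, sample_types),
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref_base=rec.ref,
                            alt_base=alt,
                            ref_count=ref_count,
                            alt_count=alt_count,
                            qual=qual,
                        )
                    )
    return out


def _read_variant_tsv(path) -> list[VariantObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    if df.empty:
        return []
    required = {"sample_id", "cell_type", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        if row.ref == row.alt:
            logger.warning("%s:%s REF==ALT record skipped", row.chrom, row.pos)
            continue
        out.append(
            VariantObservation(
                sample_id=row.sample_id,
                cell_type=row.cell_type,
                chrom=row.chrom,
                pos=int(row.pos),
                ref_base=row.ref,
                alt_base=row.alt,
                ref_count=int(row.ref_count),
                alt_count=int(row.alt_count),
                qual=float(getattr(row, "qual", 0.0)),
            )
        )
    return out


_SITE_COLUMNS = [
    "chrom", "pos", "gene_id", "all_gene_ids", "region",
    "genomic_ref", "genomic_alt", "sense_ref", "sense_alt", "edit_class",
    "n_cells_detected", "mean_rate", "mean_rate_by_type",
    "previously_annotated", "gdna_purity", "per_cell_rates",
]


def _fmt_rate(x: float) -> str:
    return format(x, ".6g")


def write_site_table(sites: Sequence[EditSite], path) -> None:
    """Write the edit-site catalog as a deterministic TSV.

    One row per (site, gene) record, sorted by (chrom, pos, gene_id); '.' for
    missing values.  The format round-trips bit-identically through
    :func:`read_site_table`.
    """
    rows = []
    for s in sorted(sites, key=lambda s: (s.chrom, s.pos, s.gene_id)):
        rates = ";".join(f"{sid}:{ct}:{_fmt_rate(r)}" for sid, ct, r in sorted(
            (sid, s.cell_types.get(sid, "other"), r) for sid, r in s.per_cell_rates.items()
        ))
        by_type = ";".join(f"{t}:{_fmt_rate(m)}" for t, m in sorted(s.mean_rate_by_type.items()))
        rows.append(
            [
                s.chrom, str(s.pos), s.gene_id, ",".join(s.gene_ids), s.region,
                s.genomic_ref, s.genomic_alt, s.sense_ref, s.sense_alt, s.edit_class,
                str(s.n_cells_detected), _fmt_rate(s.mean_rate) if s.per_cell_rates else ".",
                by_type or ".",
                "1" if s.previously_annotated else "0",
                _fmt_rate(s.gdna_purity) if s.gdna_purity is not None else ".",
                rates or ".",
            ]
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_site_table(path) -> list[EditSite]:
    """Read a site-table TSV written by :func:`write_site_table`."""
    sites = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SITE_COLUMNS:
            raise ParseError(f"{path}: unexpected site-table header")
        for line in fh:
            f = dict(zip(_SITE_COLUMNS, line.rstrip("\n").split("\t")))
            per_cell, cell_types = {}, {}
            if f["per_cell_rates"] != ".":
                for item in f["per_cell_rates"].split(";"):
                    sid, ct, r = item.rsplit(":", 2)
                    per_cell[sid] = float(r)
                    cell_types[sid] = ct
            by_type = {}
            if f["mean_rate_by_type"] != ".":
                for item in f["mean_rate_by_type"].split(";"):
                    t, m = item.rsplit(":", 1)
                    by_type[t] = float(m)
            sites.append(
                EditSite(
                    chrom=f["chrom"],
                    pos=int(f["pos"]),
                    gene_ids=f["all_gene_ids"].split(","),
                    region=f["region"],
                    genomic_ref=f["genomic_ref"],
                    genomic_alt=f["genomic_alt"],
                    sense_ref=f["sense_ref"],
                    sense_alt=f["sense_alt"],
                    edit_class=f["edit_class"],
                    per_cell_rates=per_cell,
                    cell_types=cell_types,
                    mean_rate_by_type=by_type,
                    previously_annotated=f["previously_annotated"] == "1",
                    gdna_purity=None if f["gdna_purity"] == "." else float(f["gdna_purity"]),
                )
            )
    return sites


def read_parental_vcf(path, line_id: str | None = None) -> ParentalSnpSet:
    """Parental genomic variants: single-base records become SNPs, records
    with length-changing alleles become indel positions."""
    path = Path(path)
    if line_id is None:
        line_id = path.stem.replace("parental_", "")
    snps, indels = set(), set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1:
                    snps.add((rec.chrom, rec.pos, alt))
                else:
                    indels.add((rec.chrom, rec.pos))
    return ParentalSnpSet(line_id=line_id, snps=snps, indels=indels)


def read_gdna_pileups(path) -> dict:
    """gDNA pileup TSV (line_id, chrom, pos, ref_match, mismatch) as
    line_id -> {(chrom, pos): (ref_match, mismatch)}."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.line_id, {})[(row.chrom, int(row.pos))] = (
            int(row.ref_match),
            int(row.mismatch),
        )
    return out


def load_parental_sets(directory) -> list[ParentalSnpSet]:
    """All parental_<line>.vcf files in a dataset directory, with gDNA
    pileups attached from gdna_pileups.tsv when present."""
    directory = Path(directory)
    sets = [read_parental_vcf(p) for p in sorted(directory.glob("parental_*.vcf"))]
    pileup_path = directory / "gdna_pileups.tsv"
    if pileup_path.exists():
        pileups = read_gdna_pileups(pileup_path)
        for ps in sets:
            ps.gdna_pileups = pileups.get(ps.line_id, {})
    return sets


def read_expression_table(path) -> pd.DataFrame:
    """Gene x sample TPM matrix; genes indexed by gene_id, all values >= 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative TPM values")
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")
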