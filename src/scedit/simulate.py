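"""Synthetic Patch-seq-like dataset with a known truth ledger.

The generator emulates the structure of single-cell editing data from two
larval motoneuron subtypes (tonic Ib and phasic Is, ~100 cells each) plus a
set of polynucleate muscle samples: genes on both strands, true per-site
editing rates spanning the detection threshold to 1 (including all-or-none
cells), parental-line SNPs and indels, negative-binomial read coverage scaled
by expression, and symmetric base-call error that creates the low-level
mismatch background the rate filter must remove.

Every draw flows from a single seeded generator, so identical configurations
produce identical datasets and exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .io import (
    GeneModel,
    ParentalSnpSet,
    ValidationError,
    VariantObservation,
    write_expression_table,
)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}
_CHROMS = ("2L", "2R", "3L", "3R", "X")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the toy dataset.

    Defaults mirror the sampled system: ~100 cells per neuronal subtype, mean
    read depth 40 at edited sites, per-site mean editing rates spanning the
    10% detection threshold to 1 with a population average near two-thirds,
    three sequenced parental lines, and a base miscall rate of 2e-3.
    """

    n_genes: int = 30
    frac_minus_strand: float = 0.4
    n_cells: Mapping[str, int] = field(default_factory=lambda: {"Ib": 100, "Is": 100, "muscle": 20})
    n_parental_lines: int = 3
    snp_rate: float = 1.5e-3
    n_indels: int = 5
    true_edit_sites: int = 50
    muscle_only_sites: int = 2
    muscle_active_fraction: float = 0.5
    muscle_rate_factor: float = 0.6
    rate_alpha: float = 2.0
    rate_beta: float = 1.2
    min_site_rate: float = 0.10
    cell_concentration: float = 8.0
    all_or_none_fraction: float = 0.15
    coverage_mean: float = 40.0
    coverage_dispersion: float = 3.0  # negative-binomial shape k
    coverage_expression_power: float = 0.3  # damped TPM->depth coupling
    error_rate: float = 2e-3
    canonical_fraction: float = 0.8
    rate_limiting: bool = False
    rate_limiting_tpm: float = 50.0
    overlapping_pair: bool = True
    utr5_length: int = 60
    cds_codons: int = 100
    utr3_length: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_minus_strand", "snp_rate", "muscle_active_fraction", "all_or_none_fraction",
            "error_rate", "canonical_fraction", "min_site_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0,1]")
        for name in ("n_genes", "true_edit_sites", "n_parental_lines", "n_indels", "muscle_only_sites"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.muscle_only_sites > self.true_edit_sites:
            raise ValidationError("muscle_only_sites cannot exceed true_edit_sites")


@dataclass
class TruthEdit:
    chrom: str
    pos: int
    gene_id: str
    strand: str
    region: str
    sense_ref: str
    sense_alt: str
    site_mean: float
    active_types: tuple
    true_rates: dict  # sample_id -> true per-cell rate


@dataclass
class TruthSet:
    """Simulator ledger: what was planted, for downstream oracle checks."""

    snps: dict  # line_id -> {(chrom, pos, alt)}
    indels: dict  # line_id -> {(chrom, pos)}
    edits: list  # of TruthEdit
    expression: pd.DataFrame  # gene x sample TPM used to scale coverage

    @property
    def edit_positions(self) -> set:
        return {(e.chrom, e.pos) for e in self.edits}

    @property
    def snp_positions(self) -> set:
        out = set()
        for s in self.snps.values():
            out |= {(c, p) for c, p, _ in s}
        return out


@dataclass
class ToyDataset:
    config: SimulationConfig
    reference: dict  # chrom -> sequence string
    gene_models: list
    parental_sets: list
    observations: list  # VariantObservation
    expression: pd.DataFrame
    truth: TruthSet


def _sense_base(ref: Mapping[str, str], gene: GeneModel, pos: int) -> str:
    b = ref[gene.chrom][pos - 1]
    return _COMPLEMENT[b] if gene.strand == "-" else b


def _gene_layout(config: SimulationConfig, rng: np.random.Generator):
    """Place genes (utr5+cds+utr3, no introns) along chromosomes with gaps.

    When ``overlapping_pair`` is set the last two genes of the first
    chromosome are placed on opposite strands with their 3'UTRs overlapping,
    to exercise the each-overlapping-gene listing rule.
    """
    gene_len = config.utr5_length + 3 * config.cds_codons + config.utr3_length
    per_chrom = math.ceil(config.n_genes / len(_CHROMS))
    layouts = []  # (gene_id, chrom, strand, start)
    n_minus = round(config.n_genes * config.frac_minus_strand)
    strands = ["-"] * n_minus + ["+"] * (config.n_genes - n_minus)
    rng.shuffle(strands)
    idx = 0
    for chrom in _CHROMS:
        cursor = 201
        for _ in range(per_chrom):
            if idx >= config.n_genes:
                break
            gid = f"g{idx:03d}"
            layouts.append([gid, chrom, strands[idx], cursor])
            cursor += gene_len + 200
            idx += 1
    if config.overlapping_pair and config.n_genes >= 2:
        # re-place gene 1 so its 3'UTR overlaps gene 0's 3'UTR on the other strand
        g0 = layouts[0]
        g1 = layouts[1]
        g0[2], g1[2] = "+", "-"
        overlap = min(config.utr3_length, 100)
        g1[3] = g0[3] + gene_len - config.utr3_length + (config.utr3_length - overlap)
        # shift subsequent genes on that chromosome clear of the new span
        end1 = g1[3] + gene_len
        for lay in layouts[2:]:
            if lay[1] == g1[1] and lay[3] <= end1 + 200:
                lay[3] = end1 + 201
                end1 = lay[3] + gene_len
    return layouts, gene_len


def _intervals_for(config: SimulationConfig, strand: str, start: int):
    u5, cds_len, u3 = config.utr5_length, 3 * config.cds_codons, config.utr3_length
    if strand == "+":
        utr5 = ((start, start + u5 - 1),)
        cds = ((start + u5, start + u5 + cds_len - 1),)
        utr3 = ((start + u5 + cds_len, start + u5 + cds_len + u3 - 1),)
    else:
        # transcription right-to-left: 5'UTR has the highest genomic coordinates
        utr3 = ((start, start + u3 - 1),)
        cds = ((start + u3, start + u3 + cds_len - 1),)
        utr5 = ((start + u3 + cds_len, start + u3 + cds_len + u5 - 1),)
    return utr5, cds, utr3


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Sense CDS: start codon, no internal stops, terminal stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def build_toy_dataset(config: SimulationConfig) -> ToyDataset:
    """Generate the full dataset plus its truth ledger (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    layouts, gene_len = _gene_layout(config, rng)

    # --- reference and gene models -------------------------------------
    chrom_len: dict[str, int] = {}
    for gid, chrom, strand, start in layouts:
        chrom_len[chrom] = max(chrom_len.get(chrom, 0), start + gene_len + 200)
    ref_arrays = {c: rng.choice(_BASES, size=n) for c, n in sorted(chrom_len.items())}

    gene_models = []
    for gid, chrom, strand, start in layouts:
        utr5, cds, utr3 = _intervals_for(config, strand, start)
        sense_cds = _random_cds(config.cds_codons, rng)
        plus_cds = sense_cds if strand == "+" else "".join(_COMPLEMENT[b] for b in reversed(sense_cds))
        s, e = cds[0]
        ref_arrays[chrom][s - 1 : e] = list(plus_cds)
        gene_models.append(
            GeneModel(gene_id=gid, chrom=chrom, strand=strand, utr5=utr5, cds=cds,
                      utr3=utr3, cds_sequence=sense_cds)
        )
    reference = {c: "".join(a) for c, a in ref_arrays.items()}
    # rebuild models against the final reference (overlap region may share bases)
    gene_models = [
        GeneModel(
            gene_id=g.gene_id, chrom=g.chrom, strand=g.strand, utr5=g.utr5, cds=g.cds,
            utr3=g.utr3,
            cds_sequence=_extract_cds(reference, g),
        )
        for g in gene_models
    ]
    by_gene = {g.gene_id: g for g in gene_models}

    # --- samples ---------------------------------------------------------
    samples: list[tuple[str, str]] = []  # (sample_id, cell_type)
    for cell_type, n in config.n_cells.items():
        samples.extend((f"{cell_type}_{i:03d}", cell_type) for i in range(n))
    sample_ids = [s for s, _ in samples]
    n_samples = len(samples)

    # --- parental SNPs and indels ---------------------------------------
    exonic: list[tuple[str, int, str]] = []  # (chrom, pos, gene_id)
    for g in gene_models:
        for s, e in g.exons:
            exonic.extend((g.chrom, p, g.gene_id) for p in range(s, e + 1))
    line_ids = [f"line{i + 1}" for i in range(config.n_parental_lines)]
    snp_mask = rng.random(len(exonic)) < config.snp_rate
    snp_positions = sorted({(exonic[i][0], exonic[i][1]) for i in np.flatnonzero(snp_mask)})
    snps_by_line: dict[str, set] = {l: set() for l in line_ids}
    snp_alt: dict[tuple, str] = {}
    for chrom, pos in snp_positions:
        refb = reference[chrom][pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != refb])
        snp_alt[(chrom, pos)] = alt
        carriers = [l for l in line_ids if rng.random() < 0.5]
        if not carriers:
            carriers = [line_ids[int(rng.integers(len(line_ids)))]]
        for l in carriers:
            snps_by_line[l].add((chrom, pos, alt))

    # --- true edit sites -------------------------------------------------
    taken = set(snp_positions)
    n_canonical = round(config.canonical_fraction * config.true_edit_sites)
    edits: list[TruthEdit] = []
    candidates = list(range(len(exonic)))
    rng.shuffle(candidates)
    from .annotate import assign_region, transcript_offset

    for i in candidates:
        if len(edits) == config.true_edit_sites:
            break
        chrom, pos, gid = exonic[i]
        if (chrom, pos) in taken:
            continue
        gene = by_gene[gid]
        region = assign_region(pos, gene)
        # keep planted edits clear of the excluded 5'UTR head and terminal stop codon
        if region == "5UTR" and transcript_offset(gene, pos) < 20:
            continue
        from .annotate import cds_offset
        if region == "CDS" and cds_offset(gene, pos) >= 3 * (config.cds_codons - 1):
            continue
        sense = _sense_base(reference, gene, pos)
        want_canonical = len(edits) < n_canonical
        if want_canonical:
            if sense != "A":
                continue
            sense_ref, sense_alt = "A", "G"
        else:
            if sense == "A":
                continue
            sense_ref = sense
            sense_alt = {"C": "T", "G": "A", "T": "G"}[sense]
        edits.append(
            TruthEdit(chrom=chrom, pos=pos, gene_id=gid, strand=gene.strand, region=region,
                      sense_ref=sense_ref, sense_alt=sense_alt, site_mean=0.0,
                      active_types=(), true_rates={})
        )
        taken.add((chrom, pos))
    if len(edits) < config.true_edit_sites:
        raise ValidationError(
            f"could not place {config.true_edit_sites} edit sites in the available exonic bases"
        )
    edits.sort(key=lambda e: (e.chrom, e.pos))

    # --- indels (kept clear of planted edits) ----------------------------
    indels_by_line: dict[str, set] = {l: set() for l in line_ids}
    window = 10
    indel_positions = []
    for i in candidates[::-1]:
        if len(indel_positions) == config.n_indels:
            break
        chrom, pos, gid = exonic[i]
        if (chrom, pos) in taken:
            continue
        if any(c == chrom and abs(p - pos) <= window + 1 for c, p in taken):
            continue
        indel_positions.append((chrom, pos))
        taken.add((chrom, pos))
    for chrom, pos in indel_positions:
        line = line_ids[int(rng.integers(len(line_ids)))]
        indels_by_line[line].add((chrom, pos))

    # --- expression ------------------------------------------------------
    gene_ids = [g.gene_id for g in gene_models]
    gene_mean_tpm = rng.lognormal(mean=math.log(30.0), sigma=1.2, size=len(gene_ids))
    noise = rng.gamma(shape=5.0, scale=0.2, size=(len(gene_ids), n_samples))
    tpm = gene_mean_tpm[:, None] * noise
    expression = pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)

    # --- per-site truth rates --------------------------------------------
    type_of = dict(samples)
    is_muscle = np.array([type_of[s] == "muscle" for s in sample_ids])
    for k, edit in enumerate(edits):
        raw = rng.beta(config.rate_alpha, config.rate_beta)
        site_mean = config.min_site_rate + (1.0 - config.min_site_rate) * raw
        muscle_only = k < config.muscle_only_sites
        muscle_active = muscle_only or (rng.random() < config.muscle_active_fraction)
        active_types = (
            ("muscle",) if muscle_only
            else (("Ib", "Is", "muscle") if muscle_active else ("Ib", "Is"))
        )
        conc = config.cell_concentration
        rates = np.empty(n_samples)
        allornone = rng.random(n_samples) < config.all_or_none_fraction
        rates[:] = rng.beta(site_mean * conc, (1.0 - site_mean) * conc, size=n_samples)
        rates[allornone] = (rng.random(int(allornone.sum())) < site_mean).astype(float)
        # polynucleate muscle samples average many nuclei: tighter spread, no all-or-none
        m_conc = conc * 4.0
        m_mean = min(1.0 - 1e-9, site_mean * config.muscle_rate_factor)
        rates[is_muscle] = rng.beta(m_mean * m_conc, (1.0 - m_mean) * m_conc, size=int(is_muscle.sum()))
        for j, sid in enumerate(sample_ids):
            if type_of[sid] not in active_types:
                rates[j] = 0.0
        if config.rate_limiting:
            g_tpm = expression.loc[edit.gene_id].to_numpy()
            rates = rates / (1.0 + g_tpm / config.rate_limiting_tpm)
        edit.site_mean = site_mean
        edit.active_types = active_types
        edit.true_rates = dict(zip(sample_ids, rates.tolist()))

    # --- read-count observations ----------------------------------------
    grand_mean_tpm = float(tpm.mean())
    k_disp = config.coverage_dispersion
    e = config.error_rate
    edit_at: dict[tuple, TruthEdit] = {(ed.chrom, ed.pos): ed for ed in edits}
    observations: list[VariantObservation] = []
    claimed: set = set()  # (chrom, pos) already emitted by an earlier (overlapping) gene
    for gi, g in enumerate(gene_models):
        positions = [p for s, epos in g.exons for p in range(s, epos + 1)]
        mu = config.coverage_mean * (tpm[gi] / grand_mean_tpm) ** config.coverage_expression_power
        mu = np.clip(mu, 1e-3, None)
        p_nb = k_disp / (k_disp + mu)
        depth = rng.negative_binomial(k_disp, p_nb[None, :], size=(len(positions), n_samples))
        p_alt = np.full((len(positions), n_samples), e)
        alt_base_row: dict[int, str] = {}
        skip_rows: set[int] = set()
        for ri, pos in enumerate(positions):
            key = (g.chrom, pos)
            if key in edit_at and edit_at[key].gene_id != g.gene_id:
                skip_rows.add(ri)  # locus emitted by the gene owning the edit
                continue
            if key in claimed:
                skip_rows.add(ri)  # overlap region emitted once, by the first gene
                continue
            claimed.add(key)
            if key in edit_at:
                ed = edit_at[key]
                r = np.array([ed.true_rates[s] for s in sample_ids])
                p_alt[ri] = r * (1.0 - e) + (1.0 - r) * e / 3.0
                sense_alt = ed.sense_alt
                alt_base_row[ri] = _COMPLEMENT[sense_alt] if g.strand == "-" else sense_alt
            elif key in snp_alt:
                p_alt[ri] = 1.0 - e  # near-fixed ALT in RNA of SNP carriers
                alt_base_row[ri] = snp_alt[key]
        alt = rng.binomial(depth, p_alt)
        rows, cols = np.nonzero(alt)
        err_choice = rng.integers(0, 3, size=len(rows))
        seq = reference[g.chrom]
        for ri, ci, choice in zip(rows.tolist(), cols.tolist(), err_choice.tolist()):
            if ri in skip_rows:
                continue
            pos = positions[ri]
            refb = seq[pos - 1]
            altb = alt_base_row.get(ri)
            if altb is None:
                altb = [b for b in "ACGT" if b != refb][choice]
            a = int(alt[ri, ci])
            observations.append(
                VariantObservation(
                    sample_id=sample_ids[ci],
                    cell_type=samples[ci][1],
                    chrom=g.chrom,
                    pos=pos,
                    ref_base=refb,
                    alt_base=altb,
                    ref_count=int(depth[ri, ci]) - a,
                    alt_count=a,
                    qual=min(10.0 * a, 99.0),
                )
            )

    # --- parental gDNA pileups -------------------------------------------
    pileup_sites = sorted(set(edit_at) | set(snp_alt) | set(p for p in indel_positions))
    parental_sets = []
    for line in line_ids:
        pileups = {}
        carried = {(c, p) for c, p, _ in snps_by_line[line]}
        for chrom, pos in pileup_sites:
            d = int(rng.poisson(60))
            if d == 0:
                continue
            if (chrom, pos) in carried:
                mismatch = d  # homozygous SNP: gDNA is all ALT
            else:
                mismatch = int(rng.binomial(d, e))
            pileups[(chrom, pos)] = (d - mismatch, mismatch)
        parental_sets.append(
            ParentalSnpSet(line_id=line, snps=set(snps_by_line[line]),
                           indels=set(indels_by_line[line]), gdna_pileups=pileups)
        )

    truth = TruthSet(snps=snps_by_line, indels=indels_by_line, edits=edits, expression=expression)
    return ToyDataset(config=config, reference=reference, gene_models=gene_models,
                      parental_sets=parental_sets, observations=observations,
                      expression=expression, truth=truth)


def _extract_cds(reference: Mapping[str, str], g: GeneModel) -> str:
    seq = reference[g.chrom]
    plus = "".join(seq[s - 1 : e] for s, e in g.cds)
    if g.strand == "-":
        plus = "".join(_COMPLEMENT[b] for b in reversed(plus))
    return plus


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(x, ".6g")


def export_dataset(dataset: ToyDataset, directory, overwrite: bool = False) -> dict:
    """Write the dataset as plain-text files readable by the package's readers.

    Emits reference.fasta, genes.tsv, parental_<line>.vcf, cells.vcf
    (multi-sample, AD per cell), expression.tsv, truth.tsv, and
    gdna_pileups.tsv (parental pileup counts used by the purity rule).
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    fasta = directory / "reference.fasta"
    with open(fasta, "w", encoding="utf-8") as fh:
        for chrom in sorted(dataset.reference):
            fh.write(f">{chrom}\n")
            seq = dataset.reference[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["reference"] = fasta

    genes = directory / "genes.tsv"
    with open(genes, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tfeature\tchrom\tstrand\tstart\tend\n")
        for g in sorted(dataset.gene_models, key=lambda g: g.gene_id):
            for feature, ivs in (("five_prime_UTR", g.utr5), ("CDS", g.cds), ("three_prime_UTR", g.utr3)):
                for s, e in ivs:
                    fh.write(f"{g.gene_id}\t{feature}\t{g.chrom}\t{g.strand}\t{s}\t{e}\n")
    paths["genes"] = genes

    for ps in dataset.parental_sets:
        p = directory / f"parental_{ps.line_id}.vcf"
        _write_parental_vcf(ps, dataset.reference, p)
        paths[f"parental_{ps.line_id}"] = p

    cells = directory / "cells.vcf"
    _write_cells_vcf(dataset, cells)
    paths["cells"] = cells

    expr = directory / "expression.tsv"
    write_expression_table(dataset.expression, expr)
    paths["expression"] = expr

    truth = directory / "truth.tsv"
    with open(truth, "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tgene_id\tstrand\tregion\tsense_ref\tsense_alt\t"
                 "site_mean\tactive_types\ttrue_rates\n")
        for ed in dataset.truth.edits:
            rates = ";".join(f"{s}:{_fmt(r)}" for s, r in sorted(ed.true_rates.items()))
            fh.write(
                f"{ed.chrom}\t{ed.pos}\t{ed.gene_id}\t{ed.strand}\t{ed.region}\t"
                f"{ed.sense_ref}\t{ed.sense_alt}\t{_fmt(ed.site_mean)}\t"
                f"{','.join(ed.active_types)}\t{rates}\n"
            )
    paths["truth"] = truth

    gdna = directory / "gdna_pileups.tsv"
    with open(gdna, "w", encoding="utf-8") as fh:
        fh.write("line_id\tchrom\tpos\tref_match\tmismatch\n")
        for ps in dataset.parental_sets:
            for (chrom, pos), (r, m) in sorted(ps.gdna_pileups.items()):
                fh.write(f"{ps.line_id}\t{chrom}\t{pos}\t{r}\t{m}\n")
    paths["gdna_pileups"] = gdna
    return paths


def _vcf_header(reference: Mapping[str, str], samples=()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted(reference):
        header.contigs.add(chrom, length=len(reference[chrom]))
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in samples:
        header.add_sample(s)
    return header


def _write_parental_vcf(ps: ParentalSnpSet, reference: Mapping[str, str], path) -> None:
    header = _vcf_header(reference, [ps.line_id])
    records = []
    for chrom, pos, alt in ps.snps:
        refb = reference[chrom][pos - 1]
        records.append((chrom, pos, refb, alt, "snp"))
    for chrom, pos in ps.indels:
        # single-base deletion anchored at pos
        anchor = reference[chrom][pos - 1 : pos + 1]
        records.append((chrom, pos, anchor, anchor[0], "indel"))
    records.sort(key=lambda r: (r[0], r[1]))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, pos, ref, alt, _kind in records:
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt), qual=99)
            rec.samples[ps.line_id]["AD"] = (0, 60)
            out.write(rec)


def _write_cells_vcf(dataset: ToyDataset, path) -> None:
    sample_ids = sorted({o.sample_id for o in dataset.observations}) or [
        f"{t}_{i:03d}" for t, n in dataset.config.n_cells.items() for i in range(n)
    ]
    header = _vcf_header(dataset.reference, sample_ids)
    by_site: dict[tuple, dict] = {}
    for o in dataset.observations:
        site = by_site.setdefault((o.chrom, o.pos, o.ref_base), {"alts": [], "calls": {}})
        if o.alt_base not in site["alts"]:
            site["alts"].append(o.alt_base)
        site["calls"][o.sample_id] = o
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref), site in sorted(by_site.items()):
            alts = sorted(site["alts"])
            qual = max(o.qual for o in site["calls"].values())
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=(ref, *alts), qual=qual)
            for sid, o in site["calls"].items():
                ad = [o.ref_count] + [0] * len(alts)
                ad[1 + alts.index(o.alt_base)] = o.alt_count
                rec.samples[sid]["AD"] = tuple(ad)
            out.write(rec)
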