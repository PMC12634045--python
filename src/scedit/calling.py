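"""High-confidence edit-site calling from per-cell DNA-RNA mismatches.

Candidate mismatches are first purged of genomic polymorphism (any SNP seen in
any parental line, and anything within an indel-proximity window), then pushed
through per-cell and per-site filters:

1. read depth at the site must exceed ``min_site_depth`` (default: keep > 10);
2. the variant QUAL must exceed ``min_qual`` (default 20);
3. the cell-level editing rate ALT/(REF+ALT) must exceed ``min_cell_rate``
   (default 0.10);
4. the site must be contributed by at least ``min_cells`` cells of at least
   one cell type (default 10);
5. pooled parental gDNA at the site must match the reference in at least
   ``min_gdna_ref_fraction`` of reads (default 0.96) — a latent-SNP guard.

Surviving sites must fall in an exon of at least one gene model (listed once
per overlapping gene) and, if in a 5'UTR, lie beyond the first
``utr5_start_exclusion`` transcribed nucleotides, where base-call artifacts
concentrate.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotate import assign_region, classify_edit_type, orient_to_sense, transcript_offset
from .io import EditSite, GeneModel, ParentalSnpSet, ValidationError, VariantObservation

logger = logging.getLogger(__name__)

_OPS = {">": operator.gt, ">=": operator.ge}


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the site-calling rules; comparators are configurable."""

    min_site_depth: int = 10
    depth_comparator: str = ">"  # keep if depth > min_site_depth
    min_qual: float = 20.0
    min_cell_rate: float = 0.10
    min_cells: int = 10
    min_gdna_ref_fraction: float = 0.96
    utr5_start_exclusion: int = 20
    indel_window: int = 10

    def __post_init__(self) -> None:
        if self.depth_comparator not in _OPS:
            raise ValidationError(f"depth_comparator must be one of {sorted(_OPS)}")
        for name in ("min_site_depth", "min_qual", "min_cells", "utr5_start_exclusion", "indel_window"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("min_cell_rate", "min_gdna_ref_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1]")


def subtract_parental_snps(
    observations: Iterable[VariantObservation],
    parental_sets: Sequence[ParentalSnpSet],
) -> list[VariantObservation]:
    """Drop any observation at a position carrying a SNP in any parental line."""
    if not parental_sets:
        logger.warning("no parental SNP sets supplied; no positions subtracted")
        return list(observations)
    snp_positions = set()
    for ps in parental_sets:
        snp_positions |= ps.snp_positions
    return [o for o in observations if (o.chrom, o.pos) not in snp_positions]


def filter_indel_proximity(
    observations: Iterable[VariantObservation],
    parental_sets: Sequence[ParentalSnpSet],
    window: int = 10,
) -> list[VariantObservation]:
    """Drop observations within ``window`` nt of any parental indel (|delta| <= window)."""
    indels: dict[str, list[int]] = {}
    for ps in parental_sets:
        for chrom, pos in ps.indels:
            indels.setdefault(chrom, []).append(pos)
    for chrom in indels:
        indels[chrom].sort()
    import bisect

    def near_indel(o: VariantObservation) -> bool:
        positions = indels.get(o.chrom)
        if not positions:
            return False
        i = bisect.bisect_left(positions, o.pos - window)
        return i < len(positions) and positions[i] <= o.pos + window

    return [o for o in observations if not near_indel(o)]


def editing_frequency(alt_count: int, ref_count: int) -> float:
    """Editing frequency ALT/(REF+ALT); undefined at zero total depth."""
    total = alt_count + ref_count
    if total <= 0:
        raise ValidationError("editing frequency undefined at zero depth")
    return alt_count / total


def gdna_purity(parental_sets: Sequence[ParentalSnpSet], chrom: str, pos: int) -> float | None:
    """Pooled gDNA reference-match fraction across parental lines; None if no coverage."""
    ref = mismatch = 0
    for ps in parental_sets:
        counts = ps.gdna_pileups.get((chrom, pos))
        if counts:
            ref += counts[0]
            mismatch += counts[1]
    if ref + mismatch == 0:
        return None
    return ref / (ref + mismatch)


def resolve_overlapping_genes(chrom: str, pos: int, gene_models: Sequence[GeneModel]) -> list[str]:
    """Every gene with an exon containing the position; empty means intergenic/intronic."""
    return [g.gene_id for g in gene_models if g.chrom == chrom and g.contains(pos)]


def apply_site_filters(
    observations: Iterable[VariantObservation],
    gene_models: Sequence[GeneModel],
    thresholds: FilterThresholds = FilterThresholds(),
    parental_sets: Sequence[ParentalSnpSet] = (),
    removal_log: list | None = None,
) -> list[EditSite]:
    """Run the per-cell and per-site rules and build the edit-site catalog.

    ``parental_sets`` supplies gDNA pileups for the purity rule; sites with no
    gDNA coverage are retained with purity None (flagged unknown).  A site in
    exons of several genes is emitted once per gene, with strand correction and
    region assigned against that gene.  ``removal_log`` (optional list)
    collects (chrom, pos, rule) entries for every removal.
    """
    depth_ok = _OPS[thresholds.depth_comparator]
    log = removal_log if removal_log is not None else []
    by_gene = {g.gene_id: g for g in gene_models}

    # cell-level rules 1-3
    grouped: dict[tuple, list[VariantObservation]] = {}
    for o in observations:
        key = (o.chrom, o.pos, o.ref_base, o.alt_base)
        if not depth_ok(o.depth, thresholds.min_site_depth):
            log.append((o.chrom, o.pos, "rule1_depth"))
            continue
        if not o.qual > thresholds.min_qual:
            log.append((o.chrom, o.pos, "rule2_qual"))
            continue
        if not editing_frequency(o.alt_count, o.ref_count) > thresholds.min_cell_rate:
            log.append((o.chrom, o.pos, "rule3_rate"))
            continue
        grouped.setdefault(key, []).append(o)

    sites: list[EditSite] = []
    for (chrom, pos, ref, alt), obs in sorted(grouped.items()):
        # rule 4: enough contributing cells of at least one type
        per_type: dict[str, int] = {}
        for o in obs:
            per_type[o.cell_type] = per_type.get(o.cell_type, 0) + 1
        if not any(n >= thresholds.min_cells for n in per_type.values()):
            log.append((chrom, pos, "rule4_cells"))
            continue
        # rule 5: pooled gDNA purity (unknown coverage retained, flagged)
        purity = gdna_purity(parental_sets, chrom, pos)
        if purity is not None and purity < thresholds.min_gdna_ref_fraction:
            log.append((chrom, pos, "rule5_gdna"))
            continue
        gene_ids = resolve_overlapping_genes(chrom, pos, gene_models)
        if not gene_ids:
            log.append((chrom, pos, "intergenic"))
            continue
        per_cell = {o.sample_id: editing_frequency(o.alt_count, o.ref_count) for o in obs}
        cell_types = {o.sample_id: o.cell_type for o in obs}
        by_type_rates: dict[str, list[float]] = {}
        for o in obs:
            by_type_rates.setdefault(o.cell_type, []).append(per_cell[o.sample_id])
        mean_by_type = {t: sum(v) / len(v) for t, v in by_type_rates.items()}
        for gene_id in gene_ids:
            gene = by_gene[gene_id]
            region = assign_region(pos, gene)
            if (
                region == "5UTR"
                and transcript_offset(gene, pos) < thresholds.utr5_start_exclusion
            ):
                log.append((chrom, pos, f"utr5_start:{gene_id}"))
                continue
            sense_ref, sense_alt = orient_to_sense(ref, alt, gene.strand)
            sites.append(
                EditSite(
                    chrom=chrom,
                    pos=pos,
                    gene_ids=[gene_id] + [g for g in gene_ids if g != gene_id],
                    region=region,
                    genomic_ref=ref,
                    genomic_alt=alt,
                    sense_ref=sense_ref,
                    sense_alt=sense_alt,
                    edit_class=classify_edit_type(sense_ref, sense_alt),
                    per_cell_rates=per_cell,
                    cell_types=cell_types,
                    mean_rate_by_type=mean_by_type,
                    gdna_purity=purity,
                )
            )
    return sites


def call_edit_sites(
    observations: Iterable[VariantObservation],
    gene_models: Sequence[GeneModel],
    parental_sets: Sequence[ParentalSnpSet],
    thresholds: FilterThresholds = FilterThresholds(),
    removal_log: list | None = None,
) -> list[EditSite]:
    """Full calling pipeline: SNP subtraction, indel proximity, site filters."""
    obs = subtract_parental_snps(observations, parental_sets)
    obs = filter_indel_proximity(obs, parental_sets, thresholds.indel_window)
    return apply_site_filters(
        obs, gene_models, thresholds, parental_sets=parental_sets, removal_log=removal_log
    )
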