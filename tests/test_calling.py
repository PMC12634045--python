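"""SNP subtraction, indel proximity, the five site filters and their
interaction properties."""

import numpy as np
import pytest

from scedit.calling import (
    FilterThresholds,
    apply_site_filters,
    call_edit_sites,
    editing_frequency,
    filter_indel_proximity,
    gdna_purity,
    resolve_overlapping_genes,
    subtract_parental_snps,
)
from scedit.io import GeneModel, ParentalSnpSet, ValidationError, VariantObservation


def _obs(pos=50, alt=20, ref=20, qual=99.0, sample="Ib_000", chrom="c"):
    return VariantObservation(
        sample_id=sample, cell_type=sample.split("_")[0], chrom=chrom, pos=pos,
        ref_base="A", alt_base="G", ref_count=ref, alt_count=alt, qual=qual,
    )


def _gene(chrom="c", start=1, strand="+"):
    # 5'UTR 30 nt, CDS 60 nt, 3'UTR 30 nt, contiguous
    cds = "ATG" + "GCT" * 18 + "TAA"
    if strand == "+":
        ivs = ((start, start + 29), (start + 30, start + 89), (start + 90, start + 119))
        utr5, c, utr3 = ivs
    else:
        utr3, c, utr5 = (
            (start, start + 29), (start + 30, start + 89), (start + 90, start + 119)
        )
    return GeneModel(gene_id=f"g{chrom}{start}{strand}", chrom=chrom, strand=strand,
                     utr5=(utr5,), cds=(c,), utr3=(utr3,), cds_sequence=cds)


class TestSnpSubtraction:
    def test_snp_in_any_line_removes_observation(self):
        obs = [_obs(pos=100), _obs(pos=200)]
        lines = [
            ParentalSnpSet("line1"),
            ParentalSnpSet("line2", snps={("c", 100, "G")}),
            ParentalSnpSet("line3"),
        ]
        kept = subtract_parental_snps(obs, lines)
        assert [o.pos for o in kept] == [200]

    def test_snp_free_position_retained(self):
        obs = [_obs(pos=300)]
        lines = [ParentalSnpSet("line1", snps={("c", 100, "T")})]
        assert subtract_parental_snps(obs, lines) == obs

    def test_no_truth_snp_survives_on_simulated_data(self, default_dataset):
        kept = subtract_parental_snps(
            default_dataset.observations, default_dataset.parental_sets
        )
        surviving = {(o.chrom, o.pos) for o in kept}
        assert not surviving & default_dataset.truth.snp_positions

    def test_commutes_with_indel_filter(self, small_dataset):
        obs = small_dataset.observations
        ps = small_dataset.parental_sets
        a = filter_indel_proximity(subtract_parental_snps(obs, ps), ps, 10)
        b = subtract_parental_snps(filter_indel_proximity(obs, ps, 10), ps)
        assert a == b


class TestIndelProximity:
    @pytest.mark.parametrize("pos,kept", [(510, False), (511, True), (490, False), (489, True)])
    def test_window_boundary_is_inclusive(self, pos, kept):
        lines = [ParentalSnpSet("line1", indels={("c", 500)})]
        out = filter_indel_proximity([_obs(pos=pos)], lines, window=10)
        assert bool(out) is kept

    def test_zero_window_keeps_everything_not_at_the_indel(self):
        lines = [ParentalSnpSet("line1", indels={("c", 500)})]
        assert filter_indel_proximity([_obs(pos=501)], lines, window=0)
        assert not filter_indel_proximity([_obs(pos=500)], lines, window=0)


class TestEditingFrequency:
    def test_arithmetic(self):
        assert editing_frequency(9, 1) == pytest.approx(0.9)
        assert editing_frequency(0, 25) == 0.0

    def test_zero_depth_is_undefined(self):
        with pytest.raises(ValidationError):
            editing_frequency(0, 0)

    def test_binomial_draw_recovers_probability(self):
        rng = np.random.default_rng(11)
        alt = int(rng.binomial(200, 0.45))
        f = editing_frequency(alt, 200 - alt)
        assert abs(f - 0.45) < 3 * np.sqrt(0.45 * 0.55 / 200)


class TestGdnaPurity:
    def test_pooled_fraction_against_cutoff(self):
        high = [ParentalSnpSet("l1", gdna_pileups={("c", 10): (97, 3)})]
        low = [ParentalSnpSet("l1", gdna_pileups={("c", 10): (95, 5)})]
        assert gdna_purity(high, "c", 10) == pytest.approx(0.97)
        assert gdna_purity(high, "c", 10) >= 0.96
        assert gdna_purity(low, "c", 10) == pytest.approx(0.95)
        assert gdna_purity(low, "c", 10) < 0.96

    def test_clean_site_is_pure(self):
        lines = [ParentalSnpSet("l1", gdna_pileups={("c", 10): (10, 0)})]
        assert gdna_purity(lines, "c", 10) == 1.0

    def test_no_coverage_returns_none(self):
        assert gdna_purity([ParentalSnpSet("l1")], "c", 10) is None


class TestSiteFilters:
    def test_nine_cells_per_type_is_not_enough(self):
        obs = [_obs(sample=f"Ib_{i:03d}") for i in range(9)]
        obs += [_obs(sample=f"Is_{i:03d}") for i in range(9)]
        gene = _gene()
        assert apply_site_filters(obs, [gene]) == []
        obs.append(_obs(sample="Ib_009"))
        (site,) = apply_site_filters(obs, [gene])
        assert site.n_cells_detected == 19

    def test_low_rate_cell_excluded_from_per_cell_rates(self):
        obs = [_obs(sample=f"Ib_{i:03d}") for i in range(10)]
        obs.append(_obs(sample="Ib_low", alt=2, ref=38))  # 5% editing
        (site,) = apply_site_filters(obs, [_gene()])
        assert "Ib_low" not in site.per_cell_rates
        assert all(r > 0.10 for r in site.per_cell_rates.values())

    def test_depth_rule_default_requires_more_than_ten_reads(self):
        ten = [_obs(sample=f"Ib_{i:03d}", alt=5, ref=5) for i in range(10)]
        assert apply_site_filters(ten, [_gene()]) == []
        eleven = [_obs(sample=f"Ib_{i:03d}", alt=6, ref=5) for i in range(10)]
        assert len(apply_site_filters(eleven, [_gene()])) == 1
        # Discussion-style comparator keeps depth == 10
        thr = FilterThresholds(depth_comparator=">=")
        assert len(apply_site_filters(ten, [_gene()], thr)) == 1

    def test_qual_rule(self):
        obs = [_obs(sample=f"Ib_{i:03d}", qual=20.0) for i in range(10)]
        assert apply_site_filters(obs, [_gene()]) == []

    def test_gdna_impurity_removes_site(self):
        obs = [_obs(pos=50, sample=f"Ib_{i:03d}") for i in range(10)]
        dirty = [ParentalSnpSet("l1", gdna_pileups={("c", 50): (95, 5)})]
        assert apply_site_filters(obs, [_gene()], parental_sets=dirty) == []
        clean = [ParentalSnpSet("l1", gdna_pileups={("c", 50): (97, 3)})]
        assert len(apply_site_filters(obs, [_gene()], parental_sets=clean)) == 1

    def test_unknown_gdna_coverage_retained_and_flagged(self):
        obs = [_obs(pos=50, sample=f"Ib_{i:03d}") for i in range(10)]
        (site,) = apply_site_filters(obs, [_gene()], parental_sets=[ParentalSnpSet("l1")])
        assert site.gdna_purity is None

    def test_intergenic_site_dropped_with_log(self):
        obs = [_obs(pos=5000, sample=f"Ib_{i:03d}") for i in range(10)]
        log = []
        assert apply_site_filters(obs, [_gene()], removal_log=log) == []
        assert ("c", 5000, "intergenic") in log

    def test_utr5_head_excluded_along_transcript(self):
        gene = _gene()  # plus strand: transcript starts at genomic 1
        near = [_obs(pos=15, sample=f"Ib_{i:03d}") for i in range(10)]
        far = [_obs(pos=25, sample=f"Ib_{i:03d}") for i in range(10)]
        assert apply_site_filters(near, [gene]) == []
        (site,) = apply_site_filters(far, [gene])
        assert site.region == "5UTR"

    def test_utr5_head_exclusion_honors_minus_strand(self):
        gene = _gene(strand="-")  # transcript starts at genomic 120
        near = [_obs(pos=110, sample=f"Ib_{i:03d}") for i in range(10)]  # 10 nt in
        far = [_obs(pos=95, sample=f"Ib_{i:03d}") for i in range(10)]  # 25 nt in
        assert apply_site_filters(near, [gene]) == []
        (site,) = apply_site_filters(far, [gene])
        assert site.region == "5UTR"
        # minus-strand A>G observation is reported as its sense complement
        assert (site.genomic_ref, site.genomic_alt) == ("A", "G")
        assert (site.sense_ref, site.sense_alt) == ("T", "C")


class TestOverlappingGenes:
    def test_position_in_exons_of_two_genes_lists_both(self):
        a = _gene(start=1)
        b = _gene(start=100)  # 3'UTR of a (91-120) overlaps 5'UTR head of b
        got = resolve_overlapping_genes("c", 110, [a, b])
        assert got == [a.gene_id, b.gene_id]

    def test_exon_of_one_gene_only(self):
        a = _gene(start=1)
        b = _gene(start=200)
        assert resolve_overlapping_genes("c", 210, [a, b]) == [b.gene_id]

    def test_no_exon_anywhere_is_empty(self):
        assert resolve_overlapping_genes("c", 150, [_gene(start=1)]) == []

    def test_overlap_site_emitted_once_per_gene(self):
        a = _gene(start=1)
        b = _gene(start=100)
        obs = [_obs(pos=110, sample=f"Ib_{i:03d}") for i in range(10)]
        sites = apply_site_filters(obs, [a, b])
        # position 110 is in a's 3'UTR but within the first 20 transcribed nt
        # of b, so only a's record survives the 5'UTR-head rule
        assert [s.gene_id for s in sites] == [a.gene_id]
        obs2 = [_obs(pos=120, sample=f"Ib_{i:03d}") for i in range(10)]
        sites2 = apply_site_filters(obs2, [a, b])
        assert sorted(s.gene_id for s in sites2) == sorted([a.gene_id, b.gene_id])
        assert {s.pos for s in sites2} == {120}


class TestFilterProperties:
    def test_monotonicity_raising_thresholds_never_adds_sites(self, small_dataset):
        obs = subtract_parental_snps(small_dataset.observations, small_dataset.parental_sets)
        base = FilterThresholds(min_cells=5)
        n_prev = None
        for cells in (3, 5, 8, 12):
            n = len(apply_site_filters(obs, small_dataset.gene_models,
                                       FilterThresholds(min_cells=cells)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n
        for rate in (0.05, 0.10, 0.3, 0.6):
            n = len(apply_site_filters(obs, small_dataset.gene_models,
                                       FilterThresholds(min_cells=5, min_cell_rate=rate)))
            if rate == 0.05:
                n_prev = n
            assert n <= n_prev
            n_prev = n

    def test_surviving_rates_strictly_exceed_threshold(self, default_sites):
        for s in default_sites:
            assert all(r > 0.10 for r in s.per_cell_rates.values())

    def test_truth_recall_and_no_error_sites(self, default_dataset, default_sites):
        called = {(s.chrom, s.pos) for s in default_sites}
        truth = default_dataset.truth.edit_positions
        assert len(called & truth) / len(truth) >= 0.9
        assert not called - truth  # nothing error- or SNP-derived survives

    def test_maxed_thresholds_empty_the_catalog(self, small_dataset):
        thr = FilterThresholds(min_site_depth=10_000, min_cells=10_000)
        assert call_edit_sites(small_dataset.observations, small_dataset.gene_models,
                               small_dataset.parental_sets, thr) == []
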