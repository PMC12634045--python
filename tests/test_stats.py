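"""Stochasticity statistics: summaries, ANOVA, clustering, correlations."""

import numpy as np
import pytest
from scipy import stats as sps

from scedit.io import EditSite, ValidationError
from scedit.stats import (
    SiteSummary,
    cell_profiles,
    cluster_span,
    expression_editing_correlation,
    fraction_cells_vs_rate,
    high_editing_sites,
    neighbor_fractions,
    normality_test,
    region_rate_comparison,
    region_fractions,
    summarize_sites,
)


def _site(pos, rates, region="CDS", gene="gA", chrom="c"):
    return EditSite(
        chrom=chrom, pos=pos, gene_ids=[gene], region=region,
        genomic_ref="A", genomic_alt="G", sense_ref="A", sense_alt="G",
        edit_class="canonical_AtoG", per_cell_rates=dict(rates),
        cell_types={k: k.split("_")[0] for k in rates},
        mean_rate_by_type={},
    )


def _summary(pos=1, chrom="c", rate=0.5, frac=0.5, region="CDS", gene="gA", by_type=None,
             frac_by_type=None):
    return SiteSummary(
        chrom=chrom, pos=pos, gene_id=gene, region=region, edit_class="canonical_AtoG",
        mean_rate=rate, mean_rate_by_type=by_type or {"Ib": rate},
        fraction_cells=frac, fraction_cells_by_type=frac_by_type or {"Ib": frac},
        n_cells_detected=int(frac * 10),
    )


class TestSummarizeSites:
    def test_mean_and_fraction_arithmetic(self):
        site = _site(10, {"Ib_000": 0.4, "Ib_001": 0.6})
        (s,) = summarize_sites([site], {"Ib": 10})
        assert s.mean_rate == pytest.approx(0.5)
        assert s.fraction_cells == pytest.approx(0.2)

    def test_single_cell_site(self):
        site = _site(10, {"Ib_000": 1.0})
        (s,) = summarize_sites([site], {"Ib": 10})
        assert s.mean_rate == 1.0 and s.fraction_cells == pytest.approx(0.1)

    def test_recovers_truth_mean_within_binomial_error(self):
        rng = np.random.default_rng(21)
        depth, n_cells, truth = 40, 100, 0.7
        rates = {f"Ib_{i:03d}": rng.binomial(depth, truth) / depth for i in range(n_cells)}
        (s,) = summarize_sites([_site(10, rates)], {"Ib": n_cells})
        se = np.sqrt(truth * (1 - truth) / (depth * n_cells))
        assert abs(s.mean_rate - truth) < 3 * se + 0.01


class TestRegionRateComparison:
    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(3)
        sums = []
        for i, region in enumerate(("5UTR", "CDS", "3UTR")):
            for j in range(40):
                sums.append(_summary(pos=i * 1000 + j, rate=rng.normal(0.6, 0.1), region=region))
        out = region_rate_comparison(sums)
        assert out["p"] > 0.05

    def test_separated_groups_flag_cds_vs_3utr(self):
        rng = np.random.default_rng(4)
        spec = {"CDS": 0.71, "3UTR": 0.59, "5UTR": 0.64}
        sums = []
        for i, (region, m) in enumerate(spec.items()):
            for j in range(60):
                sums.append(_summary(pos=i * 1000 + j, rate=rng.normal(m, 0.02), region=region))
        out = region_rate_comparison(sums)
        key = ("3UTR", "CDS") if ("3UTR", "CDS") in out["tukey_p"] else ("CDS", "3UTR")
        assert out["tukey_p"][key] < 0.05
        # F statistic agrees with an independent one-way ANOVA
        groups = {}
        for s in sums:
            groups.setdefault(s.region, []).append(s.mean_rate)
        f_ref, _ = sps.f_oneway(*groups.values())
        assert out["F"] == pytest.approx(f_ref)
        assert out["df_between"] == 2

    def test_identical_groups_give_zero_F(self):
        sums = [_summary(pos=p, rate=0.5, region=r) for r in ("CDS", "3UTR") for p in (1, 2, 3)]
        assert region_rate_comparison(sums)["F"] == pytest.approx(0.0)


class TestNormality:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(5).normal(size=500)
        assert normality_test(x)["p"] > 0.05

    def test_uniform_sample_fails(self):
        x = np.random.default_rng(5).uniform(size=500)
        assert normality_test(x)["p"] < 0.05

    def test_small_or_degenerate_samples_rejected(self):
        with pytest.raises(ValidationError):
            normality_test([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValidationError):
            normality_test([0.5] * 10)


class TestNeighborFractions:
    def test_two_close_sites_are_each_others_neighbors(self):
        sums = [_summary(pos=100), _summary(pos=108)]
        out = neighbor_fractions(sums)
        assert out["fractions"][10] == 1.0

    def test_distant_sites_have_zero_close_fraction(self):
        sums = [_summary(pos=p) for p in (1, 200, 400)]
        out = neighbor_fractions(sums)
        assert out["fractions"][100] == 0.0
        assert out["overflow_gt_100"] == 3

    def test_monotone_in_window_size(self, default_sites):
        from scedit.stats import summarize_sites as summ

        sums = summ(default_sites, {"Ib": 100, "Is": 100, "muscle": 20})
        out = neighbor_fractions(sums, windows=(5, 10, 50, 100, 500))
        vals = [out["fractions"][w] for w in (5, 10, 50, 100, 500)]
        assert vals == sorted(vals)

    def test_printed_cluster_span_convention(self):
        # 1-based inclusive coordinates: a 12-edit cluster bounded by
        # 4301140 and 4301258 spans 118 nt as max - min
        assert cluster_span([4301140, 4301258]) == 118


class TestCorrelations:
    def test_rate_limited_simulation_anticorrelates_with_expression(self):
        from scedit.calling import call_edit_sites
        from scedit.simulate import SimulationConfig, build_toy_dataset

        cfg = SimulationConfig(n_genes=20, n_cells={"Ib": 40, "Is": 40},
                               true_edit_sites=30, muscle_only_sites=0,
                               rate_limiting=True, seed=17)
        ds = build_toy_dataset(cfg)
        sites = call_edit_sites(ds.observations, ds.gene_models, ds.parental_sets)
        sums = summarize_sites(sites, {"Ib": 40, "Is": 40})
        out = expression_editing_correlation(sums, ds.expression)
        assert out["Ib"]["r"] < 0 and out["Is"]["r"] < 0

    def test_permuted_expression_decorrelates(self, default_dataset, default_sites):
        rng = np.random.default_rng(8)
        sums = summarize_sites(default_sites, {"Ib": 100, "Is": 100, "muscle": 20})
        expr = default_dataset.expression.copy()
        expr.index = rng.permutation(expr.index.to_numpy())
        out = expression_editing_correlation(sums, expr)
        assert abs(out["Ib"]["r"]) < 0.5  # no systematic relation survives

    def test_anti_ranked_toy_vectors(self):
        sums = [
            _summary(pos=i, rate=r, frac=f)
            for i, (r, f) in enumerate([(0.9, 0.1), (0.5, 0.5), (0.1, 0.9)])
        ]
        out = fraction_cells_vs_rate(sums)
        assert out["r"] == pytest.approx(-1.0)

    def test_constant_rates_undefined(self):
        sums = [_summary(pos=i, rate=0.5, frac=f) for i, f in enumerate((0.1, 0.5, 0.9))]
        with pytest.raises(ValidationError):
            fraction_cells_vs_rate(sums)

    def test_matches_reference_pearson_on_fixed_vectors(self):
        x = [0.12, 0.5, 0.33, 0.9, 0.71]
        y = [0.4, 0.1, 0.6, 0.2, 0.35]
        sums = [_summary(pos=i, rate=r, frac=f) for i, (f, r) in enumerate(zip(x, y))]
        r_ref = float(np.corrcoef(x, y)[0, 1])
        assert fraction_cells_vs_rate(sums)["r"] == pytest.approx(r_ref, abs=1e-10)


class TestCellProfiles:
    def test_single_cell_with_one_full_edit(self):
        (p,), _ = cell_profiles([_site(10, {"Ib_000": 1.0})])
        assert (p.n_edits, p.mean_rate) == (1, 1.0)

    def test_high_editor_cells_drive_negative_correlation(self):
        # cells editing fewer sites do so at higher rates
        rng = np.random.default_rng(9)
        sites = []
        n_cells = 60
        breadth = rng.integers(5, 40, size=n_cells)
        for pos in range(40):
            rates = {}
            for c in range(n_cells):
                if pos < breadth[c]:
                    level = 1.0 - breadth[c] / 50 + rng.normal(0, 0.03)
                    rates[f"Ib_{c:03d}"] = float(np.clip(level, 0.11, 1.0))
            if len(rates) >= 2:
                sites.append(_site(pos + 1, rates))
        _, corr = cell_profiles(sites)
        assert corr["n_edits_vs_mean_rate"]["r"] < -0.5

    def test_shuffled_adar_expression_is_uncorrelated(self, default_dataset, default_sites):
        rng = np.random.default_rng(10)
        expr = default_dataset.expression.copy()
        expr.loc["g000"] = rng.permutation(expr.loc["g000"].to_numpy())
        _, corr = cell_profiles(default_sites, expr, adar_gene="g000")
        assert abs(corr["adar_vs_mean_rate"]["r"]) < 0.25


class TestHighEditing:
    def test_strict_threshold_boundary(self):
        at = _summary(pos=1, by_type={"Ib": 0.90})
        above = _summary(pos=2, by_type={"Ib": 0.95})
        out = high_editing_sites([at, above])
        assert [s.pos for s in out["sites"]] == [2]

    def test_muscle_only_rates_do_not_count(self):
        s = _summary(pos=1, by_type={"muscle": 0.99})
        assert high_editing_sites([s])["n_sites"] == 0

    def test_fully_edited_truth_sites_recovered(self, default_dataset, default_sites):
        sums = summarize_sites(default_sites, {"Ib": 100, "Is": 100, "muscle": 20})
        high = {(s.chrom, s.pos) for s in high_editing_sites(sums, threshold=0.9)["sites"]}
        for e in default_dataset.truth.edits:
            if not {"Ib", "Is"} & set(e.active_types):
                continue
            neuron_rates = [r for sid, r in e.true_rates.items()
                            if not sid.startswith("muscle")]
            if np.mean(neuron_rates) > 0.97:
                assert (e.chrom, e.pos) in high


class TestRegionFractions:
    def test_fractions_sum_to_one(self, default_sites):
        sums = summarize_sites(default_sites, {"Ib": 100, "Is": 100, "muscle": 20})
        out = region_fractions(sums)
        assert sum(out.values()) == pytest.approx(1.0)
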