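"""Single-cell editing statistics: site/cell summaries, region comparison,
proximity clustering, expression anticorrelation and high-editing detection.

Site-level editing rate is always the mean over the cells *contributing* the
edit, while ``fraction_cells`` is computed against the full number of sampled
cells of that type — the two axes are deliberately distinct (a rarely
detected site can still be fully edited in the cells that carry it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import EditSite, ValidationError


@dataclass
class SiteSummary:
    """Per-site summary across the sampled cell population."""

    chrom: str
    pos: int
    gene_id: str
    region: str
    edit_class: str
    mean_rate: float
    mean_rate_by_type: dict
    fraction_cells: float
    fraction_cells_by_type: dict
    n_cells_detected: int
    nearest_neighbor_distance: float = float("nan")


@dataclass
class CellProfile:
    sample_id: str
    cell_type: str
    n_edits: int
    mean_rate: float
    adar_tpm: float = float("nan")


def summarize_sites(
    sites: Sequence[EditSite], n_sampled_by_type: Mapping[str, int]
) -> list[SiteSummary]:
    """Per-site mean rates (overall and per type) and detection fractions.

    ``n_sampled_by_type`` gives the full sampled-cell denominator per cell
    type (e.g. 100 Ib cells), independent of how many covered the site.
    """
    out = []
    total = sum(n_sampled_by_type.values())
    for s in sites:
        by_type_n: dict[str, int] = {}
        for sid in s.per_cell_rates:
            t = s.cell_types.get(sid, "other")
            by_type_n[t] = by_type_n.get(t, 0) + 1
        frac_by_type = {
            t: by_type_n.get(t, 0) / n for t, n in n_sampled_by_type.items() if n > 0
        }
        out.append(
            SiteSummary(
                chrom=s.chrom,
                pos=s.pos,
                gene_id=s.gene_id,
                region=s.region,
                edit_class=s.edit_class,
                mean_rate=s.mean_rate,
                mean_rate_by_type=dict(s.mean_rate_by_type),
                fraction_cells=s.n_cells_detected / total if total else float("nan"),
                fraction_cells_by_type=frac_by_type,
                n_cells_detected=s.n_cells_detected,
            )
        )
    return out


def region_rate_comparison(summaries: Sequence[SiteSummary]) -> dict:
    """One-way ANOVA of per-site mean rates across mRNA regions, with
    Tukey-Kramer pairwise post-hoc p-values."""
    groups: dict[str, list[float]] = {}
    for s in summaries:
        groups.setdefault(s.region, []).append(s.mean_rate)
    usable = {r: v for r, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValidationError("need >=2 regions with >=2 sites each")
    order = sorted(usable)
    values = [usable[r] for r in order]
    flat_all = np.concatenate(values)
    if np.ptp(flat_all) == 0:
        f_stat, p = 0.0, 1.0  # identical groups: no variance anywhere
    else:
        f_stat, p = sps.f_oneway(*values)
    flat = np.concatenate(values)
    labels = np.concatenate([[r] * len(usable[r]) for r in order])
    from itertools import combinations

    if np.ptp(flat_all) == 0:
        pairs = {(a, b): 1.0 for a, b in combinations(order, 2)}
    else:
        tukey = pairwise_tukeyhsd(flat, labels)
        pairs = {
            (str(a), str(b)): float(pv)
            for (a, b), pv in zip(combinations(tukey.groupsunique, 2), tukey.pvalues)
        }
    return {
        "F": float(f_stat),
        "p": float(p),
        "df_between": len(order) - 1,
        "group_means": {r: float(np.mean(usable[r])) for r in order},
        "tukey_p": pairs,
    }


def normality_test(rates: Sequence[float]) -> dict:
    """One-sample Kolmogorov-Smirnov test against a normal with the sample's
    mean and standard deviation."""
    x = np.asarray(rates, dtype=float)
    if x.size < 5:
        raise ValidationError("KS normality test needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("degenerate sample: zero variance")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return {"ks_stat": float(stat), "p": float(p)}


def nearest_neighbor_distances(summaries: Sequence[SiteSummary]) -> np.ndarray:
    """Nearest same-chromosome neighbor distance |delta pos| per site; NaN for
    sites alone on their chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for s in summaries:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    dist_at: dict[tuple, float] = {}
    for chrom, positions in by_chrom.items():
        ps = sorted(set(positions))
        if len(ps) == 1:
            dist_at[(chrom, ps[0])] = float("nan")
            continue
        for i, p in enumerate(ps):
            cands = []
            if i > 0:
                cands.append(p - ps[i - 1])
            if i < len(ps) - 1:
                cands.append(ps[i + 1] - p)
            dist_at[(chrom, p)] = float(min(cands))
    return np.array([dist_at[(s.chrom, s.pos)] for s in summaries])


def neighbor_fractions(
    summaries: Sequence[SiteSummary], windows: Sequence[int] = (10, 100)
) -> dict:
    """Fraction of sites with a neighboring site within each window, plus a
    distance histogram truncated at 100 nt with an overflow bin."""
    if len(summaries) < 2:
        raise ValidationError("need >= 2 sites for neighbor analysis")
    d = nearest_neighbor_distances(summaries)
    finite = d[~np.isnan(d)]
    fractions = {int(w): float(np.mean(finite <= w)) if finite.size else float("nan")
                 for w in windows}
    edges = np.arange(0, 101, 10)
    hist, _ = np.histogram(finite, bins=edges)
    overflow = int(np.sum(finite > 100))
    return {
        "fractions": fractions,
        "histogram_edges": edges.tolist(),
        "histogram": hist.tolist(),
        "overflow_gt_100": overflow,
        "distances": d,
    }


def cluster_span(positions: Sequence[int]) -> int:
    """Genomic span of a cluster of sites as max - min (1-based inclusive
    coordinates: the span counts the nucleotides *between* the endpoints)."""
    positions = list(positions)
    if not positions:
        raise ValidationError("empty position list")
    return int(max(positions) - min(positions))


def expression_editing_correlation(
    summaries: Sequence[SiteSummary],
    expression: pd.DataFrame,
    cell_types: Sequence[str] = ("Ib", "Is"),
    sample_types: Mapping[str, str] | None = None,
    log_transform: bool = True,
) -> dict:
    """Pearson correlation of per-site editing rate with target-gene
    expression, per cell type.

    Expression is joined on the mean TPM of the site's gene over that type's
    samples, log10(TPM+1)-transformed by default.
    """
    if sample_types is None:
        sample_types = {c: c.split("_", 1)[0] for c in expression.columns}
    out = {}
    for ct in cell_types:
        cols = [c for c in expression.columns if sample_types.get(c) == ct]
        if not cols:
            continue
        gene_tpm = expression[cols].mean(axis=1)
        xs, ys = [], []
        for s in summaries:
            rate = s.mean_rate_by_type.get(ct)
            if rate is None or s.gene_id not in gene_tpm.index:
                continue
            t = float(gene_tpm[s.gene_id])
            xs.append(np.log10(t + 1.0) if log_transform else t)
            ys.append(rate)
        if len(xs) < 3:
            raise ValidationError(f"{ct}: <3 sites join to expression")
        r, p = sps.pearsonr(xs, ys)
        out[ct] = {"r": float(r), "r2": float(r * r), "p": float(p), "n": len(xs)}
    return out


def cell_profiles(
    sites: Sequence[EditSite],
    expression: pd.DataFrame | None = None,
    adar_gene: str | None = None,
) -> tuple[list[CellProfile], dict]:
    """Per-cell edit counts and mean rates, with the rate-vs-breadth and
    rate-vs-Adar correlations.

    The negative n_edits/mean_rate correlation is the signature of cells that
    edit fewer targets but each at a higher rate ('high editors')."""
    per_cell: dict[str, list[float]] = {}
    types: dict[str, str] = {}
    for s in sites:
        for sid, r in s.per_cell_rates.items():
            per_cell.setdefault(sid, []).append(r)
            types[sid] = s.cell_types.get(sid, "other")
    profiles = []
    for sid in sorted(per_cell):
        rates = per_cell[sid]
        adar = float("nan")
        if expression is not None and adar_gene is not None and sid in expression.columns:
            if adar_gene in expression.index:
                adar = float(expression.at[adar_gene, sid])
        profiles.append(
            CellProfile(sample_id=sid, cell_type=types[sid], n_edits=len(rates),
                        mean_rate=float(np.mean(rates)), adar_tpm=adar)
        )
    corr: dict = {}
    n_edits = np.array([p.n_edits for p in profiles], dtype=float)
    mean_rate = np.array([p.mean_rate for p in profiles])
    if len(profiles) >= 3 and n_edits.std() > 0 and mean_rate.std() > 0:
        r, p = sps.pearsonr(n_edits, mean_rate)
        corr["n_edits_vs_mean_rate"] = {"r": float(r), "p": float(p)}
    adar = np.array([p.adar_tpm for p in profiles])
    ok = ~np.isnan(adar)
    if ok.sum() >= 3 and adar[ok].std() > 0 and mean_rate[ok].std() > 0:
        r, p = sps.pearsonr(adar[ok], mean_rate[ok])
        corr["adar_vs_mean_rate"] = {"r": float(r), "p": float(p)}
    return profiles, corr


def fraction_cells_vs_rate(summaries: Sequence[SiteSummary]) -> dict:
    """Pearson r across sites of (fraction of cells with the edit, mean rate)."""
    if len(summaries) < 3:
        raise ValidationError("need >= 3 summaries")
    x = np.array([s.fraction_cells for s in summaries])
    y = np.array([s.mean_rate for s in summaries])
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "r2": float(r * r), "p": float(p), "n": len(summaries)}


def high_editing_sites(
    summaries: Sequence[SiteSummary],
    threshold: float = 0.90,
    cell_types: Sequence[str] = ("Ib", "Is"),
    strict: bool = True,
) -> dict:
    """Sites edited above ``threshold`` (strictly, by default) in at least one
    of the given cell types, among the cells carrying the edit."""
    cmp = (lambda v: v > threshold) if strict else (lambda v: v >= threshold)
    hits = [
        s for s in summaries
        if any(cmp(s.mean_rate_by_type.get(ct, float("-inf"))) for ct in cell_types)
    ]
    genes = sorted({s.gene_id for s in hits})
    return {"sites": hits, "n_sites": len(hits), "genes": genes, "n_genes": len(genes)}


def region_fractions(summaries: Sequence[SiteSummary]) -> dict:
    counts: dict[str, int] = {}
    for s in summaries:
        counts[s.region] = counts.get(s.region, 0) + 1
    total = sum(counts.values())
    return {r: c / total for r, c in counts.items()} if total else {}
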