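"""Cell-type comparison: DEG masking, per-site differential editing,
cross-type correlation and shared/unique catalog partitions.

Differential editing between tonic (Ib) and phasic (Is) subtypes is only
meaningful for genes expressed at similar levels in both — otherwise a rate
difference can be an expression artifact — so sites in differentially
expressed genes (DEGs) are masked before testing.  The default per-site test
is a Welch two-sample t-test on per-cell edited fractions with
Benjamini-Hochberg FDR control; a count-aware pooled two-proportion test is
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .io import EditSite, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DegTable:
    """Gene-level differential-expression results supplied as an input."""

    padj: Mapping[str, float]  # gene_id -> adjusted p
    tpm_by_type: pd.DataFrame | None = None  # genes x cell types, optional

    def __post_init__(self) -> None:
        for g, p in self.padj.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{g}: adjusted p {p} outside [0,1]")

    @classmethod
    def from_tsv(cls, path) -> "DegTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        tpm_cols = [c for c in df.columns if c.startswith("tpm_")]
        tpm = df[tpm_cols].rename(columns=lambda c: c[4:]) if tpm_cols else None
        return cls(padj=df["padj"].to_dict(), tpm_by_type=tpm)


def deg_mask(sites: Sequence[EditSite], deg: DegTable, alpha: float = 0.05) -> list[EditSite]:
    """Remove sites whose gene is differentially expressed (padj < alpha).

    Sites in genes absent from the table are retained with a warning."""
    out = []
    for s in sites:
        p = deg.padj.get(s.gene_id)
        if p is None:
            logger.warning("%s:%s gene %s missing from DEG table; retained", s.chrom, s.pos, s.gene_id)
            out.append(s)
        elif not p < alpha:
            out.append(s)
    return out


def _site_rates_by_type(site: EditSite, type_a: str, type_b: str):
    a = [r for sid, r in site.per_cell_rates.items() if site.cell_types.get(sid) == type_a]
    b = [r for sid, r in site.per_cell_rates.items() if site.cell_types.get(sid) == type_b]
    return np.asarray(a), np.asarray(b)


def differential_editing(
    sites: Sequence[EditSite],
    type_a: str = "Ib",
    type_b: str = "Is",
    alpha_fdr: float = 0.05,
    min_cells: int = 10,
    method: str = "welch",
) -> pd.DataFrame:
    """Per-site two-sided test of editing-rate difference between two types.

    Sites with fewer than ``min_cells`` contributing cells in either type are
    skipped.  ``method='welch'`` tests per-cell rates; ``method='pooled'``
    dichotomizes cells at 50% editing and runs a two-proportion z-test on the
    counts of majority-edited cells.  p-values are
    BH-adjusted across tested sites; ``flag`` marks q < alpha_fdr.
    """
    rows = []
    for s in sites:
        a, b = _site_rates_by_type(s, type_a, type_b)
        if len(a) < min_cells or len(b) < min_cells:
            continue
        if method == "welch":
            if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.ttest_ind(a, b, equal_var=False)
        elif method == "pooled":
            count = np.array([(a > 0.5).sum(), (b > 0.5).sum()])
            nobs = np.array([len(a), len(b)])
            stat, p = proportions_ztest(count, nobs)
        else:
            raise ValidationError(f"unknown method {method!r}")
        rows.append(
            {
                "chrom": s.chrom, "pos": s.pos, "gene_id": s.gene_id, "region": s.region,
                f"mean_{type_a}": float(a.mean()), f"mean_{type_b}": float(b.mean()),
                f"n_{type_a}": len(a), f"n_{type_b}": len(b),
                "statistic": float(stat), "p": float(p),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["q"] = []
        df["flag"] = []
        return df
    _, q, _, _ = multipletests(df["p"], method="fdr_bh")
    df["q"] = q
    df["flag"] = df["q"] < alpha_fdr
    return df


def cross_type_correlation(
    summaries,
    type_a: str = "Ib",
    type_b: str = "Is",
) -> dict:
    """Pearson correlation of per-site mean rates and detection fractions
    between two cell types, over sites detected in both; single-type sites
    are tallied separately."""
    shared_rates, shared_frac = [], []
    only_a = only_b = 0
    for s in summaries:
        ra = s.mean_rate_by_type.get(type_a)
        rb = s.mean_rate_by_type.get(type_b)
        if ra is not None and rb is not None:
            shared_rates.append((ra, rb))
            fa = s.fraction_cells_by_type.get(type_a)
            fb = s.fraction_cells_by_type.get(type_b)
            if fa is not None and fb is not None:
                shared_frac.append((fa, fb))
        elif ra is not None:
            only_a += 1
        elif rb is not None:
            only_b += 1
    if len(shared_rates) < 3:
        raise ValidationError("fewer than 3 sites shared between the two types")
    xs, ys = zip(*shared_rates)
    r_rates, p_rates = sps.pearsonr(xs, ys)
    out = {
        "r_rates": float(r_rates), "r2_rates": float(r_rates**2), "p_rates": float(p_rates),
        "n_shared": len(shared_rates), f"n_only_{type_a}": only_a, f"n_only_{type_b}": only_b,
    }
    if len(shared_frac) >= 3:
        xs, ys = zip(*shared_frac)
        if np.std(xs) > 0 and np.std(ys) > 0:
            r_f, p_f = sps.pearsonr(xs, ys)
            out.update(r_fraction_cells=float(r_f), r2_fraction_cells=float(r_f**2),
                       p_fraction_cells=float(p_f))
    return out


def shared_unique_partition(catalogs: Mapping[str, set]) -> dict:
    """Venn-style counts keyed by the sorted membership pattern.

    ``catalogs`` maps cell type -> set of site identity keys
    (chrom, pos, sense change).  Counts over all non-empty membership
    patterns sum to the size of the union."""
    if len(catalogs) < 2:
        raise ValidationError("need >= 2 catalogs to partition")
    universe = set().union(*catalogs.values())
    counts: dict[tuple, int] = {}
    for key in universe:
        pattern = tuple(sorted(t for t, s in catalogs.items() if key in s))
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts
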