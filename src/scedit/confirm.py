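"""Cross-dataset confirmation of edit sites against external RNAseq tables.

For each external dataset, per-replicate editing frequencies ALT/(REF+ALT)
are averaged (unweighted, over replicates with reads) into a compiled
frequency; a site is *confirmed* if any dataset's compiled frequency reaches
10% — note the inclusive comparator here, unlike the strict >10% used for
per-cell calling — *no_reads* if no dataset covered it, and *not_confirmed*
otherwise.  An independent genomic-DNA check removes sites showing any
edited-base reads in gDNA (latent SNPs).  Site keys match on the
sense-corrected change so minus-strand bookkeeping cannot desynchronize
datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError

logger = logging.getLogger(__name__)

NO_READS = "no_reads"


@dataclass(frozen=True)
class ReplicateCounts:
    """ALT/REF read counts for one replicate of one external dataset."""

    dataset_id: str
    replicate_id: str
    counts: Mapping[tuple, tuple]  # site key -> (ref_count, alt_count)

    def frequency(self, site_key) -> float | None:
        c = self.counts.get(site_key)
        if c is None:
            return None
        ref, alt = c
        if ref < 0 or alt < 0:
            raise ValidationError(f"negative counts at {site_key}")
        if ref + alt == 0:
            return None
        return alt / (ref + alt)


def read_replicate_counts(path) -> list[ReplicateCounts]:
    """Replicate-counts TSV: dataset, replicate, chrom, pos, ref, alt,
    ref_count, alt_count.  Site key = (chrom, pos, ref, alt) on sense bases."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for (ds, rep), grp in df.groupby(["dataset", "replicate"], sort=True):
        counts = {
            (r.chrom, int(r.pos), r.ref, r.alt): (int(r.ref_count), int(r.alt_count))
            for r in grp.itertuples(index=False)
        }
        out.append(ReplicateCounts(dataset_id=str(ds), replicate_id=str(rep), counts=counts))
    return out


def compile_frequency(replicates: Sequence[ReplicateCounts], site_key) -> float | str:
    """Unweighted mean of per-replicate frequencies over replicates with
    reads; 'no_reads' if none has coverage."""
    if len({r.dataset_id for r in replicates}) > 1:
        raise ValidationError("replicates span multiple datasets")
    freqs = [f for f in (r.frequency(site_key) for r in replicates) if f is not None]
    if not freqs:
        return NO_READS
    return float(np.mean(freqs))


def confirm_status(compiled: Mapping[str, float | str], threshold: float = 0.10) -> str:
    """'confirmed' iff any dataset's compiled frequency is >= threshold;
    'no_reads' iff every dataset lacked coverage; else 'not_confirmed'."""
    if not compiled:
        raise ValidationError("no dataset entries for site")
    values = [v for v in compiled.values() if v != NO_READS]
    if not values:
        return NO_READS
    return "confirmed" if any(v >= threshold for v in values) else "not_confirmed"


def gdna_ref_filter(gdna_counts: tuple) -> tuple[bool, bool]:
    """(keep, flagged): drop a site iff gDNA shows any edited-base read;
    zero-depth sites are kept but flagged as unchecked."""
    ref, alt = gdna_counts
    if ref + alt == 0:
        return True, True
    return alt == 0, False


def confirmation_report(
    site_keys: Sequence[tuple],
    replicates_by_dataset: Mapping[str, Sequence[ReplicateCounts]],
    gdna_counts: Mapping[tuple, tuple] | None = None,
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Compiled per-dataset frequencies and status for every site key."""
    rows = []
    for key in site_keys:
        if gdna_counts is not None:
            keep, flagged = gdna_ref_filter(gdna_counts.get(key, (0, 0)))
            if not keep:
                continue
        else:
            flagged = True
        compiled = {
            ds: compile_frequency(reps, key) for ds, reps in replicates_by_dataset.items()
        }
        row = {"chrom": key[0], "pos": key[1], "sense_ref": key[2], "sense_alt": key[3],
               "gdna_unchecked": flagged, "status": confirm_status(compiled, threshold)}
        for ds, v in compiled.items():
            row[f"freq_{ds}"] = np.nan if v == NO_READS else v
        rows.append(row)
    return pd.DataFrame(rows)


def frequency_correlation(
    set_a: Mapping[tuple, float],
    set_b: Mapping[tuple, float],
    groups: Mapping[tuple, str] | None = None,
) -> dict:
    """Pearson r and an unconstrained least-squares line between two
    frequency maps, per annotation group.

    Sites missing (or without reads) in either map are excluded.  ``groups``
    optionally maps site keys to labels (e.g. annotated/unannotated); groups
    with fewer than 3 shared sites are skipped with a warning."""
    shared = sorted(set(set_a) & set(set_b))
    shared = [k for k in shared if set_a[k] != NO_READS and set_b[k] != NO_READS]
    by_group: dict[str, list] = {}
    for k in shared:
        label = groups.get(k, "all") if groups else "all"
        by_group.setdefault(label, []).append(k)
    out = {}
    for label, keys in sorted(by_group.items()):
        if len(keys) < 3:
            logger.warning("group %r has <3 shared sites; skipped", label)
            continue
        x = np.array([set_a[k] for k in keys], dtype=float)
        y = np.array([set_b[k] for k in keys], dtype=float)
        res = sps.linregress(x, y)
        out[label] = {
            "r": float(res.rvalue), "r2": float(res.rvalue**2),
            "slope": float(res.slope), "intercept": float(res.intercept),
            "p": float(res.pvalue), "n": len(keys),
        }
    return out
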