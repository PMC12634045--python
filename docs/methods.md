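# Methods

## Model and procedure

`scedit` implements edit-site inference by DNA–RNA mismatch filtering, not by
probabilistic genotyping: a site is called edited when, after removing every
mismatch explainable by genomic polymorphism, enough individually sampled
cells show the same base change at convincing depth, quality and rate. The
statistic of interest throughout is the per-cell editing rate
ALT/(REF+ALT) — the fraction of reads carrying the edited base — and the
catalog-level quantities derived from it (per-site means over contributing
cells, detection fractions over sampled cells, correlations between them).

All coordinates are 1-based with inclusive interval ends. A cluster's span is
reported as `max(pos) − min(pos)`, so a cluster bounded by positions 4301140
and 4301258 spans 118 nt. Reads are aligned to the plus strand while genes
live on both strands, so every downstream consumer works on *sense-corrected*
bases: a minus-strand gene's observed T→C mismatch is reported as the A→G
edit it is. Sense correction at a fixed position is base complementation
(coordinate order is unchanged); applying it twice is the identity, which the
test suite asserts over all 12 base changes.

## Filtering rules and their comparators

Thresholds live in `FilterThresholds` with these defaults, all configurable:

| rule | default | comparator |
|---|---|---|
| site depth per cell | 10 | keep if depth **> 10** |
| variant QUAL | 20 | keep if QUAL **> 20** |
| per-cell editing rate | 0.10 | keep if rate **> 0.10** |
| contributing cells | 10 | keep site if **≥ 10** cells of ≥ 1 cell type |
| parental gDNA purity | 0.96 | keep if pooled ref-match fraction **≥ 0.96** |
| 5′UTR head exclusion | 20 nt | drop if transcript offset **< 20** |
| indel proximity | 10 bp | drop if **\|Δpos\| ≤ 10** from a parental indel |

Two wordings of the depth rule circulate for this kind of pipeline (exclude
"≤10 reads" vs "fewer than 10"); the strict form (keep > 10) is the default
and the comparator is exposed (`depth_comparator=">="` keeps depth 10).
The cell-count rule is applied *per cell type*, not pooled: a site seen in 9
tonic (Ib) and 9 phasic (Is) cells fails, one seen in 10 muscle samples
passes. Parental gDNA purity pools read counts across the sequenced lines;
a site with no gDNA coverage is retained with purity `None` (flagged
unknown) rather than silently passed or dropped, preserving auditability.
The 5′UTR head exclusion is measured along the transcript (first 20
transcribed nucleotides), honoring strand — base-call artifacts concentrate
at the transcript start, not at low genomic coordinates.

The confirmation rule in `scedit.confirm` deliberately uses the *inclusive*
comparator (compiled frequency ≥ 10% confirms) while per-cell calling uses
the strict one (> 10% contributes); the two rules are stated that way in
their respective procedures and both comparators are documented side by side
here so the asymmetry is visible rather than accidental.

Sites inside exons of several overlapping genes are emitted once per gene
(`EditSite.gene_ids[0]` names the annotating gene), because region assignment
and sense correction are gene-relative; catalog identity for cross-dataset
matching is `(chrom, pos, sense_ref, sense_alt)`, which collapses the
per-gene records back to one locus.

## Codon consequences and significance

CDS edits are scored as single substitutions against the reference CDS under
the standard (nuclear) genetic code via Biopython. Effects are silent /
missense / stop_gain / stop_loss; a stop_loss (read-through) is always
treated as significant since it extends the protein. Missense significance is
a pure function of a residue-class partition — positive {R,K}, negative
{D,E}, hydrophobic {A,V,I,L,M,F,Y,W}, polar {N,Q}, phospho {S,T}, structural
{C,G,P,H} — crossing classes is significant, moving within one is not. The
partition is injected (`ResidueClassScheme` as a mapping), so alternative
chemistries can be swapped in. Edits sharing a codon are scored
independently; `combined_codon_effects` additionally enumerates the joint
codon variants (count-free, since read-level phasing is unavailable in this
data model). Conservation labels come from an externally supplied
orthologue-residue table; agreement across all mammalian entries takes
precedence over insect-only agreement, mirroring mutually exclusive
mammal/insect labels in published catalogs.

## Statistics

Region-wise rate comparison is a one-way ANOVA over per-site mean rates with
Tukey–Kramer post hoc p-values (statsmodels); identical groups report F=0
rather than NaN. Normality is the one-sample Kolmogorov–Smirnov test against
a normal with the sample's own moments (n ≥ 5, zero variance rejected).
Correlations are Pearson throughout (scipy), with expression joined as
log10(TPM+1) by default (raw TPM available — the transform choice is not
standardized in this literature). Differential editing between cell types is
a Welch two-sample t-test on per-cell rates with Benjamini–Hochberg FDR
across tested sites; per-cell edited fractions are the unit of analysis
because they are the quantity the single-cell design actually measures. A
count-aware alternative (two-proportion z-test on majority-edited cells) is
provided behind `method="pooled"`. Nearest-neighbor distances are computed
within the pooled catalog, not per cell type. Site mean rate is the mean over
cells *contributing* the edit; the fraction of cells carrying the edit uses
the full sampled-cell denominator — keeping these axes distinct is what makes
their anticorrelation a finding rather than an artifact. ">90%" and ">10%"
cutoffs are strict by default and configurable.

## Synthetic data: what it emulates, what it does not

The generator (`scedit.simulate`) emulates the *structure* of single-cell
Patch-seq editing data, not any mechanistic model of ADAR:

- **Samples**: 100 tonic-like and 100 phasic-like neurons plus 20
  polynucleate muscle samples by default.
- **Genome**: 30 intronless genes (60 nt 5′UTR, 100 codons, 120 nt 3′UTR)
  across five chromosome arms, ~40% on the minus strand, CDSs free of
  internal stops; one gene pair overlaps on opposite strands to exercise the
  per-gene listing rule.
- **Edits**: 50 sites, 80% canonical A>G on the sense strand; per-site mean
  rates are 0.1 + 0.9·Beta(2, 1.2) (support above the 10% detection
  threshold, population average ≈ 0.66). Per-cell rates draw from a Beta
  centered on the site mean (concentration 8) with a 15% all-or-none
  component (the cell is fully edited or fully unedited with probability
  equal to the site mean) — this reproduces observed cell-to-cell
  stochasticity without claiming a generative mechanism, which remains
  unknown. Muscle samples average many nuclei, so they get a 4× tighter Beta,
  no all-or-none component, and a 0.6 rate factor; two sites are muscle-only.
  Planted edits avoid the excluded 5′UTR head and the terminal stop codon.
- **Polymorphism**: exonic SNPs at 1.5 × 10⁻³ per base, each carried by a
  random non-empty subset of 3 parental lines and near-fixed in cellular
  RNA; 5 parental indels placed clear of planted edits.
- **Coverage**: negative-binomial per (site, cell) with mean 40 and shape 3,
  modulated by (TPM/mean TPM)^0.3 — a damped coupling so depth tracks
  expression monotonically while keeping the stated mean-40 depth regime
  across genes.
- **Error**: symmetric base miscalls at 2 × 10⁻³ per read, which create the
  low-level mismatch background the rate/QUAL/cell-count rules must remove.
  Per-cell variant QUAL is modeled as 10 × ALT-count (capped at 99),
  mimicking accumulating caller evidence. In the multi-sample VCF export the
  record QUAL is the maximum per-cell QUAL at the site (one QUAL per record
  is all the format allows).
- An optional rate-limiting mode divides per-cell rates by
  (1 + TPM/50), giving the expression–editing anticorrelation signal; it is
  off by default.

Not emulated: reads and alignment artifacts, splicing, PCR duplicates,
allele-specific expression, doublets, batch effects. Passing tests on this
generator therefore validate the *bookkeeping and statistics* of the
pipeline — strand handling, filter logic, estimator behavior at known truth —
not robustness to alignment-era artifacts, which are upstream of this
package's inputs.

Determinism: every draw flows from one `numpy` generator seeded by the
config; identical configs yield byte-identical exports.

## Problem sizes and numerical choices

The test suite runs the full generator at study scale (226 samples, ~15 kb
of exonic sequence, ~220 k mismatch records) once per session and smaller
configurations elsewhere; the codon-consequence oracle checks 1000 random
CDSs against full-translation diffs; the null FDR simulation uses 200 sites
of 30 cells per type at depth 40. Truth-site recall at the default
configuration is ≥ 0.9 by test (measured 0.96–1.0 across seeds) with zero
surviving error- or SNP-derived sites. Site-mean recovery bias is ≤ 0.02 at
depth 100 with 100 cells over true means {0.2, 0.5, 0.8}.

Floating-point rates are serialized at 6 significant digits, which makes the
site-table TSV round-trip byte-identical (write∘read∘write). Pearson
correlations on zero-variance inputs raise (or are omitted, where they are a
secondary output) instead of returning NaN.

## Known limitations

- The VCF dialect is deliberately narrow (CHROM/POS/REF/ALT/QUAL + AD);
  records without AD are unusable.
- QUAL handling in the multi-sample export loses per-cell resolution (see
  above); pipelines with per-cell VCFs retain it.
- The DEG table is an input; no expression differential testing is
  performed here.
- Conservation annotation requires an externally built orthologue-residue
  table; no homology search is run.
- With no read-level phasing, multi-edit codon variants are enumerated
  combinatorially, not counted.
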