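# Methods

## Clonotype definition

A cell's clonotype is the multiset of CDR3 amino-acid sequences of its
productive TRA/TRB chains, canonicalized as `sorted TRA | sorted TRB`
(";"-separated within a side, `NA` for a missing side).  Amino-acid
identity alone defines clonal relatedness — no V/J genes, no nucleotide
sequences — because convergent recombination to the same paired CDR3s is
rare enough at cohort scale that the amino-acid key is the standard
choice; a V/J-aware key is available behind `use_v_genes`.  Non-productive
and CDR3-less contigs are excluded by default (`productive_only=True`);
cells may carry one or two TRA sequences (dual-TRA cells are common in
real repertoires) and the key is order-independent.  Cells lacking a TRB
still receive a key (`NA|…`) unless `require_both_chains` is set.

## Abundance, expansion levels and the scoped denominator

Clone abundance is the percentage of TCR-bearing cells of the same
patient, tissue and scope that carry the clonotype.  The denominator is
always scoped: an analysis over CD4 single-positive cells counts only CD4
TCR-bearing cells in both numerator and denominator, so CD4-scoped and
CD8-scoped frequencies are percentages of their own compartment.
Expansion levels are Single (one occurrence, taking precedence over any
percentage bin — a 1-cell clone in a 5-cell sample is Single, not
Hyperexpanded), Small (≤ 0.1%), Medium (≤ 1%), Large (≤ 10%) and
Hyperexpanded (> 10%), with inclusive upper bounds.

At the default simulated scale (~1,600 TCR-bearing analysis cells per
tissue per patient) the Small bin is empty by arithmetic: the smallest
expanded clone (2 cells) already exceeds 0.1% of the denominator.  Small
appears once denominators reach ~2,000+ cells (or with bulk template
counts, where denominators are in the thousands); this is a property of
the bins, not of the implementation.

## Tissue enrichment

Enrichment compares one clone's frequencies across the two matched
tissues of one patient (never pooling clonotypes across patients, since
CDR3 sharing between individuals is not assumed).  The published category
definitions are qualitative ("higher" / "similar"); the quantitative rule
here is a configurable fold-change: with frequencies f_t (tissue) and f_b
(blood),

- one cell in total across both tissues → **Single**;
- f_b > 0 and f_t ≥ k·f_b, or f_b = 0 with at least `min_cells_expanded`
  tissue cells → tissue-qualifies (mirrored for blood);
- exactly one side qualifies → **TissueEnriched** / **PBMCEnriched**;
  otherwise **Unenriched**.

Defaults: fold k = 2, `min_cells_expanded` = 2.  These defaults are this
package's choice and every run logs them (`thresholds.yaml` next to the
outputs); change them deliberately, not silently.  The symmetric
formulation makes the score antisymmetric under swapping the tissue
labels, which the tests exercise.

## QC and ADT gating

Cells pass QC when they detect between 200 and 5,000 genes (both ends
inclusive — "between" read plain-language) and each flagged lncRNA
(KCNQ1OT1, UGDH-AS1, GHET1; apoptosis/doublet proxies) stays strictly
below 2% of total counts.  Zero-count cells fail outright.  QC precedes
every clonotype denominator.

Antibody-tag (ADT) counts are CLR-normalized — ln((x+1)/geometric mean of
(x+1)) — per feature across cells, the feature-barcoding convention; the
per-cell axis is available.  Gates apply to normalized values: T cells
are CD3 > 0.5 and CD14 ≤ 0.5 (artifact defaults — no published values
exist for these two, since the original gating went through clusters),
then CD4 > 0.75 and CD8 > 1.0 (strict inequalities) define CD4/CD8
single-positives; both above → double-positive, excluded from the scoped
analyses; neither → double-negative.

## Differential expression

Contrasts between clonality-defined groups (singleton vs expanded cells,
blood- vs tissue-enriched cells, one cluster across tissues) use the
two-sided Wilcoxon rank-sum test on log-normalized expression
(library-size scaled to 10⁴, log1p; ranks are invariant to the per-cell
monotone transform).  For groups of ≤ 8 cells the p-value is computed
exactly by enumerating every assignment of the pooled mid-ranks, which
handles ties; larger groups use the tie-corrected normal approximation.
Bonferroni correction multiplies by the total number of genes in the
dataset, not the number tested.  A gene is significant at p < 10⁻⁶ and
|log₂FC| ≥ 0.5; "fold change of 0.5" is read as a log₂ threshold (the
convention of the single-cell toolchain this rule comes from) and the
fold change is log₂((mean_A + 1)/(mean_B + 1)) with pseudocount 1.
Constant genes get p = 1, log₂FC = 0.

## The synthetic cohort

The generator emulates the structure the analysis is designed to detect,
with defaults fixed at the study conditions: 3 patients × 2 matched
tissues × 2,000 cells, expanded-cell fractions 23% (blood) and 29%
(tissue), about 12% non-T (myeloid) cells, ~2% double-positives, CD4:CD8
≈ 3:1, and one hyperexpanded "spike" clone in patient 1 (12% of blood,
5% of tissue, CD8, fixed TRA CDR3) emulating a dominant virus-associated
clone.  Expanded clone sizes are 1 + Geometric(p = 0.5) (mean 3,
memoryless expansion; Zipf and constant laws available); half the
expanded clones are shared across tissues, and shared clones carry a
multiplicative frequency enrichment (default factor 4) toward a side
drawn with probability 0.7 for the tissue, with stochastic rounding.
Expanded-cell budgets are filled exactly, so the planted fractions are
exact over the clean analysis cells.  QC-violating cells (2% low-gene,
1% high-gene, 2% flagged-gene by default) and myeloid cells are drawn
out of the same per-tissue cell budget but carry only singleton TCRs (or
none), so the planted clonal fractions refer to the cell set that
survives QC and gating — which is exactly what the recovery tests and
the acceptance script measure.

CDR3 strings are uniform random amino acids with C…F flanks (length
8–20); there is no V(D)J recombination model because the analysis uses
string identity only.  Gene counts are sparse draws over a filler pool
plus planted marker programs: expanded-clone cells overexpress an
activation/cytotoxicity set, singleton T cells a naive/memory set, and
tissue cells the recent-TCR-engagement genes (CD69, FOS, FOSB, JUN), so
the DE contrasts have genuine signal with known direction.  ADT counts
are negative-binomial with per-true-type means chosen so that CLR +
default gates recover the true types with ≥ 95% accuracy.  What passing
tests on this generator do **not** show: robustness to chimeric or
ambient contigs, barcode swapping, clonotype sharing across patients,
realistic transcriptome covariance, or batch effects — none of which the
generator emulates.

## Numerical and design notes

- All outputs are deterministically ordered (stable sorts, explicit
  tie-breaks: cluster-overlap rows by combined count descending then key;
  DE rows by p, then |log₂FC|, then gene name), so reruns are
  byte-identical and diffs are meaningful.
- Frequencies per stratum sum to 100% to 1e-9; class proportions per
  group sum to 1.
- The MatrixMarket reader detects on-disk orientation from the header
  dimensions against the feature/barcode list lengths and normalizes to
  cells × genes.
- Readers never filter (non-productive contigs, duplicate bulk rows are
  returned as-is); every exclusion is an explicit downstream operation
  with a report.
- Bulk TCRβ tables re-use the identical classifiers with template counts
  in place of cells, aggregating duplicate CDR3 rows per sample first.
- Problem sizes in the tests and the acceptance script (2,000–2,500
  cells per tissue, 2,000-gene null replicates) are chosen to make the
  statistical criteria sharp at interactive runtimes.

## Known limitations

- The enrichment fold-change rule is a reasonable operationalization,
  not a published constant; conclusions sensitive to the fold should be
  checked across a range of `fold_threshold`.
- Clustering is taken as an input label; the package does not cluster.
- The exact-match annotation mode finds only literal CDR3 identity on
  the same locus; no fuzzy or motif matching.
- CD3/CD14 gate defaults are artifact values on CLR units and should be
  recalibrated for real feature-barcoding panels.
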