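# Methods

## Data model and conventions

All genomic coordinates are 0-based half-open internally; site-call files
carry 1-based positions on disk and are converted on read. Interval algebra
is strand-blind; strand matters only where definitions are strand-relative:
promoters (−1 kb/+0.5 kb around the TSS in transcription orientation) and
metagene windows. On the minus strand the gene body occupies `[TES, TSS)`
half-open, so the body length is exactly `|TSS − TES|` on both strands.

Two cytosine contexts are carried throughout: WCG sites report endogenous
CpG methylation, GCH sites report exogenous GpC-methyltransferase marking of
accessible (nucleosome-depleted) chromatin. A per-cell site call is a
(position, context, methylated read fraction, depth) record.

## Quantification

Site fractions are reduced to confident binary states: > 0.9 → 1, < 0.1 → 0,
strict on both sides; intermediates are discarded. This reflects the
near-binary state of a single allele observed at ~1× depth: intermediate
fractions mostly indicate conversion or mapping artifacts. Downstream
"levels" are means of binary calls.

* **Element/tile levels** require ≥ 3 covered sites of the context; entries
  with fewer are NA (the NA pattern is exactly the < 3-site pattern, which
  tests assert).
* **Global levels** average the means of qualifying 1-kb tiles, weighting
  tiles equally rather than sites. The two-tile worked example (a 3-site
  fully methylated tile and a 300-site unmethylated tile → 0.5) pins this
  down.
* **Accessibility normalization** divides each cell's element-level GCH
  values by that cell's global GCH level, removing per-cell enzyme-efficiency
  differences.
* **Cell QC** thresholds (coverage ≥ 4%, WCG ≥ 8×10⁵, GCH ≥ 5×10⁶,
  mapping ≥ 5%, conversion ≥ 98%; RNA 1500–9000 genes and ≤ 4×10⁵ UMIs) are
  boundary-inclusive; the UMI rule is read as "more than 400,000 fails",
  consistent with the surrounding phrasing.

**Classical MDS** of promoter profiles restricts to promoters observed in
≥ 50% of cells, imputes remaining NAs with the feature mean, and performs
Torgerson scaling (eigendecomposition of the double-centred squared
Euclidean distance matrix). The distance metric and NA handling were open
design choices; Euclidean-with-mean-imputation is the least structured
option and is validated against an eigendecomposition oracle.

## NDR calling

For each cell, 100-bp windows advancing by 20 bp are scored with a 2×2
χ² test (1 df, no Yates correction) of (accessible, inaccessible) calls in
the window versus the rest of that cell's genome. The background is
deliberately per-cell, not cohort-wide: enzyme efficiency varies per cell and
the comparison must be internal. Windows pass at p < 10⁻¹⁵ *and* an
above-background rate (the χ² is two-sided, so enrichment direction is
enforced separately). Passing windows sharing ≥ 1 bp are unioned; candidates
spanning > 140 bp with ≥ 5 covered GCH calls become scNDRs (a lone 100-bp
window can never qualify). Windows with small expected counts are still
tested — the ≥ 5-site rule guards sparsity.

scNDRs merge across cells with bedtools-style negative-gap semantics: an
interval joins the running cluster when it overlaps the cluster span by
≥ 100 bp; merging is transitive, coordinates are the union span, and support
counts **distinct cells** (a cell contributing two overlapping scNDRs counts
once). The per-group support threshold is a caller-supplied integer; the
helper `support_threshold(n, 0.05)` reproduces the 5%-of-cells convention.
Group-specific mNDRs have *zero* overlap with the other group's mNDRs;
"shared" requires ≥ 100 bp overlap; pairs overlapping by 1–99 bp satisfy
neither definition and are reported in a separate ambiguous bucket rather
than silently assigned.

## Differential promoter methylation

Promoters covered (≥ 3 WCG sites) in ≥ 30% of all cells pooled (the
denominator was an open choice; pooling is the stricter reading) are tested
with four simultaneous criteria: two-sided Wilcoxon rank-sum p < 0.05, fold
change (cancer/normal) > 2 or < 0.5, absolute difference > 0.5, and SD
< 0.25 within each group. Comparators are exactly strict/non-strict as
stated; a zero normal mean with positive cancer mean yields an infinite fold
change, which passes the > 2 arm. No multiple-testing correction is applied
by default — the conjunction is the false-positive control — but a
Benjamini–Hochberg option exists. The rank-sum test uses exact enumeration
for tie-free samples with min(n, m) ≤ 8 and the normal approximation with
midranks and continuity correction otherwise.

The expression-quartile analysis normalizes expression per cell
(counts-per-total × 10⁴, log1p), averages over normal cells, splits genes
into four equal groups, and reports the mean gene-body methylation change
(cancer − normal) per quartile.

## Cross-omics correlation profiles

Genes shorter than 2.5 kb are removed; the rest get 20 equal body windows
(integer edges, cumulative span exact) plus 5 upstream and 5 downstream 3-kb
windows, mirrored on the minus strand so window 1 is always most upstream.
Within each cell, the Spearman coefficient for window k is computed **across
genes** between expression and the window-k level (pairwise NA deletion,
NA when < 20 informative genes). This reading — rather than correlating
across cells within a gene — is the one that yields per-cell coefficients
that can be compared between groups, which is how the per-cell box
comparisons are framed. Because the correlation is rank-based, the expression
normalization choice is immaterial up to monotonicity.

## Demethylation-degree mapping

For cancer cell i and window j, `R_DMeD = level / baseline` with the
baseline the *median* over normal cells in that window (medians resist the
occasional aberrant normal cell), and `DDemeD = 1 − R_DMeD`. The baseline is
NA when fewer than 3 normal cells are informative (a median of ≤ 2 values is
unstable) or zero. Negative DDemeD (cancer above baseline) is retained, not
clamped, so maps remain faithful. Feature densities are merged-track overlap
divided by the true window length; terminal partial windows keep their true
length. Correlations are per-cell Spearman coefficients of DDemeD against
each density track, repeated across window resolutions of 0.25–10 Mb.

## Copy number and subclones

Bins are an input (any interval set): the binning machinery of external CNV
tools is not reproduced, only the normalization convention. Each cell's bin
counts are converted to frequencies, divided by the median frequency profile
of the control cells (normal cells from male patients), and scaled ×2 to a
diploid baseline; no segmentation is performed. X and Y bin values are then
halved **for all cells regardless of sex**, reproducing the convention that
renders the male single-X baseline at value 1 and the female diploid X at 2;
this is a visualization/normalization convention, and for female patients it
rescales a genuinely diploid X, which is why the operation is guarded
against accidental re-application.

"Obvious SCNA" is operationalized (the wording is qualitative) as > 5% of
autosomal bins deviating from 2 by more than 0.5; both parameters are
exposed. Subclones are found by Ward hierarchical clustering on Euclidean
bin distances with k chosen by silhouette over 2–6 (the clustering method
was unspecified; Ward/silhouette is deterministic given input order, which
tests verify). The methylation/copy-number relation is assessed per
subclone: both modalities are averaged across the subclone's cells per bin
and Pearson-correlated across bins with pairwise NA deletion.

## Synthetic cohorts and what they do (not) show

The generator's defaults are the analysed regime: a 35-Mb toy genome (three
10-Mb autosomes + 5-Mb chrX), 800 genes, 14.8% per-cell site coverage,
normal global methylation 0.80, cancer demethylation 0.10 (range 0.05–0.20)
concentrated in LINE-1-dense blocks, 40 hyper- vs 15 hypomethylated
promoters, and three CNV subclones per patient. Scientifically motivated
choices where no value was prescribed:

* **Bimodal site fractions** from a Beta mixture — Beta(100,1)/Beta(1,100)
  components for the confident states plus a 10% Beta(2,2) intermediate
  component — so the usable-site filter is actually exercised (analytic
  retention 0.906).
* **Heterochromatin field.** 250-kb blocks carry a heterochromatin score
  with distinct per-chromosome baselines (0.25–0.75); LINE-1 density rises
  with the score and H3K4me3/H3K27Ac/H3K36me3 densities fall with it. The
  per-chromosome baselines keep the 10-Mb-resolution correlations (3–4
  windows) well-defined. Cancer demethylation per site is the group delta
  times the block's normalized LINE-1 weight.
* **CpG-island promoters.** WCG sites lie every ~50 bp genome-wide and every
  ~15 bp in promoters; promoters resist global demethylation (weight 0), as
  CGIs do. Without CGI-like density the ≥ 3-site and 30%-coverage rules
  would discard every promoter at 14.8% coverage. A side effect: ~6% of
  qualifying 1-kb tiles are demethylation-resistant promoter tiles, so the
  recovered group-level delta is shrunk by a few percent relative to the
  planted per-site delta (e.g. ~0.19 recovered for 0.20 planted) — the
  estimator is faithful to what a tile-weighted global level measures.
* **Accessibility.** Background GCH accessibility is 0.03–0.04 with
  accessibility 0.9 inside planted NDR loci, which are GC-dense (GCH every
  4 bp vs 15 bp background). At a realistic low background, 2–3 covered
  accessible calls in a 100-bp window clear the p < 10⁻¹⁵ bar, so per-cell
  NDR calling works at 14.8% Bernoulli coverage; against a 0.2 background it
  provably cannot (a window would need > 20 covered accessible calls).
* **Subclone offsets** (+0.05, −0.05, 0) are mean-zero across equal-sized
  subclones, preserving the group delta while planting the ~10-point
  between-subclone methylation difference.
* **Expression** is log-normal per gene, suppressed by promoter methylation
  through an exponential coupling (strength 2.0), with UMI counts Poisson at
  ~20k per cell; extra gene-body demethylation in cancer declines linearly
  with the gene's expression rank in normal cells (max 0.10).
* **CNV**: 500-kb default bins, Poisson read counts proportional to
  copy × bin length (~5×10⁵ reads/cell), one truncal gain per patient plus
  three segments per subclone at copy 1 or 3; subclones get distinct segment
  sets whenever the genome has room, falling back to cross-subclone overlaps
  (mimicking convergent SCNAs) only on small genomes; segments are always
  disjoint within a subclone. chrX is copy 1 in male patients. Methylation is drawn
  independently of copy number, which is what the correlation null tests.

What passing tests on this cohort do **not** show about real data: the
generator has no read-level coverage correlation (sites are independent
Bernoulli draws, so site coverage is less clumped than real reads), no
bisulfite non-conversion gradient, no CNV-driven coverage bias in the
methylome, uniform site spacing instead of the real CpG/GpC landscape, and
planted NDRs are intergenic, so the RNA–accessibility coupling observed in
real promoters is absent by construction.

## Problem sizes and determinism

Tests and the acceptance script run stage recoveries at 30–60 cells per
group on 4–35 Mb genomes — sizes chosen so each property is well-powered
while the whole suite stays desk-scale; the demo pipeline uses a reduced
two-patient cohort on a 10.5-Mb genome. All randomness flows from a single
seed; the pipeline fans it out to stages by CRC-hashing stage names, so any
stage can be re-run reproducibly in isolation. Identical seeds produce
byte-identical datasets and manifests (tested).

## Known limitations

* Negative or zero normal-baseline windows make DDemeD undefined (NA) rather
  than imputed; heavily demethylated normal references will thin the map.
* The exact rank-sum enumeration switches to the normal approximation in the
  presence of any tie, which is conservative for the heavily tied promoter
  levels of very sparse cells.
* The 5%-of-cells mNDR support convention is exposed as an integer because
  published usages round inconsistently; callers must pick the rounding.
* Aneuploidy calling is threshold-based, not model-based; near-tetraploid
  cells scale-normalize to diploid and would be missed, as with any
  read-depth-only method.
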