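# Methods

This note documents the models implemented in `rarecode`, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and known limitations.

## Codon adaptation index

For a usage table giving genome-wide codon frequencies `f(c)`, the relative
adaptiveness of a sense codon is `w(c) = f(c) / max{f(c') : c' synonymous
with c}`, so each synonymous family has at least one codon with w = 1
(several if frequencies tie). The CAI of a CDS is the geometric mean of w
over its scored codons, computed in log space.

Conventions (compatible with the widely used CAIcal implementation):

* the terminal stop codon is excluded from scoring; an internal stop codon
  is an error;
* Met and Trp are scored — their single-codon families have w = 1, so they
  dilute the geometric mean toward 1 but carry no synonym information;
* codons containing N are skipped and tallied separately;
* a zero-frequency codon in a family with nonzero maximum receives a
  configurable floor (default w = 1e-3) so log-space arithmetic stays
  finite. Real genome tables rarely contain zero sense codons; the floor
  matters mainly for adversarial synthetic tables.
* CAI is reported to 3 decimals in writers.

Transcripts are binned rare/mid/common at boundaries 0.68 and 0.78, with
boundary membership rare = [0, 0.68), mid = [0.68, 0.78], common =
(0.78, 1]: the bin definitions are phrased as "below 0.68" and "greater
than 0.78", so both boundary values fall in the mid bin.

Codon classes for composition profiling default to a rank rule — common
iff w = 1 in its family, rare iff w equals the family minimum in a
multi-codon family, intermediate otherwise; single-codon families (Met,
Trp) are common. No consensus numeric threshold exists for "rare codon",
so a frequency-threshold mode (`rare_threshold`) is provided as an
alternative.

`genome_cai_percentile` is the fraction of genome CAI values strictly below
the query, ×100; a query equal to the genome maximum therefore returns
100·(n−1)/n, not 100.

## PWM scanning with exact p-values

The motif model is an L×4 position probability matrix over A,C,G,T (RNA
matrices are converted on load; rows may be labelled, orientation is
auto-detected, and counts are normalized after adding a pseudocount). A
window is scored as the sum of per-position log2 odds against a background
distribution (uniform by default; the background used is recorded so
results are auditable).

P-values are exact rather than empirical: per-position log-odds are
discretized to an integer grid (granularity 0.01 log-odds units by
default), and the distribution of the discretized score of a random
background word is built by positionwise convolution — O(L·grid·4) — never
by 4^L enumeration. Window scores are discretized identically, so the
p-value of a window is an exact survival-function lookup. The test suite
checks bit-level agreement with a full 4^L enumeration oracle for L ≤ 6
and that halving the granularity changes no hit class.

Scanning conventions:

* scan region = last ⌈0.25 × n_codons⌉ codons of the CDS (codon-boundary
  aligned, ceiling rule, preserving frame semantics) concatenated with the
  whole 3'UTR; a region shorter than the motif yields zero hits;
* sense strand only — targets are mRNAs;
* two thresholds: p < 0.005 significant, p < 0.01 suboptimal;
* overlapping matches are each counted (per-position convention); a
  `merge_overlaps` option keeps the best hit per run of mutually
  overlapping hits for sensitivity analysis;
* site density = reported hits / (region length / 1000), i.e. sites per
  kilobase of the region actually scanned, not of the whole transcript;
* windows containing N are skipped;
* a motif position with zero probability takes a fixed −100 log-odds
  penalty (keeps arithmetic finite while making a mismatch decisive); a
  zero-background base with nonzero motif probability is rejected as an
  infinite score.

`frame_rarity_profile` decomposes a motif word into the codons covering it
in each of the three reading frames (completing partial codons from
flanks) and classifies them, quantifying how a frame shift of the same
U-rich element can enrich rare or common codons. Stop codons arising in a
shifted frame are labelled "stop" rather than raising, since they occur
legitimately there.

## Synonymous recoding

`optimize_cds` / `deoptimize_cds` replace every sense codon with the
maximum-/minimum-w synonym (ties broken lexicographically, so recoding is
deterministic); both are idempotent, preserve the protein exactly, and
bracket the CAI of any input (deoptimized ≤ input ≤ optimized = 1.0).
`motif_preserving_recode` optimizes everywhere except nucleotide windows
(e.g. significant scan hits), which are expanded outward to codon
boundaries — a codon is preserved if any of its three nucleotides overlaps
a window — so binding-site nucleotides survive intact. Tag sequences are
attached verbatim and must be in frame; CAI can be computed with or
without tags. Preserved windows are explicit inputs: which sites to
restore is an experimental design decision, not something inferred.

## Expression enrichment

FPKM is converted per column as TPM_i = (FPKM_i / Σ FPKM) × 10^6 (the
standard definition; every TPM column sums to one million). Genes with
zero abundance in all cell types are dropped ("genes expressed") before
percentile ranks are computed per column with average-rank tie handling,
making calls invariant under any monotone rescaling of a column. A gene is
called enriched in the target cell type when its rank percentile there is
≥ 75 (top 25%, boundary inclusive) and ≤ 60 (bottom 60%, inclusive) in
every other column supplied; the caller does not decide which columns
count as "other tissues" — the user controls the matrix. Calls from
multiple datasets are intersected, with provenance recorded.

Distribution comparisons use the two-sample Kolmogorov–Smirnov test
(exact p for n ≤ 20, asymptotic otherwise) with a two-tailed Welch t-test
reported as secondary.

## Convergence statistics

`ols_fit` is ordinary least squares with Pearson r and a two-sided p from
the t distribution with n−2 df (scipy's linregress, cross-checked against
closed-form normal equations in the tests). A constant response returns
slope 0, r 0, p 1. Regressions report raw p; a Benjamini–Hochberg adjusted
column is additionally available. `binned_regression` fits site density on
CAI separately within the rare/mid/common bins; bins with fewer than 3
points (or zero CAI variance) are flagged insufficient rather than
silently dropped.

The candidate cascade applies, in fixed order: DE direction → CAI
strictly < 0.68 → density strictly > 9 sites/kb → membership in an
explicit binding-evidence gene set → membership in an explicit
known-brain-role gene set. Inequalities are strict because the filter
definitions are phrased as "less than" and "more than". The order is fixed
because intermediate counts depend on it even though the final set does
not. Genes missing from the CAI or density maps are reported as skipped,
never silently dropped, and the stage-subset invariant is asserted on
every run.

## Quantification

Relative abundance from qRT-PCR is 2^(CT_ref − CT_target), with the sign
convention chosen so that larger values mean more target (a dilution
series with ΔCT steps of 3.32 cycles yields 10-fold abundance steps).
Decay is quantified as the per-replicate ratio of treated to untreated
relative levels after a transcription shutoff — for noiseless first-order
decay this equals exp(−kt) exactly — summarized as mean ± SEM and compared
between genotypes with a two-tailed Welch t-test (pooled-variance
optional). Welch is deliberately the default; at n = 3 per group it is
conservative (empirical type-I rate ≈ 0.02–0.04 at α = 0.05), approaching
the nominal rate by n = 5. Half-life fitting from multi-timepoint ratios
is provided as an optional extra beyond the single-timepoint design.
`protein_per_mrna` computes 100 × protein/mRNA from control-normalized
means; the function is named for what it computes.

## Synthetic data

All generators are pure functions of (parameters, seed) and return a
`SyntheticTruth` sidecar sufficient to recompute expected outputs.

* `synth_usage_table`: every multi-codon family spans a max:min frequency
  ratio of `skew` (default 4, a typical genome-wide synonym skew) with a
  seeded assignment of which codon is common; skew 1 is the documented
  degenerate case where every codon classifies as common.
* `synth_cds`: a fixed random protein per seed; positions are assigned
  max-w or min-w synonyms, with the min-w count chosen by monotone search
  on the log-CAI plus single-position swap refinement, reaching the target
  CAI within tolerance (default 0.005) or raising with the attainable
  range. Default panel targets span ~0.55–1.0, the range of codon-modified
  reporter designs.
* `plant_motifs`: writes the exact consensus at non-overlapping positions
  of a background drawn from a stated composition; when a PWM is supplied,
  background windows that spuriously reach significance are rejection-
  resampled, so the planted sites are the only significant matches.
* `synth_expression`: log-normal abundance with a per-gene baseline shared
  across cell types (log-SD `dispersion`, default 1.0) plus independent
  per-cell-type log-noise (`within_sd`, default 0.1). The shared baseline
  emulates the strong cross-cell-type correlation of real expression data;
  `dispersion=0` gives fully independent columns (for chance-rate
  analysis). Planted markers are multiplied by `effect_size` (default 100)
  in their home cell type and divided by it elsewhere; their baselines are
  clipped to ±2 SD because real marker genes are not extreme-abundance
  outliers — and an unboundedly rare transcript could otherwise fail to
  reach the top quartile even after a 100-fold boost.
* `synth_ct_table`: treated target CTs rise by k·t/ln2 cycles (the 2^ΔCT
  image of exp(−kt) decay) plus Gaussian CT noise (default SD 0.1 cycles,
  typical qPCR replicate scatter); the housekeeping reference is constant.
* `synth_de_table`: the regulated subset is sampled with probability
  (1−rare_bias)·uniform + rare_bias·(lowest-CAI-decile indicator);
  regulated genes get negative log2FC and small adjusted p (decreased on
  depletion of the regulator = normally up-regulated by it).

What the generators do **not** emulate: read-level noise and alignment
artifacts (no FASTQ), UMI/count statistics (abundances are already
normalized), RNA secondary structure around motifs, correlated motif
co-occurrence, batch effects, and amplification-efficiency differences in
qPCR. Passing tests therefore demonstrate correctness of the computations
under the stated statistical structure, not robustness to every artifact
of real data.

## Problem sizes

The acceptance script uses: 50 random CDSs + 6 CAI targets at 500 codons
(CAI engine); 20 random PWMs of L 3–6 against 120-nt sequences checked
window-by-window against the 4^L oracle, and 10 UTRs with 4 planted sites
each; three 1000-gene expression matrices with 50 planted markers per cell
type; a 400-gene planted site-density panel and cascade; 1000 null decay
simulations at 5 replicates per group; and 1000 random CDSs for protein
preservation. These sizes give stable statistics in seconds on one CPU.

## Known limitations

* The scanner handles one PWM at a time; there is no motif library, RNA
  secondary-structure weighting, or conservation scoring.
* The enrichment caller assumes the supplied columns are the complete set
  of relevant cell types; results depend on that choice.
* Exact p-values are exact for the discretized score; granularity 0.01 is
  far finer than any decision boundary in practice, and the test suite
  checks classes are stable under halving it.
* The cascade consumes externally produced DE tables and gene lists;
  differential expression itself is out of scope.
* Published reference inputs (genome usage tables, RBPmap matrices,
  deposited expression datasets) are user-supplied files; the package
  ships only synthetic stand-ins, clearly labelled as such.
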