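# Methods

## Study design emulated

The package analyses an F1-hybrid expression design: two inbred parental
strains (BL6, CAST) measured in six biological replicates each, and twelve
F1 hybrids in which every transcript's expression is estimated separately
per parental allele. Inputs are transcript-level expression estimates with
per-estimate standard errors (the granularity produced by probabilistic
read-to-isoform deconvolution tools, whose Monte Carlo standard errors play
the role of the `se` matrix), transcript models in GTF, and a per-gene
count of known inter-strain variants. Read alignment and isoform
deconvolution themselves are out of scope: the pipeline consumes estimate
tables.

## Selection funnel

Genes enter the analysis only if they express exactly two overlapping
isoforms and are heterozygous between the strains:

1. **Detection threshold** `t` = minimum mean expression among transcripts
   with at least 10 uniquely mapping reads. Transcripts with that much
   unique evidence are reliably quantifiable; the least-expressed of them
   marks the detection boundary. "Mean expression" is the mean across all
   sample columns (a single scalar per transcript; the design is open —
   any per-transcript scalar monotone in expression would do).
2. **Expressed** = strictly above `t` in ≥ 4 replicates of either F0 group
   (per group, not pooled), and in ≥ 4 of the 12 F1 libraries, where an F1
   library's value for a transcript is the sum of its two allele
   estimates. Strict inequality avoids threshold-equality ambiguity. The
   F1 requirement counts the 12 libraries, not the 24 allele columns.
3. **Analysis set** = genes with exactly two expressed transcripts that
   overlap exonically (≥ 1 shared base, same strand — span overlap would
   call two isoforms sharing only an intron a pair, contradicting the
   structural analysis) and ≥ 1 known variant. Non-overlapping pairs are
   counted separately in the funnel report.
4. Optional **uncertainty subsetting**: keep transcripts whose mean SE is
   at or below the maximum SE among transcripts with exactly 1 (`t1`) or 5
   (`t5`) unique reads. Retention is inclusive so a uniformly uncertain
   table keeps everything; if no transcript has the anchor count, the
   nearest available count anchors the threshold (with a warning).

## Regulatory classification

Per gene, isoform usage is the natural log-odds of the two expression
estimates, with a pseudocount ε (default 10⁻³ × the table's median
estimate) guarding zeros; samples where both isoforms are zero are dropped
as missing. Two statistics summarise the gene: the F0 strain difference
d₁ and the within-replicate F1 allelic difference d₂.

Variances: each group mean's squared standard error is the replicate
sample variance over n, multiplied by (n−1)/(n−3), plus the mean squared
per-estimate SE (delta-method propagated to the log-odds scale) over n.
The (n−1)/(n−3) factor matches the variance of a t-statistic with n−1
degrees of freedom: with six replicates the plug-in variance estimate is
itself noisy, and without the correction the normal marginals are
overconfident exactly in the tail that produces false divergence calls.
F1 allelic differences are paired within replicates, so their SE
contributions add per pair.

The four models (conserved, cis, trans, cis&trans) place independent
N(0, σ₀²) priors on free effects; the cis model shares a single effect
between d₁ and d₂, inducing a bivariate normal marginal with covariance
σ₀² between the two statistics. cis&trans uses independent priors on the
two effects rather than an explicit β₁ ≠ β₂ constraint — with continuous
priors the equality event has measure zero. All marginals are closed-form
normals, and the test suite checks them against brute-force numerical
integration over the effect priors.

σ₀ defaults to 2.0 on the natural-log-odds scale (≈ 7.4-fold isoform-ratio
change per prior SD): weakly informative for the effect sizes this design
can detect, and configuration-exposed. Model prior is uniform (1/4); a
gene is labelled only when one posterior exceeds 0.5, i.e. when a model is
more probable than the other three combined, else it is unclassified. The
posterior margin (best minus second-best) is reported per gene.

For genes expressing ≥ 3 isoforms, the major isoform (highest mean F0
expression; ties broken by lowest transcript id, with a warning) is
compared against the summed expression of the rest, then classified
identically. Allelic-fraction summaries (gene-level BL6 share S, isoform-
specific BL6 share U per F1 replicate) provide the computational analog of
paired allelic expression assays, with a Spearman utility for comparing
two such vectors across genes.

## Structural classification

Strand-aware, on 0-based half-open exon intervals (converted from GTF at
the io boundary and nowhere else):

* first exons do not overlap → **AFE**; overlap with different 5' ends →
  **TSS**;
* last exons do not overlap → **ALE**; overlap with different 3' ends →
  **APA**;
* **INT** when the transcripts' splice-boundary sets differ after
  excluding (a) transcript termini (the 5' end of the first exon, the 3'
  end of the last), and (b) both boundaries of the first exons when AFE is
  set, and of the last exons when ALE is set.

Exclusion (a) prevents a terminal-end shift (already TSS/APA) from also
counting as a splicing difference; exclusion (b) prevents a wholesale
first/last exon swap (already AFE/ALE) from doing the same. The five
categories are therefore independent contributions, AFE/TSS and ALE/APA
mutually exclusive by construction. "Different start sites" means any
difference (≥ 1 bp); no slack window is applied. A first-exon donor shift
in an AFE pair is attributed to AFE, not INT — one consistent choice where
the convention is genuinely open. Classification is symmetric in the two
transcripts, invariant under coordinate mirroring with strand flip, and
swaps 5'/3' categories under mirroring without flip; the test suite
enforces all three properties and cross-checks against an independent
brute-force implementation that orients transcripts 5'→3' and compares
tagged donor/acceptor sets.

## Cross-tabulation statistics

Fisher's exact test (two-sided, minimum-likelihood convention — the sum of
all equally-or-less-probable tables with the observed margins, the
dominant software convention) for category-by-mechanism contrasts; Pearson
χ² without continuity correction for independence tests (with a warning
when expected counts fall below 5); Benjamini–Hochberg adjustment across
cells. Table-style percentage matrices compare each divergence class
against the conserved class by default, with arbitrary class pairs (e.g.
cis vs trans) available. The INT-alone excess test builds the 2×2 of
INT(yes/no) × any-other-flag(yes/no) and tests independence — one
defensible reading of "more often alone than expected by chance".

## Synthetic cohorts

The generator defines the study conditions; its defaults are the emulated
design: 6 F0 replicates per strain, 12 F1 replicates, effect size 1.5 on
the log-odds scale, replicate noise SD 0.2, uniform class probabilities.
Per gene: baseline log-odds μ ~ Uniform(−0.8, 0.8) (bounded so both
isoforms remain quantifiable, mirroring the expressed-isoform
preselection); F0 replicate log-odds ~ N(μ ± β_f0/2, noise_sd²); F1
allele log-odds ~ N(μ ± β_f1/2, noise_sd²) within each replicate. Classes
set (β_f0, β_f1) = (0,0), (β,β), (β,0), (β,β/2) for conserved, cis, trans
and cis&trans respectively — for cis&trans, the allele-linked component
and the diffusible component each contribute |β|/2. Effects split
symmetrically ±β/2 around μ so total expression stays orthogonal to
usage. Log-odds become expression via a per-gene total ~ 200·LogNormal(0,
0.4) (F1 alleles carry half each); genes flagged for expression
divergence (probability 0.37, independent of usage class, enabling
true-null independence tests) get a two-fold strain shift of the total,
which leaves proportions untouched. Reported SEs follow se_floor +
se_scale/√expression (0.5 + 5/√e), decreasing with expression like Monte
Carlo standard errors do; unique reads are proportional to mean expression
(4 reads per unit).

Structural flags are drawn with marginal probabilities approximating the
relative frequencies observed in divergent mouse liver isoform pairs
(AFE 0.43, TSS 0.39, INT 0.54, ALE 0.33, APA 0.48, respecting mutual
exclusivity); the transcript-pair builder then derives the alternative
isoform from a four-exon reference by exactly the requested modifications,
so generator and classifier are closed over flag sets by construction.
Spike-in genes (single-isoform and three-isoform, zero variants) exercise
the funnel; single-isoform spike-ins are generated at low expression
(≈ 4 units, ≈ 11 unique reads) so they anchor the detection threshold the
way marginally quantifiable transcripts do in real cohorts, well below the
main genes' expression range.

The in-silico F1 constructor halves two F0 columns into pseudo-allele
columns with SE-model resampling noise, recording the originating values
as truth; correlation of reconstruction with truth (Pearson, log scale)
exceeds 0.95 at the default noise and approaches 1 as noise vanishes.

What the generator does **not** emulate: count-level (binomial/Poisson)
noise and the resulting mean–variance coupling of real read data — noise
is normal on the log-odds scale, matching the estimate-table granularity
the pipeline consumes; cross-direction (BL6×CAST vs CAST×BL6) and
parent-of-origin effects — the twelve F1 replicates are exchangeable;
isoform-deconvolution ambiguity between similar transcripts (SEs are
independent across isoforms); and real genomic sequence. Passing tests
therefore demonstrate correctness of the decision machinery under the
stated generative model, not robustness to deconvolution artefacts.

## Numerical choices and degenerate inputs

Log-odds of (0, 0) estimates are flagged missing and dropped from group
means; fewer than two usable replicates in any group is an error. Ties
for the major isoform resolve to the lowest transcript id with a warning.
Zero-margin contingency tables yield p = 1 with an undefined-odds-ratio
flag rather than an error. Posteriors are computed via log-sum-exp.
Variant counting assigns a variant to every gene whose span (introns
included) covers it — the funnel's criterion is per-gene heterozygosity,
not variant uniqueness — and counts indels identically to SNVs.

## Problem sizes

The bundled experiments use cohorts of 100–400 genes for parameter
recovery (100 per class), 1258 genes plus 24 spike-ins for the end-to-end
run, 800 transcripts for the in-silico F1 correlation, and 50 random
summaries for the marginal-likelihood integration check — sizes at which
every stage completes in seconds while estimates of rates (accuracy,
false-divergence) carry sampling error of a few percent at most.

## Known limitations

The Bayesian comparison uses summary statistics with plug-in variances,
not a full hierarchical posterior over replicate-level data; its false-
divergence behaviour is calibrated under the generator's noise model.
Structural classification is pairwise only, by design: the two-isoform
restriction is what isolates a single regulatory change per locus.
Real-data headline counts from any particular cohort depend on that
cohort's expression tables and are reproduced in shape, not in number, by
the synthetic experiments.
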