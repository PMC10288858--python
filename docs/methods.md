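# Methods

`mitoscreen` implements a screening pipeline that takes pooled,
multi-dataset bulk RNA-seq count matrices from post-mortem brain tissue to
a ranked shortlist of mitophagy-related candidate genes. This note
describes the statistical models, the deliberate simplifications, the
synthetic-data generator that stands in for controlled-access cohort data,
and the design choices made where the problem was genuinely open.

## Cohort definition

Diagnosis is assigned from the Braak neurofibrillary-tangle stage:
0/I/II → control, IV/V/VI → AD, III → excluded as diagnostically ambiguous.
A missing stage gets its own exclusion code (`braak_missing`) so absent
pathology data is never conflated with the ambiguous middle stage.
Inclusion further requires the sample's detailed brain region to map to the
target lobe (a configurable synonym table sends e.g. *dorsolateral
prefrontal cortex* and *superior frontal gyrus* to `frontal`) and donor age
strictly greater than 65 years (late-onset disease only; the boundary is
exclusive and configurable). When a sample fails several rules, the
exclusion log records the first failing rule in the fixed order
region → age → Braak, keeping logs deterministic. Censored ages ("90+")
parse to 90.0 with a flag; missing PMI (post-mortem interval, hours) is
imputed with the cohort median and flagged, because the DE design requires
complete covariates.

## Sex prediction

chrY genes are essentially silent in female samples, so the per-sample
statistic log10((ΣchrY + 1)/(ΣchrX + 1)) is bimodal with a separation of
orders of magnitude. Samples are split at the largest gap of the sorted
ratios — deterministic, seed-free, and equivalent to 2-means for bimodal
one-dimensional data; if the largest gap falls below a minimum separation
(default 1.0 log10 units, i.e. the cohort looks single-sex or degenerate) a
fixed threshold (default −1.0) is used instead and a warning logged. The
pseudocount of 1 on both sums keeps ratios finite.

A PCA on sex-chromosome expression corroborates the calls: log2 CPM values
restricted to chrX/chrY genes are gene-standardised (correlation PCA) and
decomposed by SVD; each sample's side of PC1, oriented by the mean
coordinates of the two called groups, must agree with its ratio call. The
unit-variance scaling is deliberate: without it the on/off variance of chrY
genes dominates PC1 entirely and the check could never disagree with the
ratio; with it, the milder chrX sex signal (X-inactivation-escape-like
expression) contributes, so a sample whose chrY counts contradict its chrX
pattern is flagged discordant. Mismatches against the reported sex are
flagged, never auto-corrected; the pipeline stratifies on predicted sex by
default (rescuing samples with missing labels), configurable to reported.

## Differential expression

Counts for gene g in sample s are modelled as negative binomial with
Var = μ + α·μ², log μ_gs = log N_gs + x_sᵀβ_g. The normalisation factor
N_gs combines median-of-ratios size factors with per-gene-per-sample
average-transcript-length offsets: lengths are divided by their per-gene
geometric mean to give relative length factors, size factors are computed
on the length-corrected counts, and the two multiply. The design is
intercept, standardised covariates (age, PMI), surrogate variables, and the
AD-vs-control indicator as the last, tested coefficient. The Wald
statistic β̂/SE(β̂) is referred to the standard normal; fold changes are
reported as β/ln 2. p-values are Benjamini–Hochberg adjusted (missing
entries pass through and do not count toward the family size), and DEGs are
flagged by the strict thresholds padj < 0.05 and |log2FC| > 0.1.

Fitting is IRLS vectorised across genes: the design matrix is shared, so
the weighted least-squares updates for all genes are batched with einsum
and batched solves (2,000 genes × 60 samples fit in well under a second).
Genes whose IRLS does not converge are refit as Poisson and flagged;
all-zero genes are filtered.

Simplifications relative to the full DESeq2 machinery, each deliberate and
tested through calibration properties rather than value-matching:

* **Dispersion** is a per-gene method-of-moments estimate on normalised
  counts, α̂ = max(s² − m, 0)/m², pooled across condition groups with
  degrees-of-freedom weights and floored at 1e-8 — no empirical-Bayes
  shrinkage. Pooling within condition groups (not across all samples)
  keeps the condition effect itself out of the dispersion; pooling across
  would destroy power in exactly the planted-effect settings the screen
  targets.
* **Independent filtering** is a fixed mean-normalised-count threshold
  (default 1): filtered genes keep their p-value but get a missing padj
  and leave the BH family.
* **No fold-change shrinkage.**

Null simulations show the resulting raw p-values are calibrated (type-I
error at 0.05 within [0.035, 0.065] over 2,000 genes, across seeds), which
is the property the downstream BH control relies on.

### Surrogate variables

Hidden structure (batch) is estimated by a simplified surrogate-variable
analysis on log2(normalised + 1) expression: each gene is regressed on the
known design, the residual matrix is decomposed by SVD, and — the step that
matters — each surrogate is reconstructed by projecting the
*unresidualised* expression onto the residual gene loadings. A surrogate
taken directly from the residual right-singular vectors is orthogonal to
the condition by construction, so adding it to the design is a pure
reparametrisation that cannot remove the condition-confounded component of
a batch effect (measured on simulated confounded designs: false-positive
DEGs were not reduced at all). Projecting raw expression on the loadings
recovers the full batch axis, including the confounded part, after which
the model rescues partially confounded designs (measured: false positives
drop from >1,000 to ~0 at 50% confounding). Each SV is centred,
orthogonalised within the SV block, unit-norm, and sign-fixed
(largest-magnitude entry positive). The number of SVs k defaults to 2 and
is exposed; there is no universally right k and the screen's results
should be checked for stability across small k.

Batch-adjusted expression for visualisation uses a log2(normalised + 1)
transform (a documented stand-in for the variance-stabilising transform)
with the fitted nuisance effects (covariates + SVs, never the condition)
subtracted gene-wise; it is returned in a container type the DE fitter
does not accept, because adjusted matrices must never feed the count
model.

## Geneset focusing, networks, candidate criteria

Genesets whose *names* contain any focus keyword (default: mitophagy,
lysosome, phagosome; case-insensitive substring, names only) are pooled
into an order-stable non-redundant member union, which is intersected with
the per-sex DEG lists. No enrichment statistic is involved — the focusing
step is knowledge-driven by design, so genes with small fold changes in a
relevant process are not lost to enrichment thresholds.

The per-sex PPI subnetwork starts from the keyword-focused DEGs
("members"). Edge tables are cleaned (self-loops dropped, unordered
duplicates keep the maximum score, 0–1000 combined scores auto-rescaled)
and thresholded at a combined score of 0.4 (medium confidence; the cutoff
is exposed). Any other DEG interacting with at least 20 distinct member
genes joins as a "candidate new member" — applied in one pass against the
original member set by default, with an iterate-to-fixpoint variant behind
a flag. Degrees are computed within the final augmented subgraph, since
shortlisted genes may themselves be augmented nodes.

Each miRNA's regulation direction is resolved by majority over its up/down
literature-report counts; ties (including 0–0) are excluded entirely. Per
gene, distinct up- and down-regulated targeting miRNAs are tallied
(duplicate pairs from multiple source databases count once).

Candidate criteria over down-regulated DEGs, inclusive thresholds as
printed: (1) degree ≥ 20 in the male or female network (max over available
degrees; a gene absent from both networks is an error); (2) at least 10
up-regulated targeting miRNAs; (3) down-regulated targeting miRNAs no more
than one third of the up-regulated count. A gene passing all three is
selected; failing exactly one makes it a near miss, reported in its own
tier — the mechanism by which a gene that narrowly violates the ratio
criterion still surfaces for the manual literature step. That fourth,
literature criterion is carried as an annotation column and never
computed, and never changes the automatic verdict. Reports are sorted by
(verdict, max degree desc, up-miRNA count desc, gene id) for fully
deterministic output.

## qPCR relative quantification

ΔCt = Ct(target) − mean Ct(reference genes) (arithmetic mean on the Ct
scale ≡ geometric-mean normalisation on the linear scale; defaults HPRT1
and RPL13A). ΔΔCt calibrates against the mean control ΔCt within each sex
stratum, RQ = 2^−ΔΔCt, so the control mean RQ is 1 by construction and the
identities RQ = 1 (null) and RQ = 0.5 (ΔΔCt = 1) hold exactly on
noise-free input. Group tests are two-sample t-tests on ΔCt — the log
scale, where approximate normality is plausible — Bonferroni-corrected by
the number of comparisons in the family, with significance stars at 0.05 /
0.01 / 0.005 / 0.0001. Amplification efficiency is fixed at 2.0; a
per-pair calibrator mode (`paired=True`) is available for matched designs,
unpaired is the default.

## Synthetic cohorts: what they emulate, and what they do not

`simulate_cohort` draws gamma-Poisson (hence NB) counts with mean
μ_gs = libsize_s · lengthnorm_gs · base_g · batch_gd · 2^(lfc·I[AD]),
per-gene dispersions jittered around `dispersion_base` (default 0.05,
typical of bulk brain tissue), log-normal baselines (log-mean 4, log-SD 1,
i.e. median ≈ 55 counts), per-dataset gene-wise multiplicative batch
effects (log-SD 0.1 by default; a `batch_confounding` knob skews the
AD/control composition across datasets to test SV rescue), library sizes
uniform within ±30%, and per-gene transcript lengths with small per-sample
jitter so the length-offset path is always exercised. Default cohort: 2
datasets × 15 samples per disease × sex cell (120 samples). 10% of
autosomal genes are planted DE at |log2FC| = 1 (20% of them sex-specific);
ages are uniform on 60–95 so some samples violate the >65 filter, ~5% of
samples are relabelled Braak III, ~5% carry a non-frontal region, 2% of
reported sexes are deliberately flipped and 2% are missing. chrY genes are
scaled by 1e-3 in true-female samples; chrX genes carry a 2× female factor
emulating X-inactivation escape, which is what gives the PCA concordance
check independent information.

`simulate_networks` wires the companion tables so the planted candidates —
and only they — satisfy all three automatic criteria: each candidate gets
≥ 25 high-confidence edges to geneset-member DEGs and ~12 distinct
up-regulated targeting miRNAs with at most a third as many down-regulated
ones; planted hubs sit outside the genesets but meet the augmentation
threshold; one decoy fails only the up-miRNA count, one fails only the
ratio; one miRNA has tied report counts to exercise the exclusion rule;
duplicated target rows exercise distinct counting.

Limits worth stating: real brain cohorts have correlated gene-gene
expression, cell-type composition shifts, much smaller effect sizes
(|log2FC| mostly ≤ 0.4 in pooled analyses), non-NB artefacts and
structured missingness, none of which the generator reproduces. Passing
the planted-recovery tests therefore demonstrates that the machinery is
correct and calibrated under its own assumptions — not that the screen's
operating characteristics on real tissue match the simulated ones.

## Numerical choices

Linear predictors are clipped at ±30 before exponentiation; IRLS runs at
most 60 iterations with tolerance 1e-8 and a 1e-10 ridge on the normal
equations; non-converged genes (final step > 1e-4) refit as Poisson and
are flagged. The dispersion floor is 1e-8. BH uses a stable mergesort and
enforces monotonicity by a reverse cumulative minimum. Ties in the
candidate report break lexicographically by gene id. Problem sizes used
throughout the test-suite and reproduction script (2,000 genes, 60–120
samples, 10-replicate calibration loops) were chosen as the smallest
cohorts at which the calibration and recovery properties are stable across
seeds.
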