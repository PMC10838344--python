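# Methods

## The analysis in one paragraph

A perturbation (e.g. forced receptor overexpression) dysregulates a set of
genes; a candidate drug is interesting when it pushes those genes back the
other way. Both effects are measured against the same untreated control:
gene g is a Flip(Up→Down) DEG when it passes the perturbation DEG rule
upward in the perturbation-vs-control contrast and the drug DEG rule
downward in the drug-vs-control contrast (Flip(Down→Up) mirrors this).
The flip classes are then propagated through three enrichment layers —
pathways, TF regulons, and a drug-signature library with its target
annotations — to describe the drug's mode of action and to find other
compounds that mimic it.

## Differential expression

The count model is negative binomial with variance μ + αμ². Normalization
uses median-of-ratios size factors: per-gene geometric means over samples
(genes containing a zero are excluded; a `pseudo_reference` flag adds 0.5
everywhere for sparse matrices), per-sample median ratio, factors rescaled
to geometric mean 1 so they are depth-relative only. Per-gene dispersion is
method-of-moments on normalized counts, pooling the within-group variances
of the two contrasted conditions, floored at 1e-8; no trend fitting and no
shrinkage, deliberately, so every number is traceable to a closed-form
expression. The effect estimate is `log2((mean_alt + 0.5)/(mean_ref + 0.5))`;
the pseudocount 0.5 bounds fold changes when one group is all zeros. The
Wald statistic divides by a delta-method standard error built from the NB
variance at the estimated dispersion.

**Reference distribution.** The statistic is compared to Student t with
`n_ref + n_alt − 2` degrees of freedom rather than the normal. With the few
replicates typical of these designs the plug-in dispersion is noisy, and on
null NB data (2000 genes, 3 vs 3, dispersion 0.1) the normal reference
rejects ~11% of genes at nominal 5%; the t reference brings this to ~4%,
inside the calibration band the test suite enforces, and converges to the
normal as replication grows.

**Independent filtering.** Genes with mean normalized count below 1
(configurable) are excluded from testing and from the BH family and carry
NaN p/FDR. BH adjustment is the standard step-up over the tested genes.

**DEG rules.** Rules are strict-inequality thresholds on |log2FC| plus a
significance cut on either FDR or raw p. The shipped defaults encode an
asymmetric design: the perturbation moves expression strongly
(|log2FC| > 1.5, FDR < 0.05) while a drug's reversal is weaker (fold change
> 1.5, i.e. |log2FC| > log2 1.5 ≈ 0.585, raw p < 0.05). Whether the drug
rule's p is pre- or post-filtering is exposed as configuration
(`alpha_on`, `min_base_mean`) rather than hard-coded.

## Flip classification

Both contrasts share the control as reference. Flip membership requires
passing the drug-contrast DEG rule in the opposite direction — a mere sign
change is not enough — so the flip classes are subsets of the drug DEG set,
and together with the perturbed-only classes they exactly partition the
perturbation DEGs of each sign. No reversion-magnitude requirement is
imposed (the drug need not return the gene below the perturbation rule's
threshold). An alternative reading of "reversed by the drug" — a contrast
of drug vs perturbed rather than drug vs control — is available as a
configuration mode but is not the default. The flip score,
`−sign(log2FC_perturbed) · log2FC_drug` where the signs oppose and 0
otherwise, ranks genes by reversal strength; ties and concordant genes sit
at 0.

## Pathway enrichment and network

Enrichment factor: EF = observed / expected overlap, expected =
|pathway| · |flip| / |universe|. The universe defaults to the genes tested
in the DE step — the background must match the measurement space — and
flip genes must belong to it. Significance is the hypergeometric upper tail
(evaluated through the distribution's survival function, stable in log
space), BH-corrected across pathways. The network keeps FDR < 0.05 pathways
as nodes; an edge requires the two pathways' flip-gene memberships to
overlap hypergeometrically at p < 0.05 *within the flip universe* and to
share Jaccard ≥ 0.1 (both configurable; the Jaccard floor prevents
hairballs from single shared genes). K-means runs on L2-normalized rows of
the binary pathway × flip-gene incidence matrix; with `k='auto'` the
cluster count maximizes mean silhouette over k ∈ [2, min(10, nodes−1)],
falling back to a single cluster for degenerate inputs. Catabolic-side
pathways are scored against Flip(Up→Down) genes and anabolic-side against
Flip(Down→Up); both runs are emitted.

## TF regulon enrichment

A preranked running-sum enrichment: walking down the flip ranking, the sum
gains (normalized) weight at regulon members and loses 1/(N − m) at
non-members; ES is the signed extreme deviation. The null is gene-label
permutation — random same-size regulons — with NES = ES divided by the
mean |null ES| of matching sign and an add-one p-value (never exactly 0).
Regulons need ≥ 5 ranked genes; n_perm defaults to 1000 and a seed is
required.

**Weight exponent.** The default is 0 (classical KS, equal hit increments).
With the flip score as the ranking metric most genes carry weight exactly
0, and a weighted walk (exponent 1) normalizes within each regulon's hits:
a regulon containing two strong flip genes then traces nearly the same
profile as one containing thirty, and discrimination collapses. The
equal-increment walk counts top-ranked hits and separates flip-dense
regulons cleanly; exponent is still a parameter for rankings with dense
weights. Because the engine and regulon source behind the original
analysis are not public, this module is a methodological reconstruction,
not a replication: regulons arrive as GMT, and each TF is additionally
labelled with the flip class dominating its regulon, mirroring the
two-sided presentation of flip TFs. TF→flip-gene membership edges are the
only regulatory-network output emitted.

## Connectivity-map mimicry

Profiles are reduced to signatures of the n_sig = 100 most up- and
down-regulated genes (ties broken by gene id: genes sorted by (score, id),
bottom block = down flank, top block = up flank). Only high-quality
profiles of FDA-approved drugs are screened. The default similarity is
direction-aware: concordant hits are signature-down genes among
Flip(Up→Down) plus signature-up genes among Flip(Down→Up), divided by the
union of flip and signature genes; a pooled direction-blind Jaccard is a
configuration mode. The top decile (10% of retained profiles, rounded up,
ties at the threshold included) defines mimic profiles; a drug is a mimic
if *any* of its profiles qualifies — the most sensitive collapse over a
drug's multiple doses/times/cell lines, since no collapse rule is stated
for the original screen. Target enrichment then compares mimic drugs to
all screened drugs per target: EF = (k/n)/(K/N), hypergeometric p, BH
across targets; targets with no screened annotated drug are skipped. The
profile→drug→target order (select profiles, collapse to drugs, test
targets) is this package's resolution of an ambiguity in the original
description, which tests "the top 10% of Jaccard scores" (profiles) but
scores targets (drugs).

## Synthetic data generator

The generator emulates the deposited experiment's *statistical structure*,
not its biology: baseline means log-normal (natural-log mean 4, sd 1 —
median ≈ 55 counts), NB dispersion 0.1, sample depth factors uniform on
[0.7, 1.3], n = 5 replicates per condition (the study reports n = 5
primary cultures for its functional assays; its RNA-seq replicate count is
not printed, so this is a declared surrogate). Planted perturbation genes
shift ±3 log₂ units (8-fold — a strong overexpression response); flip
genes in the drug condition revert fully (`drug_revert_fraction` = 1) and
overshoot 2 log₂ units past baseline. The overshoot calibration makes
planted flips *unambiguous* drug DEGs: the drug-contrast threshold is
log2(1.5) ≈ 0.585, and at the default depth/replication the fold-change
standard error is ≈ 0.3, so a 2.0 offset sits > 3 standard errors beyond
the rule, whereas an offset of 1.0 leaves low-expression genes within ~1
SE of it and they are not DEGs in any recoverable sense.

Planted class sizes default to 80 Up→Down and 120 Down→Up flips among 200
up- and 300 down-shifted perturbation genes in a 2000-gene universe — the
same order of flip fraction as a strong rescue compound, at a size that
keeps the full pipeline fast. Pathways: 1 planted set drawing 70% of its
members from flip genes among 200 uniform decoys. Regulons: 1 planted (80%
flip members) among 50 decoys. Drug library: 200 drugs × 2 profiles,
decoy scores N(0,1); 10 planted mimic drugs whose profiles replace 60% of
each signature flank with direction-concordant flip genes at extreme
scores; decoy profiles are retained by the quality/FDA filter at rate
0.7 × 0.7 ≈ 0.49, so the screened library (~206 profiles) puts the decile
cut (~21 profiles) right at the planted block of 20 — mimics must beat
essentially every decoy, while a diffuse decile would dilute the
drug-level mimic set. Targets: every decoy target annotates exactly
round(5% × 200) = 10 drugs; the planted target annotates 8 of the 10 mimic
drugs plus 10 decoys. Fixed annotation *counts* (rather than independent
Bernoulli draws) keep the decoy targets' enrichment-factor estimates away
from the small-denominator regime where a ratio estimator's top-1 ranking
is noise; the point estimate EF is well known to be unstable for targets
with one or two annotations.

Every generator is a pure function of the config: sub-generators draw from
independent seed streams, and the same seed reproduces every artifact bit
for bit.

**What passing tests do and do not show.** The generator plants clean,
independent, symmetric signals: no correlation between genes, no batch
effects, no dose–response, no outlier samples, no overlap between planted
structures beyond what is declared, and effect sizes chosen to be
detectable. Recovery of planted signal therefore validates the *machinery*
— contracts, determinism, calibration, ranking behaviour — and says
nothing about sensitivity on real data, where effects are smaller,
correlated and confounded, and where the DE results of this simplified NB
pipeline will differ from a DESeq2 run with dispersion shrinkage and
outlier handling.

## Numerical and design choices

- Hypergeometric tails are computed once (`pathways.hypergeom_tail`) and
  reused by the target screen; the test suite checks it against exact
  integer enumeration for every parameter tuple with N ≤ 40.
- BH adjustment passes NaN (filtered genes) through without affecting the
  family size; the suite checks it against the brute-force step-up
  definition.
- All rankings break ties deterministically by identifier; K-means and all
  permutation nulls take explicit seeds.
- Ortholog maps keep only 1:1 pairs; ambiguous rows are dropped and
  counted, since no collapse rule for many-to-many orthology is stated.
- Counts are rejected if fractional unless rounding is explicitly
  requested; estimated-count pipelines (e.g. RSEM output) should opt in.
- Whether drug-library gene space is matched to the DE gene space before
  or after ortholog mapping is a configuration choice; the mapper works in
  either direction.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the full pipeline on
2000-gene, 5-replicate studies: 100 independently seeded studies for the
pathway layer, 20 for the TF and drug layers (500 permutations per regulon
there; 1000 is the analysis default), and 10 replicates per layer in the
acceptance script. These sizes make the planted-recovery statistics stable
while the whole suite stays fast on a single CPU.

## Known limitations

- The DE module is a transparent approximation to the DESeq2 family of
  methods, not a clone; gene lists on real data will differ.
- EF is reported alongside p/FDR, but ranking targets by raw EF is
  unstable when a target has very few annotated drugs; the output table is
  sorted by p for this reason.
- The TF layer's regulon catalogue is user-supplied; results are only as
  good as the regulons.
- No multi-factor designs, no batch correction, no dose series.
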