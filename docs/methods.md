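# Methods

`tmzpgx` implements a pharmacogenomic analysis chain for temozolomide (TMZ)
response in IDH-wild-type glioblastoma (GBM): in vitro dose-response
screening of patient-derived glioma stem-like cells (GSCs), genomic and
transcriptomic feature extraction, a boosted-tree response classifier, and
multi-sector heterogeneity analysis.  Because the cohorts such analyses are
run on are controlled-access, the package ships a synthetic study generator
with recorded ground truth; everything below describes both the analysis
models and what the generator does and does not emulate.

## Growth-rate-inhibition dose-response metrics

Endpoint viability assays confound drug effect with division rate, which
varies widely between GSC cultures.  GR metrics remove that confound by
normalising the treated endpoint x(c) against both the vehicle control
x_ctrl and the treatment-start count x0:

    GR(c) = 2^( log2(x(c)/x0) / log2(x_ctrl/x0) ) − 1

so GR = 1 is no effect, 0 is cytostasis and negative values are net cell
loss.  GR is undefined when the control failed to grow (x_ctrl ≤ x0); this
is raised as an error.  When no day-0 plate is available, x0 defaults to
the seeding density of 500 cells/well.

A four-parameter sigmoid GR(c) = GRinf + (1 − GRinf)/(1 + (c/GEC50)^h) is
fitted by bounded least squares (h ∈ [0.1, 10], GEC50 within 100× of the
tested range, initialised at the median concentration, the minimum observed
GR and h = 1).  GR50 follows in closed form,
GR50 = GEC50·((1 − GRinf)/(0.5 − GRinf) − 1)^(1/h), and is infinite when
GRinf ≥ 0.5 (the curve never reaches 0.5).  An optimiser failure degrades
to a flat-curve summary with infinite GR50 rather than aborting a cohort.
The traditional AUC is the trapezoidal area of relative viability
(treated/control) over log10 concentration, normalised by the
log-concentration span so a no-effect curve scores exactly 1.

Cohort classification standardises log10(GR50) across samples with finite
GR50 (GR50 spans decades, hence the log) and AUC across all samples.  A
sample is resistant when its governing z — z(GR50) when finite, z(AUC)
otherwise — strictly exceeds a threshold, default 0.  Higher AUC means more
surviving cells, so no sign flip is needed.  The default threshold and the
choice of governing metric are exposed as configuration; both z-scores are
always reported.  A metric constant across the cohort collapses to z = 0
(samples tie below the strict threshold); only when both metrics are
constant is classification refused.

## Variant and copy-number rules

Somatic variants are retained when the effect class is moderate (missense,
in-frame indel) or high (frameshift, stop gained, splice donor/acceptor),
tumor VAF is strictly above 5%, and matched-blood VAF is exactly 0.
Hypermutation is a strict "> 350 somatic mutations" rule assessable only on
whole-exome data; targeted panels report a missing flag rather than False,
so the missingness propagates into feature tables.  EGFRvIII is called when
two or more RNA-seq reads skip exons 2–7.

Coverage CNA: per-gene log2((t_i/T)/(n_i/N)) with a pseudocount of 1
(division-by-zero guard; the exact pseudocount is immaterial after
median-centering), centered so each sample's median is 0.  Classes follow
the step function with strict inequalities — boundary values take the
milder class — at −1.58 / −0.5 / 0.5 / 1.58, except EGFR on the GliomaSCAN
targeted panel, where the gain boundary drops to 0.3 (the panel
underestimates EGFR signal).  When several platforms call the same gene,
WES wins over GliomaSCAN over RNA-based prediction.  CDKN2A and CDKN2B are
collapsed to one "CDKN2A/B" locus taking the more extreme call, since they
are co-deleted as one event.  The concurrent-lesion flag requires PTEN
loss/deletion AND EGFR gain/amplification AND CDKN2A/B loss/deletion, and
is not assessable when any locus is missing.

## CNA prediction from expression

For RNA-only samples, per-gene copy-number classes are predicted from
expression.  Predictors for a target gene are the union of the pathway gene
sets containing it plus the target itself, z-scored per gene; a gene in no
set falls back to itself as sole predictor with a warning.  A multiclass
boosted-tree model is trained on the three collapsed classes
(deletion/loss, neutral, gain/amplification); five-level resolution is not
attempted because dosage effects on expression do not reliably distinguish
gain from amplification at cohort sizes of tens of samples.  Per-class
probability cutoffs are calibrated on samples with matched DNA calls by
maximising one-vs-rest F1 over the grid of observed probabilities (ties go
to the smallest cutoff; a class absent from calibration truth is left
uncalibrated and never predicted).  Because the grid contains every
achievable threshold, calibrated training-fold F1 can never fall below the
fixed 0.5 cutoff.  At prediction time the argmax among classes whose
probability clears its cutoff wins; otherwise neutral.  Missing predictors
are imputed at z = 0, with a warning above 20% missing.

## Expression normalisation, conserved genes and markers

Counts are converted to RPKM (count·10^9 / (length·library size)), log2(x+1)
transformed, and quantile normalised (each sample's ranks mapped to the
mean sorted profile; ties receive average ranks, so exact multiset equality
across columns holds for tie-free data).

Culture models drift from the tumors they derive from, so marker discovery
is restricted to genes whose expression is conserved between matched
culture/tissue pairs: per-gene Spearman correlation across pairs on
log2(count+1), then a two-component Gaussian mixture on the correlation
distribution, with the conservation threshold at the posterior-0.5 crossing
between the component means.  A mixture whose modes are closer than two
pooled SDs, or whose minor component weighs under 1%, is reported as not
separable rather than producing an arbitrary split.  Genes constant in
either matrix are excluded with a warning (their correlation is undefined).

Differential expression between resistant and sensitive tumors uses a
negative-binomial Wald test: median-of-ratios size factors (computed on all
genes, testing optionally restricted to the conserved set), pooled
method-of-moments dispersion per gene with a floor of 1e-4, a delta-method
standard error for the log2 fold change of normalised group means, and
Benjamini–Hochberg adjustment.  This deliberately does not reproduce
shrinkage-based dispersion estimation; the selection rule it feeds —
log2FC > 2.5 and adjusted P < 0.01, resistant over sensitive — is so
stringent that the simpler test's calibration suffices, which the null and
power simulations in the test suite check directly (a 12-vs-22 null with
2000 genes selects ≤ 1 gene; four genes spiked at log2FC 3 are all
recovered at dispersion 0.1).

The marker risk rule: z-score each marker gene across the cohort; a sample
is high-risk when any marker exceeds z = 2.  Zero-variance markers are
skipped with a warning.

## ssGSEA subtyping

Each sample is scored against the classical / proneural / mesenchymal
signature sets with a rank-weighted running sum: walking the genes by
descending expression, in-set genes add rank^0.75 (normalised by the in-set
total) and out-of-set genes add 1/(N − n_set); the score is the sum of the
running difference.  The 0.75 exponent is the original single-sample GSEA
default and is configurable.  Scores depend on expression only through
ranks.  Per-subtype scores are z-normalised across samples ("normalised
across samples" could also mean min-max; z was chosen and is flagged here)
and the argmax wins, with deterministic tie order classical < proneural <
mesenchymal.  A zero-variance subtype gets z = 0 with a warning.  The
three-subtype signature is the default; a four-set (neural) GMT can be
supplied for external-cohort comparisons.

## The response classifier

The default feature schema has 25 columns: 5 continuous (MGMT, EGR4,
PAPPA, LRRC3, ANXA3 expression) and 20 binary (MGMT promoter methylation,
MGMT fusion, three subtype indicators, EGFRvIII, seven driver SNV
indicators, six driver CNA indicators, the concurrent-CNA flag).  NF2
mutation, hypermutation and 5-ALA status are deliberately withheld because
external validation cohorts lack them; the schema is config-overridable and
its hash is carried by the model to prevent silent mismatches.  Assembly
never silently zero-fills: unavailable measurements are explicit missing
values.  Imputation replaces missing binary values with 0.5 (maximal
uncertainty between absence and presence) and missing continuous values
with the mean of the 5 nearest samples by Euclidean distance over mutually
observed continuous features; binary indicators are kept out of the
distance (a documented alternative would mix them in).  Observed values
are never altered.

The classifier is a gradient-boosted logistic-loss tree ensemble: 50 trees,
depth ≤ 3, learning rate 0.74, per-iteration row subsampling 0.35, L2 leaf
penalty 1.0.  These are taken as fixed defaults rather than re-searched.
A sample is called resistant when the predicted resistance probability is
at least 0.6 (boundary inclusive; the cutoff is interpreted on the
resistant-class probability, which the source analysis leaves implicit).
Evaluation reports training ROC AUC, seeded stratified 5-fold CV AUC,
confusion counts at the cutoff, and gain importances.

## Multi-sector heterogeneity

A patient with 2–4 screened sectors is S (all sensitive), R (all
resistant) or H (both labels present).  Detection rates as a function of
sectors sampled use exact enumeration of every k-subset per patient (at
most C(4,2) = 6 subsets per patient, so Monte-Carlo is pointless):
the rate at k is (subsets containing both labels) / (all subsets), over
patients with at least k sectors; patients with fewer sectors contribute to
neither numerator nor denominator.  The subset class distribution
classifies every k-subset with the same S/H/R rule.

## Survival and association statistics

Kaplan–Meier curves, the (multivariate) log-rank test and Cox proportional
hazards (Efron tie handling) are delegated to lifelines; Fisher's exact
(two-sided hypergeometric), Wilcoxon rank-sum, Welch's t and Spearman tests
to scipy.  The module fixes conventions (two-sided tests, event = 1 /
censored = 0, months) and wraps results in containers carrying hazard
ratios with 95% CIs.  The test suite checks these engines against
hand-worked small examples (a six-subject log-rank O/E computation, full
hypergeometric enumeration for 2×2 tables) and calibration simulations
(type-I error within [0.03, 0.07] at nominal 0.05 over 10,000 null
replicates; the Fisher null uses 100 subjects per arm, where the test's
discreteness-driven conservatism is mild — at small n its type-I error
drops well below the band, which is a property of the test, not the
wrapper).

## The synthetic study generator

Defaults are the study conditions: 69 patients with resistant fraction
29/69; GR50 modes at 300 µM (resistant) and 8 µM (sensitive) with CV 0.8,
i.e. within-mode SD ≈ 0.31 on the log10 scale and mode separation ≈ 5 SDs;
marker effect log2FC 3 (above the 2.5 selection cutoff, so recovery is
well-posed); concurrent-CNA triple rates 0.45 (sensitive) vs 0.1
(resistant); PFS hazard ratio 2.75 for resistant patients on an exponential
baseline with median 10 months; independent exponential censoring tuned to
a 20% censor fraction; 2000 negative-binomial genes at dispersion 0.1 with
subtype signatures spiked at log2FC 2; 10% missing-at-random per feature.
Plate readouts are the GR-model-implied viabilities under multiplicative
log-normal noise (SD 0.05), which keeps signals positive.  A single seeded
generator is threaded through all sub-simulators, so one seed reproduces
the serialised bundle bitwise.

What the generator does not emulate: read-level sequencing noise, batch
effects, cell-type mixtures and microenvironment signal, gene–gene
correlation beyond the planted structure, informative censoring, and the
correlation structure between platforms.  Recovery results on synthetic
cohorts therefore demonstrate the correctness and calibration of the
implementations under their own model assumptions, not clinical
performance on real cohorts.

## Problem sizes and numerical choices

The bundled checks run at deliberately modest sizes chosen to make the
statistics decisive: 120-patient cohorts (40 replicates in the acceptance
script) for label recovery, 2000 genes × 34 samples for marker error
control, 5000 correlations for the mixture threshold, 200–300 patients for
classifier null/recovery, 500 patients × 30 replicates for Cox recovery,
and 10,000 replicates for type-I calibration.  The label-recovery check
generates noiseless plates: with 5-SD mode separation the irreducible
mixture overlap already leaves expected agreement near 99.4%, and the check
isolates that geometry rather than compounding it with assay noise.
Fit tolerances: GR curve fitting uses scipy's default least-squares
convergence; mixture EM runs up to 500 iterations and raises with
diagnostics if unconverged; all tie-breaks (subtype order, calibration
cutoffs, KNN neighbours by sample order) are deterministic and documented
at the definition site.
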