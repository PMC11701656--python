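# Methods

This note documents the statistical procedure implemented by `coupnet`,
its tunable parameters, the synthetic-data design used for validation,
and the numerical and design choices made where the procedure was
genuinely open.

## Model overview and assumptions

The core is a naive-Bayes integrator. For a gene pair (A, B), each
evidence type t contributes a log-likelihood ratio
`LLR_t = ln P(e_t | coupled) / P(e_t | not coupled)` and the final
Bayesian score is the sum `FBS = Σ_t LLR_t` over evidence types and
source species. The conditional-independence assumption between evidence
types is the usual naive-Bayes idealization; correlated datasets *within*
one evidence type are handled explicitly by the sequential redundancy
weighting (below), but residual dependence between types (e.g. mRNA and
protein co-expression) inflates FBS for pairs supported by correlated
layers. The "not coupled" class is operationalized as *unknown*: scored
pairs absent from the gold standard. At realistic coupling priors this
contaminates the negative class only mildly; it biases LLRs toward zero,
never away from it.

Gold standards (complexes, pathways, operons, physical interactions,
TF→target pairs) are treated as noisy proxies of true coupling. Training
is run once per gold standard, and the final network is the union of the
per-gold-standard networks at maximum confidence, so a systematic bias in
one gold standard does not leak into links better supported by another.

## Likelihood estimation and the LLR polynomial

Class densities are Gaussian-kernel KDEs with the Silverman bandwidth
`h = 0.9 min(sd, IQR/1.34) n^(-1/5)` (the factor is handed to
`scipy.stats.gaussian_kde` explicitly, as `h/sd`, so the kernel width is
exactly this rule rather than scipy's multivariate variant). The
pointwise log-ratio is evaluated on a 512-point grid and summarized by
the lowest polynomial degree in {2, 3, 4} reaching R² ≥ 0.9; evaluation
clamps the raw score to the fitted range, so extrapolation beyond the
training support is flat rather than polynomial.

Numerical choices:

- **Truncation.** The grid covers the pooled positive+negative scores
  between the 2nd and 98th percentiles. Truncating the upper tail
  excludes outliers; the same argument applies to the lower tail, where
  the density ratio of two KDEs is equally unreliable, so truncation is
  applied symmetrically.
- **Training-size bounds.** The 10³–10⁶ observation requirement is
  enforced on the positive class, which is always the scarcer one.
- **Degenerate (flat) curves.** When the two class distributions
  coincide, the true LLR is 0 everywhere and R² is ill-posed (the total
  sum of squares vanishes while the residuals are pure noise). A fit
  whose absolute residual RMSE is ≤ 0.05 is therefore accepted
  regardless of R². This only triggers for near-constant curves, where a
  constant ≈ 0 answer is the correct one.
- **Grid points where either density underflows are dropped** before
  fitting rather than clamped, so tail artifacts cannot steer the
  polynomial.

With positives N(1,1) and negatives N(0,1) the analytic LLR is x − 0.5;
at 5·10⁴ observations per class the fitted polynomial recovers it to
≈ 0.01–0.02 mean absolute error on [−1, 2] (the residual bias is the KDE
smoothing, which shrinks the slope by a factor 1/(1+h²)).

## Redundancy weighting

Datasets of one evidence type are ranked per pair by decreasing LLR; the
top dataset enters with weight 1 and each subsequent weight is
`w_k = α (1 − max(0, r)) w_{k−1}` with α = 0.7. The reference dataset
for `r` is the immediately preceding ranked dataset; an alternative that
references the most-correlated earlier dataset is available as
`pairing="most_correlated"`. Dataset–dataset correlations are Spearman
correlations of LLRs on pairs scored in both datasets; fewer than 10
shared pairs is treated as no redundancy evidence (r = 0). Negative
correlations never up-weight (the `max(0, ·)` clamp). Evidence
transferred from another species keeps its source species in the dataset
identifier and forms its own additive FBS term per (evidence type,
source species).

## Confidence calibration

PPV is measured as TP/(TP+FP) over 1000 evenly spaced FBS thresholds
with equal-sized positive and negative samples (negatives drawn
uniformly from non-gold-standard scored pairs, 30 seeded resamples,
without replacement when the pool allows). A logistic
`a / (1 + exp(−b(x − c)))` is least-squares fitted (accepted at
R² ≥ 0.9; `a` is bounded by 1.2 and evaluation clips to [0, 1], so a fit
slightly overshooting its asymptote cannot produce confidences above 1).
The logistic form is used because the calibration curve must be a
bounded, monotone confidence; a sign variant with a minus in the
denominator is retained behind `printed_form=True` for audit only — it
is singular at x = c and is not used.

Two properties of this estimator matter for interpretation:

1. It estimates precision under a *balanced* prior (equal positives and
   negatives), not under the network-wide coupling prior.
2. It is a *cumulative* (threshold-tail) precision assigned pointwise to
   each link's FBS, so the precision of links *within* a narrow PPV bin
   sits somewhat below the bin's nominal value; the gap grows with the
   variance of FBS and is a few percent in the PPV ≥ 0.85 regime for
   one or two evidence layers.

The calibration validation therefore uses a balanced synthetic world and
checks bins in the retained (PPV ≥ 0.85) regime, where the combined bias
stays well inside ±0.1.

gsPPV assigns 0.85/0.90/0.95/1.0 for membership in one/two/three/more
than three gold standards and is discarded whenever the evidence PPV
exceeds it. Assembly keeps links with final PPV ≥ 0.85; a positive
directed GRG LLR sets the direction flag (regulator → target), and the
underlying GRG LLR is stored as the direction's support.

## Evidence scores

All logarithms are natural. Conventions the metrics' definitions leave
open were fixed as follows: Spearman ties get average ranks; the MEX
min-max rescaling is applied to |r| over the retained (|r| > 0.5,
non-homolog) pairs of each dataset, a single survivor mapping to 1; the
protein-expression top-tissue set has ⌈0.25·T⌉ members with ties broken
by tissue index; ChIP-seq peaks are assigned to genes whose interval,
extended 10 kb upstream of the annotated start (strand-aware, configurable),
they overlap, keeping the maximum normalized enrichment across peaks and
datasets, and a constant-signal dataset normalizes to 1; the
phylogenetic-profile score floors zero spanning lengths at 10⁻⁶ of the
total tree length, capping the score at ±ln 10⁶, and is computed on the
rooting-invariant Steiner length, so it is symmetric in the two profiles
and invariant to leaf order; Wang semantic similarity uses edge weights
0.8 (is_a) / 0.6 (part_of) with best-match-average aggregation over term
sets.

## Orthology

Species distance is one minus the average orthologous-proteome fraction
in both directions; trees over these distances are built by neighbour
joining (negative branch lengths clamped to 0) or UPGMA. Evidence
transfer maps each source pair through the ortholog cross-product and
averages many-to-one contributions per target pair; domain, phylogenetic
profile and co-localization evidence is refused because those layers
already aggregate cross-species information. Whole-network transfer
copies link confidences to all ortholog pairs, keeping the maximum PPV
for duplicate targets (conservative for a confidence score). The closest
donor species is chosen by taxonomy lineage path length with
orthophylogram distance as tie-breaker and fallback.

## Network tools and benchmark

MaxLink ranks candidates by links into the query, then by the
hypergeometric tail p-value P(X ≥ x) drawing the candidate's degree from
a population of N − 1 nodes with the query as successes; all ranking
ties break lexicographically by gene id for determinism. EASE is the
one-sided hypergeometric test with the observed overlap reduced by one.
The random walk with restart iterates
`p = 0.75 e + 0.25 W p` on the column-normalized, unweighted adjacency
(a PPV-weighted variant is available behind a flag); the benchmark
splits a gene set in half, seeds the walk with one half and scores the
recovery of the other half by AUROC against all remaining network genes,
over 30 splits. The null model repeats the same splits on
degree-preserving rewired networks (double-edge swaps, trial count equal
to the link count, no self-loops or multi-edges);
PG = (median real − median null) / median null over 30 splits × 30
randomizations.

## Synthetic data

The generator plants a known set of coupled pairs and derives evidence
(coupled pairs draw raw scores from N(1,1), uncoupled from N(0,1), so
the true LLR is the linear x − 0.5), gold standards (per-pair inclusion
with the specified recall and false-positive rate; the validation runs
use recall 0.9 and fpr 0.01, a deliberately noisy proxy), ortholog maps
with controllable many-to-one co-ortholog groups, and Bernoulli coverage
thinning for incomplete assays. It emulates none of the marginal-score
shapes, batch effects, inter-evidence correlations or degree
heterogeneity of real omics data: passing validations demonstrate the
estimators' correctness and calibration under the generative model, not
performance on real interactomes.

Problem sizes used by the validation suite and the acceptance script
were chosen to exercise every stage at statistically meaningful scale on
a single CPU: 10⁴-pair worlds (142 proteins) for calibration and
end-to-end recovery, 5·10⁴ observations per class for LLR recovery, and
a 500-node / 4000-link network with a 400-gene set at the full 30 × 30
split/randomization scale for the null-model benchmark. The large gene
set is intentional: the performance gain of a *single* network against
its own null distribution carries irreducible wiring noise that shrinks
with the evaluated gene-set size, and at this size the null PG stays
within ±0.05.

## Known limitations

- The naive-Bayes sum ignores between-type dependence; FBS is a score,
  not a posterior probability, and PPV calibration is what makes it
  interpretable.
- PPV is a balanced-prior, cumulative quantity (see above); at sparse
  coupling priors the fraction of true couplings among links in a PPV
  bin is lower than the bin's nominal value.
- The LLR polynomial is only trusted inside its fitted range; clamping
  makes the extremes conservative but discards genuine extra evidence in
  extreme scores.
- Degree-preserving rewiring with trial count equal to the link count
  mixes only partially; null networks retain some correlation with the
  input network, which is the intended convention of the benchmark
  rather than a fully mixed null.
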