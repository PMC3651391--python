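# Methods

## Scope and model

`codp` predicts the pathogenicity of missense substitutions in human MSH6.
The core is a logistic regression over five predictors: the
domain-normalized MAPP impact score, the SIFT score, the PolyPhen-2 HumVar
score, the absolute side-chain heavy-atom change, and the relative solvent
accessibility of the substituted position. The joint score
q = σ(Z + Σ bᵢXᵢ) is interpreted as the probability that the variant is
pathogenic. The packaged default parameters are the published MSH6 fit
(Z = −3.7273; b = +0.1581, −1.2824, +4.6733, +1.0475, −8.0548). PolyPhen-2
HumDiv is accepted in input tables but never used as a predictor: on the
MSH6 training data it discriminated worse than HumVar.

The model assumes the three component scores are available per variant
(computing MAPP/SIFT/PolyPhen-2 themselves — orthologue collection,
alignment, per-column statistics — is out of scope), that the five
predictors act additively on the log-odds scale, and that a structure or a
user-supplied accessibility value exists for the position.

## Amino-acid properties

The volume change of a substitution is proxied by the difference in
side-chain heavy-atom counts (glycine 0 … tryptophan 10), taken from the
standard residue topologies. The difference is used as a magnitude: the
predictor's positive coefficient and the downstream binning of the value
into nonnegative classes both presuppose an unsigned quantity. Codes
outside the 20 canonical residues (B, Z, X, U…) are rejected rather than
imputed, since the model is only defined over the canonical types.

## Solvent accessibility

Per-atom accessible surface area follows Shrake–Rupley: each atom's van der
Waals sphere is expanded by the probe radius (default 1.4 Å, water), test
points are distributed quasi-uniformly on the expanded sphere, and the
exposed fraction — points not strictly inside any other included atom's
expanded sphere — times the sphere area gives the ASA.

Numerical choices:

- **Point scheme.** A deterministic golden-section spiral with a
  configurable count (default 960) in a fixed global frame. Results are
  exactly reproducible and translation-invariant (points are generated
  relative to each atom centre); rotating a structure perturbs ASA only
  within the sampling tolerance, which is the documented and tested
  behaviour. On the two-sphere configuration with analytic cap areas, the
  error at 960 points stays below 2% (measured ≈ 0.5%), and decreases
  monotonically over 240 → 960 → 3840 points.
- **Radii.** A single element-based table (C 1.70, N 1.55, O 1.52, S 1.80,
  P 1.80, Se 1.90 Å), overridable per call; unknown elements raise an error
  naming the atom. Hydrogens are dropped at parse time.
- **Neighbour search.** KD-tree candidate lists, verified in the tests to
  give results identical to all-pairs checking.
- **Boundary.** A test point exactly on another sphere's surface counts as
  exposed; a relative accessibility exactly at the burial threshold (0.1)
  counts as surface. Either convention is defensible; one is fixed and
  tested.
- **Reference maxima.** Relative accessibility divides a residue's summed
  atom ASA by a per-residue-type maximum computed *by the same engine* on
  isolated idealized residues (coordinates from the chemical component
  dictionary bundled with biotite, OXT removed). Self-consistent
  normalization was chosen over importing one of the several published
  extended-peptide scales, because the original study does not name its
  reference; a user-supplied table is accepted wherever the packaged one is
  used. Values above 1.0 are possible for extended conformations and are
  not clipped.
- **Missing residues.** The MSH6–MSH2 crystal (2o8b) lacks several residues
  and loops; the package does not model loops. Positions absent from a
  structure raise a dedicated missing-residue error carrying the position,
  and every pipeline entry point accepts per-position accessibility
  overrides instead.
- **Heteroatoms.** DNA, ADP and other non-water heteroatoms are excluded
  from occlusion by default and can be included with a flag; waters are
  always flagged and excluded by default. The original study is silent on
  this; the flag makes both readings available.

Structure parsing is delegated to Biopython (first model of multi-model
files; alternate locations resolved to the highest-occupancy conformer,
ties to the first listed).

## MAPP normalization

MAPP thresholds differ by domain because alignment conservation differs:
4.1 for the PCNA-binding motif (residues 4–11), 5.0 for the PWWP domain
(89–194), 4.1 for the MutS domain (362–1355), and 8.5 for the
whole-sequence alignment. Dividing a raw score by its covering domain's
threshold puts the decision boundary at 1.0 everywhere. Positions between
domains use the whole-sequence value 8.5 — the only threshold defined
outside the named regions. The domain map is a JSON config, so other
domain layouts can reuse the machinery.

## Classification boundaries

q ≤ 0.56 non-pathogenic; 0.56 < q ≤ 0.65 moderate; q > 0.65 impaired.
Boundaries are closed exactly as written and tested at machine precision.
One caveat for *published, 3-decimal* scores: a printed 0.650 may sit on
either side of the true 0.65 boundary (the published unclassified-variant
table places one such score under "impaired", implying an unrounded value
just above 0.65). The packaged table keeps the printed categories; the
0.65 boundary is therefore only asserted on rows not printed as exactly
0.650, and the headline 84/176 pathogenic split depends only on the
unambiguous 0.56 boundary.

## Evidence rules

The carrier rules are conjunctions over observed evidence; unknown,
not-determined or inconclusive observations never satisfy a predicate.
"IHC loss of only MSH6" requires MSH6 abnormal and neither MLH1 nor MSH2
abnormal — inconclusive staining of the other proteins does not veto,
which is the reading consistent with the curated records. The functional
assay aggregate is abnormal if any of the five assays is abnormal, normal
if at least one is normal and none abnormal, else unknown. A record firing
criteria on both sides is labelled `conflict` and surfaced (a flag can
downgrade it to UV); none of the 34 packaged records conflicts. Note that
because two predicates contain negative literals (the only-MSH6 veto, the
"no abnormal assay" requirement), adding evidence to a record can in
principle unfire a criterion; the invariant that holds, and is tested, is
that unknowns never fire predicates and strengthening a criterion's own
positive literals never unfires it.

In the packaged transcription, one carrier's IHC fields (K728T) follow the
study's narrative text ("normal staining pattern") rather than its
typeset table row, which conflicts with its own printed criterion list;
the fixture header documents this. A mixed "MSI L/H" observation is
encoded as H (the more severe reading) — its carrier's label is driven by
the polymorphism and assay criteria either way.

## Fitting and evaluation

- **Fitting.** Plain maximum likelihood via Newton iterations
  (statsmodels), convergence at 1e-8 parameter change or 100 iterations,
  reporting log-likelihood and per-coefficient standard errors. Perfect or
  quasi-perfect separation — plausible on evidence-classified sets of this
  size (34) — raises an explicit error suggesting the optional L2 ridge
  (scikit-learn), which returns a shrunken fit without standard errors.
- **AUC** uses the midrank Mann–Whitney identity, equal to the trapezoidal
  area over all distinct thresholds; verified against brute-force
  concordant-pair counting.
- **Cut-off selection.** The study does not state its rule; the default is
  Youden's J over midpoints between adjacent distinct scores, ties toward
  the smaller threshold, with a closest-to-(0,1) alternative.
- **Binarization conventions.** SIFT ≤ 0.05 pathogenic (low = damaging),
  PolyPhen-2 ≥ 0.446, joint score > 0.56, normalized MAPP > 1.0; all
  overridable.
- **Wilcoxon rank-sum.** Exact null distribution (scipy) when the pooled
  sample is ≤ 20 with no ties, otherwise the tie- and continuity-corrected
  normal approximation; both modes forcible. Forcing exact with ties falls
  back to complete enumeration over rank assignments with midranks.
  Two-sided p is the doubled smaller tail, capped at 1. Whether the
  original analysis used exact or approximate p-values is unstated, so
  both are provided.
- **Jackknife.** Leave-one-out refits of the regression only; component
  scores are treated as fixed inputs (an alignment-based score cannot
  meaningfully "leave out" the target sequence). Items whose refit
  separates are flagged and excluded from the summary with a reported
  count.

## Synthetic data

The labelled-dataset generator draws the five predictors uniformly
(mapp_norm ∈ [0,4], sift ∈ [0,1], pph2_humvar ∈ [0,1], delta_heavy ∈
{0…10}, rel_acc ∈ [0,1]) and samples labels Bernoulli(q) under a given
model — ranges chosen to cover the observed scales of each predictor. The
structure generator emits an isolated idealized residue (relative
accessibility 1.0 by construction), a fully caged residue (0.0), and a
Cα-trace helix on ideal parameters (1.5 Å rise, 100° twist, 2.3 Å radius,
3.8 Å between consecutive Cα). What these emulate is geometry with known
ground truth, not real data: uniform, independent predictors lack the
correlations of real component scores, and the synthetic structures lack
side-chain packing. Tests passing on them validate the numerics and the
contracts, not clinical performance.

## Reproduction status of published figures

Quantities reproducible from printed data are reproduced exactly: the
84/176 split of the 260 unclassified variants at the 0.56 cut-off, the
15/19 evidence labels with per-carrier criterion lists, and the
whole-data-set metrics from TP=14/FP=1/TN=18/FN=1 (PPV 93.3%, NPV 94.7%,
sensitivity 93.3%, specificity 94.7%, accuracy 94.1%). The published AUC
(0.954), rank-sum p (< 8.9×10⁻⁶), jackknife accuracy (85.3%) and the
LLS/ULS accessibility means (0.141/0.589) require the per-variant
component scores and the loop-completed structure, neither of which is
published; these are covered instead by property-based verification
(closed-form ASA oracles, pair-counting AUC, enumeration rank-sum,
simulation-based coefficient recovery) and, for the accessibility means,
an optional script run against a user-supplied 2o8b file.

## Problem sizes

The test suite and acceptance script use 960 sphere points for ASA checks
(240/3840 for convergence), 200 random instances for the AUC oracle, all
45 two-sample layouts with n₁+n₂ ≤ 10 for the exact rank-sum oracle, and
20 replicates of n = 2000 for coefficient recovery — sizes at which every
oracle is exact or its Monte-Carlo error is far below the asserted
tolerance.

## Known limitations

- The default coefficients are specific to MSH6 and to the component-score
  versions used in the original fit; refitting is supported but the 34
  curated carriers' component scores are not published, so the printed
  coefficients cannot be re-derived from packaged data.
- The ASA engine's absolute values depend on the radius set and reference
  maxima; only relative conventions are fixed, so cross-package ASA
  comparisons need matching tables.
- The evidence rules encode one published criterion table; they are not a
  general variant-classification framework (no ACMG, no Bayesian
  integration).
- mmCIF input, loop modelling and secondary-structure assignment are out
  of scope.
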