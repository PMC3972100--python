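# Methods

## The model

The package predicts the equilibrium fraction of a small molecule bound
to human serum albumin. Binding is treated as the sum of two
contributions: specific binding at the two structurally selective drug
sites (site I in subdomain IIA, site II in subdomain IIIA), represented
by docking, and non-specific hydrophobic association across the protein
surface, represented by the octanol/water partition coefficient. The
predictor is affine:

    combined score = c + α·s + β·logP

with s the best (most negative) docking score over the receptor
ensemble in kcal/mol. The shipped default coefficients are
c = 25.41, α = −1.95, β = 7.68, obtained by ordinary least squares of
%HSA on (s, logP) over a curated literature benchmark; `fit_combined`
refits them on any score table by the same procedure. Since α < 0 and
β > 0, a more favorable docking score and higher lipophilicity both
raise the predicted binding. The combined score is on the %HSA scale in
the interior of the data but is used as a *ranking* statistic, not as a
calibrated percentage — it is not clipped to [0, 100].

Fraction-bound algebra assumes a single dominant site at fixed albumin
concentration, the standard hyperbolic isotherm

    f_b = K_A·[HSA] / (1 + K_A·[HSA]),   K_i = 1/K_A,   [HSA] = 0.6 mM,

with %HSA = 100·f_b exactly. The fixed physiological [HSA] makes f_b,
K_A and K_i mutually convertible; all round trips are identities on
[0, 1). f_b = 1 is rejected (infinite affinity). Multi-site and
concentration-dependent binding are out of scope.

## Ensemble docking protocol

The receptor ensemble is the ten best-resolution HSA crystal structures
(1N5U 1.90 Å … 1HK4 2.40 Å), each assumed superposed onto 1N5U, whose
frame carries the site definitions: site I centroid (30.5, 13.1, 9.7) Å,
site II centroid (10.25, 2.11, −13.75) Å, inner grid box 10 Å, outer box
30 Å. Docking every compound against both sites of all ten structures
yields 20 predictions per compound; the reduction keeps the per-site
minima and the global minimum ("best over ensemble"). A reduced
two-structure model — site I of 2BXP, site II of 1N5U with its site II
myristic acid retained — performs comparably at a tenth of the cost;
fatty-acid retention is modeled as a per-structure boolean because FA
occupancy near site II measurably shifts drug binding there.

Receptor preparation (refinement, protonation — notably doubly
protonated His242 in site I — and the repositioning of the 1N5U Arg218
side chain that otherwise blocks site I) is documented required
preprocessing, not performed by this package. Structural superposition
onto 1N5U is likewise external; per-structure centroid overrides are
supported for imperfect alignments.

The docking engine is a contract, not an implementation: any callable
backend returning a kcal/mol score (more negative = better) works.
Shipped backends are (a) score-table injection, the reference path for
replaying published or precomputed scores, and (b) a command-line
adapter with Vina-style arguments (box from the site definition, fixed
seed for reproducibility, optional `--flex` side-chain list standing in
for induced-fit protocols). Failed dockings become `failed` results,
are logged, and are excluded from the minima by default; an optional
worst-case imputation score can be supplied instead. Exclusion is the
conservative choice: a penalty score would silently convert an
engineering failure into a biological claim.

## Classification and site preference

Binder classes on %HSA use strict inequalities: weak < 25, binder > 80,
intermediate otherwise. Values exactly on a cutoff are classified
intermediate and logged; with measured data exact boundary values are
rare, and logging keeps the convention auditable. The strict benchmark
set keeps only the two extreme classes.

Site preference uses Δ = best(site II) − best(site I) in kcal/mol.
Site II is a smaller pocket that favors small aromatic acids, so for a
genuine site II binder the two sites score very differently, while
site I binders (large heterocycles that site II can partially
accommodate) show a minimal gap. The default decision rule calls
|Δ| ≤ 2.0 kcal/mol site I and |Δ| > 2.0 site II; 2.0 kcal/mol is of the
order of the score uncertainty of empirical docking functions, and no
published threshold exists. Because the discriminating orientation of Δ
is an empirical matter, Δ itself is always reported and the evaluation
stage computes ROC curves for both orientations, so users can pick an
ROC-optimal cutoff.

## Evaluation metrics

ROC curves are built by a descending-score threshold sweep with tied
scores collapsed into one step (a diagonal segment); AUC is the
trapezoid integral. Internally the AUC is recomputed as the normalized
Mann–Whitney pair count (ties credited 0.5) and the two routes must
agree to 1e-12 on every call — a structural self-check, not a tolerance
on the statistic. Early enrichment is the TPR at FPR = 0, i.e. the
fraction of actives ranked strictly above every decoy; a positive tied
with a negative earns no credit (pessimistic tie handling). Rank
quality on congeneric series uses Spearman correlation with average
ranks for ties. AUC comparisons between models (DeLong etc.) are out of
scope.

## Data curation

Multi-source %HSA values for one compound are averaged; if any two
sources differ by more than 30 %HSA the compound is excluded and the
offending pair reported. The rule is applied to the pairwise maximum
spread, the strictest reading of "two or more values differed".
Curation is idempotent and conserves counts (kept + excluded = input).
Site-evidence text, when supplied, refines binder categories into
site I / site II / site-unknown.

## Synthetic data generator

The generator emulates the curated strict benchmark, with defaults that
are the study conditions: 112 strong binders, 22 weak binders, Gaussian
%HSA noise of sd 10 (the scale of inter-laboratory disagreement short of
the 30-point exclusion rule), and a target sample R² of 0.10 between
logP and docking score. Mechanism: (logP, s) pairs are drawn from a
bivariate normal — logP mean 1.5, sd 1.8 (typical oral-drug
lipophilicity); s sd 6.5 kcal/mol with mean placed by the true model so
the noise-free %HSA surface is centered between the class windows — and
a draw is accepted as a binder if its noise-free %HSA lands in (80, 100)
or as weak if in (0, 25). Noise is added afterwards and the result
clipped to the physical [0, 100] bounds; with zero noise no clipping can
occur, so `fit_combined` recovers the generating coefficients to
machine precision.

Selecting on a linear combination of the two descriptors distorts their
correlation, so the base correlation of the bivariate draw is calibrated
by bisection against the post-selection sample correlation in a seeded
pilot simulation (~4000 compounds, 20 iterations); the achieved R² at
n = 2000 lands within ±0.02 of the 0.10 target across seeds. The s sd
of 6.5 kcal/mol (scores roughly −20 to +7, matching the spread empirical
scoring functions produce over diverse drug-like sets) makes each single
descriptor an imperfect separator so that combining them helps, as it
does on real data.

Site structure: binders are split evenly between site I and site II;
a site II compound's best score comes from site II with a gap of
4.0 ± 1.5 kcal/mol to site I, while site I compounds (and weak binders)
have nearly symmetric site scores (gap 0.7 ± 0.5). The generator makes
no claim of matching real per-site score distributions; it exists to
exercise the site-preference machinery with a known answer.

What passing on synthetic data does **not** show: real %HSA is not an
affine function of two descriptors, so the synthetic single-descriptor
AUCs (≈0.98–1.0) overstate what logP or docking achieve on measured
data, and the synthetic site gap is cleaner than real per-site score
differences. Synthetic results validate the *machinery* — score
aggregation, fitting, classification, ROC analysis, reproducibility —
not the biological accuracy of the model.

## Numerical choices and degenerate inputs

- OLS via `numpy.linalg.lstsq`; exact collinearity and n < 3 are
  rejected. Bootstrap: case resampling with replacement, percentile
  95% intervals, seeded `numpy` Generator; a rank-deficient resample is
  redrawn once.
- Ensemble aggregation is a plain minimum: permutation-invariant,
  monotone under added results; ligands with zero usable results are
  reported separately, never silently dropped.
- Ligand reading skips (and logs) molecules that fail sanitization;
  zero parsable records is an error, as are duplicate ids. Enantiomers
  listed separately stay separate records.
- logP is the Wildman–Crippen atomic-contribution estimate on the input
  (neutral) form; no pKa/tautomer enumeration. Precomputed logP columns
  pass through bit-exactly. Optional Se→S mapping (off by default) for
  selenium compounds that contribution tables parameterize poorly.
- Pipeline runs are deterministic: identical configuration and injected
  scores give byte-identical prediction and evaluation tables
  (timestamps appear only in the log); artifacts carry a configuration
  hash and the seed.

## Problem sizes

Default test and reproduction runs use the strict-set scale (134
compounds; 1000 bootstrap replicates; R² measured at n = 2000), which
completes in seconds on one CPU and matches the scale of the benchmark
the model is meant for.

## Known limitations

Replaying published scores reproduces the downstream arithmetic, not
the docking itself; pose-level validation (RMSD to crystal ligands)
requires an engine and curated crystal poses and is out of scope, as are
empirical scoring-function internals, induced-fit side-chain
optimization, crystallographic refinement, multi-site binding models and
stereo-specific affinities.
The curation module implements the published rules but the full
422-compound literature corpus is not redistributed with the package.
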