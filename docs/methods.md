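# Methods

## Data model and assumptions

The pipeline starts from a feature table: a features × samples matrix of
non-negative intensities, each feature annotated with an observed [M−H]⁻
m/z (Da) and retention time (minutes). Upstream peak picking, RT alignment
and centroiding are out of scope. All ionization is assumed negative-mode
and singly charged, so neutral mass arithmetic applies directly to observed
m/z after adding one proton mass. Missing measurements are carried as an
explicit mask (NaN), never as zeros — the intensity floor and all ratio
arithmetic operate on measured values only.

The cohort design is strictly paired: every subject contributes exactly one
baseline (V1) and one post-intervention (V2) sample, validated at load
time, plus repeated pooled-QC injections spread over the run. Sample
columns are matched to the sample sheet by exact string identity; silent
mispairing is the worst failure mode of a paired design, so nothing fuzzy
is attempted.

## Conjugate discovery

Mass shifts are computed from elemental formulas (monoisotopic masses via
pyteomics): Δ(sulfate) = m(SO₃) ≈ 79.9568 Da, Δ(glucuronide) = m(C₆H₈O₆) ≈
176.0321 Da. A pair (conjugate c, aglycon a) is a candidate when
|(mz(c) − Δ) − mz(a)| / mz(c) ≤ 5 ppm. The tolerance default is
Q-TOF-appropriate and exposed (`ppm_tol`); the scan is implemented with a
sorted-m/z binary search but is exactly equivalent to the all-pairs scan
(tested against that oracle). All qualifying combinations are reported —
one conjugate may match several aglycon candidates — sorted by absolute
mass error. No RT constraint is imposed between conjugate and aglycon by
default; an optional reversed-phase heuristic (conjugate elutes earlier)
can be layered on by the caller.

Enzymatic confirmation compares the enzyme-treated and denatured-control
arms at 18 h: a pair passes when the conjugate's treated/control mean ratio
falls to ≤ 0.5 and the aglycon's rises to ≥ 2.0. These thresholds are
package defaults, not literature constants; raw ratios are always reported
so users can re-threshold. The 0 h ratios are carried as a negative
control. A zero control mean renders a pair unevaluable rather than a hit.

Stereoisomer peaks that share one m/z within tolerance but elute as
distinct peaks can be summed (`group_isomers`); the RT window (default
5 min) bounds the spread of a merged group, group intensity is the member
sum (exactly conserving per-sample totals) and group RT the
intensity-weighted mean.

## Preprocessing cascade

The stage order is fixed: filter → QC drift correction → creatinine
normalization. Features are removed when RT < 1 min or > 18 min (bounds
inclusive for retention: exactly 1.0 and 18.0 survive) or when the maximum
observed intensity across samples stays below 10,000 counts. The
max-across-samples reading of the floor keeps features genuinely present in
any sample; a mean-based variant is available. The floor is applied to raw
(pre-normalization) intensities.

Drift correction is SERRF-style: per feature, a random-forest regressor is
trained on the pooled-QC injections to predict the feature's QC intensity
from injection order plus the standardized intensities of its ten
most-correlated other features (correlation estimated on QCs only).
Dividing every sample by its predicted QC-equivalent intensity flattens
smooth drift and aligns batch levels; a final per-feature rescale restores
the QC median exactly. The correction runs per batch when each batch has
at least two QCs, otherwise globally, and refuses to run with fewer than
five QCs overall (the error advises creatinine-only normalization). The
original SERRF hyperparameters are not reproduced; the contract (QC-
trained, correlated-feature predictors, per-batch) is.

Creatinine normalization divides each non-QC sample by its sample-sheet
creatinine and multiplies by the cohort median creatinine, keeping the
output on the original intensity scale. QC columns are pooled material with
a single common dilution and pass through unchanged. Creatinine comes from
the sample sheet rather than being auto-detected as a feature, to avoid
misidentification; a feature can be mapped in explicitly by the caller.
Missing values are imputed, after normalization, by half the feature's
minimum positive intensity.

## Paired statistics and producer phenotypes

The per-feature test is a two-tailed paired *t* test on log intensities
(multiplicative noise model; raw-scale mode available). The pseudocount for
all log transforms is half the smallest positive intensity in the matrix.
Zero-variance features get t = 0, p = 1 by convention. No multiple-testing
correction is applied by default — raw p < 0.05 is the conventional call in
this setting — with Benjamini–Hochberg available (`fdr=True`). The reported
fold change is the geometric mean of per-subject V2/V1 ratios.

Producer phenotyping counts, per subject, the features with V2/V1 > 1.5
(up), < 0.67 (down) and in between (unchanged; the boundary values
themselves count as unchanged since strict inequalities define the outer
classes). Features with a zero or missing baseline are unevaluable for that
subject and excluded from the denominators. Classification runs on
normalized intensities: within-subject ratios are dilution-sensitive
otherwise. Baseline load is summarized as each subject's V1 intensity total
as a percentage of the cohort maximum. The evaluated feature set (all
conjugates vs significant only) is a parameter, not a fixed choice.

PCA on log₁₀, unit-variance-scaled data serves as the run-quality check:
QC injections should cluster tightly relative to biological samples.

## Panel search

Candidates (default: the 26 highest-confidence conjugates in the motivating
design) are searched exhaustively over all subsets of size 1..6. Each
subset is fitted with a binary logistic regression of visit label (V1 = 0,
V2 = 1) on standardized log intensities, treating the 2n paired samples as
independent observations — this mirrors the original analysis procedure; a
conditional-logistic paired variant would be the orthodox alternative and
is deliberately not the default. A mild fixed L2 penalty (λ = 0.01 on
standardized coefficients, intercept unpenalized) keeps perfectly separable
subsets finite; since AUC depends only on the ordering of the linear
scores, the penalty does not materially move AUCs (verified against
scikit-learn at matched regularization).

The full enumeration (313,911 subsets for 26 candidates) runs through a
batched Newton solver that fits ~256 models per vectorized step with a
fixed eight-iteration budget; score orderings converge within a few
iterations, and batched AUCs agree with the fully converged single-model
path to ~4×10⁻⁴. The winning panel is always refitted with the convergent
path. Subsets with AUC > 0.75 are retained; the best panel is the highest
in-sample AUC with ties broken toward smaller panels then lexicographic
order. Selection by in-sample AUC with CV only for the winner mirrors the
motivating procedure; a nested-CV mode would be the honest-selection
alternative and is intentionally not the default. Cross-validation is
10-fold with subject-grouped folds (a subject's V1 and V2 stay together),
assigned once from the seed; grouping guarantees both classes in every
fold and prevents subject leakage. An ungrouped mode exists for
replication. Fold standardization is re-estimated on each training split.

## Synthetic data

The cohort generator emulates a 100-subject × 2-visit design with pooled-QC
injections in 5 batches. Intensities follow
I(f,s) = base(f) · effect(f, visit) · dilution(s) · drift(order(s)) · exp(ε)
with log-normal baselines (ln-mean 11, ln-sd 1 — mid-10⁴ count scale),
multiplicative measurement noise (CV 0.2 by default),
per-sample log-normal dilution (σ = 0.4, the dominant nuisance in urine),
and a smooth per-batch sinusoid of injection order for drift (amplitude
0.2 by default). QC samples are the pooled mean of all subject samples
computed before drift and noise, then drift and noise are applied — exactly
what a pooled aliquot re-injected through the run experiences. The
creatinine feature scales with dilution only, and the sample sheet carries
its noiseless value, making creatinine normalization exactly invertible in
the noiseless limit (a tested property). Planted V2/V1 effects are supplied
per feature; defaults plant none.

The assay generator plants conjugate/aglycon pairs whose m/z obey the exact
shift arithmetic (Δ values imported from the discovery module — one source
of truth) with uniform ppm jitter, hydrolyzes a fixed fraction (0.9) of
each conjugate in the enzyme arm at 18 h with intensity-proportional
stoichiometric aglycon gain (equal detector response by default; a response
ratio is exposed), and rejection-samples decoy m/z at least 3× the pairing
tolerance away from any shift relation with any existing feature.
Conjugate baselines exceed aglycon baselines (median ratio 8) as urinary
phase II conjugates typically dominate their free forms.

What the generator does not emulate: chromatographic peak shapes, isotope
patterns, adducts beyond [M−H]⁻, detector saturation, ion suppression,
between-feature biological correlation, and inter-individual variance
components (which the motivating study does not report — defaults are
stated, not fitted). Passing recovery tests therefore demonstrates
correctness of the algorithms under the stated generative model, not
instrument-level realism.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 15–100 subjects and 5–1000
features, chosen to estimate each quantity stably: 1000 features for null
calibration (binomial error on a 5% rate ≈ ±0.7%), 20 planted pairs among
200 decoys for recovery, and the full 26-candidate search for scale and
recovery checks. Null-calibration cohorts set drift and dilution to zero so
the per-feature t null is exact; both nuisances are exercised separately by
the normalization tests. Calibration and recovery cohorts for the panel
search use fold 1.8 at noise CV 0.4, which puts single-marker AUCs in the
high-0.7 to low-0.9 range typical of strong dietary biomarkers.

Degenerate inputs are handled explicitly: constant matrices fail PCA with a
clear error; single-class labels fail AUC; features constant across QCs are
left untouched by drift correction; subjects with a zero baseline are
excluded per feature from producer counts. All randomness flows from a
single seed; the pipeline derives per-stage seeds by stable hashing of the
stage name so stages re-run independently yet reproducibly.

## Known limitations

- The Δm/z scan cannot see conjugates whose aglycon is absent from the
  table ("orphan conjugates"); detection counts are therefore conservative
  relative to a library-based search.
- Enzyme-response thresholds (0.5/2.0) are heuristics; borderline
  hydrolysis efficiencies will be missed.
- Treating paired samples as independent in the logistic model slightly
  miscalibrates probabilities (AUC ranking is less affected); the paired
  design is honoured in CV fold construction instead.
- SERRF-style correction can only learn drift shapes that the QC spacing
  samples; sparse QCs under fast drift will under-correct.
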