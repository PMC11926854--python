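# phenolomics

Analysis toolkit for the **phase II (poly)phenol metabolome** in untargeted
urine LC-MS studies: discovery of sulfated and glucuronidated metabolites by
exact mass-shift pairing with enzymatic confirmation, QC-anchored
normalization, paired dietary-intervention statistics, per-individual
producer phenotyping, and an exhaustive biomarker-panel search with
logistic-ROC scoring.

It is written for metabolomics researchers who have already peak-picked
their raw data (e.g. with XCMS) and hold a feature table — features
annotated with m/z and retention time, quantified across samples — from a
paired before/after (V1/V2) intervention design with repeated pooled-QC
injections.

## The science in brief

**Conjugate discovery.** Phase II metabolism attaches a sulfate (SO₃,
monoisotopic Δm = 79.9568 Da) or a glucuronic-acid moiety (C₆H₈O₆,
Δm = 176.0321 Da) to a dietary metabolite (the *aglycon*). In negative-mode
LC-MS both forms appear as [M−H]⁻ ions, so a conjugate/aglycon pair shows up
as two features whose m/z difference equals the group mass within
instrument accuracy (ppm-scale). Candidate pairs found by the Δm/z scan are
confirmed enzymatically: incubation with arylsulfatase (or β-glucuronidase)
must deplete the conjugate and raise the aglycon after 18 h relative to a
denatured-enzyme control, with the 0 h time point as a negative control.
For enterolactone (ENL, C₁₈H₁₈O₄; [M−H]⁻ m/z 297.1138) the sulfate appears
at 377.0705 and the glucuronide at 473.1450.

**Normalization.** Cohort intensities are filtered (RT within [1, 18] min,
maximum intensity ≥ 10,000 counts) and normalized in two steps: a
SERRF-style correction that trains a random forest on the pooled-QC
injections to learn each feature's systematic drift as a function of
injection order and correlated features, then division by urinary
creatinine to absorb per-sample dilution.

**Statistics.** Per feature, a two-tailed paired *t* test on log intensities
compares V2 with V1 (*p* < 0.05 called significant). Per subject, each
metabolite's V2/V1 ratio classifies it as upregulated (> 1.5), downregulated
(< 0.67) or unchanged — the individual's *producer phenotype* — and baseline
totals are expressed as a percentage of the cohort maximum.

**Biomarker panels.** Every subset of up to six metabolites from a candidate
list (e.g. 26 high-confidence conjugates) is fitted with an L2-regularized
logistic regression of visit label on standardized log intensities; subsets
with ROC AUC > 0.75 are retained, the top panel is selected by in-sample
AUC and validated by 10-fold subject-grouped cross-validation. The
exhaustive ≤6-of-26 search (313,911 fits) runs in about half a minute on
one CPU through a batched Newton solver.

A synthetic-data module generates cohorts and enzyme assays with the same
statistical structure (log-normal intensities, smooth injection-order
drift, per-sample dilution tied to a creatinine feature, planted effect
sizes and conjugate pairs obeying exact mass arithmetic) together with the
ground truth, so every stage is testable end to end.

## Worked example

```python
import phenolomics as p

# a paired cohort: 100 subjects x (V1, V2) + 25 pooled QCs in 5 batches,
# six markers planted at fold change 1.8
cfg = p.CohortConfig(n_subjects=100, n_features=26, seed=42,
                     effect_fold_changes={i: 1.8 for i in range(6)},
                     noise_cv=0.4, dilution_sd=0.4, drift_amplitude=0.0)
table, sheet, truth = p.generate_cohort(cfg)
cohort = p.align(p.creatinine_normalize(table, sheet), sheet)

res = p.paired_t_test(cohort)
print(res[["feature_id", "fold_change", "p_value"]].head(3))

cands = p.PanelCandidateSet([f"F{i+1:04d}" for i in range(26)], max_size=6)
search = p.search_best_panel(cohort, cands)
cv_mean, cv_sd = p.cross_validate_panel(cohort, list(search.best.feature_subset),
                                        k=10, seed=1)
print(search.best.feature_subset, round(search.best.in_sample_auc, 3),
      round(cv_mean, 3), round(cv_sd, 3))
```

Output:

```
  feature_id  fold_change       p_value
0      F0006     1.792036  3.666802e-19
1      F0002     1.807226  6.628476e-18
2      F0003     1.698584  8.071467e-18
```
```
('F0001', 'F0002', 'F0003', 'F0004', 'F0005', 'F0006') 0.996 0.992 0.009
```

The three smallest-p features recover planted fold changes near 1.8; the
exhaustive search selects exactly the six planted markers, whose combined
panel separates post-intervention from baseline samples with an in-sample
AUC of 0.996 and a cross-validated AUC of 0.992 ± 0.009.

The same stages are scriptable from the shell:

```bash
phenolomics simulate --seed 42 --out run/
phenolomics preprocess --features run/cohort_features.csv \
    --samples run/cohort_samples.csv --out run/processed.csv
phenolomics discover-conjugates --arm sulfatase \
    --features run/assay_sulfatase.csv --design run/assay_sulfatase_design.csv \
    --out run/sulfatase_hits.csv
phenolomics run --config run_config.yml     # full pipeline with manifest
```

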