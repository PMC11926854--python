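"""Paired V2-vs-V1 statistics, producer phenotyping and PCA QC.

All tests are two-tailed paired t tests on log-transformed intensities
(multiplicative noise model); raw p-values are reported, matching common
practice of calling p < 0.05 significant without correction, with
Benjamini-Hochberg available on request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import FeatureTable, PairedCohort

logger = logging.getLogger(__name__)


def _pseudocount(values: np.ndarray) -> float:
    """Half the smallest positive intensity — the log-transform offset."""
    pos = values[np.isfinite(values) & (values > 0)]
    return float(pos.min()) / 2.0 if pos.size else 1.0


def paired_t_test(cohort: PairedCohort, alpha: float = 0.05,
                  transform: str = "log", fdr: bool = False) -> pd.DataFrame:
    """Per-feature paired t test of V2 against V1 across subjects.

    Differences are taken on the log scale by default; a zero-variance
    feature (all per-subject differences equal zero) gets t = 0, p = 1 by
    convention.  Results come back sorted by ascending p with columns
    feature_id, mean_v1, mean_v2, fold_change (geometric mean of per-subject
    V2/V1), t_stat, p_value, significant.
    """
    v1 = cohort.v1_matrix().to_numpy(dtype=float)
    v2 = cohort.v2_matrix().to_numpy(dtype=float)
    n_subj = v1.shape[1]
    if n_subj < 2:
        raise ValueError("paired t test needs at least two complete pairs")

    if transform == "log":
        pc = _pseudocount(np.concatenate([v1.ravel(), v2.ravel()]))
        a, b = np.log(v1 + pc), np.log(v2 + pc)
    elif transform == "raw":
        a, b = v1, v2
    else:
        raise ValueError(f"unknown transform {transform!r}")

    diffs = b - a
    valid = np.isfinite(diffs)
    n = valid.sum(axis=1)
    mean_d = np.nanmean(np.where(valid, diffs, np.nan), axis=1)
    sd_d = np.nanstd(np.where(valid, diffs, np.nan), axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd_d == 0
    t[zero_var & (mean_d == 0)] = 0.0
    p[zero_var & (mean_d == 0)] = 1.0
    if zero_var.any():
        logger.info("paired_t_test: %d zero-variance features set to p=1",
                    int((zero_var & (mean_d == 0)).sum()))

    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(v2) - np.log(v1)
    fold = np.exp(np.nanmean(np.where(np.isfinite(log_ratio), log_ratio, np.nan), axis=1))

    out = pd.DataFrame({
        "feature_id": cohort.table.feature_ids,
        "mean_v1": np.nanmean(v1, axis=1),
        "mean_v2": np.nanmean(v2, axis=1),
        "fold_change": fold,
        "t_stat": t,
        "p_value": p,
    })
    if fdr:
        out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
        out["significant"] = out["q_value"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def top_k_matrix(results: pd.DataFrame, cohort: PairedCohort,
                 k: int = 50) -> pd.DataFrame:
    """log10 intensity matrix of the k smallest-p features (heatmap input)."""
    if len(results) < k:
        logger.warning("top_k_matrix: only %d features available (< k=%d)",
                       len(results), k)
        k = len(results)
    top = results.nsmallest(k, "p_value")["feature_id"].tolist()
    sub = cohort.table.intensities.loc[top]
    pc = _pseudocount(sub.to_numpy(dtype=float))
    return np.log10(sub + pc)


@dataclass
class ProducerProfile:
    """Per-individual phase II production phenotype."""

    subject_id: str
    n_up: int
    n_down: int
    n_unchanged: int
    n_unevaluable: int
    baseline_pct_of_max: float


def classify_producers(cohort: PairedCohort, up: float = 1.5,
                       down: float = 0.67) -> pd.DataFrame:
    """Count up-/down-/unchanged features per subject from V2/V1 ratios.

    A feature is upregulated for a subject when V2/V1 > ``up``, downregulated
    when V2/V1 < ``down``, unchanged otherwise (boundary values count as
    unchanged).  Features with V1 = 0 or missing values are unevaluable for
    that subject and excluded from the counts.  Profiles are sorted by n_up
    descending, then subject_id.
    """
    v1 = cohort.v1_matrix()
    v2 = cohort.v2_matrix()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = v2.to_numpy(dtype=float) / v1.to_numpy(dtype=float)
    evaluable = np.isfinite(ratio)
    baseline = baseline_percent_of_max(cohort)
    rows = []
    for j, subject in enumerate(cohort.subjects):
        r = ratio[:, j]
        ok = evaluable[:, j]
        n_up = int(((r > up) & ok).sum())
        n_down = int(((r < down) & ok).sum())
        n_unchanged = int(ok.sum()) - n_up - n_down
        rows.append(ProducerProfile(subject, n_up, n_down, n_unchanged,
                                    int((~ok).sum()), baseline[subject]))
    out = pd.DataFrame([vars(p) for p in rows])
    return out.sort_values(["n_up", "subject_id"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)


def baseline_percent_of_max(cohort: PairedCohort) -> pd.Series:
    """Per-subject baseline (V1) intensity total as % of the cohort maximum."""
    totals = cohort.v1_matrix().sum(axis=0, skipna=True)
    return 100.0 * totals / totals.max()


def pca_scores(table: FeatureTable, n_components: int = 2,
               scale: bool = True, log: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores of a PCA on (optionally scaled) log-transformed data.

    Returns (scores, explained_variance_ratio); scores is samples ×
    components with columns PC1, PC2, ...
    """
    X = table.intensities.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")
    if log:
        X = np.log10(X + _pseudocount(X))
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        if not np.any(sd > 0):
            raise ValueError("degenerate (constant) data matrix: PCA undefined")
        sd[sd == 0] = 1.0
        X = X / sd
    elif not np.any(X.std(axis=0) > 0):
        raise ValueError("degenerate (constant) data matrix: PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=table.sample_ids, columns=cols),
            pca.explained_variance_ratio_)
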