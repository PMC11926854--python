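"""Feature filtering and the two-step normalization cascade.

The fixed stage order is: retention-time/intensity filtering, then QC-based
signal-drift correction (SERRF-style, random-forest regression anchored on
the pooled-QC injections), then creatinine normalization to absorb urinary
dilution differences between individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .io import FeatureTable, SampleSheet

logger = logging.getLogger(__name__)


class CorrectionError(RuntimeError):
    """QC drift correction cannot run; creatinine-only normalization advised."""


class NormalizationError(ValueError):
    pass


@dataclass
class FilterSpec:
    """Feature exclusion rules: RT window and a total-ion-count floor.

    Features eluting before ``rt_min`` or after ``rt_max`` minutes are
    removed (bounds inclusive: only strictly-outside features go), as is any
    feature whose maximum observed intensity across samples stays below
    ``min_intensity``.
    """

    rt_min: float = 1.0
    rt_max: float = 18.0
    min_intensity: float = 10_000.0
    intensity_rule: str = "max"  # 'max' (default) or 'mean' across samples

    def __post_init__(self) -> None:
        if self.rt_min >= self.rt_max:
            raise ValueError("rt_min must be below rt_max")
        if self.min_intensity < 0:
            raise ValueError("min_intensity must be non-negative")


def filter_features(table: FeatureTable, spec: FilterSpec | None = None) -> FeatureTable:
    """Drop features outside the RT window or below the intensity floor."""
    spec = spec or FilterSpec()
    rt_ok = (table.rt >= spec.rt_min) & (table.rt <= spec.rt_max)
    agg = table.intensities.max(axis=1) if spec.intensity_rule == "max" \
        else table.intensities.mean(axis=1)
    int_ok = agg >= spec.min_intensity
    keep = rt_ok & int_ok
    logger.info("filter_features: %d removed by RT window, %d by intensity floor, "
                "%d of %d retained", int((~rt_ok).sum()),
                int((rt_ok & ~int_ok).sum()), int(keep.sum()), table.n_features)
    return table.subset(table.feature_ids[keep])


def creatinine_normalize(table: FeatureTable, sheet: SampleSheet) -> FeatureTable:
    """Divide each non-QC sample by its creatinine, rescaled to the median.

    intensity(f, s) -> intensity(f, s) / creatinine(s) * median(creatinine)
    over non-QC samples, which keeps the output on the original intensity
    scale.  QC columns are pooled material, share one dilution by
    construction, and pass through unchanged.
    """
    df = sheet.frame.set_index("sample_id")
    non_qc = df.index[df["role"] != "QC"]
    creat = df.loc[non_qc, "creatinine"]
    bad = creat.index[~(creat > 0) | creat.isna()]
    if len(bad):
        raise NormalizationError(
            f"missing or non-positive creatinine for samples: {list(bad)}")
    ref = float(creat.median())
    out = table.intensities.copy()
    cols = [c for c in out.columns if c in set(non_qc)]
    out[cols] = out[cols].div(creat[cols], axis=1) * ref
    return table.with_intensities(out)


def impute_missing(table: FeatureTable, rule: str = "half-minimum") -> FeatureTable:
    """Replace missing intensities by half the feature's minimum positive value.

    Features with no observed positive value anywhere are dropped with a
    warning — there is nothing to anchor an imputation on.
    """
    if rule != "half-minimum":
        raise ValueError(f"unknown imputation rule {rule!r}")
    inten = table.intensities
    if not inten.isna().any().any():
        return table
    pos = inten.where(inten > 0)
    fill = pos.min(axis=1) / 2.0
    dead = fill.index[fill.isna()]
    if len(dead):
        logger.warning("impute_missing: dropping %d features with no positive value",
                       len(dead))
    out = inten.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    kept = table.with_intensities(out)
    if len(dead):
        kept = kept.subset([f for f in kept.feature_ids if f not in set(dead)])
    return kept


def qc_drift_correct(table: FeatureTable, sheet: SampleSheet, *,
                     n_trees: int = 100, min_qc: int = 5,
                     n_correlated: int = 10, per_batch: bool = True,
                     seed: int = 0) -> FeatureTable:
    """SERRF-style QC-anchored drift correction.

    For each feature a random-forest regressor is trained on the pooled-QC
    injections to predict that feature's QC intensity from injection order
    plus the standardized intensities of its most-correlated other features.
    Predicting over all samples gives each sample's systematic-error factor;
    intensities are divided by the factor and rescaled so the feature's QC
    median is preserved exactly.  Runs per batch by default, falling back to
    a global fit when a batch carries fewer than two QCs.

    Raises
    ------
    CorrectionError
        When fewer than ``min_qc`` QC injections exist; fall back to
        creatinine-only normalization in that case.
    """
    df = sheet.frame.set_index("sample_id")
    qc_ids = [s for s in table.sample_ids if df.loc[s, "role"] == "QC"]
    if len(qc_ids) < min_qc:
        raise CorrectionError(
            f"only {len(qc_ids)} QC samples (< {min_qc}); "
            "drift correction is unreliable — use creatinine normalization only")

    inten = table.intensities
    order = df.loc[list(table.sample_ids), "injection_order"].to_numpy(dtype=float)
    batches = df.loc[list(table.sample_ids), "batch"].to_numpy()
    qc_mask = np.array([s in set(qc_ids) for s in table.sample_ids])

    X_all = inten.to_numpy(dtype=float)  # features x samples
    log_all = np.log1p(np.nan_to_num(X_all, nan=0.0))
    # feature-feature correlation computed on QC injections only
    qc_log = log_all[:, qc_mask]
    qc_centered = qc_log - qc_log.mean(axis=1, keepdims=True)
    qc_sd = qc_centered.std(axis=1)
    qc_sd[qc_sd == 0] = 1.0
    qc_z = qc_centered / qc_sd[:, None]
    corr = (qc_z @ qc_z.T) / qc_mask.sum()

    rng = np.random.default_rng(seed)
    corrected = X_all.copy()
    groups = [np.flatnonzero(batches == b) for b in np.unique(batches)] if per_batch \
        else [np.arange(X_all.shape[1])]
    groups = [g for g in groups if len(g)]

    for fi in range(X_all.shape[0]):
        neigh = np.argsort(-np.abs(corr[fi]), kind="stable")
        neigh = [n for n in neigh if n != fi][:n_correlated]
        for g in groups:
            g_qc = g[qc_mask[g]]
            fit_idx = g_qc if len(g_qc) >= 2 else np.flatnonzero(qc_mask)
            y = X_all[fi, fit_idx]
            if np.allclose(y, y[0]):
                pred = np.full(len(g), max(y[0], 1e-12))  # flat QC: nothing to learn
            else:
                # standardized predictors: injection order + correlated features
                preds = np.column_stack([order] + [log_all[n] for n in neigh])
                mu, sd = preds[fit_idx].mean(axis=0), preds[fit_idx].std(axis=0)
                sd[sd == 0] = 1.0
                preds_z = (preds - mu) / sd
                rf = RandomForestRegressor(
                    n_estimators=n_trees, random_state=int(rng.integers(2 ** 31)),
                    min_samples_leaf=2, n_jobs=1)
                rf.fit(preds_z[fit_idx], y)
                pred = rf.predict(preds_z[g])
                pred = np.clip(pred, a_min=max(1e-12, float(np.nanmin(y)) * 1e-3),
                               a_max=None)
            # dividing by the predicted QC-equivalent intensity flattens drift
            # and aligns batch levels; absolute scale is restored below
            corrected[fi, g] = X_all[fi, g] / pred
        # preserve the feature's QC median exactly
        before = np.nanmedian(X_all[fi, qc_mask])
        after = np.nanmedian(corrected[fi, qc_mask])
        if after > 0 and np.isfinite(after) and np.isfinite(before):
            corrected[fi] *= before / after

    out = pd.DataFrame(corrected, index=inten.index, columns=inten.columns)
    out[inten.isna()] = np.nan  # missingness is preserved, never invented
    return table.with_intensities(out)
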