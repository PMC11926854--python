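"""Synthetic cohort and enzymatic-assay generators with ground truth.

The cohort generator emulates the structure of a paired dietary-intervention
urine metabolomics study: 100 subjects sampled before (V1) and after (V2) the
intervention, injected in randomized order across 5 batches together with
repeated pooled-QC injections; log-normal baseline intensities; smooth
per-batch injection-order drift; per-sample urinary dilution tied to a
creatinine feature; and optional planted V2/V1 fold changes.

The intensity model is multiplicative:

    I(f, s) = base(f) * effect(f, visit(s)) * dilution(s) * drift(order(s)) * exp(eps)

with eps ~ Normal(0, sqrt(log(1 + noise_cv^2))).  QC samples are the pooled
average of all subject samples computed *before* drift and noise, with drift
and noise then applied to the pool — exactly what a pooled aliquot re-injected
through the run sees.  The creatinine feature scales with dilution only, and
the sample sheet's creatinine column carries its noiseless dilution signal.

The assay generator plants conjugate/aglycon feature pairs obeying exact
phase II mass arithmetic (Δ from :mod:`phenolomics.conjugates`, the single
source of truth) with ppm-scale m/z jitter, an enzyme arm that hydrolyzes a
fixed fraction of each conjugate by 18 h with stoichiometric aglycon gain,
and decoy features rejection-sampled away from any valid shift relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .conjugates import ShiftClass, theoretical_mz
from .io import AssayTable, FeatureTable, SampleSheet


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class CohortConfig:
    n_subjects: int = 100
    n_features: int = 500
    n_qc: int = 25                      # total pooled-QC injections (5 per batch)
    n_batches: int = 5
    baseline_log_mean: float = 11.0     # ln scale; e^11 ~ 6e4 counts
    baseline_log_sd: float = 1.0
    effect_fold_changes: Mapping[int, float] = field(default_factory=dict)
    drift_amplitude: float = 0.2        # fractional amplitude of smooth drift
    noise_cv: float = 0.2               # multiplicative measurement CV
    dilution_sd: float = 0.4            # log-normal sigma of per-sample dilution
    rt_range: tuple[float, float] = (1.0, 18.0)
    mz_range: tuple[float, float] = (100.0, 800.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_features <= 0 or self.n_batches <= 0:
            raise ConfigError("n_subjects, n_features and n_batches must be positive")
        if self.n_qc < 0:
            raise ConfigError("n_qc must be non-negative")
        if not (0 <= self.drift_amplitude < 1):
            raise ConfigError("drift_amplitude must lie in [0, 1)")
        if self.noise_cv < 0 or self.dilution_sd < 0:
            raise ConfigError("noise_cv and dilution_sd must be non-negative")
        if self.baseline_log_sd <= 0:
            raise ConfigError("baseline_log_sd must be positive")
        bad = [i for i in self.effect_fold_changes if not 0 <= i < self.n_features]
        if bad:
            raise ConfigError(f"effect feature indices out of range: {bad}")


@dataclass
class AssayConfig:
    n_pairs: int = 20                   # planted pairs per shift class
    n_decoys: int = 200
    hydrolysis_fraction: float = 0.9
    mz_jitter_ppm: float = 1.0
    n_replicates: int = 3
    noise_cv: float = 0.1
    aglycon_log_mean: float = 10.0      # ln scale aglycon baseline
    aglycon_log_sd: float = 0.8
    conj_over_aglycon_log_mean: float = float(np.log(8.0))
    conj_over_aglycon_log_sd: float = 0.5
    response_ratio: float = 1.0         # detector response conjugate vs aglycon
    pairing_tol_ppm: float = 5.0        # decoys kept 3x this away from shift relations
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs == 0 and self.n_decoys == 0:
            raise ConfigError("empty assay: n_pairs and n_decoys are both zero")
        if self.n_pairs < 0 or self.n_decoys < 0:
            raise ConfigError("n_pairs and n_decoys must be non-negative")
        if not 0 < self.hydrolysis_fraction <= 1:
            raise ConfigError("hydrolysis_fraction must lie in (0, 1]")
        if self.mz_jitter_ppm < 0:
            raise ConfigError("mz_jitter_ppm must be non-negative")
        if self.n_replicates < 1:
            raise ConfigError("need at least one replicate")


@dataclass
class SyntheticTruth:
    """Everything planted by a generator, for parameter-recovery tests."""

    effects: pd.Series | None = None          # V2/V1 fold per feature (1 = null)
    dilution: pd.Series | None = None         # per sample
    drift: pd.Series | None = None            # per sample (injection-order value)
    creatinine_feature_id: str | None = None
    pairs: pd.DataFrame | None = None         # conjugate/aglycon/shift per arm
    hydrolysis_fraction: float | None = None

    def to_json_dict(self) -> dict:
        out: dict = {}
        if self.effects is not None:
            out["effects"] = {k: float(v) for k, v in self.effects.items() if v != 1.0}
        if self.dilution is not None:
            out["dilution"] = {k: float(v) for k, v in self.dilution.items()}
        if self.drift is not None:
            out["drift"] = {k: float(v) for k, v in self.drift.items()}
        if self.creatinine_feature_id is not None:
            out["creatinine_feature_id"] = self.creatinine_feature_id
        if self.pairs is not None:
            out["pairs"] = self.pairs.to_dict(orient="records")
        if self.hydrolysis_fraction is not None:
            out["hydrolysis_fraction"] = self.hydrolysis_fraction
        return out


CREATININE_FORMULA = "C4H7N3O"


def generate_cohort(config: CohortConfig) -> tuple[FeatureTable, SampleSheet, SyntheticTruth]:
    """Simulate a paired V1/V2 cohort feature table with pooled QC injections."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sub, n_feat = config.n_subjects, config.n_features

    feature_ids = [f"F{i + 1:04d}" for i in range(n_feat)]
    creat_id = "F_CREA"
    mz = rng.uniform(*config.mz_range, size=n_feat)
    rt = rng.uniform(*config.rt_range, size=n_feat)

    subjects = [f"S{i + 1:03d}" for i in range(n_sub)]
    subj_samples = [f"{s}_{v}" for s in subjects for v in ("V1", "V2")]
    qc_samples = [f"QC{i + 1:02d}" for i in range(config.n_qc)]

    # randomized run order: subject samples shuffled, QCs interleaved evenly
    shuffled = list(rng.permutation(subj_samples))
    run_order: list[str] = []
    if config.n_qc:
        step = max(1, len(shuffled) // config.n_qc)
        qi = 0
        for i, s in enumerate(shuffled):
            if qi < config.n_qc and i % step == 0:
                run_order.append(qc_samples[qi])
                qi += 1
            run_order.append(s)
        run_order.extend(qc_samples[qi:])
    else:
        run_order = shuffled
    n_total = len(run_order)
    injection_order = {s: i + 1 for i, s in enumerate(run_order)}
    per_batch = int(np.ceil(n_total / config.n_batches))
    batch = {s: min(i // per_batch, config.n_batches - 1) + 1
             for i, s in enumerate(run_order)}

    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_feat))
    effects = pd.Series(1.0, index=feature_ids, name="effect")
    for idx, fold in config.effect_fold_changes.items():
        effects.iloc[idx] = float(fold)

    dilution = pd.Series(
        np.exp(rng.normal(0.0, config.dilution_sd, len(subj_samples))),
        index=subj_samples, name="dilution")

    # smooth per-batch drift: one sinusoid per batch, random phase/frequency
    phases = rng.uniform(0, 2 * np.pi, config.n_batches)
    freqs = rng.uniform(0.5, 1.5, config.n_batches)
    drift = {}
    for s in run_order:
        b = batch[s] - 1
        pos = (injection_order[s] - 1 - b * per_batch) / max(per_batch - 1, 1)
        drift[s] = 1.0 + config.drift_amplitude * np.sin(2 * np.pi * freqs[b] * pos + phases[b])
    drift_s = pd.Series(drift, name="drift")

    sigma = np.sqrt(np.log1p(config.noise_cv ** 2))

    # concentrations before drift/noise; QC = pooled mean of subject samples
    conc = np.empty((n_feat + 1, len(subj_samples)))
    for j, s in enumerate(subj_samples):
        visit = s.rsplit("_", 1)[1]
        eff = effects.to_numpy() if visit == "V2" else np.ones(n_feat)
        conc[:n_feat, j] = base * eff * dilution[s]
    creat_base = np.exp(config.baseline_log_mean)
    conc[n_feat, :] = creat_base * dilution.to_numpy()
    qc_conc = conc.mean(axis=1)

    all_ids = feature_ids + [creat_id]
    inten = pd.DataFrame(index=all_ids, columns=run_order, dtype=float)
    for j, s in enumerate(subj_samples):
        eps = rng.normal(0.0, sigma, n_feat + 1) if sigma > 0 else 0.0
        inten[s] = conc[:, j] * drift_s[s] * np.exp(eps)
    for s in qc_samples:
        eps = rng.normal(0.0, sigma, n_feat + 1) if sigma > 0 else 0.0
        inten[s] = qc_conc * drift_s[s] * np.exp(eps)

    table = FeatureTable(
        pd.Series(np.append(mz, theoretical_mz(CREATININE_FORMULA, "[M-H]-")),
                  index=all_ids, name="mz"),
        pd.Series(np.append(rt, 1.2), index=all_ids, name="rt"),
        inten)

    rows = []
    for s in run_order:
        if s.startswith("QC"):
            subj, role, creat = "", "QC", creat_base * float(dilution.mean())
        else:
            subj, role = s.rsplit("_", 1)
            creat = creat_base * float(dilution[s])
        rows.append((s, subj, role, injection_order[s], batch[s], creat))
    sheet = SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "role", "injection_order",
                       "batch", "creatinine"]))

    truth = SyntheticTruth(effects=effects, dilution=dilution, drift=drift_s,
                           creatinine_feature_id=creat_id)
    return table, sheet, truth


def _sample_decoy_mz(rng: np.random.Generator, existing: np.ndarray,
                     deltas: list[float], tol_ppm: float,
                     mz_range: tuple[float, float]) -> float:
    """Rejection-sample an m/z with no shift relation to any existing feature."""
    guard = 3.0 * tol_ppm * 1e-6
    for _ in range(10_000):
        cand = rng.uniform(*mz_range)
        ok = True
        for d in deltas:
            # cand as conjugate of an existing aglycon, or as aglycon of one
            if np.any(np.abs(cand - d - existing) <= guard * cand):
                ok = False
                break
            if np.any(np.abs(existing - d - cand) <= guard * existing):
                ok = False
                break
        if ok:
            return float(cand)
    raise RuntimeError("could not place a decoy m/z away from all shift relations")


def generate_enzyme_assay(config: AssayConfig) -> tuple[dict[str, AssayTable], SyntheticTruth]:
    """Simulate sulfatase and glucuronidase assay tables with planted pairs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shifts = {"sulfatase": ShiftClass.sulfate(), "glucuronidase": ShiftClass.glucuronide()}
    sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
    mz_range = (150.0, 500.0)

    arms: dict[str, AssayTable] = {}
    truth_pairs = []
    for arm, shift in shifts.items():
        rows = []  # (feature_id, true_mz, role)
        existing = np.empty(0)
        deltas = [s.delta for s in shifts.values()]
        for p in range(config.n_pairs):
            a_mz = _sample_decoy_mz(rng, existing, deltas, config.pairing_tol_ppm, mz_range)
            c_mz = a_mz + shift.delta
            aid = f"{arm[:3].upper()}_A{p + 1:03d}"
            cid = f"{arm[:3].upper()}_C{p + 1:03d}"
            rows.append((aid, a_mz, "aglycon", p))
            rows.append((cid, c_mz, "conjugate", p))
            existing = np.append(existing, [a_mz, c_mz])
            truth_pairs.append({"conjugate_feature_id": cid, "aglycon_feature_id": aid,
                                "shift": shift.name, "arm": arm})
        for d in range(config.n_decoys):
            d_mz = _sample_decoy_mz(rng, existing, deltas, config.pairing_tol_ppm, mz_range)
            rows.append((f"{arm[:3].upper()}_D{d + 1:03d}", d_mz, "decoy", -1))
            existing = np.append(existing, d_mz)

        ids = [r[0] for r in rows]
        true_mz = np.array([r[1] for r in rows])
        jitter = rng.uniform(-config.mz_jitter_ppm, config.mz_jitter_ppm, len(rows))
        obs_mz = true_mz * (1.0 + jitter * 1e-6)
        rt = rng.uniform(1.0, 18.0, len(rows))

        a_base = np.exp(rng.normal(config.aglycon_log_mean, config.aglycon_log_sd,
                                   config.n_pairs))
        c_base = a_base * np.exp(rng.normal(config.conj_over_aglycon_log_mean,
                                            config.conj_over_aglycon_log_sd,
                                            config.n_pairs))
        d_base = np.exp(rng.normal(config.aglycon_log_mean + 1.0, 1.0, config.n_decoys))

        base = np.empty(len(rows))
        treated18 = np.empty(len(rows))
        for i, (fid, _, role, p) in enumerate(rows):
            if role == "aglycon":
                base[i] = a_base[p]
                # stoichiometric gain from the hydrolyzed conjugate
                treated18[i] = a_base[p] + (config.hydrolysis_fraction * c_base[p]
                                            * config.response_ratio)
            elif role == "conjugate":
                base[i] = c_base[p]
                treated18[i] = c_base[p] * (1.0 - config.hydrolysis_fraction)
            else:  # decoy: untouched by the enzyme
                base[i] = d_base[int(fid.split("_D")[1]) - 1]
                treated18[i] = base[i]

        design_rows = []
        cols = {}
        for cond in AssayTable.CONDITIONS:
            for tp in AssayTable.TIMEPOINTS:
                expect = treated18 if (cond == "enzyme" and tp == "18h") else base
                for r in range(config.n_replicates):
                    sid = f"{arm[:3]}_{cond[:3]}_{tp}_r{r + 1}"
                    eps = rng.normal(0.0, sigma, len(rows)) if sigma > 0 else 0.0
                    cols[sid] = expect * np.exp(eps)
                    design_rows.append((sid, cond, tp, r + 1))
        table = FeatureTable(pd.Series(obs_mz, index=ids, name="mz"),
                             pd.Series(rt, index=ids, name="rt"),
                             pd.DataFrame(cols, index=ids))
        design = pd.DataFrame(design_rows,
                              columns=["sample_id", "condition", "timepoint", "replicate"])
        arms[arm] = AssayTable(arm=arm, table=table, design=design)

    truth = SyntheticTruth(pairs=pd.DataFrame(truth_pairs),
                           hydrolysis_fraction=config.hydrolysis_fraction)
    return arms, truth


def config_from_dict(d: Mapping, kind: str) -> CohortConfig | AssayConfig:
    """Build a generator config from a plain mapping (YAML-friendly)."""
    cls = {"cohort": CohortConfig, "assay": AssayConfig}[kind]
    cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
    if isinstance(cfg, CohortConfig) and cfg.effect_fold_changes:
        cfg.effect_fold_changes = {int(k): float(v)
                                   for k, v in cfg.effect_fold_changes.items()}
    cfg.validate()
    return cfg
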