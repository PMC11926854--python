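"""Feature tables, sample sheets and assay tables: containers, readers, writers.

The interchange format is delimited text (comma or tab, chosen by file
extension, overridable).  A feature table has the header
``feature_id,mz,rt,<sample_id...>`` with m/z in Da and retention time in
minutes; a sample sheet has
``sample_id,subject_id,role,injection_order,batch,creatinine``.

Missing intensities are written as empty cells or ``NA`` and held internally
as NaN — never as zero, because the intensity floor and all ratio arithmetic
apply to measured values only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("V1", "V2", "QC")


class FormatError(ValueError):
    """A file does not have the expected columns/layout."""


class ValidationError(ValueError):
    """A table violates a structural invariant."""


class PairingError(ValidationError):
    """The paired V1/V2 design is broken for at least one subject."""


class AlignmentError(ValueError):
    """Feature table and sample sheet cannot be matched sample-for-sample."""


def _resolve_sep(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"comma": ",", "tab": "\t", ",": ",", "\t": "\t"}.get(dialect, dialect)
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


@dataclass
class FeatureTable:
    """Feature × sample intensity matrix with per-feature m/z and RT.

    ``intensities`` is indexed by ``feature_id`` with one column per
    sample_id; NaN marks a missing measurement.
    """

    mz: pd.Series           # Da, observed [M-H]- m/z, indexed by feature_id
    rt: pd.Series           # minutes, indexed by feature_id
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature_id values: {dups}")
        if not (self.mz.index.equals(idx) and self.rt.index.equals(idx)):
            raise ValidationError("mz/rt index does not match intensity rows")
        if (self.mz <= 0).any():
            raise ValidationError("all m/z values must be > 0")
        if (self.rt < 0).any():
            raise ValidationError("all retention times must be >= 0")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError("negative intensity encountered")

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.mz.copy(), self.rt.copy(), self.intensities.copy())

    def subset(self, feature_ids: Iterable[str]) -> "FeatureTable":
        ids = pd.Index(feature_ids)
        return FeatureTable(self.mz.loc[ids], self.rt.loc[ids], self.intensities.loc[ids])

    def with_intensities(self, intensities: pd.DataFrame) -> "FeatureTable":
        """Same features/annotations, new intensity matrix (same index)."""
        return FeatureTable(self.mz.copy(), self.rt.copy(), intensities)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"feature_id": self.feature_ids, "mz": self.mz.values,
                            "rt": self.rt.values})
        out = pd.concat([out.set_index("feature_id"), self.intensities], axis=1)
        out.index.name = "feature_id"
        return out.reset_index()


@dataclass
class SampleSheet:
    """Per-sample metadata for a paired two-visit cohort with pooled QCs."""

    frame: pd.DataFrame  # sample_id, subject_id, role, injection_order, batch, creatinine

    REQUIRED = ("sample_id", "subject_id", "role", "injection_order", "batch", "creatinine")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.frame
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"sample sheet is missing mandatory column '{col}'")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        bad = set(df["role"]) - set(ROLES)
        if bad:
            raise ValidationError(f"unknown role values {sorted(bad)}; expected {ROLES}")
        if df["injection_order"].duplicated().any():
            raise ValidationError("injection_order values must be unique")
        subj = df[df["role"] != "QC"]
        counts = subj.pivot_table(index="subject_id", columns="role",
                                  values="sample_id", aggfunc="count").reindex(
                                      columns=["V1", "V2"]).fillna(0).astype(int)
        broken = counts[(counts["V1"] != 1) | (counts["V2"] != 1)]
        if len(broken):
            raise PairingError(
                "subjects without exactly one V1 and one V2 sample: "
                + ", ".join(f"{s} (V1={r.V1}, V2={r.V2})" for s, r in broken.iterrows()))

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.frame["sample_id"])

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame.loc[self.frame["role"] != "QC", "subject_id"].unique())

    @property
    def qc_sample_ids(self) -> list[str]:
        return self.frame.loc[self.frame["role"] == "QC", "sample_id"].tolist()

    def creatinine_of(self, sample_id: str) -> float:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        return float(row["creatinine"].iloc[0])


@dataclass
class PairedCohort:
    """A feature table aligned to its sample sheet, plus the V1/V2 pairing.

    ``pairs`` maps subject_id -> (v1_sample_id, v2_sample_id); column order of
    ``table`` matches the sheet's row order exactly.
    """

    table: FeatureTable
    sheet: SampleSheet
    pairs: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return list(self.pairs)

    def v1_columns(self) -> list[str]:
        return [v1 for v1, _ in self.pairs.values()]

    def v2_columns(self) -> list[str]:
        return [v2 for _, v2 in self.pairs.values()]

    def v1_matrix(self) -> pd.DataFrame:
        """Features × subjects matrix of V1 intensities (columns = subject_id)."""
        m = self.table.intensities[self.v1_columns()].copy()
        m.columns = self.subjects
        return m

    def v2_matrix(self) -> pd.DataFrame:
        m = self.table.intensities[self.v2_columns()].copy()
        m.columns = self.subjects
        return m

    def subset(self, feature_ids: Iterable[str]) -> "PairedCohort":
        return PairedCohort(self.table.subset(feature_ids), self.sheet, self.pairs)


@dataclass
class AssayTable:
    """Enzymatic-assay intensities: enzyme vs denatured control at 0 h and 18 h.

    ``design`` has one row per intensity column of ``table`` with columns
    sample_id, condition ('enzyme'|'denatured_control'), timepoint ('0h'|'18h')
    and replicate.
    """

    arm: str  # 'sulfatase' | 'glucuronidase'
    table: FeatureTable
    design: pd.DataFrame

    ARMS = ("sulfatase", "glucuronidase")
    CONDITIONS = ("enzyme", "denatured_control")
    TIMEPOINTS = ("0h", "18h")

    def __post_init__(self) -> None:
        if self.arm not in self.ARMS:
            raise ValidationError(f"unknown assay arm '{self.arm}'")
        need = {(c, t) for c in self.CONDITIONS for t in self.TIMEPOINTS}
        have = set(map(tuple, self.design[["condition", "timepoint"]].drop_duplicates()
                       .itertuples(index=False)))
        if need - have:
            raise ValidationError(f"assay arm '{self.arm}' missing conditions {sorted(need - have)}")
        missing = set(self.design["sample_id"]) - set(self.table.sample_ids)
        if missing:
            raise ValidationError(f"design rows without intensity columns: {sorted(missing)}")

    def columns(self, condition: str, timepoint: str) -> list[str]:
        d = self.design
        sel = d[(d["condition"] == condition) & (d["timepoint"] == timepoint)]
        return sel["sample_id"].tolist()

    def mean_intensity(self, condition: str, timepoint: str) -> pd.Series:
        cols = self.columns(condition, timepoint)
        return self.table.intensities[cols].mean(axis=1)


# ---------------------------------------------------------------------------
# readers / writers

def read_feature_table(path: str | Path, dialect: str | None = None) -> FeatureTable:
    """Read a delimited feature table (header feature_id,mz,rt,<samples...>)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_resolve_sep(path, dialect), dtype={"feature_id": str},
                     na_values=["NA"], keep_default_na=True)
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise FormatError(f"feature table is missing mandatory column '{col}'")
    sample_cols = [c for c in df.columns if c not in ("feature_id", "mz", "rt")]
    df = df.set_index("feature_id")
    return FeatureTable(df["mz"].astype(float), df["rt"].astype(float),
                        df[sample_cols].astype(float))


def write_feature_table(table: FeatureTable, path: str | Path,
                        dialect: str | None = None) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_resolve_sep(path, dialect), index=False,
                            na_rep="NA", float_format="%.10g")


def read_sample_sheet(path: str | Path, dialect: str | None = None) -> SampleSheet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_resolve_sep(path, dialect),
                     dtype={"sample_id": str, "subject_id": str})
    for col in SampleSheet.REQUIRED:
        if col not in df.columns:
            raise FormatError(f"sample sheet is missing mandatory column '{col}'")
    df["subject_id"] = df["subject_id"].fillna("")
    df["role"] = df["role"].str.strip().str.upper().replace({"POOL": "QC"})
    df["injection_order"] = df["injection_order"].astype(int)
    df["batch"] = df["batch"].astype(int)
    df["creatinine"] = df["creatinine"].astype(float)
    return SampleSheet(df.reset_index(drop=True))


def write_sample_sheet(sheet: SampleSheet, path: str | Path,
                       dialect: str | None = None) -> None:
    path = Path(path)
    sheet.frame.to_csv(path, sep=_resolve_sep(path, dialect), index=False,
                       float_format="%.10g")


def align(table: FeatureTable, sheet: SampleSheet) -> PairedCohort:
    """Restrict/order the table's sample columns to the sheet and build pairs.

    Columns are matched by exact string identity; silent mispairing is the
    worst failure mode in a paired design, so nothing fuzzy happens here.
    Extra table columns not in the sheet are dropped with a warning.
    """
    wanted = sheet.sample_ids
    missing = [s for s in wanted if s not in table.sample_ids]
    if missing:
        raise AlignmentError(f"samples in sheet absent from feature table: {missing}")
    extra = [c for c in table.sample_ids if c not in set(wanted)]
    if extra:
        logger.warning("dropping %d feature-table columns not in sample sheet: %s",
                       len(extra), extra[:10])
    aligned = FeatureTable(table.mz.copy(), table.rt.copy(),
                           table.intensities[list(wanted)].copy())
    pairs: dict[str, tuple[str, str]] = {}
    df = sheet.frame
    for subject in sheet.subjects:
        v1 = df.loc[(df.subject_id == subject) & (df.role == "V1"), "sample_id"].iloc[0]
        v2 = df.loc[(df.subject_id == subject) & (df.role == "V2"), "sample_id"].iloc[0]
        pairs[subject] = (v1, v2)
    return PairedCohort(aligned, sheet, pairs)
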