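import numpy as np
import pandas as pd
import pytest

from phenolomics.io import FeatureTable, SampleSheet, align


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 features x 4 samples (2 subjects x V1/V2), hand-written values."""
    ids = ["feat_a", "feat_b", "feat_c"]
    return FeatureTable(
        mz=pd.Series([297.1132, 377.0700, 473.1453], index=ids),
        rt=pd.Series([5.0, 4.2, 3.8], index=ids),
        intensities=pd.DataFrame(
            {"S1_V1": [100.0, 2000.0, 30000.0],
             "S1_V2": [150.0, 2500.0, 28000.0],
             "S2_V1": [90.0, 1800.0, 31000.0],
             "S2_V2": [210.0, 3600.0, 33000.0]},
            index=ids),
    )


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet(pd.DataFrame({
        "sample_id": ["S1_V1", "S1_V2", "S2_V1", "S2_V2"],
        "subject_id": ["S1", "S1", "S2", "S2"],
        "role": ["V1", "V2", "V1", "V2"],
        "injection_order": [1, 2, 3, 4],
        "batch": [1, 1, 1, 1],
        "creatinine": [1.0, 1.2, 0.8, 1.1],
    }))


@pytest.fixture
def tiny_cohort(tiny_table, tiny_sheet):
    return align(tiny_table, tiny_sheet)


def make_cohort_frames(n_subjects: int, intensity_fn, *, mz=None, rt=None,
                       creatinine=None):
    """Build a paired cohort from a per-(feature, sample) intensity rule."""
    samples, subjects, roles = [], [], []
    for i in range(n_subjects):
        sid = f"P{i + 1:03d}"
        for v in ("V1", "V2"):
            samples.append(f"{sid}_{v}")
            subjects.append(sid)
            roles.append(v)
    inten = pd.DataFrame({s: intensity_fn(s) for s in samples})
    n_feat = len(inten)
    ids = [f"X{i + 1:03d}" for i in range(n_feat)]
    inten.index = ids
    table = FeatureTable(
        mz=pd.Series(mz if mz is not None else np.linspace(150, 600, n_feat), index=ids),
        rt=pd.Series(rt if rt is not None else np.linspace(2, 16, n_feat), index=ids),
        intensities=inten)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": samples, "subject_id": subjects, "role": roles,
        "injection_order": np.arange(1, len(samples) + 1),
        "batch": 1,
        "creatinine": creatinine if creatinine is not None else 1.0,
    }))
    return align(table, sheet)
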