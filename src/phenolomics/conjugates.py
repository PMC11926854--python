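"""Phase II conjugate discovery by exact mass-shift pairing.

Sulfation adds SO3 (79.9568 Da) and glucuronidation adds C6H8O6
(176.0321 Da) to the aglycon; in negative-mode LC-MS both the conjugate and
the free aglycon appear as [M-H]- ions, so a conjugate/aglycon pair shows up
as two features whose m/z difference equals the neutral group mass within
instrument accuracy.  Candidate pairs found by the Δm/z scan are confirmed by
the enzymatic assay: hydrolysis by the matching enzyme (arylsulfatase or
β-glucuronidase) must deplete the conjugate and raise the aglycon relative
to a denatured-enzyme control after 18 h of incubation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from pyteomics.auxiliary import PyteomicsError

from .io import AssayTable, FeatureTable

logger = logging.getLogger(__name__)

#: monoisotopic proton mass, Da (CODATA)
PROTON_MASS = 1.00727646688


class FormulaError(ValueError):
    """Unparseable or empty elemental composition."""


def theoretical_mz(formula: str, species: str = "neutral") -> float:
    """Monoisotopic mass of an elemental formula, neutral or as [M-H]-.

    Parameters
    ----------
    formula : str
        Elemental composition, e.g. ``"C18H18O4"`` or ``"SO3"``.
    species : {"neutral", "[M-H]-"}
        For the deprotonated ion one proton mass is subtracted (the electron
        mass difference is ~0.0005 Da and is included via the proton mass
        convention used throughout negative-mode small-molecule work).
    """
    if not formula or not formula.strip():
        raise FormulaError("empty elemental formula")
    try:
        m = _ptmass.calculate_mass(formula=formula)
    except PyteomicsError as exc:  # unknown element symbol, bad syntax
        raise FormulaError(f"cannot parse formula {formula!r}: {exc}") from exc
    if species == "neutral":
        return float(m)
    if species in ("[M-H]-", "[M−H]-", "M-H"):
        return float(m - PROTON_MASS)
    raise ValueError(f"unknown species {species!r}; use 'neutral' or '[M-H]-'")


@dataclass(frozen=True)
class ShiftClass:
    """A phase II mass shift: group name and its neutral monoisotopic mass."""

    name: str
    delta: float

    @classmethod
    def sulfate(cls) -> "ShiftClass":
        return cls("sulfate", theoretical_mz("SO3"))

    @classmethod
    def glucuronide(cls) -> "ShiftClass":
        return cls("glucuronide", theoretical_mz("C6H8O6"))

    @classmethod
    def by_name(cls, name: str) -> "ShiftClass":
        try:
            return {"sulfate": cls.sulfate, "glucuronide": cls.glucuronide}[name]()
        except KeyError:
            raise ValueError(f"unknown shift class {name!r}") from None


#: assay arm that hydrolyzes each shift class
ARM_FOR_SHIFT = {"sulfate": "sulfatase", "glucuronide": "glucuronidase"}


def find_mass_shift_pairs(table: FeatureTable, shift: ShiftClass,
                          ppm_tol: float = 5.0) -> pd.DataFrame:
    """All ordered (conjugate, aglycon) feature pairs matching the shift.

    A pair (c, a) qualifies when ``|(mz(c) - delta) - mz(a)| / mz(c) * 1e6``
    is at most ``ppm_tol``.  Every qualifying combination is reported (a
    conjugate may match several aglycon candidates and vice versa), sorted by
    absolute mass error.

    Returns a DataFrame with columns conjugate_feature_id, aglycon_feature_id,
    shift, mass_error_ppm.
    """
    ids = np.asarray(table.feature_ids)
    mz = table.mz.to_numpy(dtype=float)
    order = np.argsort(mz, kind="stable")
    mz_sorted = mz[order]

    rows: list[tuple[str, str, float]] = []
    for ci in range(len(mz)):
        target = mz[ci] - shift.delta
        if target <= 0:
            continue
        tol_da = ppm_tol * 1e-6 * mz[ci]
        lo = np.searchsorted(mz_sorted, target - tol_da, side="left")
        hi = np.searchsorted(mz_sorted, target + tol_da, side="right")
        for aj in order[lo:hi]:
            if aj == ci:
                continue
            err_ppm = (mz[ci] - shift.delta - mz[aj]) / mz[ci] * 1e6
            if abs(err_ppm) <= ppm_tol:
                rows.append((ids[ci], ids[aj], err_ppm))
    out = pd.DataFrame(rows, columns=["conjugate_feature_id", "aglycon_feature_id",
                                      "mass_error_ppm"])
    out.insert(2, "shift", shift.name)
    out = out.reindex(out["mass_error_ppm"].abs().sort_values(kind="stable").index)
    return out.reset_index(drop=True)


@dataclass
class ConjugateHit:
    """A mass-shift pair with its enzyme-response evidence."""

    conjugate_feature_id: str
    aglycon_feature_id: str
    shift: str
    mass_error_ppm: float
    conjugate_response: float  # treated/control intensity ratio, 18 h
    aglycon_response: float
    conjugate_response_0h: float = np.nan
    aglycon_response_0h: float = np.nan
    passes: bool = False
    evaluable: bool = True
    note: str = ""


def score_enzyme_response(pairs: pd.DataFrame, assay: AssayTable,
                          conjugate_max_ratio: float = 0.5,
                          aglycon_min_ratio: float = 2.0) -> list[ConjugateHit]:
    """Confirm candidate pairs against the enzyme vs denatured-control assay.

    For each pair the mean enzyme/control intensity ratio at 18 h is computed
    for the conjugate and the aglycon; a hit requires the conjugate depleted
    (ratio <= ``conjugate_max_ratio``) and the aglycon raised (ratio >=
    ``aglycon_min_ratio``).  The 0 h ratios are carried along as a negative
    control.  A zero control mean makes the pair unevaluable, never a hit.
    """
    expected = {v: k for k, v in ARM_FOR_SHIFT.items()}[assay.arm]
    shifts = set(pairs["shift"]) if len(pairs) else set()
    if shifts - {expected}:
        raise ValueError(f"assay arm '{assay.arm}' scores '{expected}' pairs, got {sorted(shifts)}")

    mean_t18 = assay.mean_intensity("enzyme", "18h")
    mean_c18 = assay.mean_intensity("denatured_control", "18h")
    mean_t0 = assay.mean_intensity("enzyme", "0h")
    mean_c0 = assay.mean_intensity("denatured_control", "0h")

    hits: list[ConjugateHit] = []
    for row in pairs.itertuples(index=False):
        c, a = row.conjugate_feature_id, row.aglycon_feature_id
        hit = ConjugateHit(c, a, row.shift, float(row.mass_error_ppm),
                           np.nan, np.nan)
        if mean_c18[c] <= 0 or mean_c18[a] <= 0:
            hit.evaluable = False
            hit.note = "zero 18h control mean"
            hits.append(hit)
            continue
        hit.conjugate_response = float(mean_t18[c] / mean_c18[c])
        hit.aglycon_response = float(mean_t18[a] / mean_c18[a])
        if mean_c0[c] > 0 and mean_c0[a] > 0:
            hit.conjugate_response_0h = float(mean_t0[c] / mean_c0[c])
            hit.aglycon_response_0h = float(mean_t0[a] / mean_c0[a])
        hit.passes = (hit.conjugate_response <= conjugate_max_ratio
                      and hit.aglycon_response >= aglycon_min_ratio)
        hits.append(hit)
    return hits


def hits_to_frame(hits: list[ConjugateHit]) -> pd.DataFrame:
    return pd.DataFrame([vars(h) for h in hits])


@dataclass
class IsomerGroups:
    """Result of merging co-mass stereoisomer peaks."""

    table: FeatureTable
    members: dict[str, list[str]] = field(default_factory=dict)


def group_isomers(table: FeatureTable, mz_tol_ppm: float = 5.0,
                  rt_window: float = 5.0) -> IsomerGroups:
    """Merge features sharing one m/z but eluting as distinct peaks.

    Stereoisomer conjugates that cannot be told apart without authentic
    standards are summed: features whose m/z agree within ``mz_tol_ppm`` and
    whose retention times lie within ``rt_window`` minutes of the group are
    collapsed into one row whose per-sample intensity is the member sum and
    whose RT is the intensity-weighted mean.  Total intensity per sample is
    conserved exactly.
    """
    order = np.argsort(table.mz.to_numpy(), kind="stable")
    mz = table.mz.to_numpy()[order]
    rt = table.rt.to_numpy()[order]
    ids = np.asarray(table.feature_ids)[order]

    groups: list[list[int]] = []
    for i in range(len(ids)):
        placed = False
        if groups:
            g = groups[-1]
            ref_mz = mz[g[0]]
            if (abs(mz[i] - ref_mz) / ref_mz * 1e6 <= mz_tol_ppm
                    and abs(rt[i] - rt[g[0]]) <= rt_window):
                g.append(i)
                placed = True
        if not placed:
            groups.append([i])

    new_rows = []
    members: dict[str, list[str]] = {}
    inten = table.intensities.to_numpy(dtype=float)
    inten_sorted = inten[order]
    for g in groups:
        member_ids = [str(ids[i]) for i in g]
        if len(g) == 1:
            gid = member_ids[0]
            row_int = inten_sorted[g[0]]
            g_mz, g_rt = mz[g[0]], rt[g[0]]
        else:
            gid = member_ids[0] + "+grp"
            block = inten_sorted[g]
            row_int = np.nansum(block, axis=0)
            all_missing = np.isnan(block).all(axis=0)
            row_int[all_missing] = np.nan  # keep missing missing, not zero
            weights = np.nansum(block, axis=1)
            total = weights.sum()
            g_rt = float((weights * rt[g]).sum() / total) if total > 0 else float(rt[g].mean())
            g_mz = float(mz[g].mean())
        members[gid] = member_ids
        new_rows.append((gid, g_mz, g_rt, row_int))

    new_ids = [r[0] for r in new_rows]
    merged = FeatureTable(
        pd.Series([r[1] for r in new_rows], index=new_ids, name="mz"),
        pd.Series([r[2] for r in new_rows], index=new_ids, name="rt"),
        pd.DataFrame(np.vstack([r[3] for r in new_rows]), index=new_ids,
                     columns=table.sample_ids),
    )
    n_merged = sum(1 for m in members.values() if len(m) > 1)
    if n_merged:
        logger.info("group_isomers merged %d groups from %d features",
                    n_merged, table.n_features)
    return IsomerGroups(merged, members)
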