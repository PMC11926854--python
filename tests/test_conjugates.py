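import numpy as np
import pandas as pd
import pytest

from phenolomics.conjugates import (FormulaError, ShiftClass,
                                    find_mass_shift_pairs, group_isomers,
                                    score_enzyme_response, theoretical_mz)
from phenolomics.io import FeatureTable
from phenolomics.simulate import AssayConfig, generate_enzyme_assay

# independent oracle: IUPAC monoisotopic atomic masses, summed by hand
MONO = {"C": 12.0, "H": 1.00782503207, "O": 15.99491461956,
        "S": 31.97207100, "N": 14.0030740048}


def hand_mass(counts: dict[str, int]) -> float:
    return sum(MONO[e] * n for e, n in counts.items())


class TestTheoreticalMz:
    def test_sulfate_shift_rounds_to_printed_value(self):
        assert round(theoretical_mz("SO3"), 4) == 79.9568

    def test_glucuronide_shift_rounds_to_printed_value(self):
        assert round(theoretical_mz("C6H8O6"), 4) == 176.0321

    @pytest.mark.parametrize("formula,counts", [
        ("SO3", {"S": 1, "O": 3}),
        ("C6H8O6", {"C": 6, "H": 8, "O": 6}),
        ("C18H18O4", {"C": 18, "H": 18, "O": 4}),
    ])
    def test_matches_hand_summed_monoisotopic_masses(self, formula, counts):
        assert theoretical_mz(formula) == pytest.approx(hand_mass(counts), abs=1e-5)

    def test_enterolactone_ion_arithmetic(self):
        # measured values for ENL and its phase II conjugates
        enl = theoretical_mz("C18H18O4", "[M-H]-")
        assert enl == pytest.approx(297.1138, abs=0.002)
        assert enl + theoretical_mz("SO3") == pytest.approx(377.0705, abs=0.002)
        assert enl + theoretical_mz("C6H8O6") == pytest.approx(473.1450, abs=0.002)

    def test_additivity_of_neutral_compositions(self):
        a = theoretical_mz("C6H8O6") + theoretical_mz("C18H18O4")
        b = theoretical_mz("C24H26O10")
        assert a == pytest.approx(b, abs=1e-9)

    def test_empty_and_unknown_formula_rejected(self):
        with pytest.raises(FormulaError):
            theoretical_mz("")
        with pytest.raises(FormulaError):
            theoretical_mz("Xx3Q")


def _mz_table(mzs, rts=None, n_samples=1):
    ids = [f"f{i}" for i in range(len(mzs))]
    rts = rts if rts is not None else [5.0] * len(mzs)
    inten = pd.DataFrame({f"S{j}": np.full(len(mzs), 100.0) for j in range(n_samples)},
                         index=ids)
    return FeatureTable(pd.Series(mzs, index=ids, dtype=float),
                        pd.Series(rts, index=ids, dtype=float), inten)


class TestFindMassShiftPairs:
    def test_pairs_printed_enterolactone_values(self):
        t = _mz_table([377.0705, 297.1138])
        pairs = find_mass_shift_pairs(t, ShiftClass.sulfate(), ppm_tol=5.0)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert (row.conjugate_feature_id, row.aglycon_feature_id) == ("f0", "f1")
        assert abs(row.mass_error_ppm) < 1.0

    def test_pairs_printed_glucuronide_values(self):
        t = _mz_table([473.1450, 297.1138])
        pairs = find_mass_shift_pairs(t, ShiftClass.glucuronide(), ppm_tol=5.0)
        assert len(pairs) == 1
        # the printed measured masses carry ~2 ppm of instrument error
        assert abs(pairs.iloc[0].mass_error_ppm) <= 5.0

    def test_empty_table_gives_empty_result(self):
        t = _mz_table([])
        assert len(find_mass_shift_pairs(t, ShiftClass.sulfate())) == 0

    @pytest.mark.parametrize("shift", [ShiftClass.sulfate(), ShiftClass.glucuronide()])
    def test_matches_brute_force_oracle(self, shift):
        rng = np.random.default_rng(17)
        mzs = rng.uniform(100, 700, 500)
        # plant a few exact relations so the match set is non-trivial
        mzs[:10] = mzs[10:20] + shift.delta
        t = _mz_table(mzs)
        got = find_mass_shift_pairs(t, shift, ppm_tol=5.0)
        got_set = set(zip(got.conjugate_feature_id, got.aglycon_feature_id))
        brute = set()
        for i in range(len(mzs)):
            for j in range(len(mzs)):
                if i == j:
                    continue
                if abs(mzs[i] - shift.delta - mzs[j]) / mzs[i] * 1e6 <= 5.0:
                    brute.add((f"f{i}", f"f{j}"))
        assert got_set == brute

    def test_sorted_by_absolute_mass_error(self):
        delta = ShiftClass.sulfate().delta
        t = _mz_table([300.0, 300.0 + delta + 0.0009, 300.0 + delta + 0.0001])
        pairs = find_mass_shift_pairs(t, ShiftClass.sulfate(), ppm_tol=5.0)
        errs = pairs.mass_error_ppm.abs().to_numpy()
        assert np.all(np.diff(errs) >= 0)


def _toy_assay(conj_ratio, agly_ratio, arm="sulfatase"):
    shift = ShiftClass.sulfate() if arm == "sulfatase" else ShiftClass.glucuronide()
    mzs = [300.0 + shift.delta, 300.0]
    ids = ["conj", "agly"]
    cols, design = {}, []
    base = {"conj": 1000.0, "agly": 500.0}
    for cond in ("enzyme", "denatured_control"):
        for tp in ("0h", "18h"):
            for r in (1, 2):
                sid = f"{cond[:3]}_{tp}_r{r}"
                scale = {"conj": conj_ratio, "agly": agly_ratio} \
                    if (cond == "enzyme" and tp == "18h") else {"conj": 1, "agly": 1}
                cols[sid] = [base[i] * scale[i] for i in ids]
                design.append((sid, cond, tp, r))
    table = FeatureTable(pd.Series(mzs, index=ids), pd.Series([5.0, 6.0], index=ids),
                         pd.DataFrame(cols, index=ids))
    from phenolomics.io import AssayTable
    return AssayTable(arm=arm, table=table,
                      design=pd.DataFrame(design, columns=["sample_id", "condition",
                                                           "timepoint", "replicate"]))


class TestScoreEnzymeResponse:
    def _pairs(self, shift="sulfate"):
        return pd.DataFrame({"conjugate_feature_id": ["conj"],
                             "aglycon_feature_id": ["agly"],
                             "shift": [shift], "mass_error_ppm": [0.1]})

    def test_depleted_conjugate_raised_aglycon_passes(self):
        hits = score_enzyme_response(self._pairs(), _toy_assay(0.1, 5.0))
        assert hits[0].passes
        assert hits[0].conjugate_response == pytest.approx(0.1)
        assert hits[0].aglycon_response == pytest.approx(5.0)
        # 0 h negative control shows no response
        assert hits[0].conjugate_response_0h == pytest.approx(1.0)

    def test_no_response_fails(self):
        hits = score_enzyme_response(self._pairs(), _toy_assay(1.0, 1.0))
        assert not hits[0].passes

    def test_boundary_thresholds_inclusive(self):
        hits = score_enzyme_response(self._pairs(), _toy_assay(0.5, 2.0))
        assert hits[0].passes

    def test_zero_control_is_unevaluable_not_hit(self):
        assay = _toy_assay(0.1, 5.0)
        zeroed = assay.table.intensities.copy()
        zeroed.loc["conj", assay.columns("denatured_control", "18h")] = 0.0
        assay.table = assay.table.with_intensities(zeroed)
        hits = score_enzyme_response(self._pairs(), assay)
        assert not hits[0].passes and not hits[0].evaluable

    def test_arm_shift_mismatch_rejected(self):
        with pytest.raises(ValueError, match="arm"):
            score_enzyme_response(self._pairs("glucuronide"), _toy_assay(0.1, 5.0))

    def test_planted_pairs_recovered_with_few_false_hits(self):
        arms, truth = generate_enzyme_assay(
            AssayConfig(n_pairs=20, n_decoys=200, hydrolysis_fraction=0.9, seed=31))
        for arm_name, shift in (("sulfatase", ShiftClass.sulfate()),
                                ("glucuronidase", ShiftClass.glucuronide())):
            assay = arms[arm_name]
            pairs = find_mass_shift_pairs(assay.table, shift, ppm_tol=5.0)
            hits = score_enzyme_response(pairs, assay)
            found = {(h.conjugate_feature_id, h.aglycon_feature_id)
                     for h in hits if h.passes}
            tr = truth.pairs[truth.pairs.arm == arm_name]
            true_set = set(zip(tr.conjugate_feature_id, tr.aglycon_feature_id))
            assert len(found & true_set) >= 19
            assert len(found - true_set) <= 2
            # every recovered pair carries the correct shift-class label
            for h in hits:
                if h.passes and (h.conjugate_feature_id, h.aglycon_feature_id) in true_set:
                    assert h.shift == shift.name


class TestGroupIsomers:
    def test_two_coeluting_masses_summed(self):
        t = _mz_table([400.0, 400.0000001, 200.0], rts=[5.1, 6.3, 7.0], n_samples=2)
        res = group_isomers(t, mz_tol_ppm=5.0, rt_window=5.0)
        assert res.table.n_features == 2
        merged = [gid for gid, m in res.members.items() if len(m) == 2][0]
        np.testing.assert_allclose(res.table.intensities.loc[merged], [200.0, 200.0])

    def test_no_coincidences_is_identity(self, tiny_table):
        res = group_isomers(tiny_table, mz_tol_ppm=5.0)
        assert list(res.table.feature_ids) == list(tiny_table.feature_ids)
        pd.testing.assert_frame_equal(res.table.intensities, tiny_table.intensities)

    def test_hand_enumerated_groups(self):
        # one 3-member group + 2 singletons -> 3 rows
        t = _mz_table([500.0, 500.0004, 500.0008, 300.0, 410.0],
                      rts=[4.0, 4.5, 5.0, 6.0, 7.0])
        res = group_isomers(t, mz_tol_ppm=5.0, rt_window=5.0)
        assert res.table.n_features == 3
        sizes = sorted(len(m) for m in res.members.values())
        assert sizes == [1, 1, 3]

    def test_total_intensity_conserved_per_sample(self):
        rng = np.random.default_rng(3)
        mzs = np.concatenate([np.repeat(rng.uniform(100, 600, 10), 2) * (1 + 1e-7),
                              rng.uniform(100, 600, 30)])
        ids = [f"f{i}" for i in range(len(mzs))]
        inten = pd.DataFrame(rng.lognormal(8, 1, (len(mzs), 4)), index=ids,
                             columns=list("ABCD"))
        t = FeatureTable(pd.Series(mzs, index=ids),
                         pd.Series(rng.uniform(1, 18, len(mzs)), index=ids), inten)
        res = group_isomers(t, mz_tol_ppm=5.0, rt_window=20.0)
        np.testing.assert_allclose(res.table.intensities.sum(axis=0),
                                   t.intensities.sum(axis=0), rtol=1e-12)
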