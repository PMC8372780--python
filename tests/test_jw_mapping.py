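import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bagmf.constants import DEFAULT_CONSTANTS
from bagmf.jw_mapping import (
    RelaxationRecord,
    SpectralDensitySet,
    jackknife_J0_uncertainty,
    map_record_to_J,
    read_rates_csv,
    weighted_mean_J0,
)

C = DEFAULT_CONSTANTS


def rates_from_J(J0, JwN, JwH, field_MHz, const=C):
    """Independent algebraic inversion of the mapping (test-side oracle)."""
    d2 = const.d_NH**2
    c2 = const.c_NH(field_MHz) ** 2
    denom = 3.0 * d2 + 4.0 * c2
    sigma = 1.25 * d2 * JwH
    R1 = denom * JwN / 4.0 + 1.249 * sigma
    R2 = denom * J0 / 6.0 + 0.5 * R1 + 0.454 * sigma
    NOE = 1.0 + sigma * const.gamma_H / (R1 * const.gamma_N)
    return R1, R2, NOE


class TestMapRecord:
    def test_noe_of_one_gives_zero_high_frequency_J(self):
        rec = RelaxationRecord(1, 600.0, 1.5, 0.01, 10.0, 0.1, 1.0, 0.01)
        m = map_record_to_J(rec)
        assert m.JwH087 == 0.0

    @pytest.mark.parametrize("J0,JwN,JwH", [
        (6.0e-9, 2.0e-10, 4.0e-12),
        (2.0e-9, 4.0e-10, 2.0e-11),
        (4.5e-9, 1.0e-10, 1.0e-12),
    ])
    @pytest.mark.parametrize("field", [600.0, 900.0])
    def test_round_trip_recovers_J_triple(self, J0, JwN, JwH, field):
        R1, R2, NOE = rates_from_J(J0, JwN, JwH, field)
        rec = RelaxationRecord(1, field, R1, 0.01, R2, 0.1, NOE, 0.01)
        m = map_record_to_J(rec)
        assert m.J0 == pytest.approx(J0, rel=1e-10)
        assert m.JwN == pytest.approx(JwN, rel=1e-10)
        assert m.JwH087 == pytest.approx(JwH, rel=1e-10)

    def test_doubling_all_errors_doubles_J_errors(self):
        rec = RelaxationRecord(1, 700.0, 1.4, 0.02, 12.0, 0.15, 0.7, 0.02)
        rec2 = RelaxationRecord(1, 700.0, 1.4, 0.04, 12.0, 0.30, 0.7, 0.04)
        a, b = map_record_to_J(rec), map_record_to_J(rec2)
        assert b.J0_err == pytest.approx(2 * a.J0_err, rel=1e-12)
        assert b.JwN_err == pytest.approx(2 * a.JwN_err, rel=1e-12)
        assert b.JwH087_err == pytest.approx(2 * a.JwH087_err, rel=1e-12)

    @pytest.mark.parametrize("which", ["R1_err", "R2_err", "NOE_err"])
    def test_J_errors_increase_with_each_input_error(self, which):
        base = dict(residue=1, field_MHz=700.0, R1=1.4, R1_err=0.02,
                    R2=12.0, R2_err=0.15, NOE=0.7, NOE_err=0.02)
        bumped = dict(base)
        bumped[which] = base[which] * 3.0
        a = map_record_to_J(RelaxationRecord(**base))
        b = map_record_to_J(RelaxationRecord(**bumped))
        # each observable error feeds at least one J error
        grew = [
            b.J0_err > a.J0_err,
            b.JwN_err > a.JwN_err,
            b.JwH087_err > a.JwH087_err,
        ]
        assert any(grew)
        if which == "R2_err":
            assert b.J0_err > a.J0_err
            assert b.JwN_err == a.JwN_err  # R2 never enters J(wN)

    def test_rejects_nonpositive_rates_and_zero_field(self):
        with pytest.raises(ValueError):
            RelaxationRecord(1, 600.0, -1.0, 0.01, 10.0, 0.1, 0.7, 0.01)
        with pytest.raises(ValueError):
            RelaxationRecord(1, 0.0, 1.0, 0.01, 10.0, 0.1, 0.7, 0.01)


class TestWeightedMean:
    def test_identical_values(self):
        assert weighted_mean_J0([5.0, 5.0, 5.0], [0.1, 0.7, 2.0]) == 5.0

    def test_single_value(self):
        assert weighted_mean_J0([3.2], [0.5]) == 3.2

    def test_equal_weights(self):
        assert weighted_mean_J0([2.0, 4.0], [1.0, 1.0]) == pytest.approx(3.0)

    def test_zero_error_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_J0([1.0, 2.0], [0.0, 1.0])

    @given(
        st.lists(st.floats(1.0, 10.0), min_size=2, max_size=6),
        st.floats(0.1, 2.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_mean_within_value_range(self, values, err):
        m = weighted_mean_J0(values, [err] * len(values))
        assert min(values) - 1e-12 <= m <= max(values) + 1e-12


class TestJackknife:
    def test_identical_values_give_zero(self):
        assert jackknife_J0_uncertainty([4.0] * 4, [0.3, 0.5, 0.2, 0.9]) == 0.0

    def test_matches_brute_force_loop_for_equal_errors(self):
        # frozen from the delete-one loop over plain means of (0, 2, 4, 6)
        se = jackknife_J0_uncertainty([0.0, 2.0, 4.0, 6.0], [1.0] * 4)
        assert se == pytest.approx(1.2909944487358056, rel=1e-12)

    def test_brute_force_oracle_unequal_errors(self):
        vals = np.array([1.0, 2.5, 1.8, 3.1])
        errs = np.array([0.2, 0.5, 0.3, 0.9])
        G = 4
        loo = []
        for i in range(G):
            keep = [j for j in range(G) if j != i]
            w = 1.0 / errs[keep] ** 2
            loo.append(float(np.sum(w * vals[keep]) / np.sum(w)))
        mbar = sum(loo) / G
        expected = math.sqrt((G - 1) / G * sum((x - mbar) ** 2 for x in loo))
        got = jackknife_J0_uncertainty(vals, errs)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariance(self):
        vals = [1.0, 2.5, 1.8, 3.1]
        errs = [0.2, 0.5, 0.3, 0.9]
        ref = jackknife_J0_uncertainty(vals, errs)
        perm = [2, 0, 3, 1]
        got = jackknife_J0_uncertainty(
            [vals[i] for i in perm], [errs[i] for i in perm]
        )
        assert got == pytest.approx(ref, rel=1e-12)

    def test_single_field_falls_back_to_propagated_error(self):
        assert jackknife_J0_uncertainty([2.0], [0.4]) == 0.4


class TestSpectralDensitySet:
    def test_fit_vector_layout_and_frequency_ordering(self, disordered_sd_set):
        y, err, omega = disordered_sd_set.fit_arrays()
        assert len(y) == len(err) == len(omega) == 9
        assert np.all(np.diff(omega) >= 0)
        assert omega[0] == 0.0

    def test_raw_vector_has_3G_values(self, disordered_sd_set):
        assert disordered_sd_set.raw_vector().shape == (12,)

    def test_combined_error_mode_is_larger(self, disordered_params):
        from tests.conftest import make_sd_set
        from bagmf.synthetic_data import SyntheticScenario, generate_dataset
        from bagmf.jw_mapping import map_rates_table

        base = make_sd_set(disordered_params, seed=5)
        scenario_sets = map_rates_table(
            generate_dataset(
                SyntheticScenario(
                    residues=((1, disordered_params, "x"),), seed=5
                )
            ),
            j0_error_mode="combined",
        )
        assert scenario_sets[0].J0_mean_err >= base.J0_mean_err


def test_read_rates_csv_rejects_wrong_header(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("residue,field\n1,600\n")
    with pytest.raises(ValueError, match="expected header"):
        read_rates_csv(p)


def test_records_from_frame_names_bad_row(tmp_path):
    import pandas as pd
    from bagmf.jw_mapping import records_from_frame

    df = pd.DataFrame(
        [
            [1, 600.0, 1.4, 0.01, 12.0, 0.1, 0.7, 0.01],
            [1, 700.0, -1.4, 0.01, 12.0, 0.1, 0.7, 0.01],
        ],
        columns=["residue", "field_MHz", "R1", "R1_err", "R2", "R2_err",
                 "NOE", "NOE_err"],
    )
    with pytest.raises(ValueError, match="row 1"):
        records_from_frame(df)
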