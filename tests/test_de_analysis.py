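import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mitoskew import (call_de, de_table, ma_values, signed_fold_change,
                      sort_de_table, two_group_ttest)
from mitoskew.data_io import DataError

from conftest import make_normalized


class TestTwoGroupTtest:
    def test_pooled_t_against_hand_formula(self):
        # {1,2,3} vs {4,5,6}: sp^2 = 1, se = sqrt(2/3), t = -3/se, df = 4
        norm = make_normalized([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], 3, 3)
        out = two_group_ttest(norm)
        assert out.loc[0, "t_stat"] == pytest.approx(-3.6742346141747673, abs=1e-12)
        assert out.loc[0, "p_value"] == pytest.approx(0.021311641128756713, abs=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        x = rng.normal(size=(40, 12))
        norm = make_normalized(x, 6, 6)
        ours = two_group_ttest(norm)
        ref_t, ref_p = stats.ttest_ind(x[:, :6], x[:, 6:], axis=1)
        assert np.allclose(ours["t_stat"], ref_t)
        assert np.allclose(ours["p_value"], ref_p)

    def test_welch_matches_scipy(self, rng):
        x = rng.normal(size=(30, 10)) * np.array([1] * 4 + [3] * 6)
        norm = make_normalized(x, 4, 6)
        ours = two_group_ttest(norm, welch=True)
        ref_t, ref_p = stats.ttest_ind(x[:, :4], x[:, 4:], axis=1, equal_var=False)
        assert np.allclose(ours["t_stat"], ref_t)
        assert np.allclose(ours["p_value"], ref_p)

    def test_identical_groups(self):
        norm = make_normalized([[2.0] * 6], 3, 3)
        out = two_group_ttest(norm)
        assert out.loc[0, "t_stat"] == 0.0
        assert out.loc[0, "p_value"] == 1.0

    def test_degenerate_variance_warns_and_p_zero(self, caplog):
        norm = make_normalized([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]], 3, 3)
        with caplog.at_level("WARNING", logger="mitoskew"):
            out = two_group_ttest(norm)
        assert out.loc[0, "p_value"] == 0.0
        assert "zero variance" in caplog.text

    def test_group_swap_antisymmetry(self, rng):
        x = rng.normal(size=(25, 12))
        fwd = two_group_ttest(make_normalized(x, 6, 6))
        swapped = make_normalized(np.hstack([x[:, 6:], x[:, :6]]), 6, 6)
        rev = two_group_ttest(swapped)
        assert np.allclose(fwd["t_stat"], -rev["t_stat"])
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_small_group_rejected(self):
        with pytest.raises(DataError, match=">= 2"):
            two_group_ttest(make_normalized([[1.0, 2.0, 3.0]], 1, 2))


class TestSignedFoldChange:
    @pytest.mark.parametrize("m,fold", [(0.0, 1.0), (1.0, 2.0), (-1.0, -2.0)])
    def test_convention(self, m, fold):
        assert signed_fold_change(m) == pytest.approx(fold)

    def test_published_fold_round_trips(self):
        # a printed 48.16-fold up-regulation maps back through log2 exactly
        assert signed_fold_change(math.log2(48.16)) == pytest.approx(48.16)

    @given(st.floats(min_value=-20, max_value=20,
                     allow_nan=False, allow_infinity=False))
    def test_bijection_onto_signed_folds(self, m):
        fold = signed_fold_change(m)
        assert abs(fold) >= 1.0
        assert abs(fold) == pytest.approx(2.0 ** abs(m), rel=1e-12)
        assert (fold >= 1) == (m >= 0)
        # invert: recover m from the signed fold
        m_back = math.copysign(math.log2(abs(fold)), fold)
        assert m_back == pytest.approx(m, abs=1e-9)


class TestCallDe:
    def records(self, p, fold):
        return pd.DataFrame({"gene_id": ["g"], "p_value": [p], "fold_linear": [fold]})

    @pytest.mark.parametrize("p,fold,expected", [
        (0.04, 1.5, True),    # both criteria met
        (0.05, 2.0, False),   # p boundary is strict
        (0.01, 1.3, False),   # fold boundary is strict
        (0.01, -1.31, True),  # sign does not matter, magnitude does
    ])
    def test_strict_thresholds(self, p, fold, expected):
        out, n_de = call_de(self.records(p, fold))
        assert bool(out.loc[0, "is_de"]) is expected
        assert n_de == int(expected)

    def test_bh_correction_never_adds_calls(self, rng):
        frame = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)],
            "p_value": rng.uniform(size=200),
            "fold_linear": rng.choice([-3.0, 3.0], size=200),
        })
        raw, n_raw = call_de(frame)
        adj, n_adj = call_de(frame, fdr="bh")
        assert n_adj <= n_raw
        assert not (adj["is_de"] & ~raw["is_de"]).any()


class TestMaValues:
    def test_constant_gene(self):
        out = ma_values(make_normalized([[7.0] * 6], 3, 3))
        assert out.loc[0, "a_value"] == pytest.approx(7.0)
        assert out.loc[0, "m_value"] == pytest.approx(0.0)

    def test_group_means_five_and_three(self):
        out = ma_values(make_normalized([[5.0, 5.0, 5.0, 3.0, 3.0, 3.0]], 3, 3))
        assert out.loc[0, "a_value"] == pytest.approx(4.0)
        assert out.loc[0, "m_value"] == pytest.approx(2.0)

    def test_swap_negates_m_keeps_a(self, rng):
        x = rng.normal(size=(10, 8))
        fwd = ma_values(make_normalized(x, 4, 4))
        rev = ma_values(make_normalized(np.hstack([x[:, 4:], x[:, :4]]), 4, 4))
        assert np.allclose(fwd["m_value"], -rev["m_value"])
        assert np.allclose(fwd["a_value"], rev["a_value"])


def test_de_table_internally_consistent(rng):
    x = rng.normal(size=(60, 12))
    x[:10, :6] += 2.0  # plant strong effects
    records = de_table(make_normalized(x, 6, 6))
    sign_m = np.sign(records["m_value"].to_numpy())
    sign_f = np.sign(records["fold_linear"].to_numpy())
    nonzero = records["m_value"] != 0
    assert (sign_m[nonzero.to_numpy()] == sign_f[nonzero.to_numpy()]).all()
    assert np.allclose(np.abs(records["fold_linear"]),
                       2.0 ** np.abs(records["m_value"]), atol=1e-9)
    expected = (records["p_value"] < 0.05) & (records["fold_linear"].abs() > 1.3)
    assert (records["is_de"] == expected).all()
    ordered = sort_de_table(records)
    assert ordered["p_value"].is_monotonic_increasing
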