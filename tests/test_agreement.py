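"""Concordance, Bland-Altman and ICC statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sectmorph import (
    PairedMeasurements,
    agreement_stats,
    agreement_table,
    bland_altman,
    ccc,
    icc,
    mean_diff_sd,
    pearson,
)
from sectmorph.agreement import VARIANTS


# ---------------------------------------------------------------------------
# oracles, written longhand and independent of the implementation


def oracle_ccc_with_ci(x, y, level=1.959963984540054):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((xi - mx) ** 2 for xi in x) / n
    sy2 = sum((yi - my) ** 2 for yi in y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    p = 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    r = sxy / math.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    var_z = (
        (1 - r * r) * p * p / ((1 - p * p) * r * r)
        + 4 * p**3 * (1 - p) * u * u / (r * (1 - p * p) ** 2)
        - 2 * p**4 * u**4 / (r * r * (1 - p * p) ** 2)
    ) / (n - 2)
    z = 0.5 * math.log((1 + p) / (1 - p))
    h = level * math.sqrt(var_z)
    return p, math.tanh(z - h), math.tanh(z + h)


def oracle_bland_altman(x, y):
    n = len(x)
    d = [xi - yi for xi, yi in zip(x, y)]
    bias = sum(d) / n
    sd = math.sqrt(sum((di - bias) ** 2 for di in d) / (n - 1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def random_pairs(seed, n=16):
    rng = np.random.default_rng(seed)
    x = rng.normal(30, 8, size=n)
    y = 0.8 * x + rng.normal(2, 4, size=n)
    return x, y


# ---------------------------------------------------------------------------


class TestCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        est, lo, hi, deg = ccc(PairedMeasurements(x, x.copy()))
        assert est == 1.0

    def test_perfect_reversal(self):
        est = ccc(PairedMeasurements(np.array([-1.0, 0.0, 1.0]),
                                     np.array([1.0, 0.0, -1.0])))[0]
        assert est == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_formula_oracle(self, seed):
        x, y = random_pairs(seed)
        est, lo, hi, deg = ccc(PairedMeasurements(x, y))
        oe, ol, oh = oracle_ccc_with_ci(list(x), list(y))
        assert not deg
        assert abs(est - oe) < 1e-12
        assert abs(lo - ol) < 1e-12
        assert abs(hi - oh) < 1e-12

    def test_ci_brackets_the_estimate(self):
        x, y = random_pairs(123)
        est, lo, hi, _ = ccc(PairedMeasurements(x, y))
        assert lo <= est <= hi

    def test_both_series_constant_is_undefined(self):
        with pytest.raises(ValueError):
            ccc(PairedMeasurements(np.full(5, 2.0), np.full(5, 3.0)))

    def test_single_constant_series_is_zero_with_flag(self):
        est, lo, hi, deg = ccc(PairedMeasurements(np.full(5, 2.0),
                                                  np.arange(5.0)))
        assert est == 0.0 and deg and np.isnan(lo)

    def test_swap_invariance_and_lin_inequality(self):
        for seed in range(20):
            x, y = random_pairs(seed)
            a = ccc(PairedMeasurements(x, y))[0]
            b = ccc(PairedMeasurements(y, x))[0]
            assert abs(a - b) < 1e-12
            assert abs(a) <= abs(pearson(PairedMeasurements(x, y))) + 1e-12

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100),
           seed=st.integers(0, 1000))
    def test_invariant_under_common_affine_map(self, scale, shift, seed):
        x, y = random_pairs(seed)
        a = ccc(PairedMeasurements(x, y))[0]
        b = ccc(PairedMeasurements(scale * x + shift, scale * y + shift))[0]
        assert a == pytest.approx(b, abs=1e-9)

    def test_not_invariant_under_single_series_shift(self):
        x, _ = random_pairs(7)
        shifted = PairedMeasurements(x, x + 10.0)
        est = ccc(shifted)[0]
        assert pearson(shifted) == pytest.approx(1.0)
        assert est < 1.0


class TestDifferences:
    def test_identical_series(self):
        x = np.arange(5.0)
        assert mean_diff_sd(PairedMeasurements(x, x.copy())) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        x = np.array([3.0, 5.0])
        y = np.array([2.0, 2.0])
        md, sd = mean_diff_sd(PairedMeasurements(x, y))
        assert md == pytest.approx(2.0)
        assert sd == pytest.approx(math.sqrt(2))

    def test_sign_convention_antisymmetry(self):
        x, y = random_pairs(3)
        md1, sd1 = mean_diff_sd(PairedMeasurements(x, y))
        md2, sd2 = mean_diff_sd(PairedMeasurements(y, x))
        assert md1 == pytest.approx(-md2)
        assert sd1 == pytest.approx(sd2)


class TestBlandAltman:
    def test_identical_series_has_zero_limits(self):
        x = np.arange(4.0)
        ba = bland_altman(PairedMeasurements(x, x.copy()))
        assert (ba.bias, ba.sd, ba.loa_lower, ba.loa_upper) == (0, 0, 0, 0)
        assert (ba.points["diff"] == 0).all()

    def test_constant_offset(self):
        x = np.arange(5.0)
        ba = bland_altman(PairedMeasurements(x + 3.0, x))
        assert ba.bias == pytest.approx(3.0)
        assert ba.sd == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_limits_match_formula_oracle(self, seed):
        x, y = random_pairs(seed)
        ba = bland_altman(PairedMeasurements(x, y))
        ob, osd, olo, ohi = oracle_bland_altman(list(x), list(y))
        assert abs(ba.bias - ob) < 1e-12
        assert abs(ba.sd - osd) < 1e-12
        assert abs(ba.loa_lower - olo) < 1e-12
        assert abs(ba.loa_upper - ohi) < 1e-12
        assert np.allclose(ba.points["mean"], (x + y) / 2)


class TestICC:
    def test_identical_series(self):
        x = np.arange(6.0)
        assert icc(PairedMeasurements(x, x.copy())) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin_two_way_absolute_single(self, seed):
        pingouin = pytest.importorskip("pingouin")
        x, y = random_pairs(seed)
        n = len(x)
        long = pd.DataFrame({
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "score": np.concatenate([x, y]),
        })
        table = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                         ratings="score")
        expected = float(table.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert icc(PairedMeasurements(x, y)) == pytest.approx(expected, abs=1e-10)

    def test_icc_decreases_as_one_series_is_shifted(self):
        x, _ = random_pairs(11)
        vals = [icc(PairedMeasurements(x, x + c)) for c in (0.0, 5.0, 10.0, 20.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestAgreementTable:
    def _measurements(self, seed=0, identical=True):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(8):
            base = {"pct_bone": rng.uniform(20, 45), "pct_graft": rng.uniform(5, 25)}
            for variant in VARIANTS:
                jitter = 0.0 if identical else rng.normal(0, 2)
                rows.append({"specimen": s, "variant": variant,
                             "pct_bone": base["pct_bone"] + jitter,
                             "pct_graft": base["pct_graft"] + jitter})
        return pd.DataFrame(rows)

    def test_identical_variants_give_perfect_rows(self):
        table = agreement_table(self._measurements(identical=True), "bone")
        assert len(table) == 9
        assert list(table["block"]).count("vs_hm") == 5
        assert (table["ccc"] == 1.0).all()
        assert (table["mean_diff"] == 0.0).all()

    def test_row_order_matches_publication_layout(self):
        table = agreement_table(self._measurements(), "graft")
        assert list(table["comparison"]) == [
            "original", "offset+4", "offset-4", "rotation+10", "rotation-10",
            "offset+4", "offset-4", "rotation+10", "rotation-10",
        ]

    def test_missing_variant_names_specimen_and_variant(self):
        m = self._measurements()
        m = m[~((m.specimen == 3) & (m.variant == "offset-4"))]
        with pytest.raises(ValueError, match="3.*offset-4"):
            agreement_table(m, "bone")

    def test_table_is_invariant_to_specimen_row_order(self):
        m = self._measurements(seed=4, identical=False)
        shuffled = m.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = agreement_table(m, "bone")
        b = agreement_table(shuffled, "bone")
        pd.testing.assert_frame_equal(a, b)
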