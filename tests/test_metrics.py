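import datetime as dt
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import mobiflux as mf
from mobiflux.errors import AlignmentError, ValidationError

D0 = dt.date(2020, 3, 5)
D1 = dt.date(2020, 3, 16)


# --- independent literal oracles ------------------------------------------


def cpc_oracle(g, r):
    """Literal Sorensen-Dice over commuters, term by term."""
    num = sum(min(gi, ri) for gi, ri in zip(g, r))
    den = sum(g) + sum(r)
    return 2 * num / den if den else float("nan")


def ig_oracle(r, g, floor=1e-10):
    n = sum(r)
    total = 0.0
    for ri, gi in zip(r, g):
        if ri > 0:
            total += (ri / n) * math.log(ri / max(gi, floor))
    return total


def accuracy_oracle(g, r):
    """Fraction of correctly allocated unit trips, via multiset matching."""
    trips_g = Counter({i: int(v) for i, v in enumerate(g)})
    trips_r = Counter({i: int(v) for i, v in enumerate(r)})
    matched = sum((trips_g & trips_r).values())
    return matched / sum(trips_r.values())


flow_vectors = arrays(
    np.float64, st.integers(2, 12), elements=st.floats(0, 1e6, allow_nan=False)
)


class TestCPC:
    @pytest.mark.parametrize(
        "g, r, expected",
        [
            ((4, 6), (4, 6), 1.0),
            ((3, 1), (2, 2), 0.75),
            ((5, 0), (0, 5), 0.0),
        ],
    )
    def test_point_values(self, g, r, expected):
        assert mf.cpc(g, r) == pytest.approx(expected, abs=1e-15)

    def test_undefined_on_double_zero(self):
        assert math.isnan(mf.cpc([0, 0], [0, 0]))

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            mf.cpc([1, 2], [1, 2, 3])

    @given(g=flow_vectors, data=st.data())
    def test_symmetry_and_scale_invariance(self, g, data):
        r = data.draw(arrays(np.float64, len(g), elements=st.floats(0, 1e6, allow_nan=False)))
        c = data.draw(st.floats(1e-3, 1e3))
        v = mf.cpc(g, r)
        if math.isnan(v):
            return
        assert mf.cpc(r, g) == pytest.approx(v, abs=1e-12)
        assert mf.cpc(c * g, c * r) == pytest.approx(v, abs=1e-9)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(2, 30)
            g, r = rng.uniform(0, 1e4, n), rng.uniform(0, 1e4, n)
            assert mf.cpc(g, r) == pytest.approx(cpc_oracle(g, r), abs=1e-12)

    def test_equals_accuracy_when_totals_match(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(2, 15))
            total = int(rng.integers(n, 500))
            g = rng.multinomial(total, np.ones(n) / n)
            r = rng.multinomial(total, rng.dirichlet(np.ones(n)))
            assert mf.cpc(g, r) == pytest.approx(accuracy_oracle(g, r), abs=1e-12)


class TestInformationGain:
    @pytest.mark.parametrize(
        "r, g, expected",
        [
            ((2, 2), (2, 2), 0.0),
            ((2, 2), (1, 3), 0.5 * math.log(2) + 0.5 * math.log(2 / 3)),  # ~0.1438
            ((0, 4), (1, 3), math.log(4 / 3)),  # ~0.2877, with 0*log(0)=0
        ],
    )
    def test_point_values(self, r, g, expected):
        ig, floored = mf.information_gain(r, g)
        assert ig == pytest.approx(expected, abs=1e-12)
        assert floored == 0

    def test_zero_generated_entries_are_floored_and_counted(self):
        ig, floored = mf.information_gain([5, 5], [0, 10], floor=1e-10)
        assert floored == 1
        assert ig == pytest.approx(0.5 * math.log(5 / 1e-10) + 0.5 * math.log(0.5), rel=1e-9)

    def test_undefined_on_zero_observed_total(self):
        ig, _ = mf.information_gain([0, 0], [1, 1])
        assert math.isnan(ig)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(2, 30)
            r, g = rng.uniform(0, 1e4, n), rng.uniform(1e-3, 1e4, n)
            assert mf.information_gain(r, g)[0] == pytest.approx(ig_oracle(r, g), abs=1e-12)

    def test_nonnegative_with_equal_totals_zero_iff_equal(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(2, 10))
            r = rng.multinomial(200, rng.dirichlet(np.ones(n))).astype(float)
            g = rng.multinomial(200, rng.dirichlet(np.ones(n))).astype(float)
            ig, _ = mf.information_gain(r, np.maximum(g, 1e-12))
            assert ig >= -1e-12  # Gibbs' inequality regime
            assert mf.information_gain(r, r)[0] == pytest.approx(0.0, abs=1e-15)


class TestRelativeImprovement:
    def test_point_values(self):
        assert mf.relative_improvement(0.7, 0.7) == 0.0
        assert mf.relative_improvement(0.78, 0.348) == pytest.approx(1.2414, abs=1e-4)
        assert mf.relative_improvement(0.5, 1.0) == -0.5
        assert math.isnan(mf.relative_improvement(1.0, 0.0))


class TestEvaluate:
    def _obs(self):
        rows = [
            {"date": d, "origin": c, "destination": "UK", "flow": f}
            for d in (D0, D1)
            for c, f in (("FR", 10), ("IT", 30))
        ]
        return mf.FlowPanel(pd.DataFrame(rows), star_hub="UK")

    def test_perfect_prediction_summary(self):
        obs = self._obs()
        result = mf.evaluate({"perfect": obs.df.astype({"flow": float})}, obs)
        row = result.summary.iloc[0]
        assert row["mu_cpc"] == row["max_cpc"] == row["min_cpc"] == 1.0
        assert row["mu_ig"] == pytest.approx(0.0, abs=1e-12)

    def test_period_split_means(self):
        obs = self._obs()
        pred = obs.df.astype({"flow": float}).copy()
        # day 1 imperfect (CPC 0.75), day 2 perfect
        pred.loc[(pred["date"] == D0), "flow"] = [20.0, 20.0]
        result = mf.evaluate({"m": pred}, obs, p1_end=dt.date(2020, 3, 15))
        row = result.summary.iloc[0]
        assert row["mu_cpc_p1"] == pytest.approx(0.75)
        assert row["mu_cpc_p2"] == pytest.approx(1.0)
        assert row["mu_cpc"] == pytest.approx((0.75 + 1.0) / 2)

    def test_missing_day_is_an_error(self):
        obs = self._obs()
        pred = obs.df[obs.df["date"] == D0].astype({"flow": float})
        with pytest.raises(AlignmentError, match="2020-03-16"):
            mf.evaluate({"m": pred}, obs)

    def test_extra_pair_is_an_error(self):
        obs = self._obs()
        pred = pd.concat(
            [
                obs.df.astype({"flow": float}),
                pd.DataFrame([{"date": D0, "origin": "ES", "destination": "UK", "flow": 1.0}]),
            ]
        )
        with pytest.raises(ValidationError, match="ES"):
            mf.evaluate({"m": pred}, obs)

    def test_mean_relative_improvement_average_of_ratios(self):
        daily = pd.DataFrame(
            {
                "model": ["a", "a", "b", "b"],
                "date": [D0, D1, D0, D1],
                "cpc": [0.6, 0.9, 0.5, 0.6],
            }
        )
        expected = ((0.6 - 0.5) / 0.5 + (0.9 - 0.6) / 0.6) / 2
        assert mf.mean_relative_improvement(daily, "a", "b") == pytest.approx(expected)
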