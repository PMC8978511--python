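import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

import mobiflux as mf
from mobiflux.cgm import CGMDesign, CGMParams, delta_z_scores
from mobiflux.errors import MissingCovariateError, SingularDesignError

D0 = dt.date(2020, 3, 5)


def manual_design(rows, kind="power"):
    df = pd.DataFrame(rows)
    for col, default in (("date", D0), ("origin", "A"), ("destination", "B"), ("flow", 1)):
        if col not in df:
            df[col] = default
    return CGMDesign(df=df, kind=kind)


def manual_params(kind="power", **coef):
    base = dict(epsilon=0.0, alpha=0.0, beta=0.0, gamma=0.0, delta1=0.0, delta2=0.0)
    base.update(coef)
    return CGMParams(
        kind=kind,
        **base,
        dispersion=5.0,
        standard_errors={},
        log_likelihood=0.0,
        converged=True,
        n_obs=1,
    )


class TestBuildDesign:
    def test_one_row_per_flow_record(self, tiny_flows, tiny_locations, tiny_stringency):
        design = mf.build_design(tiny_flows, tiny_locations, tiny_stringency, "power")
        assert len(design) == len(tiny_flows)
        assert design.df["log_pop_origin"].iloc[0] == pytest.approx(
            math.log(tiny_locations.population(design.df["origin"].iloc[0]))
        )

    def test_distance_covariate_by_kind(self, tiny_flows, tiny_locations, tiny_stringency):
        dm = mf.distance_matrix(tiny_locations)
        pow_design = mf.build_design(tiny_flows, tiny_locations, tiny_stringency, "power", distances=dm)
        exp_design = mf.build_design(tiny_flows, tiny_locations, tiny_stringency, "exponential", distances=dm)
        np.testing.assert_allclose(
            np.exp(pow_design.df["distance_covariate"]), exp_design.df["distance_covariate"]
        )

    def test_missing_stringency_names_offender(self, tiny_flows, tiny_locations, tiny_stringency):
        truncated = mf.StringencyPanel(tiny_stringency.df[tiny_stringency.df["date"] > D0])
        with pytest.raises(MissingCovariateError, match="2020-03-05"):
            mf.build_design(tiny_flows, tiny_locations, truncated, "power")


class TestPredict:
    def test_log_linear_closed_form(self):
        # eps=0, alpha=beta=1, gamma=-1, log P_i = log P_j = 1, log r = 1 -> e
        design = manual_design(
            [dict(log_pop_origin=1.0, log_pop_dest=1.0, distance_covariate=1.0, si_origin=0.0, si_dest=0.0)]
        )
        params = manual_params(alpha=1.0, beta=1.0, gamma=-1.0)
        pred = mf.cgm_predict(params, design)
        assert pred["flow"].iloc[0] == pytest.approx(math.e, rel=1e-12)

    def test_stringency_multiplier(self):
        rows = [
            dict(log_pop_origin=2.0, log_pop_dest=2.0, distance_covariate=1.0, si_origin=0.0, si_dest=si)
            for si in (0.0, 10.0)
        ]
        params = manual_params(alpha=0.5, beta=0.5, gamma=-1.0, delta2=-0.03)
        pred = mf.cgm_predict(params, manual_design(rows))
        # +10 SI points at delta2 = -0.03 multiplies the mean by e^-0.3
        assert pred["flow"].iloc[1] / pred["flow"].iloc[0] == pytest.approx(math.exp(-0.3), rel=1e-12)

    def test_kind_mismatch_rejected(self):
        design = manual_design([dict(log_pop_origin=1, log_pop_dest=1, distance_covariate=1, si_origin=0, si_dest=0)])
        with pytest.raises(mf.errors.ConfigurationError):
            mf.cgm_predict(manual_params(kind="exponential"), design)

    def test_reduces_to_power_gravity_without_stringency(self, small_world):
        """delta1 = delta2 = 0 makes the CGM surface a power-law gravity surface."""
        truth = mf.CGMTruth(alpha=1.0, beta=1.0, gamma=-1.5, delta1=0.0, delta2=0.0)
        sim = mf.simulate_flows(small_world, truth, seed=0, direction="incoming")
        eps = sim.truth["epsilon"]
        from mobiflux.gravity import DeterrenceSpec, GravityFit

        gfit = GravityFit(spec=DeterrenceSpec("power", 1.5), scale=math.exp(eps), residual_norm=0, n_obs=0)
        day = sim.means[sim.means["date"] == small_world.config.start]
        gpred = mf.gravity_predict(
            small_world.locations,
            list(zip(day["origin"], day["destination"])),
            gfit,
            distances=small_world.distances,
        )
        np.testing.assert_allclose(day["flow"].to_numpy(), gpred["flow"].to_numpy(), rtol=1e-10)


class TestFit:
    def test_duplicated_covariate_is_singular(self, tiny_flows, tiny_locations, tiny_stringency):
        design = mf.build_design(tiny_flows, tiny_locations, tiny_stringency, "power")
        design.df["si_dest"] = design.df["si_origin"]
        with pytest.raises(SingularDesignError):
            mf.cgm_fit(design)

    def test_constant_covariate_raises_unless_absorbed(self, small_world):
        sim = mf.simulate_flows(small_world, mf.CGMTruth(), seed=2, direction="incoming")
        design = mf.build_design(
            sim.panel, small_world.locations, small_world.stringency, "power", distances=small_world.distances
        )
        with pytest.raises(SingularDesignError):  # hub-side mass is constant
            mf.cgm_fit(design)
        params = mf.cgm_fit(design, absorb_constant=True)
        assert params.absorbed == ["log_pop_dest"]
        assert math.isnan(params.beta)
        assert params.alpha == pytest.approx(0.8, rel=0.15)

    def test_too_few_observations(self):
        design = manual_design(
            [dict(log_pop_origin=1, log_pop_dest=1, distance_covariate=1, si_origin=0, si_dest=0)]
        )
        with pytest.raises(SingularDesignError):
            mf.cgm_fit(design)

    def test_recovers_truth_on_pooled_panel(self, small_world):
        sim = mf.simulate_flows(
            small_world, mf.CGMTruth(), noise=mf.NoiseSpec("negative_binomial", 5.0), seed=5, direction="both"
        )
        design = mf.build_design(
            sim.panel, small_world.locations, small_world.stringency, "power", distances=small_world.distances
        )
        params = mf.cgm_fit(design)
        assert params.converged
        truth = sim.truth
        for name in ("alpha", "beta", "gamma"):
            assert params.coefficients()[name] == pytest.approx(truth[name], rel=0.10)
        for name in ("delta1", "delta2"):
            assert params.coefficients()[name] == pytest.approx(truth[name], abs=0.005)
        assert params.dispersion == pytest.approx(5.0, rel=0.35)

    def test_loglikelihood_trace_is_monotone(self, small_world):
        sim = mf.simulate_flows(small_world, mf.CGMTruth(), seed=6, direction="both")
        design = mf.build_design(
            sim.panel, small_world.locations, small_world.stringency, "power", distances=small_world.distances
        )
        params = mf.cgm_fit(design)
        trace = np.array(params.loglike_trace)
        assert len(trace) > 1
        assert np.all(np.diff(trace) > -1e-6 * np.abs(trace[:-1]))

    def test_poisson_limit_matches_poisson_regression(self, small_world):
        """With Poisson noise the NB fit collapses to the Poisson fit."""
        import statsmodels.api as sm

        sim = mf.simulate_flows(
            small_world, mf.CGMTruth(), noise=mf.NoiseSpec("poisson"), seed=7, direction="both"
        )
        design = mf.build_design(
            sim.panel, small_world.locations, small_world.stringency, "power", distances=small_world.distances
        )
        params = mf.cgm_fit(design)
        pois = sm.Poisson(design.endog(), design.exog()).fit(disp=0)
        nb_coefs = [params.epsilon, params.alpha, params.beta, params.gamma, params.delta1, params.delta2]
        np.testing.assert_allclose(nb_coefs, pois.params, rtol=0.01)
        assert params.dispersion > 50  # variance ~ mean

    def test_delta_z_scores_flag_real_effects(self, small_world):
        sim = mf.simulate_flows(small_world, mf.CGMTruth(), seed=8, direction="both")
        design = mf.build_design(
            sim.panel, small_world.locations, small_world.stringency, "power", distances=small_world.distances
        )
        z = delta_z_scores(mf.cgm_fit(design))
        assert z["delta1"] < -2 and z["delta2"] < -2
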