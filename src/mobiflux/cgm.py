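"""COVID Gravity Model: negative-binomial spatial-interaction regression.

The model extends the gravity model with government-response covariates.
The mean daily flow from i to j is

    mu_ij = exp(eps + alpha*log(P_i) + beta*log(P_j)
                + gamma*x(r_ij) + delta1*SI_i + delta2*SI_j)

where P are populations, SI are daily stringency indices on the 0-100 scale,
and the distance covariate x(r) is log(r) for a power-law decay family or r
itself for an exponential decay family, with gamma absorbing the decay rate.
Counts are modeled as negative binomial (NB2): Var = mu + mu^2 / kappa with
dispersion kappa > 0.  Coefficients and dispersion are estimated jointly by
maximum likelihood (statsmodels' NB2 likelihood).

With delta1 = delta2 = 0 and the power-law distance covariate the mean
surface reduces exactly to an unconstrained gravity model with scale
K = exp(eps), free mass exponents alpha, beta and distance exponent -gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import DistanceMatrix, FlowPanel, LocationTable, StringencyPanel, distance_matrix
from .errors import (
    ConfigurationError,
    FitConvergenceError,
    MissingCovariateError,
    SingularDesignError,
)
from .gravity import canonical_kind

#: covariate column order of a CGM design (after the intercept)
COVARIATES = ["log_pop_origin", "log_pop_dest", "distance_covariate", "si_origin", "si_dest"]

#: model parameter name for each covariate column
PARAM_NAMES = {
    "log_pop_origin": "alpha",
    "log_pop_dest": "beta",
    "distance_covariate": "gamma",
    "si_origin": "delta1",
    "si_dest": "delta2",
}


@dataclass
class CGMDesign:
    """Per-observation regression design: one row per (date, origin, destination)."""

    df: pd.DataFrame  # date, origin, destination, flow + COVARIATES
    kind: str  # deterrence family the distance covariate encodes

    def __len__(self) -> int:
        return len(self.df)

    def exog(self) -> np.ndarray:
        return np.column_stack([np.ones(len(self.df))] + [self.df[c].to_numpy(dtype=float) for c in COVARIATES])

    def endog(self) -> np.ndarray:
        return self.df["flow"].to_numpy(dtype=float)


@dataclass
class CGMParams:
    """Fitted CGM coefficients, NB dispersion and diagnostics.

    ``dispersion`` is kappa in Var = mu + mu^2/kappa (the reciprocal of the
    NB2 alpha).  Coefficients of structurally constant covariates that were
    absorbed into the intercept are NaN and listed in ``absorbed``.
    """

    kind: str
    epsilon: float
    alpha: float
    beta: float
    gamma: float
    delta1: float
    delta2: float
    dispersion: float
    standard_errors: dict[str, float]
    log_likelihood: float
    converged: bool
    n_obs: int
    absorbed: list[str] = field(default_factory=list)
    absorbed_values: dict[str, float] = field(default_factory=dict)
    loglike_trace: list[float] = field(default_factory=list)

    def coefficients(self) -> dict[str, float]:
        return {
            "epsilon": self.epsilon,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "delta1": self.delta1,
            "delta2": self.delta2,
        }

    def to_dict(self) -> dict:
        out = dict(self.coefficients())
        out.update(
            kind=self.kind,
            dispersion=self.dispersion,
            standard_errors=self.standard_errors,
            log_likelihood=self.log_likelihood,
            converged=self.converged,
            n_obs=self.n_obs,
            absorbed=self.absorbed,
        )
        return out


def build_design(
    flow_panel: FlowPanel | pd.DataFrame,
    locations: LocationTable,
    stringency_panel: StringencyPanel,
    deterrence_kind: str = "power",
    distances: DistanceMatrix | None = None,
) -> CGMDesign:
    """Assemble the regression design from the three study tables.

    Every (date, origin) and (date, destination) in the flow panel must have
    a stringency value; offenders are reported in a MissingCovariateError.
    A bare ``date, origin, destination, flow`` frame (e.g. a noiseless mean
    surface) is accepted in place of a validated panel.
    """
    kind = canonical_kind(deterrence_kind)
    if distances is None:
        distances = distance_matrix(locations)
    df = (flow_panel.df if isinstance(flow_panel, FlowPanel) else flow_panel).copy()
    pops = locations.populations
    for side in ("origin", "destination"):
        unknown = set(df[side]) - set(locations.ids)
        if unknown:
            raise MissingCovariateError(f"locations absent from table: {sorted(unknown)}")
    df["log_pop_origin"] = np.log(pops.reindex(df["origin"]).to_numpy(dtype=float))
    df["log_pop_dest"] = np.log(pops.reindex(df["destination"]).to_numpy(dtype=float))
    r = np.array([distances[o, d] for o, d in zip(df["origin"], df["destination"])])
    df["distance_covariate"] = np.log(r) if kind == "power" else r

    si = stringency_panel.lookup()
    for side, col in (("origin", "si_origin"), ("destination", "si_dest")):
        keys = pd.MultiIndex.from_arrays([df["date"], df[side]])
        vals = si.reindex(keys)
        if vals.isna().any():
            missing = sorted({(d.isoformat(), l) for (d, l), v in zip(keys, vals) if pd.isna(v)})
            raise MissingCovariateError(
                f"no stringency value for {len(missing)} (date, location) pair(s), "
                f"e.g. {missing[:5]}"
            )
        df[col] = vals.to_numpy(dtype=float)
    cols = ["date", "origin", "destination", "flow"] + COVARIATES
    return CGMDesign(df=df[cols].reset_index(drop=True), kind=kind)


def cgm_fit(design: CGMDesign, absorb_constant: bool = False, maxiter: int = 500) -> CGMParams:
    """Maximum-likelihood NB2 fit of the CGM on a pooled design.

    A covariate that is constant across all observations is collinear with
    the intercept.  By default this raises SingularDesignError; with
    ``absorb_constant=True`` such columns (a structural feature of
    one-direction egocentric panels, where the hub-side mass never varies)
    are folded into the intercept and their coefficients reported as NaN.
    Deterministic given the data.
    """
    df = design.df
    n = len(df)
    if n < 7:
        raise SingularDesignError(f"need >= 7 observations (6 coefficients + dispersion), got {n}")

    active = list(COVARIATES)
    absorbed: list[str] = []
    absorbed_values: dict[str, float] = {}
    for col in COVARIATES:
        x = df[col].to_numpy(dtype=float)
        if np.ptp(x) < 1e-12 * max(1.0, np.abs(x).max()):
            if not absorb_constant:
                raise SingularDesignError(
                    f"covariate {col!r} is constant and collinear with the intercept"
                )
            active.remove(col)
            absorbed.append(col)
            absorbed_values[col] = float(x[0])

    X = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float) for c in active])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient (collinear covariates)")
    y = df["flow"].to_numpy(dtype=float)

    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    trace: list[float] = []

    def _cb(params):
        trace.append(float(model.loglike(params)))

    # Poisson warm start keeps the NB optimizer in a sane region
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        # convergence is tracked via our own flag and a Newton polish below;
        # "perfect separation" fires spuriously on noiseless oracle data
        _warnings.simplefilter("ignore", ConvergenceWarning)
        _warnings.simplefilter("ignore", PerfectSeparationWarning)
        _warnings.simplefilter("ignore", RuntimeWarning)
        start = np.append(sm.Poisson(y, X).fit(disp=0, maxiter=200).params, 0.1)
        res = model.fit(start_params=start, method="bfgs", maxiter=maxiter, disp=0, callback=_cb)
        # Newton polish for unconverged fits — except at the Poisson boundary
        # (alpha -> 0), where the NB Hessian's polygamma terms blow up
        if not res.mle_retvals.get("converged", False) and res.params[-1] > 1e-4:
            res = model.fit(start_params=res.params, method="newton", maxiter=100, disp=0)
    if np.any(~np.isfinite(res.params)):
        raise FitConvergenceError("NB fit produced non-finite parameters", status=res.mle_retvals)

    coef = dict(zip(["epsilon"] + [PARAM_NAMES[c] for c in active], map(float, res.params[: 1 + len(active)])))
    se = dict(zip(["epsilon"] + [PARAM_NAMES[c] for c in active], map(float, res.bse[: 1 + len(active)])))
    for col in absorbed:
        coef[PARAM_NAMES[col]] = float("nan")
        se[PARAM_NAMES[col]] = float("nan")
    nb_alpha = float(res.params[-1])
    se["dispersion"] = float(res.bse[-1]) / max(nb_alpha, 1e-300) ** 2  # delta method for 1/alpha

    return CGMParams(
        kind=design.kind,
        epsilon=coef["epsilon"],
        alpha=coef["alpha"],
        beta=coef["beta"],
        gamma=coef["gamma"],
        delta1=coef["delta1"],
        delta2=coef["delta2"],
        dispersion=1.0 / nb_alpha if nb_alpha > 0 else float("inf"),
        standard_errors=se,
        log_likelihood=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_obs=n,
        absorbed=absorbed,
        absorbed_values=absorbed_values,
        loglike_trace=trace,
    )


def cgm_predict(params: CGMParams, design: CGMDesign) -> pd.DataFrame:
    """Mean flows exp(X @ coef) for every design row (strictly positive).

    Returns a dated DataFrame ``date, origin, destination, flow``.  The
    design's distance-covariate family must match the fitted one, and any
    covariate absorbed at fit time must hold the same constant value here.
    """
    if design.kind != params.kind:
        raise ConfigurationError(
            f"design encodes a {design.kind!r} distance covariate but params were "
            f"fitted with {params.kind!r}"
        )
    df = design.df
    eta = np.full(len(df), params.epsilon)
    for col in COVARIATES:
        c = getattr(params, PARAM_NAMES[col])
        x = df[col].to_numpy(dtype=float)
        if col in params.absorbed:
            v0 = params.absorbed_values[col]
            if not np.allclose(x, v0, rtol=1e-9, atol=1e-9):
                raise ConfigurationError(
                    f"covariate {col!r} was absorbed at value {v0} but varies in the "
                    "prediction design"
                )
            continue  # its contribution lives in the intercept
        eta += c * x
    out = df[["date", "origin", "destination"]].copy()
    out["flow"] = np.exp(eta)
    return out


def delta_z_scores(params: CGMParams) -> dict[str, float]:
    """Wald z statistics for the two stringency coefficients."""
    return {
        name: params.coefficients()[name] / params.standard_errors[name]
        for name in ("delta1", "delta2")
        if np.isfinite(params.standard_errors.get(name, float("nan")))
        and params.standard_errors[name] > 0
    }
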