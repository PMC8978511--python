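"""Gravity-model flow prediction and parameter fitting.

The gravity model states that the flow between locations i and j scales with
their population masses and decays with distance:

    T_ij = K * m_i * m_j * f(r_ij)

with a deterrence (friction) kernel f that is either exponential,
f(r) = exp(-beta * r), or power-law, f(r) = r ** (-beta).  K and beta are
found by nonlinear least squares on the raw observed flows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .data_model import DistanceMatrix, FlowPanel, LocationTable, distance_matrix
from .errors import DegenerateDataError, FitConvergenceError, FlatResidualWarning

DeterrenceKind = Literal["exponential", "power"]

_KIND_ALIASES = {
    "exp": "exponential",
    "exponential": "exponential",
    "pow": "power",
    "power": "power",
}


def canonical_kind(kind: str) -> DeterrenceKind:
    try:
        return _KIND_ALIASES[kind]
    except KeyError:
        raise ValueError(f"unknown deterrence kind {kind!r}; use 'exponential' or 'power'") from None


@dataclass(frozen=True)
class DeterrenceSpec:
    """Distance-decay kernel: exponential exp(-beta*r) or power r**(-beta).

    For the exponential kind beta has units 1/km; for the power kind it is a
    dimensionless exponent.
    """

    kind: DeterrenceKind
    beta: float

    def __post_init__(self):
        object.__setattr__(self, "kind", canonical_kind(self.kind))
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


def deterrence(r, spec: DeterrenceSpec):
    """Evaluate the deterrence kernel at distance(s) *r* in km."""
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("distances must be non-negative")
    if spec.kind == "exponential":
        out = np.exp(-spec.beta * r)
    else:
        if (r == 0).any():
            raise ZeroDivisionError("power deterrence is singular at r = 0")
        out = r ** (-spec.beta)
    return float(out) if out.ndim == 0 else out


@dataclass
class GravityFit:
    """Fitted gravity parameters: the scale K of the proportionality and the
    deterrence spec, plus least-squares diagnostics."""

    spec: DeterrenceSpec
    scale: float
    residual_norm: float
    n_obs: int
    converged: bool = True
    beta_at_bound: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "kind": self.spec.kind,
            "beta": self.spec.beta,
            "scale": self.scale,
            "residual_norm": self.residual_norm,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


def gravity_predict(
    locations: LocationTable,
    pairs: Sequence[tuple[str, str]],
    fit: GravityFit,
    distances: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Deterministic mean flows K*m_i*m_j*f(r_ij) for the requested pairs.

    Returns a DataFrame ``origin, destination, flow`` with float flows (these
    are model means, not sampled counts).
    """
    if distances is None:
        distances = distance_matrix(locations)
    origins = [o for o, _ in pairs]
    dests = [d for _, d in pairs]
    m_i = np.array([locations.population(o) for o in origins], dtype=float)
    m_j = np.array([locations.population(d) for d in dests], dtype=float)
    r = np.array([distances[o, d] for o, d in pairs], dtype=float)
    flow = fit.scale * m_i * m_j * deterrence(r, fit.spec)
    return pd.DataFrame({"origin": origins, "destination": dests, "flow": flow})


def _design_arrays(panel, locations: LocationTable, distances: DistanceMatrix):
    # accepts a FlowPanel or a bare origin/destination/flow frame (e.g. a
    # noiseless mean surface, which need not be integer-valued)
    df = panel.df if isinstance(panel, FlowPanel) else panel
    m_i = locations.populations.reindex(df["origin"]).to_numpy(dtype=float)
    m_j = locations.populations.reindex(df["destination"]).to_numpy(dtype=float)
    r = np.array([distances[o, d] for o, d in zip(df["origin"], df["destination"])])
    y = df["flow"].to_numpy(dtype=float)
    return m_i * m_j, r, y


def gravity_fit(
    panel: FlowPanel | pd.DataFrame,
    locations: LocationTable,
    kind: str = "exponential",
    distances: DistanceMatrix | None = None,
) -> GravityFit:
    """Fit (K, beta) by nonlinear least squares on raw flows.

    Initialisation is scale-aware: beta0 = 1/median(r) (exponential) or 1
    (power), and K0 solves the total-flow balance at beta0, which keeps the
    optimizer away from overflow regardless of the mass units.  beta is
    bounded below at 0.  Deterministic given the data.
    """
    kind = canonical_kind(kind)
    if distances is None:
        distances = distance_matrix(locations)
    mm, r, y = _design_arrays(panel, locations, distances)
    if len(y) < 3:
        raise DegenerateDataError(f"need >= 3 observations to fit, got {len(y)}")
    if (r <= 0).any():
        raise DegenerateDataError("all pair distances must be positive for fitting")
    if not (y > 0).any():
        raise DegenerateDataError("all observed flows are zero; gravity fit undefined")

    beta0 = 1.0 / float(np.median(r)) if kind == "exponential" else 1.0
    spec0 = DeterrenceSpec(kind, beta0)

    def base(beta):
        return mm * deterrence(r, DeterrenceSpec(kind, beta))

    k0 = float(y.sum() / base(beta0).sum())

    if np.ptp(r) < 1e-9 * max(np.median(r), 1.0):
        # all distances equal: f(r) is one scalar, beta cannot move the fit
        warnings.warn(
            "all pair distances are (numerically) equal; beta is unidentifiable "
            "and is reported at its starting value",
            FlatResidualWarning,
        )
        resid = y - k0 * base(beta0)
        return GravityFit(
            spec=spec0,
            scale=k0,
            residual_norm=float(resid @ resid),
            n_obs=len(y),
            converged=True,
            message="flat residual in beta",
        )

    def model(_x, amp, beta):
        return amp * k0 * base(beta)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            popt, _pcov = curve_fit(
                model,
                np.zeros_like(y),
                y,
                p0=[1.0, beta0],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
    except RuntimeError as exc:
        raise FitConvergenceError(f"gravity fit did not converge: {exc}", status=str(exc)) from exc

    amp, beta = float(popt[0]), float(popt[1])
    resid = y - model(None, amp, beta)
    fit = GravityFit(
        spec=DeterrenceSpec(kind, beta),
        scale=amp * k0,
        residual_norm=float(resid @ resid),
        n_obs=len(y),
        converged=True,
        beta_at_bound=bool(beta <= 1e-12),
    )
    if fit.beta_at_bound:
        fit.message = "beta hit the lower bound 0 (constant deterrence)"
    return fit


def gravity_fit_per_day(
    panel: FlowPanel,
    locations: LocationTable,
    kind: str = "exponential",
    distances: DistanceMatrix | None = None,
) -> dict:
    """One independent (K, beta) fit per calendar day in the panel.

    Returns {date: GravityFit}.  This is the default descriptive protocol:
    each day's star flows are fitted in-sample; the alternative is a single
    global fit over the pooled panel (``gravity_fit`` on the full panel).
    """
    if distances is None:
        distances = distance_matrix(locations)
    fits = {}
    for date, day_df in panel.df.groupby("date"):
        day_panel = FlowPanel(day_df, direction=panel.direction, star_hub=panel.star_hub)
        fits[date] = gravity_fit(day_panel, locations, kind, distances=distances)
    return fits
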