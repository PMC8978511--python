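"""Parameter-free radiation-model flow generation.

The radiation model predicts the flow from i to j from the two populations
and the intervening population s_ij — the total population living closer to
the origin than the destination (excluding both endpoints):

    p_ij = m_i * m_j / ((m_i + s_ij) * (m_i + m_j + s_ij))        (standard)

A variant replaces the first factor's denominator term with (m_j + s_ij)
("as_printed"); the two coincide whenever m_i = m_j.  There is nothing to
calibrate: given populations and geometry, scores are fully determined.
Absolute flows require an origin total O_i to distribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .data_model import DistanceMatrix, LocationTable, distance_matrix
from .errors import DegenerateDataError, SelfLoopError

FirstFactor = Literal["standard", "as_printed"]
RadiusRule = Literal["strict", "inclusive"]
Normalize = Literal["origin_outflow", "none"]


@dataclass(frozen=True)
class RadiationConfig:
    """Options for the radiation formula.

    first_factor
        "standard" uses (m_i + s_ij) in the first denominator factor (the
        canonical form); "as_printed" uses (m_j + s_ij).
    radius_rule
        whether a location at exactly r_ij from the origin counts as
        intervening ("inclusive") or not ("strict").
    normalize
        "origin_outflow" rescales scores so each origin's flows sum to a
        supplied total O_i; "none" returns raw scores.
    finite_size_correction
        with normalization, divide by (1 - m_i / M) instead of the raw score
        sum, M being the total population — the usual correction for systems
        with finitely many destinations.
    """

    first_factor: FirstFactor = "standard"
    radius_rule: RadiusRule = "strict"
    normalize: Normalize = "origin_outflow"
    finite_size_correction: bool = False

    def __post_init__(self):
        if self.first_factor not in ("standard", "as_printed"):
            raise ValueError(f"unknown first_factor {self.first_factor!r}")
        if self.radius_rule not in ("strict", "inclusive"):
            raise ValueError(f"unknown radius_rule {self.radius_rule!r}")
        if self.normalize not in ("origin_outflow", "none"):
            raise ValueError(f"unknown normalize {self.normalize!r}")
        if self.finite_size_correction and self.normalize != "origin_outflow":
            raise ValueError("finite_size_correction requires normalize='origin_outflow'")


def intervening_population(
    origin: str,
    dest: str,
    locations: LocationTable,
    distances: DistanceMatrix | None = None,
    radius_rule: RadiusRule = "strict",
) -> float:
    """Total population inside the circle of radius r_ij around the origin,
    excluding origin and destination."""
    if origin == dest:
        raise SelfLoopError("intervening population undefined for origin == destination")
    if distances is None:
        distances = distance_matrix(locations)
    d_row = distances.row(origin)
    r_ij = distances[origin, dest]
    pop = locations.populations.to_numpy(dtype=float)
    if radius_rule == "strict":
        inside = d_row < r_ij
    else:
        inside = d_row <= r_ij
    idx = {loc: k for k, loc in enumerate(distances.ids)}
    inside = inside.copy()
    inside[idx[origin]] = False
    inside[idx[dest]] = False
    return float(pop[inside].sum())


def _score_matrix(locations: LocationTable, distances: DistanceMatrix, config: RadiationConfig) -> np.ndarray:
    """Radiation scores p_ij for all ordered pairs (diagonal = 0)."""
    n = len(locations)
    pop = locations.populations.reindex(distances.ids).to_numpy(dtype=float)
    d = distances.values
    scores = np.zeros((n, n))
    for i in range(n):
        # within[j, k]: location k strictly (or weakly) inside the circle of
        # radius d[i, j] centred at i
        if config.radius_rule == "strict":
            within = d[i][None, :] < d[i][:, None]
        else:
            within = d[i][None, :] <= d[i][:, None]
        s = within @ pop
        # remove origin (k == i) and destination (k == j) contributions:
        # origin is inside whenever 0 < r_ij (strict) / always (inclusive);
        # destination only under the inclusive rule (r_ij <= r_ij)
        if config.radius_rule == "strict":
            s -= np.where(d[i] > 0, pop[i], 0.0)
        else:
            s -= pop[i] + pop
        s = np.clip(s, 0.0, None)
        m_i, m_j = pop[i], pop
        first = m_i + s if config.first_factor == "standard" else m_j + s
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (m_i * m_j) / (first * (m_i + m_j + s))
        p[i] = 0.0
        scores[i] = p
    return scores


def radiation_scores(
    locations: LocationTable,
    config: RadiationConfig = RadiationConfig(),
    distances: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Raw radiation scores as a square DataFrame indexed by location id."""
    if distances is None:
        distances = distance_matrix(locations)
    return pd.DataFrame(_score_matrix(locations, distances, config), index=distances.ids, columns=distances.ids)


def radiation_predict(
    locations: LocationTable,
    origin_totals: Mapping[str, float] | None = None,
    config: RadiationConfig = RadiationConfig(),
    distances: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Deterministic radiation flows for every ordered pair.

    With ``normalize='origin_outflow'`` each origin i listed in
    *origin_totals* distributes its total O_i over all destinations in
    proportion to the scores (optionally with the finite-size correction
    denominator 1 - m_i/M); origins not listed are omitted.  With
    ``normalize='none'`` raw scores are returned for all origins.
    Returns a DataFrame ``origin, destination, flow``.
    """
    if distances is None:
        distances = distance_matrix(locations)
    scores = _score_matrix(locations, distances, config)
    ids = distances.ids
    rows = []
    if config.normalize == "origin_outflow":
        if origin_totals is None:
            raise ValueError("origin_totals required with normalize='origin_outflow'")
        total_pop = float(locations.populations.sum())
        for origin, o_total in origin_totals.items():
            i = ids.index(origin)
            p = scores[i]
            if config.finite_size_correction:
                denom = 1.0 - locations.population(origin) / total_pop
            else:
                denom = p.sum()
            if denom <= 0:
                raise DegenerateDataError(f"zero total radiation score from origin {origin!r}")
            flows = o_total * p / denom
            rows.extend((origin, ids[j], flows[j]) for j in range(len(ids)) if j != i)
    else:
        for i, origin in enumerate(ids):
            rows.extend((origin, ids[j], scores[i, j]) for j in range(len(ids)) if j != i)
    return pd.DataFrame(rows, columns=["origin", "destination", "flow"])


def radiation_star_predict(
    locations: LocationTable,
    daily_totals: pd.Series,
    direction: Literal["incoming", "outgoing"],
    config: RadiationConfig = RadiationConfig(),
    distances: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Dated radiation predictions on the egocentric star.

    On a star network only hub-side totals are observable.  Outgoing flows
    are the hub's radiation distribution scaled to each day's observed total
    outflow (ordinary origin-outflow normalization).  Incoming flows
    distribute each day's observed total arrivals across origin countries in
    proportion to each origin's radiation score toward the hub — the same
    score surface, normalized over origins because the shared destination is
    the hub.  *daily_totals* is a Series of observed totals indexed by date.
    Returns a dated DataFrame ``date, origin, destination, flow``.
    """
    if distances is None:
        distances = distance_matrix(locations)
    hub = locations.hub_id
    ids = distances.ids
    scores = _score_matrix(locations, distances, config)
    h = ids.index(hub)
    if direction == "outgoing":
        p = scores[h].copy()
    elif direction == "incoming":
        p = scores[:, h].copy()
    else:
        raise ValueError("direction must be 'incoming' or 'outgoing' on a star")
    p[h] = 0.0
    if p.sum() <= 0:
        raise DegenerateDataError("zero total radiation score on the star")
    share = p / p.sum()
    frames = []
    for date, total in daily_totals.items():
        flows = float(total) * share
        df = pd.DataFrame(
            {
                "date": date,
                "origin": hub if direction == "outgoing" else ids,
                "destination": ids if direction == "outgoing" else hub,
                "flow": flows,
            }
        )
        frames.append(df[df["origin"] != df["destination"]])
    return pd.concat(frames, ignore_index=True)
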