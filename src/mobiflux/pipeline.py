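"""End-to-end orchestration: synth -> fit -> predict -> evaluate -> synchrony.

The pipeline reproduces the full study protocol on one set of inputs —
either a generated synthetic world or three CSV tables — and writes, to a
fresh output directory: per-model dated predictions, a period-split
``summary.csv`` (one row per model and direction), per-day metric series,
a ``synchrony.json`` report against the reference series, and a run
manifest.  Everything is deterministic given the configuration and seed.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .cgm import build_design, cgm_fit, cgm_predict
from .data_model import (
    FlowPanel,
    LocationTable,
    aggregate_daily_total,
    load_flows,
    load_locations,
    load_reference_series,
    load_stringency,
)
from .errors import ConfigurationError
from .gravity import gravity_fit, gravity_fit_per_day, gravity_predict
from .metrics import DEFAULT_P1_END, evaluate, mean_relative_improvement
from .radiation import RadiationConfig, radiation_star_predict
from .synchrony import DEFAULT_WINDOWS, synchrony_report
from .synthetic import (
    CGMTruth,
    GravityTruth,
    NoiseSpec,
    SynthConfig,
    generate_reference_series,
    generate_world,
    simulate_flows,
)

ALL_MODELS = ("gravity-exp", "gravity-pow", "radiation", "cgm-exp", "cgm-pow")

_KIND_OF_MODEL = {"gravity-exp": "exponential", "gravity-pow": "power", "cgm-exp": "exponential", "cgm-pow": "power"}


def gravity_daily_predictions(
    panel: FlowPanel,
    locations: LocationTable,
    kind: str,
    fit_scope: str = "per-day",
    distances=None,
) -> pd.DataFrame:
    """Dated gravity predictions for every observed (date, pair).

    ``per-day`` refits (K, beta) each day in-sample; ``global`` fits once on
    the pooled panel and predicts every day with the same parameters.
    """
    if fit_scope not in ("per-day", "global"):
        raise ConfigurationError(f"fit_scope must be 'per-day' or 'global', got {fit_scope!r}")
    frames = []
    if fit_scope == "global":
        fit = gravity_fit(panel, locations, kind, distances=distances)
        fits = {date: fit for date in panel.dates}
    else:
        fits = gravity_fit_per_day(panel, locations, kind, distances=distances)
    for date, day_df in panel.df.groupby("date"):
        pairs = list(zip(day_df["origin"], day_df["destination"]))
        pred = gravity_predict(locations, pairs, fits[date], distances=distances)
        pred.insert(0, "date", date)
        frames.append(pred)
    return pd.concat(frames, ignore_index=True)


def cgm_direction_predictions(
    panel: FlowPanel,
    locations: LocationTable,
    stringency,
    kind: str,
    distances=None,
):
    """Fit the CGM on one direction's pooled panel and predict its means.

    On a one-direction star the hub-side log-population is constant, so it
    is absorbed into the intercept (predictions are unaffected).
    """
    design = build_design(panel, locations, stringency, kind, distances=distances)
    params = cgm_fit(design, absorb_constant=True)
    return cgm_predict(params, design), params


def _load_inputs(config: dict, seed: int, out_dir: Path):
    """Resolve inputs: either generate a synthetic world or load CSVs."""
    if "synth" in config and "inputs" in config:
        raise ConfigurationError("config must give either a 'synth' block or an 'inputs' block, not both")
    if "synth" in config:
        s = dict(config["synth"])
        generator = s.pop("generator", "cgm")
        noise = NoiseSpec(kind=s.pop("noise", "negative_binomial"), dispersion=float(s.pop("dispersion", 5.0)))
        truth_overrides = s.pop("truth", {})
        if "start" in s:
            s["start"] = _as_date(s["start"])
        synth_cfg = SynthConfig(seed=seed, **s)
        if generator == "cgm":
            truth = CGMTruth(**truth_overrides)
        elif generator in ("gravity_exp", "gravity_pow"):
            truth = GravityTruth(kind="exponential" if generator == "gravity_exp" else "power", **truth_overrides)
        else:
            raise ConfigurationError(f"unknown generator {generator!r}")
        world = generate_world(synth_cfg, seed=seed)
        sim = simulate_flows(world, truth, noise=noise, seed=seed + 1, direction="both")
        reference, _ = generate_reference_series(sim.panel, scale=0.9, noise_sd_fraction=0.05, seed=seed + 2)
        world.locations.to_csv(out_dir / "locations.csv")
        sim.panel.to_csv(out_dir / "flows.csv")
        world.stringency.to_csv(out_dir / "stringency.csv")
        _series_to_csv(reference, out_dir / "reference.csv")
        (out_dir / "truth.json").write_text(json.dumps(sim.truth, indent=2, default=str) + "\n")
        return world.locations, sim.panel, world.stringency, reference, world.distances
    if "inputs" not in config:
        raise ConfigurationError("config needs a 'synth' or an 'inputs' block")
    inp = config["inputs"]
    locations = load_locations(inp["locations"], hub_id=inp.get("hub"))
    panel = load_flows(inp["flows"], hub_id=locations.hub_id)
    stringency = load_stringency(inp["stringency"]) if "stringency" in inp else None
    reference = load_reference_series(inp["reference"]) if "reference" in inp else None
    return locations, panel, stringency, reference, None


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the whole protocol; returns the paths and summary in memory.

    ``config`` mirrors the YAML accepted by ``mobiflux pipeline``: a
    ``synth`` (or ``inputs``) block, an optional ``models`` list, gravity
    ``fit_scope``, evaluation ``p1_end`` and synchrony ``windows``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    models = list(config.get("models", ALL_MODELS))
    unknown = set(models) - set(ALL_MODELS)
    if unknown:
        raise ConfigurationError(f"unknown model(s) {sorted(unknown)}; choose from {ALL_MODELS}")
    needs_cgm = any(m.startswith("cgm") for m in models)
    if needs_cgm and "inputs" in config and "stringency" not in config["inputs"]:
        raise ConfigurationError("cgm models requested but no stringency input given")

    locations, panel, stringency, reference, distances = _load_inputs(config, seed, out_dir)
    if needs_cgm and stringency is None:
        raise ConfigurationError("cgm models requested but no stringency panel available")
    hub = locations.hub_id
    fit_scope = config.get("fit_scope", "per-day")
    p1_end = _as_date(config.get("p1_end", DEFAULT_P1_END))

    daily_frames, summary_frames, cgm_fits = [], [], {}
    for direction in ("incoming", "outgoing"):
        obs = panel.restrict(direction, hub)
        if len(obs) == 0:
            continue
        preds = {}
        for model in models:
            if model.startswith("gravity"):
                preds[model] = gravity_daily_predictions(
                    obs, locations, _KIND_OF_MODEL[model], fit_scope=fit_scope, distances=distances
                )
            elif model == "radiation":
                totals = aggregate_daily_total(obs, direction, hub)
                preds[model] = radiation_star_predict(
                    locations, totals, direction, RadiationConfig(), distances=distances
                )
            else:  # cgm-*
                preds[model], params = cgm_direction_predictions(
                    obs, locations, stringency, _KIND_OF_MODEL[model], distances=distances
                )
                cgm_fits[f"{model}-{direction}"] = params.to_dict()
        result = evaluate(preds, obs, p1_end=p1_end)
        summary_d = result.summary.assign(direction=direction)
        # per-day relative improvement of each CGM variant over each baseline,
        # averaged over days, attached to that CGM's row
        for baseline in models:
            if baseline.startswith("cgm"):
                continue
            col = f"rel_cpc_over_{baseline}"
            summary_d[col] = float("nan")
            for model in models:
                if model.startswith("cgm"):
                    summary_d.loc[summary_d["model"] == model, col] = mean_relative_improvement(
                        result.daily, model, baseline
                    )
        daily_frames.append(result.daily.assign(direction=direction))
        summary_frames.append(summary_d)

    summary = pd.concat(summary_frames, ignore_index=True)
    daily = pd.concat(daily_frames, ignore_index=True)
    summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.6f")
    daily.assign(date=daily["date"].map(_dt.date.isoformat)).to_csv(
        out_dir / "daily_metrics.csv", index=False, float_format="%.6f"
    )
    if cgm_fits:
        (out_dir / "cgm_fits.json").write_text(json.dumps(cgm_fits, indent=2, default=_json_default) + "\n")

    synchrony = None
    if reference is not None:
        a_t = aggregate_daily_total(panel, "incoming", hub)
        windows = [w for w in config.get("windows", DEFAULT_WINDOWS) if w <= len(a_t)]
        report = synchrony_report(a_t.astype(float), reference, window_sizes=windows)
        synchrony = report.to_dict()
        (out_dir / "synchrony.json").write_text(json.dumps(synchrony, indent=2) + "\n")

    manifest = {
        "command": "pipeline",
        "package_version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "input_digests": _digests(config.get("inputs", {})),
        "models": models,
        "written": sorted(p.name for p in out_dir.iterdir()),
        "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {"summary": summary, "daily": daily, "synchrony": synchrony, "out_dir": out_dir}


# ---------------------------------------------------------------------------
# small helpers


def _as_date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def _series_to_csv(series: pd.Series, path) -> None:
    pd.DataFrame({"date": [d.isoformat() for d in series.index], "count": series.to_numpy()}).to_csv(
        path, index=False
    )


def _digests(inputs: dict) -> dict:
    out = {}
    for key, path in inputs.items():
        p = Path(str(path))
        if p.is_file():
            out[key] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def _json_default(obj):
    try:
        return float(obj)
    except (TypeError, ValueError):
        return str(obj)
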