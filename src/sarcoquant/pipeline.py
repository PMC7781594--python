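"""Configuration-driven orchestration of the analysis stages.

A run config is a YAML/dict with a seed, an output directory and an ordered
stage list; each stage has a ``kind`` naming a registered operation and a
parameter block. Outputs (CSV/JSON per stage plus a combined report and a
provenance log) are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import yaml

from . import __version__, defaults, io
from .afm import find_contact_point, fit_hertz
from .balance import BalanceParams, centering_force
from .fracture import score_image
from .gel import quantify_bands
from .synthetic import (
    HertzCurveSpec,
    LaneSpec,
    ViscoelasticModelSpec,
    default_band_layout,
    default_protocol,
    gen_em_micrograph,
    gen_gel_lane,
    gen_indentation_curve,
    gen_ramp_hold_trace,
)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _stage_simulate_em(params, seed, outdir, state):
    img, gt = gen_em_micrograph(seed=seed, **params)
    state["micrograph"] = img
    state["ground_truth"] = gt
    io.write_micrograph(outdir / "em.tiff", img)
    return {"shape_px": list(img.shape), "nm_per_px": img.nm_per_px,
            "n_zdisks": len(gt.zdisk_paths)}


def _stage_fracture_score(params, seed, outdir, state):
    img = state.get("micrograph")
    if img is None:
        img = io.read_micrograph(params.pop("image"), params.pop("nm_per_px", None))
    result = score_image(img, **params)
    out = _jsonable(result)
    (outdir / "fracture.json").write_text(json.dumps(out, indent=2))
    return {"fracture_area_nm2": result.fracture_area_nm2, "n_segments": result.n_segments}


def _stage_simulate_trace(params, seed, outdir, state):
    model = ViscoelasticModelSpec(**params.pop("model", {"k_elastic": 1.0}))
    protocol = params.pop("protocol", None) or default_protocol()
    trace = gen_ramp_hold_trace(model, [tuple(p) for p in protocol], seed=seed, **params)
    state["trace"] = trace
    io.write_trace(outdir / "trace.csv", trace)
    return {"n_samples": len(trace.time_s)}


def _stage_simulate_afm(params, seed, outdir, state):
    spec = HertzCurveSpec(**params)
    curve = gen_indentation_curve(spec, seed=seed)
    state["curve"] = curve
    io.write_curve(outdir / "afm_curve.csv", curve)
    return {"n_samples": len(curve.position_nm)}


def _stage_afm_fit(params, seed, outdir, state):
    curve = state.get("curve")
    if curve is None:
        curve = io.read_curve(params.pop("curve"), params.pop("radius_um", defaults.BEAD_RADIUS_UM))
    find_contact_point(curve)
    fit = fit_hertz(curve, **params)
    (outdir / "hertz_fit.json").write_text(json.dumps(_jsonable(fit), indent=2))
    return {"E_kpa": fit.E_kpa, "depth_at_trigger_nm": fit.depth_at_trigger_nm}


def _stage_simulate_gel(params, seed, outdir, state):
    positions, widths = default_band_layout()
    spec = LaneSpec(
        band_positions=params.pop("band_positions", positions),
        band_widths=params.pop("band_widths", widths),
        **params,
    )
    profile, truth = gen_gel_lane(spec, seed=seed)
    state["lane_profile"] = profile
    io.write_lane_profile(outdir / "lane.csv", profile)
    return {"true_areas": truth}


def _stage_gel_quantify(params, seed, outdir, state):
    profile = state.get("lane_profile")
    if profile is None:
        profile = io.read_lane_profile(params.pop("profile"), params.pop("band_windows", None))
    quant = quantify_bands(profile, **params)
    (outdir / "bands.json").write_text(json.dumps(_jsonable(quant), indent=2))
    return {"percent_cleaved": quant.percent_cleaved, "areas": quant.areas}


def _stage_balance(params, seed, outdir, state):
    displacement = params.pop("displacement_nm", defaults.REFERENCE_DISPLACEMENT_NM)
    convention = params.pop("convention", "one-sided")
    result = centering_force(BalanceParams(**params), displacement, convention)
    (outdir / "balance.json").write_text(json.dumps(_jsonable(result), indent=2))
    return _jsonable(result)


STAGES = {
    "simulate_em": _stage_simulate_em,
    "fracture_score": _stage_fracture_score,
    "simulate_trace": _stage_simulate_trace,
    "simulate_afm": _stage_simulate_afm,
    "afm_fit": _stage_afm_fit,
    "simulate_gel": _stage_simulate_gel,
    "gel_quantify": _stage_gel_quantify,
    "balance": _stage_balance,
}


def validate_config(config: dict) -> None:
    if "stages" not in config or not config["stages"]:
        raise ValueError("config must define a non-empty stage list")
    for stage in config["stages"]:
        kind = stage.get("kind")
        if kind not in STAGES:
            raise ValueError(f"unknown stage kind {kind!r}")


def run(config, outdir=None) -> dict:
    """Execute the configured stages in order and write the report bundle.

    ``config`` is a dict or a path to a YAML file. Validation happens
    before any stage runs; stage outputs land in the output directory along
    with ``report.json`` and a provenance log.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    validate_config(config)
    outdir = Path(outdir or config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    state: dict = {}
    report = {"seed": seed, "stages": []}
    for i, stage in enumerate(config["stages"]):
        kind = stage["kind"]
        params = dict(stage.get("params", {}))
        summary = STAGES[kind](params, seed + i, outdir, state)
        report["stages"].append({"kind": kind, "summary": _jsonable(summary)})

    provenance = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": _jsonable(config),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
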