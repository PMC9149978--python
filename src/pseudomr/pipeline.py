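"""End-to-end orchestration: phantom -> segment -> fit -> map -> synthesize -> evaluate.

``run_pipeline`` chains the workflow stages on a simulated phantom study:
it builds a training slice A and a nearby validation slice B sharing the
same tissue set, learns the (mu, sigma) -> {T1, T2, rho} surfaces on A,
regenerates the maps of B from B's CT alone, synthesizes weighted images at
the configured (TE, TR) pairs, and scores them against simulated reference
acquisitions of B with slope and PRD.

Configuration is a plain dict (or YAML file via the CLI) with per-stage
blocks; every stochastic stage draws its seed deterministically from the
single top-level ``seed``, so identical config implies identical outputs.
Each stage's parameters and the SHA-256 checksums of its array outputs are
recorded in ``pipeline_log.json``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .ct_mapping import apply_mapping, build_mapping, ct_window_features
from .errors import ConfigError
from .metrics import compare_images
from .phantom import default_phantom, simulate_ct, simulate_mr_series, t1_series_params, t2_series_params
from .relaxometry import compute_parameter_maps
from .segmentation import extract_region_mask, fcm_segment
from .signal_model import SequenceParams, synthesize_weighted_image
from . import io as pio

__all__ = ["DEFAULTS", "validate_config", "run_pipeline"]

DEFAULTS = {
    "phantom": {
        "shape": [128, 128],
        "texture_correlation": 2.0,
        "ct_noise_sd": 10.0,
        "ct_repeats": 9,
        "mr_noise_fraction": 0.01,
    },
    "segmentation": {
        "n_clusters": 3,
        "m": 2.0,
        "tol": 1e-5,
        "max_iter": 300,
        "rule": "brightest",
        "largest_component": True,
    },
    "fit": {"t2_saturation_correction": True, "t2_weighted": True},
    "features": {"window_size": 5, "min_count": 6},
    "mapping": {"fallback": "nearest"},
    "evaluate": {"normalization": "none"},
}

_MAPPING_MODES = ("piecewise_linear", "nearest")


def validate_config(config: dict) -> dict:
    """Check required fields and fill stage defaults; raises ConfigError."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    if "seed" not in config:
        raise ConfigError("missing required field 'seed'")
    if not isinstance(config["seed"], int):
        raise ConfigError("field 'seed' must be an integer")
    mapping = config.get("mapping")
    if not isinstance(mapping, dict) or "mode" not in mapping:
        raise ConfigError("missing required field 'mapping.mode'")
    if mapping["mode"] not in _MAPPING_MODES:
        raise ConfigError(
            f"field 'mapping.mode' must be one of {_MAPPING_MODES}, got {mapping['mode']!r}"
        )
    synth = config.get("synthesize")
    if not isinstance(synth, list) or not synth:
        raise ConfigError("missing required field 'synthesize' (non-empty list of {te, tr})")
    for i, s in enumerate(synth):
        if not isinstance(s, dict) or "te" not in s or "tr" not in s:
            raise ConfigError(f"field 'synthesize[{i}]' must provide 'te' and 'tr'")

    cfg = {"seed": config["seed"], "synthesize": synth, "mapping": dict(mapping)}
    for block, defaults in DEFAULTS.items():
        user = config.get(block, {})
        if not isinstance(user, dict):
            raise ConfigError(f"field {block!r} must be a mapping")
        merged = dict(defaults)
        merged.update(user)
        if block == "mapping":
            merged["mode"] = mapping["mode"]
        cfg[block] = merged
    return cfg


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _stage_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: dict, output_dir) -> dict:
    """Run the full phantom-study workflow; returns the report dict.

    Artifacts written under ``output_dir``: CT images, masks, fitted and
    regenerated parameter maps, the mapping-model JSON, synthesized and
    reference weighted images, ``report.json`` and ``pipeline_log.json``.
    """
    cfg = validate_config(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": cfg, "stages": {}}
    seeds = _stage_seeds(cfg["seed"], 6)
    pcfg = cfg["phantom"]
    shape = tuple(int(v) for v in pcfg["shape"])

    # --- simulate the study -------------------------------------------------
    slice_a = default_phantom("A", shape, texture_correlation=pcfg["texture_correlation"], seed=seeds[0])
    slice_b = default_phantom("B", shape, texture_correlation=pcfg["texture_correlation"], seed=seeds[1])
    ct_a, _ = simulate_ct(slice_a, noise_sd=pcfg["ct_noise_sd"], n_repeats=pcfg["ct_repeats"], seed=seeds[2])
    ct_b, _ = simulate_ct(slice_b, noise_sd=pcfg["ct_noise_sd"], n_repeats=pcfg["ct_repeats"], seed=seeds[3])

    seqs_t1, seqs_t2 = t1_series_params(), t2_series_params()
    peak = max(
        synthesize_weighted_image(slice_a.truth_maps, s).max() for s in seqs_t1 + seqs_t2
    )
    mr_sd = pcfg["mr_noise_fraction"] * peak
    tr_series = simulate_mr_series(slice_a, seqs_t1, noise_sd=mr_sd, seed=seeds[4])
    te_series = simulate_mr_series(slice_a, seqs_t2, noise_sd=mr_sd, seed=seeds[4] + 1)
    pio.write_nifti(out / "ct_a.nii", ct_a)
    pio.write_nifti(out / "ct_b.nii", ct_b)
    log["stages"]["simulate"] = {
        "mr_noise_sd": float(mr_sd),
        "ct_a": _checksum(ct_a),
        "ct_b": _checksum(ct_b),
    }

    # --- segment ------------------------------------------------------------
    scfg = cfg["segmentation"]
    masks = {}
    for name, ct in (("a", ct_a), ("b", ct_b)):
        part = fcm_segment(
            ct,
            scfg["n_clusters"],
            m=scfg["m"],
            tol=scfg["tol"],
            max_iter=scfg["max_iter"],
            seed=seeds[5],
        )
        rule = scfg["rule"]
        if isinstance(rule, list):
            rule = tuple(rule if rule[0] != "seed" else (rule[0], tuple(rule[1])))
        masks[name] = extract_region_mask(
            part, rule, largest_component=scfg["largest_component"]
        )
        pio.write_text_grid(out / f"mask_{name}.txt", masks[name].astype(int))
    log["stages"]["segment"] = {k: _checksum(v) for k, v in masks.items()}

    # --- fit maps on slice A ------------------------------------------------
    fcfg = cfg["fit"]
    maps_a = compute_parameter_maps(
        tr_series,
        te_series,
        masks["a"],
        t2_saturation_correction=fcfg["t2_saturation_correction"],
        t2_weighted=fcfg["t2_weighted"],
    )
    pio.write_parameter_maps(out / "maps_a.nii", maps_a)
    log["stages"]["fit_maps"] = {"n_pixels": int(maps_a.mask.sum()), "maps_a": _checksum(maps_a.t1)}

    # --- features + mapping -------------------------------------------------
    ftcfg = cfg["features"]
    feats_a = ct_window_features(
        ct_a, masks["a"], window_size=ftcfg["window_size"], min_count=ftcfg["min_count"]
    )
    model = build_mapping(
        feats_a,
        maps_a,
        mode=cfg["mapping"]["mode"],
        fallback=cfg["mapping"]["fallback"],
        provenance="slice_a",
    )
    model.save(out / "mapping_model.json")
    log["stages"]["mapping"] = {"n_nodes": model.n_points}

    # --- regenerate maps for slice B and synthesize -------------------------
    feats_b = ct_window_features(
        ct_b, masks["b"], window_size=ftcfg["window_size"], min_count=ftcfg["min_count"]
    )
    maps_b = apply_mapping(model, feats_b)
    pio.write_parameter_maps(out / "maps_b.nii", maps_b)

    reports = []
    for i, s in enumerate(cfg["synthesize"]):
        seq = SequenceParams(te=float(s["te"]), tr=float(s["tr"]))
        synth = synthesize_weighted_image(maps_b, seq)
        # reference acquisition of slice B: truth forward model + scanner noise
        rng = np.random.default_rng(seeds[4] + 2 + i)
        ref = synthesize_weighted_image(slice_b.truth_maps, seq)
        if mr_sd > 0:
            ref = ref + rng.normal(0.0, mr_sd, size=ref.shape)
        cmp_mask = maps_b.mask & slice_b.mask
        rep = compare_images(ref, synth, cmp_mask, normalization=cfg["evaluate"]["normalization"])
        reports.append({"te": seq.te, "tr": seq.tr, **rep.to_dict()})
        pio.write_nifti(out / f"synthetic_te{int(seq.te)}_tr{int(seq.tr)}.nii", synth)
        pio.write_nifti(out / f"reference_te{int(seq.te)}_tr{int(seq.tr)}.nii", ref)

    report = {"seed": cfg["seed"], "similarity": reports}
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "pipeline_log.json").write_text(json.dumps(log, indent=2, default=str))
    return report
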