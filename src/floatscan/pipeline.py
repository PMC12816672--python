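"""End-to-end orchestration: simulate -> index -> label -> train -> segment
-> quantify -> composite -> trend -> evaluate, from one YAML config.

Every stage draws its randomness from a seed derived deterministically from
the global seed, so an identical (config, seed) pair reproduces identical
numerical outputs byte for byte.  A JSON manifest records inputs, outputs,
parameters, and content hashes for each executed stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, labeling, trends
from .compositing import AreaSeries, composite, integrate_area
from .indices import compute_afai
from .raster_io import ensure_dir, write_detection, write_raster, write_scene
from .scenes import SceneParams, default_library, generate_area_series, generate_scene
from .segmentation import TrainConfig, normalize_bands, segment, tile, train_segmenter, save_model
from .unmixing import quantify_scene

logger = logging.getLogger("floatscan.pipeline")

STAGE_ORDER = (
    "simulate",
    "afai",
    "label",
    "train",
    "segment",
    "quantify",
    "composite",
    "trend",
    "evaluate",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict) or "stages" not in cfg:
        raise ValueError("config must be a mapping with a 'stages' block")
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGE_ORDER}")
    stages = cfg["stages"]
    if "segment" in stages and "train" not in stages and "model_path" not in stages["segment"]:
        raise ValueError("segment stage needs a train stage or an explicit model_path")
    if "quantify" in stages:
        q = stages["quantify"] or {}
        if (
            "segment" not in stages
            and "label" not in stages
            and "mask" not in q
            and not q.get("use_truth_mask", False)
        ):
            raise ValueError(
                "quantify stage needs a mask: add a segment or label stage, "
                "set quantify.mask to a path, or set quantify.use_truth_mask"
            )


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return int.from_bytes(hashlib.sha256(f"{seed}:{stage}".encode()).digest()[:4], "little")


def run(config: dict, out_dir=None) -> dict:
    """Execute the configured stages in pipeline order; returns the manifest."""
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = ensure_dir(out_dir or config.get("out_dir", "floatscan_run"))
    stages = config["stages"]
    manifest: dict = {"seed": seed, "stages": {}, "outputs": {}}
    state: dict = {}

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        params = stages[stage] or {}
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](state, params, seed, out)
        except PipelineError:
            raise
        except Exception as exc:  # propagate with stage context
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = params

    for f in sorted(out.glob("*")):
        if f.is_file():
            manifest["outputs"][f.name] = _hash_file(f)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def _stage_simulate(state, params, seed, out) -> None:
    sseed = _stage_seed(seed, "simulate")
    library = default_library()
    state["library"] = library
    scene_cfg = dict(params.get("scene", {}))
    for key in ("chi_range", "patch_radius", "aerosol_range", "fa_types"):
        if key in scene_cfg and scene_cfg[key] is not None:
            scene_cfg[key] = tuple(scene_cfg[key])
    n_scenes = int(params.get("n_scenes", 4))
    width = int(params.get("width", 96))
    height = int(params.get("height", 96))
    sp = SceneParams(**scene_cfg)
    state["scenes"] = [
        generate_scene(width, height, library, sp, seed=sseed + k) for k in range(n_scenes)
    ]
    for k, sc in enumerate(state["scenes"]):
        write_scene(out / f"scene_{k:03d}.nc", sc)
    series_cfgs = params.get("series", [])
    if series_cfgs:
        frames = []
        for i, scfg in enumerate(series_cfgs):
            s = generate_area_series(seed=sseed + 1000 + i, **scfg)
            frames.append(s.frame)
        import pandas as pd

        state["series"] = AreaSeries(pd.concat(frames, ignore_index=True))
        state["series"].to_csv(out / "area_series.csv")


def _stage_afai(state, params, seed, out) -> None:
    if "scenes" not in state:
        raise PipelineError("afai", "no scenes available; add a simulate stage")
    state["afai"] = [compute_afai(sc) for sc in state["scenes"]]
    for k, idx in enumerate(state["afai"]):
        write_raster(
            out / f"afai_{k:03d}.tif", idx.values, {"wavelengths_used": idx.wavelengths_used}
        )


def _stage_label(state, params, seed, out) -> None:
    if "afai" not in state:
        raise PipelineError("label", "no index rasters; add an afai stage")
    thr = float(params.get("threshold", 5e-4))
    masks = []
    for k, idx in enumerate(state["afai"]):
        h, w = idx.values.shape
        region = labeling.LabelRegion(geometry=(0, 0, h, w), threshold=thr)
        mask = labeling.make_labels(idx, [region])
        masks.append(mask)
        write_raster(out / f"labels_{k:03d}.tif", mask.astype(np.uint8), {"threshold": thr})
    state["labels"] = masks


def _stage_train(state, params, seed, out) -> None:
    if "scenes" not in state or "labels" not in state:
        raise PipelineError("train", "needs scenes and labels")
    tile_size = int(params.get("tile_size", 64))
    cfg_kwargs = {k: v for k, v in params.items() if k != "tile_size"}
    cfg_kwargs.setdefault("seed", _stage_seed(seed, "train"))
    config = TrainConfig(**cfg_kwargs)
    all_tiles, all_labels = [], []
    for sc, lab in zip(state["scenes"], state["labels"]):
        stack, _ = normalize_bands(sc)
        ts = tile(stack, tile_size=tile_size)
        lt = tile(lab.astype(float), tile_size=tile_size)
        all_tiles.append(ts.tiles)
        all_labels.append(lt.tiles[:, 0])
    tiles_arr = np.concatenate(all_tiles)
    labels_arr = np.concatenate(all_labels)
    model, history = train_segmenter(tiles_arr, labels_arr, config)
    state["model"] = model
    state["tile_size"] = tile_size
    save_model(model, history, out / "model.npz")
    import pandas as pd

    pd.DataFrame(history).to_csv(out / "training_log.csv", index=False)


def _stage_segment(state, params, seed, out) -> None:
    if "model" not in state:
        from .segmentation import load_model

        if "model_path" not in params:
            raise PipelineError("segment", "no trained model; add a train stage or model_path")
        state["model"], _ = load_model(params["model_path"])
    thr = float(params.get("threshold", 0.5))
    masks = [
        segment(sc, state["model"], threshold=thr, tile_size=state.get("tile_size", 64))
        for sc in state["scenes"]
    ]
    state["seg_masks"] = masks
    for k, m in enumerate(masks):
        write_raster(out / f"segmask_{k:03d}.tif", m.astype(np.uint8), {"threshold": thr})


def _stage_quantify(state, params, seed, out) -> None:
    if "scenes" not in state:
        raise PipelineError("quantify", "no scenes available")
    if params.get("use_truth_mask", False):
        masks = [sc.truth.fa_mask for sc in state["scenes"]]
    elif "seg_masks" in state:
        masks = state["seg_masks"]
    elif "labels" in state:
        masks = state["labels"]
    else:
        raise PipelineError("quantify", "no mask source; run segment or label first")
    library = state.get("library", default_library())
    dets = [
        quantify_scene(
            sc,
            m,
            library,
            water_window=int(params.get("water_window", 11)),
            chi_mode=params.get("chi_mode", "exact"),
        )
        for sc, m in zip(state["scenes"], masks)
    ]
    state["detections"] = dets
    for k, d in enumerate(dets):
        write_detection(out / f"detection_{k:03d}.nc", d)


def _stage_composite(state, params, seed, out) -> None:
    if "detections" not in state:
        raise PipelineError("composite", "no detections; run quantify first")
    grid = composite(
        state["detections"],
        period=tuple(params.get("period", (0,))),
        cell_area=state["scenes"][0].pixel_area if state.get("scenes") else 1.0,
    )
    state["density_grid"] = grid
    np.save(out / "density_grid.npy", grid.grid)
    (out / "composite_area.json").write_text(
        json.dumps({"area_km2": integrate_area(grid), "period": [int(p) for p in grid.period]})
    )


def _stage_trend(state, params, seed, out) -> None:
    if "series" not in state:
        raise PipelineError("trend", "no area series; configure simulate.series")
    table = trends.trend_table(
        state["series"],
        alpha=float(params.get("alpha", 0.05)),
        baseline=params.get("baseline", "first_year_mean"),
    )
    state["trend_table"] = table
    table.to_csv(out / "trends.csv", index=False, float_format="%.10g")


def _stage_evaluate(state, params, seed, out) -> None:
    if "scenes" not in state:
        raise PipelineError("evaluate", "no scenes with truth to evaluate against")
    preds = state.get("seg_masks") or state.get("labels")
    if preds is None:
        raise PipelineError("evaluate", "no predictions; run segment or label first")
    pairs = []
    type_hits = type_total = 0
    for sc, pred in zip(state["scenes"], preds):
        truth = sc.truth
        pairs.append((pred, truth.fa_mask, None, truth.chi_map))
    report = evaluation.evaluate_pairs(pairs)
    result = report.to_dict()
    if "detections" in state:
        for sc, det in zip(state["scenes"], state["detections"]):
            on = det.mask & sc.truth.fa_mask
            if on.any():
                type_hits += int((det.type_labels()[on] == sc.truth.fa_type_map[on]).sum())
                type_total += int(on.sum())
        if type_total:
            result["type_accuracy"] = type_hits / type_total
    state["report"] = result
    (out / "evaluation.json").write_text(json.dumps(result, indent=2, sort_keys=True))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "afai": _stage_afai,
    "label": _stage_label,
    "train": _stage_train,
    "segment": _stage_segment,
    "quantify": _stage_quantify,
    "composite": _stage_composite,
    "trend": _stage_trend,
    "evaluate": _stage_evaluate,
}
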