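"""Stage orchestration: run configured analysis stages reproducibly.

A run is described by a YAML/dict config with a ``stages`` list; each stage
names its kind and parameters.  Outputs (images, curve CSVs, fit JSONs) and
a manifest recording versions, seeds and thresholds are written to a result
directory.  Deterministic stages rerun bit-identically for the same config;
the manifest differs only in its timestamp.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .io import CalibratedImage, load_image, save_image

KNOWN_STAGES = ("fiber_image", "correlated_field", "texture", "morphometry",
                "indentation")


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def validate_config(config: dict[str, Any]) -> None:
    """Fail fast on malformed configs, naming the offending field."""
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ValueError("config must contain a 'stages' list")
    seen_names: set[str] = set()
    for i, stage in enumerate(config["stages"]):
        if not isinstance(stage, dict) or "kind" not in stage:
            raise ValueError(f"stages[{i}] must be a mapping with a 'kind' key")
        if stage["kind"] not in KNOWN_STAGES:
            raise ValueError(
                f"stages[{i}].kind: unknown stage {stage['kind']!r}; "
                f"expected one of {KNOWN_STAGES}"
            )
        thr = stage.get("threshold")
        if thr is not None and not isinstance(thr, (int, float)) and thr != "otsu":
            raise ValueError(
                f"stages[{i}].threshold: expected 'otsu' or a number, got {thr!r}"
            )
        src = stage.get("input")
        # an input may name an earlier stage or point at a file on disk
        if src is not None and src not in seen_names and not Path(src).exists():
            raise ValueError(f"stages[{i}].input: missing input file {src}")
        seen_names.add(stage.get("name", f"stage{i}_{stage['kind']}"))


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> Path:
    """Execute the configured stages in order and write results + manifest."""
    from . import indentation, morphometry, synthetic, texture

    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    images: dict[str, CalibratedImage] = {}

    for i, stage in enumerate(config["stages"]):
        kind = stage["kind"]
        name = stage.get("name", f"stage{i}_{kind}")
        params = {k: v for k, v in stage.items() if k not in ("kind", "name", "input")}

        if kind == "fiber_image":
            img = synthetic.make_fiber_image(synthetic.FiberImageSpec(**params))
            images[name] = img
            save_image(img, out_dir / f"{name}.tif")
            log.append(f"{name}: fiber image {img.shape}")
        elif kind == "correlated_field":
            img = synthetic.make_correlated_field(synthetic.FieldSpec(**params))
            images[name] = img
            save_image(img, out_dir / f"{name}.tif")
            log.append(f"{name}: correlated field {img.shape}")
        elif kind == "texture":
            img = _stage_image(stage, images)
            curve = texture.correlation_curve(
                img, d_max=params.get("d_max", 100), levels=params.get("levels", 64)
            )
            fit = texture.fit_correlation_length(curve)
            _write_curve_csv(curve, out_dir / f"{name}_curve.csv")
            (out_dir / f"{name}_fit.json").write_text(
                json.dumps(_jsonable(fit), indent=2)
            )
            log.append(f"{name}: texture fit λ={fit.corr_length_px}")
        elif kind == "morphometry":
            img = _stage_image(stage, images)
            metric = params.get("metric", "collagen-fraction")
            thr = params.get("threshold", "otsu")
            if metric == "collagen-fraction":
                value, roi = morphometry.collagen_fraction(img, threshold=thr)
                payload = {"metric": metric, "value_pct": value,
                           "threshold_used": roi.threshold_used}
            elif metric == "nuclei":
                payload = {"metric": metric,
                           "value": morphometry.count_nuclei(img, threshold=thr)}
            elif metric == "diameter":
                payload = {"metric": metric,
                           "value_um": morphometry.microtissue_diameter(img, threshold=thr)}
            else:
                raise ValueError(f"unknown morphometry metric {metric!r}")
            (out_dir / f"{name}.json").write_text(json.dumps(_jsonable(payload), indent=2))
            log.append(f"{name}: morphometry {metric}")
        elif kind == "indentation":
            curve = synthetic.make_indentation_curve(
                synthetic.IndentationSpec(**params)
            )
            fit = indentation.elastic_modulus(curve)
            (out_dir / f"{name}_fit.json").write_text(
                json.dumps(_jsonable(fit), indent=2)
            )
            log.append(f"{name}: indentation E={fit.E_pa:.6g} Pa")

    manifest = {
        "stromaquant_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "config": _jsonable(config),
        "stages_run": log,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return out_dir


def _stage_image(stage: dict[str, Any], images: dict[str, CalibratedImage]) -> CalibratedImage:
    src = stage.get("input")
    if src is None:
        raise ValueError(f"stage {stage.get('name', stage['kind'])!r} needs an 'input'")
    if src in images:
        return images[src]
    return load_image(src)


def _write_curve_csv(curve, path: Path) -> None:
    import pandas as pd

    pd.DataFrame({
        "d_px": curve.distances,
        "C_h": curve.horizontal,
        "C_v": curve.vertical,
        "C_mean": curve.mean,
    }).to_csv(path, index=False)
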