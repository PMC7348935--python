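"""Image and table input/output.

Images are carried in memory as :class:`CalibratedImage` (floating point)
and written to disk as single-channel unsigned 16-bit TIFF with the pixel
size recorded in a JSON sidecar (``<image>.json``).  Curves and tables go
through CSV with a header row; run configurations through YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml


@dataclass
class CalibratedImage:
    """A 2D intensity image with physical pixel-size calibration.

    Parameters
    ----------
    data
        Intensity grid, shape (rows, cols), non-negative reals. Stored as
        float64 internally regardless of the on-disk representation.
    pixel_size
        Physical edge length of one pixel in µm/px. Must be finite, > 0.
    ground_truth
        Optional dictionary of generator annotations (e.g. a fiber mask or
        a true object count) attached by the synthetic-data module.
    """

    data: np.ndarray
    pixel_size: float = 1.0
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("image must be a non-empty 2D array")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError("pixel_size must be finite and positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size ** 2


def save_image(img: CalibratedImage, path: str | Path) -> Path:
    """Write a CalibratedImage as uint16 TIFF plus a JSON sidecar.

    Intensities are linearly rescaled so the data maximum maps to 65535;
    the scale factor is recorded in the sidecar so reads can invert it.
    """
    path = Path(path)
    lo = float(img.data.min())
    hi = float(img.data.max())
    scale = (hi - lo) if hi > lo else 1.0
    raw = np.round((img.data - lo) / scale * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, raw)
    sidecar = {
        "pixel_size_um": img.pixel_size,
        "intensity_offset": lo,
        "intensity_scale": scale / 65535.0,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_image(path: str | Path) -> CalibratedImage:
    """Read a TIFF/PNG image; use the JSON sidecar for calibration if present."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim == 3:  # collapse an RGB(A) read to a single channel
        raw = raw[..., :3].mean(axis=-1)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    pixel_size = 1.0
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        pixel_size = float(meta.get("pixel_size_um", 1.0))
        raw = raw * float(meta.get("intensity_scale", 1.0)) + float(
            meta.get("intensity_offset", 0.0)
        )
    return CalibratedImage(raw, pixel_size=pixel_size)


def load_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return out


def save_yaml(obj: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path
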