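"""File formats and run configuration.

Images are single-channel grayscale TIFFs (8- or 16-bit). A run
manifest is a CSV with one row per picture: condition id, role (test
or control), replicate index, and the image path. Configuration is
JSON, validated strictly — unknown keys are rejected so a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field

from .beadseg import SegParams
from .flipsignal import RimParams
from .image import FluorImage, ImageFormatError

MANIFEST_COLUMNS = ("condition", "role", "replicate", "path")


class ManifestError(ValueError):
    """Manifest missing, malformed, or inconsistent."""


def read_image(path: str | Path, channel: int | None = None) -> FluorImage:
    """Read a grayscale TIFF into a FluorImage.

    Accepts 2-D 8- or 16-bit images. A multi-channel or multi-page file
    is rejected unless ``channel`` selects one plane explicitly.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt or non-TIFF
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc

    if arr.ndim == 3:
        if channel is None:
            raise ImageFormatError(
                f"{path} has {arr.shape} planes/channels; pass a channel index"
            )
        axis = int(np.argmin(arr.shape))  # channel axis is the short one
        arr = np.take(arr, channel, axis=axis)
    elif arr.ndim != 2:
        raise ImageFormatError(f"{path}: expected a 2-D image, got shape {arr.shape}")

    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ImageFormatError(
            f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16"
        )
    return FluorImage(pixels=arr.astype(np.float64), bit_depth=depth, source_path=str(path))


def write_image(image: FluorImage, path: str | Path) -> Path:
    """Write a FluorImage as an 8- or 16-bit grayscale TIFF (rounded)."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    tifffile.imwrite(path, np.round(image.pixels).astype(dtype))
    return path


@dataclass(frozen=True)
class ManifestRow:
    condition: str
    role: str  # "test" | "control"
    replicate: int
    path: Path


def read_manifest(path: str | Path) -> list[ManifestRow]:
    """Read and validate a run-manifest CSV.

    Requires the columns condition, role, replicate, path; every
    condition must have at least one test image, and roles must be
    ``test`` or ``control``. Paths are resolved relative to the
    manifest's directory. Raises :class:`ManifestError` before any
    image I/O when the table is invalid.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    if df.empty:
        raise ManifestError("manifest is empty")
    bad_roles = set(df["role"].unique()) - {"test", "control"}
    if bad_roles:
        raise ManifestError(f"unknown roles in manifest: {sorted(bad_roles)}")
    rows = [
        ManifestRow(
            condition=str(r.condition),
            role=str(r.role),
            replicate=int(r.replicate),
            path=(path.parent / str(r.path)).resolve()
            if not Path(str(r.path)).is_absolute()
            else Path(str(r.path)),
        )
        for r in df.itertuples()
    ]
    by_condition: dict[str, list[ManifestRow]] = {}
    for row in rows:
        by_condition.setdefault(row.condition, []).append(row)
    for condition, group in by_condition.items():
        if not any(r.role == "test" for r in group):
            raise ManifestError(f"condition {condition!r} has no test image")
    return rows


class SegConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    smoothing_sigma: float = 2.0
    threshold: float | None = None
    mask_smooth_sigma: float = 1.5
    min_radius: float = 5.0
    max_radius: float = 100.0
    min_circularity: float = 0.80
    min_solidity: float = 0.90
    max_aspect_ratio: float = 2.0
    exclude_border: bool = True

    def to_params(self) -> SegParams:
        return SegParams(**self.model_dump())


class RimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rim_fraction: float = Field(default=0.15, gt=0, le=0.5)
    min_rim_px: float = Field(default=2.0, ge=1)
    guard_px: float = Field(default=1.0, ge=0)

    def to_params(self) -> RimParams:
        return RimParams(**self.model_dump())


class ScreenConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ipib_index_threshold: float = 0.0  # % tot. lysate above which IP/IB is positive


class Config(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    segmentation: SegConfig = SegConfig()
    rim: RimConfig = RimConfig()
    screening: ScreenConfig = ScreenConfig()
    seed: int = 0
    out_dir: str = "flip_out"
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "Config":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def digest(self) -> str:
        """Stable short hash of the configuration, for provenance."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
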