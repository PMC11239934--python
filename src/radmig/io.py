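"""Image-stack, annotation and configuration I/O.

Coordinate conventions (package-wide)
-------------------------------------
* Pixel coordinates are 0-based; row index 0 is the image top.
* Spatial intervals are half-open ``[start, end)`` unless stated otherwise.
* The radial (pial-ventricular) axis is the image *row* axis.  The
  :class:`LayerAnnotation` flag ``radial_up`` is true when *decreasing* row
  index points toward the pial surface (slice mounted "pia up").
* Frame ``i`` of a stack is stamped with its *start* time
  ``t0_h + i * frame_interval_h``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "LayerAnnotation",
    "RunConfig",
    "read_stack",
    "write_stack",
    "max_intensity_project",
    "read_annotation",
    "write_annotation",
    "read_config",
    "write_config",
    "write_results",
    "read_results",
]


@dataclass
class ImageStack:
    """A single-channel time-lapse stack with physical metadata.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of non-negative, finite intensities.
    frame_interval_h
        Hours between consecutive frame starts (> 0).
    pixel_size_um
        Micrometres per pixel (> 0), isotropic.
    t0_h
        Acquisition-start offset in hours (timestamp of frame 0).
    """

    frames: np.ndarray
    frame_interval_h: float
    pixel_size_um: float
    t0_h: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (time, row, col); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1 or min(self.frames.shape[1:]) < 1:
            raise ValueError("empty stack")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("stack contains non-finite intensities")
        if np.any(self.frames < 0):
            raise ValueError("stack contains negative intensities")
        if not self.frame_interval_h > 0:
            raise ValueError("frame_interval_h must be > 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def timestamps_h(self) -> np.ndarray:
        """Frame-start times in hours, strictly increasing."""
        return self.t0_h + np.arange(self.n_frames) * self.frame_interval_h


@dataclass
class LayerAnnotation:
    """Laminar geometry of one slice: pial and ventricular boundary rows,
    the subplate (SP) band centre, and the radial orientation.

    ``radial_up=True`` means decreasing row index points toward the pia.
    """

    pial_row: float
    ventricular_row: float
    sp_center_row: float
    radial_up: bool = True

    def __post_init__(self) -> None:
        if self.pial_row == self.ventricular_row:
            raise ValueError("pial_row must differ from ventricular_row")
        lo, hi = sorted((self.pial_row, self.ventricular_row))
        if not (lo < self.sp_center_row < hi):
            raise ValueError(
                "sp_center_row must lie strictly between pial_row and "
                f"ventricular_row; got {self.sp_center_row} outside ({lo}, {hi})"
            )

    def validate_for_height(self, height: int) -> None:
        """Check all annotated rows fall inside an image of ``height`` rows."""
        for name in ("pial_row", "ventricular_row", "sp_center_row"):
            v = getattr(self, name)
            if not (0 <= v <= height - 1):
                raise ValueError(f"{name}={v} outside image height {height}")

    def pia_direction(self) -> int:
        """Sign of the row increment that moves toward the pia (-1 or +1)."""
        return -1 if self.radial_up else 1


@dataclass
class RunConfig:
    """Analysis parameters, mirroring the published quantification settings.

    The spectral bands are inclusive DFT *bin-index* ranges along the frame
    axis (see :mod:`radmig.luminescence` for why bins, not physical hertz).
    """

    grid_cols: int = 16
    grid_rows: int = 14
    low_band: tuple[int, int] = (2, 30)
    high_band: tuple[int, int] = (30, 75)
    exclude_initial_h: float = 4.5
    sp_half_rows: int = 4
    include_sp_center: bool = False
    n_bins: int = 5
    spike_correction: str = "broadband_subtract"
    use_power_spectrum: bool = True
    t_test_variant: str = "student"
    linking_max_disp_um: float = 15.0
    detect_threshold: float = 70.0  # above process intensity: somata only
    min_area_px: int = 4
    min_neurite_px: int = 4
    min_soma_px: int = 2
    leading_cone_deg: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.low_band = tuple(int(b) for b in self.low_band)
        self.high_band = tuple(int(b) for b in self.high_band)
        for name, band in (("low_band", self.low_band), ("high_band", self.high_band)):
            if len(band) != 2 or band[0] > band[1] or band[0] < 0:
                raise ValueError(f"{name} must be a non-empty inclusive range, got {band}")
        if self.grid_cols < 1 or self.grid_rows < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.spike_correction not in ("broadband_subtract", "mask", "none"):
            raise ValueError(f"unknown spike_correction {self.spike_correction!r}")
        if self.t_test_variant not in ("student", "welch"):
            raise ValueError(f"unknown t_test_variant {self.t_test_variant!r}")


# ---------------------------------------------------------------------------
# Stacks


def read_stack(path: str | Path, frame_interval_h: float, pixel_size_um: float,
               t0_h: float = 0.0) -> ImageStack:
    """Read a multi-frame grayscale TIFF into an :class:`ImageStack`.

    The acquisition frame interval is required metadata: it is never guessed
    from the file.  Multi-channel pages and non-uniform page shapes are
    rejected with an error naming the offending page.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        if len(pages) == 0:
            raise ValueError(f"empty stack: {path}")
        shape0 = pages[0].shape
        for i, page in enumerate(pages):
            if page.ndim != 2:
                raise ValueError(
                    f"page {i} of {path} is not single-channel grayscale "
                    f"(shape {page.shape})"
                )
            if page.shape != shape0:
                raise ValueError(
                    f"page {i} of {path} has shape {page.shape}, "
                    f"expected {shape0} (non-uniform frame shapes)"
                )
        frames = tif.asarray()
    if frames.ndim == 2:  # single page
        frames = frames[None]
    return ImageStack(frames=frames.astype(float), frame_interval_h=frame_interval_h,
                      pixel_size_um=pixel_size_um, t0_h=t0_h)


def write_stack(stack: ImageStack, path: str | Path, dtype=np.float32) -> None:
    """Write an :class:`ImageStack` as an uncompressed multi-page TIFF."""
    tifffile.imwrite(Path(path), stack.frames.astype(dtype), photometric="minisblack")


def max_intensity_project(zstack: np.ndarray, frame_interval_h: float,
                          pixel_size_um: float, t0_h: float = 0.0) -> ImageStack:
    """Maximum-intensity projection of a ``(T, Z, H, W)`` volume time series.

    ``out[t, r, c] = max_z in[t, z, r, c]`` — the per-pixel maximum across
    z-planes, producing the 2-D frames the rest of the pipeline consumes.
    """
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 4:
        raise ValueError(f"expected 4-D (time, z, row, col), got shape {zstack.shape}")
    if zstack.shape[1] < 1:
        raise ValueError("z dimension must be >= 1")
    return ImageStack(frames=zstack.max(axis=1), frame_interval_h=frame_interval_h,
                      pixel_size_um=pixel_size_um, t0_h=t0_h)


# ---------------------------------------------------------------------------
# Annotations and config

_ANNOTATION_FIELDS = ("pial_row", "ventricular_row", "sp_center_row", "radial_up")


def _load_mapping(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return data


def read_annotation(path: str | Path) -> LayerAnnotation:
    """Read a layer annotation from JSON or YAML (by extension)."""
    path = Path(path)
    data = _load_mapping(path)
    missing = [k for k in _ANNOTATION_FIELDS if k not in data]
    if missing:
        raise ValueError(f"annotation {path} missing fields: {missing}")
    extra = [k for k in data if k not in _ANNOTATION_FIELDS]
    if extra:
        raise ValueError(f"annotation {path} has unknown fields: {extra}")
    return LayerAnnotation(
        pial_row=float(data["pial_row"]),
        ventricular_row=float(data["ventricular_row"]),
        sp_center_row=float(data["sp_center_row"]),
        radial_up=bool(data["radial_up"]),
    )


def write_annotation(annotation: LayerAnnotation, path: str | Path) -> None:
    path = Path(path)
    data = dataclasses.asdict(annotation)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from YAML; unknown keys are an error."""
    data = _load_mapping(Path(path))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    extra = [k for k in data if k not in known]
    if extra:
        raise ValueError(f"config {path} has unknown fields: {extra}")
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["low_band"] = list(data["low_band"])
    data["high_band"] = list(data["high_band"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# Tabular results


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as a rectangular CSV with header."""
    table.to_csv(Path(path), index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
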