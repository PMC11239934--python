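"""Ground-truthed synthetic slice movies and section images.

The generator emulates the statistical structure the downstream analyses
assume, not microscope optics: radially migrating cells with
condition-dependent velocity, a multipolar-to-bipolar (MP->BP) morphology
switch at a configurable laminar band, transient luminescence bursts
confined to a band around the subplate, cosmic-ray single-frame pixel
spikes, and additive Gaussian background noise.  Every generator is fully
deterministic under a fixed seed, and the returned :class:`GroundTruth`
is sufficient to score every downstream estimator (velocity, morphology
class, laminar bin, burst timing) without re-simulation.

Cells are rendered as isotropic Gaussian somata (sigma ~2 px) with
1-px-wide polyline processes; photorealism is not attempted because the
estimators consume centroids and skeletons, not texture.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .io import ImageStack, LayerAnnotation

__all__ = [
    "SimParams",
    "GroundTruth",
    "default_annotation",
    "generate_migration_movie",
    "generate_luminescence_movie",
    "inject_cosmic_rays",
    "generate_section",
    "generate_cell_masks",
]

_SOMA_SIGMA = 2.0
_SOMA_AMP = 100.0
_PROCESS_AMP = 60.0
_SOMA_RADIUS = 3


@dataclass
class SimParams:
    """Forward-model parameters for one synthetic condition.

    Defaults describe the packaged luminescence fixture: a 160-frame movie
    at 0.5 h/frame so that, after the standard 4.5 h initial exclusion
    (9 frames), 151 frames remain and the one-sided spectrum reaches bin
    75, making the full printed band range well defined.  The field of
    view is a heavily binned luminescence-camera frame (56 x 64 px at
    8 um/px, i.e. ~450 x 510 um of cortical wall): photon-starved
    bioluminescence imaging is acquired with aggressive on-chip binning,
    which is also why single cosmic-ray events visibly contaminate whole
    analysis grid squares.  The burst-permissive band spans the
    subplate-adjacent region where the reporter is active.
    """

    image_shape: tuple[int, int] = (56, 64)
    n_frames: int = 160
    frame_interval_h: float = 0.5
    pixel_size_um: float = 8.0
    n_cells: int = 40
    velocity_um_per_h: tuple[float, float] = (12.0, 2.0)  # (mean, sd)
    jitter_px_sd: float = 0.25  # 2 um per frame at the default 8 um/px
    transition_row: int = 26
    burst_amplitude: float = 50.0
    burst_duration_h: float = 24.0
    burst_band_rows: tuple[int, int] = (10, 42)  # half-open [lo, hi)
    burst_radius_px: int = 1
    spike_rate_per_frame: float = 0.0
    spike_amplitude: float = 250.0
    noise_sd: float = 5.0
    radial_up: bool = True
    start_row_range: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("jitter_px_sd", "noise_sd", "spike_rate_per_frame",
                     "burst_amplitude", "spike_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.velocity_um_per_h[1] < 0:
            raise ValueError("velocity sd must be >= 0")
        lo, hi = self.burst_band_rows
        if not (0 <= lo < hi <= self.image_shape[0]):
            raise ValueError("burst_band_rows must lie inside the image")

    @property
    def duration_h(self) -> float:
        """Elapsed time from first to last frame start."""
        return (self.n_frames - 1) * self.frame_interval_h


@dataclass
class GroundTruth:
    """Everything needed to score the estimators against the simulation.

    ``trajectories[i, t]`` is cell *i*'s true (row, col) centroid at frame
    *t*, in pixels.  ``morphology[i][t]`` is ``"MP"`` or ``"BP"``.  Burst
    windows are ``(start_h, end_h)`` in hours or ``None`` for cells that
    never burst.  ``spikes`` lists every injected cosmic-ray event as
    ``(frame, row, col)``.
    """

    trajectories: np.ndarray  # (n_cells, n_frames, 2) float
    velocities_um_per_h: np.ndarray  # (n_cells,)
    morphology: list[list[str]]
    n_arms: np.ndarray  # (n_cells,) int, arms in the MP phase
    burst_windows: list[tuple[float, float] | None] = field(default_factory=list)
    spikes: list[tuple[int, int, int]] = field(default_factory=list)
    clamped: np.ndarray | None = None  # (n_cells,) bool

    @property
    def n_cells(self) -> int:
        return self.trajectories.shape[0]

    def to_json(self, path: str | Path) -> None:
        data = {
            "trajectories": self.trajectories.tolist(),
            "velocities_um_per_h": self.velocities_um_per_h.tolist(),
            "morphology": self.morphology,
            "n_arms": self.n_arms.tolist(),
            "burst_windows": [list(w) if w is not None else None
                              for w in self.burst_windows],
            "spikes": [list(s) for s in self.spikes],
            "clamped": self.clamped.tolist() if self.clamped is not None else None,
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            trajectories=np.asarray(data["trajectories"], dtype=float),
            velocities_um_per_h=np.asarray(data["velocities_um_per_h"], dtype=float),
            morphology=data["morphology"],
            n_arms=np.asarray(data["n_arms"], dtype=int),
            burst_windows=[tuple(w) if w is not None else None
                           for w in data["burst_windows"]],
            spikes=[tuple(s) for s in data["spikes"]],
            clamped=(np.asarray(data["clamped"], dtype=bool)
                     if data["clamped"] is not None else None),
        )


def default_annotation(params: SimParams) -> LayerAnnotation:
    """Annotation consistent with the generator's laminar geometry."""
    h = params.image_shape[0]
    if params.radial_up:
        return LayerAnnotation(pial_row=2, ventricular_row=h - 3,
                               sp_center_row=params.transition_row, radial_up=True)
    return LayerAnnotation(pial_row=h - 3, ventricular_row=2,
                           sp_center_row=params.transition_row, radial_up=False)


# ---------------------------------------------------------------------------
# Rendering primitives


def _add_gaussian(img: np.ndarray, r: float, c: float, amp: float,
                  sigma: float) -> None:
    """Add an isotropic Gaussian blob, truncated at 4 sigma."""
    h, w = img.shape
    rad = int(math.ceil(4 * sigma))
    r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    img[r0:r1, c0:c1] += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2)
                                      / (2 * sigma ** 2))


def _draw_process(img: np.ndarray, r: float, c: float, angle: float,
                  length: float, value: float) -> None:
    """Paint a 1-px line from the soma centre outward (max-composited).

    ``angle`` is measured from the -row axis (image "up"), clockwise.
    """
    h, w = img.shape
    er = r - length * math.cos(angle)
    ec = c + length * math.sin(angle)
    rr, cc = draw_line(int(round(r)), int(round(c)), int(round(er)), int(round(ec)))
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    img[rr[keep], cc[keep]] = np.maximum(img[rr[keep], cc[keep]], value)


def _mp_arm_angles(rng: np.random.Generator, n_arms: int,
                   min_sep_deg: float = 55.0) -> np.ndarray:
    """Draw arm directions with a minimum pairwise circular separation."""
    min_sep = math.radians(min_sep_deg)
    for _ in range(50):
        angles = np.sort(rng.uniform(0, 2 * math.pi, size=n_arms))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * math.pi]]))
        if np.all(gaps >= min_sep):
            return angles
    # fall back to evenly spaced with a random offset
    return (rng.uniform(0, 2 * math.pi)
            + np.arange(n_arms) * 2 * math.pi / n_arms) % (2 * math.pi)


@dataclass
class _CellGeometry:
    """Per-cell fixed morphological parameters drawn once at generation."""

    n_arms: int
    mp_angles: np.ndarray
    mp_lengths: np.ndarray
    leading_angle: float  # within +/-30 deg of the pia direction
    leading_length: float
    trailing_angle: float
    trailing_length: float


def _draw_geometry(rng: np.random.Generator, pia_angle: float) -> _CellGeometry:
    n_arms = int(rng.integers(3, 6))
    return _CellGeometry(
        n_arms=n_arms,
        mp_angles=_mp_arm_angles(rng, n_arms),
        mp_lengths=rng.uniform(8, 12, size=n_arms) + _SOMA_RADIUS,
        leading_angle=pia_angle + rng.uniform(-math.pi / 6, math.pi / 6),
        leading_length=rng.uniform(16, 22) + _SOMA_RADIUS,
        trailing_angle=pia_angle + math.pi + rng.uniform(-math.pi / 6, math.pi / 6),
        trailing_length=rng.uniform(6, 8) + _SOMA_RADIUS,
    )


def _render_cell(img: np.ndarray, r: float, c: float, cls: str,
                 geom: _CellGeometry) -> None:
    _add_gaussian(img, r, c, _SOMA_AMP, _SOMA_SIGMA)
    if cls == "MP":
        for a, L in zip(geom.mp_angles, geom.mp_lengths):
            _draw_process(img, r, c, a, L, _PROCESS_AMP)
    else:  # BP: one elongated pia-directed leading process + short trailer
        _draw_process(img, r, c, geom.leading_angle, geom.leading_length,
                      _PROCESS_AMP)
        _draw_process(img, r, c, geom.trailing_angle, geom.trailing_length,
                      _PROCESS_AMP)


# ---------------------------------------------------------------------------
# Movie generators


def generate_migration_movie(params: SimParams) -> tuple[ImageStack, GroundTruth]:
    """Simulate the labelled-cell channel of a slice time-lapse movie.

    Each cell is assigned a radial velocity drawn from the condition's
    Normal(mean, sd), moves toward the pial side at that velocity plus
    isotropic positional jitter, and switches from multipolar to bipolar
    rendering once it crosses ``transition_row`` (the switch is permanent).
    Cells that would exit the frame are clamped at the border and flagged.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    n, T = params.n_cells, params.n_frames
    pia_sign = -1 if params.radial_up else 1
    pia_angle = 0.0 if params.radial_up else math.pi  # rendering angle of "up"

    v_mean, v_sd = params.velocity_um_per_h
    velocities = rng.normal(v_mean, v_sd, size=n)  # um/h, + toward pia
    v_px_per_frame = velocities / params.pixel_size_um * params.frame_interval_h

    if params.start_row_range is not None:
        lo, hi = params.start_row_range
    elif params.radial_up:
        lo, hi = int(0.55 * h), h - 8
    else:
        lo, hi = 8, int(0.45 * h)
    start_rows = rng.uniform(lo, hi, size=n)
    # stratified columns keep cells resolvable for the tracker
    margin = 12.0
    base_cols = margin + (np.arange(n) + 0.5) / n * (w - 2 * margin)
    start_cols = base_cols + rng.normal(0, 2.0, size=n)

    jitter = rng.normal(0, params.jitter_px_sd, size=(n, T, 2))
    jitter[:, 0, :] = 0.0

    traj = np.empty((n, T, 2), dtype=float)
    clamped = np.zeros(n, dtype=bool)
    for t in range(T):
        rows = start_rows + pia_sign * v_px_per_frame * t + jitter[:, t, 0]
        cols = start_cols + jitter[:, t, 1]
        out = (rows < 3) | (rows > h - 4) | (cols < 3) | (cols > w - 4)
        clamped |= out
        traj[:, t, 0] = np.clip(rows, 3, h - 4)
        traj[:, t, 1] = np.clip(cols, 3, w - 4)

    geoms = [_draw_geometry(rng, pia_angle) for _ in range(n)]

    # morphology: MP until the first crossing of transition_row, BP after
    morphology: list[list[str]] = []
    for i in range(n):
        crossed = False
        states = []
        for t in range(T):
            row = traj[i, t, 0]
            if not crossed:
                past = (row <= params.transition_row if params.radial_up
                        else row >= params.transition_row)
                crossed = past
            states.append("BP" if crossed else "MP")
        morphology.append(states)

    frames = np.zeros((T, h, w), dtype=float)
    for t in range(T):
        for i in range(n):
            _render_cell(frames[t], traj[i, t, 0], traj[i, t, 1],
                         morphology[i][t], geoms[i])

    stack = ImageStack(frames=frames, frame_interval_h=params.frame_interval_h,
                       pixel_size_um=params.pixel_size_um)
    truth = GroundTruth(
        trajectories=traj,
        velocities_um_per_h=velocities,
        morphology=morphology,
        n_arms=np.array([g.n_arms for g in geoms], dtype=int),
        burst_windows=[None] * n,
        clamped=clamped,
    )
    return stack, truth


def generate_luminescence_movie(params: SimParams,
                                truth: GroundTruth) -> ImageStack:
    """Simulate the reporter-luminescence channel for given trajectories.

    Each cell emits a disk of peak value ``burst_amplitude`` for
    ``burst_duration_h`` starting when its centroid first enters
    ``burst_band_rows``, and only while the centroid stays inside the band.
    Gaussian background noise of sd ``noise_sd`` is added and the result is
    clamped at zero.  Burst windows are recorded into ``truth``.
    """
    h, w = params.image_shape
    T = params.n_frames
    lo, hi = params.burst_band_rows
    timestamps = np.arange(T) * params.frame_interval_h
    rng = np.random.default_rng(params.seed + 1)

    frames = np.zeros((T, h, w), dtype=float)
    windows: list[tuple[float, float] | None] = []
    for i in range(truth.n_cells):
        rows = truth.trajectories[i, :, 0]
        in_band = (rows >= lo) & (rows < hi)
        if not in_band.any():
            windows.append(None)
            continue
        # one contiguous window: first band entry until first exit or the
        # emission duration elapses, whichever comes first
        entry = int(np.argmax(in_band))
        exit_rel = np.argmax(~in_band[entry:]) if not in_band[entry:].all() \
            else len(in_band) - entry
        t_entry = timestamps[entry]
        t_exit = t_entry + exit_rel * params.frame_interval_h
        t_end = min(t_exit, t_entry + params.burst_duration_h,
                    timestamps[-1] + params.frame_interval_h)
        active = (timestamps >= t_entry) & (timestamps < t_end)
        windows.append((float(t_entry), float(t_end)))
        for t in np.nonzero(active)[0]:
            rr, cc = draw_disk((truth.trajectories[i, t, 0],
                                truth.trajectories[i, t, 1]),
                               params.burst_radius_px + 0.5, shape=(h, w))
            frames[t, rr, cc] = np.maximum(frames[t, rr, cc],
                                           params.burst_amplitude)
    truth.burst_windows = windows

    if params.noise_sd > 0:
        frames += rng.normal(0, params.noise_sd, size=frames.shape)
    np.clip(frames, 0, None, out=frames)
    return ImageStack(frames=frames, frame_interval_h=params.frame_interval_h,
                      pixel_size_um=params.pixel_size_um)


def inject_cosmic_rays(stack: ImageStack, rate: float, amplitude: float,
                       seed: int) -> tuple[ImageStack, list[tuple[int, int, int]]]:
    """Add Poisson-distributed single-pixel single-frame additive spikes.

    Cosmic rays on long-exposure luminescence cameras are temporal
    impulses: one pixel, one frame, high amplitude.  The returned spike
    list is exhaustive: ``sum(out) - sum(in) == amplitude * len(spikes)``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    frames = stack.frames.copy()
    T, h, w = frames.shape
    spikes: list[tuple[int, int, int]] = []
    for t in range(T):
        for _ in range(rng.poisson(rate)):
            r = int(rng.integers(0, h))
            c = int(rng.integers(0, w))
            frames[t, r, c] += amplitude
            spikes.append((t, r, c))
    out = ImageStack(frames=frames, frame_interval_h=stack.frame_interval_h,
                     pixel_size_um=stack.pixel_size_um, t0_h=stack.t0_h)
    return out, spikes


# ---------------------------------------------------------------------------
# Section generator (static laminar distributions)


def generate_section(n_cells: int, bin_weights: np.ndarray,
                     annotation: LayerAnnotation, seed: int,
                     col_range: tuple[float, float] = (5.0, 250.0),
                     ) -> tuple[np.ndarray, LayerAnnotation, np.ndarray]:
    """Draw labelled-cell coordinates from a per-bin mixture.

    The pial-ventricular span is divided into ``len(bin_weights)``
    equal-height bins (bin 1 pial-most, matching
    :func:`radmig.morphology.assign_bins`); each cell's bin is drawn from
    the normalised ``bin_weights`` and its row uniformly within that bin.

    Returns ``(positions (n, 2) rows/cols, annotation, true_bins 1-based)``.
    """
    weights = np.asarray(bin_weights, dtype=float)
    if weights.ndim != 1 or len(weights) < 2:
        raise ValueError("bin_weights must be a 1-D array of length >= 2")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("bin_weights must be non-negative with positive sum")
    weights = weights / weights.sum()
    n_bins = len(weights)
    rng = np.random.default_rng(seed)

    bins = rng.choice(n_bins, size=n_cells, p=weights)  # 0-based
    u = rng.uniform(0, 1, size=n_cells)
    # fraction along the pial->ventricular axis, half-open within each bin
    f = (bins + u) / n_bins
    rows = annotation.pial_row + f * (annotation.ventricular_row
                                      - annotation.pial_row)
    cols = rng.uniform(col_range[0], col_range[1], size=n_cells)
    positions = np.column_stack([rows, cols])
    return positions, annotation, bins + 1


# ---------------------------------------------------------------------------
# Isolated-cell mask gallery (morphology ground truth)


def generate_cell_masks(n: int, seed: int, shape: tuple[int, int] = (64, 64),
                        radial_up: bool = True,
                        classes: list[str] | None = None,
                        ) -> list[dict]:
    """Render ``n`` isolated binary cell masks with known morphology.

    Each entry is ``{"mask": bool array, "class": "MP"|"BP",
    "n_arms": int}``.  ``classes`` fixes the class sequence; otherwise
    classes alternate.  Masks are noiseless: a soma disk of radius 3 px
    plus 1-px processes, the geometry the skeleton classifier consumes.
    """
    rng = np.random.default_rng(seed)
    pia_angle = 0.0 if radial_up else math.pi
    center = (shape[0] / 2.0, shape[1] / 2.0)
    out = []
    for i in range(n):
        cls = classes[i] if classes is not None else ("MP" if i % 2 == 0 else "BP")
        geom = _draw_geometry(rng, pia_angle)
        img = np.zeros(shape, dtype=float)
        rr, cc = draw_disk(center, _SOMA_RADIUS + 0.5, shape=shape)
        img[rr, cc] = 1.0
        if cls == "MP":
            for a, L in zip(geom.mp_angles, geom.mp_lengths):
                _draw_process(img, center[0], center[1], a, L, 1.0)
        else:
            _draw_process(img, center[0], center[1], geom.leading_angle,
                          geom.leading_length, 1.0)
            _draw_process(img, center[0], center[1], geom.trailing_angle,
                          geom.trailing_length, 1.0)
        out.append({"mask": img > 0, "class": cls,
                    "n_arms": geom.n_arms if cls == "MP" else 2})
    return out
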