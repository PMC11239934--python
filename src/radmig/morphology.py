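"""Morphology classification, MP:BP composition, laminar bins, zone signal.

Morphology is a reproducible surrogate for the by-eye criterion used with
slice imaging: the cell mask is skeletonized, primary neurites are the
skeleton branches leaving the soma (largest inscribed disk), and a cell
is multipolar (MP) with >= 3 primary neurites, bipolar (BP) with 1-2
neurites the longest of which points toward the pia within a +/-45 deg
cone, and ambiguous otherwise.

Laminar BIN analysis divides the pial-ventricular span into ``n_bins``
equal-height half-open intervals, BIN 1 adjacent to the pial surface
(last bin closed), and counts labelled cells per bin.  Zone scoring
assigns each cell to below/in/above the subplate (SP) band in the radial
sense and averages a secondary channel (e.g. in situ zymography) over the
cell footprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .io import ImageStack, LayerAnnotation

__all__ = [
    "CellRecord",
    "BinDistribution",
    "classify_polarity",
    "mp_bp_composition",
    "assign_bins",
    "zone_signal",
]

_ZONES = ("below_SP", "in_SP", "above_SP")


@dataclass
class CellRecord:
    """Per-cell quantification record."""

    cell_id: int
    position: tuple[float, float]  # (row, col) px
    morphology: str = "ambiguous"  # MP | BP | ambiguous
    n_primary_neurites: int = 0
    leading_process: bool = False
    bin_index: int | None = None  # 1-based, 1 = pial-most
    zone: str | None = None
    zone_signal: float | None = None


@dataclass
class BinDistribution:
    """Per-bin counts/fractions plus per-cell assignments."""

    n_bins: int
    bin_of: np.ndarray  # (n,) int, 1-based; 0 = out of span (excluded)
    counts: np.ndarray  # (n_bins,)
    fractions: np.ndarray  # (n_bins,), sums to 1 over included cells
    n_excluded: int

    def to_frame(self, condition: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "condition": condition,
            "n_bins": self.n_bins,
            "bin": np.arange(1, self.n_bins + 1),
            "count": self.counts,
            "fraction": self.fractions,
            "n_excluded": self.n_excluded,
        })


# ---------------------------------------------------------------------------
# Morphology classification


def classify_polarity(mask: np.ndarray, annotation: LayerAnnotation,
                      min_soma_px: int = 2, min_neurite_px: int = 4,
                      leading_cone_deg: float = 45.0,
                      ) -> tuple[str, int, bool]:
    """Classify one cell mask as MP / BP / ambiguous.

    The soma is located at the maximum of the Euclidean distance
    transform (largest inscribed disk, radius >= ``min_soma_px``
    required).  Skeleton pixels within ``soma_radius + 2`` of the soma
    centre are removed; the remaining connected components of length
    >= ``min_neurite_px`` are the primary neurites.  The leading process
    is the longest neurite when its far endpoint lies within
    ``leading_cone_deg`` of the pial direction.

    Returns ``(morphology, n_primary_neurites, leading_process)``.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n_comp = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        raise ValueError("empty mask")
    if n_comp > 1:
        raise ValueError(f"mask has {n_comp} connected components; expected 1")

    dist = ndi.distance_transform_edt(mask)
    soma_radius = float(dist.max())
    if soma_radius < min_soma_px:
        raise ValueError(
            f"largest inscribed disk radius {soma_radius:.2f} px < "
            f"min_soma_px {min_soma_px}")
    center = np.array(np.unravel_index(int(np.argmax(dist)), mask.shape),
                      dtype=float)

    skel = skeletonize(mask)
    rr, cc = np.nonzero(skel)
    d_center = np.hypot(rr - center[0], cc - center[1])
    keep = d_center > soma_radius + 2.0
    pruned = np.zeros_like(skel)
    pruned[rr[keep], cc[keep]] = True

    comp_labels, n = ndi.label(pruned, structure=np.ones((3, 3), dtype=int))
    pia = np.array([-1.0, 0.0]) if annotation.radial_up else np.array([1.0, 0.0])
    cos_cone = np.cos(np.deg2rad(leading_cone_deg))

    neurites = []  # (length_px, unit direction to far endpoint)
    for lbl in range(1, n + 1):
        pr, pc = np.nonzero(comp_labels == lbl)
        if len(pr) < min_neurite_px:
            continue
        d = np.hypot(pr - center[0], pc - center[1])
        # primary neurites emanate from the soma boundary
        if d.min() > soma_radius + 4.0:
            continue
        far = np.argmax(d)
        vec = np.array([pr[far] - center[0], pc[far] - center[1]])
        neurites.append((len(pr), vec / np.linalg.norm(vec)))

    n_neurites = len(neurites)
    if n_neurites == 0:
        return "ambiguous", 0, False
    longest = max(neurites, key=lambda x: x[0])
    leading = bool(np.dot(longest[1], pia) >= cos_cone)
    if n_neurites >= 3:
        return "MP", n_neurites, leading
    if leading:
        return "BP", n_neurites, True
    return "ambiguous", n_neurites, False


def mp_bp_composition(records_t0: list[CellRecord],
                      records_t1: list[CellRecord],
                      t0_h: float = 0.0, t1_h: float = 10.0) -> pd.DataFrame:
    """MP/BP counts and fractions at two timepoints (default 0 h and 10 h).

    Ambiguous cells are excluded from the fractions but counted in the
    output; an all-ambiguous timepoint is an error.
    """
    rows = []
    for label, t, records in (("t0", t0_h, records_t0), ("t1", t1_h, records_t1)):
        if not records:
            raise ValueError(f"no cells at {label}")
        n_mp = sum(r.morphology == "MP" for r in records)
        n_bp = sum(r.morphology == "BP" for r in records)
        n_amb = sum(r.morphology == "ambiguous" for r in records)
        if n_mp + n_bp == 0:
            raise ValueError(f"all cells ambiguous at {label}")
        rows.append({"timepoint": label, "t_h": t, "n_mp": n_mp, "n_bp": n_bp,
                     "n_ambiguous": n_amb,
                     "frac_mp": n_mp / (n_mp + n_bp),
                     "frac_bp": n_bp / (n_mp + n_bp)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Laminar bins


def assign_bins(positions: np.ndarray, annotation: LayerAnnotation,
                n_bins: int = 5) -> BinDistribution:
    """Assign cells to equal-height laminar bins, BIN 1 pial-most.

    The pial-ventricular span is split into ``n_bins`` half-open
    intervals along the pial->ventricular axis; the ventricular-most bin
    is closed so a cell exactly on the ventricular boundary is included.
    Cells outside the span are excluded and counted separately.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    rows = positions[:, 0]
    span = annotation.ventricular_row - annotation.pial_row
    f = (rows - annotation.pial_row) / span  # 0 at pia, 1 at ventricle
    in_span = (f >= 0) & (f <= 1)
    bins = np.zeros(len(rows), dtype=int)  # 0 = excluded
    k = np.floor(f[in_span] * n_bins).astype(int)
    k = np.minimum(k, n_bins - 1)  # closed last bin
    bins[in_span] = k + 1
    counts = np.bincount(bins[in_span], minlength=n_bins + 1)[1:]
    total = counts.sum()
    fractions = counts / total if total > 0 else np.zeros(n_bins)
    return BinDistribution(n_bins=n_bins, bin_of=bins, counts=counts,
                           fractions=fractions,
                           n_excluded=int((~in_span).sum()))


# ---------------------------------------------------------------------------
# Zone-wise secondary-channel signal


def zone_of(row: float, sp_band_rows: tuple[float, float],
            annotation: LayerAnnotation) -> str:
    """Zone of a centroid row relative to the SP band, in the radial sense.

    The band is the half-open image-row interval ``[lo, hi)``; "above"
    means on the pial side, "below" on the ventricular side.
    """
    lo, hi = sorted(sp_band_rows)
    if lo <= row < hi:
        return "in_SP"
    pial_side = row < lo if annotation.radial_up else row >= hi
    return "above_SP" if pial_side else "below_SP"


def zone_signal(positions: np.ndarray, stack: ImageStack,
                annotation: LayerAnnotation,
                sp_band_rows: tuple[float, float],
                frame_indices: np.ndarray | None = None,
                masks: list[np.ndarray] | None = None,
                radius_px: float = 3.0) -> pd.DataFrame:
    """Per-cell zone assignment and mean secondary-channel signal.

    The signal is averaged over the cell mask when ``masks`` is given,
    otherwise over a disk of ``radius_px`` around the centroid, at each
    cell's matching frame (``frame_indices``, default frame 0).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    if frame_indices is None:
        frame_indices = np.zeros(n, dtype=int)
    frame_indices = np.asarray(frame_indices, dtype=int)
    if np.any(frame_indices < 0) or np.any(frame_indices >= stack.n_frames):
        raise ValueError("frame index out of range")
    T, H, W = stack.shape
    rows_out = []
    for i in range(n):
        r, c = positions[i]
        frame = stack.frames[frame_indices[i]]
        if masks is not None:
            sig = float(frame[np.asarray(masks[i], bool)].mean())
        else:
            rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
            disk = (rr - r) ** 2 + (cc - c) ** 2 <= radius_px ** 2
            sig = float(frame[disk].mean())
        rows_out.append({"cell_id": i, "row": r, "col": c,
                         "frame": int(frame_indices[i]),
                         "zone": zone_of(r, sp_band_rows, annotation),
                         "zone_signal": sig})
    return pd.DataFrame(rows_out)
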