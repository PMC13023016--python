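"""Displacement maps and per-scan summary measures.

The pipeline's product is a per-frame, per-voxel 3-vector displacement field
(A/P, L/R, S/I components, mm).  The headline per-scan scalar is the
peak-to-peak displacement: for each voxel, the maximum Euclidean distance
between the 3-D displacement vectors of any two cardiac timepoints.  Scans
are summarized by the in-mask mean of that map and by a "maximum" defined as
the mean of the highest 5% of in-mask values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

__all__ = [
    "DisplacementField",
    "PeakToPeakMap",
    "peak_to_peak_map",
    "summarize_p2p",
    "mean_displacement_curves",
    "per_average_curves",
    "interior_peripheral_compare",
]


@dataclass
class DisplacementField:
    """Per-frame voxelwise displacement vectors.

    ``data`` has shape ``(n_frames, 3, ny, nx)`` with components ordered
    (A/P, L/R, S/I), in mm. ``masks`` is the ``(left, right)`` hemisphere
    pair (may be ``None`` for raw fields).
    """

    data: np.ndarray
    frame_times_ms: np.ndarray
    masks: tuple[np.ndarray, np.ndarray] | None = None
    voxel_mm: float = 4.0
    axis_labels: tuple[str, str, str] = ("A/P", "L/R", "S/I")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)
        if self.data.ndim != 4 or self.data.shape[1] != 3:
            raise ValueError("displacement data must be (n_frames, 3, ny, nx)")
        if len(self.frame_times_ms) != self.data.shape[0]:
            raise ValueError("frame_times_ms length mismatch")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def combined_mask(self) -> np.ndarray:
        if self.masks is None:
            raise ValueError("field carries no hemisphere masks")
        return self.masks[0] | self.masks[1]


@dataclass
class PeakToPeakMap:
    """Voxelwise peak-to-peak displacement (mm), nonnegative."""

    data: np.ndarray
    parent: DisplacementField | None = dc_field(default=None, repr=False)


def peak_to_peak_map(field: DisplacementField) -> PeakToPeakMap:
    """Exhaustive peak-to-peak map over all frame pairs.

    ``p2p(v) = max over (t1, t2) of ||u(v,t1) - u(v,t2)||_2``.  With at most
    19 frames this is at most 171 pairs, so exhaustive enumeration is exact
    and cheap.
    """
    u = field.data
    T = u.shape[0]
    if T < 2:
        raise ValueError("peak-to-peak needs at least 2 frames")
    p2p = np.zeros(u.shape[2:], dtype=float)
    for t1 in range(T - 1):
        diff = u[t1 + 1 :] - u[t1]  # (T-t1-1, 3, ny, nx)
        d = np.sqrt((diff**2).sum(axis=1)).max(axis=0)
        np.maximum(p2p, d, out=p2p)
    return PeakToPeakMap(data=p2p, parent=field)


def _combined(masks) -> np.ndarray:
    if isinstance(masks, (tuple, list)):
        out = np.zeros_like(np.asarray(masks[0], dtype=bool))
        for m in masks:
            out |= np.asarray(m, dtype=bool)
        return out
    return np.asarray(masks, dtype=bool)


def summarize_p2p(
    p2p: PeakToPeakMap | np.ndarray,
    masks,
    top_fraction: float = 0.05,
    top_rule: str = "ceil",
) -> tuple[float, float]:
    """(mean, max) peak-to-peak summary over the in-mask voxels.

    The "max" is the mean of the top ``ceil(top_fraction * N)`` values
    (``top_rule="floor"`` uses the floor count, clipped to at least 1).
    """
    data = p2p.data if isinstance(p2p, PeakToPeakMap) else np.asarray(p2p)
    mask = _combined(masks)
    vals = data[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    n_top = (
        math.ceil(top_fraction * vals.size)
        if top_rule == "ceil"
        else max(1, math.floor(top_fraction * vals.size))
    )
    top = np.sort(vals)[-n_top:]
    return float(vals.mean()), float(top.mean())


def mean_displacement_curves(field: DisplacementField, masks=None) -> np.ndarray:
    """Spatial in-mask mean displacement per frame and direction.

    Returns an ``(n_frames, 3)`` array — the displacement curve over the
    cardiac cycle for each anatomical direction, averaged across both
    hemispheres.
    """
    mask = _combined(masks if masks is not None else field.masks)
    return field.data[:, :, mask].mean(axis=2)


def per_average_curves(fields, masks=None) -> np.ndarray:
    """Displacement curves for separately reconstructed averages.

    ``fields`` is a sequence of :class:`DisplacementField`, one per repeated
    average; returns ``(n_averages, n_frames, 3)`` so repeated measures can
    be overlaid and compared.
    """
    return np.stack(
        [mean_displacement_curves(f, masks) for f in fields], axis=0
    )


def interior_peripheral_compare(
    p2p: PeakToPeakMap | np.ndarray,
    masks,
    erosion_depth: int = 2,
) -> dict:
    """Peak-to-peak summaries for interior vs peripheral tissue.

    The interior is the combined hemisphere mask eroded ``erosion_depth``
    times (4-connectivity); the periphery is what erosion removed.  With
    ``erosion_depth=0`` the interior is the full mask and the periphery is
    the standard one-voxel outer ring.  Used to check the stationary-ring
    assumption: cardiac-driven displacement should concentrate interiorly.
    """
    from .motion import extract_outer_ring

    data = p2p.data if isinstance(p2p, PeakToPeakMap) else np.asarray(p2p)
    mask = _combined(masks)
    if erosion_depth == 0:
        interior = mask
        peripheral = extract_outer_ring(mask).ring
    else:
        structure = ndimage.generate_binary_structure(2, 1)
        interior = ndimage.binary_erosion(
            mask, structure=structure, iterations=erosion_depth
        )
        if not interior.any():
            raise ValueError("erosion leaves empty interior")
        peripheral = mask & ~interior
    return {
        "interior": summarize_p2p(data, interior),
        "peripheral": summarize_p2p(data, peripheral),
        "interior_n": int(interior.sum()),
        "peripheral_n": int(peripheral.sum()),
    }
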