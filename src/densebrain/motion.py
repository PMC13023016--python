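"""Outer-ring bulk-motion estimation and subtraction.

Rigid head motion during the DENSE mixing period adds a spatially planar
phase to each image: a translation contributes a constant offset
(2*pi*ke * e_i.delta) and a small rotation contributes a first-order term,
so their combination is a plane ``a*x + b*y + c`` over the slice.  Because
the skull constrains the brain's periphery, the outermost one-voxel ring of
the combined hemisphere mask is assumed free of cardiac-driven displacement;
any phase observed there is attributed to bulk motion.  Fitting a plane to
the ring phase of each individual (frame, encoding) image and subtracting it
from the whole image removes the bulk-motion contribution.

Two fitters are provided:

``fit_plane_ols``
    ordinary least squares on the (already unwrapped) ring phase — fast, but
    blind to residual phase wraps;
``fit_plane_wrapped``
    coarse grid search plus simplex refinement of the wrap-invariant
    objective ``J = sum(1 - cos(phi - plane))``, which treats phases modulo
    2*pi and therefore recovers the plane even when it wraps several times
    across the ring.

Correction can be applied in the real domain (plain subtraction) or in the
complex domain (multiply unit phasors, take the angle), the latter removing
2*pi ledges exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .util import wrap_to_pi

__all__ = [
    "RingMask",
    "PlaneFit",
    "segment_hemispheres",
    "extract_outer_ring",
    "fit_plane_ols",
    "fit_plane_wrapped",
    "apply_correction",
    "plane_image",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
_SQUARE = ndimage.generate_binary_structure(2, 2)  # 8-connectivity


@dataclass
class RingMask:
    """One-voxel-wide outer boundary of a (combined hemisphere) mask.

    Coordinates used by the plane fitters are voxel indices centered at the
    centroid of the *parent* mask, which decorrelates the slopes from the
    intercept.
    """

    ring: np.ndarray
    parent: np.ndarray
    centroid: tuple[float, float]  # (row, col) of parent mask centroid

    @property
    def n_voxels(self) -> int:
        return int(self.ring.sum())

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered (x, y) coordinates of the ring voxels (x = column)."""
        rows, cols = np.nonzero(self.ring)
        cy, cx = self.centroid
        return cols - cx, rows - cy

    def half_extents(self) -> tuple[float, float]:
        """Half the parent-mask bounding-box extent along (x, y), voxels."""
        rows, cols = np.nonzero(self.parent)
        rx = (cols.max() - cols.min() + 1) / 2.0
        ry = (rows.max() - rows.min() + 1) / 2.0
        return rx, ry


@dataclass
class PlaneFit:
    """First-order spatial polynomial ``a*x + b*y + c`` for one image.

    Slopes are rad/voxel in centered coordinates; the intercept is the value
    at the parent-mask centroid.
    """

    slope_x: float
    slope_y: float
    intercept: float
    objective: float
    method: str  # "ols" | "wrapped"
    converged: bool = True

    @property
    def coeffs(self) -> np.ndarray:
        return np.array([self.slope_x, self.slope_y, self.intercept])


def segment_hemispheres(
    magnitude: np.ndarray, threshold_method: str | float = "otsu"
) -> tuple[np.ndarray, np.ndarray]:
    """Segment left/right hemisphere masks from a magnitude image.

    Foreground is obtained by automatic (Otsu) or explicit thresholding.
    Connected components smaller than 5% of the largest are discarded as
    noise (the two hemispheres are separate components, so *only* keeping
    the single largest would drop one).  The surviving foreground is split
    at the midline column (its column centroid).

    Returns ``(left, right)`` boolean masks, disjoint by construction.
    Externally supplied mask files bypass this operation entirely.
    """
    mag = np.asarray(magnitude, dtype=float)
    if mag.min() < 0:
        raise ValueError("magnitude image must be nonnegative")
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {threshold_method!r}")
        if mag.max() == 0:
            raise ValueError("empty foreground: all-zero magnitude image")
        thr = threshold_otsu(mag)
    else:
        thr = float(threshold_method)
    fg = mag > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    labels, n = ndimage.label(fg, structure=_SQUARE)
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= 0.05 * sizes.max()) + 1
    fg = np.isin(labels, keep)
    cols = np.nonzero(fg)[1]
    midline = cols.mean()
    X = np.arange(fg.shape[1])[None, :]
    left = fg & (X < midline)
    right = fg & (X >= midline)
    return left, right


def extract_outer_ring(mask: np.ndarray, connectivity: int = 4) -> RingMask:
    """One-voxel outer ring: ``mask & ~erode(mask)``.

    Erosion uses a 4-connectivity cross element by default (yields a closed
    single-voxel ring on convex masks); 8-connectivity is available.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    structure = _CROSS if connectivity == 4 else _SQUARE
    eroded = ndimage.binary_erosion(mask, structure=structure)
    ring = mask & ~eroded
    if not eroded.any():
        warnings.warn(
            "mask erodes to empty: ring equals the whole mask "
            "(degenerate thin object)",
            stacklevel=2,
        )
    rows, cols = np.nonzero(mask)
    centroid = (rows.mean(), cols.mean())
    return RingMask(ring=ring, parent=mask, centroid=centroid)


def _ring_design(ring: RingMask):
    x, y = ring.coords()
    return x, y, np.column_stack([x, y, np.ones_like(x)])


def fit_plane_ols(phase: np.ndarray, ring: RingMask) -> PlaneFit:
    """Ordinary least-squares plane fit to the ring phase.

    Minimizes ``sum((phi - a*x - b*y - c)**2)`` in centered voxel
    coordinates via the normal equations.  Raises for fewer than three ring
    voxels or collinear geometry ("underdetermined plane fit").
    """
    phi = np.asarray(phase, dtype=float)[ring.ring]
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite phase on ring")
    x, y, A = _ring_design(ring)
    if len(phi) < 3 or np.linalg.matrix_rank(A) < 3:
        raise ValueError("underdetermined plane fit: <3 non-collinear ring voxels")
    coef, *_ = np.linalg.lstsq(A, phi, rcond=None)
    resid = phi - A @ coef
    return PlaneFit(
        slope_x=float(coef[0]),
        slope_y=float(coef[1]),
        intercept=float(coef[2]),
        objective=float(resid @ resid),
        method="ols",
    )


def _objective(phi, x, y, coeffs, kind):
    r = phi - coeffs[0] * x - coeffs[1] * y - coeffs[2]
    if kind == "cosine":
        return float(np.sum(1.0 - np.cos(r)))
    return float(np.sum(wrap_to_pi(r) ** 2))


def fit_plane_wrapped(
    phase: np.ndarray,
    ring: RingMask,
    n_slope: int = 21,
    n_intercept: int = 16,
    objective: str = "cosine",
    refine: bool = True,
    fatol: float = 1e-8,
) -> PlaneFit:
    """Wrap-aware plane fit: coarse grid search then local refinement.

    Stage 1 evaluates the wrap-invariant objective
    ``J(a,b,c) = sum(1 - cos(phi - a*x - b*y - c))`` on a coarse grid:
    slopes over ``[-pi/R, pi/R]`` per axis (R = half the parent-mask extent
    on that axis, so any plane with a total across-mask excursion up to 2*pi
    per axis is covered) at ``n_slope`` steps, intercept over ``(-pi, pi]``
    at ``n_intercept`` steps.  Stage 2 refines the best grid point with a
    derivative-free simplex (Nelder-Mead, tolerance ``fatol`` on J) followed
    by a linearized least-squares polish on the wrapped residual, which the
    locally quadratic objective makes exact.  The result never has a larger
    objective than the best grid point.

    ``objective="squared"`` uses ``sum(wrap(phi - plane)**2)`` instead.
    """
    if objective not in ("cosine", "squared"):
        raise ValueError(f"unknown objective {objective!r}")
    phi = np.asarray(phase, dtype=float)[ring.ring]
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite phase on ring")
    x, y, A = _ring_design(ring)
    if len(phi) < 3 or np.linalg.matrix_rank(A) < 3:
        raise ValueError("underdetermined plane fit: <3 non-collinear ring voxels")

    rx, ry = ring.half_extents()
    a_grid = np.linspace(-np.pi / rx, np.pi / rx, n_slope)
    b_grid = np.linspace(-np.pi / ry, np.pi / ry, n_slope)
    # (-pi, pi] with n_intercept steps, includes 0
    c_grid = -np.pi + 2.0 * np.pi * np.arange(1, n_intercept + 1) / n_intercept

    # residual phase for every (a, b): shape (n_slope, n_slope, n_ring)
    r = (
        phi[None, None, :]
        - a_grid[:, None, None] * x[None, None, :]
        - b_grid[None, :, None] * y[None, None, :]
    )
    n = len(phi)
    if objective == "cosine":
        # sum cos(r - c) = cos(c) sum cos r + sin(c) sum sin r
        C = np.cos(r).sum(axis=-1)
        S = np.sin(r).sum(axis=-1)
        J = n - (
            np.cos(c_grid)[None, None, :] * C[..., None]
            + np.sin(c_grid)[None, None, :] * S[..., None]
        )
    else:
        J = (wrap_to_pi(r[..., None, :] - c_grid[None, None, :, None]) ** 2).sum(
            axis=-1
        )
    ia, ib, ic = np.unravel_index(np.argmin(J), J.shape)
    best = np.array([a_grid[ia], b_grid[ib], c_grid[ic]])
    j_grid = float(J[ia, ib, ic])

    if not refine:
        return PlaneFit(*best, objective=j_grid, method="wrapped")

    res = optimize.minimize(
        lambda p: _objective(phi, x, y, p, objective),
        best,
        method="Nelder-Mead",
        options={"fatol": fatol, "xatol": 1e-10, "maxiter": 2000},
    )
    coeffs = res.x if res.fun <= j_grid else best
    j_val = min(float(res.fun), j_grid)

    # Gauss-Newton polish: near the optimum both objectives are quadratic in
    # the wrapped residual, so iterated OLS on wrap(phi - plane) converges.
    for _ in range(30):
        resid = wrap_to_pi(phi - A @ coeffs)
        delta, *_ = np.linalg.lstsq(A, resid, rcond=None)
        cand = coeffs + delta
        j_cand = _objective(phi, x, y, cand, objective)
        if j_cand > j_val:
            break
        coeffs, j_val = cand, j_cand
        if np.max(np.abs(delta)) < 1e-13:
            break

    converged = bool(res.success) or j_val <= j_grid
    return PlaneFit(
        slope_x=float(coeffs[0]),
        slope_y=float(coeffs[1]),
        intercept=float(wrap_to_pi(coeffs[2])),
        objective=j_val,
        method="wrapped",
        converged=converged,
    )


def plane_image(fit: PlaneFit, ring: RingMask) -> np.ndarray:
    """Evaluate the fitted plane over the full image grid."""
    ny, nx = ring.parent.shape
    cy, cx = ring.centroid
    Y, X = np.mgrid[0:ny, 0:nx]
    return fit.slope_x * (X - cx) + fit.slope_y * (Y - cy) + fit.intercept


def apply_correction(
    phase: np.ndarray, fit: PlaneFit, ring: RingMask, domain: str = "complex"
) -> np.ndarray:
    """Subtract the fitted bulk-motion plane from a whole phase image.

    ``domain="real"``: plain subtraction, ``phi - plane`` (leaves any 2*pi
    ledges in place).  ``domain="complex"``: phases are mapped onto the unit
    circle, the plane phasor is divided out, and the angle is taken, so the
    output lies in (-pi, pi] and integer-2*pi offsets vanish exactly.

    The correction is applied to every voxel of the image, not only the
    ring, independently per (frame, encoding) image.
    """
    phi = np.asarray(phase, dtype=float)
    plane = plane_image(fit, ring)
    if domain == "real":
        return phi - plane
    if domain == "complex":
        return np.angle(np.exp(1j * phi) * np.exp(-1j * plane))
    raise ValueError(f"unknown correction domain {domain!r}")
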