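"""Synthetic cardiac-gated DENSE acquisitions with known ground truth.

The phantom is a 2-D brain-slice stand-in: two elliptical hemispheres
separated by a one-voxel midline gap, unit tissue magnitude, and a
cardiac-driven interior displacement field

    u(v, t) = a(v) * s(t) * p

where ``p`` is the per-axis peak displacement vector, ``a(v)`` is a
raised-cosine envelope of the normalized distance to the tissue boundary
(zero on the outer ring, 1 at the deepest voxel — deeper tissue moves more,
the periphery is held still by the skull), and ``s(t)`` is a smooth pulse
that is zero at the first and last sampled frame (net-zero cycle) and is
normalized so its sampled peak is exactly 1.

On top of the tissue motion the simulator can impose rigid bulk motion:
per-frame translations add a constant phase per encoding direction and
small in-plane rotations add a first-order (planar) phase, both computable
in closed form — this is the acceptance surface for the motion-correction
pipelines.  Phase is wrapped into (-pi, pi] and complex Gaussian noise is
added on the real/imaginary channels, in that order (a scanner yields
wrapped, noisy phase).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .dispstats import DisplacementField
from .encoding import EncodingScheme, encode_series
from .metrics import PPGTrace
from .motion import RingMask, extract_outer_ring
from .pipeline import (
    CardiacTiming,
    ComplexSeries,
    acquired_frame_times,
    detrend_reference_array,
    resample_linear,
)
from .util import wrap_to_pi

__all__ = [
    "PhantomConfig",
    "BulkMotionParams",
    "PhantomTruth",
    "generate_phantom",
    "simulate_acquisition",
    "bulk_plane_coefficients",
    "generate_ppg",
    "make_smooth_background",
]


@dataclass
class PhantomConfig:
    """Geometry, timing, motion amplitude and noise of the phantom scan.

    ``peak_displacement_mm`` is the per-axis (A/P, L/R, S/I) peak of the
    tissue displacement; each component must stay below half the encoding
    sensitivity (1/(2*ke), i.e. no intra-voxel wrap of the tissue phase
    alone) unless ``allow_wraps`` is set for wrap testing.
    """

    grid_size: tuple[int, int] = (60, 60)
    voxel_mm: float = 4.0
    n_frames: int = 10
    coverage_fraction: float = 1.10
    rr_ms: float = 1000.0
    peak_displacement_mm: tuple[float, float, float] = (0.10, 0.04, 0.12)
    noise_sd: float = 0.0
    background_phase: np.ndarray | None = None
    seed: int = 0
    allow_wraps: bool = False
    ke: float = 2.02

    def __post_init__(self) -> None:
        ny, nx = self.grid_size
        if min(ny, nx) < 16:
            raise ValueError("grid_size must be at least 16 voxels per axis")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        peaks = np.asarray(self.peak_displacement_mm, dtype=float)
        if peaks.shape != (3,):
            raise ValueError("peak_displacement_mm must be a 3-vector")
        if not self.allow_wraps:
            limit = 1.0 / (2.0 * self.ke)
            if np.any(peaks <= 0) or np.any(peaks >= limit):
                raise ValueError(
                    f"per-axis peak displacement must lie in (0, {limit:.4f}) mm "
                    "unless allow_wraps=True"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def frame_times_ms(self) -> np.ndarray:
        return acquired_frame_times(
            self.n_frames, self.rr_ms, self.coverage_fraction
        )


@dataclass
class BulkMotionParams:
    """Rigid bulk motion per cardiac frame.

    ``translations_mm`` is ``(n_frames, 3)`` in (A/P, L/R, S/I) components;
    ``rotations_deg`` is the in-plane rotation angle per frame about
    ``pivot`` (voxel (row, col); defaults to the mask centroid).  Frame 0 is
    the reference frame and must carry zero motion.
    """

    translations_mm: np.ndarray
    rotations_deg: np.ndarray
    pivot: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.translations_mm = np.asarray(self.translations_mm, dtype=float)
        self.rotations_deg = np.asarray(self.rotations_deg, dtype=float)
        if self.translations_mm.ndim != 2 or self.translations_mm.shape[1] != 3:
            raise ValueError("translations_mm must be (n_frames, 3)")
        if len(self.rotations_deg) != len(self.translations_mm):
            raise ValueError("translations and rotations length mismatch")
        if np.any(self.translations_mm[0] != 0) or self.rotations_deg[0] != 0:
            raise ValueError("frame 0 is the reference frame: motion must be zero")

    @property
    def n_frames(self) -> int:
        return len(self.rotations_deg)

    @classmethod
    def none(cls, n_frames: int) -> "BulkMotionParams":
        return cls(np.zeros((n_frames, 3)), np.zeros(n_frames))

    @classmethod
    def random(
        cls,
        n_frames: int,
        max_translation_mm: float = 0.3,
        max_rotation_deg: float = 0.15,
        seed: int = 0,
        pivot: tuple[float, float] | None = None,
    ) -> "BulkMotionParams":
        """Uniform per-frame motion within the given amplitudes, frame 0 zero."""
        rng = np.random.default_rng(seed)
        trans = rng.uniform(-max_translation_mm, max_translation_mm, (n_frames, 3))
        rot = rng.uniform(-max_rotation_deg, max_rotation_deg, n_frames)
        trans[0] = 0.0
        rot[0] = 0.0
        return cls(trans, rot, pivot=pivot)


@dataclass
class PhantomTruth:
    """Ground truth: displacement field, masks, and bulk-motion planes."""

    u: np.ndarray  # (n_frames, 3, ny, nx) mm
    masks: tuple[np.ndarray, np.ndarray]
    ring: RingMask
    frame_times_ms: np.ndarray
    config: PhantomConfig
    magnitude: np.ndarray
    envelope: np.ndarray
    pulse: np.ndarray
    # (n_frames, n_enc, 3) plane coeffs per encoding, set by the simulator
    bulk_planes: np.ndarray | None = dc_field(default=None)

    def combined_mask(self) -> np.ndarray:
        return self.masks[0] | self.masks[1]

    def field(self) -> DisplacementField:
        """Raw truth displacement at the acquired frame times."""
        return DisplacementField(
            data=self.u,
            frame_times_ms=self.frame_times_ms,
            masks=self.masks,
            voxel_mm=self.config.voxel_mm,
        )

    def expected_field(
        self,
        rr_measured_ms: float | None = None,
        n_interpolated_frames: int = 19,
    ) -> DisplacementField:
        """Truth mapped through the pipeline's temporal normalization.

        The pipeline linearly interpolates the acquired frames onto the
        fine cardiac grid, trims frames beyond the measured RR, removes the
        per-voxel OLS line in time, and references to frame 0.  Those
        operations are exactly linear and define what the pipeline *should*
        report; applying them to the analytic truth yields the comparison
        target that isolates phase-domain errors.
        """
        timing = CardiacTiming(
            rr_prescription_ms=self.config.rr_ms,
            rr_measured_ms=rr_measured_ms or self.config.rr_ms,
            n_acquired_frames=self.config.n_frames,
            n_interpolated_frames=n_interpolated_frames,
            coverage_fraction=self.config.coverage_fraction,
        )
        window = timing.coverage_fraction * timing.rr_prescription_ms
        times_out = np.arange(timing.n_interpolated_frames) * (
            window / timing.n_interpolated_frames
        )
        u = resample_linear(self.u, self.frame_times_ms, times_out, axis=0)
        keep = times_out <= timing.rr_measured_ms
        u = detrend_reference_array(u[keep], times_out[keep])
        return DisplacementField(
            data=u,
            frame_times_ms=times_out[keep],
            masks=self.masks,
            voxel_mm=self.config.voxel_mm,
        )


def _hemisphere_geometry(config: PhantomConfig):
    ny, nx = config.grid_size
    cy = (ny - 1) / 2.0
    cx = nx // 2  # midline gap column
    Y, X = np.mgrid[0:ny, 0:nx]
    ax_ = 0.45 * nx
    ay_ = 0.45 * ny
    ellipse = ((X - cx) / ax_) ** 2 + ((Y - cy) / ay_) ** 2 <= 1.0
    left = ellipse & (X < cx)
    right = ellipse & (X > cx)
    return left, right


def generate_phantom(
    config: PhantomConfig,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray], PhantomTruth]:
    """Build the phantom geometry and its ground-truth displacement field.

    Returns ``(magnitude, (left, right) masks, truth)``.  By construction
    the outer-ring voxels carry zero displacement at every frame, the field
    is zero at the first and last sampled frame, and the maximum
    displacement sits at the interior voxels deepest inside the mask.
    """
    left, right = _hemisphere_geometry(config)
    combined = left | right
    magnitude = combined.astype(float)

    # raised-cosine envelope of normalized depth; ring voxels (depth 1) -> 0
    depth = ndimage.distance_transform_edt(combined)
    dmax = depth.max()
    if dmax <= 1:
        raise ValueError("mask too thin for an interior displacement field")
    dn = np.clip((depth - 1.0) / (dmax - 1.0), 0.0, 1.0)
    envelope = 0.5 * (1.0 - np.cos(np.pi * dn))
    envelope[~combined] = 0.0

    times = config.frame_times_ms
    span = times[-1]
    pulse = np.sin(np.pi * times / span) ** 2
    pulse[0] = pulse[-1] = 0.0  # exact net-zero cycle (sin(pi) != 0 in float)
    pulse /= pulse.max()  # sampled peak exactly 1

    peaks = np.asarray(config.peak_displacement_mm, dtype=float)
    u = (
        pulse[:, None, None, None]
        * peaks[None, :, None, None]
        * envelope[None, None, :, :]
    )

    truth = PhantomTruth(
        u=u,
        masks=(left, right),
        ring=extract_outer_ring(combined),
        frame_times_ms=times,
        config=config,
        magnitude=magnitude,
        envelope=envelope,
        pulse=pulse,
    )
    return magnitude, (left, right), truth


def bulk_plane_coefficients(
    bulk: BulkMotionParams,
    scheme: EncodingScheme,
    centroid: tuple[float, float],
    voxel_mm: float,
) -> np.ndarray:
    """Closed-form phase planes induced by the rigid bulk motion.

    Returns ``(n_frames, n_enc, 3)`` coefficients ``(slope_x, slope_y,
    intercept)`` in voxel coordinates centered at ``centroid`` (row, col).

    A translation ``delta`` adds the constant ``2*pi*ke*(e_i . delta)``.  A
    small in-plane rotation ``theta`` about the pivot displaces the tissue
    at in-plane offset ``(r_LR, r_AP)`` (mm, relative to the pivot) by
    ``(dAP, dLR) = theta * (r_LR, -r_AP)`` — the displacement field
    linearized at the pivot — which encodes to a plane with slopes
    ``2*pi*ke*voxel*theta*e_AP`` (per column) and
    ``-2*pi*ke*voxel*theta*e_LR`` (per row).
    """
    k = 2.0 * np.pi * scheme.ke
    cy, cx = centroid
    if bulk.pivot is None:
        py, px = cy, cx
    else:
        py, px = bulk.pivot
    n_frames = bulk.n_frames
    n_enc = scheme.n_directions
    coeffs = np.zeros((n_frames, n_enc, 3))
    for t in range(n_frames):
        theta = np.deg2rad(bulk.rotations_deg[t])
        delta = bulk.translations_mm[t]
        for e in range(n_enc):
            e_ap, e_lr, e_si = scheme.directions[e]
            slope_x = k * voxel_mm * theta * e_ap
            slope_y = -k * voxel_mm * theta * e_lr
            # intercept at the centroid: shift the pivot-centered plane
            intercept = (
                k * float(scheme.directions[e] @ delta)
                + slope_x * (cx - px)
                + slope_y * (cy - py)
            )
            coeffs[t, e] = (slope_x, slope_y, intercept)
    return coeffs


def _plane_images(coeffs: np.ndarray, centroid, shape) -> np.ndarray:
    """Evaluate (n_frames, n_enc, 3) plane coeffs on the image grid."""
    cy, cx = centroid
    ny, nx = shape
    Y, X = np.mgrid[0:ny, 0:nx]
    xc = X - cx
    yc = Y - cy
    return (
        coeffs[..., 0, None, None] * xc
        + coeffs[..., 1, None, None] * yc
        + coeffs[..., 2, None, None]
    )


def simulate_acquisition(
    truth: PhantomTruth,
    bulk: BulkMotionParams | None = None,
    scheme: EncodingScheme | None = None,
    config: PhantomConfig | None = None,
) -> ComplexSeries:
    """Encode the truth field into a wrapped, noisy complex series.

    Per voxel, frame t and encoding i the simulated phase is::

        encode(u(v,t), i) + plane_i(bulk_t)(v) + background(v)

    wrapped into (-pi, pi]; the magnitude is the phantom magnitude and
    complex Gaussian noise of SD ``config.noise_sd`` is added to the real
    and imaginary channels after wrapping.  Rotations beyond 5 degrees
    invalidate the linearized plane model and raise.
    """
    config = config or truth.config
    scheme = scheme or EncodingScheme(ke=config.ke)
    if bulk is None:
        bulk = BulkMotionParams.none(config.n_frames)
    if bulk.n_frames != config.n_frames:
        raise ValueError("bulk motion frame count does not match config")
    if np.any(np.abs(bulk.rotations_deg) > 5.0):
        raise ValueError("small-angle model invalid: rotation exceeds 5 degrees")
    if truth.u.shape[0] != config.n_frames or truth.u.shape[2:] != tuple(
        config.grid_size
    ):
        raise ValueError("truth/config shape mismatch")

    tissue = encode_series(truth.u, scheme)  # (n_enc, n_frames, ny, nx)
    coeffs = bulk_plane_coefficients(
        bulk, scheme, truth.ring.centroid, config.voxel_mm
    )
    planes = _plane_images(coeffs, truth.ring.centroid, config.grid_size)
    phase = tissue + np.moveaxis(planes, 0, 1)
    if config.background_phase is not None:
        bg = np.asarray(config.background_phase, dtype=float)
        if bg.shape != tuple(config.grid_size):
            raise ValueError("background_phase shape mismatch")
        phase = phase + bg

    z = truth.magnitude * np.exp(1j * wrap_to_pi(phase))
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        z = z + config.noise_sd * (
            rng.standard_normal(z.shape) + 1j * rng.standard_normal(z.shape)
        )
    truth.bulk_planes = coeffs
    return ComplexSeries(
        data=z,
        voxel_mm=config.voxel_mm,
        rr_ms=config.rr_ms,
        coverage_fraction=config.coverage_fraction,
    )


def generate_ppg(
    rr_mean_ms: float,
    rr_jitter_sd_ms: float = 0.0,
    n_beats: int = 64,
    seed: int = 0,
) -> PPGTrace:
    """Simulated PPG beat times with i.i.d. normal RR jitter.

    Successive RR intervals are drawn i.i.d. from
    ``Normal(rr_mean_ms, rr_jitter_sd_ms)``, truncated to stay positive
    (floored at 1 ms — only relevant for extreme jitter).
    """
    if n_beats < 3:
        raise ValueError("need at least 3 beats")
    rng = np.random.default_rng(seed)
    rr = np.full(n_beats - 1, float(rr_mean_ms))
    if rr_jitter_sd_ms > 0:
        rr = rng.normal(rr_mean_ms, rr_jitter_sd_ms, n_beats - 1)
        rr = np.maximum(rr, 1.0)
    beats = np.concatenate([[0.0], np.cumsum(rr)])
    return PPGTrace(beat_times_ms=beats)


def make_smooth_background(
    shape: tuple[int, int], amplitude: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Smooth static background phase map (low-order 2-D cosine mixture)."""
    ny, nx = shape
    rng = np.random.default_rng(seed)
    Y, X = np.mgrid[0:ny, 0:nx]
    xn = X / nx
    yn = Y / ny
    bg = np.zeros(shape, dtype=float)
    for fy in range(2):
        for fx in range(2):
            c = rng.uniform(-1.0, 1.0)
            ph = rng.uniform(0, 2 * np.pi)
            bg += c * np.cos(np.pi * (fx * xn + fy * yn) + ph)
    bg *= amplitude / max(np.abs(bg).max(), 1e-12)
    return bg
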