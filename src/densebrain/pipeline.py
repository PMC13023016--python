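"""Post-processing pipelines from complex DENSE series to displacement.

The Standard Pipeline turns the cardiac-gated complex image series into a
3-D displacement field in six stages:

1. background-phase removal — multiply every frame by the complex conjugate
   of the first frame of its series, cancelling static (non-motion) phase;
2. phase extraction;
3. 1-D temporal unwrapping per voxel;
4. linear interpolation of the acquired frames (10 by default) onto a finer
   cardiac grid (19 frames) followed by retrospective trimming: frames whose
   nominal time exceeds the measured mean RR interval (from the PPG trace)
   are dropped from the end of the cycle;
5. voxelwise linear detrending over time (constant-velocity bulk motion
   assumption) and referencing to the first frame, so displacement starts
   at zero;
6. least-squares decoding through the encoding matrix.

The Linear Fit pipeline additionally subtracts an OLS plane fitted to the
outer-ring phase, applied after detrending and referencing, just before
decoding.  The Complex Fit pipeline instead fits a wrap-invariant plane
right after temporal unwrapping — before interpolation, since interpolation
smears residual wraps and makes complex-domain subtraction ineffective — and
subtracts it in the complex domain, removing 2*pi ledges exactly; the
temporal unwrap is then re-run because complex subtraction returns phase
wrapped back into (-pi, pi].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.interpolate import interp1d

from .dispstats import DisplacementField
from .encoding import EncodingScheme, decode_series
from .metrics import PPGTrace
from .motion import (
    RingMask,
    apply_correction,
    extract_outer_ring,
    fit_plane_ols,
    fit_plane_wrapped,
)

__all__ = [
    "ComplexSeries",
    "PhaseSeries",
    "CardiacTiming",
    "PipelineResult",
    "remove_background_phase",
    "extract_phase",
    "unwrap_temporal",
    "interpolate_and_trim",
    "detrend_and_reference",
    "run_pipeline",
    "PIPELINE_MODES",
]

PIPELINE_MODES = ("standard", "linear_fit", "complex_fit")


def acquired_frame_times(n_frames: int, rr_ms: float, coverage: float) -> np.ndarray:
    """Nominal acquisition times: frame k at ``k * coverage * RR / n``.

    The frame spacing equals the protocol's temporal resolution
    (``coverage * RR / n_echoes``), so the train of n frames covers
    ``coverage`` of the prescribed cardiac cycle.
    """
    return np.arange(n_frames) * (coverage * rr_ms / n_frames)


def resample_linear(
    data: np.ndarray, times_in: np.ndarray, times_out: np.ndarray, axis: int = 0
) -> np.ndarray:
    """Linear resampling in time, with linear extrapolation at the ends."""
    f = interp1d(
        times_in, data, axis=axis, kind="linear", fill_value="extrapolate"
    )
    return f(times_out)


def detrend_reference_array(
    data: np.ndarray, times: np.ndarray, detrend: bool = True
) -> np.ndarray:
    """Subtract the per-voxel OLS line over time, then the frame-0 value.

    ``data`` has frames on axis 0.  Exactly linear, so it commutes with the
    (linear) encoding/decoding maps.
    """
    d = np.asarray(data, dtype=float)
    t = np.asarray(times, dtype=float)
    if detrend:
        tc = t - t.mean()
        denom = float(tc @ tc)
        mean = d.mean(axis=0)
        slope = np.tensordot(tc, d, axes=(0, 0)) / denom
        line = (
            tc.reshape((-1,) + (1,) * (d.ndim - 1)) * slope[None] + mean[None]
        )
        d = d - line
    return d - d[0]


@dataclass
class ComplexSeries:
    """Cardiac-gated complex images, one series per encoding direction.

    ``data`` has shape ``(n_enc, n_frames, ny, nx)``.  Timing metadata
    carries the prescription RR and the fraction of the cycle covered by the
    echo train.
    """

    data: np.ndarray
    voxel_mm: float = 4.0
    rr_ms: float = 1000.0
    coverage_fraction: float = 1.10

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4:
            raise ValueError("complex series must be (n_enc, n_frames, ny, nx)")
        if self.data.shape[1] < 1:
            raise ValueError("series needs at least one frame")

    @property
    def n_encodings(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def frame_times_ms(self) -> np.ndarray:
        return acquired_frame_times(
            self.n_frames, self.rr_ms, self.coverage_fraction
        )


@dataclass
class PhaseSeries:
    """Phase images with the same (encoding, frame) axes, radians."""

    data: np.ndarray
    wrapped: bool
    voxel_mm: float = 4.0
    rr_ms: float = 1000.0
    coverage_fraction: float = 1.10
    frame_times_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("phase series must be (n_enc, n_frames, ny, nx)")
        if self.frame_times_ms is None:
            self.frame_times_ms = acquired_frame_times(
                self.data.shape[1], self.rr_ms, self.coverage_fraction
            )
        else:
            self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def _like(self, data, wrapped, times=None) -> "PhaseSeries":
        return PhaseSeries(
            data=data,
            wrapped=wrapped,
            voxel_mm=self.voxel_mm,
            rr_ms=self.rr_ms,
            coverage_fraction=self.coverage_fraction,
            frame_times_ms=self.frame_times_ms if times is None else times,
        )


@dataclass
class CardiacTiming:
    """Prescription vs measured cardiac timing for interpolation/trimming."""

    rr_prescription_ms: float
    rr_measured_ms: float
    n_acquired_frames: int = 10
    n_interpolated_frames: int = 19
    coverage_fraction: float = 1.10

    def __post_init__(self) -> None:
        for name in (
            "rr_prescription_ms",
            "rr_measured_ms",
            "n_acquired_frames",
            "n_interpolated_frames",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coverage_fraction < 1:
            raise ValueError("coverage_fraction must be >= 1")


def remove_background_phase(series: ComplexSeries) -> ComplexSeries:
    """Multiply every frame by the conjugate of frame 0 of its series.

    Static background phase (receive-chain, off-resonance, encoding-gradient
    residuals) is common to all frames and cancels; frame 0's output phase
    becomes identically zero wherever tissue signal exists.  Voxels with
    zero frame-0 magnitude simply produce zero output.
    """
    ref = np.conj(series.data[:, :1])
    return ComplexSeries(
        data=series.data * ref,
        voxel_mm=series.voxel_mm,
        rr_ms=series.rr_ms,
        coverage_fraction=series.coverage_fraction,
    )


def extract_phase(series: ComplexSeries) -> PhaseSeries:
    """Wrapped phase in (-pi, pi] from the complex series."""
    return PhaseSeries(
        data=np.angle(series.data),
        wrapped=True,
        voxel_mm=series.voxel_mm,
        rr_ms=series.rr_ms,
        coverage_fraction=series.coverage_fraction,
    )


def unwrap_temporal(phase: PhaseSeries) -> PhaseSeries:
    """1-D phase unwrapping along the time axis, per voxel and encoding.

    ``phi'[0] = phi[0]; phi'[t] = phi'[t-1] + wrap_to_pi(phi[t] - phi[t-1])``
    — i.e. the smallest inter-frame change is assumed.  A true inter-frame
    jump beyond pi aliases by design (documented failure mode of any 1-D
    unwrap).
    """
    return phase._like(np.unwrap(phase.data, axis=1), wrapped=False)


def interpolate_and_trim(
    phase: PhaseSeries, timing: CardiacTiming
) -> PhaseSeries:
    """Interpolate acquired frames to the fine cardiac grid, then trim.

    The acquired window spans ``coverage * RR_prescription``; the output
    grid places ``n_interpolated_frames`` frames at
    ``j * coverage * RR / n_interpolated`` (same spacing convention as the
    acquisition).  Frames whose nominal time exceeds the measured mean RR
    are removed from the end of the cycle — this retrospectively corrects a
    mismatch between the heart rate at prescription and during the scan.
    """
    if phase.wrapped:
        raise ValueError("interpolate_and_trim expects unwrapped phase")
    if phase.n_frames != timing.n_acquired_frames:
        raise ValueError(
            f"expected {timing.n_acquired_frames} acquired frames, "
            f"got {phase.n_frames}"
        )
    window = timing.coverage_fraction * timing.rr_prescription_ms
    times_in = phase.frame_times_ms
    times_out = np.arange(timing.n_interpolated_frames) * (
        window / timing.n_interpolated_frames
    )
    data = resample_linear(phase.data, times_in, times_out, axis=1)
    keep = times_out <= timing.rr_measured_ms
    if keep.sum() < 2:
        raise ValueError(
            "measured RR too short: fewer than 2 frames remain after trimming"
        )
    return phase._like(data[:, keep], wrapped=False, times=times_out[keep])


def detrend_and_reference(phase: PhaseSeries) -> PhaseSeries:
    """Voxelwise linear detrend over time, then reference to frame 0.

    The full OLS line (slope and intercept) is subtracted per voxel and
    encoding; re-referencing to the first frame then makes the intercept
    choice irrelevant and forces frame 0 to be identically zero.  With
    fewer than 3 frames the detrend is skipped (warning) but referencing is
    still applied.
    """
    if phase.wrapped:
        raise ValueError("detrend_and_reference expects unwrapped phase")
    detrend = phase.n_frames >= 3
    if not detrend:
        warnings.warn(
            "fewer than 3 frames: linear detrend skipped, referencing only",
            stacklevel=2,
        )
    out = np.moveaxis(
        detrend_reference_array(
            np.moveaxis(phase.data, 1, 0), phase.frame_times_ms, detrend=detrend
        ),
        0,
        1,
    )
    return phase._like(out, wrapped=False)


@dataclass
class PipelineResult:
    """Displacement field plus the corrected phase and fit audit trail."""

    field: DisplacementField
    phase: PhaseSeries
    fits: list = dc_field(default_factory=list)
    timing: CardiacTiming | None = None
    mode: str = "standard"


def _measured_rr(ppg, default: float) -> float:
    if ppg is None:
        return default
    if isinstance(ppg, PPGTrace):
        return ppg.mean_rr_ms
    if np.isscalar(ppg):
        return float(ppg)
    return PPGTrace(np.asarray(ppg, dtype=float)).mean_rr_ms


def _correct_series(phase, ring, mode, fit_options, audit):
    """Plane-fit and subtract bulk motion per (encoding, frame) image."""
    fit_options = fit_options or {}
    data = phase.data.copy()
    for e in range(data.shape[0]):
        for t in range(data.shape[1]):
            if mode == "complex_fit":
                fit = fit_plane_wrapped(data[e, t], ring, **fit_options)
                data[e, t] = apply_correction(data[e, t], fit, ring, "complex")
            else:
                fit = fit_plane_ols(data[e, t], ring)
                data[e, t] = apply_correction(data[e, t], fit, ring, "real")
            audit.append(
                {
                    "encoding": e,
                    "frame": t,
                    "slope_x": fit.slope_x,
                    "slope_y": fit.slope_y,
                    "intercept": fit.intercept,
                    "objective": fit.objective,
                    "method": fit.method,
                    "converged": fit.converged,
                }
            )
    return data


def run_pipeline(
    series: ComplexSeries,
    masks=None,
    ppg=None,
    mode: str = "standard",
    scheme: EncodingScheme | None = None,
    n_interpolated_frames: int = 19,
    fit_options: dict | None = None,
) -> PipelineResult:
    """Run one of the three post-processing pipelines end to end.

    Parameters
    ----------
    series:
        Raw complex series, ``(n_enc, n_frames, ny, nx)``.
    masks:
        ``(left, right)`` hemisphere masks; required for the two
        motion-correcting modes (the outer ring of their union is the fit
        region) and for the attached field masks.
    ppg:
        Beat times (ms), a :class:`~densebrain.metrics.PPGTrace`, or a
        scalar measured mean RR in ms; defaults to the prescription RR.
    mode:
        ``"standard"``, ``"linear_fit"`` or ``"complex_fit"``.
    """
    if mode not in PIPELINE_MODES:
        raise ValueError(f"unknown pipeline mode {mode!r}")
    scheme = scheme or EncodingScheme()
    if series.n_encodings != scheme.n_directions:
        raise ValueError("series encoding count does not match scheme")

    ring: RingMask | None = None
    if masks is not None:
        left, right = masks
        combined = np.asarray(left, dtype=bool) | np.asarray(right, dtype=bool)
        if combined.shape != series.data.shape[2:]:
            raise ValueError("mask/series shape mismatch")
        ring = extract_outer_ring(combined)
    elif mode in ("linear_fit", "complex_fit"):
        raise ValueError(f"{mode} mode requires hemisphere masks")

    timing = CardiacTiming(
        rr_prescription_ms=series.rr_ms,
        rr_measured_ms=_measured_rr(ppg, series.rr_ms),
        n_acquired_frames=series.n_frames,
        n_interpolated_frames=n_interpolated_frames,
        coverage_fraction=series.coverage_fraction,
    )

    audit: list[dict] = []
    phase = unwrap_temporal(extract_phase(remove_background_phase(series)))

    if mode == "complex_fit":
        corrected = _correct_series(phase, ring, mode, fit_options, audit)
        # complex-domain subtraction returns wrapped phase; restore temporal
        # continuity before interpolation
        phase = unwrap_temporal(phase._like(corrected, wrapped=True))

    phase = detrend_and_reference(interpolate_and_trim(phase, timing))

    if mode == "linear_fit":
        corrected = _correct_series(phase, ring, mode, fit_options, audit)
        phase = phase._like(corrected, wrapped=False)

    u = decode_series(phase.data, scheme)
    field = DisplacementField(
        data=u,
        frame_times_ms=phase.frame_times_ms,
        masks=masks,
        voxel_mm=series.voxel_mm,
        axis_labels=scheme.axis_labels,
    )
    return PipelineResult(
        field=field, phase=phase, fits=audit, timing=timing, mode=mode
    )
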