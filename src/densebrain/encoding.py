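"""Displacement encoding for DENSE MRI.

DENSE (Displacement ENcoding with Stimulated Echoes) stores tissue
displacement accumulated during the mixing period in the phase of the
reconstructed image.  A voxel that moves by ``u`` (mm) between tagging and
readout acquires a phase of ``2*pi*ke*(e_i . u)`` radians in the series
encoded along unit direction ``e_i``, where ``ke`` is the encoding frequency
in cycles/mm.  The reciprocal ``1/ke`` is the displacement sensitivity in
mm per phase cycle (0.495 mm/cycle at the default ke = 2.02).

The default scheme is the balanced four-point set: four tetrahedral unit
directions plus their negations from phase cycling, eight acquired series in
total.  Displacement is recovered per voxel by least squares across all
encoded directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EncodingScheme",
    "build_encoding_matrix",
    "encode_displacement",
    "encode_series",
    "decode_phase",
    "decode_series",
]

_TETRAHEDRAL = np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]
) / np.sqrt(3.0)

#: Balanced four-point directions with phase cycling (the four tetrahedral
#: unit vectors and their negations), in acquisition order.
DEFAULT_DIRECTIONS = np.vstack([_TETRAHEDRAL, -_TETRAHEDRAL])

DEFAULT_AXIS_LABELS = ("A/P", "L/R", "S/I")


@dataclass(frozen=True)
class EncodingScheme:
    """Displacement-encoding scheme: frequency, directions, axis labels.

    Parameters
    ----------
    ke:
        Encoding frequency in cycles/mm. Must be positive.
    directions:
        ``(n_enc, 3)`` array of unit vectors, components ordered as
        ``axis_labels``. The stacked matrix must have rank 3 so that a 3-D
        displacement is recoverable.
    axis_labels:
        Anatomical axis names for the three vector components.
    """

    ke: float = 2.02
    directions: np.ndarray = field(
        default_factory=lambda: DEFAULT_DIRECTIONS.copy()
    )
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        dirs = np.asarray(self.directions, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError("directions must be an (n_enc, 3) array")
        norms = np.linalg.norm(dirs, axis=1)
        if not np.all(np.abs(norms - 1.0) <= 1e-12):
            raise ValueError("every encoding direction must have unit norm")
        if self.ke <= 0:
            raise ValueError("encoding frequency ke must be positive")
        object.__setattr__(self, "directions", dirs)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    @property
    def sensitivity_mm_per_cycle(self) -> float:
        """Displacement producing one full phase cycle (mm/cycle)."""
        return 1.0 / self.ke

    def to_dict(self) -> dict:
        return {
            "ke": float(self.ke),
            "directions": [[float(c) for c in d] for d in self.directions],
            "axis_labels": list(self.axis_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingScheme":
        return cls(
            ke=d.get("ke", 2.02),
            directions=np.asarray(d["directions"], dtype=float)
            if "directions" in d
            else DEFAULT_DIRECTIONS.copy(),
            axis_labels=tuple(d.get("axis_labels", DEFAULT_AXIS_LABELS)),
        )


def build_encoding_matrix(scheme: EncodingScheme) -> tuple[np.ndarray, np.ndarray]:
    """Return the encoding matrix and its Moore-Penrose pseudo-inverse.

    Row ``i`` of the returned matrix is encoding direction ``i``. The
    pseudo-inverse is what :func:`decode_phase` applies, so
    ``E @ pinv(E) @ E == E`` to machine precision.

    Raises
    ------
    ValueError
        If the direction matrix has rank < 3 ("degenerate encoding scheme").
    """
    E = np.asarray(scheme.directions, dtype=float).copy()
    if np.linalg.matrix_rank(E) < 3:
        raise ValueError("degenerate encoding scheme: direction matrix rank < 3")
    return E, np.linalg.pinv(E)


def encode_displacement(
    u, scheme: EncodingScheme, direction_index: int
) -> float:
    """Phase (radians) encoded along direction ``direction_index`` by
    displacement ``u`` (3-vector, mm).

    No wrapping is applied; wrapping is the acquisition's (or the
    simulator's) job.
    """
    u = np.asarray(u, dtype=float)
    if not 0 <= direction_index < scheme.n_directions:
        raise IndexError("direction_index out of range")
    return float(
        2.0 * np.pi * scheme.ke * scheme.directions[direction_index] @ u
    )


def encode_series(u: np.ndarray, scheme: EncodingScheme) -> np.ndarray:
    """Encode a displacement field into per-direction phase images.

    Parameters
    ----------
    u:
        Array with the 3-vector on axis 1, shape ``(n_frames, 3, ny, nx)``
        (or any ``(..., 3, ny, nx)``), in mm.

    Returns
    -------
    ``(n_enc, n_frames, ny, nx)`` unwrapped phase in radians.
    """
    u = np.asarray(u, dtype=float)
    # (n_enc, 3) . (n_frames, 3, ny, nx) -> (n_enc, n_frames, ny, nx)
    phases = np.einsum("ec,tcyx->etyx", scheme.directions, u)
    return 2.0 * np.pi * scheme.ke * phases


def decode_phase(phases, scheme: EncodingScheme) -> np.ndarray:
    """Least-squares displacement (mm) from the per-direction phases.

    Solves ``u = (1/(2*pi*ke)) * pinv(E) @ phi`` so that
    ``decode(encode(u)) == u`` for any ``u``.
    """
    phi = np.asarray(phases, dtype=float)
    if phi.shape[0] != scheme.n_directions:
        raise ValueError(
            f"expected {scheme.n_directions} phases, got {phi.shape[0]}"
        )
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite phase input")
    _, pinv = build_encoding_matrix(scheme)
    return (pinv @ phi) / (2.0 * np.pi * scheme.ke)


def decode_series(phases: np.ndarray, scheme: EncodingScheme) -> np.ndarray:
    """Voxelwise least-squares decode of a phase series.

    Parameters
    ----------
    phases:
        ``(n_enc, n_frames, ny, nx)`` unwrapped phase, radians.

    Returns
    -------
    ``(n_frames, 3, ny, nx)`` displacement in mm.
    """
    phi = np.asarray(phases, dtype=float)
    if phi.shape[0] != scheme.n_directions:
        raise ValueError(
            f"expected {scheme.n_directions} encodings, got {phi.shape[0]}"
        )
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite phase input")
    _, pinv = build_encoding_matrix(scheme)
    u = np.einsum("ce,etyx->tcyx", pinv, phi)
    return u / (2.0 * np.pi * scheme.ke)
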