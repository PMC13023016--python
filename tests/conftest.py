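"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from densebrain import (
    EncodingScheme,
    PhantomConfig,
    extract_outer_ring,
    generate_phantom,
)


@pytest.fixture(scope="session")
def scheme() -> EncodingScheme:
    return EncodingScheme()


@pytest.fixture(scope="session")
def phantom_default():
    """Default noiseless phantom: (config, magnitude, masks, truth)."""
    config = PhantomConfig()
    magnitude, masks, truth = generate_phantom(config)
    return config, magnitude, masks, truth


@pytest.fixture(scope="session")
def small_ring():
    """16x16 disk mask and its outer ring, for plane-fit oracle tests."""
    Y, X = np.mgrid[0:16, 0:16]
    mask = (X - 7.5) ** 2 + (Y - 7.5) ** 2 <= 7.0**2
    return extract_outer_ring(mask)


def brute_force_wrapped_min(
    phase: np.ndarray,
    ring,
    n_slope: int = 61,
    n_intercept: int = 64,
    levels: int = 7,
) -> tuple[np.ndarray, float]:
    """Exhaustive zooming-grid minimizer of the wrap-invariant objective.

    Independent of the package's fitter: evaluates
    J(a,b,c) = sum(1 - cos(phi - a*x - b*y - c)) on successively refined
    exhaustive grids (each level zooms into +-2 steps around the argmin).
    Returns (coeffs, J).
    """
    x, y = ring.coords()
    phi = np.asarray(phase, dtype=float)[ring.ring]
    n = len(phi)
    rx, ry = ring.half_extents()
    a_lo, a_hi = -np.pi / rx, np.pi / rx
    b_lo, b_hi = -np.pi / ry, np.pi / ry
    c_lo, c_hi = -np.pi, np.pi
    best = None
    for _ in range(levels):
        a = np.linspace(a_lo, a_hi, n_slope)
        b = np.linspace(b_lo, b_hi, n_slope)
        c = np.linspace(c_lo, c_hi, n_intercept)
        r = (
            phi[None, None, :]
            - a[:, None, None] * x[None, None, :]
            - b[None, :, None] * y[None, None, :]
        )
        C = np.cos(r).sum(axis=-1)
        S = np.sin(r).sum(axis=-1)
        J = n - (
            np.cos(c)[None, None, :] * C[..., None]
            + np.sin(c)[None, None, :] * S[..., None]
        )
        ia, ib, ic = np.unravel_index(np.argmin(J), J.shape)
        best = (np.array([a[ia], b[ib], c[ic]]), float(J[ia, ib, ic]))
        da = (a_hi - a_lo) / (n_slope - 1)
        db = (b_hi - b_lo) / (n_slope - 1)
        dc = (c_hi - c_lo) / (n_intercept - 1)
        a_lo, a_hi = a[ia] - 2 * da, a[ia] + 2 * da
        b_lo, b_hi = b[ib] - 2 * db, b[ib] + 2 * db
        c_lo, c_hi = c[ic] - 2 * dc, c[ic] + 2 * dc
    return best


@pytest.fixture(scope="session")
def brute_wrapped_oracle():
    return brute_force_wrapped_min
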