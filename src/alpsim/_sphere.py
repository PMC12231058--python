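"""Deterministic unit-vector sets on the sphere.

Diffusion gradient tables and orientation-distribution quadratures both need
reasonably uniform direction sets.  A spherical Fibonacci lattice is used
throughout: it is deterministic, cheap, and uniform enough for the quadrature
and gradient-scheme purposes here (no electrostatic optimisation is needed).
"""

from __future__ import annotations

import numpy as np

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def fibonacci_sphere(n: int) -> np.ndarray:
    """Return ``n`` approximately uniform unit vectors on the full sphere."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = 2.0 * np.pi * i / _GOLDEN
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """``n`` roughly uniform directions on the upper hemisphere (z >= 0).

    Used for gradient schemes, where antipodal directions are redundant.
    """
    full = fibonacci_sphere(2 * n)
    upper = full[full[:, 2] >= 0.0]
    if len(upper) >= n:
        return upper[:n]
    # pad from the lower hemisphere, sign-flipped (rare off-by-one cases)
    lower = -full[full[:, 2] < 0.0]
    return np.vstack([upper, lower[: n - len(upper)]])


def symmetric_quadrature(n_half: int = 362) -> tuple[np.ndarray, np.ndarray]:
    """Antipodally symmetric quadrature: ``2*n_half`` points, equal weights.

    Returns (points, weights); weights sum to 1 (i.e. quadrature of the
    uniform density over the sphere returns the mean of the integrand).
    """
    half = fibonacci_sphere(2 * n_half)[:n_half]
    pts = np.vstack([half, -half])
    w = np.full(len(pts), 1.0 / len(pts))
    return pts, w


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
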