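"""Fiber-orientation distributions in spherical-harmonic form and their peaks.

FODs are antipodally symmetric spherical functions; their local maxima mark
fiber populations.  This module evaluates real even-order SH expansions,
extracts up to three peaks per voxel by seeded gradient ascent, and derives
the crossing metrics used to characterise white-matter regions: the
single-fiber fraction, the crossing angle between the two largest peaks
(folded to [0, 90] deg), and the crossing fraction (relative weight of
non-dominant peaks).

Basis dialect: the canonical internal ordering is l = 0, 2, ..., lmax with
m = -l..l inside each l, where the m < 0 functions are sqrt(2) * Im(Y_l^|m|)
and m > 0 are sqrt(2) * (-1)^m-free Re(Y_l^m) (no Condon-Shortley sign; see
``sh_basis``).  A second dialect ("imag-last") with the m < 0 / m > 0 blocks
swapped is accepted via ``convert_dialect`` — the two common conventions
differ exactly this way and silently disagree if mixed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._sphere import fibonacci_sphere
from .io_formats import ROILabelMap

__all__ = [
    "SHImage",
    "PeakSet",
    "sh_basis",
    "sh_eval",
    "synthesize_sh",
    "find_peaks",
    "crossing_metrics",
    "convert_dialect",
    "n_coefficients",
    "CANONICAL_DIALECT",
]

CANONICAL_DIALECT = "real-sym"


def n_coefficients(lmax: int) -> int:
    """Number of real even-order SH coefficients: (lmax+1)(lmax+2)/2."""
    if lmax < 0 or lmax % 2:
        raise ValueError("lmax must be a non-negative even integer")
    return (lmax + 1) * (lmax + 2) // 2


def _lm_pairs(lmax: int):
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def sh_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Real symmetric SH basis matrix (n_dirs, n_coefficients).

    Functions: m = 0 -> Re(Y_l^0); m > 0 -> sqrt(2) Re(Y_l^m);
    m < 0 -> sqrt(2) Im(Y_l^|m|); even l only (antipodal symmetry).
    """
    from scipy.special import sph_harm_y

    d = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero direction vector")
    d = d / norms
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(d[:, 1], d[:, 0])  # azimuth
    cols = []
    for l, m in _lm_pairs(lmax):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m == 0:
            cols.append(y.real)
        elif m > 0:
            cols.append(np.sqrt(2.0) * y.real)
        else:
            cols.append(np.sqrt(2.0) * y.imag)
    return np.column_stack(cols)


@dataclasses.dataclass
class SHImage:
    """Per-voxel real even-order SH coefficients with a dialect tag."""

    coeffs: np.ndarray  # (..., n_coefficients)
    lmax: int
    dialect: str = CANONICAL_DIALECT

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        expected = n_coefficients(self.lmax)
        if self.coeffs.shape[-1] != expected:
            raise ValueError(
                f"lmax={self.lmax} needs {expected} coefficients, "
                f"got {self.coeffs.shape[-1]}"
            )


def convert_dialect(sh: SHImage, to: str = CANONICAL_DIALECT) -> SHImage:
    """Convert between the "real-sym" and "imag-last" coefficient orderings
    (the m < 0 and m > 0 blocks of each l are swapped between the two)."""
    known = (CANONICAL_DIALECT, "imag-last")
    if sh.dialect not in known or to not in known:
        raise ValueError(f"unknown SH dialect (known: {known})")
    if sh.dialect == to:
        return sh
    perm = []
    off = 0
    for l in range(0, sh.lmax + 1, 2):
        n = 2 * l + 1
        block = list(range(off, off + n))
        # reverse the m ordering within the block: m -> -m
        perm.extend(block[::-1])
        off += n
    return SHImage(sh.coeffs[..., perm], sh.lmax, to)


def sh_eval(sh: SHImage | np.ndarray, directions: np.ndarray, lmax: int | None = None) -> np.ndarray:
    """Evaluate the SH expansion at unit directions -> (..., n_dirs)."""
    if isinstance(sh, SHImage):
        if sh.dialect != CANONICAL_DIALECT:
            raise ValueError(
                f"dialect {sh.dialect!r} must be converted to "
                f"{CANONICAL_DIALECT!r} before evaluation"
            )
        coeffs, lmax = sh.coeffs, sh.lmax
    else:
        coeffs = np.asarray(sh, dtype=float)
        if lmax is None:
            raise ValueError("lmax required when passing a bare coefficient array")
    B = sh_basis(directions, lmax)
    return coeffs @ B.T


def synthesize_sh(
    directions: np.ndarray,
    fractions: np.ndarray,
    lmax: int = 8,
    kernel_kappa: float = 20.0,
) -> SHImage:
    """SH coefficients of planted fiber orientations.

    Each fiber contributes an axially symmetric Watson-like lobe
    exp(kappa ((u.d)^2 - 1)) scaled by its fraction; coefficients come from a
    least-squares projection on a dense sphere sampling.  This stands in for
    a CSD output with known ground truth.
    """
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    fr = np.atleast_1d(np.asarray(fractions, dtype=float))
    if len(fr) != len(dirs):
        raise ValueError("one fraction per direction required")
    sample = fibonacci_sphere(1600)
    f = np.zeros(len(sample))
    for d, w in zip(dirs, fr):
        f += w * np.exp(kernel_kappa * ((sample @ d) ** 2 - 1.0))
    B = sh_basis(sample, lmax)
    coeffs, *_ = np.linalg.lstsq(B, f, rcond=None)
    return SHImage(coeffs, lmax)


@dataclasses.dataclass
class PeakSet:
    """Up to three amplitude-sorted peaks per voxel (unit directions)."""

    directions: np.ndarray  # (..., 3 peaks, 3)
    amplitudes: np.ndarray  # (..., 3), zero-padded
    n_peaks: np.ndarray  # (...,) int

    @property
    def max_peaks(self) -> int:
        return self.directions.shape[-2]


def _local_maxima_candidates(amp: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """amp (V, S); neighbors (S, k) index array -> bool (V, S) local maxima."""
    neigh_amp = amp[:, neighbors]  # (V, S, k)
    return amp >= neigh_amp.max(axis=2)


_SEED_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _seed_set(n_seeds: int) -> tuple[np.ndarray, np.ndarray]:
    """Hemisphere seed directions and their k-nearest (antipodally folded)
    neighbor index table, cached per size."""
    if n_seeds not in _SEED_CACHE:
        seeds = fibonacci_sphere(2 * n_seeds)
        seeds = seeds[seeds[:, 2] >= 0.0][:n_seeds]
        cosim = np.abs(seeds @ seeds.T)
        np.fill_diagonal(cosim, -1.0)
        k = min(6, n_seeds - 1)
        neighbors = np.argsort(-cosim, axis=1)[:, :k]
        _SEED_CACHE[n_seeds] = (seeds, neighbors)
    return _SEED_CACHE[n_seeds]


def _tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.where(np.abs(u[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    return e1, e2


def _refine_on_sphere(coeffs: np.ndarray, u0: np.ndarray, lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Batched projected gradient ascent of per-row SH functions.

    coeffs (M, C) paired row-by-row with start directions u0 (M, 3).
    """
    u = u0.copy()
    step = np.full(len(u), 0.1)
    h = 1e-4
    f = np.einsum("mc,mc->m", coeffs, sh_basis(u, lmax))
    for _ in range(60):
        e1, e2 = _tangent_basis(u)
        fp1 = np.einsum("mc,mc->m", coeffs, sh_basis(u + h * e1, lmax))
        fm1 = np.einsum("mc,mc->m", coeffs, sh_basis(u - h * e1, lmax))
        fp2 = np.einsum("mc,mc->m", coeffs, sh_basis(u + h * e2, lmax))
        fm2 = np.einsum("mc,mc->m", coeffs, sh_basis(u - h * e2, lmax))
        g1 = (fp1 - fm1) / (2 * h)
        g2 = (fp2 - fm2) / (2 * h)
        gnorm = np.hypot(g1, g2)
        if np.all(step * gnorm < 1e-7):
            break
        cand = u + (step * g1)[:, None] * e1 + (step * g2)[:, None] * e2
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        fc = np.einsum("mc,mc->m", coeffs, sh_basis(cand, lmax))
        better = fc > f
        u[better] = cand[better]
        f[better] = fc[better]
        step = np.where(better, np.minimum(step * 1.2, 0.2), step * 0.5)
    return u, f


def find_peaks(
    sh: SHImage,
    n_seeds: int = 64,
    min_sep_deg: float = 15.0,
    rel_threshold: float = 0.05,
    max_peaks: int = 3,
) -> PeakSet:
    """Extract up to ``max_peaks`` FOD peaks per voxel.

    Seeds on a uniform hemisphere tessellation, keeps local maxima, refines
    them by gradient ascent on the sphere, merges antipodes/near-duplicates
    (closer than ``min_sep_deg``), and discards peaks below
    ``rel_threshold`` x the voxel's largest peak amplitude.
    """
    if sh.dialect != CANONICAL_DIALECT:
        sh = convert_dialect(sh)
    coeffs = sh.coeffs.reshape(-1, sh.coeffs.shape[-1])
    V = coeffs.shape[0]
    seeds, neighbors = _seed_set(n_seeds)
    amp = coeffs @ sh_basis(seeds, sh.lmax).T  # (V, S)
    vox_max = amp.max(axis=1)
    nonzero = vox_max > 1e-12

    is_cand = _local_maxima_candidates(amp, neighbors)
    is_cand &= amp > 0.25 * rel_threshold * np.maximum(vox_max, 1e-300)[:, None]
    is_cand &= nonzero[:, None]

    vox_idx, seed_idx = np.nonzero(is_cand)
    out_dirs = np.zeros((V, max_peaks, 3))
    out_amps = np.zeros((V, max_peaks))
    out_n = np.zeros(V, dtype=int)
    if len(vox_idx):
        u, f = _refine_on_sphere(coeffs[vox_idx], seeds[seed_idx], sh.lmax)
        cos_sep = np.cos(np.deg2rad(min_sep_deg))
        for v in np.unique(vox_idx):
            rows = np.nonzero(vox_idx == v)[0]
            order = rows[np.argsort(-f[rows])]
            kept: list[int] = []
            for r in order:
                if f[r] < rel_threshold * f[order[0]] or f[r] <= 0:
                    continue
                if all(abs(u[r] @ u[k]) < cos_sep for k in kept):
                    kept.append(r)
                if len(kept) == max_peaks:
                    break
            for i, r in enumerate(kept):
                out_dirs[v, i] = u[r]
                out_amps[v, i] = f[r]
            out_n[v] = len(kept)

    spatial = sh.coeffs.shape[:-1]
    return PeakSet(
        directions=out_dirs.reshape(spatial + (max_peaks, 3)),
        amplitudes=out_amps.reshape(spatial + (max_peaks,)),
        n_peaks=out_n.reshape(spatial),
    )


def crossing_metrics(peaks: PeakSet, rois: ROILabelMap | None = None, labels=None):
    """Per-ROI single-fiber fraction, mean crossing angle, crossing fraction.

    Crossing angle = angle between the two largest peaks, folded to
    [0, 90] deg, averaged over multi-peak voxels (NaN if none).  Crossing
    fraction = mean over peaked voxels of (sum of non-dominant amplitudes) /
    (sum of all amplitudes).
    """
    import pandas as pd

    n = peaks.n_peaks
    amps = peaks.amplitudes
    dirs = peaks.directions
    with np.errstate(invalid="ignore", divide="ignore"):
        dot = np.abs(np.einsum("...i,...i->...", dirs[..., 0, :], dirs[..., 1, :]))
        angle = np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))
        amp_tot = amps.sum(axis=-1)
        cross_frac = np.where(
            amp_tot > 0, (amp_tot - amps[..., 0]) / np.where(amp_tot > 0, amp_tot, 1), np.nan
        )

    if rois is None:
        label_iter = [(0, "all", np.ones(n.shape, dtype=bool))]
    else:
        use = labels if labels is not None else rois.present_labels
        label_iter = [
            (lab, rois.name_table.get(int(lab), str(lab)), rois.labels == lab)
            for lab in use
        ]
    rows = []
    for lab, name, m in label_iter:
        valid = m & (n > 0)
        multi = m & (n >= 2)
        row = {
            "label": int(lab),
            "name": name,
            "n_voxels": int(valid.sum()),
            "flagged_empty": bool(valid.sum() == 0),
        }
        if valid.sum() == 0:
            row.update(
                single_fiber_fraction=np.nan,
                crossing_angle_deg=np.nan,
                crossing_fraction=np.nan,
            )
        else:
            row["single_fiber_fraction"] = float((n[valid] == 1).mean())
            row["crossing_angle_deg"] = (
                float(angle[multi].mean()) if multi.any() else np.nan
            )
            row["crossing_fraction"] = float(np.nanmean(cross_frac[valid]))
        rows.append(row)
    return pd.DataFrame(rows)
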