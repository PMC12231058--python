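"""Vessel orientation from 3D intensity volumes via multiscale Hessian analysis.

The Frangi vesselness filter scores how tubular the local intensity
structure is from the eigenvalues of the scale-normalised Hessian
(|h1| <= |h2| <= |h3|; note these are image-Hessian eigenvalues, unrelated
to diffusion-tensor eigenvalues).  For a tube, h1 ~ 0 along the axis and
h2 ~ h3 across it, so the eigenvector of the smallest-|h| eigenvalue at the
best-responding scale estimates the vessel axis.  Orientations are axial
data (sign-ambiguous): every comparison folds angles to [0, 90] deg, and
block-averaging uses the mean outer product (orientation tensor) rather
than the mean vector.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import ROILabelMap, VolumeImage
from .tensor_metrics import TensorField

__all__ = [
    "OrientationField",
    "frangi_vesselness",
    "angular_difference",
    "downsample_orientations",
    "alps_assumption_report",
    "RL_AXIS",
]

RL_AXIS = np.array([1.0, 0.0, 0.0])  # right-left = image x


@dataclasses.dataclass
class OrientationField:
    """Per-voxel unit axis (sign-ambiguous) + validity mask + confidence."""

    vectors: np.ndarray  # (..., 3)
    mask: np.ndarray  # (...,) bool
    confidence: np.ndarray | None = None  # e.g. vesselness

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        norms = np.linalg.norm(self.vectors[self.mask], axis=-1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("orientation vectors must be unit-norm on the mask")

    @staticmethod
    def constant(axis, shape) -> "OrientationField":
        v = np.asarray(axis, dtype=float)
        v = v / np.linalg.norm(v)
        return OrientationField(
            np.broadcast_to(v, tuple(shape) + (3,)).copy(),
            np.ones(shape, dtype=bool),
        )


def _hessian_eigensystem(vol: np.ndarray, sigma_vox: np.ndarray, voxel_mm: np.ndarray):
    """Hessian (per mm^2) eigenvalues/vectors sorted by |h1| <= |h2| <= |h3|."""
    axes = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    H = np.empty(vol.shape + (3, 3))
    for a, b in axes:
        order = [0, 0, 0]
        order[a] += 1
        order[b] += 1
        d = gaussian_filter(vol, sigma=sigma_vox, order=order, mode="nearest")
        d /= voxel_mm[a] * voxel_mm[b]  # voxel-index -> physical derivatives
        H[..., a, b] = d
        H[..., b, a] = d
    evals, evecs = np.linalg.eigh(H)
    order = np.argsort(np.abs(evals), axis=-1)
    evals = np.take_along_axis(evals, order, axis=-1)
    evecs = np.take_along_axis(evecs, order[..., None, :], axis=-1)
    return evals, evecs


def frangi_vesselness(
    vol: VolumeImage,
    scales_mm=(0.5, 1.0, 1.5),
    alpha: float = 0.5,
    beta: float = 0.5,
    c: float | None = None,
    polarity: str = "dark",
) -> tuple[np.ndarray, OrientationField]:
    """Multiscale Frangi vesselness plus the vessel-axis orientation field.

    Dark polarity (SWI veins are dark on a bright background) expects the
    two large Hessian eigenvalues to be positive.  The orientation per voxel
    is the smallest-|eigenvalue| Hessian eigenvector at the scale of maximal
    response; ``c`` defaults to half the maximum Hessian norm per scale.
    """
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    data = np.asarray(vol.data, dtype=float)
    if data.ndim != 3:
        raise ValueError("vesselness expects a 3D volume")
    voxel = np.asarray(vol.voxel_size, dtype=float)
    best_v = np.zeros(data.shape)
    best_dir = np.zeros(data.shape + (3,))
    for scale in scales_mm:
        sigma_vox = np.maximum(scale / voxel, 0.0)
        if np.any(sigma_vox < 0.5):
            warnings.warn(
                f"scale {scale} mm is below the voxel size; clamping", stacklevel=2
            )
            sigma_vox = np.maximum(sigma_vox, 0.5)
        evals, evecs = _hessian_eigensystem(data, sigma_vox, voxel)
        evals = evals * scale**2  # gamma = 2 scale normalisation
        h1, h2, h3 = evals[..., 0], evals[..., 1], evals[..., 2]
        a2, a3 = np.abs(h2), np.abs(h3)
        with np.errstate(divide="ignore", invalid="ignore"):
            ra = a2 / np.where(a3 > 0, a3, np.inf)
            rb = np.abs(h1) / np.where(a2 * a3 > 0, np.sqrt(a2 * a3), np.inf)
        s = np.sqrt((evals**2).sum(axis=-1))
        cc = 0.5 * s.max() if c is None else c
        if cc <= 0:
            v = np.zeros_like(s)
        else:
            v = (
                (1.0 - np.exp(-(ra**2) / (2 * alpha**2)))
                * np.exp(-(rb**2) / (2 * beta**2))
                * (1.0 - np.exp(-(s**2) / (2 * cc**2)))
            )
        sign_ok = (h2 > 0) & (h3 > 0) if polarity == "dark" else (h2 < 0) & (h3 < 0)
        v = np.where(sign_ok, v, 0.0)
        upd = v > best_v
        best_v = np.where(upd, v, best_v)
        best_dir[upd] = evecs[..., :, 0][upd]
    mask = best_v > 0
    norms = np.linalg.norm(best_dir, axis=-1)
    safe = norms > 0
    best_dir[safe] /= norms[safe][..., None]
    best_dir[~safe] = [1.0, 0.0, 0.0]
    field = OrientationField(best_dir, mask & safe, confidence=best_v)
    return best_v, field


def angular_difference(
    a: OrientationField, b: OrientationField | np.ndarray
) -> np.ndarray:
    """Per-voxel acute angle (deg) between two axial fields (or a fixed axis).

    Sign-invariant: arccos(|a.b|) in [0, 90].  NaN outside the mask
    intersection; an empty intersection raises.
    """
    va = a.vectors
    if isinstance(b, OrientationField):
        vb = b.vectors
        mask = a.mask & b.mask
    else:
        axis = np.asarray(b, dtype=float)
        axis = axis / np.linalg.norm(axis)
        vb = np.broadcast_to(axis, va.shape)
        mask = a.mask
    if not mask.any():
        raise ValueError("empty mask intersection between orientation fields")
    dot = np.abs(np.einsum("...i,...i->...", va, vb))
    ang = np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))
    return np.where(mask, ang, np.nan)


def downsample_orientations(field: OrientationField, factor: int) -> OrientationField:
    """Block-average an axial field by orientation-tensor (outer-product)
    averaging; the principal eigenvector of each block's mean outer product
    is the downsampled axis.  Sign-consistent by construction."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    v = field.vectors
    m = field.mask
    shape = v.shape[:-1]
    trimmed = tuple((s // factor) * factor for s in shape)
    sl = tuple(slice(0, t) for t in trimmed)
    v = v[sl]
    m = m[sl]
    outer = np.einsum("...i,...j->...ij", v, v) * m[..., None, None]
    new_shape = tuple(t // factor for t in trimmed)
    resh = outer.reshape(
        new_shape[0], factor, new_shape[1], factor, new_shape[2], factor, 3, 3
    )
    cnt = m.reshape(new_shape[0], factor, new_shape[1], factor, new_shape[2], factor)
    T = resh.sum(axis=(1, 3, 5))
    n = cnt.sum(axis=(1, 3, 5))
    ok = n > 0
    T[ok] /= n[ok][..., None, None]
    evals, evecs = np.linalg.eigh(T)
    principal = evecs[..., :, -1]
    principal = np.where(
        ok[..., None], principal, np.array([1.0, 0.0, 0.0])
    )
    return OrientationField(principal, ok)


def alps_assumption_report(
    vessels: OrientationField,
    tensors: TensorField,
    rois: ROILabelMap,
    labels=None,
    wm_mask: np.ndarray | None = None,
):
    """Per-ROI distributions of vessel-vs-WM angles.

    For every ROI: median and IQR of vessel angle to V1 (fiber axis), to V2
    (presumed perivascular axis), and to the right-left x axis, plus the
    fraction of voxels within 10 deg (aligned) and beyond 80 deg
    (orthogonal).  The ALPS construction assumes vessel~RL ~ 0, vessel~V1
    ~ 90, vessel~V2 ~ 0.
    """
    import pandas as pd

    if vessels.vectors.shape[:-1] != tensors.evals.shape[:-1]:
        raise ValueError("vessel field and tensor field grids differ")
    base_mask = vessels.mask & tensors.mask
    if wm_mask is not None:
        base_mask = base_mask & np.asarray(wm_mask, dtype=bool)
    comparisons = {
        "v1": OrientationField(_safe_unit(tensors.v(1)), tensors.mask),
        "v2": OrientationField(_safe_unit(tensors.v(2)), tensors.mask),
        "rl": RL_AXIS,
    }
    angle_maps = {k: angular_difference(vessels, v) for k, v in comparisons.items()}
    rows = []
    for label in labels if labels is not None else rois.present_labels:
        m = (rois.labels == label) & base_mask
        row = {
            "label": int(label),
            "name": rois.name_table.get(int(label), str(label)),
            "n_voxels": int(m.sum()),
        }
        for key, amap in angle_maps.items():
            vals = amap[m]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                row.update(
                    {
                        f"vessel_{key}_median_deg": np.nan,
                        f"vessel_{key}_iqr_deg": np.nan,
                        f"vessel_{key}_frac_lt10": np.nan,
                        f"vessel_{key}_frac_gt80": np.nan,
                    }
                )
                continue
            q1, q3 = np.percentile(vals, [25, 75])
            row.update(
                {
                    f"vessel_{key}_median_deg": float(np.median(vals)),
                    f"vessel_{key}_iqr_deg": float(q3 - q1),
                    f"vessel_{key}_frac_lt10": float((vals < 10.0).mean()),
                    f"vessel_{key}_frac_gt80": float((vals > 80.0).mean()),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _safe_unit(v: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.where(norms > 0, v / np.where(norms > 0, norms, 1.0), [1.0, 0.0, 0.0])
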