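"""Standard-format I/O: NIfTI volumes, FSL bval/bvec tables, ROI label maps.

All orientation comparisons in this package happen in RAS image coordinates:
x = left-to-right (the "RL" axis of the ALPS construction), y = posterior-to-
anterior, z = inferior-to-superior.  Gradient tables are read in the FSL
dialect (bvec = 3 rows by N columns, image frame).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from ._sphere import fibonacci_hemisphere

__all__ = [
    "GradientScheme",
    "VolumeImage",
    "ROILabelMap",
    "ALPS_ROLES",
    "read_dwi",
    "write_dwi",
    "read_labels",
    "write_labels",
    "read_table",
    "write_table",
    "make_scheme",
    "preset_scheme",
    "load_config",
]

#: canonical ALPS role names, in serialisation order
ALPS_ROLES = (
    "projection_left",
    "projection_right",
    "association_left",
    "association_right",
)

DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2
_SHELL_ROUND = 50.0  # shells assigned by rounding b to nearest 50 s/mm^2


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected dialect."""


@dataclasses.dataclass(frozen=True)
class GradientScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    Volumes are grouped into shells by rounding the b-value to the nearest
    50 s/mm^2; b-values at or below ``b0_threshold`` form the b0 group
    (shell id 0).
    """

    bvals: np.ndarray  # (N,)
    bvecs: np.ndarray  # (N, 3)
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise FormatError(
                f"{len(bvals)} b-values but {len(bvecs)} gradient directions"
            )
        dw = bvals > self.b0_threshold
        norms = np.linalg.norm(bvecs[dw], axis=1)
        bad = np.abs(norms - 1.0) > 1e-3
        if np.any(bad):
            if np.all((norms[bad] > 0.9) & (norms[bad] < 1.1)):
                import warnings

                warnings.warn(
                    "non-unit bvecs at b > threshold; rescaling to unit norm",
                    stacklevel=3,
                )
                bvecs = bvecs.copy()
                bvecs[dw] /= np.linalg.norm(bvecs[dw], axis=1, keepdims=True)
            else:
                raise FormatError(
                    "gradient directions at b > threshold are not unit vectors "
                    f"(norms outside [0.9, 1.1]: {norms[bad]})"
                )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def shell_bvals(self) -> np.ndarray:
        """Rounded shell b-value per volume (0 for the b0 group)."""
        rounded = _SHELL_ROUND * np.round(self.bvals / _SHELL_ROUND)
        rounded[self.bvals <= self.b0_threshold] = 0.0
        return rounded

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique non-zero shell b-values."""
        sb = self.shell_bvals
        return np.unique(sb[sb > 0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    def shell_mask(self, shell: float | None) -> np.ndarray:
        """Boolean mask selecting one shell plus all b0 volumes.

        ``shell=None`` selects every volume.
        """
        if shell is None:
            return np.ones(len(self.bvals), dtype=bool)
        return self.b0_mask | (self.shell_bvals == float(shell))

    def subset(self, mask: np.ndarray) -> "GradientScheme":
        return GradientScheme(self.bvals[mask], self.bvecs[mask], self.b0_threshold)

    def __len__(self) -> int:
        return len(self.bvals)


@dataclasses.dataclass
class VolumeImage:
    """A 3D or 4D scalar image on a regular grid, RAS axis convention."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise FormatError(f"expected 3D/4D image, got ndim={self.data.ndim}")
        if any(v <= 0 for v in self.voxel_size):
            raise FormatError(f"voxel size must be positive, got {self.voxel_size}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclasses.dataclass
class ROILabelMap:
    """Integer label volume plus the ALPS role assignment of some labels."""

    labels: np.ndarray  # (X, Y, Z) int
    name_table: dict[int, str] = dataclasses.field(default_factory=dict)
    alps_roles: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("label map must be 3D")
        for role, label in self.alps_roles.items():
            if role not in ALPS_ROLES and role != "other":
                raise FormatError(f"unknown ALPS role {role!r}")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def role_mask(self, role: str) -> np.ndarray:
        if role not in self.alps_roles:
            raise KeyError(f"ALPS role {role!r} not present in label map")
        m = self.mask(self.alps_roles[role])
        if not m.any():
            raise ValueError(f"ALPS role {role!r} maps to an empty voxel set")
        return m

    @property
    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dwi(
    image_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> tuple[VolumeImage, GradientScheme]:
    """Read a 4D diffusion volume with FSL-style bval/bvec sidecars."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4D diffusion image")
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2 or bvecs.shape[0] != 3:
        raise FormatError(f"{bvec_path}: bvec must be 3 rows x N columns")
    bvecs = bvecs.T
    if data.shape[3] != len(bvals):
        raise FormatError(
            f"{image_path}: {data.shape[3]} volumes but {len(bvals)} b-values"
        )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    scheme = GradientScheme(bvals, bvecs, b0_threshold)
    return VolumeImage(data, voxel_size), scheme


def write_dwi(
    prefix: str | Path,
    image: VolumeImage,
    scheme: GradientScheme,
) -> dict[str, Path]:
    """Write ``<prefix>.nii.gz`` + ``<prefix>.bval``/``.bvec`` (FSL dialect)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": prefix.with_suffix(".nii.gz"),
        "bval": prefix.with_suffix(".bval"),
        "bvec": prefix.with_suffix(".bvec"),
    }
    nib.save(
        nib.Nifti1Image(image.data.astype(np.float64), image.affine),
        str(paths["image"]),
    )
    np.savetxt(paths["bval"], scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(paths["bvec"], scheme.bvecs.T, fmt="%.9f")
    return paths


def write_volume(path: str | Path, image: VolumeImage) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(image.data, dtype=np.float64), image.affine), str(path))
    return path


def read_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(
        np.asarray(img.dataobj, dtype=np.float64),
        tuple(float(z) for z in img.header.get_zooms()[:3]),
    )


def write_labels(prefix: str | Path, rois: ROILabelMap, voxel_size=(1.0, 1.0, 1.0)) -> dict[str, Path]:
    """Write ``<prefix>.nii.gz`` plus a JSON sidecar with names and ALPS roles."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    img_path = prefix.with_suffix(".nii.gz")
    meta_path = prefix.with_suffix(".json")
    aff = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(rois.labels.astype(np.int16), aff), str(img_path))
    meta = {
        "names": {str(k): v for k, v in rois.name_table.items()},
        "alps_roles": rois.alps_roles,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"image": img_path, "meta": meta_path}


def read_labels(prefix: str | Path) -> ROILabelMap:
    prefix = Path(prefix)
    img = nib.load(str(prefix.with_suffix(".nii.gz")))
    labels = np.asarray(img.dataobj).astype(int)
    meta_path = prefix.with_suffix(".json")
    names: dict[int, str] = {}
    roles: dict[str, int] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        names = {int(k): v for k, v in meta.get("names", {}).items()}
        roles = {k: int(v) for k, v in meta.get("alps_roles", {}).items()}
    return ROILabelMap(labels, names, roles)


def read_table(path: str | Path):
    """Read a delimited covariate/metric table (TSV or CSV by extension)."""
    import pandas as pd

    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def write_table(path: str | Path, table) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# gradient scheme construction
# ---------------------------------------------------------------------------

def make_scheme(
    shells: Mapping[float, int],
    n_b0: int,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> GradientScheme:
    """Build a multi-shell scheme: ``{b: n_directions}`` plus ``n_b0`` b0s.

    Directions per shell come from a Fibonacci hemisphere lattice, rotated
    per shell by a deterministic angle so shells do not share directions.
    """
    bvals = [np.zeros(n_b0)]
    bvecs = [np.zeros((n_b0, 3))]
    for k, (b, n) in enumerate(sorted(shells.items())):
        dirs = fibonacci_hemisphere(n)
        ang = 0.4 * (k + 1)  # small deterministic twist about z per shell
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        bvals.append(np.full(n, float(b)))
        bvecs.append(dirs @ rot.T)
    return GradientScheme(np.concatenate(bvals), np.vstack(bvecs), b0_threshold)


def preset_scheme(name: str) -> GradientScheme:
    """Named multi-shell schemes emulating the HCP acquisitions.

    ``hcp-ya``: b = 1000/2000/3000 s/mm^2, 90 directions each, 18 b0.
    ``hcp-a``:  b = 1500/3000 s/mm^2, 93/92 directions, 24 b0.
    """
    name = name.lower()
    if name in ("hcp-ya", "hcp_ya", "hcpya"):
        return make_scheme({1000.0: 90, 2000.0: 90, 3000.0: 90}, n_b0=18)
    if name in ("hcp-a", "hcp_a", "hcpa"):
        return make_scheme({1500.0: 93, 3000.0: 92}, n_b0=24)
    raise ValueError(f"unknown scheme preset {name!r}")


# ---------------------------------------------------------------------------
# flat config files (key = value with [sections]); CLI flags win on conflict
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict[str, dict[str, str]]:
    """Parse a flat INI-style config into {section: {key: value}}."""
    import configparser

    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    return {s: dict(cp.items(s)) for s in cp.sections()}


def run_cli(argv=None) -> int:
    """Entry point for the command-line pipeline (see :mod:`alpsim.cli`)."""
    from .cli import run_cli as _run

    return _run(argv)
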