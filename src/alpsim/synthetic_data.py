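"""Synthetic fixtures with known ground truth.

Everything downstream consumes phantoms made here: multi-shell dMRI volumes
with planted fiber geometry (single fibers, crossings at a set angle and
fraction, Bingham-dispersed neurites, optional fast PVS compartment),
ALPS-style ROI layouts (5 mm spheres; projection fibers along z, association
fibers along y, presumed perivascular axis along x), tubular vessel volumes
with known axes, and age cohorts with planted linear trends.

Defaults emulate the study conditions: an HCP-style three-shell scheme
(b = 1000/2000/3000 s/mm^2, 90 directions each), 1.5 mm voxels on a
40 x 40 x 20 grid, Rician noise at SNR 25 when noise is requested.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .crossing_sim import (
    FiberConfig,
    add_rician_noise,
    axially_symmetric_tensor,
    multitensor_signal,
)
from .io_formats import (
    ALPS_ROLES,
    GradientScheme,
    ROILabelMap,
    VolumeImage,
    preset_scheme,
)
from .vessel_geometry import OrientationField

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "generate_phantom",
    "generate_vessel_volume",
    "generate_cohort",
    "sphere_mask",
]

DEFAULT_SHAPE = (40, 40, 20)
DEFAULT_VOXEL_MM = 1.5
ALPS_SPHERE_DIAMETER_MM = 5.0


def sphere_mask(shape, center_vox, radius_mm, voxel_mm) -> np.ndarray:
    """Boolean ball of physical radius ``radius_mm`` on the voxel grid."""
    grid = np.indices(shape, dtype=float)
    d2 = sum(
        ((grid[i] - center_vox[i]) * voxel_mm) ** 2 for i in range(3)
    )
    return d2 <= radius_mm**2


@dataclasses.dataclass
class RegionSpec:
    """One labelled region: geometry plus the signal model inside it."""

    label: int
    name: str
    center_vox: tuple[float, float, float]
    radius_mm: float
    config: FiberConfig | None = None
    # alternative: Bingham-dispersed neurites (used when config is None)
    dispersion: dict | None = None
    alps_role: str | None = None


@dataclasses.dataclass
class PhantomSpec:
    """Full phantom recipe; serialisable to a JSON sidecar."""

    regions: list[RegionSpec]
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    voxel_mm: float = DEFAULT_VOXEL_MM
    scheme_preset: str = "hcp-ya"
    snr: float | None = None
    seed: int = 0

    # ---- canned layouts -------------------------------------------------
    @staticmethod
    def alps(
        pvs_fraction: float = 0.0,
        snr: float | None = None,
        seed: int = 0,
        proj_lambdas: tuple[float, float] = (1.7e-3, 0.3e-3),
        assoc_lambdas: tuple[float, float] = (1.5e-3, 0.25e-3),
    ) -> "PhantomSpec":
        """ALPS layout: projection fibers along z, association along y, four
        5 mm spheres (left/right pairs), optional PVS compartment along x."""
        proj = FiberConfig.single((0, 0, 1.0), *proj_lambdas)
        assoc = FiberConfig.single((0, 1.0, 0), *assoc_lambdas)
        if pvs_fraction > 0:
            proj = proj.with_pvs(pvs_fraction)
            assoc = assoc.with_pvs(pvs_fraction)
        r = ALPS_SPHERE_DIAMETER_MM / 2.0
        regions = [
            RegionSpec(1, "SCR_left", (12, 20, 10), r, proj, alps_role="projection_left"),
            RegionSpec(2, "SCR_right", (28, 20, 10), r, proj, alps_role="projection_right"),
            RegionSpec(3, "SLF_left", (8, 28, 10), r, assoc, alps_role="association_left"),
            RegionSpec(4, "SLF_right", (32, 28, 10), r, assoc, alps_role="association_right"),
        ]
        return PhantomSpec(regions, snr=snr, seed=seed)

    @staticmethod
    def crossing(
        angle_deg: float = 65.0,
        fraction: float = 0.3,
        snr: float | None = None,
        seed: int = 0,
    ) -> "PhantomSpec":
        """A single-fiber reference sphere plus a crossing sphere."""
        regions = [
            RegionSpec(1, "single", (12, 20, 10), 4.5, FiberConfig.single()),
            RegionSpec(
                2,
                "crossing",
                (28, 20, 10),
                4.5,
                FiberConfig.crossing(angle_deg, fraction),
            ),
        ]
        return PhantomSpec(regions, snr=snr, seed=seed)

    @staticmethod
    def dispersion(
        kappa1: float = 16.0,
        kappa2: float = 4.0,
        v_ic: float = 0.6,
        snr: float | None = None,
        seed: int = 0,
    ) -> "PhantomSpec":
        regions = [
            RegionSpec(
                1,
                "dispersed",
                (20, 20, 10),
                5.0,
                None,
                dispersion=dict(kappa1=kappa1, kappa2=kappa2, v_ic=v_ic, v_iso=0.0),
            ),
        ]
        return PhantomSpec(regions, snr=snr, seed=seed)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (PhantomSpec, RegionSpec)):
                return dataclasses.asdict(o)
            if isinstance(o, FiberConfig):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)


@dataclasses.dataclass
class Phantom:
    """A generated phantom: image + scheme + labels + ground truth."""

    dwi: VolumeImage
    scheme: GradientScheme
    rois: ROILabelMap
    truth: pd.DataFrame  # one row per region
    spec: PhantomSpec

    def save(self, prefix: str | Path) -> dict:
        from .io_formats import write_dwi, write_labels, write_table

        prefix = Path(prefix)
        paths = write_dwi(prefix, self.dwi, self.scheme)
        paths.update(
            write_labels(
                Path(str(prefix) + "_labels"),
                self.rois,
                voxel_size=self.dwi.voxel_size,
            )
        )
        paths["truth"] = write_table(Path(str(prefix) + "_truth.tsv"), self.truth)
        sidecar = prefix.with_suffix(".spec.json")
        sidecar.write_text(self.spec.to_json())
        paths["spec"] = sidecar
        return paths


def _region_signal(region: RegionSpec, scheme: GradientScheme) -> np.ndarray:
    if region.config is not None:
        return multitensor_signal(region.config, scheme)
    if region.dispersion is not None:
        from .dispersion_model import dispersed_signal

        return dispersed_signal(scheme, mu1=(0, 0, 1.0), **region.dispersion)
    raise ValueError(f"region {region.name!r} has neither config nor dispersion")


def _region_truth(region: RegionSpec) -> dict:
    row = dict(
        label=region.label,
        name=region.name,
        alps_role=region.alps_role or "other",
    )
    if region.config is not None:
        # mixture tensor (exact signal model only for single compartments)
        D = sum(
            f * axially_symmetric_tensor(d, lp, lt)
            for d, f, lp, lt in region.config.all_compartments()
        )
        evals = np.sort(np.linalg.eigvalsh(D))[::-1]
        row.update(
            dxx=float(D[0, 0]),
            dyy=float(D[1, 1]),
            dzz=float(D[2, 2]),
            lambda1=float(evals[0]),
            lambda2=float(evals[1]),
            lambda3=float(evals[2]),
            asymmetry=float(evals[1] / evals[2]) if evals[2] > 0 else np.nan,
            n_compartments=len(region.config.compartments),
            pvs_fraction=float(region.config.pvs[1]) if region.config.pvs else 0.0,
        )
    if region.dispersion is not None:
        row.update({f"disp_{k}": v for k, v in region.dispersion.items()})
    return row


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterise the regions, synthesise signals, add Rician noise.

    Region voxel sets must be disjoint; ground truth (planted tensors,
    crossing parameters, dispersion concentrations) is returned per region
    so every downstream metric can be checked against it.
    """
    scheme = preset_scheme(spec.scheme_preset)
    labels = np.zeros(spec.shape, dtype=np.int16)
    data = np.zeros(spec.shape + (len(scheme),))
    rng = np.random.default_rng(spec.seed)
    truth_rows = []
    name_table: dict[int, str] = {}
    alps_roles: dict[str, int] = {}
    for region in spec.regions:
        m = sphere_mask(spec.shape, region.center_vox, region.radius_mm, spec.voxel_mm)
        if not m.any():
            raise ValueError(f"region {region.name!r} rasterises to zero voxels")
        if (labels[m] != 0).any():
            raise ValueError(f"region {region.name!r} overlaps another region")
        labels[m] = region.label
        sig = _region_signal(region, scheme)
        data[m] = sig
        name_table[region.label] = region.name
        if region.alps_role:
            if region.alps_role not in ALPS_ROLES:
                raise ValueError(f"bad ALPS role {region.alps_role!r}")
            alps_roles[region.alps_role] = region.label
        truth_rows.append({**_region_truth(region), "n_voxels": int(m.sum())})
    if spec.snr is not None:
        mask = labels > 0
        data[mask] = add_rician_noise(data[mask], spec.snr, rng)
    dwi = VolumeImage(data, (spec.voxel_mm,) * 3)
    rois = ROILabelMap(labels, name_table, alps_roles)
    return Phantom(dwi, scheme, rois, pd.DataFrame(truth_rows), spec)


# ---------------------------------------------------------------------------
# vessel phantoms
# ---------------------------------------------------------------------------

def generate_vessel_volume(
    shape=(40, 40, 40),
    tubes: Sequence[tuple[tuple[float, float, float], tuple[float, float, float], float]] = (
        ((20.0, 20.0, 20.0), (1.0, 0.0, 0.0), 2.0),
    ),
    voxel_mm: float = 1.0,
    noise_sd: float = 0.0,
    polarity: str = "dark",
    seed: int = 0,
) -> tuple[VolumeImage, OrientationField]:
    """Rasterise straight tubes with smooth (anti-aliased) profiles.

    ``tubes`` is a sequence of (point_on_axis_vox, direction, radius_vox).
    Dark polarity embeds low-intensity tubes in a bright background (the SWI
    vein convention).  Returns the volume and the ground-truth orientation
    field (tube axis wherever a voxel lies within any tube, nearest tube
    wins).
    """
    grid = np.stack(np.indices(shape, dtype=float), axis=-1)  # (X,Y,Z,3)
    background = 1.0 if polarity == "dark" else 0.0
    vol = np.full(shape, background)
    truth = np.zeros(shape + (3,))
    best_d = np.full(shape, np.inf)
    inside_any = np.zeros(shape, dtype=bool)
    for point, direction, radius in tubes:
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        rel = grid - np.asarray(point, dtype=float)
        along = rel @ u
        perp = rel - along[..., None] * u[None, :]
        dist = np.linalg.norm(perp, axis=-1)
        profile = np.exp(-((dist / radius) ** 4))  # flat core, smooth edge
        if polarity == "dark":
            vol = np.minimum(vol, 1.0 - profile)
        else:
            vol = np.maximum(vol, profile)
        inside = dist <= radius
        closer = inside & (dist < best_d)
        truth[closer] = u
        best_d[closer] = dist[closer]
        inside_any |= inside
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, vol.shape)
    truth[~inside_any] = [1.0, 0.0, 0.0]
    field = OrientationField(truth, inside_any)
    return VolumeImage(vol, (voxel_mm,) * 3), field


# ---------------------------------------------------------------------------
# age cohorts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CohortSpec:
    """Cohort with planted linear age trends.

    ``metrics`` maps metric name -> (intercept, slope_per_year); optionally
    ``rois`` maps ROI name -> {metric: (intercept, slope)} for per-ROI rows.
    Defaults mirror an aging-cohort design: n=50, ages 35-90.
    """

    n_subjects: int = 50
    age_range: tuple[float, float] = (35.0, 90.0)
    metrics: dict = dataclasses.field(
        default_factory=lambda: {"asymmetry": (1.6, -0.002)}
    )
    rois: dict | None = None
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """metric_i = intercept + slope * age_i + N(0, noise_sd^2) per metric."""
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(*spec.age_range, spec.n_subjects)
    rows = []
    roi_map = spec.rois if spec.rois is not None else {None: spec.metrics}
    for i, age in enumerate(ages):
        for roi, metrics in roi_map.items():
            row = {"subject": f"sub-{i:03d}", "age": float(age)}
            if roi is not None:
                row["roi"] = roi
            for name, (intercept, slope) in metrics.items():
                row[name] = float(
                    intercept + slope * age + rng.normal(0.0, spec.noise_sd)
                )
            rows.append(row)
    return pd.DataFrame(rows)
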