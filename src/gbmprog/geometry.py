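"""3D morphological descriptors of labelled tumor masks.

A :class:`VoxelMask` holds an integer label volume (0 background, 1
contrast-enhancing tissue, 2 necrosis) with anisotropic physical spacing in
mm. :func:`compute_morphology` derives the seven headline measures — total, CE
and necrotic volumes, CE rim width, maximum 3D diameter, total surface and
surface regularity — plus nine auxiliary measures completing a set of 16.

Conventions: voxel centers sit at integer indices scaled by spacing; all
distances are mm internally and reported in cm / cm^2 / cm^3. Surfaces come
from a marching-cubes interface mesh (voxel-face counting overestimates
sphere areas by tens of percent and would bias the regularity index), and
surface regularity is the sphericity-style index (36*pi*V^2)^(1/3) / S,
equal to 1 for a perfect sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

__all__ = [
    "VoxelMask",
    "MorphologyFeatures",
    "compute_morphology",
    "read_mask",
    "write_mask",
]

MM3_PER_CM3 = 1000.0
MM2_PER_CM2 = 100.0
MM_PER_CM = 10.0


@dataclass(frozen=True)
class VoxelMask:
    """Labelled 3D tumor segmentation with physical voxel spacing (mm)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        extra = set(np.unique(labels)) - {0, 1, 2}
        if extra:
            raise ValueError(f"labels must be in {{0, 1, 2}}; found {sorted(extra)}")
        spacing = tuple(float(v) for v in self.spacing)
        if len(spacing) != 3 or min(spacing) <= 0:
            raise ValueError("spacing must be three positive components")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing", spacing)

    @property
    def tumor(self) -> np.ndarray:
        return self.labels > 0

    @property
    def ce(self) -> np.ndarray:
        return self.labels == 1

    @property
    def necrosis(self) -> np.ndarray:
        return self.labels == 2

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / MM3_PER_CM3


@dataclass(frozen=True)
class MorphologyFeatures:
    """The 16 morphology measures (7 headline + 9 auxiliary)."""

    total_volume: float            # cm^3
    ce_volume: float               # cm^3
    necrotic_volume: float         # cm^3
    ce_rim_width: float            # cm
    max_diameter: float            # cm
    total_surface: float           # cm^2
    surface_regularity: float      # dimensionless, 1 = sphere
    # auxiliary measures completing the set of 16
    necrotic_surface: float        # cm^2 (0 without necrosis)
    necrotic_surface_regularity: float  # sphericity of the core (nan if none)
    ce_rim_width_sd: float         # cm, variability of the rim thickness
    equivalent_diameter_total: float    # cm, sphere-equivalent of total volume
    equivalent_diameter_ce: float       # cm, sphere-equivalent of CE volume
    necrotic_volume_fraction: float     # necrotic / total
    ce_volume_fraction: float           # CE / total
    surface_to_volume: float            # cm^-1
    necrotic_max_diameter: float        # cm (0 without necrosis)

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _mesh_surface_mm2(region: np.ndarray, spacing) -> float:
    """Marching-cubes interface area of a binary region, in mm^2.

    The binary volume is lightly smoothed (Gaussian, 1 voxel) before
    meshing: the level-0.5 isosurface of the smoothed field removes the
    rasterization staircase that otherwise inflates sphere areas by ~9%.
    Falls back to the raw binary interface for regions too small to
    survive smoothing.
    """
    if not region.any():
        return 0.0
    padded = np.pad(region.astype(np.float64), 2)
    smoothed = ndimage.gaussian_filter(padded, 1.0)
    field = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=spacing)
    return float(measure.mesh_surface_area(verts, faces))


def _max_pairwise_diameter_mm(region: np.ndarray, spacing) -> float:
    """Maximum Euclidean distance between boundary voxel centers (mm).

    Boundary voxels are reduced to their convex hull before the O(m^2)
    pairwise scan, which is exact for a maximum distance.
    """
    boundary = region & ~ndimage.binary_erosion(region)
    pts = np.argwhere(boundary) * np.asarray(spacing)
    if pts.shape[0] < 2:
        return 0.0
    if pts.shape[0] > 16:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def _rim_width_mm(mask: VoxelMask) -> tuple[float, float]:
    """Mean and SD of the CE shell thickness at CE voxels, in mm.

    With necrosis: per CE voxel, distance to the outer tumor boundary plus
    distance to the necrotic core (their sum is the local shell thickness
    along the radial direction for a concentric shell). Without necrosis the
    measure degenerates to twice the mean distance to the outer boundary, a
    diameter-like thickness of the solid lesion.
    """
    spacing = mask.spacing
    dist_out = ndimage.distance_transform_edt(mask.tumor, sampling=spacing)
    ce = mask.ce
    if mask.necrosis.any():
        dist_core = ndimage.distance_transform_edt(~mask.necrosis, sampling=spacing)
        width = dist_out[ce] + dist_core[ce]
    else:
        width = 2.0 * dist_out[ce]
    return float(width.mean()), float(width.std())


def compute_morphology(mask: VoxelMask) -> MorphologyFeatures:
    """All 16 morphology measures of a labelled mask.

    Volumes are voxel counts times the voxel volume, so
    total = CE + necrotic holds exactly. Warns (and proceeds) when necrosis
    exists without enclosing CE tissue.
    """
    if not mask.ce.any():
        raise ValueError("mask has no contrast-enhancing voxels")
    if mask.necrosis.any() and not _core_enclosed(mask):
        warnings.warn("necrosis not enclosed by CE tissue", stacklevel=2)

    vv = mask.voxel_volume_cm3
    ce_volume = float(mask.ce.sum()) * vv
    necrotic_volume = float(mask.necrosis.sum()) * vv
    # labels partition the tumor, so the sum is exact by construction
    total_volume = ce_volume + necrotic_volume

    surface_mm2 = _mesh_surface_mm2(mask.tumor, mask.spacing)
    total_surface = surface_mm2 / MM2_PER_CM2
    regularity = float(
        (36.0 * np.pi * (total_volume * MM3_PER_CM3) ** 2) ** (1.0 / 3.0)
        / surface_mm2
    )

    rim_mean_mm, rim_sd_mm = _rim_width_mm(mask)
    diameter_mm = _max_pairwise_diameter_mm(mask.tumor, mask.spacing)

    nec_surface_mm2 = _mesh_surface_mm2(mask.necrosis, mask.spacing)
    if nec_surface_mm2 > 0:
        nec_regularity = float(
            (36.0 * np.pi * (necrotic_volume * MM3_PER_CM3) ** 2) ** (1.0 / 3.0)
            / nec_surface_mm2
        )
        nec_diam_mm = _max_pairwise_diameter_mm(mask.necrosis, mask.spacing)
    else:
        nec_regularity = float("nan")
        nec_diam_mm = 0.0

    eq_d = lambda v_cm3: 2.0 * (3.0 * v_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return MorphologyFeatures(
        total_volume=total_volume,
        ce_volume=ce_volume,
        necrotic_volume=necrotic_volume,
        ce_rim_width=rim_mean_mm / MM_PER_CM,
        max_diameter=diameter_mm / MM_PER_CM,
        total_surface=total_surface,
        surface_regularity=regularity,
        necrotic_surface=nec_surface_mm2 / MM2_PER_CM2,
        necrotic_surface_regularity=nec_regularity,
        ce_rim_width_sd=rim_sd_mm / MM_PER_CM,
        equivalent_diameter_total=eq_d(total_volume),
        equivalent_diameter_ce=eq_d(ce_volume),
        necrotic_volume_fraction=necrotic_volume / total_volume,
        ce_volume_fraction=ce_volume / total_volume,
        surface_to_volume=total_surface / total_volume,
        necrotic_max_diameter=nec_diam_mm / MM_PER_CM,
    )


def _core_enclosed(mask: VoxelMask) -> bool:
    """True when every necrotic voxel's 6-neighbours are tumor tissue."""
    dilated = ndimage.binary_dilation(mask.necrosis)
    return bool(np.all(mask.tumor[dilated]))


def read_mask(path: str | Path) -> VoxelMask:
    """Load a NIfTI-1 label volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: non-integer label data")
    labels = np.round(data).astype(np.int16)
    if not (labels > 0).any():
        raise ValueError(f"{path}: empty label volume")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelMask(labels=labels, spacing=spacing)


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a NIfTI-1 label volume with spacing in the header.

    NIfTI-1 stores pixdim in float32, so spacing survives exactly at that
    precision; a read-back mask round-trips bit-exactly thereafter.
    """
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.labels.astype(np.int16), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
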