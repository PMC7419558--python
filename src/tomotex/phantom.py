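"""Voxelized compressed-breast phantoms with controllable glandular fraction.

The generator is a procedural surrogate for anthropomorphic breast phantoms:
a compressed slab of uniform thickness with a skin rind, whose interior is
partitioned into adipose and fibroglandular compartments by a seeded
nearest-seed (Voronoi) tessellation, with thin ligament sheets carved on
compartment boundaries.  Spherical lesions can be inserted into the
fibroglandular compartment at a requested depth, replacing (not blending
with) the background tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from tomotex.errors import DegenerateInputError, GeometryError, ParameterError, PlacementError, SchemaError

# Label codes for the voxel grid.
AIR = 0
ADIPOSE = 1
FIBROGLANDULAR = 2
LIGAMENT = 3
SKIN = 4
LESION = 5

LABEL_NAMES = {
    AIR: "air",
    ADIPOSE: "adipose",
    FIBROGLANDULAR: "fibroglandular",
    LIGAMENT: "ligament",
    SKIN: "skin",
    LESION: "lesion",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

#: Tissue labels counted as "interior" for glandular-fraction accounting.
INTERIOR_LABELS = (ADIPOSE, FIBROGLANDULAR, LIGAMENT)


@dataclass(frozen=True)
class MaterialTable:
    """Linear attenuation coefficients (1/mm) tabulated on an energy grid (keV).

    ``mu_table`` maps material name -> array of coefficients aligned with
    ``energies_keV``.  Values are interpolated linearly in energy.
    """

    energies_keV: np.ndarray
    mu_table: dict

    def __post_init__(self):
        energies = np.asarray(self.energies_keV, dtype=float)
        object.__setattr__(self, "energies_keV", energies)
        if energies.ndim != 1 or energies.size == 0:
            raise SchemaError("energy grid must be a non-empty 1D array")
        if np.any(np.diff(energies) <= 0):
            raise SchemaError("energy grid must be strictly increasing")
        table = {}
        for name, mu in self.mu_table.items():
            mu = np.asarray(mu, dtype=float)
            if mu.shape != energies.shape:
                raise SchemaError(f"mu for {name!r} does not match the energy grid")
            if np.any(mu < 0):
                raise SchemaError(f"mu for {name!r} has negative entries")
            table[name] = mu
        object.__setattr__(self, "mu_table", table)

    def mu(self, material: str, energy_keV: float) -> float:
        """Interpolated linear attenuation coefficient (1/mm)."""
        if material not in self.mu_table:
            raise SchemaError(f"unknown material {material!r}")
        return float(np.interp(energy_keV, self.energies_keV, self.mu_table[material]))

    def mu_by_label(self, energy_keV: float) -> np.ndarray:
        """Attenuation for each integer label code at one energy, as a lookup array."""
        out = np.zeros(max(LABEL_NAMES) + 1)
        for code, name in LABEL_NAMES.items():
            if name in self.mu_table:
                out[code] = self.mu(name, energy_keV)
        return out

    def to_csv(self, path) -> None:
        rows = [
            {"material": name, "energy_keV": e, "mu_per_mm": m}
            for name, mus in self.mu_table.items()
            for e, m in zip(self.energies_keV, mus)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MaterialTable":
        df = pd.read_csv(path)
        required = {"material", "energy_keV", "mu_per_mm"}
        if not required.issubset(df.columns):
            raise SchemaError(f"material CSV must have columns {sorted(required)}")
        energies = np.array(sorted(df["energy_keV"].unique()), dtype=float)
        table = {}
        for name, grp in df.groupby("material"):
            grp = grp.sort_values("energy_keV")
            if not np.allclose(grp["energy_keV"].to_numpy(float), energies):
                raise SchemaError(f"material {name!r} is not tabulated on the common energy grid")
            table[name] = grp["mu_per_mm"].to_numpy(float)
        return cls(energies, table)


def default_materials() -> MaterialTable:
    """Nominal attenuation table on a coarse keV grid.

    Values are nominal soft-tissue coefficients chosen to preserve the
    ordering adipose < fibroglandular <= lesion at every energy; they are
    config-overridable and not calibrated measurements.
    """
    energies = np.array([15.0, 20.0, 25.0, 30.0, 40.0])
    return MaterialTable(
        energies,
        {
            "air": np.array([0.0, 0.0, 0.0, 0.0, 0.0]),
            "adipose": np.array([0.110, 0.056, 0.037, 0.029, 0.023]),
            "fibroglandular": np.array([0.170, 0.080, 0.049, 0.037, 0.027]),
            "ligament": np.array([0.175, 0.082, 0.050, 0.038, 0.028]),
            "skin": np.array([0.180, 0.085, 0.052, 0.039, 0.028]),
            "lesion": np.array([0.190, 0.091, 0.056, 0.042, 0.030]),
        },
    )


@dataclass(frozen=True)
class Lesion:
    center: tuple  # voxel indices (ix, iy, iz)
    diameter_mm: float


@dataclass
class BreastPhantom:
    """Compressed-breast label volume.

    Axes are (x, y, z) with z the compression/depth axis; z = 0 is the
    detector-side surface.  ``labels`` holds one material code per voxel.
    """

    labels: np.ndarray
    voxel_size_mm: float = 0.2
    vgf_target: Optional[float] = None
    vgf_realized: Optional[float] = None
    lesion: Optional[Lesion] = None
    seed: Optional[int] = None

    @property
    def thickness_mm(self) -> float:
        return self.labels.shape[2] * self.voxel_size_mm

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def interior_mask(self) -> np.ndarray:
        return np.isin(self.labels, INTERIOR_LABELS)

    def support_mask(self) -> np.ndarray:
        return self.labels != AIR


def _breast_support(grid_shape: tuple) -> np.ndarray:
    """Half-elliptical-cylinder support: chest wall at x=0, rounded outer edge."""
    nx, ny, nz = grid_shape
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    a = 0.96 * nx
    b = 0.48 * ny
    cy = (ny - 1) / 2.0
    cross = (x / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
    return np.broadcast_to(cross[:, :, None], (nx, ny, nz)).copy()


def _skin_rind(support: np.ndarray) -> np.ndarray:
    """1-voxel skin layer on the support boundary, except at the chest wall (x=0)."""
    padded = np.pad(support, 1, mode="constant", constant_values=False)
    # The chest wall is a cut plane, not a surface: extend support across it.
    padded[0, :, :] = padded[1, :, :]
    eroded = ndimage.binary_erosion(padded)[1:-1, 1:-1, 1:-1]
    return support & ~eroded


def generate_phantom(
    vgf_target: float,
    grid_shape: tuple,
    seed: int,
    voxel_size_mm: float = 0.2,
    n_compartments: Optional[int] = None,
) -> BreastPhantom:
    """Generate a seeded compressed-breast phantom hitting ``vgf_target``.

    The interior is split into nearest-seed compartments; compartments are
    greedily assigned fibroglandular (in seeded random order) until the
    realized volumetric glandular fraction best matches the target.
    Compartment boundaries receive a 1-voxel ligament sheet.
    """
    if not (0.0 < vgf_target < 1.0):
        raise ParameterError(f"vgf_target must lie in (0, 1); got {vgf_target}")
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3:
        raise GeometryError("grid_shape must be 3D (nx, ny, nz)")
    if min(grid_shape) < 8:
        raise GeometryError(f"grid {grid_shape} too small to contain skin and an interior")

    rng = np.random.default_rng(seed)
    support = _breast_support(grid_shape)
    skin = _skin_rind(support)
    interior = support & ~skin
    n_interior = int(interior.sum())
    if n_interior == 0:
        raise GeometryError("grid has no interior voxels inside the skin rind")

    if n_compartments is None:
        # Enough compartments that greedy assignment lands within the VGF
        # tolerance, but not so many that sheets dominate tiny grids.
        n_compartments = int(np.clip(n_interior // 3000, 48, 400))
    n_compartments = min(n_compartments, max(2, n_interior // 8))

    coords = np.argwhere(interior)
    seed_idx = rng.choice(len(coords), size=n_compartments, replace=False)
    tree = cKDTree(coords[seed_idx])
    _, comp_of_voxel = tree.query(coords, workers=-1)

    comp_map = np.full(grid_shape, -1, dtype=np.int32)
    comp_map[interior] = comp_of_voxel

    # Ligament sheets: interior voxels whose forward neighbor lies in a
    # different compartment (1-voxel sheet per internal boundary).
    ligament = np.zeros(grid_shape, dtype=bool)
    for axis in range(3):
        a = comp_map
        b = np.roll(comp_map, -1, axis=axis)
        sl = [slice(None)] * 3
        sl[axis] = slice(0, grid_shape[axis] - 1)
        sl = tuple(sl)
        differ = (a[sl] != b[sl]) & (a[sl] >= 0) & (b[sl] >= 0)
        lig = np.zeros(grid_shape, dtype=bool)
        lig[sl] = differ
        ligament |= lig

    # Greedy glandular assignment on non-ligament voxel counts.
    assignable = interior & ~ligament
    comp_sizes = np.bincount(comp_map[assignable], minlength=n_compartments)
    target_count = vgf_target * n_interior
    order = rng.permutation(n_compartments)
    glandular_comps = np.zeros(n_compartments, dtype=bool)
    running = 0
    for c in order:
        if abs(running + comp_sizes[c] - target_count) < abs(running - target_count):
            glandular_comps[c] = True
            running += comp_sizes[c]

    labels = np.full(grid_shape, AIR, dtype=np.uint8)
    labels[skin] = SKIN
    labels[assignable] = np.where(glandular_comps[comp_map[assignable]], FIBROGLANDULAR, ADIPOSE)
    labels[ligament & interior] = LIGAMENT

    phantom = BreastPhantom(
        labels=labels,
        voxel_size_mm=float(voxel_size_mm),
        vgf_target=float(vgf_target),
        seed=int(seed),
    )
    phantom.vgf_realized = measure_vgf(phantom)
    return phantom


def measure_vgf(phantom: BreastPhantom) -> float:
    """Fibroglandular voxels over all interior tissue voxels (lesion excluded)."""
    labels = phantom.labels
    n_interior = int(np.isin(labels, INTERIOR_LABELS).sum())
    if n_interior == 0:
        raise DegenerateInputError("phantom has no interior tissue voxels")
    return float((labels == FIBROGLANDULAR).sum() / n_interior)


def _sphere_offsets(radius_vox: float) -> np.ndarray:
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = ox**2 + oy**2 + oz**2 <= radius_vox**2
    return np.stack([ox[inside], oy[inside], oz[inside]], axis=1)


def insert_lesion(phantom: BreastPhantom, diameter_mm: float, depth_mm: float, seed: int) -> BreastPhantom:
    """Insert a homogeneous sphere at a seeded fibroglandular site at ``depth_mm``.

    Depth is measured along the compression axis from the detector-side
    surface.  Background tissue inside the sphere is removed, not blended.
    Returns a new phantom; the input is left unmodified.
    """
    if diameter_mm <= 0:
        raise ParameterError(f"lesion diameter must be positive; got {diameter_mm}")
    labels = phantom.labels
    vox = phantom.voxel_size_mm
    radius_vox = (diameter_mm / 2.0) / vox
    iz = int(round(depth_mm / vox))
    if not (0 <= iz < labels.shape[2]):
        raise PlacementError(f"depth {depth_mm} mm outside the phantom thickness")

    interior = phantom.interior_mask()
    # Distance (voxels) from each interior voxel to the nearest non-interior
    # voxel (grid boundary counts as non-interior); the full sphere fits iff
    # this exceeds the radius.
    dist = ndimage.distance_transform_edt(np.pad(interior, 1))[1:-1, 1:-1, 1:-1]
    feasible = (labels == FIBROGLANDULAR) & (dist > radius_vox)
    candidates = np.argwhere(feasible[:, :, iz])
    if len(candidates) == 0:
        raise PlacementError(
            f"no fibroglandular center at depth {depth_mm} mm can contain a {diameter_mm} mm sphere"
        )
    rng = np.random.default_rng(seed)
    cx, cy = candidates[rng.integers(len(candidates))]
    center = (int(cx), int(cy), iz)

    offsets = _sphere_offsets(radius_vox)
    pts = offsets + np.array(center)
    new_labels = labels.copy()
    new_labels[pts[:, 0], pts[:, 1], pts[:, 2]] = LESION
    return replace(
        phantom,
        labels=new_labels,
        lesion=Lesion(center=center, diameter_mm=float(diameter_mm)),
    )


def save_phantom(phantom: BreastPhantom, path) -> None:
    """Write the label volume as NIfTI with a JSON sidecar of metadata."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([phantom.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.uint8), affine), str(path))
    sidecar = {
        "voxel_size_mm": phantom.voxel_size_mm,
        "vgf_target": phantom.vgf_target,
        "vgf_realized": phantom.vgf_realized,
        "seed": phantom.seed,
        "lesion": None
        if phantom.lesion is None
        else {"center": list(phantom.lesion.center), "diameter_mm": phantom.lesion.diameter_mm},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(path) -> BreastPhantom:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(path.with_suffix(".json").read_text())
    lesion = meta.get("lesion")
    return BreastPhantom(
        labels=np.asarray(img.dataobj, dtype=np.uint8),
        voxel_size_mm=meta["voxel_size_mm"],
        vgf_target=meta.get("vgf_target"),
        vgf_realized=meta.get("vgf_realized"),
        seed=meta.get("seed"),
        lesion=None if lesion is None else Lesion(tuple(lesion["center"]), lesion["diameter_mm"]),
    )
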