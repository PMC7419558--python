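"""Filtered back projection over the tomosynthesis arc, apodization, slabbing.

Projections are air-normalized into line integrals, ramp-filtered along the
source-motion direction, and back-projected onto a voxel grid (Feldkamp-style
cone-beam geometry with cosine pre-weighting).  A 3D Butterworth filter
apodizes the volume, which is then cut into thin slabs for reading and
texture analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from tomotex.errors import DegenerateInputError, ParameterError
from tomotex.phantom import BreastPhantom
from tomotex.projector import AcquisitionGeometry, ProjectionSet


@dataclass(frozen=True)
class VolumeSpec:
    """Reconstruction grid: corner at ``origin_mm``, voxel centers at +1/2."""

    shape: tuple  # (nx, ny, nz)
    in_plane_mm: float = 0.27
    slice_mm: float = 0.2
    origin_mm: tuple = (0.0, 0.0, 0.0)

    @property
    def depth_mm(self) -> float:
        return self.shape[2] * self.slice_mm

    def voxel_centers(self) -> tuple:
        nx, ny, nz = self.shape
        x = self.origin_mm[0] + (np.arange(nx) + 0.5) * self.in_plane_mm
        y = self.origin_mm[1] + (np.arange(ny) + 0.5) * self.in_plane_mm
        z = self.origin_mm[2] + (np.arange(nz) + 0.5) * self.slice_mm
        return x, y, z

    @classmethod
    def covering(cls, phantom: BreastPhantom, in_plane_mm: float = 0.27, slice_mm: Optional[float] = None) -> "VolumeSpec":
        """Grid covering the phantom footprint at the requested sampling."""
        if slice_mm is None:
            slice_mm = phantom.voxel_size_mm
        ext = np.asarray(phantom.shape) * phantom.voxel_size_mm
        nx = int(math.floor(ext[0] / in_plane_mm))
        ny = int(math.floor(ext[1] / in_plane_mm))
        nz = int(round(ext[2] / slice_mm))
        return cls((nx, ny, nz), in_plane_mm, slice_mm)


@dataclass
class ReconVolume:
    voxels: np.ndarray  # (nx, ny, nz)
    spec: VolumeSpec
    provenance: dict = field(default_factory=dict)


@dataclass
class SlabImage:
    """One thin reconstructed slab with truth and condition bookkeeping."""

    pixels: np.ndarray  # 2D (rows = x, cols = y)
    pixel_size_mm: float
    breast_mask: np.ndarray
    truth_present: bool = False
    truth_center: Optional[tuple] = None  # (row, col) in pixels
    condition: dict = field(default_factory=dict)
    slab_index: int = 0
    thickness_mm: float = 1.0


def _ramp_filter(sino: np.ndarray, pitch_mm: float) -> np.ndarray:
    """Ramp-filter each view along axis 0 (the source-motion direction)."""
    nu = sino.shape[0]
    n = 1 << max(6, int(np.ceil(np.log2(2 * nu))))
    freqs = np.fft.rfftfreq(n, d=pitch_mm)
    ramp = np.abs(freqs)
    padded = np.zeros((n,) + sino.shape[1:])
    padded[:nu] = sino
    filtered = np.fft.irfft(np.fft.rfft(padded, axis=0) * ramp[(slice(None),) + (None,) * (sino.ndim - 1)], n=n, axis=0)
    return filtered[:nu]


def line_integrals(projections: ProjectionSet, floor_fraction: float = 1e-6) -> np.ndarray:
    """Air-normalized log transform: g = -ln(I / I_air), clipped at a floor."""
    ref = projections.air_reference
    if not np.isfinite(ref) or ref <= 0:
        raise ParameterError("projection set is missing a positive air reference")
    ratio = np.maximum(projections.images / ref, floor_fraction)
    return -np.log(ratio)


def fbp_from_line_integrals(
    sinogram: np.ndarray, geometry: AcquisitionGeometry, out_grid: VolumeSpec
) -> ReconVolume:
    """Ramp-filter and back-project line integrals.  Linear in the input."""
    p = sinogram.shape[0]
    if p != geometry.n_projections:
        raise ParameterError("sinogram view count does not match the geometry")
    pitch = geometry.pixel_pitch_mm
    xs, ys, zs = out_grid.voxel_centers()
    vol = np.zeros(out_grid.shape)
    vx = xs[:, None, None]
    vy = ys[None, :, None]
    vz = zs[None, None, :]

    for k, ang in enumerate(geometry.angles_deg):
        src = geometry.source_position(ang)
        view = _ramp_filter(sinogram[k], pitch)
        # Central projection of each voxel center onto the detector plane z=0.
        t = src[2] / (src[2] - vz)
        u = src[0] + t * (vx - src[0])
        v = src[1] + t * (vy - src[1])
        u_px = (u - geometry.detector_origin_mm[0]) / pitch - 0.5
        v_px = (v - geometry.detector_origin_mm[1]) / pitch - 0.5
        u_px, v_px = np.broadcast_arrays(u_px, v_px)
        sampled = ndimage.map_coordinates(
            view, [u_px.ravel(), v_px.ravel()], order=1, mode="constant", cval=0.0
        ).reshape(out_grid.shape)
        vol += sampled

    vol /= p
    return ReconVolume(
        voxels=vol,
        spec=out_grid,
        provenance={"geometry": geometry, "n_projections": p},
    )


def fbp_reconstruct(projections: ProjectionSet, out_grid: VolumeSpec) -> ReconVolume:
    """Feldkamp FBP of an air-normalized projection set."""
    sino = line_integrals(projections)
    vol = fbp_from_line_integrals(sino, projections.geometry, out_grid)
    vol.provenance["noise_meta"] = dict(projections.noise_meta)
    return vol


def butterworth3d(volume: ReconVolume, cutoff: float = 0.25, order: int = 4) -> ReconVolume:
    """Isotropic low-pass apodization, gain 1/sqrt(1 + (f/cutoff)^(2*order)).

    Frequency is radial in cycles/pixel (index space).  DC gain is exactly 1.
    """
    if not (0.0 < cutoff <= 0.5):
        raise ParameterError(f"cutoff must lie in (0, 0.5]; got {cutoff}")
    v = volume.voxels
    fx = np.fft.fftfreq(v.shape[0])[:, None, None]
    fy = np.fft.fftfreq(v.shape[1])[None, :, None]
    fz = np.fft.rfftfreq(v.shape[2])[None, None, :]
    f = np.sqrt(fx**2 + fy**2 + fz**2)
    gain = 1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))
    out = np.fft.irfftn(np.fft.rfftn(v) * gain, s=v.shape, axes=(0, 1, 2))
    prov = dict(volume.provenance)
    prov["butterworth"] = {"cutoff": cutoff, "order": order}
    return ReconVolume(voxels=out, spec=volume.spec, provenance=prov)


def project_support(phantom: BreastPhantom, grid: VolumeSpec) -> np.ndarray:
    """2D in-plane footprint of the phantom tissue, resampled to the slab grid."""
    support2d = phantom.support_mask().any(axis=2)
    xs, ys, _ = grid.voxel_centers()
    ix = np.floor(xs / phantom.voxel_size_mm).astype(int)
    iy = np.floor(ys / phantom.voxel_size_mm).astype(int)
    ok_x = (ix >= 0) & (ix < support2d.shape[0])
    ok_y = (iy >= 0) & (iy < support2d.shape[1])
    mask = np.zeros((len(xs), len(ys)), dtype=bool)
    sub = support2d[np.clip(ix, 0, support2d.shape[0] - 1)][:, np.clip(iy, 0, support2d.shape[1] - 1)]
    mask = sub & ok_x[:, None] & ok_y[None, :]
    return mask


def build_breast_mask(slab: SlabImage) -> np.ndarray:
    """Validated breast mask of a slab (from phantom support, not thresholds)."""
    if not np.all(np.isfinite(slab.pixels)):
        raise ParameterError("slab contains non-finite pixels")
    mask = np.asarray(slab.breast_mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("slab has an empty breast support")
    return mask


def slab_volume(
    volume: ReconVolume,
    thickness_mm: float = 1.0,
    phantom: Optional[BreastPhantom] = None,
    mode: str = "mean",
    condition: Optional[dict] = None,
) -> list:
    """Cut the volume into contiguous non-overlapping slabs of ``thickness_mm``.

    Each slab is the mean (or max, per ``mode``) over its slice group.  If a
    phantom is given, its projected support becomes the breast mask and any
    lesion truth is attached to the slab containing the lesion center.
    """
    if thickness_mm <= 0:
        raise ParameterError("slab thickness must be positive")
    spec = volume.spec
    if spec.depth_mm < thickness_mm:
        raise ParameterError("volume depth is smaller than the slab thickness")
    per = thickness_mm / spec.slice_mm
    n_per = int(round(per))
    if abs(per - n_per) > 1e-9 or n_per < 1:
        raise ParameterError(
            f"slab thickness {thickness_mm} mm must be a multiple of the slice spacing {spec.slice_mm} mm"
        )
    n_slabs = int(math.floor(spec.depth_mm / thickness_mm))

    if phantom is not None:
        mask = project_support(phantom, spec)
        lesion = phantom.lesion
    else:
        mask = np.ones(spec.shape[:2], dtype=bool)
        lesion = None

    truth_slab = truth_center = None
    if lesion is not None:
        cx, cy, cz = lesion.center
        depth = (cz + 0.5) * phantom.voxel_size_mm
        truth_slab = int(math.floor(depth / thickness_mm))
        row = (cx + 0.5) * phantom.voxel_size_mm / spec.in_plane_mm - 0.5
        col = (cy + 0.5) * phantom.voxel_size_mm / spec.in_plane_mm - 0.5
        truth_center = (float(row), float(col))

    reducer = np.max if mode == "max" else np.mean
    slabs = []
    for s in range(n_slabs):
        block = volume.voxels[:, :, s * n_per : (s + 1) * n_per]
        present = truth_slab == s
        slabs.append(
            SlabImage(
                pixels=reducer(block, axis=2),
                pixel_size_mm=spec.in_plane_mm,
                breast_mask=mask,
                truth_present=bool(present),
                truth_center=truth_center if present else None,
                condition=dict(condition or {}),
                slab_index=s,
                thickness_mm=float(thickness_mm),
            )
        )
    return slabs
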