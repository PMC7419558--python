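"""Noisy limited-arc X-ray projection of a voxel phantom.

Geometry: stationary detector in the z = 0 plane, phantom resting on it, and
a point source rotating in the x-z plane about a center above the phantom.
X-ray transmission uses Siddon ray tracing through the label grid; the
detector cascade applies Poisson quantum noise (per energy bin), Gaussian
blur for the combined focal-spot/scintillator response, a scalar gain, and
additive electronic noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from tomotex.errors import ParameterError, SchemaError
from tomotex.phantom import LABEL_NAMES, BreastPhantom, MaterialTable

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Nominal detector-entrance fluence per pixel per mGy at the reference
#: geometry.  Only relative noise across conditions matters downstream.
PHOTONS_PER_PIXEL_PER_MGY = 40000.0


@dataclass(frozen=True)
class Spectrum:
    """Source spectrum: fluence weights (relative) on an energy grid in keV.

    ``qde`` is the detector quantum detection efficiency per bin (default 1).
    """

    energies_keV: np.ndarray
    weights: np.ndarray
    qde: Optional[np.ndarray] = None

    def __post_init__(self):
        e = np.atleast_1d(np.asarray(self.energies_keV, dtype=float))
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if e.shape != w.shape:
            raise SchemaError("spectrum energies and weights must align")
        if np.any(w < 0) or not np.any(w > 0):
            raise SchemaError("spectrum weights must be nonnegative with at least one positive")
        q = self.qde
        q = np.ones_like(w) if q is None else np.atleast_1d(np.asarray(q, dtype=float))
        if q.shape != w.shape:
            raise SchemaError("QDE grid must align with the spectrum")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "weights", w / w.sum())
        object.__setattr__(self, "qde", q)

    @classmethod
    def monoenergetic(cls, energy_keV: float = 20.0) -> "Spectrum":
        return cls(np.array([energy_keV]), np.array([1.0]))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"energy_keV": self.energies_keV, "weight": self.weights, "qde": self.qde}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        import pandas as pd

        df = pd.read_csv(path)
        qde = df["qde"].to_numpy(float) if "qde" in df.columns else None
        return cls(df["energy_keV"].to_numpy(float), df["weight"].to_numpy(float), qde)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Rotating-source, stationary-detector tomosynthesis arc."""

    n_projections: int
    arc_span_deg: float = 60.0
    sdd_mm: float = 650.0  # source to detector plane, at the central view
    scd_mm: float = 600.0  # source to rotation center
    pixel_pitch_mm: float = 0.14
    detector_shape: tuple = (760, 240)  # pixels (u along x, v along y)
    detector_origin_mm: tuple = (0.0, 0.0)
    total_dose_mGy: float = 1.5

    def __post_init__(self):
        if self.n_projections < 1:
            raise ParameterError(f"n_projections must be >= 1; got {self.n_projections}")
        if self.total_dose_mGy <= 0:
            raise ParameterError("total_dose_mGy must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        """Equally spaced view angles, symmetric about the detector normal."""
        p = self.n_projections
        if p == 1:
            return np.array([0.0])
        return np.linspace(-self.arc_span_deg / 2.0, self.arc_span_deg / 2.0, p)

    @property
    def rotation_center_mm(self) -> np.ndarray:
        cx = self.detector_origin_mm[0] + self.detector_shape[0] * self.pixel_pitch_mm / 2.0
        cy = self.detector_origin_mm[1] + self.detector_shape[1] * self.pixel_pitch_mm / 2.0
        return np.array([cx, cy, self.sdd_mm - self.scd_mm])

    def source_position(self, angle_deg: float) -> np.ndarray:
        th = np.deg2rad(angle_deg)
        c = self.rotation_center_mm
        return np.array([c[0] + self.scd_mm * np.sin(th), c[1], c[2] + self.scd_mm * np.cos(th)])

    def detector_pixel_centers(self) -> tuple:
        """(xs, ys) of pixel centers along u and v, in mm."""
        nu, nv = self.detector_shape
        xs = self.detector_origin_mm[0] + (np.arange(nu) + 0.5) * self.pixel_pitch_mm
        ys = self.detector_origin_mm[1] + (np.arange(nv) + 0.5) * self.pixel_pitch_mm
        return xs, ys

    @classmethod
    def centered_on(cls, phantom: BreastPhantom, **kwargs) -> "AcquisitionGeometry":
        """Geometry whose detector is centered under the phantom footprint."""
        geo = cls(**kwargs)
        ext_x = phantom.shape[0] * phantom.voxel_size_mm
        ext_y = phantom.shape[1] * phantom.voxel_size_mm
        det_x = geo.detector_shape[0] * geo.pixel_pitch_mm
        det_y = geo.detector_shape[1] * geo.pixel_pitch_mm
        origin = ((ext_x - det_x) / 2.0, (ext_y - det_y) / 2.0)
        return cls(**{**kwargs, "detector_origin_mm": origin})


@dataclass
class ProjectionSet:
    """P detector images with acquisition and noise provenance."""

    images: np.ndarray  # (P, nu, nv)
    geometry: AcquisitionGeometry
    air_reference: float  # detector value of an unattenuated ray
    noise_meta: dict = field(default_factory=dict)
    noiseless: Optional[np.ndarray] = None
    energy_images: Optional[np.ndarray] = None  # (E, P, nu, nv) expected counts/bin

    @property
    def n_projections(self) -> int:
        return self.images.shape[0]


def per_view_exposure(total_dose_mGy: float, n_projections: int) -> float:
    """Dose per projection when the total dose is split evenly across views."""
    if n_projections < 1:
        raise ParameterError(f"n_projections must be >= 1; got {n_projections}")
    if total_dose_mGy <= 0:
        raise ParameterError("total_dose_mGy must be positive")
    return total_dose_mGy / n_projections


def siddon_trace(ray: tuple, grid: tuple) -> list:
    """Exact voxel traversal of one ray through a regular grid.

    Parameters
    ----------
    ray : ((x0, y0, z0), (x1, y1, z1)) endpoints in mm.
    grid : (shape, voxel_size_mm) — grid corner at the origin.

    Returns
    -------
    list of ((ix, iy, iz), length_mm), ordered along the ray.  Empty if the
    ray misses the grid.
    """
    p0 = np.asarray(ray[0], dtype=float)
    p1 = np.asarray(ray[1], dtype=float)
    shape, vox = grid
    shape = np.asarray(shape, dtype=int)
    d = p1 - p0
    length = float(np.linalg.norm(d))
    if length == 0.0:
        raise ParameterError("zero-length ray")

    box_max = shape * vox
    amin, amax = 0.0, 1.0
    for ax in range(3):
        if d[ax] != 0.0:
            a0 = (0.0 - p0[ax]) / d[ax]
            a1 = (box_max[ax] - p0[ax]) / d[ax]
            amin = max(amin, min(a0, a1))
            amax = min(amax, max(a0, a1))
        elif not (0.0 <= p0[ax] <= box_max[ax]):
            return []
    if amax <= amin:
        return []

    alphas = [amin, amax]
    for ax in range(3):
        if d[ax] != 0.0:
            planes = np.arange(shape[ax] + 1) * vox
            a = (planes - p0[ax]) / d[ax]
            alphas.extend(a[(a > amin) & (a < amax)])
    alphas = np.unique(np.asarray(alphas, dtype=float))

    out = []
    eps = 1e-12
    for k in range(len(alphas) - 1):
        da = alphas[k + 1] - alphas[k]
        if da * length <= eps:
            continue
        mid = p0 + 0.5 * (alphas[k] + alphas[k + 1]) * d
        frac = mid / vox
        idx = np.floor(frac).astype(int)
        # Tangent rays sitting exactly on a voxel face: lower-index rule.
        on_face = np.isclose(frac, np.round(frac), rtol=0.0, atol=1e-9) & (np.round(frac) == idx)
        idx = np.where(on_face & (idx > 0), idx - 1, idx)
        idx = np.clip(idx, 0, shape - 1)
        out.append(((int(idx[0]), int(idx[1]), int(idx[2])), float(da * length)))
    return out


def _label_path_lengths(
    src: np.ndarray,
    det_pts: np.ndarray,
    labels: np.ndarray,
    vox: float,
    n_labels: int,
    chunk: int = 20000,
) -> np.ndarray:
    """Per-ray path length through each material label, batched Siddon.

    Returns an array of shape (n_rays, n_labels) of intersection lengths in mm.
    """
    shape = np.asarray(labels.shape)
    box_max = shape * vox
    n_rays = det_pts.shape[0]
    out = np.zeros((n_rays, n_labels))

    for lo in range(0, n_rays, chunk):
        pts = det_pts[lo : lo + chunk]
        d = pts - src[None, :]
        length = np.linalg.norm(d, axis=1)

        amin = np.zeros(len(pts))
        amax = np.ones(len(pts))
        miss = np.zeros(len(pts), dtype=bool)
        for ax in range(3):
            dax = d[:, ax]
            nonpar = dax != 0.0
            with np.errstate(divide="ignore", invalid="ignore"):
                a0 = (0.0 - src[ax]) / dax
                a1 = (box_max[ax] - src[ax]) / dax
            lo_a = np.minimum(a0, a1)
            hi_a = np.maximum(a0, a1)
            amin = np.where(nonpar, np.maximum(amin, lo_a), amin)
            amax = np.where(nonpar, np.minimum(amax, hi_a), amax)
            miss |= ~nonpar & ~((0.0 <= src[ax]) & (src[ax] <= box_max[ax]))
        miss |= amax <= amin

        # All candidate plane crossings; out-of-range ones collapse onto amin.
        cols = [amin[:, None], amax[:, None]]
        for ax in range(3):
            planes = np.arange(shape[ax] + 1) * vox
            dax = d[:, ax]
            with np.errstate(divide="ignore", invalid="ignore"):
                a = (planes[None, :] - src[ax]) / dax[:, None]
            a = np.where(np.isfinite(a), a, -1.0)
            a = np.clip(a, amin[:, None], amax[:, None])
            cols.append(a)
        alphas = np.sort(np.concatenate(cols, axis=1), axis=1)

        seg = np.diff(alphas, axis=1)
        mids = src[None, None, :] + 0.5 * (alphas[:, :-1, None] + alphas[:, 1:, None]) * d[:, None, :]
        idx = np.floor(mids / vox).astype(np.int64)
        np.clip(idx, 0, (shape - 1)[None, None, :], out=idx)
        seg_labels = labels[idx[..., 0], idx[..., 1], idx[..., 2]]
        seg_len = seg * length[:, None]
        seg_len[miss] = 0.0
        for lab in range(n_labels):
            out[lo : lo + chunk, lab] = np.sum(seg_len * (seg_labels == lab), axis=1)
    return out


def project_noiseless(
    phantom: BreastPhantom,
    geometry: AcquisitionGeometry,
    materials: MaterialTable,
    spectrum: Spectrum,
    photons_per_mGy: float = PHOTONS_PER_PIXEL_PER_MGY,
) -> ProjectionSet:
    """Expected detector counts for each view (Beer-Lambert, no noise).

    Each pixel receives sum_E w(E) * QDE(E) * I0 * exp(-sum_v mu(label_v, E) * l_v)
    with the per-view fluence I0 set by the evenly split total dose.
    """
    nu, nv = geometry.detector_shape
    xs, ys = geometry.detector_pixel_centers()
    det_pts = np.stack(
        [np.repeat(xs, nv), np.tile(ys, nu), np.zeros(nu * nv)], axis=1
    )
    n_labels = max(LABEL_NAMES) + 1
    energies = spectrum.energies_keV
    mu_lookup = np.stack([materials.mu_by_label(e) for e in energies])  # (E, n_labels)

    i0 = photons_per_mGy * per_view_exposure(geometry.total_dose_mGy, geometry.n_projections)
    bin_fluence = i0 * spectrum.weights * spectrum.qde  # (E,)

    p = geometry.n_projections
    energy_images = np.empty((len(energies), p, nu, nv))
    for k, ang in enumerate(geometry.angles_deg):
        src = geometry.source_position(ang)
        pl = _label_path_lengths(src, det_pts, phantom.labels, phantom.voxel_size_mm, n_labels)
        att = np.exp(-pl @ mu_lookup.T)  # (n_rays, E)
        energy_images[:, k] = (att * bin_fluence[None, :]).T.reshape(len(energies), nu, nv)

    images = energy_images.sum(axis=0)
    air_reference = float(bin_fluence.sum())
    return ProjectionSet(
        images=images,
        geometry=geometry,
        air_reference=air_reference,
        noise_meta={"noisy": False},
        energy_images=energy_images if len(energies) > 1 else None,
    )


def apply_detector(
    noiseless: ProjectionSet,
    blur_fwhm_mm: float = 0.0,
    gain: float = 1.0,
    electronic_sd: float = 0.0,
    seed: int = 0,
    poisson: bool = True,
) -> ProjectionSet:
    """Detector cascade: Poisson quanta, blur, gain, additive electronic noise.

    With Poisson disabled and zero blur and electronic noise, the output is
    exactly ``gain`` times the input.  For polychromatic inputs the Poisson
    draw happens per energy bin before summation.
    """
    if gain <= 0:
        raise ParameterError("gain must be positive")
    if blur_fwhm_mm < 0 or electronic_sd < 0:
        raise ParameterError("blur_fwhm_mm and electronic_sd must be nonnegative")
    if np.any(noiseless.images < 0):
        raise ParameterError("noiseless projections must be nonnegative")

    rng = np.random.default_rng(seed)
    if poisson:
        if noiseless.energy_images is not None:
            quanta = rng.poisson(noiseless.energy_images).astype(float).sum(axis=0)
        else:
            quanta = rng.poisson(noiseless.images).astype(float)
    else:
        quanta = noiseless.images.astype(float)

    if blur_fwhm_mm > 0:
        sigma_px = blur_fwhm_mm * _FWHM_TO_SIGMA / noiseless.geometry.pixel_pitch_mm
        quanta = np.stack([ndimage.gaussian_filter(im, sigma_px, mode="nearest") for im in quanta])

    out = quanta * gain
    if electronic_sd > 0:
        out = out + rng.normal(0.0, electronic_sd, size=out.shape)

    return ProjectionSet(
        images=out,
        geometry=noiseless.geometry,
        air_reference=noiseless.air_reference * gain,
        noise_meta={
            "noisy": True,
            "seed": int(seed),
            "gain": float(gain),
            "electronic_sd": float(electronic_sd),
            "blur_fwhm_mm": float(blur_fwhm_mm),
            "poisson": bool(poisson),
        },
        noiseless=noiseless.images,
    )


def save_projections(pset: ProjectionSet, path) -> None:
    """Multi-page TIFF plus a JSON sidecar with geometry and noise metadata."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(str(path), pset.images.astype(np.float32), photometric="minisblack")
    geo = pset.geometry
    sidecar = {
        "angles_deg": geo.angles_deg.tolist(),
        "arc_span_deg": geo.arc_span_deg,
        "n_projections": geo.n_projections,
        "sdd_mm": geo.sdd_mm,
        "scd_mm": geo.scd_mm,
        "pixel_pitch_mm": geo.pixel_pitch_mm,
        "detector_shape": list(geo.detector_shape),
        "detector_origin_mm": list(geo.detector_origin_mm),
        "total_dose_mGy": geo.total_dose_mGy,
        "air_reference": pset.air_reference,
        "noise_meta": pset.noise_meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_projections(path) -> ProjectionSet:
    import tifffile

    path = Path(path)
    images = np.asarray(tifffile.imread(str(path)), dtype=float)
    if images.ndim == 2:
        images = images[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    geometry = AcquisitionGeometry(
        n_projections=meta["n_projections"],
        arc_span_deg=meta["arc_span_deg"],
        sdd_mm=meta["sdd_mm"],
        scd_mm=meta["scd_mm"],
        pixel_pitch_mm=meta["pixel_pitch_mm"],
        detector_shape=tuple(meta["detector_shape"]),
        detector_origin_mm=tuple(meta["detector_origin_mm"]),
        total_dose_mGy=meta["total_dose_mGy"],
    )
    return ProjectionSet(
        images=images,
        geometry=geometry,
        air_reference=meta["air_reference"],
        noise_meta=meta.get("noise_meta", {}),
    )
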