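"""Study configuration, image-inventory bookkeeping, and pipeline orchestration.

The default configuration mirrors the full study design: 6 phantoms (half at
25% and half at 50% glandular fraction), 8 lesion-present variants plus one
lesion-free run per phantom, 12 projection-number conditions over a 60° arc
at 1.5 mGy total dose, and both an unfiltered and a Wiener-filtered arm.
``reduced()`` provides a desk-scale preset for end-to-end runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator

from tomotex import correlate as corr_mod
from tomotex import lroc as lroc_mod
from tomotex import texture as tex_mod
from tomotex.errors import DependencyError, ParameterError
from tomotex.phantom import BreastPhantom, default_materials, generate_phantom, insert_lesion, save_phantom
from tomotex.projector import AcquisitionGeometry, Spectrum, apply_detector, project_noiseless
from tomotex.recon import VolumeSpec, butterworth3d, fbp_reconstruct, slab_volume
from tomotex.wiener import WienerConfig, filter_projection_set

log = logging.getLogger("tomotex.study")

DEFAULT_P_LIST = (3, 7, 11, 15, 19, 21, 25, 31, 35, 41, 45, 51)


class StudyConfig(BaseModel):
    """Complete, validated description of one simulation study."""

    # phantoms
    n_phantoms: int = 6
    vgfs: tuple = (0.25, 0.5)  # assigned round-robin across phantoms
    grid_shape: tuple = (1016, 320, 250)
    voxel_size_mm: float = 0.2
    phantom_seed: int = 0
    phantom_compartments: Optional[int] = None  # None: scale with grid size
    # lesions
    lesion_variants: int = 8
    lesion_diameter_mm: float = 8.0
    # acquisition
    p_list: tuple = DEFAULT_P_LIST
    arc_span_deg: float = 60.0
    total_dose_mGy: float = 1.5
    detector_shape: tuple = (760, 240)
    pixel_pitch_mm: float = 0.27
    energy_keV: float = 20.0
    photons_per_mGy: float = 40000.0
    blur_fwhm_mm: float = 0.2
    gain: float = 1.0
    electronic_sd: float = 12.0
    # processing arms
    arms: tuple = ("noisy", "filtered")
    wiener_window: int = 5
    # reconstruction
    recon_in_plane_mm: float = 0.27
    slab_thickness_mm: float = 1.0
    butterworth_cutoff: float = 0.25
    butterworth_order: int = 4
    # texture
    quant_levels: int = 256
    quant_range_quantiles: Optional[tuple] = None  # e.g. (1, 99) robust range
    roi_side: int = 35
    glcm_d: int = 1
    ngtdm_n: int = 1
    # observer
    n_train: int = 18
    n_test: int = 54
    localization_radius_px: float = 15.0
    loc_error_scale_px: float = 4.0
    detectability_gain: float = 1.0
    # bookkeeping
    seed: int = 0
    output_root: str = "study_out"

    @field_validator("n_phantoms", "lesion_variants")
    @classmethod
    def _positive(cls, v, info):
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1")
        return v

    @field_validator("p_list")
    @classmethod
    def _valid_p(cls, v):
        if not v or any(p < 1 for p in v):
            raise ValueError("p_list must be non-empty with all P >= 1")
        return tuple(int(p) for p in v)

    @field_validator("arms")
    @classmethod
    def _valid_arms(cls, v):
        bad = set(v) - {"noisy", "filtered"}
        if bad or not v:
            raise ValueError(f"arms must be a non-empty subset of ('noisy', 'filtered'); got {v}")
        return tuple(v)

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]

    def phantom_vgf(self, phantom_index: int) -> float:
        return float(self.vgfs[phantom_index % len(self.vgfs)])

    @classmethod
    def reduced(cls, **overrides) -> "StudyConfig":
        """Desk-scale preset: coarse grids, short P list, small sessions."""
        base = dict(
            n_phantoms=2,
            grid_shape=(64, 64, 50),
            voxel_size_mm=1.0,
            phantom_compartments=150,
            lesion_variants=2,
            p_list=(3, 25),
            detector_shape=(72, 72),
            pixel_pitch_mm=1.0,
            photons_per_mGy=12000.0,
            electronic_sd=2.0,
            recon_in_plane_mm=1.0,
            slab_thickness_mm=2.0,
            butterworth_cutoff=0.3,
            roi_side=16,
            quant_levels=16,
            quant_range_quantiles=(2.0, 98.0),
            n_train=4,
            n_test=24,
            blur_fwhm_mm=0.0,
            loc_error_scale_px=3.0,
            detectability_gain=5.0,
        )
        base.update(overrides)
        return cls(**base)


def _lesion_depths(config: StudyConfig) -> np.ndarray:
    """Seeded per-variant lesion depths (mm), kept clear of the surfaces."""
    rng = np.random.default_rng(config.seed + 104729)
    thickness = config.grid_shape[2] * config.voxel_size_mm
    margin = config.lesion_diameter_mm / 2.0 + 2.0 * config.voxel_size_mm
    return rng.uniform(margin, thickness - margin, size=config.lesion_variants)


def build_inventory(
    config: StudyConfig,
    p_list: Optional[Sequence[int]] = None,
    arms: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Enumerate every unique slab of the study without simulating images.

    Per phantom and condition: one lesion-present slab per variant, plus the
    same number of depth-matched lesion-absent slabs from the lesion-free run.
    """
    p_list = tuple(config.p_list if p_list is None else p_list)
    arms = tuple(config.arms if arms is None else arms)
    depths = _lesion_depths(config)
    rows = []
    for arm in arms:
        for p in p_list:
            for ph in range(config.n_phantoms):
                for variant, depth in enumerate(depths):
                    for present in (True, False):
                        rows.append(
                            {
                                "image_id": f"ph{ph}_v{variant}_{'les' if present else 'bg'}_P{p}_{arm}",
                                "phantom": ph,
                                "vgf": config.phantom_vgf(ph),
                                "variant": variant,
                                "truth_present": present,
                                "depth_mm": float(depth),
                                "P": int(p),
                                "arm": arm,
                            }
                        )
    return pd.DataFrame(rows)


def inventory_counts(config: StudyConfig) -> dict:
    """Slab counts per condition, per arm, and in total."""
    inv = build_inventory(config)
    per_condition = int(len(inv) // (len(config.p_list) * len(config.arms)))
    per_arm = int(len(inv) // len(config.arms))
    return {"per_condition": per_condition, "per_arm": per_arm, "total": int(len(inv))}


# ---------------------------------------------------------------------------
# In-memory simulation of one phantom/variant/condition


def _geometry(config: StudyConfig, p: int, phantom: BreastPhantom) -> AcquisitionGeometry:
    return AcquisitionGeometry.centered_on(
        phantom,
        n_projections=p,
        arc_span_deg=config.arc_span_deg,
        pixel_pitch_mm=config.pixel_pitch_mm,
        detector_shape=tuple(config.detector_shape),
        total_dose_mGy=config.total_dose_mGy,
    )


def simulate_condition_slabs(
    config: StudyConfig,
    phantom: BreastPhantom,
    p: int,
    arm: str,
    noise_seed: int,
    noiseless=None,
    condition: Optional[dict] = None,
):
    """Project, add detector noise, optionally Wiener-filter, reconstruct, slab."""
    geometry = _geometry(config, p, phantom)
    if noiseless is None:
        noiseless = project_noiseless(
            phantom, geometry, default_materials(), Spectrum.monoenergetic(config.energy_keV),
            photons_per_mGy=config.photons_per_mGy,
        )
    noisy = apply_detector(
        noiseless,
        blur_fwhm_mm=config.blur_fwhm_mm,
        gain=config.gain,
        electronic_sd=config.electronic_sd,
        seed=noise_seed,
    )
    if arm == "filtered":
        noisy = filter_projection_set(noisy, WienerConfig(window=config.wiener_window))
    grid = VolumeSpec.covering(phantom, in_plane_mm=config.recon_in_plane_mm)
    vol = fbp_reconstruct(noisy, grid)
    vol = butterworth3d(vol, cutoff=config.butterworth_cutoff, order=config.butterworth_order)
    return slab_volume(
        vol,
        thickness_mm=config.slab_thickness_mm,
        phantom=phantom,
        condition=condition,
    )


def _lesion_regions(slab, lesion_radius_px: float) -> tuple:
    """Signal-disk and background boolean masks around the known lesion center."""
    if not slab.truth_present or slab.truth_center is None:
        raise ParameterError("CNR needs a lesion-present slab with a truth center")
    h, w = slab.pixels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - slab.truth_center[0], cc - slab.truth_center[1])
    sig = dist <= 0.7 * lesion_radius_px
    bg = slab.breast_mask & (dist > 2.0 * lesion_radius_px)
    if not sig.any() or bg.sum() < 16:
        raise ParameterError("slab too small for the CNR regions")
    return sig, bg


def lesion_cnr(slab, lesion_radius_px: float, signal_amplitude: Optional[float] = None) -> float:
    """Contrast-to-noise of the known lesion against the in-mask background.

    When ``signal_amplitude`` is given (e.g. measured on a noiseless
    reconstruction, which is more robust at low photon counts), only the
    background SD is taken from this slab.
    """
    sig, bg = _lesion_regions(slab, lesion_radius_px)
    std_bg = float(slab.pixels[bg].std())
    if signal_amplitude is None:
        signal_amplitude = float(slab.pixels[sig].mean() - slab.pixels[bg].mean())
    if std_bg == 0:
        return float("inf")
    return float(signal_amplitude / std_bg)


def noiseless_signal_amplitude(config: StudyConfig, lesioned, base, p: int,
                               noiseless_les, noiseless_bg, lesion_radius_px: float) -> tuple:
    """Lesion amplitude from the matched noiseless present/absent recon pair.

    Returns (amplitude, present-slab index).  Seed-independent.
    """
    grid = VolumeSpec.covering(lesioned, in_plane_mm=config.recon_in_plane_mm)

    def _recon_slabs(phantom, nset):
        pset = apply_detector(
            nset, blur_fwhm_mm=config.blur_fwhm_mm, gain=config.gain,
            electronic_sd=0.0, seed=0, poisson=False,
        )
        vol = butterworth3d(
            fbp_reconstruct(pset, grid), config.butterworth_cutoff, config.butterworth_order
        )
        return slab_volume(vol, thickness_mm=config.slab_thickness_mm, phantom=phantom)

    pres = next(s for s in _recon_slabs(lesioned, noiseless_les) if s.truth_present)
    absent = _recon_slabs(base, noiseless_bg)[pres.slab_index]
    sig, _ = _lesion_regions(pres, lesion_radius_px)
    amp = float((pres.pixels - absent.pixels)[sig].mean())
    return amp, pres.slab_index


# ---------------------------------------------------------------------------
# Reduced-scale trend experiment (qualitative reproduction at desk scale)


def run_trend_experiment(
    config: Optional[StudyConfig] = None,
    p_subset: Sequence[int] = (3, 11, 25, 45),
    seeds: Sequence[int] = tuple(range(20)),
    session_size: int = 50,
) -> dict:
    """Simulate AUC-vs-P and feature-vs-P curves on a reduced grid.

    For each seed and condition (P, arm), the lesion contrast-to-noise ratio
    measured on simulated slabs drives the synthetic observer's
    detectability; texture features are pooled over the lattice ROIs of the
    same slabs.  Returns per-seed AUC and feature-mean arrays.
    """
    if config is None:
        # Equal-density phantoms: mixing 25%/50% at desk scale smears the
        # photon-starvation onset across P and washes out feature curvature.
        config = StudyConfig.reduced(p_list=tuple(p_subset), vgfs=(0.25, 0.25))
    p_subset = list(p_subset)
    arms = list(config.arms)
    depths = _lesion_depths(config)

    # Phantoms and their lesioned variants are fixed across seeds.
    phantoms = []
    for ph in range(config.n_phantoms):
        base = generate_phantom(
            config.phantom_vgf(ph),
            config.grid_shape,
            seed=config.phantom_seed + ph,
            voxel_size_mm=config.voxel_size_mm,
            n_compartments=config.phantom_compartments,
        )
        lesioned = insert_lesion(
            base, config.lesion_diameter_mm, float(depths[0]), seed=config.seed + 31 * ph
        )
        phantoms.append((base, lesioned))

    # Noiseless projections are seed-independent: compute once.
    materials = default_materials()
    spectrum = Spectrum.monoenergetic(config.energy_keV)
    noiseless = {}
    for ph, (base, lesioned) in enumerate(phantoms):
        for p in p_subset:
            geometry = _geometry(config, p, base)
            noiseless[(ph, p, False)] = project_noiseless(
                base, geometry, materials, spectrum, photons_per_mGy=config.photons_per_mGy
            )
            noiseless[(ph, p, True)] = project_noiseless(
                lesioned, geometry, materials, spectrum, photons_per_mGy=config.photons_per_mGy
            )

    lesion_radius_px = (config.lesion_diameter_mm / 2.0) / config.recon_in_plane_mm
    # Seed-independent lesion amplitude per phantom and P, from the noiseless
    # present/absent recon pair (robust at low photon counts).
    amplitude = {}
    for ph, (base, lesioned) in enumerate(phantoms):
        for p in p_subset:
            amplitude[(ph, p)] = noiseless_signal_amplitude(
                config, lesioned, base, p,
                noiseless[(ph, p, True)], noiseless[(ph, p, False)], lesion_radius_px,
            )[0]

    n_seeds = len(seeds)
    auc = {arm: np.zeros((n_seeds, len(p_subset))) for arm in arms}
    cnr = {arm: np.zeros((n_seeds, len(p_subset))) for arm in arms}
    feats = {
        arm: {name: np.zeros((n_seeds, len(p_subset))) for name in tex_mod.FEATURE_NAMES}
        for arm in arms
    }

    for si, seed in enumerate(seeds):
        for pi, p in enumerate(p_subset):
            for arm in arms:
                cnrs = []
                rois_features = []
                guess_mask = None
                for ph, (base, lesioned) in enumerate(phantoms):
                    noise_seed = 1_000_003 * seed + 101 * ph + p
                    pres = simulate_condition_slabs(
                        config, lesioned, p, arm, noise_seed, noiseless=noiseless[(ph, p, True)]
                    )
                    pres_slab = next(s for s in pres if s.truth_present)
                    cnrs.append(
                        lesion_cnr(pres_slab, lesion_radius_px, signal_amplitude=amplitude[(ph, p)])
                    )
                    abs_slabs = simulate_condition_slabs(
                        config, base, p, arm, noise_seed + 7, noiseless=noiseless[(ph, p, False)]
                    )
                    bg_slab = abs_slabs[pres_slab.slab_index]
                    guess_mask = bg_slab.breast_mask
                    # Texture is pooled over central depth-matched slabs of
                    # the lesion-free run (stable against lesion placement).
                    mid = len(abs_slabs) // 2
                    picks = (mid - 4, mid - 2, mid, mid + 2, mid + 4)
                    tex_slabs = [abs_slabs[k] for k in picks if 0 <= k < len(abs_slabs)]
                    for slab in tex_slabs:
                        rois = tex_mod.lattice_rois(
                            slab, side=config.roi_side, levels=config.quant_levels,
                            range_quantiles=config.quant_range_quantiles,
                        )
                        for roi in rois:
                            rois_features.append(
                                tex_mod.feature_vector(roi, d=config.glcm_d, n=config.ngtdm_n)
                            )
                mean_cnr = float(np.mean(cnrs))
                cnr[arm][si, pi] = mean_cnr
                for name in tex_mod.FEATURE_NAMES:
                    vals = np.array([fv[name] for fv in rois_features])
                    feats[arm][name][si, pi] = float(np.nanmean(vals))

                detectability = config.detectability_gain * max(mean_cnr, 0.0)
                # Common random numbers across conditions within one seed:
                # AUC differences then reflect detectability differences only.
                session = _virtual_session(session_size, guess_mask, seed=seed)
                trials = lroc_mod.simulate_observer(
                    session,
                    detectability,
                    config.loc_error_scale_px,
                    guess_mask,
                    seed=7_000_003 * seed,
                )
                auc[arm][si, pi] = lroc_mod.lroc_auc(
                    trials, radius=config.localization_radius_px
                ).auc

    return {"p_subset": p_subset, "auc": auc, "cnr": cnr, "features": feats, "config": config}


def _virtual_session(n_images: int, mask: np.ndarray, seed: int) -> pd.DataFrame:
    """Balanced present/absent session with truth centers inside the mask."""
    rng = np.random.default_rng(seed)
    inside = np.argwhere(mask)
    rows = []
    for k in range(n_images):
        present = k % 2 == 0
        r, c = inside[rng.integers(len(inside))]
        rows.append(
            {
                "image_id": f"virtual{k}",
                "truth_present": present,
                "truth_row": float(r),
                "truth_col": float(c),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk staged study


STAGES = ("phantoms", "slabs", "texture", "observer", "correlate")


def run_study(config: StudyConfig, stages: Optional[Sequence[str]] = None, resume: bool = True) -> dict:
    """Run the staged pipeline, writing artifacts under ``config.output_root``.

    Completed stages (marker file present) are skipped when ``resume`` is
    true.  Returns the paths of the produced artifacts.
    """
    stages = list(STAGES if stages is None else stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ParameterError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    (root / "config.json").write_text(config.model_dump_json(indent=2))
    artifacts = {"root": str(root)}

    for stage in STAGES:
        if stage not in stages:
            continue
        marker = root / f".done_{stage}"
        if resume and marker.exists():
            log.info("stage %s: already complete, skipping", stage)
            continue
        t0 = time.time()
        log.info("stage %s: starting (config %s, seed %d)", stage, config.config_hash(), config.seed)
        _STAGE_FUNCS[stage](config, root, artifacts)
        marker.write_text(json.dumps({"elapsed_s": time.time() - t0, "config": config.config_hash()}))
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    return artifacts


def _stage_phantoms(config: StudyConfig, root: Path, artifacts: dict) -> None:
    pdir = root / "phantoms"
    pdir.mkdir(exist_ok=True)
    for ph in range(config.n_phantoms):
        phantom = generate_phantom(
            config.phantom_vgf(ph),
            config.grid_shape,
            seed=config.phantom_seed + ph,
            voxel_size_mm=config.voxel_size_mm,
            n_compartments=config.phantom_compartments,
        )
        save_phantom(phantom, pdir / f"phantom{ph}.nii")
    artifacts["phantoms"] = str(pdir)


def _stage_slabs(config: StudyConfig, root: Path, artifacts: dict) -> None:
    import tifffile

    from tomotex.phantom import load_phantom

    pdir = root / "phantoms"
    if not pdir.exists():
        raise DependencyError("slabs stage needs the phantoms stage output")
    sdir = root / "slabs"
    sdir.mkdir(exist_ok=True)
    inventory = build_inventory(config)
    depths = _lesion_depths(config)
    materials = default_materials()
    spectrum = Spectrum.monoenergetic(config.energy_keV)
    lesion_radius_px = (config.lesion_diameter_mm / 2.0) / config.recon_in_plane_mm

    manifest_rows = []
    for ph in range(config.n_phantoms):
        base = load_phantom(pdir / f"phantom{ph}.nii")
        variants = {
            v: insert_lesion(base, config.lesion_diameter_mm, float(depths[v]), seed=config.seed + 31 * ph + v)
            for v in range(config.lesion_variants)
        }
        for p in sorted(set(inventory["P"])):
            geometry = _geometry(config, p, base)
            noiseless_bg = project_noiseless(
                base, geometry, materials, spectrum, photons_per_mGy=config.photons_per_mGy
            )
            for v, lesioned in variants.items():
                noiseless_les = project_noiseless(
                    lesioned, geometry, materials, spectrum, photons_per_mGy=config.photons_per_mGy
                )
                for arm in config.arms:
                    noise_seed = config.seed + 100_000 * ph + 1000 * v + p
                    pres = simulate_condition_slabs(
                        config, lesioned, p, arm, noise_seed, noiseless=noiseless_les,
                        condition={"P": p, "arm": arm, "phantom": ph, "variant": v},
                    )
                    pres_slab = next(s for s in pres if s.truth_present)
                    bg = simulate_condition_slabs(
                        config, base, p, arm, noise_seed + 7, noiseless=noiseless_bg,
                        condition={"P": p, "arm": arm, "phantom": ph, "variant": v},
                    )
                    bg_slab = bg[pres_slab.slab_index]
                    for present, slab in ((True, pres_slab), (False, bg_slab)):
                        image_id = f"ph{ph}_v{v}_{'les' if present else 'bg'}_P{p}_{arm}"
                        fname = f"{image_id}.tif"
                        lo, hi = slab.pixels.min(), slab.pixels.max()
                        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
                        tifffile.imwrite(str(sdir / fname), ((slab.pixels - lo) * scale).astype(np.uint16))
                        manifest_rows.append(
                            {
                                "image_id": image_id,
                                "file": fname,
                                "phantom": ph,
                                "vgf": config.phantom_vgf(ph),
                                "variant": v,
                                "truth_present": present,
                                "truth_row": pres_slab.truth_center[0] if present else "",
                                "truth_col": pres_slab.truth_center[1] if present else "",
                                "depth_mm": float(depths[v]),
                                "P": p,
                                "arm": arm,
                                "slab_index": slab.slab_index,
                                "cnr": lesion_cnr(slab, lesion_radius_px) if present else "",
                                "intensity_lo": float(lo),
                                "intensity_hi": float(hi),
                            }
                        )
    pd.DataFrame(manifest_rows).to_csv(sdir / "manifest.csv", index=False)
    np.save(sdir / "breast_mask.npy", _geometry_mask(config, root))
    artifacts["slabs"] = str(sdir)


def _geometry_mask(config: StudyConfig, root: Path) -> np.ndarray:
    from tomotex.phantom import load_phantom
    from tomotex.recon import VolumeSpec, project_support

    base = load_phantom(root / "phantoms" / "phantom0.nii")
    grid = VolumeSpec.covering(base, in_plane_mm=config.recon_in_plane_mm)
    return project_support(base, grid)


def _load_slabs_by_condition(config: StudyConfig, root: Path) -> dict:
    import tifffile

    from tomotex.recon import SlabImage

    sdir = root / "slabs"
    if not (sdir / "manifest.csv").exists():
        raise DependencyError("texture stage needs the slabs stage manifest")
    manifest = pd.read_csv(sdir / "manifest.csv")
    mask = np.load(sdir / "breast_mask.npy")
    groups = {}
    for _, row in manifest.iterrows():
        img = np.asarray(tifffile.imread(str(sdir / row["file"])), dtype=float)
        present = bool(row["truth_present"])
        slab = SlabImage(
            pixels=img,
            pixel_size_mm=config.recon_in_plane_mm,
            breast_mask=mask,
            truth_present=present,
            truth_center=(float(row["truth_row"]), float(row["truth_col"])) if present else None,
            condition={"P": int(row["P"]), "arm": row["arm"]},
            slab_index=int(row["slab_index"]),
            thickness_mm=config.slab_thickness_mm,
        )
        groups.setdefault((int(row["P"]), row["arm"]), []).append(slab)
    return groups


def _stage_texture(config: StudyConfig, root: Path, artifacts: dict) -> None:
    groups = _load_slabs_by_condition(config, root)
    tdir = root / "texture"
    tdir.mkdir(exist_ok=True)
    roi_frames = []
    summary_rows = []
    for (p, arm), slabs in sorted(groups.items()):
        df = tex_mod.roi_feature_frame(
            slabs, side=config.roi_side, levels=config.quant_levels, d=config.glcm_d,
            n=config.ngtdm_n, range_quantiles=config.quant_range_quantiles,
        )
        df["P"] = p
        df["arm"] = arm
        roi_frames.append(df)
        rec = {"P": p, "arm": arm, "n_roi": len(df)}
        for name in tex_mod.FEATURE_NAMES:
            rec[f"{name}_mean"] = df[name].mean(skipna=True) if len(df) else float("nan")
            rec[f"{name}_sd"] = df[name].std(skipna=True, ddof=1) if len(df) > 1 else 0.0
        summary_rows.append(rec)
    pd.concat(roi_frames, ignore_index=True).to_csv(tdir / "roi_features.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(tdir / "condition_features.csv", index=False)
    artifacts["texture"] = str(tdir)


def _stage_observer(config: StudyConfig, root: Path, artifacts: dict) -> None:
    sdir = root / "slabs"
    if not (sdir / "manifest.csv").exists():
        raise DependencyError("observer stage needs the slabs stage manifest")
    manifest = pd.read_csv(sdir / "manifest.csv")
    mask = np.load(sdir / "breast_mask.npy")
    odir = root / "observer"
    odir.mkdir(exist_ok=True)

    results = []
    all_trials = []
    for (p, arm), grp in sorted(manifest.groupby(["P", "arm"])):
        mean_cnr = float(pd.to_numeric(grp["cnr"], errors="coerce").dropna().mean())
        detectability = config.detectability_gain * max(mean_cnr, 0.0)
        session_df = grp.rename(columns={"truth_row": "truth_row", "truth_col": "truth_col"}).copy()
        session_df["truth_row"] = pd.to_numeric(session_df["truth_row"], errors="coerce").fillna(0.0)
        session_df["truth_col"] = pd.to_numeric(session_df["truth_col"], errors="coerce").fillna(0.0)
        n_train = min(config.n_train, max(0, len(session_df) - 2))
        sessions = lroc_mod.build_sessions(
            session_df, n_train=n_train, n_test=min(config.n_test, len(session_df) - n_train),
            seed=config.seed + p,
        )
        trials = lroc_mod.simulate_observer(
            sessions["test"],
            detectability,
            config.loc_error_scale_px,
            mask,
            seed=config.seed + 17 * p + (0 if arm == "noisy" else 1),
            condition=f"P={p}|arm={arm}",
        )
        res = lroc_mod.lroc_auc(trials, radius=config.localization_radius_px, condition=f"P={p}|arm={arm}")
        results.append({"P": int(p), "arm": arm, "auc": res.auc, "n_present": res.n_present,
                        "n_absent": res.n_absent, "cloc": res.correct_localization_fraction,
                        "mean_cnr": mean_cnr, "detectability": detectability})
        all_trials.append(lroc_mod.trials_to_frame(trials))
    pd.concat(all_trials, ignore_index=True).to_csv(odir / "trials.csv", index=False)
    pd.DataFrame(results).to_csv(odir / "auc.csv", index=False)
    (odir / "auc.json").write_text(json.dumps(results, indent=2))
    artifacts["observer"] = str(odir)


def _stage_correlate(config: StudyConfig, root: Path, artifacts: dict) -> None:
    tdir, odir = root / "texture", root / "observer"
    if not (tdir / "condition_features.csv").exists() or not (odir / "auc.csv").exists():
        raise DependencyError("correlate stage needs the texture and observer outputs")
    features = pd.read_csv(tdir / "condition_features.csv")
    aucs = pd.read_csv(odir / "auc.csv")
    cdir = root / "correlation"
    cdir.mkdir(exist_ok=True)
    subset = [p for p in config.p_list if p in set(aucs["P"])]
    arms_present = set(features["arm"])
    if {"noisy", "filtered"} <= arms_present and len(subset) >= 3:
        table = corr_mod.correlate_conditions(features, aucs, subset)
        table.to_csv(cdir / "correlations.csv", index=False)
    report = {}
    if len(subset) >= 4:
        for arm in sorted(arms_present):
            report[arm] = corr_mod.concavity_report(features, subset, arm=arm)
    (cdir / "concavity.json").write_text(json.dumps(report, indent=2))
    artifacts["correlate"] = str(cdir)


_STAGE_FUNCS = {
    "phantoms": _stage_phantoms,
    "slabs": _stage_slabs,
    "texture": _stage_texture,
    "observer": _stage_observer,
    "correlate": _stage_correlate,
}
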