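"""Synthetic PET phantoms with known ground truth.

Generates the kind of data the quantification pipeline assumes: hot,
uniform, (near-)spherical lesions on a low uniform background, degraded
by an isotropic Gaussian point-spread function that produces the
partial-volume signal loss the recovery-coefficient correction is meant
to undo, plus optional voxel noise.  Ground truth (crisp masks, volumes,
uniform SUVs) is recorded before blur and noise and never mutated, so
every downstream stage can be checked against it.

The default geometry mirrors a small-animal PET reconstruction: 0.5 mm
isotropic voxels on a 128^3 grid, lesion SUV around 1 on a background an
order of magnitude lower, PSF sigma 0.8 mm.  At that resolution spheres
of 1-5 mm diameter lose most of their apparent uptake, which is exactly
the regime a tabulated recovery-coefficient correction addresses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .imaging_io import AcquisitionMeta, LesionMask, SUVImage

#: Nominal acquisition metadata attached to generated SUV images
#: (4 MBq injected in a 20 g animal — typical FDG microPET dosing).
NOMINAL_META = AcquisitionMeta(injected_activity_bq=4e6, body_weight_g=20.0)

#: Margin (multiples of psf sigma) a lesion must keep from the grid edge.
PSF_SUPPORT_SIGMAS = 3.0


@dataclass(frozen=True)
class Lesion:
    """A uniform-uptake lesion: a sphere, or an ellipsoid when
    ``radius_mm`` is a 3-tuple of semi-axes (z, y, x)."""

    center_mm: tuple[float, float, float]
    radius_mm: Union[float, tuple[float, float, float]]
    true_suv: float

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        r = self.radius_mm
        return tuple(r) if isinstance(r, (tuple, list)) else (r, r, r)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic scan; identical spec + seed gives a
    bit-identical phantom."""

    lesions: tuple[Lesion, ...]
    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    background_suv: float = 0.1
    psf_sigma_mm: float = 0.8
    noise_model: str = "none"  # none | gaussian | poisson_scaled
    noise_param: float = 0.0  # sigma for gaussian, count scale k for poisson
    rng_seed: int = 0

    def __post_init__(self):
        if self.background_suv < 0:
            raise PhantomSpecError("background SUV must be >= 0")
        if self.psf_sigma_mm < 0:
            raise PhantomSpecError("PSF sigma must be >= 0")
        if self.noise_model not in {"none", "gaussian", "poisson_scaled"}:
            raise PhantomSpecError(f"unknown noise model {self.noise_model!r}")
        if not self.lesions:
            raise PhantomSpecError("at least one lesion is required")
        extent = np.array(self.shape) * np.array(self.spacing)
        margin = PSF_SUPPORT_SIGMAS * self.psf_sigma_mm
        for les in self.lesions:
            axes = np.array(les.semi_axes)
            if np.any(axes <= 0):
                raise PhantomSpecError("lesion radii must be > 0")
            c = np.array(les.center_mm)
            if np.any(c - axes - margin < 0) or np.any(c + axes + margin > extent):
                raise PhantomSpecError(
                    f"lesion at {les.center_mm} (axes {tuple(axes)}) does not fit "
                    f"inside the grid with a {margin:.1f} mm PSF-support margin"
                )
            if les.true_suv <= self.background_suv:
                raise PhantomSpecError("lesion SUV must exceed the background SUV")


@dataclass
class PhantomTruth:
    """Ground truth recorded before blur and noise."""

    masks: list[np.ndarray]  # one crisp boolean mask per lesion
    volumes_mm3: list[float]
    suv_means: list[float]
    background_suv: float

    def lesion_mask(self, i: int, spacing, origin=(0.0, 0.0, 0.0)) -> LesionMask:
        return LesionMask(self.masks[i], spacing, origin)


def _voxel_centers(shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _voxelize(lesion: Lesion, shape, spacing) -> np.ndarray:
    """Voxel-center inclusion test for a sphere/ellipsoid."""
    zz, yy, xx = _voxel_centers(shape, spacing)
    cz, cy, cx = lesion.center_mm
    az, ay, ax = lesion.semi_axes
    q = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    return q <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[SUVImage, PhantomTruth]:
    """Build the crisp truth image, blur it with the PSF, add noise.

    Returns the degraded :class:`SUVImage` plus a :class:`PhantomTruth`
    holding the per-lesion crisp masks, exact voxelized volumes and true
    uniform SUV means.  Later lesions in the spec overwrite earlier ones,
    which is how concentric two-compartment lesions are composed.
    """
    voxvol = float(np.prod(spec.spacing))
    img = np.full(spec.shape, spec.background_suv, dtype=np.float64)
    masks, volumes, means = [], [], []
    for les in spec.lesions:
        m = _voxelize(les, spec.shape, spec.spacing)
        img[m] = les.true_suv
        masks.append(m)
        volumes.append(float(m.sum()) * voxvol)
        means.append(float(les.true_suv))
    truth = PhantomTruth(masks, volumes, means, spec.background_suv)

    if spec.psf_sigma_mm > 0:
        sigma_vox = [spec.psf_sigma_mm / s for s in spec.spacing]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="reflect")

    if spec.noise_model != "none":
        rng = np.random.default_rng(spec.rng_seed)
        if spec.noise_model == "gaussian":
            img = img + rng.normal(0.0, spec.noise_param, size=img.shape)
        else:  # poisson_scaled: counts ~ Poisson(k * img) / k
            k = spec.noise_param
            if k <= 0:
                raise PhantomSpecError("poisson_scaled noise needs a positive scale")
            img = rng.poisson(np.clip(img, 0, None) * k).astype(np.float64) / k
        img = np.clip(img, 0.0, None)  # SUV images are non-negative

    suv = SUVImage(voxels=img, spacing=spec.spacing, meta=NOMINAL_META)
    return suv, truth


def make_response_pair(
    spec_pre: PhantomSpec,
    delta_suv_pct: float = 0.0,
    delta_mtv_pct: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[SUVImage, PhantomTruth, SUVImage, PhantomTruth, dict]:
    """Generate a baseline/follow-up scan pair with prescribed true changes.

    The follow-up lesion SUV is scaled by ``1 + delta_suv_pct/100`` and the
    lesion volume by ``1 + delta_mtv_pct/100`` (radius scaled by the cube
    root), both applied to the truth before blur and noise.  Returns
    ``(img_pre, truth_pre, img_post, truth_post, truth_deltas)`` where the
    deltas dict holds the prescribed percent changes and the realized
    (voxelized) volume change.
    """
    if delta_suv_pct <= -100:
        raise PhantomSpecError("delta SUV must keep uptake positive")
    if delta_mtv_pct <= -100:
        raise PhantomSpecError("delta MTV must keep the lesion volume positive")
    suv_scale = 1.0 + delta_suv_pct / 100.0
    rad_scale = (1.0 + delta_mtv_pct / 100.0) ** (1.0 / 3.0)

    voxvol = float(np.prod(spec_pre.spacing))
    post_lesions = []
    for les in spec_pre.lesions:
        axes = tuple(a * rad_scale for a in les.semi_axes)
        if (4.0 / 3.0) * np.pi * axes[0] * axes[1] * axes[2] < voxvol:
            raise PhantomSpecError("effect shrinks a lesion below one voxel")
        radius = axes if isinstance(les.radius_mm, (tuple, list)) else axes[0]
        post_lesions.append(replace(les, radius_mm=radius, true_suv=les.true_suv * suv_scale))
    spec_post = replace(
        spec_pre,
        lesions=tuple(post_lesions),
        rng_seed=spec_pre.rng_seed + 1 if seed is None else seed,
    )

    img_pre, truth_pre = make_phantom(spec_pre)
    img_post, truth_post = make_phantom(spec_post)
    realized_dmtv = [
        100.0 * (vb - va) / va
        for va, vb in zip(truth_pre.volumes_mm3, truth_post.volumes_mm3)
    ]
    deltas = {
        "delta_suv_pct": delta_suv_pct,
        "delta_mtv_pct": delta_mtv_pct,
        "realized_delta_mtv_pct": realized_dmtv,
    }
    return img_pre, truth_pre, img_post, truth_post, deltas


def make_qc_negative(kind: str, spec: PhantomSpec) -> tuple[SUVImage, PhantomTruth]:
    """Rebuild the spec's first lesion so that exactly one QC check fails.

    ``elongated`` replaces it with a 2.5:1 ellipsoid (fails the sphericity
    gate, uptake stays uniform); ``bimodal`` replaces it with a hot core
    inside a cooler shell (fails the single-peak uniformity rule, shape
    stays spherical).  The returned truth's first mask covers the whole
    lesion (core plus shell for ``bimodal``).
    """
    base = spec.lesions[0]
    r = base.semi_axes[0]
    if kind == "elongated":
        lesions = (replace(base, radius_mm=(2.5 * r, r, r)),) + spec.lesions[1:]
        img, truth = make_phantom(replace(spec, lesions=lesions))
        return img, truth
    if kind == "bimodal":
        # core/shell volumes comparable and contrast strong enough that the
        # two modes stay resolvable after PSF blur (needs shell thickness
        # comfortably above the PSF sigma)
        core = Lesion(base.center_mm, 0.72 * r, 3.5 * base.true_suv)
        lesions = (base, core) + spec.lesions[1:]
        img, truth = make_phantom(replace(spec, lesions=lesions))
        # merge core into the whole-lesion truth entry
        truth.masks = [truth.masks[0] | truth.masks[1]] + truth.masks[2:]
        voxvol = float(np.prod(spec.spacing))
        truth.volumes_mm3 = [float(truth.masks[0].sum()) * voxvol] + truth.volumes_mm3[2:]
        truth.suv_means = [base.true_suv] + truth.suv_means[2:]
        return img, truth
    raise ValueError(f"unknown QC-negative kind {kind!r}")
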