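"""Synthetic stereotaxic template, T1-like phantoms and cohorts.

The generator builds geometric head phantoms: an ellipsoidal
intracranial cavity with a grey-matter shell and white-matter core, and
CSF-filled lateral ventricles composed of a body plus frontal, temporal
and occipital horns per hemisphere.  Shape factors scale the horn
volumes so cohorts can encode group-level contrasts (larger total
ventricular volume and a larger anterior-posterior ratio in the
bvFTD-like group than in the psychiatric-like group).  Acquisition
effects — Gaussian noise, a smooth multiplicative bias field, a
grey/white contrast multiplier emulating scanner/field-strength
variation, and a random rigid+scale transform into "native" space — are
applied on top of the noise-free template-space anatomy, whose voxelised
masks serve as ground truth.

Everything is seeded and bit-reproducible; phantoms are geometric, not
anatomically realistic — they exercise the pipeline's mathematics, not
its radiological plausibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import HEMIS, LOBES, LobarAtlas, compute_features
from .io_model import (AffineTransform, LabelVolume, SubjectRecord,
                       VolumeImage, write_volume)


class GenerationError(ValueError):
    """Shape factors produced anatomy outside the intracranial cavity."""


# ---------------------------------------------------------------------------
# ventricle geometry (template world mm, per hemisphere; x mirrored)
#
# Each structure is an ellipsoid (centre, semi-axes).  The base constants
# are calibrated so that the neutral phantom (all factors 1) has an
# anterior/posterior ratio of ~1 about the y = -12 mm plane and a single
# connected ventricle per hemisphere.  FRONTAL_SEMI_CAL below is the one
# calibrated constant; see docs/methods.md.
# ---------------------------------------------------------------------------

FRONTAL_SEMI_CAL = 0.87  # numeric calibration factor for the frontal horn

_STRUCTURES = {
    # name: (centre (|x|, y, z), semi-axes (a, b, c))
    "body": ((9.0, -12.0, 10.0), (5.5, 20.0, 7.0)),
    "frontal_horn": ((8.0, 13.0, 9.0), (5.0, 10.0, 5.5)),
    "temporal_horn": ((13.0, -16.0, 3.0), (4.5, 13.0, 5.0)),
    "occipital_horn": ((9.0, -30.0, 7.0), (4.0, 7.0, 4.0)),
}


@dataclass
class AffinePerturbation:
    """Range of the random rigid+scale jitter mapping template to native."""

    max_translation_mm: float = 3.0
    max_rotation_deg: float = 4.0
    scale_range: tuple[float, float] = (0.95, 1.05)

    def draw(self, rng: np.random.Generator) -> AffineTransform:
        """A random native->template world transform within the range."""
        t = rng.uniform(-self.max_translation_mm, self.max_translation_mm, 3)
        ang = np.deg2rad(rng.uniform(-self.max_rotation_deg,
                                     self.max_rotation_deg, 3))
        s = rng.uniform(*self.scale_range, 3)
        m = np.eye(4)
        m[:3, :3] = _euler_matrix(*ang) @ np.diag(s)
        m[:3, 3] = t
        return AffineTransform(m)


def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class PhantomSpec:
    """Parameters of one synthetic head phantom."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 1.0
    icv_semiaxes_mm: tuple[float, float, float] = (32.0, 42.0, 32.0)
    apr_factor: float = 1.0          # anterior (frontal) horn volume scale
    lr_frontal_factor: float = 1.0   # left frontal horn volume scale
    lr_temporal_factor: float = 1.0  # left temporal horn volume scale
    total_scale: float = 1.0         # global ventricle volume scale
    white_mean: float = 70.0         # tissue means on the [0, 100] scale
    grey_mean: float = 50.0
    csf_mean: float = 10.0
    noise_sd: float = 2.0
    bias_amplitude: float = 0.15     # peak fractional multiplicative bias
    contrast_shift: float = 1.0      # grey/white contrast multiplier
    perturbation: AffinePerturbation = field(default_factory=AffinePerturbation)
    seed: int = 0
    acquisition_seed: int | None = None   # noise/bias draw; None -> from seed

    def __post_init__(self) -> None:
        for name in ("apr_factor", "lr_frontal_factor",
                     "lr_temporal_factor", "total_scale",
                     "contrast_shift"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.grid_shape) < 64:
            raise ValueError("phantom grid must be >= 64 voxels per axis")


def template_affine(spec: PhantomSpec) -> np.ndarray:
    """RAS affine with the world origin at the grid centre voxel.

    The origin anchors the anterior-commissure-like centre of the
    template, making the stereotaxic y = -12 mm plane well defined.
    """
    a = np.diag([spec.spacing_mm] * 3 + [1.0])
    centre = (np.array(spec.grid_shape) - 1) / 2.0
    # place the origin on an exact voxel centre so x = 0 is a voxel plane
    centre = np.floor(centre)
    a[:3, 3] = -centre * spec.spacing_mm
    return a


def _world_grids(spec: PhantomSpec):
    aff = template_affine(spec)
    axes = [
        (np.arange(n, dtype=np.float32) * aff[i, i] + aff[i, 3])
        for i, n in enumerate(spec.grid_shape)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _inside_ellipsoid(X, Y, Z, centre, semi) -> np.ndarray:
    return ((X - centre[0]) ** 2 / semi[0] ** 2
            + (Y - centre[1]) ** 2 / semi[1] ** 2
            + (Z - centre[2]) ** 2 / semi[2] ** 2) <= 1.0


def ventricle_mask_array(spec: PhantomSpec) -> np.ndarray:
    """Voxelised ventricle mask for the given shape factors."""
    X, Y, Z = _world_grids(spec)
    g = spec.total_scale ** (1.0 / 3.0)
    out = np.zeros(spec.grid_shape, dtype=bool)
    for sign, hemi in ((-1.0, "L"), (1.0, "R")):
        for name, (centre, semi) in _STRUCTURES.items():
            f = g
            if name == "frontal_horn":
                f *= (spec.apr_factor * FRONTAL_SEMI_CAL) ** (1.0 / 3.0)
                if hemi == "L":
                    f *= spec.lr_frontal_factor ** (1.0 / 3.0)
            elif name == "temporal_horn" and hemi == "L":
                f *= spec.lr_temporal_factor ** (1.0 / 3.0)
            c = (sign * centre[0], centre[1], centre[2])
            s = tuple(f * v for v in semi)
            out |= _inside_ellipsoid(X, Y, Z, c, s)
    return out


def icv_mask_array(spec: PhantomSpec) -> np.ndarray:
    X, Y, Z = _world_grids(spec)
    return _inside_ellipsoid(X, Y, Z, (0.0, 0.0, 0.0), spec.icv_semiaxes_mm)


_GM_SHELL_FRACTION = 0.86  # white matter core = ICV scaled by this


def tissue_image_array(spec: PhantomSpec, icv: np.ndarray,
                       ventricles: np.ndarray) -> np.ndarray:
    """Noise-free tissue intensity image on the template grid."""
    X, Y, Z = _world_grids(spec)
    core = _inside_ellipsoid(
        X, Y, Z, (0.0, 0.0, 0.0),
        tuple(_GM_SHELL_FRACTION * v for v in spec.icv_semiaxes_mm))
    csf = spec.csf_mean
    grey = csf + (spec.grey_mean - csf) * spec.contrast_shift
    white = csf + (spec.white_mean - csf) * spec.contrast_shift
    img = np.zeros(spec.grid_shape, dtype=np.float32)
    img[icv] = grey
    img[icv & core] = white
    img[ventricles] = csf
    # partial-volume-like softening of tissue interfaces
    return ndimage.gaussian_filter(img, sigma=0.8)


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias: 1 + random degree-2 polynomial of
    normalised world coordinates, peak amplitude ~ bias_amplitude."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape, dtype=np.float32)
    X, Y, Z = _world_grids(spec)
    half = max(spec.icv_semiaxes_mm)
    u, v, w = X / half, Y / half, Z / half
    coef = rng.uniform(-1.0, 1.0, 9)
    poly = (coef[0] * u + coef[1] * v + coef[2] * w
            + coef[3] * u * v + coef[4] * u * w + coef[5] * v * w
            + coef[6] * u * u + coef[7] * v * v + coef[8] * w * w)
    peak = float(np.abs(poly).max())
    if peak > 0:
        poly = poly * (spec.bias_amplitude / peak)
    return (1.0 + poly).astype(np.float32)


@dataclass
class TemplateArtifacts:
    """The stereotaxic template space: image, ICV mask, lobar atlas and
    ventricle prior, plus the spec that generated them."""

    template: VolumeImage
    icv_mask: LabelVolume
    atlas: LobarAtlas
    ventricle_prior: LabelVolume
    spec: PhantomSpec

    @property
    def icv_volume_mm3(self) -> float:
        return float(self.icv_mask.data.sum()) * self.icv_mask.voxel_volume


# lobar atlas partition rules in template world mm (hemisphere by sign
# of x; x > 0 is the subject's right in RAS)
_ATLAS_Y_FRONTAL = 10.0
_ATLAS_Y_OCCIPITAL = -40.0
_ATLAS_Z_PARIETAL = 10.0

ATLAS_CODE_TABLE = {
    code: (lobe, hemi)
    for code, (lobe, hemi) in enumerate(
        ((lobe, hemi) for lobe in LOBES for hemi in HEMIS), start=1)
}


def _atlas_codes(spec: PhantomSpec, icv: np.ndarray) -> np.ndarray:
    X, Y, Z = _world_grids(spec)
    shape = spec.grid_shape
    bc = lambda cond: np.broadcast_to(cond, shape)
    lobe = np.full(shape, -1, dtype=np.int32)
    lobe[bc(Y > _ATLAS_Y_FRONTAL)] = 0                     # frontal
    mid = (Y <= _ATLAS_Y_FRONTAL) & (Y >= _ATLAS_Y_OCCIPITAL)
    lobe[bc(mid & (Z > _ATLAS_Z_PARIETAL))] = 1            # parietal
    lobe[bc(mid & (Z <= _ATLAS_Z_PARIETAL))] = 2           # temporal
    lobe[bc(Y < _ATLAS_Y_OCCIPITAL)] = 3                   # occipital
    hemi = bc(X > 0).astype(np.int32)                      # 1 = R
    codes = (lobe * 2 + hemi + 1).astype(np.int32)
    codes[~icv] = 0
    return codes


def make_template(spec: PhantomSpec | None = None) -> TemplateArtifacts:
    """Build the noise-free template space with neutral shape factors."""
    spec = spec or PhantomSpec()
    spec = replace(spec, apr_factor=1.0, lr_frontal_factor=1.0,
                   lr_temporal_factor=1.0, total_scale=1.0,
                   noise_sd=0.0, bias_amplitude=0.0, contrast_shift=1.0)
    aff = template_affine(spec)
    icv = icv_mask_array(spec)
    vent = ventricle_mask_array(spec)
    if np.any(vent & ~icv):
        raise GenerationError("template ventricles exit the ICV")
    img = tissue_image_array(spec, icv, vent)
    codes = _atlas_codes(spec, icv)
    return TemplateArtifacts(
        template=VolumeImage(img, aff),
        icv_mask=LabelVolume(icv.astype(np.int32), aff),
        atlas=LobarAtlas(LabelVolume(codes, aff), dict(ATLAS_CODE_TABLE)),
        ventricle_prior=LabelVolume(vent.astype(np.int32), aff),
        spec=spec,
    )


@dataclass
class PhantomResult:
    """One synthetic subject: the native image, ground truth and the true
    native->template transform."""

    native: VolumeImage
    truth_mask_native: LabelVolume
    truth_mask_template: LabelVolume
    true_transform: AffineTransform   # native world -> template world
    truth_features: "object"          # VentricleFeatures on the truth mask
    spec: PhantomSpec


def make_phantom(spec: PhantomSpec,
                 template_art: TemplateArtifacts) -> PhantomResult:
    """Generate one native-space phantom with ground truth.

    Anatomy is built in template space from the shape factors; the
    "native" image is the template-space phantom resampled through a
    random rigid+scale transform, with bias, contrast shift and noise
    applied in native space.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_geo, rng_acq_default = (np.random.default_rng(s)
                                for s in ss.spawn(2))
    rng_acq = (np.random.default_rng(spec.acquisition_seed)
               if spec.acquisition_seed is not None else rng_acq_default)

    aff = template_affine(spec)
    icv = icv_mask_array(spec)
    vent = ventricle_mask_array(spec)
    if np.any(vent & ~icv):
        raise GenerationError(
            "ventricle exits the ICV; shape factors too extreme "
            f"(apr={spec.apr_factor:.3g}, total={spec.total_scale:.3g})")
    tissue = tissue_image_array(spec, icv, vent)

    truth_template = LabelVolume(vent.astype(np.int32), aff)
    icv_mm3 = float(icv.sum()) * abs(np.linalg.det(aff[:3, :3]))
    truth_features = compute_features(truth_template, template_art.atlas,
                                      icv=icv_mm3)

    t = spec.perturbation.draw(rng_geo)  # native -> template world

    # native grid shares the template grid; its content is the template
    # anatomy carried through the transform: native(x) = tissue(T x)
    vox_map = np.linalg.inv(aff) @ t.matrix @ aff
    coords = _grid_coords(spec.grid_shape, vox_map)
    native_data = ndimage.map_coordinates(tissue, coords, order=1,
                                          mode="constant", cval=0.0)
    native_mask = ndimage.map_coordinates(vent.astype(np.float32), coords,
                                          order=0, mode="constant", cval=0.0)
    native_data = native_data.reshape(spec.grid_shape)
    native_mask = native_mask.reshape(spec.grid_shape) > 0.5

    bias = _bias_field(spec, rng_acq)
    native_data = native_data * bias
    if spec.noise_sd > 0:
        native_data = native_data + rng_acq.normal(
            0.0, spec.noise_sd, spec.grid_shape).astype(np.float32)

    return PhantomResult(
        native=VolumeImage(native_data.astype(np.float32), aff),
        truth_mask_native=LabelVolume(native_mask.astype(np.int32), aff),
        truth_mask_template=truth_template,
        true_transform=t,
        truth_features=truth_features,
        spec=spec,
    )


def _grid_coords(shape, vox_map: np.ndarray) -> np.ndarray:
    """Voxel coordinates of ``shape`` mapped through a 4x4 voxel map,
    shaped (3, N) for map_coordinates."""
    idx = np.indices(shape, dtype=np.float32).reshape(3, -1)
    return (vox_map[:3, :3].astype(np.float32) @ idx
            + vox_map[:3, 3:4].astype(np.float32))


def rescan_spec(spec: PhantomSpec, contrast_shift: float,
                acquisition_seed: int) -> PhantomSpec:
    """Same anatomy and native geometry; new scanner contrast and noise."""
    return replace(spec, contrast_shift=contrast_shift,
                   acquisition_seed=acquisition_seed)


# ---------------------------------------------------------------------------
# library of labelled template-space examples
# ---------------------------------------------------------------------------

def make_library(template_art: TemplateArtifacts, k: int = 5,
                 seed: int = 0, noise_sd: float = 2.0
                 ) -> list[tuple[VolumeImage, LabelVolume]]:
    """k labelled (image, ventricle mask) pairs on the template grid.

    Shape factors span the cohort range (total volume 0.8-1.45x,
    anterior factor 0.9-1.4x) so the fused library covers both small
    psychiatric-like and large bvFTD-like ventricles.  Library images go
    through the same native-space synthesis and template resampling as
    test subjects (using their known ground-truth transform, standing in
    for the manual alignment of a curated library), so their intensity
    statistics — noise and interpolation blur included — match the
    images the fusion will segment.  The labels are the template-space
    ground-truth masks, playing the role of expert manual segmentations.
    """
    if k < 2:
        raise ValueError("library needs at least 2 entries")
    rng = np.random.default_rng(seed)
    totals = np.linspace(0.80, 1.45, k)
    aprs = rng.permutation(np.linspace(0.90, 1.40, k))
    seeds = _subject_seeds(seed, k)
    pairs = []
    for i in range(k):
        spec = replace(
            template_art.spec,
            total_scale=float(totals[i]),
            apr_factor=float(aprs[i]),
            lr_frontal_factor=float(np.clip(rng.normal(1.0, 0.06),
                                            0.8, 1.25)),
            lr_temporal_factor=float(np.clip(rng.normal(1.0, 0.06),
                                             0.8, 1.25)),
            noise_sd=noise_sd, bias_amplitude=0.0, contrast_shift=1.0,
            seed=seeds[i],
        )
        res = make_phantom(spec, template_art)
        aff = res.native.affine
        # carry the native image back to template space through the
        # known transform (trilinear), as the pipeline does for subjects
        vox_map = (np.linalg.inv(aff) @ np.linalg.inv(res.true_transform.matrix)
                   @ template_affine(spec))
        coords = _grid_coords(spec.grid_shape, vox_map)
        img = ndimage.map_coordinates(res.native.data, coords, order=1,
                                      mode="constant", cval=0.0
                                      ).reshape(spec.grid_shape)
        pairs.append((VolumeImage(img.astype(np.float32), aff),
                      res.truth_mask_template))
    return pairs


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Shape/demographic distribution of one diagnostic-like group."""

    n: int
    label: str                 # true_label written to the subject table
    group: str                 # cohort name kept as metadata
    apr_mean: float
    apr_sd: float
    total_mean: float
    total_sd: float
    age_mean: float
    age_sd: float
    male_fraction: float = 0.5


def default_groups(n_bvftd: int, n_ppd: int, n_other: int = 0
                   ) -> list[GroupSpec]:
    """Study-condition defaults: the bvFTD-like group has larger total
    ventricular volume and a larger anterior-posterior ratio and is
    younger than the psychiatric-like group."""
    groups = [
        GroupSpec(n=n_bvftd, label="bvFTD", group="bvFTD",
                  apr_mean=1.30, apr_sd=0.15, total_mean=1.3, total_sd=0.1,
                  age_mean=63.0, age_sd=8.0),
        GroupSpec(n=n_ppd, label="other", group="PPD",
                  apr_mean=1.00, apr_sd=0.15, total_mean=1.0, total_sd=0.1,
                  age_mean=69.0, age_sd=10.0),
    ]
    if n_other:
        groups.append(
            GroupSpec(n=n_other, label="other", group="other_dementia",
                      apr_mean=1.05, apr_sd=0.15, total_mean=1.15,
                      total_sd=0.1, age_mean=74.0, age_sd=8.0))
    return groups


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    seed: int = 0
    noise_sd: float = 2.0
    bias_amplitude: float = 0.15
    contrast_range: tuple[float, float] = (0.85, 1.15)

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.n < 0 or g.apr_sd < 0 or g.total_sd < 0 or g.age_sd < 0:
                raise ValueError(f"invalid group spec {g.group}")


# safe factor ranges: beyond these the ventricle can exit the ICV
_APR_CLIP = (0.6, 1.7)
_TOTAL_CLIP = (0.7, 1.5)
_LR_CLIP = (0.75, 1.3)


def _draw_subject_spec(g: GroupSpec, cohort: CohortSpec, base: PhantomSpec,
                       rng: np.random.Generator, seed: int) -> tuple:
    apr = float(np.clip(rng.normal(g.apr_mean, g.apr_sd), *_APR_CLIP))
    total = float(np.clip(rng.normal(g.total_mean, g.total_sd), *_TOTAL_CLIP))
    lrf = float(np.clip(rng.normal(1.0, 0.08), *_LR_CLIP))
    lrt = float(np.clip(rng.normal(1.0, 0.08), *_LR_CLIP))
    age = float(np.clip(rng.normal(g.age_mean, g.age_sd), 40.0, 95.0))
    sex = "male" if rng.random() < g.male_fraction else "female"
    contrast = float(rng.uniform(*cohort.contrast_range))
    spec = replace(base, apr_factor=apr, total_scale=total,
                   lr_frontal_factor=lrf, lr_temporal_factor=lrt,
                   noise_sd=cohort.noise_sd,
                   bias_amplitude=cohort.bias_amplitude,
                   contrast_shift=contrast, seed=seed,
                   acquisition_seed=None)
    return spec, age, sex


def _subject_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31 for portability of the CSV record
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def make_cohort(spec: CohortSpec, output_dir,
                template_art: TemplateArtifacts) -> pd.DataFrame:
    """Write per-subject NIfTI phantoms plus subject and truth CSVs.

    Returns the truth table; ``subjects.csv`` in the output directory is
    the pipeline's input table and ``truth.csv`` records the generator's
    ground-truth features and transform parameters per subject.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    total_n = sum(g.n for g in spec.groups)
    seeds = _subject_seeds(spec.seed, total_n)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    sub_rows, truth_rows = [], []
    i = 0
    for g in spec.groups:
        for _ in range(g.n):
            sid = f"sub-{i:04d}"
            pspec, age, sex = _draw_subject_spec(g, spec, template_art.spec,
                                                 rng, seeds[i])
            res = make_phantom(pspec, template_art)
            img_path = out / f"{sid}.nii.gz"
            write_volume(res.native, img_path)
            sub_rows.append({"id": sid, "image_path": str(img_path),
                             "age": age, "sex": sex, "true_label": g.label,
                             "group": g.group})
            tf = res.truth_features
            truth_rows.append({
                "id": sid, "group": g.group, "true_label": g.label,
                "age": age, "sex": sex,
                "apr_factor": pspec.apr_factor,
                "total_scale": pspec.total_scale,
                "contrast_shift": pspec.contrast_shift,
                "seed": pspec.seed,
                "true_icv_mm3": tf.icv,
                "true_total_mm3": tf.total_vol,
                "true_apr": tf.apr, "true_apr_log": tf.apr_log,
                "true_lr_frontal_log": tf.lr_frontal_log,
                "true_lr_temporal_log": tf.lr_temporal_log,
                "true_scale_det": res.true_transform.scale_det,
            })
            i += 1
    pd.DataFrame(sub_rows).to_csv(out / "subjects.csv", index=False)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out / "truth.csv", index=False)
    return truth


def sample_cohort_features(spec: CohortSpec,
                           template_art: TemplateArtifacts) -> pd.DataFrame:
    """Ground-truth feature vectors for a cohort, without image synthesis.

    Builds only the voxelised truth masks and measures them with the
    feature stage — the fast path for classifier experiments where the
    imaging chain is not under test.
    """
    total_n = sum(g.n for g in spec.groups)
    seeds = _subject_seeds(spec.seed, total_n)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    aff = template_affine(template_art.spec)
    icv_mm3 = template_art.icv_volume_mm3
    rows = []
    i = 0
    for g in spec.groups:
        for _ in range(g.n):
            pspec, age, sex = _draw_subject_spec(g, spec, template_art.spec,
                                                 rng, seeds[i])
            vent = ventricle_mask_array(pspec)
            mask = LabelVolume(vent.astype(np.int32), aff)
            # ICV scales with the subject's random head-size jitter only
            # through the transform; truth features use the template ICV
            feats = compute_features(mask, template_art.atlas, icv=icv_mm3,
                                     age=age,
                                     sex_code=1 if sex == "male" else 0)
            row = {"id": f"sub-{i:04d}", "group": g.group,
                   "true_label": g.label, "age": age, "sex": sex,
                   "sex_code": 1 if sex == "male" else 0}
            row.update(feats.as_dict())
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)
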