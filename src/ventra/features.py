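"""Ventricular morphometry: anterior/posterior split, lobar parcellation,
ICV-normalised volume, log-ratio features, and automated segmentation QC.

All operations work on binary ventricle masks in stereotaxic template
space.  The anterior/posterior split is a fixed coronal plane at
y = -12 mm in template world coordinates: a voxel whose centre has
world y > -12 is anterior, otherwise posterior.  Left/right follows the
RAS convention (world x > 0 is the subject's right).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_model import GeometryError, LabelVolume

Y_CUT_MM = -12.0  # coronal anterior/posterior boundary, template world mm

LOBES = ("frontal", "parietal", "temporal", "occipital")
HEMIS = ("L", "R")


class UndefinedFeatureError(ValueError):
    """A ratio denominator (posterior / right frontal / right temporal
    volume) is zero, so the feature vector is undefined."""


@dataclass
class LobarAtlas:
    """Integer lobar parcellation of the template ICV.

    ``labels`` holds one code per voxel (0 = background); ``code_table``
    maps each code to a (lobe, hemisphere) pair, e.g. 1 -> ("frontal", "L").
    """

    labels: LabelVolume
    code_table: dict[int, tuple[str, str]]

    def __post_init__(self) -> None:
        for code, (lobe, hemi) in self.code_table.items():
            if lobe not in LOBES or hemi not in HEMIS:
                raise ValueError(f"bad atlas code table entry {code}: "
                                 f"({lobe}, {hemi})")

    def code_for(self, lobe: str, hemi: str) -> int:
        for code, pair in self.code_table.items():
            if pair == (lobe, hemi):
                return code
        raise KeyError((lobe, hemi))

    def save(self, nifti_path, csv_path) -> None:
        from .io_model import write_volume
        write_volume(self.labels, nifti_path)
        rows = [{"code": c, "lobe": lo, "hemisphere": h}
                for c, (lo, h) in sorted(self.code_table.items())]
        pd.DataFrame(rows).to_csv(csv_path, index=False)

    @classmethod
    def load(cls, nifti_path, csv_path) -> "LobarAtlas":
        from .io_model import read_label_volume
        labels = read_label_volume(nifti_path)
        df = pd.read_csv(csv_path)
        table = {int(r.code): (str(r.lobe), str(r.hemisphere))
                 for r in df.itertuples()}
        return cls(labels=labels, code_table=table)


@dataclass
class VentricleFeatures:
    """The feature vector extracted from one ventricle segmentation."""

    icv: float                      # mm^3
    total_vol: float                # mm^3, template space
    total_vv_norm: float            # total_vol / icv (dimensionless)
    anterior_vol: float             # mm^3
    posterior_vol: float            # mm^3
    apr: float                      # anterior / posterior
    apr_log: float                  # ln(apr)
    lr_frontal_log: float           # ln(left frontal / right frontal)
    lr_temporal_log: float          # ln(left temporal / right temporal)
    vol: dict = field(default_factory=dict)   # (lobe, hemi) -> mm^3
    age: float = float("nan")
    sex_code: int = -1              # male=1, female=0

    def as_dict(self) -> dict:
        d = {
            "icv_mm3": self.icv,
            "total_vol_mm3": self.total_vol,
            "total_vv_norm": self.total_vv_norm,
            "anterior_vol_mm3": self.anterior_vol,
            "posterior_vol_mm3": self.posterior_vol,
            "apr": self.apr,
            "apr_log": self.apr_log,
            "lr_frontal_log": self.lr_frontal_log,
            "lr_temporal_log": self.lr_temporal_log,
        }
        for lobe in LOBES:
            for hemi in HEMIS:
                d[f"vol_{lobe}_{hemi}"] = self.vol.get((lobe, hemi), 0.0)
        return d

    @classmethod
    def field_names(cls) -> list[str]:
        names = ["icv_mm3", "total_vol_mm3", "total_vv_norm",
                 "anterior_vol_mm3", "posterior_vol_mm3", "apr", "apr_log",
                 "lr_frontal_log", "lr_temporal_log"]
        names += [f"vol_{lobe}_{hemi}" for lobe in LOBES for hemi in HEMIS]
        return names

    def classifier_vector(self) -> np.ndarray:
        """Features in the fixed order the classifier expects."""
        return np.array([self.apr_log, self.total_vv_norm,
                         self.lr_frontal_log, self.lr_temporal_log,
                         self.age, float(self.sex_code)])


def world_y_grid(mask: LabelVolume) -> np.ndarray:
    """World y coordinate of every voxel centre."""
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in mask.shape),
                             indexing="ij", sparse=True)
    A = mask.affine
    return A[1, 0] * ii + A[1, 1] * jj + A[1, 2] * kk + A[1, 3]


def split_anterior_posterior(
    mask: LabelVolume, y_cut: float = Y_CUT_MM
) -> tuple[LabelVolume, LabelVolume]:
    """Split a ventricle mask at the coronal plane world y = ``y_cut``.

    Anterior collects voxels whose centre lies strictly anterior to the
    plane (y > y_cut); the plane itself belongs to the posterior part.
    The two outputs partition the input mask.
    """
    if not mask.is_binary:
        raise ValueError("anterior/posterior split needs a binary mask")
    y = world_y_grid(mask)
    ant = (mask.data == 1) & (y > y_cut)
    post = (mask.data == 1) & ~(y > y_cut)
    return (LabelVolume(ant.astype(np.int32), mask.affine),
            LabelVolume(post.astype(np.int32), mask.affine))


def compute_apr(anterior_vol: float, posterior_vol: float
                ) -> tuple[float, float]:
    """Anterior-posterior ratio and its natural log."""
    if posterior_vol <= 0:
        raise UndefinedFeatureError(
            "posterior ventricle volume is zero; APR undefined")
    if anterior_vol <= 0:
        raise UndefinedFeatureError(
            "anterior ventricle volume is zero; APR log undefined")
    apr = anterior_vol / posterior_vol
    return apr, math.log(apr)


def parcellate_volumes(mask: LabelVolume, atlas: LobarAtlas) -> dict:
    """Ventricle volume (mm^3) per (lobe, hemisphere) atlas compartment.

    Mask voxels falling on the atlas background (outside the coded ICV)
    are assigned to the nearest coded compartment by Euclidean distance
    in world mm, so compartment volumes always sum to the total.
    """
    if not mask.same_grid(atlas.labels):
        raise GeometryError("mask and atlas are not on the same grid")
    if not mask.is_binary:
        raise ValueError("parcellation needs a binary mask")
    codes = atlas.labels.data
    m = mask.data == 1
    if np.any(m & (codes == 0)):
        # nearest-compartment reassignment for out-of-atlas voxels
        _, idx = ndimage.distance_transform_edt(
            codes == 0, sampling=mask.spacing, return_indices=True)
        codes = codes[tuple(idx)]
    voxvol = mask.voxel_volume
    out = {pair: 0.0 for pair in atlas.code_table.values()}
    found, counts = np.unique(codes[m], return_counts=True)
    for code, n in zip(found, counts):
        pair = atlas.code_table.get(int(code))
        if pair is None:
            raise ValueError(f"atlas voxel code {code} missing from table")
        out[pair] += float(n) * voxvol
    return out


def compute_features(mask: LabelVolume, atlas: LobarAtlas, icv: float,
                     age: float = float("nan"), sex_code: int = -1,
                     y_cut: float = Y_CUT_MM) -> VentricleFeatures:
    """Full ventricular feature vector from a template-space mask."""
    if icv <= 0:
        raise ValueError("ICV must be positive")
    ant, post = split_anterior_posterior(mask, y_cut=y_cut)
    voxvol = mask.voxel_volume
    ant_vol = float(ant.data.sum()) * voxvol
    post_vol = float(post.data.sum()) * voxvol
    total = ant_vol + post_vol
    if total <= 0:
        raise UndefinedFeatureError("empty ventricle mask")
    apr, apr_log = compute_apr(ant_vol, post_vol)
    vol = parcellate_volumes(mask, atlas)
    for lobe in ("frontal", "temporal"):
        for hemi in HEMIS:
            if vol.get((lobe, hemi), 0.0) <= 0:
                raise UndefinedFeatureError(
                    f"{lobe} {hemi} compartment volume is zero; "
                    "left-right ratio undefined")
    lr_frontal_log = math.log(vol[("frontal", "L")] / vol[("frontal", "R")])
    lr_temporal_log = math.log(vol[("temporal", "L")] / vol[("temporal", "R")])
    return VentricleFeatures(
        icv=icv, total_vol=total, total_vv_norm=total / icv,
        anterior_vol=ant_vol, posterior_vol=post_vol,
        apr=apr, apr_log=apr_log,
        lr_frontal_log=lr_frontal_log, lr_temporal_log=lr_temporal_log,
        vol=vol, age=age, sex_code=sex_code)


@dataclass
class QCThresholds:
    """Automated surrogate for visual segmentation QC."""

    min_prior_dice: float = 0.3
    volume_range_mm3: tuple[float, float] = (5_000.0, 250_000.0)
    max_components: int = 4          # 6-connected components ...
    min_component_voxels: int = 50   # ... counting only ones this large


@dataclass
class QCResult:
    status: str                      # "pass" | "fail"
    reasons: list[str]
    overlap_with_prior: float        # Dice vs template ventricle prior
    component_count: int

    @property
    def passed(self) -> bool:
        return self.status == "pass"


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def qc_segmentation(mask: LabelVolume, prior: LabelVolume,
                    thresholds: QCThresholds | None = None,
                    atlas: LobarAtlas | None = None,
                    y_cut: float = Y_CUT_MM) -> QCResult:
    """Flag incomplete or implausible ventricle segmentations.

    Checks: overlap with the template ventricle prior, total volume
    plausibility, fragmentation (number of sizeable 6-connected
    components), and non-emptiness of every compartment a downstream
    ratio divides by (posterior; right frontal and right temporal when
    an atlas is supplied, otherwise right-hemisphere anterior/posterior
    proxies).
    """
    thr = thresholds or QCThresholds()
    if not mask.same_grid(prior):
        raise GeometryError("mask and prior are not on the same grid")
    from .evaluation import dice

    reasons: list[str] = []
    d = dice(mask, prior)
    if d < thr.min_prior_dice:
        reasons.append("low_overlap")

    voxvol = mask.voxel_volume
    total = float((mask.data == 1).sum()) * voxvol
    lo, hi = thr.volume_range_mm3
    if not (lo <= total <= hi):
        reasons.append("volume_out_of_range")

    labeled, ncomp = ndimage.label(mask.data == 1, structure=_SIX_CONN)
    if ncomp:
        sizes = np.bincount(labeled.ravel())[1:]
        big = int((sizes >= thr.min_component_voxels).sum())
    else:
        big = 0
    if big > thr.max_components:
        reasons.append("fragmented")

    ant, post = split_anterior_posterior(mask, y_cut=y_cut)
    if post.data.sum() == 0:
        reasons.append("empty_posterior")
    if atlas is not None:
        vol = parcellate_volumes(mask, atlas) if total > 0 else {}
        if vol.get(("frontal", "R"), 0.0) <= 0:
            reasons.append("empty_right_frontal")
        if vol.get(("temporal", "R"), 0.0) <= 0:
            reasons.append("empty_right_temporal")
    else:
        # right-hemisphere proxies: any right-sided voxels anterior
        # (frontal horn territory) and posterior (temporal/body)
        ii, jj, kk = np.meshgrid(*(np.arange(n) for n in mask.shape),
                                 indexing="ij", sparse=True)
        A = mask.affine
        x = A[0, 0] * ii + A[0, 1] * jj + A[0, 2] * kk + A[0, 3]
        right = x > 0
        if not np.any((ant.data == 1) & right):
            reasons.append("empty_right_frontal")
        if not np.any((post.data == 1) & right):
            reasons.append("empty_right_temporal")

    return QCResult(status="fail" if reasons else "pass",
                    reasons=reasons, overlap_with_prior=d,
                    component_count=big)
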