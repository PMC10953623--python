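"""Patch-based label fusion segmentation of the lateral ventricles.

Each voxel of the target image (in template space) is labelled by
comparing its surrounding 3D intensity patch against all patches within
a search window in every library image, and fusing the library labels by
weighted vote.  Weights follow the non-local means form

    w_i = exp(-||P(x) - P_i||^2 / h^2),   h^2 = min_i ||P(x) - P_i||^2 + eps

with an adaptive bandwidth set by the best-matching patch, so that a
near-perfect library match dominates the vote.  Patches whose
luminance-contrast structural similarity to the target patch falls below
a preselection threshold are discarded before voting; if every patch at
a voxel is discarded the vote falls back to the unweighted majority of
the (unfiltered) window centre labels.

Computation is restricted to a candidate mask — the union of library
labels dilated by a few voxels — which is sound because the ventricles
are spatially consistent after affine stereotaxic registration.  Voxels
outside the candidate mask get label 0 with confidence 0.  Search
windows are clipped at the volume boundary (centres outside the volume
contribute no patch); patches straddling the boundary read zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_model import GeometryError, LabelVolume, VolumeImage

# SSIM stabilising constants on the [0, 100] normalised intensity range
_SSIM_RANGE = 100.0
_SSIM_C1 = (0.01 * _SSIM_RANGE) ** 2
_SSIM_C2 = (0.03 * _SSIM_RANGE) ** 2


class ConfigurationError(ValueError):
    pass


@dataclass
class FusionParams:
    """Tunable parameters of the label fusion.

    patch_radius 1 gives 3x3x3 patches; search_radius 4 gives 9x9x9
    search windows; preselection_threshold is the minimum
    luminance-contrast similarity for a library patch to enter the vote;
    bandwidth_floor is the eps added to the minimum patch distance;
    dilation is the candidate-mask dilation radius in voxels;
    decision_threshold binarises the fused vote (ties count foreground).
    """

    patch_radius: int = 1
    search_radius: int = 4
    preselection_threshold: float = 0.95
    bandwidth_floor: float = 1e-4
    dilation: int = 3
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise ValueError("patch_radius must be >= 1")
        if self.search_radius < self.patch_radius:
            raise ValueError("search_radius must be >= patch_radius")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.bandwidth_floor <= 0:
            raise ValueError("bandwidth_floor must be > 0")


@dataclass
class PatchLibrary:
    """Labelled (image, ventricle mask) examples on the template grid."""

    entries: list[tuple[VolumeImage, LabelVolume]]
    candidate_mask: LabelVolume
    dilation: int


def _ball(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    g = np.indices((2 * radius + 1,) * 3) - radius
    return (g ** 2).sum(axis=0) <= radius ** 2


def build_library(pairs, d: int = 3) -> PatchLibrary:
    """Assemble a patch library and its candidate mask.

    The candidate mask is the union of all library labels dilated by a
    ball of radius ``d`` voxels (d = 0 keeps the exact union).
    """
    if len(pairs) < 2:
        raise ConfigurationError("library needs at least 2 labelled pairs")
    ref_img, ref_lab = pairs[0]
    for i, (img, lab) in enumerate(pairs):
        if not img.same_grid(ref_img) or not lab.same_grid(ref_img):
            raise GeometryError(f"library entry {i} is not on the "
                                "template grid")
        if not lab.is_binary:
            raise ValueError(f"library entry {i} label volume is not binary")
    union = np.zeros(ref_img.shape, dtype=bool)
    for _, lab in pairs:
        union |= lab.data == 1
    if d > 0:
        union = ndimage.binary_dilation(union, structure=_ball(d))
    return PatchLibrary(
        entries=list(pairs),
        candidate_mask=LabelVolume(union.astype(np.int32), ref_img.affine),
        dilation=d,
    )


def segmentation_volume(mask: LabelVolume) -> float:
    """Volume of a binary mask in mm^3."""
    if not mask.is_binary:
        raise TypeError("segmentation_volume needs a binary mask")
    return float((mask.data == 1).sum()) * mask.voxel_volume


def _pad_to_box(arr: np.ndarray, lo, hi, margin: int, fill=0.0) -> np.ndarray:
    """Extract arr[lo:hi] expanded by ``margin``, zero-padding where the
    expanded box leaves the array."""
    shape = arr.shape
    src = tuple(slice(max(lo[a] - margin, 0), min(hi[a] + margin, shape[a]))
                for a in range(3))
    pad = tuple((margin - (lo[a] - src[a].start),
                 margin - (src[a].stop - hi[a]))
                for a in range(3))
    out = arr[src]
    if any(p != (0, 0) for p in pad):
        out = np.pad(out, pad, mode="constant", constant_values=fill)
    return np.ascontiguousarray(out)


def segment_ventricles(target: VolumeImage, lib: PatchLibrary,
                       params: FusionParams | None = None
                       ) -> tuple[LabelVolume, np.ndarray]:
    """Segment the lateral ventricles of a template-space image.

    Returns the binary segmentation and the fused-vote confidence map
    (in [0, 1]; 0 outside the candidate mask).  The target must be on
    the library grid and intensity-normalised like the library entries.
    """
    params = params or FusionParams()
    if not lib.entries:
        raise ConfigurationError("empty patch library")
    if not target.same_grid(lib.candidate_mask):
        raise GeometryError("target is not on the library template grid")

    pr, sr = params.patch_radius, params.search_radius
    cand = lib.candidate_mask.data == 1
    confidence = np.zeros(target.shape, dtype=np.float32)
    if not cand.any():
        label = np.zeros(target.shape, dtype=np.int32)
        return LabelVolume(label, target.affine), confidence

    # working box: candidate bounding box + search + patch margin
    pos = np.argwhere(cand)
    lo, hi = pos.min(axis=0), pos.max(axis=0) + 1
    margin = sr + pr
    T = _pad_to_box(target.data.astype(np.float32), lo, hi, margin)
    imgs = [_pad_to_box(img.data.astype(np.float32), lo, hi, margin)
            for img, _ in lib.entries]
    labs = [_pad_to_box(lab.data.astype(np.int8), lo, hi, margin)
            for _, lab in lib.entries]
    cand_box = _pad_to_box(cand, lo, hi, margin, fill=False)
    # window centres must lie inside the original volume
    valid_box = _pad_to_box(np.ones(target.shape, dtype=bool), lo, hi,
                            margin, fill=False)

    # voxels where every window-centre label of every entry agrees need
    # no patch arithmetic: any convex vote of identical labels (and the
    # preselection fallback) returns that label
    win = 2 * sr + 1
    lab_min = np.minimum.reduce(
        [ndimage.minimum_filter(lb, size=win) for lb in labs])
    lab_max = np.maximum.reduce(
        [ndimage.maximum_filter(lb, size=win) for lb in labs])
    decided = (lab_min == lab_max) & cand_box
    undecided = cand_box & ~decided

    conf_box = np.zeros(T.shape, dtype=np.float32)
    conf_box[decided] = lab_max[decided].astype(np.float32)

    if undecided.any():
        conf_box[undecided] = _fuse_votes(T, imgs, labs, undecided,
                                          valid_box, params)

    inner = tuple(slice(margin, margin + (hi[a] - lo[a])) for a in range(3))
    out_slices = tuple(slice(lo[a], hi[a]) for a in range(3))
    confidence[out_slices] = conf_box[inner]
    confidence[~cand] = 0.0
    label = (confidence >= params.decision_threshold).astype(np.int32)
    label[~cand] = 0
    return LabelVolume(label, target.affine), confidence


def _fuse_votes(T: np.ndarray, imgs, labs, undecided: np.ndarray,
                valid: np.ndarray, params: FusionParams,
                chunk: int = 16384) -> np.ndarray:
    """Fused votes at the undecided voxels (flat gather implementation)."""
    pr, sr = params.patch_radius, params.search_radius
    psz = 2 * pr + 1
    npatch = psz ** 3
    shape = T.shape
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)

    rng = np.arange(-pr, pr + 1, dtype=np.int64)
    dp = (rng[:, None, None] * strides[0] + rng[None, :, None] * strides[1]
          + rng[None, None, :] * strides[2]).ravel()            # patch
    rngs = np.arange(-sr, sr + 1, dtype=np.int64)
    do = (rngs[:, None, None] * strides[0] + rngs[None, :, None] * strides[1]
          + rngs[None, None, :] * strides[2]).ravel()           # window

    # per-entry patch-moment fields for preselection and distances
    flat_imgs = [im.ravel() for im in imgs]
    flat_labs = [lb.ravel() for lb in labs]
    mu_fields, sq_fields = [], []
    for im in imgs:
        mu_fields.append(ndimage.uniform_filter(im, size=psz).ravel())
        sq_fields.append(ndimage.uniform_filter(im * im, size=psz).ravel())

    Tflat = T.ravel()
    valid_flat = valid.ravel()
    u_idx_all = np.flatnonzero(undecided.ravel()).astype(np.int64)
    out = np.empty(u_idx_all.size, dtype=np.float32)

    sigma = params.preselection_threshold
    eps = params.bandwidth_floor

    for start in range(0, u_idx_all.size, chunk):
        u_idx = u_idx_all[start:start + chunk]
        n = u_idx.size
        Tp = Tflat[u_idx[:, None] + dp[None, :]]               # (n, npatch)
        sumsqT = np.einsum("ij,ij->i", Tp, Tp)
        muT = Tp.mean(axis=1)
        varT = sumsqT / npatch - muT * muT
        sigT = np.sqrt(np.maximum(varT, 0.0))

        ne = len(imgs)
        no = do.size
        D = np.empty((ne, no, n), dtype=np.float32)
        L = np.empty((ne, no, n), dtype=np.int8)
        V = np.empty((no, n), dtype=bool)
        for oi, off in enumerate(do):
            pidx = u_idx[:, None] + (off + dp)[None, :]
            cidx = u_idx + off
            V[oi] = valid_flat[cidx]
            for ei in range(ne):
                Lp = flat_imgs[ei][pidx]
                cross = np.einsum("ij,ij->i", Tp, Lp)
                muL = mu_fields[ei][cidx]
                sqL = sq_fields[ei][cidx]
                d = sumsqT + npatch * sqL - 2.0 * cross
                sigL = np.sqrt(np.maximum(sqL - muL * muL, 0.0))
                lum = ((2 * muT * muL + _SSIM_C1)
                       / (muT * muT + muL * muL + _SSIM_C1))
                con = ((2 * sigT * sigL + _SSIM_C2)
                       / (varT.clip(0) + sigL * sigL + _SSIM_C2))
                d[lum * con < sigma] = np.inf
                d[~V[oi]] = np.inf
                D[ei, oi] = np.maximum(d, 0.0)
                L[ei, oi] = flat_labs[ei][cidx]

        Df = D.reshape(ne * no, n)
        Lf = L.reshape(ne * no, n).astype(np.float32)
        dmin = Df.min(axis=0)
        h2 = np.where(np.isfinite(dmin), dmin, 0.0) + eps
        with np.errstate(over="ignore"):
            W = np.exp(-Df / h2[None, :])
        W[~np.isfinite(Df)] = 0.0
        den = W.sum(axis=0)
        num = (W * Lf).sum(axis=0)
        vote = np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)
        # all patches preselection-rejected: unweighted majority of the
        # unfiltered (in-volume) window centre labels
        rejected = den == 0
        if rejected.any():
            Vr = V[:, rejected].astype(np.float32)
            Lr = L[:, :, rejected].astype(np.float32)
            vote[rejected] = ((Lr * Vr[None]).sum(axis=(0, 1))
                              / np.maximum(ne * Vr.sum(axis=0), 1.0))
        out[start:start + chunk] = vote.astype(np.float32)
    return out
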