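"""Intensity normalisation and affine stereotaxic registration.

Normalisation removes a smooth multiplicative bias field (low-order
polynomial fit to log-intensities of foreground voxels) and rescales
intensities to [0, 100] between robust percentiles.  Registration
maximises normalised cross-correlation (NCC) over a rigid (6 dof),
rigid+anisotropic-scale (9 dof) or full affine (12 dof) transform,
coarse to fine over a multiresolution pyramid, with a deterministic
Powell search initialised by centre-of-mass alignment.  Subject
intracranial volume is obtained by carrying the template ICV mask
through the inverse transform: ICV = template mask volume / |det|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .io_model import AffineTransform, LabelVolume, VolumeImage


class DegenerateInputError(ValueError):
    pass


class InvalidTransformError(ValueError):
    pass


@dataclass
class RegistrationParams:
    """Settings of the NCC affine registration.

    levels: pyramid depth; level i is downsampled by 2**(levels-1-i).
    dof: 6 (rigid), 9 (rigid + per-axis scale) or 12 (full affine).
    max_iter: Powell iteration cap per level.
    tol: relative metric convergence tolerance.
    finest_stride: voxel stride of the metric sample grid at full
        resolution (coarser levels always use every voxel).
    """

    levels: int = 3
    dof: int = 12
    max_iter: int = 200
    tol: float = 1e-5
    finest_stride: int = 2

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.dof not in (6, 9, 12):
            raise ValueError("dof must be 6, 9 or 12")


def normalize_intensity(img: VolumeImage, bias_degree: int = 2,
                        clip_percentiles: tuple[float, float] = (0.1, 99.9)
                        ) -> VolumeImage:
    """Bias-correct and rescale an image to the [0, 100] range.

    A degree <= 2 polynomial in normalised voxel coordinates is fit to
    the log-intensities of foreground voxels and divided out, then
    intensities are clamped at robust percentiles and linearly mapped to
    [0, 100].  The result is invariant to any positive global scaling of
    the input.
    """
    data = np.asarray(img.data, dtype=np.float64)
    if float(data.max() - data.min()) <= 0:
        raise DegenerateInputError("constant image cannot be normalized")
    if not 0 <= bias_degree <= 2:
        raise ValueError("bias polynomial degree must be 0, 1 or 2")

    if bias_degree > 0:
        data = _remove_bias(data, degree=bias_degree)

    lo, hi = np.percentile(data, clip_percentiles)
    if hi <= lo:
        raise DegenerateInputError("degenerate intensity distribution")
    out = np.clip(data, lo, hi)
    out = (out - lo) * (100.0 / (hi - lo))
    return VolumeImage(out.astype(np.float32), img.affine)


def _poly_design(shape, mask, degree: int) -> tuple[np.ndarray, list]:
    """Design matrix of polynomial terms evaluated at masked voxels."""
    grids = np.indices(shape, dtype=np.float64)
    # normalise coordinates to [-1, 1] for conditioning
    for ax in range(3):
        n = shape[ax]
        grids[ax] = 2.0 * grids[ax] / max(n - 1, 1) - 1.0
    u, v, w = (g[mask] for g in grids)
    cols = [np.ones_like(u), u, v, w]
    if degree >= 2:
        cols += [u * v, u * w, v * w, u * u, v * v, w * w]
    return np.column_stack(cols), [g for g in grids]


def _remove_bias(data: np.ndarray, degree: int) -> np.ndarray:
    """Divide out a smooth multiplicative field.

    The field is a low-order polynomial fit to the log-intensities of
    head (brain-intensity) voxels.  Smooth tissue structure partly leaks
    into the fit, but only the bias share varies between acquisitions of
    the same anatomy, which is what downstream stages rely on.  The
    correction is clamped to the range observed over the fitted voxels:
    a polynomial extrapolates without bound outside the head, and an
    unclamped correction there would amplify background noise into the
    intensity percentiles.
    """
    lo, hi = np.percentile(data, (1.0, 99.0))
    head = data > lo + 0.25 * (hi - lo)
    if head.sum() < 200:
        return data
    fg = head
    # deterministic subsample for the fit
    idx = np.flatnonzero(fg.ravel())
    step = max(1, idx.size // 20000)
    sel = np.zeros(data.shape, dtype=bool).ravel()
    sel[idx[::step]] = True
    sel = sel.reshape(data.shape)
    vals = np.log(np.maximum(data[sel], 1e-6))
    A, grids = _poly_design(data.shape, sel, degree)
    coef, *_ = np.linalg.lstsq(A, vals, rcond=None)
    u, v, w = grids
    field = coef[0] + coef[1] * u + coef[2] * v + coef[3] * w
    if degree >= 2:
        field = (field + coef[4] * u * v + coef[5] * u * w + coef[6] * v * w
                 + coef[7] * u * u + coef[8] * v * v + coef[9] * w * w)
    # keep the mean level, remove only the spatial modulation
    field = field - field[sel].mean()
    field = np.clip(field, field[sel].min(), field[sel].max())
    return data / np.exp(field)


# ---------------------------------------------------------------------------
# NCC affine registration
# ---------------------------------------------------------------------------

def _euler(rx, ry, rz):
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _params_to_matrix(p: np.ndarray, dof: int, centre: np.ndarray,
                      init_shift: np.ndarray) -> np.ndarray:
    """Template-world -> moving-world map from the parameter vector.

    Parameters: [tx ty tz rx ry rz | log_sx log_sy log_sz | hxy hxz hyz],
    rotations in radians about the template centre-of-mass; the
    centre-of-mass shift ``init_shift`` is composed on top.
    """
    t = p[0:3]
    M = _euler(*p[3:6])
    if dof >= 9:
        M = M @ np.diag(np.exp(p[6:9]))
    if dof >= 12:
        S = np.eye(3)
        S[0, 1], S[0, 2], S[1, 2] = p[9], p[10], p[11]
        M = M @ S
    out = np.eye(4)
    out[:3, :3] = M
    out[:3, 3] = centre + init_shift + t - M @ centre
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _com_world(img: VolumeImage) -> np.ndarray:
    """Intensity centre of mass in world coordinates."""
    d = np.maximum(img.data, 0)
    if d.sum() == 0:
        return img.voxel_to_world((np.array(img.shape) - 1) / 2)
    com = np.array(ndimage.center_of_mass(d))
    return img.voxel_to_world(com)


def _sample_grid(shape, stride: int) -> np.ndarray:
    axes = [np.arange(0, n, stride, dtype=np.float64) for n in shape]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([x.ravel() for x in g])


def register_affine(moving: VolumeImage, template: VolumeImage,
                    params: RegistrationParams | None = None
                    ) -> AffineTransform:
    """Affine registration of a native image to the stereotaxic template.

    Returns the native-world -> template-world transform that maximises
    NCC.  Deterministic given identical inputs and parameters.  If the
    finest level stops on the iteration cap instead of the tolerance the
    result is flagged ``low_confidence`` with a warning.
    """
    params = params or RegistrationParams()
    centre = _com_world(template)
    init_shift = _com_world(moving) - centre

    ndof = {6: 6, 9: 9, 12: 12}[params.dof]
    # optimisation is done in scaled coordinates so that a unit step in
    # any direction moves the image by roughly 1 mm at the head radius
    scales = np.array([1.0, 1.0, 1.0,             # translation, mm
                       0.02, 0.02, 0.02,          # rotation, rad
                       0.02, 0.02, 0.02,          # log scale
                       0.02, 0.02, 0.02][:ndof])  # shear
    bounds = [(-30, 30)] * 3 + [(-20, 20)] * (ndof - 3)
    p = np.zeros(ndof)
    inv_mov = np.linalg.inv(moving.affine)
    low_confidence = False

    # metric samples are restricted to the template head region (plus a
    # margin) — background voxels far from the head carry no alignment
    # information and dominate the voxel count otherwise
    head = template.data > 0.02 * float(template.data.max())
    head = ndimage.binary_dilation(head, iterations=3)

    factors = [2 ** (params.levels - 1 - i) for i in range(params.levels)]
    for factor in factors:
        tpl = template.data
        if factor > 1:
            tpl = ndimage.gaussian_filter(template.data, factor / 2.0)
        mov = (ndimage.gaussian_filter(moving.data, factor / 2.0)
               if factor > 1 else moving.data)
        stride = max(factor, params.finest_stride) if factor > 1 \
            else params.finest_stride
        grid_vox = _sample_grid(template.shape, stride)
        keep = head[tuple(grid_vox.astype(np.intp))]
        grid_vox = grid_vox[:, keep]
        tpl_vals = tpl[tuple(grid_vox.astype(np.intp))].astype(np.float64)
        grid_world = (template.affine[:3, :3] @ grid_vox
                      + template.affine[:3, 3:4])

        def neg_ncc(pv):
            W = _params_to_matrix(pv * scales, params.dof, centre,
                                  init_shift)
            mov_world = W[:3, :3] @ grid_world + W[:3, 3:4]
            mov_vox = inv_mov[:3, :3] @ mov_world + inv_mov[:3, 3:4]
            vals = ndimage.map_coordinates(mov, mov_vox, order=1,
                                           mode="constant", cval=0.0)
            return -_ncc(tpl_vals, vals)

        res = optimize.minimize(
            neg_ncc, p, method="Powell", bounds=bounds,
            options={"maxiter": params.max_iter,
                     "xtol": 1e-3, "ftol": params.tol})
        p = res.x
        if factor == factors[-1] and not res.success:
            low_confidence = True
            warnings.warn("registration did not converge at the finest "
                          "level; returning best-found transform")

    W = _params_to_matrix(p * scales, params.dof, centre,
                          init_shift)                         # tpl -> native
    T = np.linalg.inv(W)                                      # native -> tpl
    return AffineTransform(T, low_confidence=low_confidence)


def resample_to_template(img: VolumeImage, t: AffineTransform,
                         template: VolumeImage, order: int = 1
                         ) -> VolumeImage:
    """Resample a native image onto the template grid through ``t``.

    Trilinear interpolation for intensities; out-of-field voxels are 0.
    """
    vox_map = (np.linalg.inv(img.affine) @ np.linalg.inv(t.matrix)
               @ template.affine)
    idx = np.indices(template.shape, dtype=np.float64).reshape(3, -1)
    coords = vox_map[:3, :3] @ idx + vox_map[:3, 3:4]
    out = ndimage.map_coordinates(img.data, coords, order=order,
                                  mode="constant", cval=0.0)
    return VolumeImage(out.reshape(template.shape).astype(np.float32),
                       template.affine)


def resample_label_to_template(mask: LabelVolume, t: AffineTransform,
                               template: VolumeImage) -> LabelVolume:
    """Nearest-neighbour resampling for label volumes."""
    vox_map = (np.linalg.inv(mask.affine) @ np.linalg.inv(t.matrix)
               @ template.affine)
    idx = np.indices(template.shape, dtype=np.float64).reshape(3, -1)
    coords = vox_map[:3, :3] @ idx + vox_map[:3, 3:4]
    out = ndimage.map_coordinates(mask.data.astype(np.float32), coords,
                                  order=0, mode="constant", cval=0.0)
    return LabelVolume(out.reshape(template.shape).astype(np.int32),
                       template.affine)


def estimate_icv(t: AffineTransform, template_icv_mask: LabelVolume) -> float:
    """Subject intracranial volume in mm^3.

    The template ICV mask back-projected to native space has volume
    (template mask volume) / |det| of the native->template linear part;
    no native-space segmentation is needed.
    """
    if t.scale_det <= 0:
        raise InvalidTransformError("non-positive transform determinant")
    mask_mm3 = float((template_icv_mask.data > 0).sum()) \
        * template_icv_mask.voxel_volume
    return mask_mm3 / t.scale_det
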