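"""Seven-parameter chromatic channel alignment.

Multichannel super-resolution microscopes image each colour through a
different camera and optical path, so channels are mutually translated,
slightly rotated about the optical (z) axis and anisotropically magnified
(astigmatism of the focusing lens). The alignment model here has seven
parameters: translations ``(tz, ty, tx)`` in nm, a rotation ``theta_z``
about the z axis in degrees, and per-axis magnifications ``(mz, my, mx)``.

Composition order is fixed as scale -> rotate -> translate, both scale and
rotation taken about the geometric centre of the stack, in physical nm:

    q = Rz(theta_z) @ diag(mz, my, mx) @ (p - c) + c + (tz, ty, tx)

``apply_transform`` samples the input at ``q`` for every output-voxel
coordinate ``p`` (pull-back, trilinear interpolation, zero outside the
frame). The inverse of this map for ``mx != my`` is not itself of the
scale->rotate->translate form, so ``inverse=True`` applies the exact
matrix inverse instead of re-parameterizing.

Calibration is estimated once from a multicolour bead field; because
chromatic aberration is sample- and slide-dependent (chiefly in z), the
three translations are re-estimated per acquisition from the DAPI signal
imaged through both optical paths (``refine_translation``), keeping the
bead rotation and magnifications.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .core import ImageStack, logger

__all__ = [
    "TransformParams",
    "SearchBounds",
    "apply_transform",
    "estimate_transform",
    "refine_translation",
]


@dataclass(frozen=True)
class TransformParams:
    """Translations in nm, z-rotation in degrees, per-axis magnifications."""

    tz: float = 0.0
    ty: float = 0.0
    tx: float = 0.0
    theta_z: float = 0.0
    mz: float = 1.0
    my: float = 1.0
    mx: float = 1.0

    composition: str = "scale->rotate(z,center)->translate, physical nm"

    def __post_init__(self) -> None:
        if min(self.mz, self.my, self.mx) <= 0:
            raise ValueError("magnifications must be positive")

    @classmethod
    def identity(cls) -> "TransformParams":
        return cls()

    def matrix(self) -> np.ndarray:
        """Linear part ``Rz @ S`` in (z, y, x) coordinate order."""
        th = np.deg2rad(self.theta_z)
        c, s = np.cos(th), np.sin(th)
        rot = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        return rot @ np.diag([self.mz, self.my, self.mx])

    def translation(self) -> np.ndarray:
        return np.array([self.tz, self.ty, self.tx])

    def as_vector(self) -> np.ndarray:
        return np.array([self.tz, self.ty, self.tx, self.theta_z, self.mz, self.my, self.mx])

    @classmethod
    def from_vector(cls, v) -> "TransformParams":
        v = np.asarray(v, dtype=float)
        return cls(tz=v[0], ty=v[1], tx=v[2], theta_z=v[3], mz=v[4], my=v[5], mx=v[6])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransformParams":
        d = json.loads(Path(path).read_text())
        d.pop("composition", None)
        return cls(**d)


@dataclass(frozen=True)
class SearchBounds:
    """Absolute search box for :func:`estimate_transform`."""

    translation_nm: float = 500.0
    rotation_deg: float = 2.0
    mag_deviation: float = 0.01

    def contains(self, p: TransformParams) -> bool:
        return (
            max(abs(p.tz), abs(p.ty), abs(p.tx)) <= self.translation_nm
            and abs(p.theta_z) <= self.rotation_deg
            and max(abs(p.mz - 1), abs(p.my - 1), abs(p.mx - 1)) <= self.mag_deviation
        )


def _sample_coords(stack: ImageStack, p: TransformParams, inverse: bool) -> np.ndarray:
    """Fractional voxel indices into ``stack`` for every output voxel."""
    shape = stack.shape
    vs = np.asarray(stack.voxel_size)
    center = stack.physical_center_nm()
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    phys = np.stack([(g + 0.5) * s for g, s in zip(grids, vs)], axis=0)
    flat = phys.reshape(3, -1)
    if not inverse:
        q = p.matrix() @ (flat - center[:, None]) + center[:, None] + p.translation()[:, None]
    else:
        q = np.linalg.inv(p.matrix()) @ (
            flat - center[:, None] - p.translation()[:, None]
        ) + center[:, None]
    return q / vs[:, None] - 0.5


def _resample(stack: ImageStack, p: TransformParams, inverse: bool):
    idx = _sample_coords(stack, p, inverse)
    shape = stack.shape
    out = ndimage.map_coordinates(
        np.asarray(stack.voxels, dtype=float), idx, order=1, mode="constant", cval=0.0
    ).reshape(shape)
    in_frame = np.ones(idx.shape[1], dtype=bool)
    for ax in range(3):
        in_frame &= (idx[ax] >= 0) & (idx[ax] <= shape[ax] - 1)
    return out, in_frame.reshape(shape)


def apply_transform(stack: ImageStack, p: TransformParams, inverse: bool = False) -> ImageStack:
    """Resample a stack through the alignment transform.

    With ``inverse=False`` the output at voxel coordinate ``x`` is the input
    sampled at the transformed coordinate, so if ``moving`` was produced by
    ``apply_transform(reference, p)``, then
    ``apply_transform(moving, p, inverse=True)`` recovers ``reference`` (up
    to interpolation error). Out-of-frame samples are zero.
    """
    out, _ = _resample(stack, p, inverse)
    out = np.clip(out, 0.0, None)
    return ImageStack(voxels=out, voxel_size=stack.voxel_size, channel=stack.channel)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _objective(reference: ImageStack, moving: ImageStack):
    """Negative Pearson correlation over the reference's signal support.

    The support (a smoothed copy of the reference thresholded at 15% of
    its max, dilated) excludes empty background whose noise would both
    dilute the correlation and slow every evaluation; the moving image is
    sampled there through precomputed cubic-spline coefficients, which
    avoids the magnification bias that linear interpolation's
    high-frequency attenuation would introduce. Candidates sampling fewer
    than 8 support voxels in frame score worst (cost 1).
    """
    ref = np.asarray(reference.voxels, dtype=float)
    sm = ndimage.gaussian_filter(ref, 1.5)
    support = ndimage.binary_dilation(sm > 0.15 * sm.max(), iterations=2)
    sel = np.nonzero(support)
    vs = np.asarray(reference.voxel_size)
    center = reference.physical_center_nm()
    phys = np.stack([(s + 0.5) * v for s, v in zip(sel, vs)], axis=0)
    ref_sel = ref[sel]
    coef = ndimage.spline_filter(np.asarray(moving.voxels, dtype=float), order=3)
    shape = np.asarray(moving.shape)

    def f(p: TransformParams) -> float:
        q = np.linalg.inv(p.matrix()) @ (
            phys - center[:, None] - p.translation()[:, None]
        ) + center[:, None]
        idx = q / vs[:, None] - 0.5
        ok = np.all((idx >= 0) & (idx <= (shape - 1)[:, None]), axis=0)
        if ok.sum() < 8:
            return 1.0
        out = ndimage.map_coordinates(
            coef, idx[:, ok], order=3, prefilter=False, mode="constant", cval=0.0
        )
        return -_pearson(ref_sel[ok], out)

    return f


# normalized-parameter scales: ~1 unit = one voxel / one degree / 1% magnification
def _param_scales(stack: ImageStack) -> np.ndarray:
    dz, dy, dx = stack.voxel_size
    return np.array([dz, dy, dx, 1.0, 0.01, 0.01, 0.01])


def estimate_transform(
    reference: ImageStack,
    moving: ImageStack,
    initial: TransformParams | None = None,
    bounds: SearchBounds | None = None,
    tol: float = 1e-4,
    translations_only: bool = False,
) -> TransformParams:
    """Find the alignment parameters maximizing Pearson correlation.

    The correlation is computed between ``reference`` and ``moving``
    resampled through the inverse of the candidate transform, over the
    voxels where the resampling stays in frame; the returned parameters
    therefore describe the distortion of ``moving`` relative to
    ``reference`` (forward-model convention). The search seeds the
    translations at the integer-voxel cross-correlation peak and refines
    all requested parameters with a Nelder-Mead simplex.
    """
    if reference.shape != moving.shape or reference.voxel_size != moving.voxel_size:
        raise ValueError("reference and moving stacks must share grid shape and voxel size")
    if float(np.var(reference.voxels)) == 0 or float(np.var(moving.voxels)) == 0:
        raise ValueError("cannot register a flat (zero-variance) image")
    bounds = bounds or SearchBounds()
    initial = initial or TransformParams.identity()
    if not bounds.contains(initial):
        raise ValueError("initial guess lies outside the search bounds")

    cost = _objective(reference, moving)
    vs = np.asarray(reference.voxel_size)

    # integer-voxel translation seed via cross-correlation peak, rotation
    # and magnification seeded from `initial`
    shift_vox = phase_cross_correlation(
        np.asarray(reference.voxels, float),
        np.asarray(moving.voxels, float),
        upsample_factor=1,
    )[0]
    seed_t = np.asarray(shift_vox) * vs
    seed = dataclasses.replace(
        initial, tz=float(seed_t[0]), ty=float(seed_t[1]), tx=float(seed_t[2])
    )
    candidates = [initial]
    if bounds.contains(seed):
        candidates.append(seed)
    start = min(candidates, key=cost)

    scales = _param_scales(reference)
    free = np.arange(3) if translations_only else np.arange(7)
    x_start = start.as_vector()

    def cost_vec(u: np.ndarray) -> float:
        x = x_start.copy()
        x[free] = u * scales[free]
        p = TransformParams.from_vector(x)
        if not bounds.contains(p):
            return 1.0
        return cost(p)

    u0 = x_start[free] / scales[free]
    res = optimize.minimize(
        cost_vec,
        u0,
        method="Powell",
        options={"xtol": tol, "ftol": 1e-12, "maxiter": 15},
    )
    x_best = x_start.copy()
    x_best[free] = res.x * scales[free]
    best = TransformParams.from_vector(x_best)

    # the optimum never scores worse than the supplied initial guess
    result = min([initial, start, best], key=cost)
    logger.info("estimate_transform: corr %.5f at %s", -cost(result), result)
    return result


def refine_translation(
    reference_dapi: ImageStack,
    moving_dapi: ImageStack,
    calibration: TransformParams,
    bounds: SearchBounds | None = None,
    tol: float = 1e-4,
) -> TransformParams:
    """Re-estimate only the translations, keeping the bead calibration.

    Chromatic aberration differs between bead slides and biological
    samples and between acquisitions (coverslip distance, z in particular),
    so the translations are corrected per stack from the DAPI signal imaged
    through both channels' optical paths; rotation and magnifications pass
    through unchanged, bit-exactly.
    """
    est = estimate_transform(
        reference_dapi,
        moving_dapi,
        initial=calibration,
        bounds=bounds,
        tol=tol,
        translations_only=True,
    )
    return dataclasses.replace(
        calibration, tz=est.tz, ty=est.ty, tx=est.tx
    )
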