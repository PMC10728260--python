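"""Registration, subtraction, and iodine calibration.

The subtraction chain mirrors the acquisition protocol: the baseline
(0 mg I/ml) image is affinely registered to each contrast-enhanced image,
resampled, and subtracted voxelwise to give a ΔHU map whose signal is
iodine only; a linear calibration (fitted on the calibrated phantom set)
then converts ΔHU to C_I in mg I/ml.

World coordinates are mm with the volume centre at the origin, in
``(z, y, x)`` order to match array indexing.  ROIs are defined in world
coordinates so that measurements are comparable across the different voxel
grids used by the two reconstruction algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation

from .phantoms import GridSpec, ImageVolume

__all__ = ["AffineTransform", "CalibrationFn", "RoiSpec", "register_affine",
           "subtract", "fit_ci_calibration", "apply_ci_calibration",
           "measure_roi", "resample"]


@dataclass(frozen=True)
class AffineTransform:
    """World-coordinate affine map p_moving = linear @ p_fixed + translation,
    with p in (z, y, x) mm."""

    linear: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=np.float64).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(lin)) < 1e-12:
            raise ValueError("linear part must be invertible")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix (plain-text serialisable)."""
        M = np.eye(4)
        M[:3, :3] = self.linear
        M[:3, 3] = self.translation
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "AffineTransform":
        M = np.asarray(M, dtype=np.float64).reshape(4, 4)
        return cls(linear=M[:3, :3], translation=M[:3, 3])


@dataclass(frozen=True)
class CalibrationFn:
    """Linear ΔHU → C_I map: C_I = slope * ΔHU + intercept (mg I/ml)."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class RoiSpec:
    """Region of interest in world mm: ``center`` (z, y, x), ``radius``.

    ``shape='sphere'`` uses the 3D distance; ``shape='disk'`` uses the
    in-plane distance and includes slices whose centre lies within
    ``z_extent / 2`` of the ROI centre (default: one slice).
    """

    center: tuple[float, float, float]
    radius: float
    shape: str = "sphere"
    z_extent: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")
        if self.shape not in ("sphere", "disk"):
            raise ValueError("ROI shape must be 'sphere' or 'disk'")

    def mask(self, grid: GridSpec) -> np.ndarray:
        """Boolean voxel mask; membership by voxel-centre inclusion."""
        z = grid.axis_coords(0) - self.center[0]
        y = grid.axis_coords(1) - self.center[1]
        x = grid.axis_coords(2) - self.center[2]
        if self.shape == "sphere":
            d2 = (z[:, None, None] ** 2 + y[None, :, None] ** 2
                  + x[None, None, :] ** 2)
            return d2 <= self.radius ** 2
        inplane = (y[None, :, None] ** 2 + x[None, None, :] ** 2
                   <= self.radius ** 2)
        zext = self.z_extent if self.z_extent is not None else grid.spacing[0]
        inz = np.abs(z) <= zext / 2.0 + 1e-12
        return inz[:, None, None] & inplane


# ---------------------------------------------------------------------------
# Registration and resampling
# ---------------------------------------------------------------------------

def _world_to_index(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """index = S^-1 world + c, with S = diag(spacing), c = (shape-1)/2."""
    S_inv = np.diag(1.0 / np.asarray(grid.spacing))
    c = (np.asarray(grid.shape) - 1) / 2.0
    return S_inv, c


def resample(vol: ImageVolume, t: AffineTransform,
             grid: GridSpec | None = None) -> ImageVolume:
    """Resample ``vol`` onto ``grid`` (default: its own grid) through the
    world-coordinate transform ``t`` with linear interpolation."""
    out_grid = grid or vol.grid
    Si_in, c_in = _world_to_index(vol.grid)
    S_out = np.diag(np.asarray(out_grid.spacing))
    c_out = (np.asarray(out_grid.shape) - 1) / 2.0
    # input index = Si_in (L (S_out (i_out - c_out)) + tr) + c_in
    M = Si_in @ t.linear @ S_out
    offset = Si_in @ (t.linear @ (-S_out @ c_out) + t.translation) + c_in
    vals = ndi.affine_transform(vol.values, M, offset=offset,
                                output_shape=out_grid.shape, order=1,
                                mode="nearest")
    return ImageVolume(values=vals, grid=out_grid, semantics=vol.semantics,
                       provenance=vol.provenance)


def _mse_between(moving: ImageVolume, fixed: ImageVolume,
                 t: AffineTransform) -> float:
    res = resample(moving, t, fixed.grid)
    return float(np.mean((res.values - fixed.values) ** 2))


def register_affine(moving: ImageVolume, fixed: ImageVolume,
                    mode: str = "affine") -> AffineTransform:
    """Intensity-based registration of ``moving`` onto ``fixed``.

    Translation is initialised by subpixel phase correlation; with
    ``mode='affine'`` the full 12-parameter transform is then refined by
    multi-resolution Powell descent on the mean-squared intensity
    difference.  ``mode='translation'`` skips the refinement (appropriate
    when inputs are simulator-aligned up to a shift).  Raises if the final
    metric is worse than the identity metric.
    """
    if mode not in ("translation", "affine"):
        raise ValueError("mode must be 'translation' or 'affine'")
    if moving.grid.shape != fixed.grid.shape or \
            moving.grid.spacing != fixed.grid.spacing:
        # resample moving to the fixed grid first (world coords align centres)
        moving = resample(moving, AffineTransform.identity(), fixed.grid)
    shift_vox, _, _ = phase_cross_correlation(
        fixed.values, moving.values, upsample_factor=20, normalization=None)
    # moving(p + tr) aligns with fixed(p): phase shift (fixed vs moving) in
    # voxels converts to a world translation of the sampling point.
    tr = -np.asarray(shift_vox) * np.asarray(fixed.grid.spacing)
    t0 = AffineTransform(translation=tr)
    if mode == "translation":
        return t0

    def pack(params: np.ndarray) -> AffineTransform:
        lin = np.eye(3) + params[:9].reshape(3, 3)
        return AffineTransform(linear=lin, translation=params[9:])

    identity_mse = _mse_between(moving, fixed, AffineTransform.identity())
    x0 = np.concatenate([np.zeros(9), tr])
    factors = [f for f in (2, 1) if min(fixed.grid.shape) // f >= 8]
    for factor in factors or [1]:
        if factor > 1:
            f_vals = ndi.zoom(fixed.values, 1.0 / factor, order=1)
            m_vals = ndi.zoom(moving.values, 1.0 / factor, order=1)
            sp = tuple(s * factor for s in fixed.grid.spacing)
            f_small = ImageVolume(f_vals, GridSpec(f_vals.shape, sp),
                                  fixed.semantics)
            m_small = ImageVolume(m_vals, GridSpec(m_vals.shape, sp),
                                  moving.semantics)
        else:
            f_small, m_small = fixed, moving
        res = minimize(lambda p: _mse_between(m_small, f_small, pack(p)),
                       x0, method="Powell",
                       options={"maxiter": 20, "xtol": 1e-4, "ftol": 1e-8})
        x0 = res.x
    # keep the better of {refined affine, translation-only init}
    candidates = [(_mse_between(moving, fixed, pack(x0)), pack(x0)),
                  (_mse_between(moving, fixed, t0), t0)]
    best_mse, best = min(candidates, key=lambda c: c[0])
    if best_mse > identity_mse * (1.0 + 1e-9):
        raise RuntimeError("registration failed to improve the MSE metric")
    return best


def subtract(ce: ImageVolume, baseline: ImageVolume,
             t: AffineTransform | None = None) -> ImageVolume:
    """ΔHU = CE − baseline∘t, voxelwise on the CE grid."""
    if ce.semantics != "HU" or baseline.semantics != "HU":
        raise ValueError("subtract expects HU volumes")
    t = t or AffineTransform.identity()
    base = resample(baseline, t, ce.grid)
    return ImageVolume(values=ce.values - base.values, grid=ce.grid,
                       semantics="dHU", provenance=ce.provenance)


# ---------------------------------------------------------------------------
# Iodine calibration
# ---------------------------------------------------------------------------

def fit_ci_calibration(pairs) -> CalibrationFn:
    """Ordinary least squares of nominal C_I on mean ΔHU.

    ``pairs`` is a sequence of ``(mean_dhu, nominal_ci)`` with at least
    three distinct concentration levels.
    """
    pairs = list(pairs)
    dhu = np.asarray([p[0] for p in pairs], dtype=np.float64)
    ci = np.asarray([p[1] for p in pairs], dtype=np.float64)
    if len(np.unique(ci)) < 3:
        raise ValueError("calibration requires >= 3 distinct C_I levels")
    if np.ptp(dhu) == 0:
        raise ValueError("zero variance in ΔHU values")
    slope, intercept = np.polyfit(dhu, ci, 1)
    pred = slope * dhu + intercept
    ss_res = float(np.sum((ci - pred) ** 2))
    ss_tot = float(np.sum((ci - ci.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return CalibrationFn(slope=float(slope), intercept=float(intercept),
                         r_squared=min(max(r2, 0.0), 1.0))


def apply_ci_calibration(sub: ImageVolume, fn: CalibrationFn) -> ImageVolume:
    """Convert a ΔHU map to a C_I map (mg I/ml) voxelwise."""
    if sub.semantics != "dHU":
        raise ValueError("apply_ci_calibration expects a ΔHU volume")
    return sub.with_values(fn.slope * sub.values + fn.intercept,
                           semantics="CI")


def measure_roi(vol: ImageVolume, roi: RoiSpec) -> tuple[float, float, int]:
    """Mean, sample SD (n−1 denominator) and voxel count over the ROI."""
    mask = roi.mask(vol.grid)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI contains no voxels (outside volume?)")
    vals = vol.values[mask]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return float(vals.mean()), sd, n
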