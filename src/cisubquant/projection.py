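"""Parallel-beam forward projection and counting noise.

The acquisition model is 2D parallel-beam geometry applied slice by slice:
each sinogram entry is the line integral of linear attenuation (mm^-1)
along a ray, computed with Joseph-style linear-interpolation ray tracing.
The projector is materialised once per (geometry, grid) pair as a sparse
matrix, so the backprojector used by iterative reconstruction is its exact
adjoint (``A.T``) by construction.

Counting noise follows the transmission model: for incident fluence ``I0``
photons per detector bin, transmitted counts are Poisson distributed with
mean ``I0 * exp(-line_integral)`` and are log-converted back to noisy line
integrals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .phantoms import GridSpec, ImageVolume

__all__ = ["ScanGeometry", "Sinogram", "system_matrix", "forward_project",
           "add_noise"]


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam scan geometry.

    ``n_angles`` view angles uniformly spaced over [0, pi); ``detector_bins``
    detector elements of pitch ``detector_spacing`` (mm), centred on the
    rotation axis; ``I0`` incident photons per bin (used by the noise
    model).
    """

    n_angles: int = 200
    detector_bins: int = 160
    detector_spacing: float = 0.25
    I0: float = 1e5

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.detector_bins < 1:
            raise ValueError("detector_bins must be >= 1")
        if self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")

    @property
    def angles(self) -> np.ndarray:
        """View angles in radians, uniform over [0, pi)."""
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def detector_coords(self) -> np.ndarray:
        """Detector bin centres t (mm), centred on the rotation axis."""
        n = self.detector_bins
        return (np.arange(n) - (n - 1) / 2.0) * self.detector_spacing


@dataclass
class Sinogram:
    """Per-slice projection data: ``line_integrals`` has shape
    (n_slices, n_angles, detector_bins) and is dimensionless (mm^-1 x mm)."""

    line_integrals: np.ndarray
    geometry: ScanGeometry
    noise_applied: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.line_integrals = np.asarray(self.line_integrals, dtype=np.float64)
        if self.line_integrals.ndim != 3:
            raise ValueError("line_integrals must be (slice, angle, bin)")
        ns, na, nb = self.line_integrals.shape
        if na != self.geometry.n_angles or nb != self.geometry.detector_bins:
            raise ValueError("sinogram shape inconsistent with geometry")


# ---------------------------------------------------------------------------
# System matrix (Joseph linear-interpolation ray tracing)
# ---------------------------------------------------------------------------

_MATRIX_CACHE: dict[tuple, sp.csr_matrix] = {}
_MATRIX_CACHE_MAX = 4


def system_matrix(geom: ScanGeometry, ny: int, nx: int,
                  spacing: float) -> sp.csr_matrix:
    """Sparse projection operator A of shape (n_angles*bins, ny*nx).

    A ray at angle theta and detector coordinate t is the line
    ``x cos(theta) + y sin(theta) = t``.  Joseph's method steps along the
    grid axis most orthogonal to the ray and linearly interpolates between
    the two neighbouring pixel centres on the other axis; the weight of
    each sample is the intersection length ``h / max(|cos|, |sin|)``.
    The matrix is cached per (geometry, grid) key.
    """
    key = (geom.n_angles, geom.detector_bins, round(geom.detector_spacing, 12),
           ny, nx, round(float(spacing), 12))
    hit = _MATRIX_CACHE.get(key)
    if hit is not None:
        return hit

    h = float(spacing)
    t = geom.detector_coords  # (B,)
    B = geom.detector_bins
    ycoords = (np.arange(ny) - (ny - 1) / 2.0) * h
    xcoords = (np.arange(nx) - (nx - 1) / 2.0) * h

    rows_all, cols_all, vals_all = [], [], []
    for a, th in enumerate(geom.angles):
        c, s = np.cos(th), np.sin(th)
        if abs(c) >= abs(s):
            # step along y (rows); x = (t - y s) / c
            L = h / abs(c)
            # f: fractional x-index, shape (B, ny)
            x = (t[:, None] - ycoords[None, :] * s) / c
            f = x / h + (nx - 1) / 2.0
            j0 = np.floor(f).astype(np.int64)
            w = f - j0
            i_idx = np.broadcast_to(np.arange(ny)[None, :], f.shape)
            col0 = i_idx * nx + j0
            col1 = col0 + 1
            row = np.broadcast_to((a * B + np.arange(B))[:, None], f.shape)
            m0 = (j0 >= 0) & (j0 <= nx - 1)
            m1 = (j0 + 1 >= 0) & (j0 + 1 <= nx - 1)
            rows_all.append(row[m0]); cols_all.append(col0[m0])
            vals_all.append(((1.0 - w) * L)[m0])
            rows_all.append(row[m1]); cols_all.append(col1[m1])
            vals_all.append((w * L)[m1])
        else:
            # step along x (cols); y = (t - x c) / s
            L = h / abs(s)
            y = (t[:, None] - xcoords[None, :] * c) / s
            f = y / h + (ny - 1) / 2.0
            i0 = np.floor(f).astype(np.int64)
            w = f - i0
            j_idx = np.broadcast_to(np.arange(nx)[None, :], f.shape)
            col0 = i0 * nx + j_idx
            col1 = col0 + nx
            row = np.broadcast_to((a * B + np.arange(B))[:, None], f.shape)
            m0 = (i0 >= 0) & (i0 <= ny - 1)
            m1 = (i0 + 1 >= 0) & (i0 + 1 <= ny - 1)
            rows_all.append(row[m0]); cols_all.append(col0[m0])
            vals_all.append(((1.0 - w) * L)[m0])
            rows_all.append(row[m1]); cols_all.append(col1[m1])
            vals_all.append((w * L)[m1])

    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    vals = np.concatenate(vals_all)
    A = sp.coo_matrix((vals, (rows, cols)),
                      shape=(geom.n_angles * B, ny * nx)).tocsr()
    if len(_MATRIX_CACHE) >= _MATRIX_CACHE_MAX:
        _MATRIX_CACHE.pop(next(iter(_MATRIX_CACHE)))
    _MATRIX_CACHE[key] = A
    return A


def forward_project(vol: ImageVolume, geom: ScanGeometry) -> Sinogram:
    """Project an attenuation volume into a noiseless sinogram.

    The grid must be square in-plane with isotropic in-plane spacing.
    Deterministic; output shape (n_slices, n_angles, detector_bins).
    """
    if vol.semantics != "attenuation":
        raise ValueError("forward_project requires attenuation semantics")
    nz, ny, nx = vol.grid.shape
    dy, dx = vol.grid.spacing[1], vol.grid.spacing[2]
    if not np.isclose(dy, dx):
        raise ValueError("in-plane spacing must be isotropic")
    A = system_matrix(geom, ny, nx, dx)
    X = vol.values.reshape(nz, ny * nx).T  # (npix, nslices)
    P = A @ X  # (n_angles*B, nslices)
    sino = P.T.reshape(nz, geom.n_angles, geom.detector_bins)
    return Sinogram(line_integrals=sino, geometry=geom)


def add_noise(sino: Sinogram, I0: float | None = None,
              seed: int | None = None) -> Sinogram:
    """Apply transmission Poisson noise to a noiseless sinogram.

    Counts ``N ~ Poisson(I0 * exp(-p))`` per bin are converted back to line
    integrals ``-log(N / I0)``; zero counts are floored at 0.5 counts so the
    log stays finite.  Same seed, same output.
    """
    if sino.noise_applied:
        raise ValueError("noise already applied to this sinogram")
    if I0 is None:
        I0 = sino.geometry.I0
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    rng = np.random.default_rng(seed)
    expected = I0 * np.exp(-sino.line_integrals)
    counts = rng.poisson(expected).astype(np.float64)
    counts = np.maximum(counts, 0.5)
    noisy = -np.log(counts / I0)
    return Sinogram(line_integrals=noisy, geometry=sino.geometry,
                    noise_applied=True, seed=seed)
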