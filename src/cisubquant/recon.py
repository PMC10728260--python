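"""Reconstruction: filtered backprojection and SIRT, with HU calibration.

FBP is the classic per-slice ramp-filter algorithm: each projection is
filtered in the frequency domain (ramp, optionally Hann-apodized), then
backprojected pixel-driven with linear interpolation and scaled by
``pi / n_angles``.

SIRT iterates

    x_{k+1} = x_k + lam * C * A^T * R * (p - A x_k)

from a zero image, where ``A`` is the Joseph projector of the projection
module, ``R`` the inverse row-sum and ``C`` the inverse column-sum diagonal
weightings (zero sums contribute zero, pseudo-inverse convention).  Running
it for a fixed iteration count — 180 by default, mirroring the optimized
trade-off between noise and resolution — makes the iteration count itself
an image-quality parameter, which ``optimize_iterations`` sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantoms import GridSpec, ImageVolume
from .projection import ScanGeometry, Sinogram, system_matrix

__all__ = ["FbpParams", "SirtParams", "fbp_reconstruct", "sirt_reconstruct",
           "to_hounsfield", "optimize_iterations"]


@dataclass(frozen=True)
class FbpParams:
    """Ramp-filter FBP parameters: ``filter`` in {"ramp", "hann"};
    ``cutoff`` is the filter cutoff as a fraction of the detector Nyquist
    frequency."""

    filter: str = "hann"
    cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.filter not in ("ramp", "hann"):
            raise ValueError("filter must be 'ramp' or 'hann'")
        if not (0 < self.cutoff <= 1):
            raise ValueError("cutoff must lie in (0, 1]")


@dataclass(frozen=True)
class SirtParams:
    """SIRT parameters: iteration count, relaxation in (0, 2], optional
    non-negativity projection. Initial image is zero."""

    n_iterations: int = 180
    relaxation: float = 1.0
    nonnegativity: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 < self.relaxation <= 2):
            raise ValueError("relaxation must lie in (0, 2]")


def _check_grid(sino: Sinogram, grid: GridSpec) -> tuple[int, int, int, float]:
    nz, ny, nx = grid.shape
    if sino.line_integrals.shape[0] != nz:
        raise ValueError("sinogram slice count does not match grid")
    dy, dx = grid.spacing[1], grid.spacing[2]
    if not np.isclose(dy, dx):
        raise ValueError("in-plane spacing must be isotropic")
    return nz, ny, nx, dx


# ---------------------------------------------------------------------------
# FBP
# ---------------------------------------------------------------------------

def _ramp_filter(n_pad: int, spacing: float, params: FbpParams) -> np.ndarray:
    """Frequency response (cycles/mm) of the apodized ramp on a padded axis."""
    freqs = np.fft.fftfreq(n_pad, d=spacing)
    nyq = 1.0 / (2.0 * spacing)
    fc = params.cutoff * nyq
    H = np.abs(freqs)
    if params.filter == "hann":
        H = H * 0.5 * (1.0 + np.cos(np.pi * freqs / fc))
    H[np.abs(freqs) > fc] = 0.0
    return H


def fbp_reconstruct(sino: Sinogram, params: FbpParams,
                    grid: GridSpec) -> ImageVolume:
    """Per-slice filtered backprojection onto ``grid`` (attenuation, mm^-1)."""
    nz, ny, nx, h = _check_grid(sino, grid)
    geom = sino.geometry
    B = geom.detector_bins
    d = geom.detector_spacing
    n_pad = int(2 ** np.ceil(np.log2(max(64, 2 * B))))
    H = _ramp_filter(n_pad, d, params)

    # filter all slices/angles at once
    p = sino.line_integrals  # (nz, na, B)
    P = np.fft.fft(p, n=n_pad, axis=-1)
    q = np.fft.ifft(P * H[None, None, :], axis=-1).real[..., :B]

    yc = grid.axis_coords(1)
    xc = grid.axis_coords(2)
    X, Y = np.meshgrid(xc, yc)
    t0 = geom.detector_coords[0]
    out = np.zeros((nz, ny, nx))
    for a, th in enumerate(geom.angles):
        t = X * np.cos(th) + Y * np.sin(th)
        f = (t - t0) / d
        j0 = np.floor(f).astype(np.int64)
        w = f - j0
        j0c = np.clip(j0, 0, B - 1)
        j1c = np.clip(j0 + 1, 0, B - 1)
        inside = (f >= 0) & (f <= B - 1)
        qa = q[:, a, :]  # (nz, B)
        interp = (1.0 - w)[None] * qa[:, j0c] + w[None] * qa[:, j1c]
        out += np.where(inside[None], interp, 0.0)
    out *= np.pi / geom.n_angles
    return ImageVolume(values=out, grid=grid, semantics="attenuation")


# ---------------------------------------------------------------------------
# SIRT
# ---------------------------------------------------------------------------

def _sirt_run(A, p_cols: np.ndarray, params: SirtParams,
              snapshots: list[int] | None = None) -> dict[int, np.ndarray]:
    """Core SIRT loop on stacked right-hand sides.

    ``p_cols`` has shape (n_rays, n_cols); each column is one slice's
    sinogram.  Returns {iteration: solution array} for each requested
    snapshot (default: only the final count).
    """
    n_iter = params.n_iterations
    if snapshots is None:
        snapshots = [n_iter]
    row_sum = np.asarray(A.sum(axis=1)).ravel()
    col_sum = np.asarray(A.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        R = np.where(row_sum > 0, 1.0 / row_sum, 0.0)
        C = np.where(col_sum > 0, 1.0 / col_sum, 0.0)
    x = np.zeros((A.shape[1], p_cols.shape[1]))
    out: dict[int, np.ndarray] = {}
    lam = params.relaxation
    for k in range(1, n_iter + 1):
        resid = p_cols - A @ x
        x = x + lam * (C[:, None] * (A.T @ (R[:, None] * resid)))
        if params.nonnegativity:
            np.maximum(x, 0.0, out=x)
        if k in snapshots:
            out[k] = x.copy()
    return out


def sirt_reconstruct(sino: Sinogram, params: SirtParams,
                     grid: GridSpec) -> ImageVolume:
    """SIRT reconstruction onto ``grid`` (attenuation, mm^-1); runs exactly
    ``params.n_iterations`` iterations from a zero image."""
    nz, ny, nx, h = _check_grid(sino, grid)
    geom = sino.geometry
    A = system_matrix(geom, ny, nx, h)
    p_cols = sino.line_integrals.reshape(nz, -1).T  # (n_rays, nz)
    sols = _sirt_run(A, p_cols, params)
    x = sols[params.n_iterations]
    return ImageVolume(values=x.T.reshape(nz, ny, nx), grid=grid,
                       semantics="attenuation")


# ---------------------------------------------------------------------------
# HU calibration
# ---------------------------------------------------------------------------

def to_hounsfield(vol: ImageVolume, mu_water_measured: float) -> ImageVolume:
    """HU = 1000 (mu - mu_water) / mu_water, voxelwise.

    ``mu_water_measured`` is the mean reconstructed attenuation of water for
    the same reconstruction algorithm (measured on a water phantom), so the
    calibration absorbs any algorithm-specific scale.
    """
    if vol.semantics != "attenuation":
        raise ValueError("to_hounsfield requires attenuation semantics")
    if mu_water_measured <= 0:
        raise ValueError("mu_water_measured must be positive")
    hu = 1000.0 * (vol.values - mu_water_measured) / mu_water_measured
    return vol.with_values(hu, semantics="HU")


# ---------------------------------------------------------------------------
# Iteration-count sweep (noise vs resolution trade-off)
# ---------------------------------------------------------------------------

def optimize_iterations(iter_grid: list[int], water_sino: Sinogram,
                        edge_sino: Sinogram, grid: GridSpec,
                        params: SirtParams | None = None,
                        roi_radius_mm: float = 6.0) -> pd.DataFrame:
    """Sweep SIRT iteration counts, recording uniform-ROI noise SD (HU) and
    edge-method MTF50 (lp/mm) at each count.

    One SIRT run per sinogram with snapshots at the requested counts; the
    water phantom provides noise (SD in a centred ROI after HU calibration
    against its own mean) and the edge phantom provides resolution.
    Returns a DataFrame with columns ``n_iterations, noise_sd, mtf50``.
    """
    from .image_quality import compute_mtf_edge
    from .subtraction import RoiSpec, measure_roi

    if len(iter_grid) == 0:
        raise ValueError("iter_grid must be non-empty")
    counts = sorted(set(int(k) for k in iter_grid))
    if counts != [int(k) for k in iter_grid]:
        raise ValueError("iter_grid must be ascending and unique")
    base = params or SirtParams()
    run_params = SirtParams(n_iterations=counts[-1], relaxation=base.relaxation,
                            nonnegativity=base.nonnegativity)
    nz, ny, nx, h = _check_grid(water_sino, grid)
    A = system_matrix(water_sino.geometry, ny, nx, h)

    water_sols = _sirt_run(A, water_sino.line_integrals.reshape(nz, -1).T,
                           run_params, snapshots=counts)
    edge_sols = _sirt_run(A, edge_sino.line_integrals.reshape(nz, -1).T,
                          run_params, snapshots=counts)

    roi = RoiSpec(center=(0.0, 0.0, 0.0), radius=roi_radius_mm, shape="sphere")
    edge_roi = RoiSpec(center=(0.0, 0.0, 0.0), radius=5.0, shape="disk",
                       z_extent=grid.extent[0])
    rows = []
    for k in counts:
        wat = ImageVolume(water_sols[k].T.reshape(grid.shape), grid,
                          "attenuation")
        mu_w = measure_roi(wat, roi)[0]
        wat_hu = to_hounsfield(wat, mu_w)
        noise_sd = measure_roi(wat_hu, roi)[1]
        edge = ImageVolume(edge_sols[k].T.reshape(grid.shape), grid,
                           "attenuation")
        edge_hu = to_hounsfield(edge, mu_w)
        mtf = compute_mtf_edge(edge_hu, edge_roi)
        rows.append({"n_iterations": k, "noise_sd": noise_sd,
                     "mtf50": mtf.mtf50})
    return pd.DataFrame(rows)
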