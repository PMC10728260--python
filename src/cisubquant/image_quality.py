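"""Image-quality metrology: NPS, edge-method MTF, and CNR.

Noise power spectrum (NPS)
    Estimated from uniform (water-phantom) images following the usual CT
    practice: square ROIs are taken from the uniform region, each ROI is
    detrended with a fitted second-order 2D polynomial (removes DC and
    residual shading), Fourier transformed, and the squared modulus scaled
    by ``dx*dy/(Nx*Ny)`` so that the integral of the 2D NPS over frequency
    equals the noise variance (Parseval).  The 1D curve is the radial
    average of the 2D NPS in annular bins one frequency sample wide.

MTF (edge method)
    The straight flat face of the acrylic semi-cylinder provides a
    high-contrast edge.  Pixels in an ROI straddling the edge are projected
    onto the edge normal (the edge line is fitted from per-row 50%
    crossings), binned into an oversampled edge-spread function,
    differentiated into a line-spread function, Hann-windowed, and Fourier
    transformed; the modulus normalised to 1 at f = 0 is the MTF.

CNR
    Contrast of each iodinated phantom relative to the 0 mg I/ml phantom in
    the subtracted images, divided by the noise of the 0-level subtracted
    image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantoms import ImageVolume
from .subtraction import RoiSpec, measure_roi

__all__ = ["NpsResult", "MtfResult", "CnrRecord", "compute_nps",
           "compute_mtf_edge", "compute_cnr", "compute_cnr_muscle"]


@dataclass
class NpsResult:
    """2D NPS over (fy, fx) in mm^-1 (units HU^2 mm^2), its radial 1D
    profile, and the estimation bookkeeping."""

    nps2d: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    nps1d_freq: np.ndarray
    nps1d: np.ndarray
    roi_size: int
    n_rois: int
    detrend: str = "poly2"

    @property
    def mean_nps(self) -> float:
        """Mean of the radial NPS curve (summary statistic)."""
        return float(np.mean(self.nps1d))


@dataclass
class MtfResult:
    """MTF curve (f in lp/mm, modulation), with the 50% and 10% frequencies."""

    freq: np.ndarray
    modulation: np.ndarray
    mtf50: float
    mtf10: float


@dataclass(frozen=True)
class CnrRecord:
    nominal_ci: float
    contrast: float
    noise: float
    cnr: float


# ---------------------------------------------------------------------------
# NPS
# ---------------------------------------------------------------------------

def _poly2_detrend(roi: np.ndarray) -> np.ndarray:
    ny, nx = roi.shape
    y, x = np.mgrid[0:ny, 0:nx].astype(np.float64)
    y = y / (ny - 1) - 0.5
    x = x / (nx - 1) - 0.5
    Adm = np.stack([np.ones_like(x), x, y, x * x, x * y, y * y],
                   axis=-1).reshape(-1, 6)
    coef, *_ = np.linalg.lstsq(Adm, roi.ravel(), rcond=None)
    return roi - (Adm @ coef).reshape(ny, nx)


def _roi_positions(vol: ImageVolume, roi_size: int,
                   uniform_radius_mm: float) -> list[tuple[int, int, int]]:
    """Top-left corners of square ROIs fully inside the central uniform disk,
    on a half-overlapping stride grid, for every slice."""
    nz, ny, nx = vol.grid.shape
    dy, dx = vol.grid.spacing[1], vol.grid.spacing[2]
    yc = vol.grid.axis_coords(1)
    xc = vol.grid.axis_coords(2)
    stride = max(1, roi_size // 2)
    pos = []
    for iy in range(0, ny - roi_size + 1, stride):
        for ix in range(0, nx - roi_size + 1, stride):
            # ROI corner world coords; require all four corners inside disk
            ys = (yc[iy], yc[iy + roi_size - 1])
            xs = (xc[ix], xc[ix + roi_size - 1])
            if all(np.hypot(yv, xv) <= uniform_radius_mm
                   for yv in ys for xv in xs):
                pos.append((iy, ix))
    return [(iz, iy, ix) for iz in range(nz) for (iy, ix) in pos]


def compute_nps(noise_volumes: list[ImageVolume], roi_size: int = 32,
                n_rois: int | None = None,
                uniform_radius_mm: float = 7.5,
                detrend: str = "poly2") -> NpsResult:
    """Ensemble NPS estimate from one or more uniform noise volumes.

    ``n_rois`` caps the total number of ROIs used (default: all available);
    at least 2 are required.
    """
    if not noise_volumes:
        raise ValueError("at least one noise volume required")
    grid = noise_volumes[0].grid
    dy, dx = grid.spacing[1], grid.spacing[2]
    all_rois = []
    for vol in noise_volumes:
        for (iz, iy, ix) in _roi_positions(vol, roi_size, uniform_radius_mm):
            all_rois.append(vol.values[iz, iy:iy + roi_size, ix:ix + roi_size])
    if n_rois is not None:
        all_rois = all_rois[:n_rois]
    if len(all_rois) < 2:
        raise ValueError("fewer than 2 ROIs fit the uniform region")

    acc = np.zeros((roi_size, roi_size))
    for roi in all_rois:
        if detrend == "poly2":
            roi = _poly2_detrend(roi)
        elif detrend == "mean":
            roi = roi - roi.mean()
        else:
            raise ValueError("detrend must be 'poly2' or 'mean'")
        F = np.fft.fft2(roi)
        acc += (np.abs(F) ** 2) * (dx * dy) / (roi_size * roi_size)
    nps2d = np.fft.fftshift(acc / len(all_rois))
    fx = np.fft.fftshift(np.fft.fftfreq(roi_size, d=dx))
    fy = np.fft.fftshift(np.fft.fftfreq(roi_size, d=dy))

    # radial binning, width = one frequency sample
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    fr = np.hypot(FY, FX)
    df = min(1.0 / (roi_size * dx), 1.0 / (roi_size * dy))
    k = np.floor(fr / df).astype(int)
    nbins = k.max() + 1
    sums = np.bincount(k.ravel(), weights=nps2d.ravel(), minlength=nbins)
    counts = np.bincount(k.ravel(), minlength=nbins)
    prof = sums / np.maximum(counts, 1)
    freqs = (np.arange(nbins) + 0.5) * df
    # keep radii up to the axis Nyquist
    keep = freqs <= min(abs(fx).max(), abs(fy).max())
    return NpsResult(nps2d=nps2d, fx=fx, fy=fy, nps1d_freq=freqs[keep],
                     nps1d=prof[keep], roi_size=roi_size,
                     n_rois=len(all_rois), detrend=detrend)


# ---------------------------------------------------------------------------
# MTF (edge method)
# ---------------------------------------------------------------------------

def compute_mtf_edge(edge_vol: ImageVolume, edge_roi: RoiSpec,
                     oversample: int = 4) -> MtfResult:
    """Edge-method MTF in the transverse plane.

    Pools pixels of every slice whose in-plane position lies inside
    ``edge_roi``; the edge must run roughly along y within the ROI (as for
    the standard semi-cylinder phantom with a near-vertical flat face).
    """
    grid = edge_vol.grid
    dy, dx = grid.spacing[1], grid.spacing[2]
    yc = grid.axis_coords(1)
    xc = grid.axis_coords(2)
    cy, cx_ = edge_roi.center[1], edge_roi.center[2]
    iy = np.where(np.abs(yc - cy) <= edge_roi.radius)[0]
    ix = np.where(np.abs(xc - cx_) <= edge_roi.radius)[0]
    if len(iy) < 8 or len(ix) < 8:
        raise ValueError("edge ROI too small")
    sub = edge_vol.values[:, iy[0]:iy[-1] + 1, ix[0]:ix[-1] + 1]
    ys = yc[iy]
    xs = xc[ix]

    prof = sub.mean(axis=0)  # z-average (edge is z-invariant)
    lo = np.percentile(prof, 5)
    hi = np.percentile(prof, 95)
    if hi - lo < 1e-9 or (hi - lo) < 0.05 * max(abs(hi), abs(lo), 1.0):
        raise ValueError("no detectable edge in ROI (contrast too low)")
    mid = 0.5 * (hi + lo)

    # per-row subpixel 50% crossing
    crossings = []
    for r in range(prof.shape[0]):
        row = prof[r]
        sgn = row - mid
        idx = np.where(np.diff(np.signbit(sgn)))[0]
        if len(idx) == 0:
            continue
        i = idx[0]
        frac = sgn[i] / (sgn[i] - sgn[i + 1])
        crossings.append((ys[r], xs[i] + frac * (xs[i + 1] - xs[i])))
    if len(crossings) < 4:
        raise ValueError("no detectable edge in ROI")
    ey = np.array([c[0] for c in crossings])
    ex = np.array([c[1] for c in crossings])
    slope, inter = np.polyfit(ey, ex, 1)  # x_edge(y)
    cos_t = 1.0 / np.sqrt(1.0 + slope ** 2)

    # signed distance of every pixel (all slices) to the edge line
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    dist = (X - (slope * Y + inter)) * cos_t
    dist3 = np.broadcast_to(dist[None], sub.shape).ravel()
    vals = sub.ravel()

    pitch = dx / oversample
    kbin = np.round(dist3 / pitch).astype(int)
    k0 = kbin.min()
    sums = np.bincount(kbin - k0, weights=vals)
    counts = np.bincount(kbin - k0)
    esf = np.full(len(sums), np.nan)
    nz_mask = counts > 0
    esf[nz_mask] = sums[nz_mask] / counts[nz_mask]
    # interpolate empty bins
    if (~nz_mask).any():
        idxs = np.arange(len(esf))
        esf[~nz_mask] = np.interp(idxs[~nz_mask], idxs[nz_mask], esf[nz_mask])

    lsf = np.gradient(esf, pitch)
    peak = int(np.argmax(np.abs(lsf)))
    # centre a Hann window on the LSF peak to suppress tail noise
    n = len(lsf)
    half = min(peak, n - 1 - peak)
    w = np.zeros(n)
    win = np.hanning(2 * half + 1)
    w[peak - half:peak + half + 1] = win
    lsf_w = lsf * w

    spec = np.abs(np.fft.rfft(lsf_w))
    if spec[0] == 0:
        raise ValueError("degenerate LSF (zero area)")
    mtf = spec / spec[0]
    freq = np.fft.rfftfreq(n, d=pitch)

    def crossing(level: float) -> float:
        below = np.where(mtf < level)[0]
        if len(below) == 0:
            return float(freq[-1])
        i = below[0]
        if i == 0:
            return 0.0
        f = (mtf[i - 1] - level) / (mtf[i - 1] - mtf[i])
        return float(freq[i - 1] + f * (freq[i] - freq[i - 1]))

    return MtfResult(freq=freq, modulation=mtf,
                     mtf50=crossing(0.5), mtf10=crossing(0.1))


# ---------------------------------------------------------------------------
# CNR
# ---------------------------------------------------------------------------

def compute_cnr(sub_images: dict[float, ImageVolume], insert_roi: RoiSpec,
                background_roi: RoiSpec | None = None,
                noise_mode: str = "voxel_sd",
                replicate_means: list[float] | None = None) -> list[CnrRecord]:
    """CNR of each iodinated level in the subtracted images.

    ``contrast(level) = mean(level ROI) − mean(0-level ROI)``;
    ``noise`` defaults to the voxel SD within the ROI of the 0 mg I/ml
    subtracted image (``noise_mode='voxel_sd'``), with the alternative
    reading — SD of ROI means across replicates — available via
    ``noise_mode='replicate_sd'`` and ``replicate_means``.
    """
    if 0.0 not in sub_images:
        raise ValueError("the 0 mg I/ml subtracted image is required")
    noise_roi = background_roi or insert_roi
    zero = sub_images[0.0]
    mean0, sd0, _ = measure_roi(zero, insert_roi)
    if noise_mode == "voxel_sd":
        noise = measure_roi(zero, noise_roi)[1]
    elif noise_mode == "replicate_sd":
        if replicate_means is None or len(replicate_means) < 2:
            raise ValueError("replicate_sd mode needs >= 2 replicate means")
        noise = float(np.std(replicate_means, ddof=1))
    else:
        raise ValueError("noise_mode must be 'voxel_sd' or 'replicate_sd'")
    if noise <= 0:
        raise ValueError("zero noise in the 0-level subtracted image")
    records = []
    for level in sorted(sub_images):
        mean_l, _, _ = measure_roi(sub_images[level], insert_roi)
        contrast = mean_l - mean0
        records.append(CnrRecord(nominal_ci=float(level), contrast=contrast,
                                 noise=noise, cnr=contrast / noise))
    return records


def compute_cnr_muscle(ci_map: ImageVolume,
                       tissue_rois: dict[str, RoiSpec],
                       muscle_roi: RoiSpec) -> dict[str, CnrRecord]:
    """In-vivo-style CNR relative to muscle on a C_I map: per tissue,
    (mean C_I tissue − mean C_I muscle) / SD(muscle)."""
    mu_m, sd_m, _ = measure_roi(ci_map, muscle_roi)
    if sd_m <= 0:
        raise ValueError("zero muscle SD")
    out = {}
    for label, roi in tissue_rois.items():
        mu_t, _, _ = measure_roi(ci_map, roi)
        out[label] = CnrRecord(nominal_ci=float("nan"),
                               contrast=mu_t - mu_m, noise=sd_m,
                               cnr=(mu_t - mu_m) / sd_m)
    return out
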