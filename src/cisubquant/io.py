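"""File I/O: volumes (NIfTI / multi-page TIFF), sinograms (npz with
embedded geometry), transforms (plain-text 4x4), ROI sets (YAML)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .phantoms import GridSpec, ImageVolume
from .projection import ScanGeometry, Sinogram
from .subtraction import AffineTransform, RoiSpec

__all__ = ["save_volume", "load_volume", "save_sinogram", "load_sinogram",
           "save_transform", "load_transform", "save_rois", "load_rois"]


def save_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz, spacing in the header and the
    semantics tag in the description) or multi-page TIFF (.tif/.tiff)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, vol.values.astype(np.float32),
                         photometric="minisblack",
                         metadata={"spacing": list(vol.grid.spacing),
                                   "semantics": vol.semantics,
                                   "provenance": vol.provenance})
        return
    # NIfTI stores (x, y, z); our arrays are (z, y, x)
    data = np.transpose(vol.values, (2, 1, 0))
    affine = np.diag([vol.grid.spacing[2], vol.grid.spacing[1],
                      vol.grid.spacing[0], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = f"{vol.semantics}|{vol.provenance}"[:79].encode()
    img.header.set_zooms((vol.grid.spacing[2], vol.grid.spacing[1],
                          vol.grid.spacing[0]))
    nib.save(img, str(path))


def load_volume(path) -> ImageVolume:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            vals = tf.asarray().astype(np.float64)
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        spacing = tuple(meta.get("spacing", (1.0, 1.0, 1.0)))
        return ImageVolume(vals, GridSpec(vals.shape, spacing),
                           meta.get("semantics", "attenuation"),
                           meta.get("provenance", ""))
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(float)
    zx, zy, zz = img.header.get_zooms()[:3]
    desc = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="ignore")
    semantics, _, provenance = desc.partition("|")
    return ImageVolume(data, GridSpec(data.shape, (zz, zy, zx)),
                       semantics or "attenuation", provenance)


def save_sinogram(sino: Sinogram, path) -> None:
    """Compressed array container with geometry metadata embedded as JSON."""
    g = sino.geometry
    meta = {"n_angles": g.n_angles, "detector_bins": g.detector_bins,
            "detector_spacing": g.detector_spacing, "I0": g.I0,
            "noise_applied": sino.noise_applied, "seed": sino.seed}
    np.savez_compressed(path, line_integrals=sino.line_integrals,
                        meta=json.dumps(meta))


def load_sinogram(path) -> Sinogram:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return Sinogram(
            line_integrals=z["line_integrals"],
            geometry=ScanGeometry(meta["n_angles"], meta["detector_bins"],
                                  meta["detector_spacing"], meta["I0"]),
            noise_applied=meta["noise_applied"], seed=meta["seed"])


def save_transform(t: AffineTransform, path) -> None:
    np.savetxt(path, t.as_matrix(), fmt="%.12g")


def load_transform(path) -> AffineTransform:
    return AffineTransform.from_matrix(np.loadtxt(path))


def save_rois(rois: dict[str, RoiSpec], path) -> None:
    d = {name: {"center": list(r.center), "radius": r.radius,
                "shape": r.shape, "z_extent": r.z_extent}
         for name, r in rois.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_rois(path) -> dict[str, RoiSpec]:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return {name: RoiSpec(center=tuple(v["center"]), radius=v["radius"],
                          shape=v.get("shape", "sphere"),
                          z_extent=v.get("z_extent"))
            for name, v in d.items()}
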