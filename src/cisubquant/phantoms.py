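"""Digital phantoms for subtracted contrast-enhanced micro-CT simulation.

Defines the geometric phantom specifications (uniform water cylinder for
noise metrology, acrylic semi-cylinder for edge-method MTF, a set of
calibrated iodinated cylinders, and an in-vivo-like multi-insert body) and
voxelizes them into ground-truth linear-attenuation volumes on a regular
grid.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``; world coordinates are millimetres with
  the volume centre at the origin.
* The forward model is monoenergetic: each material is a single linear
  attenuation coefficient (mm^-1) at the effective energy, and iodine adds
  ``k_iodine`` mm^-1 per mg I/ml on top of the host material.  Spectral
  effects are absorbed by the downstream iodine calibration, which is
  fitted rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "MaterialModel",
    "GridSpec",
    "ImageVolume",
    "Insert",
    "Body",
    "PhantomSpec",
    "make_standard_phantom",
    "voxelize",
]

#: Recognised value semantics for :class:`ImageVolume`.
SEMANTICS = ("attenuation", "HU", "dHU", "CI")


@dataclass(frozen=True)
class MaterialModel:
    """Monoenergetic attenuation coefficients (mm^-1) at the effective energy.

    Defaults approximate ~30 keV effective energy of a 45 kVp micro-CT
    spectrum: water 0.0375 mm^-1, acrylic (PMMA, 1.18 g/cm3) slightly above
    water, and an iodine increment of 0.0022 mm^-1 per mg I/ml (mass
    attenuation ~22 cm2/g at this energy).
    """

    mu_water: float = 0.0375
    k_iodine: float = 0.0022
    mu_air: float = 0.0
    mu_acrylic: float = 0.044

    def __post_init__(self) -> None:
        if not (self.mu_water > self.mu_air >= 0.0):
            raise ValueError("require mu_water > mu_air >= 0")
        if self.k_iodine <= 0:
            raise ValueError("k_iodine must be positive")

    def mu_of(self, material: str) -> float:
        try:
            return {"water": self.mu_water, "air": self.mu_air,
                    "acrylic": self.mu_acrylic}[material]
        except KeyError:
            raise ValueError(f"unknown material {material!r}") from None


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid, centre of the volume at world (0,0,0).

    ``shape`` and ``spacing`` are ``(z, y, x)``; spacing in mm/voxel.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("shape and spacing must be length-3 (z, y, x)")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError("shape entries must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        h = self.spacing[axis]
        return (np.arange(n) - (n - 1) / 2.0) * h

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the grid (mm) per axis."""
        return tuple(n * h for n, h in zip(self.shape, self.spacing))


@dataclass
class ImageVolume:
    """A scalar field on a :class:`GridSpec` with explicit value semantics.

    ``semantics`` is one of ``attenuation`` (mm^-1), ``HU``, ``dHU``
    (subtracted HU) or ``CI`` (mg I/ml); ``provenance`` is a free-form
    scenario label carried through the pipeline.
    """

    values: np.ndarray
    grid: GridSpec
    semantics: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.semantics not in SEMANTICS:
            raise ValueError(f"semantics must be one of {SEMANTICS}")

    def with_values(self, values: np.ndarray, semantics: str | None = None,
                    provenance: str | None = None) -> "ImageVolume":
        return ImageVolume(
            values=values,
            grid=self.grid,
            semantics=self.semantics if semantics is None else semantics,
            provenance=self.provenance if provenance is None else provenance,
        )


@dataclass(frozen=True)
class Insert:
    """Cylindrical iodinated insert: in-plane centre (x, y) mm, radius mm,
    iodine concentration mg I/ml."""

    center: tuple[float, float]
    radius: float
    ci: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("insert radius must be positive")
        if self.ci < 0:
            raise ValueError("insert C_I must be >= 0")


@dataclass(frozen=True)
class Body:
    """Phantom body: a full cylinder or a semi-cylinder (axis along z).

    For a semi-cylinder only the half-plane
    ``(p - center) . n <= 0`` with ``n = (cos a, sin a)`` is kept, where
    ``a = edge_angle_deg``; the flat face passes through the centre.  A small
    non-zero tilt makes the face slightly slanted in-plane, which is what
    the edge-method MTF estimator needs for sub-pixel edge sampling.
    """

    kind: str  # "cylinder" | "semicylinder"
    center: tuple[float, float]
    radius: float
    height: float
    material: str
    edge_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "semicylinder"):
            raise ValueError("body kind must be 'cylinder' or 'semicylinder'")
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("body radius and height must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: body, iodinated inserts and background."""

    name: str
    body: Body
    inserts: tuple[Insert, ...] = ()
    background_material: str = "air"

    def __post_init__(self) -> None:
        object.__setattr__(self, "inserts", tuple(self.inserts))
        cx, cy = self.body.center
        for ins in self.inserts:
            d = np.hypot(ins.center[0] - cx, ins.center[1] - cy)
            if d + ins.radius > self.body.radius:
                raise ValueError(
                    f"insert at {ins.center} (r={ins.radius}) not fully inside body")

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "body": {
                "kind": self.body.kind,
                "center": list(self.body.center),
                "radius": self.body.radius,
                "height": self.body.height,
                "material": self.body.material,
                "edge_angle_deg": self.body.edge_angle_deg,
            },
            "inserts": [
                {"center": list(i.center), "radius": i.radius, "ci": i.ci}
                for i in self.inserts
            ],
            "background_material": self.background_material,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            name=d["name"],
            body=Body(
                kind=d["body"]["kind"],
                center=tuple(d["body"]["center"]),
                radius=d["body"]["radius"],
                height=d["body"]["height"],
                material=d["body"]["material"],
                edge_angle_deg=d["body"].get("edge_angle_deg", 0.0),
            ),
            inserts=tuple(
                Insert(center=tuple(i["center"]), radius=i["radius"], ci=i["ci"])
                for i in d.get("inserts", [])
            ),
            background_material=d.get("background_material", "air"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Standard phantoms
# ---------------------------------------------------------------------------

_DEFAULT_BODY_RADIUS = 12.0   # mm; desk-scale surrogate, not a claim about hardware
_DEFAULT_INSERT_RADIUS = 4.0  # mm
_DEFAULT_HEIGHT = 100.0       # mm; tall enough to cover every simulated slice
_EDGE_TILT_DEG = 3.0          # slight slant for the edge-method MTF


def make_standard_phantom(kind: str,
                          ci_levels: Sequence[float] | None = None,
                          body_radius: float = _DEFAULT_BODY_RADIUS,
                          insert_radius: float = _DEFAULT_INSERT_RADIUS,
                          height: float = _DEFAULT_HEIGHT) -> list[PhantomSpec]:
    """Build the standard study phantoms.

    Parameters
    ----------
    kind
        ``"water"`` — uniform water cylinder (noise/NPS phantom);
        ``"edge"`` — acrylic semi-cylinder in air (MTF phantom);
        ``"iodine_set"`` — one phantom per entry of ``ci_levels``, a
        water-equivalent cylinder with a single centred iodinated insert,
        geometrically identical across levels;
        ``"invivo_like"`` — a body with tumour/vessel/muscle surrogate
        inserts of distinct C_I.
    ci_levels
        Iodine concentrations (mg I/ml); required for ``iodine_set`` only.

    Returns
    -------
    list of PhantomSpec
    """
    if kind == "water":
        return [PhantomSpec(
            name="water",
            body=Body("cylinder", (0.0, 0.0), body_radius, height, "water"),
        )]
    if kind == "edge":
        return [PhantomSpec(
            name="edge",
            body=Body("semicylinder", (0.0, 0.0), body_radius, height,
                      "acrylic", edge_angle_deg=_EDGE_TILT_DEG),
        )]
    if kind == "iodine_set":
        if ci_levels is None or len(ci_levels) == 0:
            raise ValueError("iodine_set requires a non-empty ci_levels list")
        if any(c < 0 for c in ci_levels):
            raise ValueError("ci_levels must be non-negative")
        phantoms = []
        for c in ci_levels:
            phantoms.append(PhantomSpec(
                name=f"iodine_{c:g}",
                body=Body("cylinder", (0.0, 0.0), body_radius, height, "water"),
                inserts=(Insert((0.0, 0.0), insert_radius, float(c)),),
            ))
        return phantoms
    if kind == "invivo_like":
        r = body_radius
        return [PhantomSpec(
            name="invivo_like",
            body=Body("cylinder", (0.0, 0.0), r, height, "water"),
            inserts=(
                Insert((0.42 * r, 0.0), 0.17 * r, 2.0),    # tumour surrogate
                Insert((-0.42 * r, 0.25 * r), 0.08 * r, 3.0),  # vessel surrogate
                Insert((0.0, -0.5 * r), 0.25 * r, 0.3),    # muscle surrogate
            ),
        )]
    raise ValueError(f"unknown phantom kind {kind!r}")


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def _coverage_2d(grid: GridSpec, inside_fn, supersample: int) -> np.ndarray:
    """Fractional in-plane coverage of a region on one slice.

    Each voxel is supersampled ``supersample`` times per axis and the inside
    mask averaged, giving a smooth partial-volume edge (required for a clean
    edge-spread function downstream).
    """
    _, ny, nx = grid.shape
    _, dy, dx = grid.spacing
    s = supersample
    # supersample offsets centred within each voxel
    off = (np.arange(s) + 0.5) / s - 0.5
    ys = (grid.axis_coords(1)[:, None] + off[None, :] * dy).ravel()
    xs = (grid.axis_coords(2)[:, None] + off[None, :] * dx).ravel()
    X, Y = np.meshgrid(xs, ys)
    mask = inside_fn(X, Y).astype(np.float64)
    return mask.reshape(ny, s, nx, s).mean(axis=(1, 3))


def voxelize(spec: PhantomSpec, grid: GridSpec, materials: MaterialModel,
             supersample: int = 4) -> ImageVolume:
    """Rasterize a phantom into a ground-truth attenuation volume (mm^-1).

    Voxels take the attenuation of their material; insert voxels take
    ``mu(body material) + k_iodine * C_I``.  Boundary voxels are area-
    weighted via supersampling.  The operation is deterministic (no RNG).
    """
    if spec.body.radius * 2 > min(grid.extent[1], grid.extent[2]):
        raise ValueError("phantom body exceeds grid in-plane extent")

    cx, cy = spec.body.center
    r = spec.body.radius
    if spec.body.kind == "cylinder":
        def body_in(X, Y):
            return (X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2
    else:  # semicylinder: keep half-plane n.(p-c) <= 0
        a = np.deg2rad(spec.body.edge_angle_deg)
        nxv, nyv = np.cos(a), np.sin(a)

        def body_in(X, Y):
            circ = (X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2
            half = (X - cx) * nxv + (Y - cy) * nyv <= 0.0
            return circ & half

    mu_bg = materials.mu_of(spec.background_material)
    mu_body = materials.mu_of(spec.body.material)

    cov_body = _coverage_2d(grid, body_in, supersample)
    plane = mu_bg + cov_body * (mu_body - mu_bg)

    for ins in spec.inserts:
        icx, icy = ins.center
        ir = ins.radius

        def ins_in(X, Y, icx=icx, icy=icy, ir=ir):
            return (X - icx) ** 2 + (Y - icy) ** 2 <= ir ** 2

        cov = _coverage_2d(grid, ins_in, supersample)
        plane = plane + cov * (materials.k_iodine * ins.ci)

    # z extent: slices whose centre lies within the body height
    z = grid.axis_coords(0)
    inz = np.abs(z) <= spec.body.height / 2.0
    vol = np.where(inz[:, None, None], plane[None, :, :], mu_bg)
    if not inz.any():
        raise ValueError("phantom height does not cover any slice")
    return ImageVolume(values=vol, grid=grid, semantics="attenuation",
                       provenance=spec.name)
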