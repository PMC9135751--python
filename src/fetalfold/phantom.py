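"""Synthetic labeled brain phantoms with known analytic geometry.

The phantom stands in for the labeled volumes a fetal-MRI segmentation
pipeline would produce: a folded "cerebral" white-matter core wrapped in a
cortical gray-matter shell, with ellipsoidal accessory structures (deep gray
matter and ventricles carved out of the core; cerebellum, brainstem and
hippocampi placed below it).  The white-matter boundary follows the radial
perturbation

    r(theta, phi) = R * (1 + a * sin(f * theta) * sin(f * phi))

with polar angle ``theta``, azimuth ``phi``, base radius ``R``
(``wm_radius``), folding amplitude ``a`` and integer angular wavenumber
``f``.  At ``a = 0`` every structure has a closed-form volume
(:func:`analytic_volumes`), which anchors the volumetry and surface oracles.

The cortical sheet is parcellated into eight angular sectors (the four lobes
plus cingulate, insula and corpus callosum regions) around the left-right
axis, mirrored in both hemispheres; deep gray matter and ventricles complete
the ten parcellation regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .volume import REGIONS, SEGMENTATION_LABELS, LabelVolume, region_label

TWO_PI = 2.0 * math.pi

#: the eight cortical regions assigned by angular sector (the remaining two
#: parcellation regions, dgm and ventricles, come from structure masks)
SECTOR_REGIONS: tuple[str, ...] = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "anterior_cingulate",
    "posterior_cingulate",
    "insula",
    "corpus_callosum",
)


def default_region_sectors() -> dict[str, tuple[float, float]]:
    """Default angular partition of the cortical sheet.

    Sectors are half-open intervals ``[lo, hi)`` of the azimuth around the
    left-right axis (angle of ``(y, z)`` relative to the cerebrum centre),
    covering ``[0, 2*pi)`` exactly.  The four lobes get wide sectors so that
    lobar features are supported by many vertices.
    """
    edges = [0.0, 0.50, 1.00, 1.40, 1.80, 1.85, 1.90, 1.95, 2.00]
    return {
        name: (edges[i] * math.pi, edges[i + 1] * math.pi)
        for i, name in enumerate(SECTOR_REGIONS)
    }


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid; ``center`` is relative to the cerebrum centre (mm)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.radii) != 3:
            raise ValidationError("ellipsoid center and radii must be 3-vectors")
        if any(r <= 0 for r in self.radii):
            raise ValidationError("ellipsoid radii must be positive")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.radii
        return 4.0 / 3.0 * math.pi * a * b * c

    def mask(self, xc: np.ndarray, yc: np.ndarray, zc: np.ndarray) -> np.ndarray:
        """Boolean mask of voxels inside the ellipsoid (coords rel. centre)."""
        cx, cy, cz = self.center
        a, b, c = self.radii
        return (
            ((xc - cx) / a) ** 2 + ((yc - cy) / b) ** 2 + ((zc - cz) / c) ** 2
        ) <= 1.0


#: structures carved out of the white-matter core
INTERIOR_STRUCTURES = ("dgm", "ventricles")
#: structures placed outside the cerebral shell
EXTERIOR_STRUCTURES = ("cerebellum", "brainstem", "hippocampus")


def default_accessory_structures(
    wm_radius: float, fold_amplitude: float, cgm_thickness: float
) -> dict[str, list[Ellipsoid]]:
    """Default accessory layout, scaled to the white-matter radius.

    Interior structures sit well inside the minimum folded radius
    ``R*(1-a)``; exterior structures hang below the cerebrum with a clearance
    from the outer cortical surface ``R*(1+a) + cgm_thickness``.
    """
    R = wm_radius
    outer = R * (1.0 + fold_amplitude) + cgm_thickness
    zc = outer + 0.45 * R + 2.0  # cerebellum depth below centre
    zb = math.sqrt(max((outer + 0.42 * R + 2.0) ** 2 - (0.5 * R) ** 2, 0.0))
    zh = math.sqrt(
        max((outer + 0.20 * R + 2.0) ** 2 - (0.6 * R) ** 2 - (0.1 * R) ** 2, 0.0)
    )
    return {
        "dgm": [Ellipsoid((0.0, 0.0, -0.15 * R), (0.32 * R, 0.26 * R, 0.22 * R))],
        "ventricles": [
            Ellipsoid((s * 0.30 * R, 0.0, 0.30 * R), (0.08 * R, 0.18 * R, 0.12 * R))
            for s in (-1, 1)
        ],
        "cerebellum": [
            Ellipsoid((0.0, -0.5 * R, -zc), (0.55 * R, 0.45 * R, 0.36 * R))
        ],
        "brainstem": [Ellipsoid((0.0, 0.5 * R, -zb), (0.18 * R, 0.18 * R, 0.42 * R))],
        "hippocampus": [
            Ellipsoid((s * 0.6 * R, 0.1 * R, -zh), (0.12 * R, 0.20 * R, 0.12 * R))
            for s in (-1, 1)
        ],
    }


@dataclass
class PhantomSpec:
    """Full parametric description of one labeled phantom.

    Use :meth:`create` to build a spec with an automatically sized grid and
    the default accessory layout.
    """

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    center_mm: tuple[float, float, float]
    wm_radius: float
    fold_amplitude: float = 0.0
    fold_frequency: int = 8
    cgm_thickness: float = 3.0
    region_sectors: dict[str, tuple[float, float]] = field(
        default_factory=default_region_sectors
    )
    accessory_structures: dict[str, list[Ellipsoid]] = field(default_factory=dict)

    # -- construction ---------------------------------------------------------
    @classmethod
    def create(
        cls,
        wm_radius: float = 30.0,
        fold_amplitude: float = 0.0,
        fold_frequency: int = 8,
        cgm_thickness: float = 3.0,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        with_accessories: bool = True,
        margin_mm: float = 4.0,
    ) -> "PhantomSpec":
        """Build a spec whose grid tightly fits the cerebrum and accessories."""
        acc = (
            default_accessory_structures(wm_radius, fold_amplitude, cgm_thickness)
            if with_accessories
            else {}
        )
        outer = wm_radius * (1.0 + fold_amplitude) + cgm_thickness
        lo = np.full(3, -outer)
        hi = np.full(3, outer)
        for ells in acc.values():
            for e in ells:
                c, r = np.asarray(e.center), np.asarray(e.radii)
                lo = np.minimum(lo, c - r)
                hi = np.maximum(hi, c + r)
        lo -= margin_mm
        hi += margin_mm
        sp = np.asarray(spacing, dtype=float)
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / sp[i])) + 1 for i in range(3))
        center = tuple(float(-lo[i]) for i in range(3))
        spec = cls(
            grid_shape=shape,
            spacing=tuple(float(s) for s in sp),
            center_mm=center,
            wm_radius=float(wm_radius),
            fold_amplitude=float(fold_amplitude),
            fold_frequency=int(fold_frequency),
            cgm_thickness=float(cgm_thickness),
            accessory_structures=acc,
        )
        spec.validate()
        return spec

    def with_(self, **changes) -> "PhantomSpec":
        """A copy with the given fields replaced (re-validated)."""
        spec = replace(self, **changes)
        spec.validate()
        return spec

    # -- validation -----------------------------------------------------------
    def validate(self) -> None:
        if self.wm_radius <= 0 or self.cgm_thickness <= 0:
            raise ValidationError("wm_radius and cgm_thickness must be positive")
        if self.fold_amplitude < 0:
            raise ValidationError("fold_amplitude must be >= 0")
        if self.fold_amplitude >= 1:
            raise ValidationError("fold_amplitude must be < 1")
        if self.fold_frequency < 1:
            raise ValidationError("fold_frequency must be a positive integer")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if any(n < 2 for n in self.grid_shape):
            raise ValidationError("grid_shape must be at least 2 voxels per axis")
        self._validate_sectors()
        self._validate_fit()

    def _validate_sectors(self) -> None:
        if set(self.region_sectors) != set(SECTOR_REGIONS):
            raise ValidationError(
                f"region_sectors must cover exactly {sorted(SECTOR_REGIONS)}"
            )
        ivals = sorted(self.region_sectors.values())
        if not math.isclose(ivals[0][0], 0.0, abs_tol=1e-12):
            raise ValidationError("sectors must start at azimuth 0")
        for (_lo1, hi1), (lo2, _hi2) in zip(ivals, ivals[1:]):
            if lo2 < hi1 - 1e-9:
                raise ValidationError("sectors must not overlap")
            if not math.isclose(hi1, lo2, abs_tol=1e-9):
                raise ValidationError("sectors must tile the azimuth without gaps")
        if not math.isclose(ivals[-1][1], TWO_PI, abs_tol=1e-9):
            raise ValidationError("sectors must end at azimuth 2*pi")

    def _validate_fit(self) -> None:
        outer = self.outer_radius
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        c = np.asarray(self.center_mm)
        if np.any(c - outer < -1e-9) or np.any(c + outer > extent + 1e-9):
            raise ValidationError(
                "cerebrum (wm_radius*(1+fold_amplitude)+cgm_thickness) "
                "does not fit inside the grid"
            )
        r_min = self.wm_radius * (1.0 - self.fold_amplitude)
        for name, ells in self.accessory_structures.items():
            if name in INTERIOR_STRUCTURES:
                for e in ells:
                    if np.linalg.norm(e.center) + max(e.radii) > r_min:
                        raise ValidationError(
                            f"interior structure {name!r} does not fit inside "
                            "the folded white-matter core"
                        )
            elif name in EXTERIOR_STRUCTURES:
                for e in ells:
                    if np.linalg.norm(e.center) - max(e.radii) < outer:
                        raise ValidationError(
                            f"exterior structure {name!r} intersects the "
                            "cortical shell"
                        )
                    ec = np.asarray(e.center)
                    er = np.asarray(e.radii)
                    if np.any(c + ec - er < -1e-9) or np.any(
                        c + ec + er > extent + 1e-9
                    ):
                        raise ValidationError(
                            f"exterior structure {name!r} does not fit in the grid"
                        )
            else:
                raise ValidationError(f"unknown accessory structure {name!r}")
        # exterior structures must not overlap each other (keeps volumes additive)
        ext = [
            (n, e)
            for n in EXTERIOR_STRUCTURES
            for e in self.accessory_structures.get(n, [])
        ]
        for i, (n1, e1) in enumerate(ext):
            for n2, e2 in ext[i + 1 :]:
                d = np.linalg.norm(np.asarray(e1.center) - np.asarray(e2.center))
                if d < max(e1.radii) + max(e2.radii) - 1e-9 and d > 0:
                    # conservative bound; exact overlap not checked
                    if d < max(e1.radii) + max(e2.radii):
                        raise ValidationError(
                            f"exterior structures {n1!r} and {n2!r} may overlap"
                        )

    @property
    def outer_radius(self) -> float:
        """Maximum radius of the outer cortical surface (mm)."""
        return self.wm_radius * (1.0 + self.fold_amplitude) + self.cgm_thickness


def analytic_volumes(spec: PhantomSpec) -> dict[str, float]:
    """Closed-form structure volumes (mm^3) at ``fold_amplitude = 0``.

    The white-matter volume is the core sphere minus the carved interior
    structures; the cortical shell volume is the spherical-shell closed form.
    Only valid for an unfolded spec.
    """
    if spec.fold_amplitude != 0:
        raise ValidationError("analytic volumes are defined at fold_amplitude = 0")
    R, t = spec.wm_radius, spec.cgm_thickness
    sphere = 4.0 / 3.0 * math.pi * R**3
    out: dict[str, float] = {}
    carved = 0.0
    for name in INTERIOR_STRUCTURES:
        v = sum(e.volume_mm3 for e in spec.accessory_structures.get(name, []))
        if v:
            out[name] = v
        carved += v
    out["wm"] = sphere - carved
    out["cgm"] = 4.0 / 3.0 * math.pi * ((R + t) ** 3 - R**3)
    for name in EXTERIOR_STRUCTURES:
        v = sum(e.volume_mm3 for e in spec.accessory_structures.get(name, []))
        if v:
            out[name] = v
    return out


def make_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[LabelVolume, LabelVolume]:
    """Rasterize a phantom into a (segmentation, parcellation) pair.

    Construction is fully deterministic given ``spec``; ``seed`` is accepted
    for interface symmetry with the cohort simulator and reserved for future
    stochastic texture.  Voxel centres sit at ``index * spacing`` in world
    coordinates.
    """
    spec.validate()
    del seed  # deterministic construction

    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    cx, cy, cz = spec.center_mm
    xs = np.arange(nx) * sx - cx
    ys = np.arange(ny) * sy - cy
    zs = np.arange(nz) * sz - cz
    xc, yc, zc = np.meshgrid(xs, ys, zs, indexing="ij")

    r = np.sqrt(xc**2 + yc**2 + zc**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, zc / np.where(r > 0, r, 1.0), 1.0), -1, 1))
    phi = np.mod(np.arctan2(yc, xc), TWO_PI)
    a, f = spec.fold_amplitude, spec.fold_frequency
    r_wm = spec.wm_radius * (1.0 + a * np.sin(f * theta) * np.sin(f * phi))

    seg = np.zeros(spec.grid_shape, dtype=np.int16)
    wm_mask = r <= r_wm
    cgm_mask = (r > r_wm) & (r <= r_wm + spec.cgm_thickness)
    seg[wm_mask] = SEGMENTATION_LABELS["wm"]
    seg[cgm_mask] = SEGMENTATION_LABELS["cgm"]

    struct_masks: dict[str, np.ndarray] = {}
    for name, ells in spec.accessory_structures.items():
        m = np.zeros(spec.grid_shape, dtype=bool)
        for e in ells:
            m |= e.mask(xc, yc, zc)
        if name in INTERIOR_STRUCTURES:
            m &= wm_mask  # carve out of the core only
        struct_masks[name] = m
        seg[m] = SEGMENTATION_LABELS[name]

    # -- parcellation ---------------------------------------------------------
    parc = np.zeros(spec.grid_shape, dtype=np.int16)
    psi = np.mod(np.arctan2(zc, yc), TWO_PI)  # azimuth around the left-right axis
    cortex = wm_mask | cgm_mask
    for name in INTERIOR_STRUCTURES:
        if name in struct_masks:
            cortex &= ~struct_masks[name]
    left = xc <= 0.0  # mid-sagittal plane assigned left by convention
    for region, (lo, hi) in spec.region_sectors.items():
        in_sector = cortex & (psi >= lo) & (psi < hi)
        parc[in_sector & left] = region_label(region, "left")
        parc[in_sector & ~left] = region_label(region, "right")
    for name in INTERIOR_STRUCTURES:
        m = struct_masks.get(name)
        if m is not None:
            parc[m & left] = region_label(name, "left")
            parc[m & ~left] = region_label(name, "right")

    return (
        LabelVolume(seg, spec.spacing),
        LabelVolume(parc, spec.spacing),
    )
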