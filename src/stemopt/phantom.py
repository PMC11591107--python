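"""Synthetic proximal-femur phantom and single-wedge stem geometry.

The phantom emulates a coronal-plane proximal femur on a regular pixel grid:
a closed cortical shell (label 1) encloses a density-graded cancellous
interior (label 2); the diaphyseal medullary canal is carried as cancellous
pixels at marrow density 0.01; a spherical femoral head sits on a neck at a
128 deg neck-shaft angle with a 44.6 mm horizontal offset from the shaft axis.
The default extent is 100.4 x 131.2 mm. Head resection and insertion of a
single-wedge titanium stem (label 3) mimic total hip replacement.

Coordinate convention: pixel (row, col) with row 0 at the proximal (top)
edge; physical x grows medially (toward the femoral head), physical y grows
downward; all placements are in mm and raster tests use pixel centers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely import affinity
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import unary_union

from .materials import (
    LABEL_BACKGROUND,
    LABEL_CANCELLOUS,
    LABEL_CORTICAL,
    LABEL_STEM,
    MARROW_DENSITY,
)

VALID_LABELS = frozenset((LABEL_BACKGROUND, LABEL_CORTICAL, LABEL_CANCELLOUS, LABEL_STEM))


class PhantomError(ValueError):
    """Raised for geometrically impossible phantom or insertion requests."""


@dataclass
class LabeledImage:
    """Labelled raster of a femur cross-section.

    ``labels`` holds region codes {0 background, 1 cortical, 2 cancellous,
    3 stem}; ``density`` the relative density on bone pixels (0 elsewhere);
    ``pixel_size`` the physical pitch in mm; ``origin`` the physical (x, y)
    of the grid's top-left corner. ``landmarks`` records the analytic
    geometry (head center, trochanter apex, resection plane, ...) that the
    loading module uses to locate surfaces.
    """

    labels: np.ndarray
    density: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.density = np.asarray(self.density, dtype=float)
        if self.labels.shape != self.density.shape:
            raise PhantomError("labels and density grids must share a shape")
        if self.pixel_size <= 0:
            raise PhantomError("pixel_size must be positive")
        if not set(np.unique(self.labels)) <= VALID_LABELS:
            raise PhantomError("labels must be drawn from {0, 1, 2, 3}")
        bone = (self.labels == LABEL_CORTICAL) | (self.labels == LABEL_CANCELLOUS)
        if np.any(self.density[bone] <= 0):
            raise PhantomError("density must be positive on every bone pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def pixel_centers(self):
        """Physical (x, y) coordinates of every pixel center, as 2D grids."""
        nr, nc = self.labels.shape
        x = self.origin[0] + (np.arange(nc) + 0.5) * self.pixel_size
        y = self.origin[1] + (np.arange(nr) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def copy(self) -> "LabeledImage":
        return LabeledImage(
            self.labels.copy(),
            self.density.copy(),
            self.pixel_size,
            self.origin,
            dict(self.landmarks),
        )


@dataclass(frozen=True)
class StemSpec:
    """Shape parameters of the single-wedge stem (all mm / degrees).

    The proximal section (shoulder plus neck and head) is fixed; only the
    distal wedge below ``shoulder_length`` stretches with the design length.
    ``width`` is metadata: the overall mediolateral span of the implant
    including the head offset, as quoted for the reference implant.
    """

    width: float = 57.8
    head_offset: float = 44.0
    neck_shaft_angle: float = 128.0
    head_radius: float = 12.0
    neck_radius: float = 6.5
    shoulder_half_width: float = 8.5
    shoulder_length: float = 30.0
    shoulder_taper_to: float = 6.0
    tip_half_width: float = 2.0
    neck_origin_drop: float = 46.0


@dataclass
class StemProfile:
    """A placed single-wedge stem polygon in physical coordinates."""

    length: float
    spec: StemSpec
    axis_x: float
    top_y: float
    polygon: Polygon
    head_center: tuple[float, float]

    @property
    def width(self) -> float:
        return self.spec.width

    @property
    def head_offset(self) -> float:
        return self.spec.head_offset

    @property
    def neck_shaft_angle(self) -> float:
        return self.spec.neck_shaft_angle

    @property
    def tip_y(self) -> float:
        return self.top_y + self.length

    @property
    def points(self) -> list[tuple[float, float]]:
        if self.polygon.is_empty:
            return []
        return list(self.polygon.exterior.coords)

    @property
    def wedge_start_y(self) -> float:
        return self.top_y + self.spec.shoulder_length


@dataclass(frozen=True)
class PhantomParams:
    """Analytic construction parameters of the default femur phantom.

    Lengths in mm. The defaults reproduce the reference geometry: overall
    extent 100.4 x 131.2, head offset 44.6, neck-shaft angle 128 deg, with
    the stem entry ("top of stem") placed so that the lesser-trochanter
    level and the model base sit 68.75 and 117.25 mm below it.
    """

    width_mm: float = 100.4
    height_mm: float = 131.2
    shaft_axis_x: float = 32.0
    shaft_half_width: float = 16.0
    shaft_top_y: float = 40.0
    head_offset: float = 44.6
    head_center_y: float = 25.0
    head_radius: float = 23.0
    neck_shaft_angle: float = 128.0
    neck_radius: float = 11.0
    gt_capsule: tuple = ((18.0, 22.0), (30.0, 36.0))
    gt_radius: float = 15.0
    meta_capsule: tuple = ((34.0, 32.0), (46.0, 48.0))
    meta_radius: float = 16.0
    outline_smooth_mm: float = 6.0
    shell_head_mm: float = 1.6
    shell_shaft_mm: float = 5.0
    shell_ramp_y: tuple[float, float] = (45.0, 95.0)
    canal_half_width: float = 6.0
    canal_start_y: float = 92.0
    canal_taper_end_y: float = 131.2
    canal_end_half_width: float = 6.0
    density_base: float = 0.75
    density_ref_y: float = 10.0
    density_slope_per_mm: float = 0.005
    density_clip: tuple[float, float] = (0.15, 0.95)
    # principal trabecular arcs: compressive (head -> calcar) and tensile
    # (head -> greater trochanter), as density ridges over the base field
    compressive_arc: tuple = ((76.6, 25.0), (52.0, 50.0), (44.0, 85.0))
    tensile_arc: tuple = ((70.0, 18.0), (40.0, 20.0), (22.0, 30.0), (20.0, 55.0))
    arc_sigma: float = 10.0
    arc_amplitude: float = 0.6
    tensile_rel_amplitude: float = 1.0
    marrow_density: float = MARROW_DENSITY
    noise_amplitude: float = 0.0
    noise_smooth_px: float = 2.0
    seed: int = 0
    stem_top_y: float = 13.95
    lesser_troch_y: float = 82.7
    resection_point: tuple[float, float] = (30.0, 17.0)

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "shaft_half_width", "head_radius",
                     "neck_radius", "shell_head_mm", "shell_shaft_mm"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be positive")

    @property
    def neck_direction(self) -> tuple[float, float]:
        """Unit vector along the neck axis, from shaft toward the head.

        Measured as the neck-shaft angle from the distal (downward) shaft
        axis, so 128 deg points medially and upward.
        """
        a = math.radians(self.neck_shaft_angle)
        return (math.sin(a), math.cos(a))

    @property
    def head_center(self) -> tuple[float, float]:
        return (self.shaft_axis_x + self.head_offset, self.head_center_y)

    @property
    def neck_origin(self) -> tuple[float, float]:
        dx, dy = self.neck_direction
        L = self.head_offset / dx
        hx, hy = self.head_center
        return (self.shaft_axis_x, hy - L * dy)


def _bone_outline(params: PhantomParams) -> Polygon:
    p = params
    shaft = box(p.shaft_axis_x - p.shaft_half_width, p.shaft_top_y,
                p.shaft_axis_x + p.shaft_half_width, p.height_mm)
    gt = LineString(p.gt_capsule).buffer(p.gt_radius, quad_segs=32)
    meta = LineString(p.meta_capsule).buffer(p.meta_radius, quad_segs=32)
    neck = LineString([p.neck_origin, p.head_center]).buffer(p.neck_radius, quad_segs=32)
    head = Point(p.head_center).buffer(p.head_radius, quad_segs=64)
    outline = unary_union([shaft, gt, meta, neck, head])
    # round the junctions between primitives (closing, then opening): tangent
    # discontinuities on the boundary act as artificial stress raisers
    r = p.outline_smooth_mm
    if r > 0:
        outline = outline.buffer(r, quad_segs=32).buffer(-r, quad_segs=32)
        outline = outline.buffer(-r / 2, quad_segs=32).buffer(r / 2, quad_segs=32)
    # clip to the raster extent (the base edge is a section cut)
    outline = outline.intersection(box(0.0, 0.0, p.width_mm, p.height_mm))
    if outline.geom_type != "Polygon":
        outline = max(outline.geoms, key=lambda g: g.area)
    return outline


def _shell_thickness(params: PhantomParams, y: np.ndarray) -> np.ndarray:
    """Cortical shell thickness (mm) as a function of depth y."""
    y0, y1 = params.shell_ramp_y
    return np.interp(y, [y0, y1], [params.shell_head_mm, params.shell_shaft_mm])


def generate_femur_phantom(params: PhantomParams = PhantomParams(),
                           pixel_size: float = 0.5) -> LabeledImage:
    """Rasterize the analytic femur outline into a labelled density image.

    The grid covers ``width_mm x height_mm`` at ``pixel_size`` pitch (sizes
    rounded up). The cortical shell is the band of bone pixels within the
    depth-dependent shell thickness of the outer boundary; the model base is
    treated as a cut plane, not a free surface, so the shell does not wrap
    around the bottom edge. Deterministic given ``params.seed``.
    """
    if pixel_size <= 0:
        raise PhantomError("pixel_size must be positive")
    if params.shell_head_mm < 2.0 * pixel_size:
        raise PhantomError(
            f"pixel_size {pixel_size} mm too coarse to resolve the cortical shell "
            f"({params.shell_head_mm} mm, needs >= 2 px)")
    nc = int(math.ceil(params.width_mm / pixel_size))
    nr = int(math.ceil(params.height_mm / pixel_size))
    outline = _bone_outline(params)
    xs = (np.arange(nc) + 0.5) * pixel_size
    ys = (np.arange(nr) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)
    bone = shapely.contains_xy(outline, X.ravel(), Y.ravel()).reshape(nr, nc)
    if not bone.any():
        raise PhantomError("phantom outline rasterized to an empty image")

    # distance to the outer surface; pad below the base so the bottom edge is
    # a section cut rather than a free surface
    last_bone_row = int(np.nonzero(bone.any(axis=1))[0].max())
    n_pad = int(math.ceil(2 * params.shell_shaft_mm / pixel_size))
    padded = np.vstack([bone[:last_bone_row + 1],
                        np.repeat(bone[last_bone_row:last_bone_row + 1, :], n_pad, axis=0)])
    dist = ndimage.distance_transform_edt(padded, sampling=pixel_size)[:nr, :]
    shell = bone & (dist <= _shell_thickness(params, Y))

    labels = np.zeros((nr, nc), dtype=np.uint8)
    labels[bone] = LABEL_CANCELLOUS
    labels[shell] = LABEL_CORTICAL

    # smooth longitudinal density gradient, densest proximally, with dense
    # ridges along the principal compressive and tensile trabecular arcs so
    # the intact interior carries load the way a real metaphysis does
    rho = params.density_base - params.density_slope_per_mm * (Y - params.density_ref_y)
    rho = np.clip(rho, *params.density_clip)
    pts = shapely.points(X.ravel(), Y.ravel())
    d_comp = shapely.distance(LineString(params.compressive_arc), pts).reshape(nr, nc)
    d_tens = shapely.distance(LineString(params.tensile_arc), pts).reshape(nr, nc)
    ridge = params.arc_amplitude * np.maximum(
        np.exp(-0.5 * (d_comp / params.arc_sigma) ** 2),
        params.tensile_rel_amplitude * np.exp(-0.5 * (d_tens / params.arc_sigma) ** 2))
    rho = np.clip(rho + ridge, *((params.density_clip[0], 0.98)))
    if params.noise_amplitude > 0:
        rng = np.random.default_rng(params.seed)
        noise = rng.standard_normal((nr, nc))
        noise = ndimage.gaussian_filter(noise, params.noise_smooth_px)
        noise /= max(noise.std(), 1e-12)
        rho = np.clip(rho + params.noise_amplitude * noise, 0.02, 0.98)
    # medullary canal: marrow-density cancellous pixels inside the diaphysis,
    # tapering toward the isthmus so long stems engage distal bone
    canal_hw = np.interp(Y, [params.canal_start_y, params.canal_taper_end_y],
                         [params.canal_half_width, params.canal_end_half_width])
    canal = (np.abs(X - params.shaft_axis_x) <= canal_hw) & \
        (Y >= params.canal_start_y) & (labels == LABEL_CANCELLOUS)
    rho[canal] = params.marrow_density

    density = np.where(labels > 0, rho, 0.0)

    d = params.neck_direction
    landmarks = {
        "head_center": params.head_center,
        "head_radius": params.head_radius,
        "gt_apex": (params.gt_capsule[0][0], params.gt_capsule[0][1] - params.gt_radius),
        "gt_patch_radius": 12.0,
        "shaft_axis_x": params.shaft_axis_x,
        "neck_origin": params.neck_origin,
        "neck_direction": d,
        "resection_point": params.resection_point,
        "stem_top_y": params.stem_top_y,
        "lesser_troch_y": params.lesser_troch_y,
        "resected": False,
        "seed": params.seed,
    }
    return LabeledImage(labels, density, pixel_size, (0.0, 0.0), landmarks)


def generate_stem_profile(length: float,
                          spec: StemSpec = StemSpec(),
                          axis_x: float = 32.0,
                          top_y: float = 13.95) -> StemProfile:
    """Build a placed single-wedge stem polygon of the given design length.

    ``length`` is measured from the top of the stem (the shoulder, at
    ``top_y``) straight down the shaft axis to the distal tip. The shoulder,
    neck strut and head are fixed; only the distal wedge stretches, so two
    profiles differing in length are identical above the wedge start.
    """
    if length <= 0:
        raise PhantomError("stem length must be positive")
    if length <= spec.shoulder_length:
        raise PhantomError(
            f"stem length {length} mm does not clear the fixed proximal "
            f"section ({spec.shoulder_length} mm)")
    a = math.radians(spec.neck_shaft_angle)
    d = (math.sin(a), math.cos(a))
    # stem neck axis mirrors the femoral neck: origin on the shaft axis,
    # head one neck-length along the neck direction (head_offset medial)
    L = spec.head_offset / d[0]
    neck_origin = (axis_x, top_y + spec.neck_origin_drop)
    head_center = (neck_origin[0] + L * d[0], neck_origin[1] + L * d[1])

    y_top = top_y
    y_sh = top_y + spec.shoulder_length
    y_tip = top_y + length
    wedge = Polygon([
        (axis_x - spec.shoulder_half_width, y_top),
        (axis_x + spec.shoulder_half_width, y_top),
        (axis_x + spec.shoulder_taper_to, y_sh),
        (axis_x + spec.tip_half_width, y_tip),
        (axis_x - spec.tip_half_width, y_tip),
        (axis_x - spec.shoulder_taper_to, y_sh),
    ])
    neck = LineString([ (axis_x, top_y + 6.0), head_center]).buffer(spec.neck_radius, quad_segs=32)
    head = Point(head_center).buffer(spec.head_radius, quad_segs=64)
    poly = unary_union([wedge, neck, head])
    # round junction notches between the wedge, neck strut and head
    poly = poly.buffer(2.0, quad_segs=16).buffer(-2.0, quad_segs=16)
    if poly.geom_type != "Polygon":
        raise PhantomError("stem components did not fuse into a single polygon")
    if not poly.is_simple:
        raise PhantomError("stem polygon is self-intersecting")
    return StemProfile(length, spec, axis_x, top_y, poly, head_center)


def resect_and_insert(image: LabeledImage, stem: StemProfile | None,
                      placement: tuple[float, float] = (0.0, 0.0)) -> LabeledImage:
    """Remove the femoral head and rasterize the stem into the image.

    Resection blanks every bone pixel on the head side of the resection
    plane (perpendicular to the neck axis through the neck-base landmark).
    Stem pixels overwrite background and cancellous bone only; touching a
    cortical pixel is a hard error naming the first offending pixel, since
    it signals an impossible fit. Idempotent on its own output.
    """
    out = image.copy()
    labels = out.labels
    X, Y = out.pixel_centers()

    cx, cy = image.landmarks["resection_point"]
    dx, dy = image.landmarks["neck_direction"]
    above = (X - cx) * dx + (Y - cy) * dy > 0.0
    bone = (labels == LABEL_CORTICAL) | (labels == LABEL_CANCELLOUS)
    removed = bone & above
    labels[removed] = LABEL_BACKGROUND
    out.density[removed] = 0.0

    if stem is not None and not stem.polygon.is_empty:
        poly = stem.polygon
        if placement != (0.0, 0.0):
            poly = affinity.translate(poly, xoff=placement[0], yoff=placement[1])
        inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(labels.shape)
        clash = inside & (labels == LABEL_CORTICAL)
        if clash.any():
            r, c = np.argwhere(clash)[0]
            raise PhantomError(
                f"stem (length {stem.length} mm) overlaps cortical bone at "
                f"pixel (row={r}, col={c})")
        labels[inside] = LABEL_STEM
        out.density[inside] = 0.0
        out.landmarks["stem_head_center"] = stem.head_center
        out.landmarks["stem_head_radius"] = stem.spec.head_radius
        out.landmarks["stem_length"] = stem.length
    out.landmarks["resected"] = True
    return out


# ---------------------------------------------------------------------------
# raster IO: labels as 8-bit PNG, density as a float array, metadata sidecar

_META_KEYS = ("pixel_size_mm", "origin_mm", "seed")


def write_labeled_image(image: LabeledImage, path) -> None:
    """Write ``labels.png`` + ``density.npy`` + ``meta.json`` under ``path``."""
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path / "labels.png", image.labels.astype(np.uint8))
    np.save(path / "density.npy", image.density)
    landmarks = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in image.landmarks.items()}
    meta = {
        "pixel_size_mm": image.pixel_size,
        "origin_mm": list(image.origin),
        "seed": image.landmarks.get("seed", 0),
        "landmarks": landmarks,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_labeled_image(path) -> LabeledImage:
    """Read an image written by :func:`write_labeled_image`."""
    import imageio.v3 as iio

    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise PhantomError(
            f"missing metadata sidecar {meta_path}; required keys: {', '.join(_META_KEYS)}")
    meta = json.loads(meta_path.read_text())
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise PhantomError(f"metadata sidecar lacks required keys: {', '.join(missing)}")
    labels = np.asarray(iio.imread(path / "labels.png"))
    if labels.ndim == 3:
        labels = labels[..., 0]
    if not set(np.unique(labels)) <= VALID_LABELS:
        bad = sorted(set(np.unique(labels)) - VALID_LABELS)
        raise PhantomError(f"file contains labels outside 0..3: {bad}")
    density = np.load(path / "density.npy")
    landmarks = {k: (tuple(v) if isinstance(v, list) else v)
                 for k, v in meta.get("landmarks", {}).items()}
    return LabeledImage(labels, density, float(meta["pixel_size_mm"]),
                        tuple(meta["origin_mm"]), landmarks)
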