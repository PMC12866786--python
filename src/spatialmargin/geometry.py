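"""Tumor-border detection and 500-µm zonal band construction.

The tumor region is detected from a raster of the malignant ("AT2-like")
cell-type abundance: thresholding (Otsu by default) → Gaussian blur →
Canny edge detection → morphological closing of the edge map → hole
filling and connected-contour extraction → polyline simplification.  The
candidate contour enclosing the largest area is the region of interest;
its boundary is the borderline separating tumor from adjacent tissue.

The peri-tumoral zone is partitioned into six 500-µm-wide bands by
perpendicular offsets at 500, 1000 and 1500 µm on either side of the
borderline: TR1-TR3 inward (tumor side), NR1-NR3 outward (normal side).
Band membership of a spot is decided by its exact signed distance to the
borderline, with tumor-side intervals half-open ``[lo, hi)`` (the
borderline itself belongs to TR1) and normal-side intervals ``(lo, hi]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, MultiPolygon, Polygon, box
from shapely.geometry.polygon import orient
from sklearn.base import BaseEstimator
from skimage import feature, filters, measure, morphology

from .exceptions import GeometryError, NoRegionFound, ParameterError
from .simulate import SpatialSection, signed_band_label

__all__ = [
    "RasterGrid",
    "TumorRegion",
    "BandSet",
    "rasterize_abundance",
    "detect_tumor_region",
    "extract_borderline",
    "build_bands",
    "assign_spots_to_bands",
    "TumorMarginDetector",
]


@dataclass
class RasterGrid:
    """Raster image of a per-spot quantity, one pixel per grid cell.

    ``image[iy, ix]`` covers x in [ix·pixel_um, (ix+1)·pixel_um) relative
    to ``origin``; row index increases with y (origin bottom-left).
    """

    pixel_um: float
    image: np.ndarray
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixel_um <= 0:
            raise ParameterError("pixel_um must be positive")
        if self.image.ndim != 2:
            raise ParameterError("image must be 2-D")


@dataclass
class TumorRegion:
    """Detected tumor region of interest.

    ``polygon`` is the largest-area candidate; every closed candidate is
    retained in ``all_candidates`` (e.g. a second tumor focus on the same
    slide), sorted by decreasing area.
    """

    polygon: Polygon
    area_um2: float
    all_candidates: list[tuple[Polygon, float]] = field(default_factory=list)


def rasterize_abundance(section: SpatialSection, cell_type: str,
                        pixel_um: float | None = None) -> RasterGrid:
    """Paint one cell type's abundance onto the pixel grid.

    At ``pixel_um`` equal to the spot pitch this is a lossless, invertible
    mapping (one spot per pixel); coarser pixels accumulate by summation.
    Pixels with no spot hold 0.
    """
    if cell_type not in section.cell_types:
        raise ParameterError(f"unknown cell type {cell_type!r}")
    if pixel_um is None:
        pixel_um = section.pitch_um or 50.0
    col = section.cell_types.index(cell_type)
    vals = np.asarray(section.abundance[:, col], dtype=float)
    ix = np.floor(section.x_um / pixel_um).astype(int)
    iy = np.floor(section.y_um / pixel_um).astype(int)
    img = np.zeros((iy.max() + 1, ix.max() + 1))
    np.add.at(img, (iy, ix), vals)
    return RasterGrid(pixel_um=pixel_um, image=img)


def _contour_to_polygon(contour: np.ndarray, pixel_um: float,
                        origin: tuple[float, float]) -> Polygon | None:
    """Sub-pixel contour (row, col) -> polygon in µm coordinates."""
    if len(contour) < 4:
        return None
    x = (contour[:, 1] + 0.5) * pixel_um + origin[0]
    y = (contour[:, 0] + 0.5) * pixel_um + origin[1]
    poly = Polygon(zip(x, y))
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area <= 0:
        return None
    if isinstance(poly, MultiPolygon):
        poly = max(poly.geoms, key=lambda p: p.area)
    return poly


def detect_tumor_region(
    grid: RasterGrid,
    threshold_method: str = "otsu",
    fixed_tau: float | None = None,
    blur_sigma_um: float = 50.0,
    canny_low: float = 0.1,
    canny_high: float = 0.3,
    simplify_eps_um: float = 25.0,
    close_kernel_um: float = 150.0,
) -> TumorRegion:
    """Detect the tumor region of interest from an abundance raster.

    Pipeline: threshold (``otsu`` on the positive-pixel histogram, or a
    ``fixed`` τ) → binary image → Gaussian blur (σ = ``blur_sigma_um``) →
    Canny edges (hysteresis thresholds as fractions of the maximum
    gradient) → morphological closing of the edge map → hole filling and
    connected-component extraction → sub-pixel contour refinement against
    the blurred field → Douglas-Peucker simplification with tolerance
    ``simplify_eps_um`` (0 keeps the raw contour).  The maximal-area
    candidate is the ROI.

    Raises
    ------
    NoRegionFound
        If the image has no positive pixel or no closed contour survives.
    """
    img = np.asarray(grid.image, dtype=float)
    pos = img[img > 0]
    if pos.size == 0:
        raise NoRegionFound("image contains no positive pixel")

    if threshold_method == "fixed":
        if fixed_tau is None:
            raise ParameterError("fixed threshold requires fixed_tau")
        tau = float(fixed_tau)
    elif threshold_method == "otsu":
        tau = float(pos.min()) / 2.0 if np.allclose(pos, pos[0]) else float(
            filters.threshold_otsu(pos)
        )
    else:
        raise ParameterError(f"unknown threshold method {threshold_method!r}")

    binary = (img >= tau).astype(float)
    sigma_px = blur_sigma_um / grid.pixel_um
    blurred = filters.gaussian(binary, sigma=sigma_px, preserve_range=True)

    # Canny hysteresis thresholds as fractions of the peak gradient of the
    # internally smoothed image (sigma=1 px, matching canny's default).
    grad_max = float(filters.sobel(filters.gaussian(blurred, sigma=1.0)).max())
    if grad_max <= 0:
        raise NoRegionFound("flat image after blurring: no gradient")
    edges = feature.canny(
        blurred,
        sigma=1.0,
        low_threshold=canny_low * grad_max,
        high_threshold=canny_high * grad_max,
    )
    k = max(1, int(round(close_kernel_um / grid.pixel_um)))
    closed = morphology.closing(edges, footprint=np.ones((k, k), dtype=bool))
    filled = ndimage.binary_fill_holes(closed)
    interior = filled & ~closed  # enclosed area only; open curves vanish
    if not interior.any():
        raise NoRegionFound("no closed contour found")

    labeled, n_lab = ndimage.label(filled)

    # Sub-pixel contour refinement: the filled Canny map decides WHICH
    # closed regions exist; their boundary geometry is traced at the
    # 0.5-level of the blurred field, which is sub-pixel accurate for a
    # blurred binary step (the mask's own staircase is half-pixel only).
    refined = measure.find_contours(blurred, 0.5)
    candidates: list[tuple[Polygon, float]] = []
    claimed: set[int] = set()
    for contour in sorted(refined, key=len, reverse=True):
        if not np.allclose(contour[0], contour[-1]):
            continue  # open curve hitting the image border
        poly = _contour_to_polygon(contour, grid.pixel_um, grid.origin_um)
        if poly is None:
            continue
        rp = poly.representative_point()
        iy = int(round((rp.y - grid.origin_um[1]) / grid.pixel_um - 0.5))
        ix = int(round((rp.x - grid.origin_um[0]) / grid.pixel_um - 0.5))
        if not (0 <= iy < labeled.shape[0] and 0 <= ix < labeled.shape[1]):
            continue
        lab = labeled[iy, ix]
        if lab == 0 or lab in claimed or not (labeled[interior] == lab).any():
            continue
        claimed.add(lab)
        if simplify_eps_um > 0:
            poly = poly.simplify(simplify_eps_um, preserve_topology=True)
        if poly.is_valid and poly.area > 0:
            candidates.append((poly, float(poly.area)))
    if not candidates:
        raise NoRegionFound("no closed contour found")
    candidates.sort(key=lambda t: t[1], reverse=True)
    roi = candidates[0][0]
    return TumorRegion(polygon=roi, area_um2=float(roi.area),
                       all_candidates=candidates)


def extract_borderline(region: TumorRegion) -> LineString:
    """Borderline = the ROI boundary, oriented counter-clockwise
    (tumor interior on the left of the traversal)."""
    poly = region.polygon
    if poly is None or poly.is_empty or len(poly.exterior.coords) < 4:
        raise GeometryError("degenerate region: fewer than 3 vertices")
    return LineString(orient(poly, sign=1.0).exterior.coords)


@dataclass
class BandSet:
    """Six signed-distance zonal bands around one borderline.

    ``bands`` maps NR3..TR3 to (possibly clipped, possibly empty) polygon
    geometry built from buffer-ring differences; spot labelling uses the
    exact signed distance (see :func:`spatialmargin.simulate.signed_band_label`)
    so the half-open interval conventions are honoured.
    """

    borderline: LineString
    offsets: tuple[float, ...]
    bands: dict
    tumor_polygon: Polygon

    @property
    def labels(self) -> tuple[str, ...]:
        k = len(self.offsets)
        return tuple(f"NR{i}" for i in range(k, 0, -1)) + tuple(
            f"TR{i}" for i in range(1, k + 1)
        )

    def label_points(self, x_um, y_um) -> np.ndarray:
        """Band label (or None) per point from exact signed distance."""
        pts = shapely.points(np.asarray(x_um, float), np.asarray(y_um, float))
        inside = shapely.covers(self.tumor_polygon, pts)
        dist = shapely.distance(pts, self.borderline)
        return signed_band_label(inside, dist, self.offsets)

    def distance_to_border(self, x_um, y_um) -> np.ndarray:
        pts = shapely.points(np.asarray(x_um, float), np.asarray(y_um, float))
        return shapely.distance(pts, self.borderline)


def build_bands(
    borderline: LineString,
    offsets: tuple[float, ...] = (500.0, 1000.0, 1500.0),
    extent: tuple[float, float, float, float] | None = None,
) -> BandSet:
    """Partition the peri-tumoral zone into 2·len(offsets) bands.

    TR_k holds interior points with distance to the borderline in
    [offset_{k-1}, offset_k); NR_k holds exterior points in
    (offset_{k-1}, offset_k]; offset_0 = 0.  Band polygons are realised as
    buffer-ring differences of the tumor polygon and clipped to ``extent``
    (minx, miny, maxx, maxy) when given.

    Raises
    ------
    GeometryError
        If the borderline self-intersects or offsets are not strictly
        increasing and positive.
    ParameterError
        If offsets are invalid.
    """
    offs = tuple(float(o) for o in offsets)
    if not offs or offs[0] <= 0 or any(b <= a for a, b in zip(offs, offs[1:])):
        raise ParameterError("offsets must be strictly increasing and positive")
    if not borderline.is_simple:
        raise GeometryError("borderline is self-intersecting")
    coords = list(borderline.coords)
    if coords[0] != coords[-1]:
        coords.append(coords[0])
    poly = Polygon(coords)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("borderline does not bound a valid polygon")

    clip = box(*extent) if extent is not None else None
    bands: dict = {}
    edges = (0.0, *offs)
    for i in range(len(offs)):
        inner = poly.buffer(-edges[i]) if edges[i] > 0 else poly
        tr = inner.difference(poly.buffer(-edges[i + 1]))
        nr = poly.buffer(edges[i + 1]).difference(poly.buffer(edges[i]) if edges[i] > 0 else poly)
        if clip is not None:
            tr, nr = tr.intersection(clip), nr.intersection(clip)
        bands[f"TR{i + 1}"] = tr
        bands[f"NR{i + 1}"] = nr
    return BandSet(borderline=LineString(coords), offsets=offs, bands=bands,
                   tumor_polygon=poly)


def assign_spots_to_bands(section: SpatialSection,
                          bands: BandSet | list[BandSet]) -> np.ndarray:
    """Band label (or None) for every spot center.

    With several band sets (multi-focal tumors) the set whose borderline
    is nearest to the spot wins; empty bands simply receive no spots and
    remain present in downstream tables.
    """
    if isinstance(bands, BandSet):
        return bands.label_points(section.x_um, section.y_um)
    if not bands:
        raise ParameterError("at least one BandSet required")
    dists = np.stack([b.distance_to_border(section.x_um, section.y_um) for b in bands])
    nearest = np.argmin(dists, axis=0)
    labels = np.full(section.n_spots, None, dtype=object)
    for i, b in enumerate(bands):
        sel = nearest == i
        if sel.any():
            labels[sel] = b.label_points(section.x_um[sel], section.y_um[sel])
    return labels


class TumorMarginDetector(BaseEstimator):
    """End-to-end margin detector: raster → ROI → borderline → bands.

    :meth:`fit` runs border detection on a :class:`SpatialSection` and
    stores the raster, candidate regions, borderline and band set;
    :meth:`predict` labels spots with their zonal band.

    Parameters mirror :func:`detect_tumor_region` plus the target cell
    type and band offsets.

    Attributes
    ----------
    raster_ : RasterGrid
    region_ : TumorRegion
    borderline_ : shapely LineString (counter-clockwise)
    bands_ : BandSet
    """

    def __init__(
        self,
        cell_type: str = "AT2-like",
        pixel_um: float | None = None,
        threshold_method: str = "otsu",
        fixed_tau: float | None = None,
        blur_sigma_um: float = 50.0,
        canny_low: float = 0.1,
        canny_high: float = 0.3,
        simplify_eps_um: float = 25.0,
        close_kernel_um: float = 150.0,
        offsets: tuple[float, ...] = (500.0, 1000.0, 1500.0),
    ):
        self.cell_type = cell_type
        self.pixel_um = pixel_um
        self.threshold_method = threshold_method
        self.fixed_tau = fixed_tau
        self.blur_sigma_um = blur_sigma_um
        self.canny_low = canny_low
        self.canny_high = canny_high
        self.simplify_eps_um = simplify_eps_um
        self.close_kernel_um = close_kernel_um
        self.offsets = offsets

    def fit(self, X: SpatialSection, y=None):
        self.raster_ = rasterize_abundance(X, self.cell_type, self.pixel_um)
        self.region_ = detect_tumor_region(
            self.raster_,
            threshold_method=self.threshold_method,
            fixed_tau=self.fixed_tau,
            blur_sigma_um=self.blur_sigma_um,
            canny_low=self.canny_low,
            canny_high=self.canny_high,
            simplify_eps_um=self.simplify_eps_um,
            close_kernel_um=self.close_kernel_um,
        )
        self.borderline_ = extract_borderline(self.region_)
        extent = (
            0.0,
            0.0,
            float(np.max(X.x_um) + (X.pitch_um or 0) / 2),
            float(np.max(X.y_um) + (X.pitch_um or 0) / 2),
        )
        self.bands_ = build_bands(self.borderline_, self.offsets, extent=extent)
        return self

    def predict(self, X: SpatialSection) -> np.ndarray:
        if not hasattr(self, "bands_"):
            raise RuntimeError("fit the detector first")
        return assign_spots_to_bands(X, self.bands_)
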