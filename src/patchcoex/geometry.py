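"""Habitat-patch outlines and rasterized simulation domains.

A habitat patch is a closed, simple planar polygon (counter-clockwise,
first vertex not repeated). For simulation it is rasterized onto a regular
grid of cell centres; cells strictly inside the polygon are habitat, all
others — including a guaranteed one-cell frame around the grid — are
hostile exterior, which realizes the absorbing (Dirichlet) boundary.

Conventions used throughout the package: coordinates are continuous planar
(arbitrary length units); grids are indexed 0-based as (row, col) = (y, x);
``origin`` is the coordinate of the lower-left cell centre.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import shapely
from shapely.geometry import Polygon

from .errors import (
    InvalidOutlineError,
    OutlineParseError,
    ResolutionTooCoarseError,
    UnsupportedTopologyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PatchOutline",
    "RasterDomain",
    "polygon_measures",
    "rasterize",
    "erode_domain",
    "read_outlines",
    "write_outlines",
    "write_pgm",
]


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class PatchOutline:
    """A closed simple polygon bounding a habitat patch.

    Parameters
    ----------
    vertices
        ``(N, 2)`` array of (x, y) coordinates, counter-clockwise, the
        first vertex not repeated at the end.
    label
        Free-text identifier carried through rasterization and output.
    properties
        Optional metadata (e.g. the generator recipe) stored alongside the
        outline in GeoJSON feature properties.
    """

    vertices: np.ndarray
    label: str = ""
    properties: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidOutlineError(
                f"outline {self.label!r}: need an (N>=3, 2) vertex array, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidOutlineError(f"outline {self.label!r}: non-finite vertex")
        area = _shoelace(v)
        if area <= 0:
            raise InvalidOutlineError(
                f"outline {self.label!r}: signed area {area:g} not positive "
                "(vertices must be counter-clockwise and non-degenerate)"
            )
        poly = Polygon(v)
        if not poly.is_valid or not poly.is_simple:
            raise InvalidOutlineError(f"outline {self.label!r}: polygon is not simple")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def translated(self, dx: float, dy: float) -> "PatchOutline":
        return replace(self, vertices=self.vertices + np.array([dx, dy]))

    def scaled(self, k: float) -> "PatchOutline":
        if k <= 0:
            raise InvalidOutlineError("scale factor must be positive")
        return replace(self, vertices=self.vertices * k)

    def normalized_to_area(self, target_area: float = 0.25) -> "PatchOutline":
        """Rescale about the origin so the polygon area equals ``target_area``.

        Experiments normalize all patches to a common area (default 0.25 in
        model units) so that complexity–coexistence comparisons reflect
        shape, not size.
        """
        area, _ = polygon_measures(self)
        return self.scaled(float(np.sqrt(target_area / area)))


def polygon_measures(outline: PatchOutline) -> tuple[float, float]:
    """Area (shoelace) and perimeter (closed edge-length sum) of an outline."""
    v = outline.vertices
    area = abs(_shoelace(v))
    if area == 0:
        raise InvalidOutlineError(f"outline {outline.label!r}: zero area")
    edges = np.roll(v, -1, axis=0) - v
    perimeter = float(np.sum(np.hypot(edges[:, 0], edges[:, 1])))
    return area, perimeter


@dataclass(frozen=True)
class RasterDomain:
    """Binary habitat mask on a regular grid with spacing ``h``.

    ``mask[r, c]`` is True for interior (habitat) cells; the outer frame of
    the grid is always exterior so a Dirichlet rim exists. ``origin`` is the
    (x, y) coordinate of the centre of cell (0, 0) (lower-left); row r maps
    to y = origin[1] + r*h.
    """

    mask: np.ndarray
    h: float
    origin: tuple[float, float]
    source_label: str = ""

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
            raise ValueError("grid frame must be exterior (Dirichlet rim)")
        if self.h <= 0:
            raise ValueError("grid spacing must be positive")
        object.__setattr__(self, "mask", m)

    # -- domain protocol used by the dynamics module ------------------------
    dims = 2

    @property
    def n_interior(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_interior == 0

    @property
    def interior_area(self) -> float:
        return self.n_interior * self.h**2

    def interior_indices(self) -> np.ndarray:
        """Flat indices (row-major) of interior cells, in scan order."""
        return np.flatnonzero(self.mask.ravel())

    def cell_centers(self) -> np.ndarray:
        """(n_interior, 2) array of (x, y) coordinates of interior cells."""
        rr, cc = np.nonzero(self.mask)
        x0, y0 = self.origin
        return np.column_stack([x0 + cc * self.h, y0 + rr * self.h])

    def laplacian(self) -> sp.csr_matrix:
        """Discrete 5-point Laplacian over interior cells, scaled by 1/h².

        Neighbours outside the mask contribute their Dirichlet zero: the row
        keeps the full -4 diagonal and simply omits the exterior coupling.
        """
        return _masked_laplacian(self.mask, self.h)


def _masked_laplacian(mask: np.ndarray, h: float) -> sp.csr_matrix:
    idx = -np.ones(mask.shape, dtype=np.int64)
    rr, cc = np.nonzero(mask)
    n = rr.size
    idx[rr, cc] = np.arange(n)
    rows, cols, vals = [np.arange(n)], [np.arange(n)], [np.full(n, -4.0)]
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = idx[rr + dr, cc + dc]
        ok = nb >= 0
        rows.append(np.arange(n)[ok])
        cols.append(nb[ok])
        vals.append(np.ones(ok.sum()))
    lap = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    lap.sort_indices()
    return lap * (1.0 / h**2)


def rasterize(outline: PatchOutline, target_cells: int = 100) -> RasterDomain:
    """Rasterize an outline: a cell is habitat iff its centre is strictly inside.

    ``target_cells`` is the number of cells along the longest bounding-box
    side; the grid is padded with a one-cell exterior frame on all sides.
    """
    if target_cells < 16:
        raise ValueError(f"target_cells must be >= 16, got {target_cells}")
    domain = _try_rasterize(outline, target_cells)
    if domain.n_interior > 0:
        return domain
    # find the minimum feasible resolution by doubling, for the error message
    tc = target_cells
    for _ in range(8):
        tc *= 2
        if _try_rasterize(outline, tc).n_interior > 0:
            raise ResolutionTooCoarseError(
                f"outline {outline.label!r}: no interior cells at "
                f"target_cells={target_cells}; minimum feasible is <= {tc}",
                min_feasible=tc,
            )
    raise ResolutionTooCoarseError(
        f"outline {outline.label!r}: no interior cells up to target_cells={tc}"
    )


def _try_rasterize(outline: PatchOutline, target_cells: int) -> RasterDomain:
    poly = outline.polygon
    xmin, ymin, xmax, ymax = poly.bounds
    h = max(xmax - xmin, ymax - ymin) / target_cells
    nx = int(np.ceil((xmax - xmin) / h)) + 2
    ny = int(np.ceil((ymax - ymin) / h)) + 2
    # cell (0,0) centre sits half a cell outside the bbox: exterior frame
    x0 = xmin - h / 2
    y0 = ymin - h / 2
    xs = x0 + np.arange(nx) * h
    ys = y0 + np.arange(ny) * h
    gx, gy = np.meshgrid(xs, ys)
    shapely.prepare(poly)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(ny, nx)
    inside[0, :] = inside[-1, :] = False
    inside[:, 0] = inside[:, -1] = False
    return RasterDomain(inside, h, (x0, y0), source_label=outline.label)


def erode_domain(domain: RasterDomain, depth: float) -> RasterDomain:
    """Remove interior cells within ``depth`` of the exterior.

    A cell stays habitat iff the Euclidean distance from its centre to the
    nearest exterior cell centre exceeds ``depth``. Emulates peripheral
    habitat loss; an entirely eroded domain is legal and flagged in the
    provenance string.
    """
    if depth < 0:
        raise ValueError("erosion depth must be >= 0")
    if depth == 0:
        return domain
    dist = ndi.distance_transform_edt(domain.mask) * domain.h
    new_mask = dist > depth
    label = f"{domain.source_label}|eroded:{depth:g}"
    if not new_mask.any():
        label += "|empty"
    return RasterDomain(new_mask, domain.h, domain.origin, source_label=label)


# ---------------------------------------------------------------------------
# GeoJSON I/O (RFC 7946; exterior rings only)
# ---------------------------------------------------------------------------


def _ring_from_geometry(geom: dict, i: int) -> list:
    gtype = geom.get("type")
    if gtype == "Polygon":
        rings = geom.get("coordinates", [])
    elif gtype == "MultiPolygon":
        parts = geom.get("coordinates", [])
        if len(parts) != 1:
            raise UnsupportedTopologyError(
                f"feature {i}: MultiPolygon with {len(parts)} parts (only 1 supported)"
            )
        rings = parts[0]
    else:
        raise OutlineParseError(f"feature {i}: geometry type {gtype!r} not supported", i)
    if not rings:
        raise OutlineParseError(f"feature {i}: empty polygon", i)
    if len(rings) > 1:
        raise UnsupportedTopologyError(f"feature {i}: polygon has interior rings (holes)")
    return rings[0]


def read_outlines(path) -> list[PatchOutline]:
    """Read patch outlines from a GeoJSON FeatureCollection.

    Clockwise exterior rings are reversed to the counter-clockwise
    convention with a logged notice. Holes raise UnsupportedTopologyError.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise OutlineParseError(f"{path}: not valid JSON: {e}") from e
    if doc.get("type") != "FeatureCollection":
        raise OutlineParseError(f"{path}: expected a FeatureCollection")
    outlines = []
    for i, feature in enumerate(doc.get("features", [])):
        geom = feature.get("geometry")
        if geom is None:
            raise OutlineParseError(f"feature {i}: missing geometry", i)
        ring = _ring_from_geometry(geom, i)
        v = np.asarray(ring, dtype=float)
        if v.ndim != 2 or v.shape[1] < 2:
            raise OutlineParseError(f"feature {i}: malformed coordinates", i)
        v = v[:, :2]
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]  # GeoJSON rings repeat the first vertex
        if v.shape[0] >= 3 and _shoelace(v) < 0:
            logger.info("feature %d: clockwise ring reversed to counter-clockwise", i)
            v = v[::-1]
        props = dict(feature.get("properties") or {})
        label = props.pop("label", f"feature_{i}")
        try:
            outlines.append(PatchOutline(v, label=label, properties=props))
        except InvalidOutlineError as e:
            raise OutlineParseError(f"feature {i}: {e}", i) from e
    return outlines


def write_outlines(outlines, path) -> None:
    """Write outlines as a GeoJSON FeatureCollection (full float precision)."""
    features = []
    for o in outlines:
        ring = [[float(x), float(y)] for x, y in o.vertices]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"label": o.label, **o.properties},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_pgm(domain: RasterDomain, path) -> None:
    """Dump a mask as plain (P2) PGM, 1 = habitat, 0 = exterior, row 0 at top."""
    m = domain.mask[::-1].astype(int)
    with open(path, "w") as fh:
        fh.write(f"P2\n{m.shape[1]} {m.shape[0]}\n1\n")
        for row in m:
            fh.write(" ".join(map(str, row)) + "\n")
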