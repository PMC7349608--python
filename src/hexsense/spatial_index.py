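"""Hierarchical hexagonal grid indexing (a discrete global grid system).

The grid partitions the WGS84 longitude/latitude plane into hexagonal
cells at 16 resolutions (0 = coarsest, 15 = finest).  Each refinement
step is an aperture-7 subdivision: the finer lattice is scaled by
1/sqrt(7) and rotated by ``alpha = atan(sqrt(3)/5) ~ 19.1 deg`` so that
every coarse cell center coincides exactly with a fine cell center and
each coarse cell owns seven fine cells (itself plus its six immediate
neighbours).  Cell sizes are chosen so that a resolution-10 hexagon is
roughly 60 m across and a resolution-15 hexagon under a metre, the
scale at which mobile noise measurements are bucketed for aggregation.

Membership is *hierarchical by assignment*: a point is placed
geometrically only at the finest resolution, and its cell at any
coarser resolution is the exact parent chain of that finest cell.
Hexagon hierarchies do not nest geometrically — no hexagonal grid can
make "the parent's polygon contains all its children's points" true —
so assignment-based membership is what makes

    parent_cell(index_point(p, fine), coarse) == index_point(p, coarse)

an identity rather than a high-probability event.  The price is that a
point can lie slightly outside the plotted hexagon of its coarse cell;
the offset is bounded by ``sqrt(7)/(sqrt(7)-1) ~ 1.61`` circumradii
(geometric series over the refinement steps).

Cell identifiers are 64-bit integers rendered as 16-character lowercase
hex tokens: 4 bits of resolution and two 30-bit offset-biased axial
coordinates.  Tokens are opaque to callers but stable across runs and
platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from shapely.geometry import Point as _ShpPoint, Polygon as _ShpPolygon

__all__ = [
    "CellId",
    "GridError",
    "MIN_RESOLUTION",
    "MAX_RESOLUTION",
    "index_point",
    "cell_boundary",
    "cell_centroid",
    "parent_cell",
    "cover_boundary",
    "cell_circumradius_deg",
]

MIN_RESOLUTION = 0
MAX_RESOLUTION = 15

# Circumradius (center -> vertex) of a resolution-0 hexagon, in degrees.
# 10 deg ~ 1100 km, matching the coarsest scale of comparable grid
# systems; each resolution divides the linear scale by sqrt(7).
BASE_SIZE_DEG = 10.0

_SQRT3 = math.sqrt(3.0)
_SQRT7 = math.sqrt(7.0)
# Aperture-7 inter-resolution rotation: the vector 2*a1 + 1*a2 of the
# fine lattice (length sqrt(7) cells) becomes the coarse basis vector.
_ALPHA = math.atan2(_SQRT3, 5.0)

_COORD_BITS = 30
_COORD_OFFSET = 1 << (_COORD_BITS - 1)
_COORD_MASK = (1 << _COORD_BITS) - 1


class GridError(ValueError):
    """Invalid resolution, token, or query geometry."""


def _check_resolution(res: int) -> None:
    if not isinstance(res, int) or isinstance(res, bool):
        raise GridError(f"resolution must be an integer, got {res!r}")
    if not MIN_RESOLUTION <= res <= MAX_RESOLUTION:
        raise GridError(
            f"resolution must be in [{MIN_RESOLUTION}, {MAX_RESOLUTION}], got {res}"
        )


def cell_circumradius_deg(res: int) -> float:
    """Center-to-vertex distance of a cell at ``res``, in degrees."""
    _check_resolution(res)
    return BASE_SIZE_DEG * _SQRT7 ** (-res)


@dataclass(frozen=True, order=True)
class CellId:
    """One hexagonal cell: an opaque token plus its resolution."""

    token: str
    resolution: int

    @staticmethod
    def from_axial(res: int, i: int, j: int) -> "CellId":
        _check_resolution(res)
        bi = i + _COORD_OFFSET
        bj = j + _COORD_OFFSET
        if not (0 <= bi <= _COORD_MASK and 0 <= bj <= _COORD_MASK):
            raise GridError(f"axial coordinates out of range: ({i}, {j})")
        value = (res << (2 * _COORD_BITS)) | (bi << _COORD_BITS) | bj
        return CellId(token=f"{value:016x}", resolution=res)

    @staticmethod
    def from_token(token: str) -> "CellId":
        if not isinstance(token, str) or len(token) != 16:
            raise GridError(f"malformed cell token: {token!r}")
        try:
            value = int(token, 16)
        except ValueError:
            raise GridError(f"malformed cell token: {token!r}") from None
        res = value >> (2 * _COORD_BITS)
        if res > MAX_RESOLUTION:
            raise GridError(f"malformed cell token (bad resolution): {token!r}")
        return CellId(token=token, resolution=res)

    @property
    def axial(self) -> tuple[int, int]:
        value = int(self.token, 16)
        bi = (value >> _COORD_BITS) & _COORD_MASK
        bj = value & _COORD_MASK
        return bi - _COORD_OFFSET, bj - _COORD_OFFSET


# --- lattice geometry -------------------------------------------------

def _frame(res: int) -> tuple[float, float, float]:
    """(size, cos, sin) of the lattice frame at ``res``.

    The resolution-r frame is rotated by ``-r * alpha`` relative to the
    plane (each refinement rotates clockwise), so that coarse centers
    are exact fine-lattice points.
    """
    size = BASE_SIZE_DEG * _SQRT7 ** (-res)
    theta = -res * _ALPHA
    return size, math.cos(theta), math.sin(theta)


def _plane_to_axial(x: float, y: float, res: int) -> tuple[float, float]:
    size, c, s = _frame(res)
    # rotate into the lattice frame, then pointy-top pixel->axial
    xr = c * x + s * y
    yr = -s * x + c * y
    q = (_SQRT3 / 3.0 * xr - yr / 3.0) / size
    r = (2.0 / 3.0 * yr) / size
    return q, r


def _axial_to_plane(q: float, r: float, res: int) -> tuple[float, float]:
    size, c, s = _frame(res)
    xr = size * (_SQRT3 * q + _SQRT3 / 2.0 * r)
    yr = size * (1.5 * r)
    return c * xr - s * yr, s * xr + c * yr


def _hex_round(q: float, r: float) -> tuple[int, int]:
    """Round fractional axial coordinates to the containing cell."""
    x, z = q, r
    y = -x - z
    rx, ry, rz = round(x), round(y), round(z)
    dx, dy, dz = abs(rx - x), abs(ry - y), abs(rz - z)
    if dx > dy and dx > dz:
        rx = -ry - rz
    elif dy > dz:
        ry = -rx - rz
    else:
        rz = -rx - ry
    return int(rx), int(rz)


def _parent_axial(i: int, j: int) -> tuple[int, int]:
    """Axial coordinates of the parent cell, one resolution coarser.

    Inverse of the integer child matrix [[2, -1], [1, 3]] (det 7),
    rounded on the hex lattice.  Exact for the seven child cosets.
    """
    return _hex_round((3 * i + j) / 7.0, (-i + 2 * j) / 7.0)


# --- public operations ------------------------------------------------

def index_point(lon: float, lat: float, res: int) -> CellId:
    """Assign a WGS84 point to its cell at ``res``.

    The point is placed geometrically at the finest resolution and the
    result is that cell's ancestor, so results at different resolutions
    are always hierarchy-consistent.
    """
    _check_resolution(res)
    if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
        raise GridError(f"coordinates out of range: ({lon}, {lat})")
    q, r = _plane_to_axial(lon, lat, MAX_RESOLUTION)
    i, j = _hex_round(q, r)
    for _ in range(MAX_RESOLUTION - res):
        i, j = _parent_axial(i, j)
    return CellId.from_axial(res, i, j)


def parent_cell(cell: CellId, coarser: int) -> CellId:
    """The unique ancestor of ``cell`` at resolution ``coarser``."""
    _check_resolution(coarser)
    if coarser >= cell.resolution:
        raise GridError(
            f"parent resolution must be coarser than {cell.resolution}, got {coarser}"
        )
    i, j = cell.axial
    for _ in range(cell.resolution - coarser):
        i, j = _parent_axial(i, j)
    return CellId.from_axial(coarser, i, j)


def cell_centroid(cell: CellId) -> tuple[float, float]:
    """(lon, lat) of the cell center."""
    i, j = cell.axial
    return _axial_to_plane(float(i), float(j), cell.resolution)


def cell_boundary(cell: CellId) -> list[tuple[float, float]]:
    """Closed hexagonal ring of the cell, 7 points (last == first).

    Vertices are ordered counter-clockwise starting from the "top"
    vertex of the (rotated) pointy-top hexagon.
    """
    if not isinstance(cell, CellId):
        cell = CellId.from_token(cell)
    size, c, s = _frame(cell.resolution)
    cx, cy = cell_centroid(cell)
    ring = []
    for k in range(6):
        ang = math.pi / 2.0 + k * math.pi / 3.0
        vx, vy = size * math.cos(ang), size * math.sin(ang)
        ring.append((cx + c * vx - s * vy, cy + s * vx + c * vy))
    ring.append(ring[0])
    return ring


def _validate_ring(ring: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    pts = [tuple(map(float, p[:2])) for p in ring]
    if len(pts) >= 2 and pts[0] == pts[-1]:
        pts = pts[:-1]
    if len(pts) < 3:
        raise GridError(f"degenerate boundary ring with {len(pts)} distinct vertices")
    lons = [p[0] for p in pts]
    lats = [p[1] for p in pts]
    if not all(-180.0 <= x <= 180.0 for x in lons) or not all(
        -90.0 <= y <= 90.0 for y in lats
    ):
        raise GridError("boundary ring has out-of-range coordinates")
    for (x0, _), (x1, _) in zip(pts, pts[1:] + pts[:1]):
        if abs(x1 - x0) > 180.0:
            raise GridError("antimeridian-crossing query polygons are not supported")
    return pts


def cover_boundary(ring: Sequence[tuple[float, float]], res: int) -> set[CellId]:
    """All cells at ``res`` whose centroid lies inside the polygon.

    ``ring`` is a simple closed ring of (lon, lat) pairs; the closing
    point may be repeated or omitted.  Centroid-in-polygon membership
    makes the cover deterministic and monotone in the polygon.
    """
    _check_resolution(res)
    pts = _validate_ring(ring)
    poly = _ShpPolygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.is_empty:
            raise GridError("invalid query polygon")
    minx, miny, maxx, maxy = poly.bounds
    # conservative axial bounding box from the four plane corners
    corners = [(minx, miny), (minx, maxy), (maxx, miny), (maxx, maxy)]
    qs, rs = [], []
    for x, y in corners:
        q, r = _plane_to_axial(x, y, res)
        qs.append(q)
        rs.append(r)
    pad = 2
    qlo, qhi = math.floor(min(qs)) - pad, math.ceil(max(qs)) + pad
    rlo, rhi = math.floor(min(rs)) - pad, math.ceil(max(rs)) + pad
    out: set[CellId] = set()
    for i in range(qlo, qhi + 1):
        for j in range(rlo, rhi + 1):
            cx, cy = _axial_to_plane(float(i), float(j), res)
            if poly.covers(_ShpPoint(cx, cy)):
                out.add(CellId.from_axial(res, i, j))
    return out
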