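"""Room geometry, boundary patches and structured Cartesian grids.

The computational domain is a rectangular room with one window (the
ventilation inlet) and one door.  In the *open* scenario the whole door is a
pressure outlet; in the *closed* scenario only a thin under-door gap vents
the room, while the door leaf itself is a no-slip wall.  Patches are snapped
to the nearest grid-face boundaries when a grid is generated, so every
boundary face carries exactly one tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: wall identifiers: plane held fixed and side (0 = low coordinate, 1 = high)
WALLS = ("x0", "x1", "y0", "y1", "z0", "z1")

#: integer face tags
TAG_WALL = 0
TAG_INLET = 1
TAG_OUTLET = 2

# in-plane axes for each wall (the two free coordinates, in cyclic order)
_PLANE_AXES = {
    "x0": ("y", "z"), "x1": ("y", "z"),
    "y0": ("x", "z"), "y1": ("x", "z"),
    "z0": ("x", "y"), "z1": ("x", "y"),
}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class RoomConfigError(ValueError):
    """Raised for invalid room geometry or configuration documents."""


@dataclass(frozen=True)
class RectPatch:
    """Axis-aligned rectangle on one of the six room walls.

    ``center`` is given in the wall's own in-plane coordinates (see
    ``_PLANE_AXES``): e.g. for a wall at x = const the pair is (y, z).
    ``width`` extends along the first in-plane axis, ``height`` along the
    second.
    """

    wall: str
    center: tuple[float, float]
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.wall not in WALLS:
            raise RoomConfigError(f"unknown wall {self.wall!r}; expected one of {WALLS}")
        if self.width <= 0 or self.height <= 0:
            raise RoomConfigError("patch width and height must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    def bounds(self) -> tuple[float, float, float, float]:
        """(a0, a1, b0, b1) extents in the wall's in-plane coordinates."""
        ca, cb = self.center
        return (ca - self.width / 2, ca + self.width / 2,
                cb - self.height / 2, cb + self.height / 2)


@dataclass(frozen=True)
class RoomGeometry:
    """The room box with its window and door patches.

    Defaults reproduce a 3.0 m (W) x 4.0 m (L) x 2.8 m (H) office with a
    1.2 x 0.8 m window centred on the x = Lx wall and a 1.0 x 2.2 m door on
    the y = 0 wall, flush to the left with a 0.1 m reveal.  ``door_gap_height``
    is the under-door gap that vents the room when the door is closed.
    """

    lx: float = 3.0
    ly: float = 4.0
    lz: float = 2.8
    window: RectPatch = field(
        default_factory=lambda: RectPatch("x1", (2.0, 1.4), 1.2, 0.8))
    door: RectPatch = field(
        default_factory=lambda: RectPatch("y0", (0.6, 1.1), 1.0, 2.2))
    door_gap_height: float = 0.03
    scenario: str = "closed"

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise RoomConfigError("room dimensions must be positive")
        if self.scenario not in ("open", "closed"):
            raise RoomConfigError(
                f"scenario must be 'open' or 'closed', got {self.scenario!r}")
        if not (0 < self.door_gap_height <= self.door.height):
            raise RoomConfigError(
                "door_gap_height must be positive and no taller than the door")
        for name, patch in (("window", self.window), ("door", self.door)):
            a0, a1, b0, b1 = patch.bounds()
            la, lb = self._wall_plane_dims(patch.wall)
            eps = 1e-12
            if a0 < -eps or a1 > la + eps or b0 < -eps or b1 > lb + eps:
                raise RoomConfigError(
                    f"{name} patch ({patch.width} x {patch.height} m on wall "
                    f"{patch.wall}) extends outside the {la} x {lb} m wall")

    def _wall_plane_dims(self, wall: str) -> tuple[float, float]:
        dims = {"x": self.lx, "y": self.ly, "z": self.lz}
        a, b = _PLANE_AXES[wall]
        return dims[a], dims[b]

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz

    def wall_area(self, wall: str) -> float:
        la, lb = self._wall_plane_dims(wall)
        return la * lb

    @property
    def total_surface_area(self) -> float:
        return sum(self.wall_area(w) for w in WALLS)

    @property
    def vent_area(self) -> float:
        """Ventilation (window) area A_vent in m^2."""
        return self.window.area


_ROOM_KEYS = {"lx", "ly", "lz"}
_PATCH_KEYS = {"wall", "center", "width", "height"}
_TOP_KEYS = {"room", "window", "door", "door_gap_height", "scenario", "grid"}


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise RoomConfigError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"allowed: {sorted(allowed)}")


def _patch_from_config(name: str, doc: dict, default: RectPatch) -> RectPatch:
    _check_keys(name, doc, _PATCH_KEYS)
    center = doc.get("center", default.center)
    return RectPatch(
        wall=doc.get("wall", default.wall),
        center=(float(center[0]), float(center[1])),
        width=float(doc.get("width", default.width)),
        height=float(doc.get("height", default.height)),
    )


def build_room(config: dict | None = None) -> RoomGeometry:
    """Build a validated :class:`RoomGeometry` from a key-value document.

    ``config`` is a (possibly nested) mapping with optional sections
    ``room`` (lx/ly/lz), ``window``, ``door`` (wall/center/width/height),
    and top-level ``door_gap_height`` and ``scenario``.  Missing entries
    fall back to the default room; unknown keys are rejected.  ``None`` or
    an empty mapping returns the default room (33.6 m^3).
    """
    if config is None:
        return RoomGeometry()
    _check_keys("<top level>", config, _TOP_KEYS)
    default = RoomGeometry()
    room = dict(config.get("room", {}))
    _check_keys("room", room, _ROOM_KEYS)
    kwargs = dict(
        lx=float(room.get("lx", default.lx)),
        ly=float(room.get("ly", default.ly)),
        lz=float(room.get("lz", default.lz)),
        door_gap_height=float(config.get("door_gap_height",
                                         default.door_gap_height)),
        scenario=str(config.get("scenario", default.scenario)),
    )
    kwargs["window"] = _patch_from_config("window", dict(config.get("window", {})),
                                          default.window)
    kwargs["door"] = _patch_from_config("door", dict(config.get("door", {})),
                                        default.door)
    return RoomGeometry(**kwargs)


@dataclass(frozen=True)
class Grid:
    """Uniform structured Cartesian grid over a :class:`RoomGeometry`.

    ``boundary_tags[wall]`` is an integer array over that wall's boundary
    faces (one entry per face) holding TAG_WALL / TAG_INLET / TAG_OUTLET.
    Shapes: x-walls (ny, nz), y-walls (nx, nz), z-walls (nx, ny).
    """

    geom: RoomGeometry
    nx: int
    ny: int
    nz: int
    boundary_tags: dict[str, np.ndarray]

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def dx(self) -> float:
        return self.geom.lx / self.nx

    @property
    def dy(self) -> float:
        return self.geom.ly / self.ny

    @property
    def dz(self) -> float:
        return self.geom.lz / self.nz

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    @property
    def cell_volume(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = (np.arange(self.nx) + 0.5) * self.dx
        y = (np.arange(self.ny) + 0.5) * self.dy
        z = (np.arange(self.nz) + 0.5) * self.dz
        return x, y, z

    def face_area(self, wall: str) -> float:
        """Area of a single boundary face on the given wall."""
        areas = {"x": self.dy * self.dz, "y": self.dx * self.dz,
                 "z": self.dx * self.dy}
        return areas[wall[0]]

    def tagged_area(self, tag: int) -> float:
        """Total boundary area carrying ``tag``."""
        return sum(float(np.count_nonzero(self.boundary_tags[w] == tag))
                   * self.face_area(w) for w in WALLS)


def _snap_index_range(lo: float, hi: float, d: float, n: int) -> tuple[int, int]:
    """Snap a physical interval [lo, hi] to face-boundary indices on an
    n-cell axis of spacing d, keeping at least one face row."""
    i0 = int(round(lo / d))
    i1 = int(round(hi / d))
    i0 = min(max(i0, 0), n - 1)
    i1 = min(max(i1, i0 + 1), n)
    return i0, i1


def _tag_patch(tags: dict[str, np.ndarray], grid_shape: tuple[int, int, int],
               spacing: tuple[float, float, float], patch: RectPatch,
               tag: int, b_hi: float | None = None) -> None:
    """Paint ``tag`` over the faces covered by ``patch`` (optionally only up
    to in-plane height ``b_hi``, used for the under-door gap)."""
    a_ax, b_ax = _PLANE_AXES[patch.wall]
    ia, ib = _AXIS_INDEX[a_ax], _AXIS_INDEX[b_ax]
    a0, a1, b0, b1 = patch.bounds()
    if b_hi is not None:
        b1 = min(b1, b_hi)
    ja0, ja1 = _snap_index_range(a0, a1, spacing[ia], grid_shape[ia])
    jb0, jb1 = _snap_index_range(b0, b1, spacing[ib], grid_shape[ib])
    tags[patch.wall][ja0:ja1, jb0:jb1] = tag


def generate_grid(geom: RoomGeometry,
                  resolution: float | Sequence[int]) -> Grid:
    """Generate a uniform Cartesian grid with tagged boundary patches.

    ``resolution`` is either a cells-per-metre density or an explicit
    (nx, ny, nz) triple.  Patch rectangles are snapped to the nearest face
    boundaries; a patch narrower than one spacing (the under-door gap on
    coarse grids) still receives one full face row, so its tagged area is
    resolution-limited from below by one face.

    Tags follow the scenario: the window is always the velocity inlet; in
    the *open* scenario the whole door is a pressure outlet, in the
    *closed* scenario only the under-door gap strip is, the door leaf being
    a no-slip wall like the rest of that surface.
    """
    if np.isscalar(resolution):
        cells = (max(int(round(geom.lx * float(resolution))), 1),
                 max(int(round(geom.ly * float(resolution))), 1),
                 max(int(round(geom.lz * float(resolution))), 1))
    else:
        cells = tuple(int(c) for c in resolution)
        if len(cells) != 3:
            raise RoomConfigError("resolution triple must have three entries")
    if min(cells) < 4:
        raise RoomConfigError(
            f"grid {cells} too coarse: need at least 4 cells per axis "
            "(increase resolution)")
    nx, ny, nz = cells
    spacing = (geom.lx / nx, geom.ly / ny, geom.lz / nz)
    shapes = {"x0": (ny, nz), "x1": (ny, nz),
              "y0": (nx, nz), "y1": (nx, nz),
              "z0": (nx, ny), "z1": (nx, ny)}
    tags = {w: np.full(shapes[w], TAG_WALL, dtype=np.int8) for w in WALLS}

    _tag_patch(tags, cells, spacing, geom.window, TAG_INLET)
    if geom.scenario == "open":
        _tag_patch(tags, cells, spacing, geom.door, TAG_OUTLET)
    else:
        # the under-door gap strip: door footprint, from the floor up to the
        # gap height (at least one face row on coarse grids)
        _a0, _a1, b0, _b1 = geom.door.bounds()
        _tag_patch(tags, cells, spacing, geom.door, TAG_OUTLET,
                   b_hi=b0 + geom.door_gap_height)
    return Grid(geom=geom, nx=nx, ny=ny, nz=nz, boundary_tags=tags)


def refine_series(geom: RoomGeometry,
                  levels: Sequence[float | Sequence[int]]) -> list[Grid]:
    """Grids at strictly increasing resolutions, for convergence studies."""
    if len(levels) == 0:
        raise RoomConfigError("refine_series needs at least one level")
    counts = []
    grids = []
    for lvl in levels:
        g = generate_grid(geom, lvl)
        counts.append(g.n_cells)
        grids.append(g)
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise RoomConfigError(
            f"refinement levels must be strictly increasing, got cell counts {counts}")
    return grids


def with_scenario(geom: RoomGeometry, scenario: str) -> RoomGeometry:
    """The same room with the other door scenario."""
    return replace(geom, scenario=scenario)


def box_grid(lx: float, ly: float, lz: float,
             cells: Sequence[int]) -> Grid:
    """A plain box grid with every boundary face tagged as wall.

    Used by verification presets (cavity flow, manufactured solutions)
    where openings are irrelevant or boundary conditions are prescribed
    directly.
    """
    nx, ny, nz = (int(c) for c in cells)
    s = min(lx, ly, lz) / 100.0
    # dummy in-wall patches: the geometry type requires a window and door,
    # but every face is re-tagged as wall below
    geom = RoomGeometry(
        lx=lx, ly=ly, lz=lz,
        window=RectPatch("x1", (ly / 2, lz / 2), s, s),
        door=RectPatch("y0", (lx / 2, lz / 2), s, s),
        door_gap_height=s / 2, scenario="closed")
    shapes = {"x0": (ny, nz), "x1": (ny, nz),
              "y0": (nx, nz), "y1": (nx, nz),
              "z0": (nx, ny), "z1": (nx, ny)}
    tags = {w: np.full(shapes[w], TAG_WALL, dtype=np.int8) for w in WALLS}
    return Grid(geom=geom, nx=nx, ny=ny, nz=nz, boundary_tags=tags)
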