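"""Synthetic inputs: the reference-room fixture, manufactured solutions
for solver verification, and noisy synthetic detector readings.

The manufactured case prescribes a closed-form divergence-free velocity
(a Taylor–Green-type vortex) and a smooth concentration field, derives
the source term that makes the pair an exact steady solution of the
advection–diffusion–decay equation, and supplies Dirichlet boundary
values from the exact field — the standard method-of-manufactured-
solutions setup for checking the transport discretisation's order of
accuracy.

Synthetic detector readings sample a ground-truth field at given points
and perturb the samples with a stated noise model (multiplicative
lognormal by default, sigma = 10%, typical of passive track detectors).
All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .room import Grid, RoomGeometry, WALLS
from .air import VentilationSpec
from .transport import SourceSpec, sample_at
from .compare import (DETECTOR_HEIGHTS, DETECTOR_POINTS, MeasurementSet,
                      load_detector_tables, measurement_set_from_table)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for synthetic detectors.

    ``multiplicative_lognormal``: value * exp(sigma * Z); ``sigma`` is the
    relative scale.  ``additive_gaussian``: value + sigma * Z with sigma in
    Bq m^-3.  Identical seeds give identical draws.
    """

    kind: str = "multiplicative_lognormal"
    sigma: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, values: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        z = rng.standard_normal(np.shape(values))
        if self.kind == "multiplicative_lognormal":
            return np.asarray(values) * np.exp(self.sigma * z)
        return np.maximum(np.asarray(values) + self.sigma * z, 0.0)


@dataclass(frozen=True)
class ReferenceRoomFixture:
    """The reference-room configuration with its detector layout."""

    geometry: RoomGeometry
    ventilation: VentilationSpec
    source: SourceSpec
    measurements: pd.DataFrame   # published detector records, both scenarios

    def measurement_set(self, scenario: str, device: str,
                        z_m: float | None = None) -> MeasurementSet:
        return measurement_set_from_table(scenario, device, z_m=z_m)


def detector_locations() -> pd.DataFrame:
    """The 5 plan positions x 3 heights = 15 detector locations."""
    rows = [
        {"point": name, "x_m": xy[0], "y_m": xy[1], "z_m": z}
        for name, xy in DETECTOR_POINTS.items()
        for z in DETECTOR_HEIGHTS
    ]
    return pd.DataFrame(rows)


def reference_room_fixture(ach: float = 1.0,
                           scenario: str = "closed") -> ReferenceRoomFixture:
    """The exact reference configuration: 3.0 x 4.0 x 2.8 m room,
    1.2 x 0.8 m window, 1.0 x 2.2 m door, E = 3.1 Bq m^-2 h^-1 on every
    surface, outdoor concentration 10 Bq m^-3."""
    geom = RoomGeometry(scenario=scenario)
    vent = VentilationSpec(ach=ach, room_volume=geom.volume,
                           vent_area=geom.vent_area)
    src = SourceSpec(exhalation_bq_m2_h=3.1, outdoor_bq_m3=10.0)
    return ReferenceRoomFixture(geometry=geom, ventilation=vent, source=src,
                                measurements=load_detector_tables())


# ---------------------------------------------------------------------------
# manufactured solutions


@dataclass(frozen=True)
class ManufacturedCase:
    """Closed-form velocity/concentration pair with its derived source."""

    grid: Grid
    amplitude: float        # velocity amplitude, m/s
    gamma: float            # diffusivity used, m^2/s
    decay: float            # s^-1
    c_mean: float
    c_amp: float

    def _waves(self):
        g = self.grid.geom
        return (np.pi / g.lx, np.pi / g.ly, np.pi / g.lz)

    def velocity(self, x, y, z):
        """Analytically divergence-free Taylor–Green velocity."""
        a, b, c = self._waves()
        u0 = self.amplitude
        u = u0 * np.sin(a * x) * np.cos(b * y) * np.cos(c * z)
        v = u0 * np.cos(a * x) * np.sin(b * y) * np.cos(c * z)
        w = (-u0 * (a + b) / c) * np.cos(a * x) * np.cos(b * y) * np.sin(c * z)
        return u, v, w

    def exact(self, x, y, z):
        a, b, c = self._waves()
        return self.c_mean + self.c_amp * (np.cos(a * x) * np.cos(b * y)
                                           * np.cos(c * z))

    def source(self, x, y, z):
        """S = U . grad C + lambda C - Gamma lap C (Bq m^-3 s^-1)."""
        a, b, c = self._waves()
        u, v, w = self.velocity(x, y, z)
        sx = np.sin(a * x); sy = np.sin(b * y); sz = np.sin(c * z)
        cx = np.cos(a * x); cy = np.cos(b * y); cz = np.cos(c * z)
        grad = (-self.c_amp * a * sx * cy * cz,
                -self.c_amp * b * cx * sy * cz,
                -self.c_amp * c * cx * cy * sz)
        lap = -self.c_amp * (a ** 2 + b ** 2 + c ** 2) * cx * cy * cz
        adv = u * grad[0] + v * grad[1] + w * grad[2]
        return adv + self.decay * self.exact(x, y, z) - self.gamma * lap

    # -- discrete helpers ------------------------------------------------

    def face_fluxes(self):
        """Volumetric face fluxes (m^3/s) of the exact velocity."""
        g = self.grid
        dx, dy, dz = g.spacing
        xc, yc, zc = g.cell_centers
        xf = np.arange(g.nx + 1) * dx
        yf = np.arange(g.ny + 1) * dy
        zf = np.arange(g.nz + 1) * dz
        u = self.velocity(xf[:, None, None], yc[None, :, None],
                          zc[None, None, :])[0]
        v = self.velocity(xc[:, None, None], yf[None, :, None],
                          zc[None, None, :])[1]
        w = self.velocity(xc[:, None, None], yc[None, :, None],
                          zf[None, None, :])[2]
        return u * dy * dz, v * dx * dz, w * dx * dy

    def cell_source(self) -> np.ndarray:
        xc, yc, zc = self.grid.cell_centers
        return self.source(xc[:, None, None], yc[None, :, None],
                           zc[None, None, :])

    def cell_exact(self) -> np.ndarray:
        xc, yc, zc = self.grid.cell_centers
        return self.exact(xc[:, None, None], yc[None, :, None],
                          zc[None, None, :])

    def solve(self) -> np.ndarray:
        """Solve the discrete problem with Dirichlet boundaries from the
        exact field; returns the numerical cell field."""
        from .transport import BC_DIRICHLET, solve_scalar

        g = self.grid
        dx, dy, dz = g.spacing
        xc, yc, zc = g.cell_centers
        face_centers = {
            "x0": (0.0, yc[:, None], zc[None, :]),
            "x1": (g.geom.lx, yc[:, None], zc[None, :]),
            "y0": (xc[:, None], 0.0, zc[None, :]),
            "y1": (xc[:, None], g.geom.ly, zc[None, :]),
            "z0": (xc[:, None], yc[None, :], 0.0),
            "z1": (xc[:, None], yc[None, :], g.geom.lz),
        }
        bc = {}
        for w in WALLS:
            x, y, z = face_centers[w]
            val = np.broadcast_to(self.exact(x, y, z),
                                  g.boundary_tags[w].shape).astype(float)
            kind = np.full(val.shape, BC_DIRICHLET, dtype=np.int8)
            bc[w] = (kind, val, np.zeros(val.shape))
        return solve_scalar(g, self.face_fluxes(), self.gamma, bc,
                            decay_per_s=self.decay,
                            volumetric_source=self.cell_source())

    def l2_error(self) -> float:
        diff = self.solve() - self.cell_exact()
        return float(np.sqrt(np.mean(diff ** 2)))


def manufactured_case(grid: Grid, params: SourceSpec | None = None,
                      amplitude: float = 0.05, c_mean: float = 50.0,
                      c_amp: float = 20.0) -> ManufacturedCase:
    """Build the standard manufactured verification case on a grid."""
    params = params or SourceSpec()
    return ManufacturedCase(grid=grid, amplitude=amplitude,
                            gamma=params.diffusion_m2_s,
                            decay=params.decay_per_s,
                            c_mean=c_mean, c_amp=c_amp)


def synthetic_measurements(truth, grid: Grid, points,
                           noise: NoiseModel = NoiseModel(),
                           device: str = "synthetic",
                           scenario: str = "closed",
                           ach: float = 1.0) -> MeasurementSet:
    """Sample a truth field at points and perturb with the noise model.

    ``truth`` is a RadonField, a cell array on ``grid``, or a callable
    f(x, y, z).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if callable(truth):
        exact = truth(pts[:, 0], pts[:, 1], pts[:, 2])
    else:
        exact = sample_at(truth, grid, pts)
    noisy = noise.apply(np.asarray(exact, dtype=float))
    records = pd.DataFrame({
        "point": [f"P{i}" for i in range(len(pts))],
        "x_m": pts[:, 0], "y_m": pts[:, 1], "z_m": pts[:, 2],
        "concentration_bq_m3": noisy,
    })
    return MeasurementSet(device=device, records=records,
                          scenario=scenario, ach=ach)
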