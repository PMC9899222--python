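"""Steady advection–diffusion–decay transport of radon on a frozen flow.

The activity concentration C (Bq m^-3) obeys

    0 = S + div(Gamma grad C) - div(U C) - lambda C,

discretised by a conservative finite-volume scheme on the structured grid:
first-order upwind advection (positivity preserving), central diffusion
with the effective diffusivity Gamma = D + nu_t / Sc_t, and implicit
decay.  Once the flow is frozen the problem is linear and is solved
directly with a sparse LU factorisation.

Sources enter either as prescribed exhalation fluxes E_i on the solid
surfaces (``boundary_flux`` mode, the physical picture of building
materials emitting radon) or as a uniform volumetric generation rate G
(``volumetric`` mode, the structure of the well-mixed analytical model).
The ventilation inlet carries a purely advective influx at the outdoor
concentration; pressure outlets are zero-diffusive-flux advective
outflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .room import Grid, TAG_INLET, TAG_OUTLET, TAG_WALL, WALLS
from .boxmodel import generation_from_exhalation

# boundary-condition kinds for the scalar kernel
BC_NEUMANN = 0    # prescribed total flux through the face (walls)
BC_INFLOW = 1     # advective influx at a given concentration, no diffusion
BC_OUTFLOW = 2    # advective outflow (upwind), zero diffusive flux
BC_DIRICHLET = 3  # fixed boundary value (used for verification cases)


class TransportError(RuntimeError):
    """Raised when a transport solve fails or is mis-configured."""


@dataclass(frozen=True)
class SourceSpec:
    """Radon source and material parameters.

    ``exhalation_bq_m2_h`` is either one rate for every solid surface or a
    mapping wall-name -> rate (Bq m^-2 h^-1).
    """

    exhalation_bq_m2_h: float | dict = 3.1
    outdoor_bq_m3: float = 10.0
    decay_per_s: float = 2.1e-6
    diffusion_m2_s: float = 1.2e-5
    turbulent_schmidt: float = 0.7

    def __post_init__(self) -> None:
        rates = (self.exhalation_bq_m2_h.values()
                 if isinstance(self.exhalation_bq_m2_h, dict)
                 else [self.exhalation_bq_m2_h])
        if any(r < 0 for r in rates) or self.outdoor_bq_m3 < 0:
            raise TransportError("exhalation rates and outdoor concentration "
                                 "must be non-negative")
        if self.decay_per_s < 0 or self.diffusion_m2_s < 0:
            raise TransportError("decay and diffusion must be non-negative")
        if self.turbulent_schmidt <= 0:
            raise TransportError("turbulent Schmidt number must be positive")

    def exhalation_for(self, wall: str) -> float:
        if isinstance(self.exhalation_bq_m2_h, dict):
            return float(self.exhalation_bq_m2_h.get(wall, 0.0))
        return float(self.exhalation_bq_m2_h)


@dataclass(frozen=True)
class RadonField:
    """Steady concentration field with its balance diagnostics."""

    concentration: np.ndarray   # (nx, ny, nz), Bq m^-3
    volume_average: float       # Bq m^-3
    balance: dict = dc_field(default_factory=dict)

    @property
    def min(self) -> float:
        return float(self.concentration.min())

    @property
    def max(self) -> float:
        return float(self.concentration.max())


def volumetric_generation_rate(exhalation_by_surface: dict[str, float],
                               area_by_surface: dict[str, float],
                               volume: float) -> float:
    """G = sum_i E_i A_i / V in Bq m^-3 h^-1 (see also ``per_second``)."""
    return generation_from_exhalation(exhalation_by_surface, area_by_surface,
                                      volume)


def per_second(rate_per_hour: float) -> float:
    """Convert a Bq m^-3 h^-1 (or h^-1) rate to per-second units."""
    return rate_per_hour / 3600.0


# ---------------------------------------------------------------------------
# generic scalar kernel


def _ravel(grid: Grid):
    nx, ny, nz = grid.shape
    return lambda i, j, k: (i * ny + j) * nz + k


def default_bc_from_tags(grid: Grid, inflow_value: float,
                         face_sources: dict[str, np.ndarray] | None = None):
    """Boundary-condition arrays for the radon problem from the grid tags."""
    bc = {}
    for w in WALLS:
        tags = grid.boundary_tags[w]
        kind = np.full(tags.shape, BC_NEUMANN, dtype=np.int8)
        kind[tags == TAG_INLET] = BC_INFLOW
        kind[tags == TAG_OUTLET] = BC_OUTFLOW
        value = np.full(tags.shape, inflow_value, dtype=float)
        src = (face_sources[w] if face_sources is not None
               else np.zeros(tags.shape))
        bc[w] = (kind, value, src)
    return bc


def solve_scalar(grid: Grid,
                 face_fluxes: tuple[np.ndarray, np.ndarray, np.ndarray],
                 gamma_cells: np.ndarray | float,
                 bc: dict,
                 decay_per_s: float = 0.0,
                 volumetric_source: np.ndarray | float = 0.0) -> np.ndarray:
    """Solve the steady conservative advection–diffusion–decay equation.

    ``face_fluxes`` are volumetric fluxes (m^3 s^-1) on x/y/z faces with
    shapes (nx+1,ny,nz), (nx,ny+1,nz), (nx,ny,nz+1), positive along the
    axis.  ``bc[wall] = (kind, value, face_source)`` arrays over that
    wall's faces; ``volumetric_source`` is Bq s^-1 m^-3 (per cell volume).
    Returns the cell-centred solution array.
    """
    nx, ny, nz = grid.shape
    n = grid.n_cells
    dx, dy, dz = grid.spacing
    vol = grid.cell_volume
    gamma = np.broadcast_to(np.asarray(gamma_cells, dtype=float),
                            grid.shape)

    idx = np.arange(n).reshape(grid.shape)
    a_p = np.full(grid.shape, decay_per_s * vol, dtype=float)
    b = np.full(grid.shape,
                np.broadcast_to(np.asarray(volumetric_source, dtype=float),
                                grid.shape) * vol, dtype=float)

    rows, cols, vals = [], [], []

    def add_links(qf, gface, area, delta, p_idx, e_idx):
        """Interior-face links between cell P (low side) and E (high side)."""
        dcoef = gface * area / delta
        a_e = dcoef + np.maximum(-qf, 0.0)   # coefficient of E in P's eq
        a_w = dcoef + np.maximum(qf, 0.0)    # coefficient of P in E's eq
        rows.append(p_idx.ravel()); cols.append(e_idx.ravel())
        vals.append(-a_e.ravel())
        rows.append(e_idx.ravel()); cols.append(p_idx.ravel())
        vals.append(-a_w.ravel())
        np.add.at(a_p, np.unravel_index(p_idx.ravel(), grid.shape),
                  (dcoef + np.maximum(qf, 0.0)).ravel())
        np.add.at(a_p, np.unravel_index(e_idx.ravel(), grid.shape),
                  (dcoef + np.maximum(-qf, 0.0)).ravel())

    qx, qy, qz = face_fluxes
    # x-direction interior faces
    if nx > 1:
        gf = 0.5 * (gamma[:-1] + gamma[1:])
        add_links(qx[1:-1], gf, dy * dz, dx, idx[:-1], idx[1:])
    if ny > 1:
        gf = 0.5 * (gamma[:, :-1] + gamma[:, 1:])
        add_links(qy[:, 1:-1], gf, dx * dz, dy, idx[:, :-1], idx[:, 1:])
    if nz > 1:
        gf = 0.5 * (gamma[:, :, :-1] + gamma[:, :, 1:])
        add_links(qz[:, :, 1:-1], gf, dx * dy, dz, idx[:, :, :-1],
                  idx[:, :, 1:])

    # boundary faces
    wall_face = {
        "x0": (qx[0], 1.0, (slice(0, 1), slice(None), slice(None)), dy * dz, dx),
        "x1": (qx[-1], -1.0, (slice(nx - 1, nx), slice(None), slice(None)), dy * dz, dx),
        "y0": (qy[:, 0], 1.0, (slice(None), slice(0, 1), slice(None)), dx * dz, dy),
        "y1": (qy[:, -1], -1.0, (slice(None), slice(ny - 1, ny), slice(None)), dx * dz, dy),
        "z0": (qz[:, :, 0], 1.0, (slice(None), slice(None), slice(0, 1)), dx * dy, dz),
        "z1": (qz[:, :, -1], -1.0, (slice(None), slice(None), slice(nz - 1, nz)), dx * dy, dz),
    }
    for w in WALLS:
        qb, inward_sign, cell_slice, area, delta = wall_face[w]
        kind, value, fsrc = bc[w]
        q_in = np.maximum(inward_sign * qb, 0.0)   # volumetric influx
        q_out = np.maximum(-inward_sign * qb, 0.0)  # volumetric outflux
        ap_w = np.zeros(kind.shape)
        b_w = np.zeros(kind.shape)
        is_neu = kind == BC_NEUMANN
        b_w[is_neu] += fsrc[is_neu]
        adv = kind != BC_NEUMANN
        b_w[adv] += (q_in * value)[adv]
        ap_w[adv] += q_out[adv]
        is_dir = kind == BC_DIRICHLET
        if np.any(is_dir):
            gcell = gamma[cell_slice].reshape(kind.shape)
            dcoef = 2.0 * gcell * area / delta
            ap_w[is_dir] += dcoef[is_dir]
            b_w[is_dir] += (dcoef * value)[is_dir]
        a_p[cell_slice] += ap_w.reshape(a_p[cell_slice].shape)
        b[cell_slice] += b_w.reshape(b[cell_slice].shape)

    rows.append(idx.ravel()); cols.append(idx.ravel()); vals.append(a_p.ravel())
    a_mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    sol = spla.spsolve(a_mat, b.ravel())
    if not np.all(np.isfinite(sol)):
        raise TransportError("scalar solve produced non-finite values")
    return sol.reshape(grid.shape)


# ---------------------------------------------------------------------------
# radon-specific driver


def _face_fluxes_from_flow(grid: Grid, flow):
    dx, dy, dz = grid.spacing
    if flow is None:
        nx, ny, nz = grid.shape
        return (np.zeros((nx + 1, ny, nz)), np.zeros((nx, ny + 1, nz)),
                np.zeros((nx, ny, nz + 1)))
    return (flow.u * dy * dz, flow.v * dx * dz, flow.w * dx * dy)


def effective_diffusivity(grid: Grid, flow, src: SourceSpec) -> np.ndarray:
    """Gamma = D + nu_t/Sc_t, cell-centred."""
    gamma = np.full(grid.shape, src.diffusion_m2_s, dtype=float)
    if flow is not None and getattr(flow, "nu_t", None) is not None:
        gamma = gamma + np.broadcast_to(flow.nu_t, grid.shape) / \
            src.turbulent_schmidt
    return gamma


def solve_radon(grid: Grid, flow, src: SourceSpec,
                source_mode: str = "boundary_flux",
                generation_bq_m3_h: float | None = None,
                diffusion_override: float | None = None) -> RadonField:
    """Steady radon field on a converged flow.

    In ``boundary_flux`` mode each solid surface emits its exhalation rate
    E_i; in ``volumetric`` mode a uniform generation rate G (default: Eq.
    G = sum E_i A_i / V from the same exhalation rates, overridable with a
    calibrated value) is applied with zero-flux walls.
    """
    if source_mode not in ("boundary_flux", "volumetric"):
        raise TransportError(f"unknown source mode {source_mode!r}")
    geom = grid.geom
    face_fluxes = _face_fluxes_from_flow(grid, flow)
    gamma = effective_diffusivity(grid, flow, src)
    if diffusion_override is not None:
        gamma = np.full(grid.shape, float(diffusion_override))

    face_sources = {w: np.zeros(grid.boundary_tags[w].shape) for w in WALLS}
    vol_source = 0.0
    if source_mode == "boundary_flux":
        for w in WALLS:
            e_si = per_second(src.exhalation_for(w))  # Bq m^-2 s^-1
            mask = grid.boundary_tags[w] == TAG_WALL
            face_sources[w][mask] = e_si * grid.face_area(w)
    else:
        if generation_bq_m3_h is None:
            areas = {w: geom.wall_area(w) for w in WALLS}
            rates = {w: src.exhalation_for(w) for w in WALLS}
            generation_bq_m3_h = volumetric_generation_rate(rates, areas,
                                                            geom.volume)
        vol_source = per_second(generation_bq_m3_h)

    bc = default_bc_from_tags(grid, src.outdoor_bq_m3, face_sources)
    conc = solve_scalar(grid, face_fluxes, gamma, bc,
                        decay_per_s=src.decay_per_s,
                        volumetric_source=vol_source)
    if conc.min() < -1e-9 * max(1.0, abs(conc.max())):
        raise TransportError(
            f"negative concentration {conc.min():.3e} after solve; "
            "the scheme should be positivity preserving")
    balance = activity_balance(grid, conc, face_fluxes, src, face_sources,
                               vol_source)
    return RadonField(concentration=conc,
                      volume_average=volume_average(conc, grid),
                      balance=balance)


def activity_balance(grid: Grid, conc: np.ndarray, face_fluxes, src,
                     face_sources, vol_source) -> dict:
    """Steady activity budget: sources + inlet advection vs outlet
    advection + decay, all in Bq s^-1, with the relative residual."""
    qx, qy, qz = face_fluxes
    inflow = outflow = 0.0
    boundary_q = {
        "x0": (qx[0], 1.0, conc[0]), "x1": (qx[-1], -1.0, conc[-1]),
        "y0": (qy[:, 0], 1.0, conc[:, 0]), "y1": (qy[:, -1], -1.0, conc[:, -1]),
        "z0": (qz[:, :, 0], 1.0, conc[:, :, 0]),
        "z1": (qz[:, :, -1], -1.0, conc[:, :, -1]),
    }
    for w in WALLS:
        qb, sign, cface = boundary_q[w]
        q_in = np.maximum(sign * qb, 0.0)
        q_out = np.maximum(-sign * qb, 0.0)
        inflow += float(np.sum(q_in) * src.outdoor_bq_m3)
        outflow += float(np.sum(q_out * cface))
    exhalation = float(sum(fs.sum() for fs in face_sources.values()))
    generation = float(np.sum(np.broadcast_to(vol_source, grid.shape))
                       * grid.cell_volume)
    decay = float(np.sum(conc) * grid.cell_volume * src.decay_per_s)
    total_in = exhalation + generation + inflow
    total_out = outflow + decay
    scale = max(total_in, total_out, 1e-300)
    return {
        "exhalation_bq_s": exhalation,
        "generation_bq_s": generation,
        "inlet_advective_bq_s": inflow,
        "outlet_advective_bq_s": outflow,
        "decay_bq_s": decay,
        "relative_residual": abs(total_in - total_out) / scale,
    }


def volume_average(field, grid: Grid) -> float:
    """Volume-weighted mean concentration (uniform cells -> plain mean)."""
    conc = field.concentration if isinstance(field, RadonField) else field
    return float(np.mean(conc))


def sample_at(field, grid: Grid, points) -> np.ndarray:
    """Trilinear interpolation of the field at physical points (m).

    Points must lie inside the room; coordinates inside the boundary
    half-cells are clamped to the nearest cell-centre plane (constant
    extrapolation), matching how a detector against a wall reads the
    adjacent air.
    """
    conc = field.concentration if isinstance(field, RadonField) else field
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise TransportError("points must be (n, 3) (x, y, z) in metres")
    geom = grid.geom
    lims = np.array([geom.lx, geom.ly, geom.lz])
    bad = np.any((pts < -1e-12) | (pts > lims + 1e-12), axis=1)
    if np.any(bad):
        raise TransportError(
            f"point(s) outside the room: {pts[bad].tolist()}")
    x, y, z = grid.cell_centers
    interp = RegularGridInterpolator((x, y, z), conc, method="linear",
                                     bounds_error=False)
    clamped = np.clip(pts, [x[0], y[0], z[0]], [x[-1], y[-1], z[-1]])
    return interp(clamped)


def layer_mean(field, grid: Grid, z_max: float) -> float:
    """Mean concentration of the layer z < z_max (e.g. floor-adjacent air)."""
    conc = field.concentration if isinstance(field, RadonField) else field
    _, _, z = grid.cell_centers
    mask = z < z_max
    if not np.any(mask):
        raise TransportError(f"no cell centres below z = {z_max}")
    return float(conc[:, :, mask].mean())
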