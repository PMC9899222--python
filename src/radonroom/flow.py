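"""Steady incompressible room airflow by SIMPLE on a staggered grid.

The solver advances the discrete continuity and momentum equations

    div(U) = 0,
    div(rho U u_i) = -dP/dx_i + div(mu_e grad u_i),

to a steady state with SIMPLE pressure–velocity coupling: an
under-relaxed momentum predictor (hybrid central/upwind finite-volume
scheme), followed by a pressure-correction Poisson solve whose
correction restores discrete continuity in every cell, every iteration.
The pressure-correction matrix uses fixed (diffusion-based) face
coefficients, so it is factorised once per run; because velocity
corrections use the same coefficients, mass conservation is exact
regardless of that approximation — only the convergence rate depends on
it.

Viscosity closure is either a constant effective viscosity (default: the
zero-equation estimate nu_t = 0.03874 U_in H for ventilated enclosures)
or the standard k-epsilon model (see ``turbulence``).

Boundary conditions: fixed uniform normal velocity on inlet patches,
no-slip walls (optionally free-slip or tangentially moving, used by
verification presets), and pressure outlets with zero-gradient velocity
that absorb the ventilation flow.  Outlet fluxes are rescaled to the
inlet flow every iteration, so the global mass balance is exact by
construction once the field is converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .room import Grid, TAG_INLET, TAG_OUTLET, WALLS
from .air import AirProperties, VentilationSpec, air_properties

#: zero-equation turbulent-viscosity constant for room airflow
ZERO_EQUATION_COEFF = 0.03874

_AXIS_WALLS = (("x0", "x1"), ("y0", "y1"), ("z0", "z1"))


class FlowSolverError(RuntimeError):
    """Raised when the flow solve is mis-configured or fails to converge."""


@dataclass
class SolverSettings:
    """Numerical settings of the SIMPLE loop."""

    closure: str = "constant_nu_eff"      # or "k_epsilon"
    tolerance: float = 1e-6               # relative successive-change criterion
    max_iterations: int = 5000
    alpha_u: float = 0.7                  # momentum under-relaxation
    alpha_p: float = 0.3                  # pressure under-relaxation
    alpha_turb: float = 0.5               # k/eps under-relaxation
    advection_scheme: str = "hybrid"      # or "upwind"
    n_sweeps: int = 4                     # Jacobi sweeps per momentum solve
    nu_eff: float | None = None           # constant-closure nu_t override
    turb_every: int = 2                   # k-eps update cadence (iterations)
    mu_t_floor_fraction: float = 0.25     # k-eps stabilising viscosity floor

    def __post_init__(self) -> None:
        if self.closure not in ("constant_nu_eff", "k_epsilon"):
            raise FlowSolverError(f"unknown closure {self.closure!r}")
        if self.advection_scheme not in ("hybrid", "upwind"):
            raise FlowSolverError(
                f"unknown advection scheme {self.advection_scheme!r}")
        if not (0 < self.alpha_u <= 1 and 0 < self.alpha_p <= 1
                and 0 < self.alpha_turb <= 1):
            raise FlowSolverError("under-relaxation factors must lie in (0, 1]")
        if self.tolerance <= 0:
            raise FlowSolverError("tolerance must be positive")


@dataclass
class FlowBCs:
    """Per-wall boundary data for the velocity field.

    ``normal_value[wall]``: fixed *inward* normal speed per face (0 on
    solid walls, the inlet speed on inlet faces, NaN on pressure-outlet
    faces whose velocity is solved for).
    ``tangential_factor[wall]``: 1 for no-slip, 0 for free-slip /
    zero-gradient, per face.
    ``wall_velocity[wall]``: tangential wall velocity vector (moving-lid
    presets).
    """

    normal_value: dict[str, np.ndarray]
    tangential_factor: dict[str, np.ndarray]
    wall_velocity: dict[str, np.ndarray] = dc_field(default_factory=dict)

    @classmethod
    def from_grid(cls, grid: Grid, inlet_speed: float,
                  slip_walls: tuple[str, ...] = ()) -> "FlowBCs":
        normal, tang = {}, {}
        for w in WALLS:
            tags = grid.boundary_tags[w]
            nv = np.zeros(tags.shape)
            nv[tags == TAG_INLET] = inlet_speed
            nv[tags == TAG_OUTLET] = np.nan
            tf = np.where(tags == TAG_OUTLET, 0.0, 1.0)
            if w in slip_walls:
                tf[:] = 0.0
                nv[:] = 0.0
            normal[w], tang[w] = nv, tf
        return cls(normal_value=normal, tangential_factor=tang)

    def reference_speed(self) -> float:
        mags = [np.nanmax(np.abs(v), initial=0.0)
                for v in self.normal_value.values()]
        mags += [float(np.max(np.abs(v), initial=0.0))
                 for v in self.wall_velocity.values()]
        return max(mags + [0.0])


@dataclass
class FlowField:
    """Converged staggered velocity field and companions."""

    u: np.ndarray               # (nx+1, ny, nz) m/s
    v: np.ndarray               # (nx, ny+1, nz)
    w: np.ndarray               # (nx, ny, nz+1)
    p: np.ndarray               # (nx, ny, nz) relative pressure, Pa
    rho: float
    mu: float
    mu_t: np.ndarray | float    # turbulent viscosity, Pa s (cell or scalar)
    k: np.ndarray | None = None
    eps: np.ndarray | None = None
    residual_history: list = dc_field(default_factory=list)
    converged: bool = False
    mass_balance: dict = dc_field(default_factory=dict)

    @property
    def nu_t(self) -> np.ndarray | float:
        return (self.mu_t / self.rho if np.isscalar(self.mu_t)
                else np.asarray(self.mu_t) / self.rho)

    def cell_velocity(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell-centred velocity components."""
        return (0.5 * (self.u[:-1] + self.u[1:]),
                0.5 * (self.v[:, :-1] + self.v[:, 1:]),
                0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:]))

    def speed(self) -> np.ndarray:
        uc, vc, wc = self.cell_velocity()
        return np.sqrt(uc ** 2 + vc ** 2 + wc ** 2)


def zero_flow(grid: Grid, air: AirProperties | None = None) -> FlowField:
    """A quiescent flow field (useful for diffusion-only transport)."""
    air = air or air_properties()
    nx, ny, nz = grid.shape
    return FlowField(u=np.zeros((nx + 1, ny, nz)),
                     v=np.zeros((nx, ny + 1, nz)),
                     w=np.zeros((nx, ny, nz + 1)),
                     p=np.zeros((nx, ny, nz)),
                     rho=air.density, mu=air.dynamic_viscosity, mu_t=0.0,
                     converged=True)


# ---------------------------------------------------------------------------
# helpers


def _perm_wall(arr: np.ndarray, wall: str, perm: tuple[int, int, int]
               ) -> np.ndarray:
    """A wall-face array re-ordered to the permuted axis frame."""
    ax = {"x": 0, "y": 1, "z": 2}[wall[0]]
    natural = tuple(sorted({0, 1, 2} - {ax}))
    want = tuple(p for p in perm if p != ax)
    return arr if want == natural else arr.T


def divergence(grid: Grid, u: np.ndarray, v: np.ndarray,
               w: np.ndarray) -> np.ndarray:
    """Per-cell net volumetric outflux (m^3/s)."""
    dx, dy, dz = grid.spacing
    return ((u[1:] - u[:-1]) * dy * dz
            + (v[:, 1:] - v[:, :-1]) * dx * dz
            + (w[:, :, 1:] - w[:, :, :-1]) * dx * dy)


def check_continuity(field: FlowField, grid: Grid) -> dict:
    """Max and RMS scaled divergence of a flow field.

    Divergence is scaled by a reference flux (the largest face flux
    magnitude), so the numbers are resolution-independent.
    """
    div = divergence(grid, field.u, field.v, field.w)
    dx, dy, dz = grid.spacing
    ref = max(np.abs(field.u).max() * dy * dz,
              np.abs(field.v).max() * dx * dz,
              np.abs(field.w).max() * dx * dy, 1e-300)
    return {"max_scaled": float(np.abs(div).max() / ref),
            "rms_scaled": float(np.sqrt(np.mean(div ** 2)) / ref),
            "divergence": div}


def bcs_for_room(grid: Grid, vent: VentilationSpec) -> FlowBCs:
    """Room boundary conditions with the inlet speed adjusted to the
    snapped window area, preserving the exact ACH volume flow."""
    a_inlet = grid.tagged_area(TAG_INLET)
    if a_inlet <= 0:
        raise FlowSolverError("grid has no inlet faces")
    if grid.tagged_area(TAG_OUTLET) <= 0:
        raise FlowSolverError("grid has no pressure-outlet faces")
    speed = vent.volumetric_flow / a_inlet
    return FlowBCs.from_grid(grid, inlet_speed=speed)


# ---------------------------------------------------------------------------
# the SIMPLE solver


class _Simple:
    """One solver instance; holds the factorised pressure matrix."""

    def __init__(self, grid: Grid, bcs: FlowBCs, air: AirProperties,
                 settings: SolverSettings):
        self.grid, self.bcs, self.air, self.settings = grid, bcs, air, settings
        self.rho = air.density
        self.mu = air.dynamic_viscosity
        nx, ny, nz = grid.shape
        self.vel = [np.zeros((nx + 1, ny, nz)), np.zeros((nx, ny + 1, nz)),
                    np.zeros((nx, ny, nz + 1))]
        self.p = np.zeros(grid.shape)
        self.mu_t: np.ndarray | float = 0.0
        self.k = self.eps = None
        self.u_ref = max(bcs.reference_speed(), 1e-300)
        self._apply_fixed_normals()
        self._base_mu_eff = self._initial_mu_eff()
        # rescales the pressure update when the actual effective viscosity
        # departs from the one the (fixed) correction matrix was built
        # with; the velocity corrections are self-consistent either way
        self.p_scale = 1.0
        self._build_pressure_matrix()

    # -- setup ----------------------------------------------------------

    def _initial_mu_eff(self) -> float:
        s = self.settings
        if s.closure == "constant_nu_eff" and s.nu_eff is not None:
            return self.mu + self.rho * s.nu_eff
        # zero-equation estimate with the room height as the length scale
        length = self.grid.geom.lz
        return self.mu + self.rho * ZERO_EQUATION_COEFF * self.u_ref * length

    def _apply_fixed_normals(self) -> None:
        """Impose fixed inward-normal velocities on boundary faces."""
        for axis, (wlo, whi) in enumerate(_AXIS_WALLS):
            arr = self.vel[axis]
            for wall, side in ((wlo, 0), (whi, -1)):
                nv = self.bcs.normal_value[wall]
                fixed = ~np.isnan(nv)
                sign = 1.0 if side == 0 else -1.0
                face = arr[side] if axis == 0 else (
                    arr[:, side] if axis == 1 else arr[:, :, side])
                face[fixed] = sign * nv[fixed]

    def _outlet_masks(self, axis: int):
        wlo, whi = _AXIS_WALLS[axis]
        return (np.isnan(self.bcs.normal_value[wlo]),
                np.isnan(self.bcs.normal_value[whi]))

    def _build_pressure_matrix(self) -> None:
        g = self.grid
        nx, ny, nz = g.shape
        dx, dy, dz = g.spacing
        areas = (dy * dz, dx * dz, dx * dy)
        spacings = (dx, dy, dz)
        alpha = self.settings.alpha_u
        mu0 = self._base_mu_eff
        # diffusion-only momentum diagonal per component (relaxed)
        self.d_face = []
        # diffusion-only CV diagonal: sum of D = mu*A_f/delta_f over 6 faces
        a_p0 = 2.0 * mu0 * sum(areas[a] / spacings[a] for a in range(3))
        for axis in range(3):
            self.d_face.append(areas[axis] / (a_p0 / alpha))
        n = g.n_cells
        idx = np.arange(n).reshape(g.shape)
        rows, cols, vals = [], [], []
        diag = np.zeros(g.shape)

        def link(pi, ei, coef):
            rows.append(pi.ravel()); cols.append(ei.ravel())
            vals.append(np.full(pi.size, -coef))
            rows.append(ei.ravel()); cols.append(pi.ravel())
            vals.append(np.full(pi.size, -coef))

        coefs = [self.d_face[a] * areas[a] for a in range(3)]
        if nx > 1:
            link(idx[:-1], idx[1:], coefs[0])
            diag[:-1] += coefs[0]; diag[1:] += coefs[0]
        if ny > 1:
            link(idx[:, :-1], idx[:, 1:], coefs[1])
            diag[:, :-1] += coefs[1]; diag[:, 1:] += coefs[1]
        if nz > 1:
            link(idx[:, :, :-1], idx[:, :, 1:], coefs[2])
            diag[:, :, :-1] += coefs[2]; diag[:, :, 1:] += coefs[2]

        self.has_outlet = False
        cell_slices = {
            "x0": (0,), "x1": (nx - 1,),
            "y0": (slice(None), 0), "y1": (slice(None), ny - 1),
            "z0": (slice(None), slice(None), 0),
            "z1": (slice(None), slice(None), nz - 1)}
        for axis, (wlo, whi) in enumerate(_AXIS_WALLS):
            for wall in (wlo, whi):
                outlet = np.isnan(self.bcs.normal_value[wall])
                if np.any(outlet):
                    self.has_outlet = True
                    add = np.where(outlet, coefs[axis], 0.0)
                    diag[cell_slices[wall]] += add
        if not self.has_outlet:
            diag.flat[0] += diag.flat[0]  # pin the pressure level
        rows.append(idx.ravel()); cols.append(idx.ravel())
        vals.append(diag.ravel())
        mat = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n))
        self._plu = spla.splu(mat)

    # -- per-iteration pieces -------------------------------------------

    def _mu_eff_cells(self) -> np.ndarray | float:
        if self.settings.closure == "constant_nu_eff":
            return self._base_mu_eff
        # stabilising floor: at desk-scale resolution the wall-function
        # k-eps viscosity collapses below the level at which the steady
        # coupled iteration is stable (y+ far below the log-law range), so
        # the model viscosity is floored at a fraction of the zero-equation
        # estimate
        floor = self.settings.mu_t_floor_fraction * (self._base_mu_eff
                                                     - self.mu)
        return self.mu + np.maximum(self.mu_t, floor)

    def _momentum_component(self, m: int, mu_eff) -> float:
        """Assemble and sweep one velocity component; returns max change."""
        g, s = self.grid, self.settings
        rho, alpha = self.rho, s.alpha_u
        perm = (m, (m + 1) % 3, (m + 2) % 3)
        shape = tuple(g.shape[a] for a in perm)
        n0, n1, n2 = shape
        d0, d1, d2 = (g.spacing[a] for a in perm)
        a0, a1, a2 = d1 * d2, d0 * d2, d0 * d1

        v0 = self.vel[perm[0]].transpose(perm)
        v1 = self.vel[perm[1]].transpose(perm)
        v2 = self.vel[perm[2]].transpose(perm)
        p_t = self.p.transpose(perm)

        # face mass fluxes of the component CV (shape (n0-1, n1, n2))
        f0p = rho * a0 * 0.5 * (v0[1:-1] + v0[2:])
        f0m = rho * a0 * 0.5 * (v0[:-2] + v0[1:-1])
        f1p = rho * a1 * 0.5 * (v1[:-1, 1:, :] + v1[1:, 1:, :])
        f1m = rho * a1 * 0.5 * (v1[:-1, :-1, :] + v1[1:, :-1, :])
        f2p = rho * a2 * 0.5 * (v2[:-1, :, 1:] + v2[1:, :, 1:])
        f2m = rho * a2 * 0.5 * (v2[:-1, :, :-1] + v2[1:, :, :-1])

        if np.isscalar(mu_eff):
            mu0p = mu0m = np.full((1, 1, 1), mu_eff)
            mu1 = mu2 = np.full((1, 1, 1), mu_eff)
        else:
            mu_c = np.asarray(mu_eff).transpose(perm)
            mu_node = 0.5 * (mu_c[:-1] + mu_c[1:])      # at CV centres
            mu0p = mu_c[1:]                              # east face = cell i
            mu0m = mu_c[:-1]                             # west face = cell i-1
            mu1 = np.empty((n0 - 1, n1 + 1, n2))
            mu1[:, 1:-1, :] = 0.5 * (mu_node[:, :-1, :] + mu_node[:, 1:, :])
            mu1[:, 0, :] = mu_node[:, 0, :]
            mu1[:, -1, :] = mu_node[:, -1, :]
            mu2 = np.empty((n0 - 1, n1, n2 + 1))
            mu2[:, :, 1:-1] = 0.5 * (mu_node[:, :, :-1] + mu_node[:, :, 1:])
            mu2[:, :, 0] = mu_node[:, :, 0]
            mu2[:, :, -1] = mu_node[:, :, -1]

        dd0p = mu0p * a0 / d0
        dd0m = mu0m * a0 / d0
        if np.isscalar(mu_eff):
            dd1p = dd1m = mu_eff * a1 / d1
            dd1s = mu_eff * a1 / d1
            dd2p = dd2m = mu_eff * a2 / d2
            dd2s = mu_eff * a2 / d2
        else:
            dd1p = mu1[:, 1:, :] * a1 / d1
            dd1m = mu1[:, :-1, :] * a1 / d1
            dd1s = mu1 * a1 / d1
            dd2p = mu2[:, :, 1:] * a2 / d2
            dd2m = mu2[:, :, :-1] * a2 / d2
            dd2s = mu2 * a2 / d2

        if s.advection_scheme == "hybrid":
            a_e = np.maximum(np.maximum(-f0p, dd0p - 0.5 * f0p), 0.0)
            a_w = np.maximum(np.maximum(f0m, dd0m + 0.5 * f0m), 0.0)
            a_n = np.maximum(np.maximum(-f1p, dd1p - 0.5 * f1p), 0.0)
            a_s = np.maximum(np.maximum(f1m, dd1m + 0.5 * f1m), 0.0)
            a_t = np.maximum(np.maximum(-f2p, dd2p - 0.5 * f2p), 0.0)
            a_b = np.maximum(np.maximum(f2m, dd2m + 0.5 * f2m), 0.0)
        else:
            a_e = dd0p + np.maximum(-f0p, 0.0)
            a_w = dd0m + np.maximum(f0m, 0.0)
            a_n = dd1p + np.maximum(-f1p, 0.0)
            a_s = dd1m + np.maximum(f1m, 0.0)
            a_t = dd2p + np.maximum(-f2p, 0.0)
            a_b = dd2m + np.maximum(f2m, 0.0)
        a_e = np.broadcast_to(a_e, (n0 - 1, n1, n2)).copy()
        a_w = np.broadcast_to(a_w, (n0 - 1, n1, n2)).copy()
        a_n = np.broadcast_to(a_n, (n0 - 1, n1, n2)).copy()
        a_s = np.broadcast_to(a_s, (n0 - 1, n1, n2)).copy()
        a_t = np.broadcast_to(a_t, (n0 - 1, n1, n2)).copy()
        a_b = np.broadcast_to(a_b, (n0 - 1, n1, n2)).copy()

        b = (p_t[:-1] - p_t[1:]) * a0
        a_p = np.zeros((n0 - 1, n1, n2))

        # transverse walls: fold the missing neighbour into wall shear
        for trans, (a_lo, a_hi, dd_side) in (
                (1, (a_s, a_n, dd1s)), (2, (a_b, a_t, dd2s))):
            wall_axis = perm[trans]
            wlo, whi = _AXIS_WALLS[wall_axis]
            for wall, hi in ((wlo, False), (whi, True)):
                tf = _perm_wall(self.bcs.tangential_factor[wall], wall, perm)
                # tf is over p-cell faces (n0, n_other); average to CV nodes
                tf_node = 0.5 * (tf[:-1] + tf[1:])       # (n0-1, n_other)
                wv = self.bcs.wall_velocity.get(wall)
                uw = 0.0 if wv is None else float(wv[perm[0]])
                if trans == 1:
                    sl = (slice(None), -1 if hi else 0, slice(None))
                else:
                    sl = (slice(None), slice(None), -1 if hi else 0)
                dd_w = dd_side[sl] if not np.isscalar(dd_side) else dd_side
                shear = 2.0 * dd_w * tf_node
                coef_arr = a_hi if hi else a_lo
                coef_arr[sl] = 0.0
                a_p[sl] += shear
                if uw:
                    b[sl] += shear * uw

        # net CV outflux; clipped at zero so the diagonal stays positive
        # while continuity is still converging (the term vanishes at
        # convergence)
        dflux = np.maximum((f0p - f0m) + (f1p - f1m) + (f2p - f2m), 0.0)
        a_p += a_e + a_w + a_n + a_s + a_t + a_b + dflux
        a_p = np.maximum(a_p, 1e-300)
        a_p_rel = a_p / alpha
        v_old = v0[1:-1].copy()
        b = b + (1.0 - alpha) * a_p_rel * v_old

        pad = ((0, 0), (1, 1), (1, 1))
        for _ in range(s.n_sweeps):
            vp = np.pad(v0[1:-1], pad)
            num = (a_e * v0[2:] + a_w * v0[:-2]
                   + a_n * vp[:, 2:, 1:-1] + a_s * vp[:, :-2, 1:-1]
                   + a_t * vp[:, 1:-1, 2:] + a_b * vp[:, 1:-1, :-2]
                   + b)
            v0[1:-1] = num / a_p_rel
        return float(np.max(np.abs(v0[1:-1] - v_old)))

    def _inlet_flow(self) -> float:
        q = 0.0
        for axis, (wlo, whi) in enumerate(_AXIS_WALLS):
            area = [self.grid.dy * self.grid.dz,
                    self.grid.dx * self.grid.dz,
                    self.grid.dx * self.grid.dy][axis]
            for wall in (wlo, whi):
                nv = self.bcs.normal_value[wall]
                q += np.nansum(np.where(np.isnan(nv), 0.0, nv)) * area
        return float(q)

    def _outlet_faces(self):
        """Yield (axis, side_index, mask, area, outward_sign)."""
        g = self.grid
        areas = (g.dy * g.dz, g.dx * g.dz, g.dx * g.dy)
        for axis, (wlo, whi) in enumerate(_AXIS_WALLS):
            for wall, side, outward in ((wlo, 0, -1.0), (whi, -1, 1.0)):
                mask = np.isnan(self.bcs.normal_value[wall])
                if np.any(mask):
                    yield axis, side, mask, areas[axis], outward

    def _face_view(self, axis: int, side: int) -> np.ndarray:
        arr = self.vel[axis]
        if axis == 0:
            return arr[side]
        if axis == 1:
            return arr[:, side]
        return arr[:, :, side]

    def _interior_face_view(self, axis: int, side: int) -> np.ndarray:
        arr = self.vel[axis]
        inner = 1 if side == 0 else -2
        if axis == 0:
            return arr[inner]
        if axis == 1:
            return arr[:, inner]
        return arr[:, :, inner]

    def _update_outlets(self, q_in: float) -> None:
        outlets = list(self._outlet_faces())
        if not outlets:
            return
        q_out = 0.0
        a_out = 0.0
        for axis, side, mask, area, outward in outlets:
            face = self._face_view(axis, side)
            face[mask] = self._interior_face_view(axis, side)[mask]
            q_out += float(np.sum(outward * face[mask]) * area)
            a_out += float(np.count_nonzero(mask)) * area
        if q_in <= 0:
            return
        if q_out > 1e-14 * max(q_in, 1.0):
            factor = q_in / q_out
            for axis, side, mask, area, outward in outlets:
                face = self._face_view(axis, side)
                face[mask] *= factor
        else:
            for axis, side, mask, area, outward in outlets:
                face = self._face_view(axis, side)
                face[mask] = outward * q_in / a_out

    def _pressure_correction(self) -> float:
        g = self.grid
        div = divergence(g, *self.vel)
        rhs = -div.ravel()
        p_prime = self._plu.solve(rhs).reshape(g.shape)
        dpx, dpy, dpz = self.d_face
        self.vel[0][1:-1] += dpx * (p_prime[:-1] - p_prime[1:])
        self.vel[1][:, 1:-1] += dpy * (p_prime[:, :-1] - p_prime[:, 1:])
        self.vel[2][:, :, 1:-1] += dpz * (p_prime[:, :, :-1] - p_prime[:, :, 1:])
        for axis, side, mask, area, outward in self._outlet_faces():
            face = self._face_view(axis, side)
            cells = [p_prime[0], p_prime[-1], p_prime[:, 0], p_prime[:, -1],
                     p_prime[:, :, 0], p_prime[:, :, -1]]
            cell_p = cells[2 * axis + (0 if side == 0 else 1)]
            d = self.d_face[axis]
            # correction toward the zero-pressure ghost outside the outlet
            face[mask] += d * (-cell_p[mask] if side == 0 else cell_p[mask])
        self.p += self.settings.alpha_p * self.p_scale * p_prime
        if not self.has_outlet:
            self.p -= self.p.mean()
        return float(np.abs(div).sum())

    # -- main loop -------------------------------------------------------

    def solve(self) -> FlowField:
        from . import turbulence

        s = self.settings
        g = self.grid
        q_in = self._inlet_flow()
        u_ref = self.u_ref
        if u_ref <= 1e-300:
            return self._result([], converged=True)
        flux_ref = max(q_in, u_ref * min(g.dy * g.dz, g.dx * g.dz,
                                         g.dx * g.dy))
        if s.closure == "k_epsilon":
            self.k, self.eps, self.mu_t = turbulence.initial_state(
                g, self.air, u_ref)
        history = []
        for it in range(1, s.max_iterations + 1):
            mu_eff = self._mu_eff_cells()
            if not np.isscalar(mu_eff):
                self.p_scale = float(np.mean(mu_eff)) / self._base_mu_eff
            dmax = 0.0
            for m in range(3):
                dmax = max(dmax, self._momentum_component(m, mu_eff))
            self._update_outlets(q_in)
            div_sum = self._pressure_correction()
            if s.closure == "k_epsilon" and it % s.turb_every == 0:
                self.k, self.eps, self.mu_t = turbulence.k_epsilon_step(
                    (self.k, self.eps, self.mu_t), g, s,
                    self._flow_snapshot(), self.air, self.bcs)
            res_mom = dmax / u_ref
            res_cont = div_sum / max(flux_ref, 1e-300)
            history.append((it, res_mom, res_cont))
            if res_mom < s.tolerance and res_cont < s.tolerance:
                return self._result(history, converged=True)
        raise FlowSolverError(
            f"flow solver did not converge in {s.max_iterations} iterations "
            f"(last momentum residual {history[-1][1]:.3e}, continuity "
            f"{history[-1][2]:.3e}); residual history attached",
        )

    def _flow_snapshot(self) -> FlowField:
        return FlowField(u=self.vel[0], v=self.vel[1], w=self.vel[2],
                         p=self.p, rho=self.rho, mu=self.mu, mu_t=self.mu_t,
                         k=self.k, eps=self.eps)

    def _mass_balance(self, q_in: float) -> dict:
        q_out = 0.0
        for axis, side, mask, area, outward in self._outlet_faces():
            face = self._face_view(axis, side)
            q_out += float(np.sum(outward * face[mask]) * area)
        rel = abs(q_in - q_out) / max(q_in, 1e-300) if q_in > 0 else 0.0
        return {"inlet_m3_s": q_in, "outlet_m3_s": q_out,
                "relative_imbalance": rel}

    def _result(self, history, converged: bool) -> FlowField:
        q_in = self._inlet_flow()
        if self.settings.closure == "constant_nu_eff":
            mu_t = self._base_mu_eff - self.mu
        else:
            # report the effective (floored) turbulent viscosity so scalar
            # transport sees the same mixing as the momentum equations
            mu_t = np.asarray(self._mu_eff_cells()) - self.mu
        return FlowField(u=self.vel[0], v=self.vel[1], w=self.vel[2],
                         p=self.p, rho=self.rho, mu=self.mu, mu_t=mu_t,
                         k=self.k, eps=self.eps,
                         residual_history=history, converged=converged,
                         mass_balance=self._mass_balance(q_in))


def solve_flow(grid: Grid, vent: VentilationSpec | None = None,
               air: AirProperties | None = None,
               settings: SolverSettings | None = None,
               bcs: FlowBCs | None = None) -> FlowField:
    """Solve the steady room airflow.

    Either pass a :class:`VentilationSpec` (room configuration: window
    inlet at the ACH-derived speed, pressure outlets from the grid tags)
    or explicit :class:`FlowBCs` (verification presets).  Raises
    :class:`FlowSolverError` on non-convergence, with the residual
    history in the message.
    """
    air = air or air_properties()
    settings = settings or SolverSettings()
    if bcs is None:
        if vent is None:
            raise FlowSolverError("need either a VentilationSpec or FlowBCs")
        bcs = bcs_for_room(grid, vent)
    return _Simple(grid, bcs, air, settings).solve()


def lid_driven_cavity(n: int = 48, reynolds: float = 100.0,
                      settings: SolverSettings | None = None):
    """Lid-driven cavity verification preset (quasi-2D, free-slip span).

    A unit square cavity (x: 0..1, y: 0..1) with the y = 1 wall sliding at
    unit speed in +x; the short z span uses free-slip walls so the solution
    is two-dimensional.  Returns (grid, field).
    """
    from .room import box_grid

    nz = 4
    grid = box_grid(1.0, 1.0, nz / n, (n, n, nz))
    bcs = FlowBCs.from_grid(grid, inlet_speed=0.0, slip_walls=("z0", "z1"))
    bcs.wall_velocity["y1"] = np.array([1.0, 0.0, 0.0])
    air = AirProperties(temperature_c=20.0, relative_humidity=0.0,
                        pressure_pa=101325.0, density=1.0,
                        dynamic_viscosity=1.0 / reynolds)
    settings = settings or SolverSettings(
        closure="constant_nu_eff", nu_eff=0.0, advection_scheme="hybrid",
        tolerance=2e-6, max_iterations=20000, alpha_u=0.7, alpha_p=0.3)
    field = solve_flow(grid, air=air, settings=settings, bcs=bcs)
    return grid, field
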