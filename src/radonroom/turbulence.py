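"""Standard k-epsilon closure for the room-airflow solver.

Two transport equations for turbulent kinetic energy k and its
dissipation rate eps, with the canonical constants
C_mu = 0.09, C1 = 1.44, C2 = 1.92, sigma_k = 1.0, sigma_eps = 1.3 and
log-law wall treatment in wall-adjacent cells.  The turbulent viscosity
is mu_t = rho C_mu k^2 / eps.

The update is a single under-relaxed upwind finite-volume step per call;
the flow solver calls it repeatedly inside its outer iteration, so k and
eps converge together with the mean flow.
"""

from __future__ import annotations

import numpy as np

from .room import Grid, TAG_WALL, WALLS

C_MU = 0.09
C1_EPS = 1.44
C2_EPS = 1.92
SIGMA_K = 1.0
SIGMA_EPS = 1.3
KAPPA = 0.41

#: default inlet turbulence: 5% intensity, length scale 0.07 x opening size
INLET_INTENSITY = 0.05
INLET_LENGTH_FRACTION = 0.07

K_FLOOR = 1e-12
EPS_FLOOR = 1e-14
MU_T_RATIO_CAP = 1e5


def inlet_conditions(u_ref: float, length_scale: float
                     ) -> tuple[float, float]:
    """(k, eps) from turbulence intensity and mixing length."""
    k_in = max(1.5 * (u_ref * INLET_INTENSITY) ** 2, K_FLOOR)
    ell = max(INLET_LENGTH_FRACTION * length_scale, 1e-6)
    eps_in = max(C_MU ** 0.75 * k_in ** 1.5 / ell, EPS_FLOOR)
    return k_in, eps_in


def initial_state(grid: Grid, air, u_ref: float):
    """Uniform initial k, eps, mu_t fields from the inlet estimate."""
    length = min(grid.geom.lx, grid.geom.ly, grid.geom.lz)
    k_in, eps_in = inlet_conditions(u_ref, length)
    k = np.full(grid.shape, k_in)
    eps = np.full(grid.shape, eps_in)
    mu_t = turbulent_viscosity(k, eps, air.density, air.dynamic_viscosity)
    return k, eps, mu_t


def turbulent_viscosity(k: np.ndarray, eps: np.ndarray, rho: float,
                        mu: float) -> np.ndarray:
    """mu_t = rho C_mu k^2/eps, floored and capped for robustness."""
    mu_t = rho * C_MU * np.maximum(k, K_FLOOR) ** 2 / np.maximum(eps, EPS_FLOOR)
    return np.clip(mu_t, 0.0, MU_T_RATIO_CAP * mu)


def strain_rate_squared(grid: Grid, flow) -> np.ndarray:
    """2 S_ij S_ij from cell-centred velocity gradients."""
    uc, vc, wc = flow.cell_velocity()
    dx, dy, dz = grid.spacing
    ux, uy, uz = np.gradient(uc, dx, dy, dz)
    vx, vy, vz = np.gradient(vc, dx, dy, dz)
    wx, wy, wz = np.gradient(wc, dx, dy, dz)
    return (2.0 * (ux ** 2 + vy ** 2 + wz ** 2)
            + (uy + vx) ** 2 + (uz + wx) ** 2 + (vz + wy) ** 2)


def _wall_adjacent_masks(grid: Grid):
    """Boolean cell masks of the first layer next to each no-slip wall,
    with the wall-normal half-spacing."""
    nx, ny, nz = grid.shape
    dx, dy, dz = grid.spacing
    out = []
    sl = {
        "x0": ((0,), dx / 2), "x1": ((nx - 1,), dx / 2),
        "y0": ((slice(None), 0), dy / 2), "y1": ((slice(None), ny - 1), dy / 2),
        "z0": ((slice(None), slice(None), 0), dz / 2),
        "z1": ((slice(None), slice(None), nz - 1), dz / 2),
    }
    for w in WALLS:
        cells, delta = sl[w]
        wall_faces = grid.boundary_tags[w] == TAG_WALL
        out.append((w, cells, wall_faces, delta))
    return out


def _upwind_scalar_update(grid: Grid, phi: np.ndarray, fluxes, gamma,
                          source: np.ndarray, sink_coef: np.ndarray,
                          bc_value: float, alpha: float,
                          inflow_masks) -> np.ndarray:
    """One under-relaxed Jacobi step of an upwind transport equation.

    ``sink_coef`` multiplies phi implicitly (positive, stabilising);
    ``bc_value`` is carried in through inflow boundary faces.
    """
    dx, dy, dz = grid.spacing
    vol = grid.cell_volume
    qx, qy, qz = fluxes
    areas = (dy * dz, dx * dz, dx * dy)
    spacings = (dx, dy, dz)

    a_p = sink_coef * vol
    num = source * vol

    gamma = np.broadcast_to(gamma, grid.shape)

    for axis in range(3):
        q = (qx, qy, qz)[axis]

        def faceslice(lo, hi):
            s = [slice(None)] * 3
            s[axis] = slice(lo, hi)
            return tuple(s)

        g_lo = gamma[faceslice(None, -1)]
        g_hi = gamma[faceslice(1, None)]
        gf = 0.5 * (g_lo + g_hi)
        dcoef = gf * areas[axis] / spacings[axis]
        qi = q[faceslice(1, -1)]
        a_hi = dcoef + np.maximum(-qi, 0.0)   # neighbour above
        a_lo = dcoef + np.maximum(qi, 0.0)    # neighbour below
        phi_hi = phi[faceslice(1, None)]
        phi_lo = phi[faceslice(None, -1)]
        # contributions to the low cell (neighbour above it)
        num[faceslice(None, -1)] += a_hi * phi_hi
        a_p[faceslice(None, -1)] += dcoef + np.maximum(qi, 0.0)
        num[faceslice(1, None)] += a_lo * phi_lo
        a_p[faceslice(1, None)] += dcoef + np.maximum(-qi, 0.0)

        # boundary faces: inflow carries bc_value; outflow is upwind
        for side, sign in ((0, 1.0), (-1, -1.0)):
            qb = q[faceslice(0, 1)] if side == 0 else q[faceslice(-1, None)]
            q_in = np.maximum(sign * qb, 0.0)
            q_out = np.maximum(-sign * qb, 0.0)
            cell = faceslice(0, 1) if side == 0 else faceslice(-1, None)
            num[cell] += q_in * bc_value
            a_p[cell] += q_out

    phi_new = num / np.maximum(a_p, 1e-300)
    return (1.0 - alpha) * phi + alpha * phi_new


def k_epsilon_step(state, grid: Grid, settings, flow, air, bcs=None):
    """One under-relaxed k and eps transport update.

    ``state`` is (k, eps, mu_t); returns the updated triple.  Production
    uses the current mu_t and strain rate; wall-adjacent cells get the
    equilibrium log-law dissipation eps = C_mu^{3/4} k^{3/2} / (kappa y).
    """
    k, eps, mu_t = state
    rho, mu = air.density, air.dynamic_viscosity
    if np.any(k < 0) or np.any(eps <= 0):
        raise ValueError("k must be >= 0 and eps > 0 on entry")
    alpha = settings.alpha_turb
    dxs = grid.spacing
    fluxes = (flow.u * dxs[1] * dxs[2], flow.v * dxs[0] * dxs[2],
              flow.w * dxs[0] * dxs[1])
    fluxes = tuple(rho * q for q in fluxes)

    s2 = strain_rate_squared(grid, flow)
    prod = mu_t * s2

    u_ref = max(float(np.max(np.abs(flow.speed()), initial=0.0)), 1e-300)
    length = min(grid.geom.lx, grid.geom.ly, grid.geom.lz)
    k_in, eps_in = inlet_conditions(u_ref, length)

    k_new = _upwind_scalar_update(
        grid, k, fluxes, mu + mu_t / SIGMA_K,
        source=prod, sink_coef=rho * eps / np.maximum(k, K_FLOOR),
        bc_value=k_in, alpha=alpha, inflow_masks=None)
    eps_new = _upwind_scalar_update(
        grid, eps, fluxes, mu + mu_t / SIGMA_EPS,
        source=C1_EPS * eps / np.maximum(k, K_FLOOR) * prod,
        sink_coef=C2_EPS * rho * eps / np.maximum(k, K_FLOOR),
        bc_value=eps_in, alpha=alpha, inflow_masks=None)

    # realisability bounds: k below the resolved kinetic-energy scale,
    # eps within mixing-length limits ell in [L/1000, L]
    k_cap = max(10.0 * u_ref ** 2, 10.0 * K_FLOOR)
    k_new = np.clip(k_new, K_FLOOR, k_cap)
    eps_lo = C_MU ** 0.75 * k_new ** 1.5 / length
    eps_hi = C_MU ** 0.75 * k_new ** 1.5 / (1e-3 * length)
    eps_new = np.clip(eps_new, np.maximum(eps_lo, EPS_FLOOR), eps_hi)

    # log-law equilibrium dissipation in wall-adjacent cells
    for wall, cells, wall_faces, delta in _wall_adjacent_masks(grid):
        if not np.any(wall_faces):
            continue
        layer_k = k_new[cells].reshape(wall_faces.shape)
        eq = C_MU ** 0.75 * layer_k ** 1.5 / (KAPPA * delta)
        layer_eps = eps_new[cells].reshape(wall_faces.shape)
        layer_eps[wall_faces] = np.maximum(eq[wall_faces], EPS_FLOOR)
        eps_new[cells] = layer_eps.reshape(eps_new[cells].shape)

    if not (np.all(np.isfinite(k_new)) and np.all(np.isfinite(eps_new))):
        raise RuntimeError("k-epsilon update produced non-finite values")
    mu_t_new = turbulent_viscosity(k_new, eps_new, rho, mu)
    return k_new, eps_new, mu_t_new
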