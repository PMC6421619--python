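"""Method-of-lines solver for the six-field defect model.

Space is the scaled defect thickness x in [0, 1] (x = 0: subchondral bone,
x = 1: cartilage surface), discretised with second-order conservative finite
differences on a uniform grid. Nonlinear cell diffusivities are evaluated at
interface midpoints from the averaged matrix density, which keeps the scheme
second order and conservative. The semi-discrete system is integrated with
scipy's implicit BDF method (the kinetics are stiff: nutrient uptake rates
are ~1e4 in dimensionless units).

Boundary conditions (``bc_mode="paper"``): no flux for everything at the
bone side; at the cartilage surface no flux for cells and matrix, a fixed
nutrient reservoir (n = 1, pinned algebraically), and Robin outflow for the
growth factors (outward flux proportional to concentration).
``bc_mode="all_no_flux"`` reflects every field at both ends and is used for
conservation tests and zero-dimensional reductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import csr_matrix, diags, kron

from chondrosim.kinetics import DEFAULT_EPS, reaction_terms
from chondrosim.params import DimensionlessParams

__all__ = [
    "Grid",
    "State",
    "Trajectory",
    "IntegrationError",
    "N_FIELDS",
    "FIELDS",
    "assemble_rhs",
    "integrate",
    "richardson_order",
]

FIELDS = ("c_s", "c_c", "n", "m", "g", "b")
N_FIELDS = len(FIELDS)

BC_MODES = ("paper", "all_no_flux")


class IntegrationError(RuntimeError):
    """Stiff integration failed; carries the last successfully reached time
    and state for diagnosis."""

    def __init__(self, message: str, t_last: float | None = None,
                 state_last: "State | None" = None):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


@dataclass(frozen=True)
class Grid:
    """Uniform 1-D mesh on the scaled defect thickness [0, 1]."""

    n_nodes: int

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError(f"Grid needs at least 3 nodes, got {self.n_nodes}")

    @property
    def h(self) -> float:
        return 1.0 / (self.n_nodes - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_nodes)


@dataclass
class State:
    """The six field profiles on one grid at one instant."""

    c_s: np.ndarray
    c_c: np.ndarray
    n: np.ndarray
    m: np.ndarray
    g: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        lengths = {name: len(getattr(self, name)) for name in FIELDS}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"field profiles have mismatched lengths: {lengths}")
        for name in FIELDS:
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_nodes(self) -> int:
        return len(self.c_s)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([getattr(self, name) for name in FIELDS])

    @classmethod
    def from_vector(cls, y: np.ndarray, n_nodes: int) -> "State":
        if y.size != N_FIELDS * n_nodes:
            raise ValueError(
                f"state vector length {y.size} does not conform to "
                f"{N_FIELDS} fields x {n_nodes} nodes")
        blocks = y.reshape(N_FIELDS, n_nodes)
        return cls(*(blocks[i].copy() for i in range(N_FIELDS)))

    def copy(self) -> "State":
        return State(*(getattr(self, name).copy() for name in FIELDS))


@dataclass
class Trajectory:
    """Time-stamped solution: states on a fixed grid plus run metadata."""

    times: np.ndarray                 # dimensionless time stamps, increasing
    states: list[State]
    grid: Grid
    params: DimensionlessParams
    solver_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        for s in self.states:
            if s.n_nodes != self.grid.n_nodes:
                raise ValueError("all states must live on the trajectory grid")

    def field_matrix(self, name: str) -> np.ndarray:
        """Profiles of one field stacked over time, shape (n_times, n_nodes)."""
        if name not in FIELDS:
            raise KeyError(f"unknown field {name!r}; expected one of {FIELDS}")
        return np.stack([getattr(s, name) for s in self.states])


def _check_finite(y: np.ndarray, n_nodes: int) -> None:
    if np.all(np.isfinite(y)):
        return
    bad = np.flatnonzero(~np.isfinite(y))[0]
    fld, node = divmod(int(bad), n_nodes)
    raise FloatingPointError(
        f"non-finite value {y[bad]!r} in field {FIELDS[fld]!r} at node {node}")


def _laplacian_no_flux(u: np.ndarray, D_iface, h: float) -> np.ndarray:
    """Flux-form div(D grad u) with ghost-node reflection at both ends.

    ``D_iface`` is the diffusivity at the n-1 cell interfaces (scalar for
    constant-coefficient fields).
    """
    flux = D_iface * (u[1:] - u[:-1]) / h          # D du/dx at interfaces
    lap = np.empty_like(u)
    lap[1:-1] = (flux[1:] - flux[:-1]) / h
    lap[0] = 2.0 * flux[0] / h
    lap[-1] = -2.0 * flux[-1] / h
    return lap


def assemble_rhs(t: float, y: np.ndarray, grid: Grid, p: DimensionlessParams,
                 eps: float = DEFAULT_EPS, bc_mode: str = "paper") -> np.ndarray:
    """Semi-discrete right-hand side d(fields)/dt for the flattened state.

    Field blocks are ordered (c_s, c_c, n, m, g, b), each of length
    ``grid.n_nodes``.
    """
    if bc_mode not in BC_MODES:
        raise ValueError(f"bc_mode must be one of {BC_MODES}, got {bc_mode!r}")
    N = grid.n_nodes
    y = np.asarray(y, dtype=float)
    if y.size != N_FIELDS * N:
        raise ValueError(
            f"state vector length {y.size} does not conform to grid "
            f"({N_FIELDS} x {N} expected)")
    _check_finite(y, N)
    h = grid.h
    c_s, c_c, n, m, g, b = y.reshape(N_FIELDS, N)

    # interface diffusivities for the matrix-dependent cell motilities
    m_mid = 0.5 * (m[:-1] + m[1:])
    biphasic = m_mid / (m_mid * m_mid + p.m1 * p.m1)
    lap_cs = _laplacian_no_flux(c_s, p.DS0 * biphasic, h)
    lap_cc = _laplacian_no_flux(c_c, p.DC0 * biphasic, h)
    lap_n = _laplacian_no_flux(n, p.Dn, h)
    lap_m = _laplacian_no_flux(m, p.Dm, h)
    lap_g = _laplacian_no_flux(g, p.Dg, h)
    lap_b = _laplacian_no_flux(b, p.Db, h)

    if bc_mode == "paper":
        # cartilage-surface (x = 1) conditions: Robin outflow for the growth
        # factors via ghost-node elimination, nutrient pinned to the reservoir
        if p.Dg > 0:
            lap_g[-1] = 2.0 * p.Dg * (g[-2] - g[-1]) / h**2 - 2.0 * p.gamma * g[-1] / h
        if p.Db > 0:
            lap_b[-1] = 2.0 * p.Db * (b[-2] - b[-1]) / h**2 - 2.0 * p.chi * b[-1] / h

    dc_s, dc_c, dn, dm, dg, db = reaction_terms(c_s, c_c, n, m, g, b, p, eps)
    out = np.empty_like(y).reshape(N_FIELDS, N)
    out[0] = lap_cs + dc_s
    out[1] = lap_cc + dc_c
    out[2] = lap_n + dn
    out[3] = lap_m + dm
    out[4] = lap_g + dg
    out[5] = lap_b + db
    if bc_mode == "paper":
        out[2][-1] = 0.0  # n = 1 held algebraically at the surface node
    return out.reshape(-1)


def _jac_sparsity(n_nodes: int) -> csr_matrix:
    """Block sparsity of the semi-discrete Jacobian.

    Every field at node i couples (through the shared closures and the
    diffusion stencil) to every field at nodes i-1, i, i+1.
    """
    tri = diags([1.0, 1.0, 1.0], [-1, 0, 1], shape=(n_nodes, n_nodes))
    return csr_matrix(kron(np.ones((N_FIELDS, N_FIELDS)), tri))


def integrate(state0: State, t_eval: Sequence[float], grid: Grid,
              p: DimensionlessParams, eps: float = DEFAULT_EPS,
              bc_mode: str = "paper", rtol: float = 1e-6, atol: float = 1e-9,
              method: str = "BDF") -> Trajectory:
    """Integrate the semi-discrete system and sample it at ``t_eval``.

    Uses an implicit stiff integrator (BDF by default) with a banded-block
    Jacobian sparsity pattern. Raises :class:`IntegrationError` on step-size
    collapse, carrying the last good time and state.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or len(t_eval) < 2 or np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be an increasing 1-D sequence")
    if t_eval[0] != 0.0:
        raise ValueError("t_eval must start at 0")
    if state0.n_nodes != grid.n_nodes:
        raise ValueError("initial state does not conform to grid")

    y0 = state0.to_vector()
    sol = solve_ivp(
        assemble_rhs, (0.0, float(t_eval[-1])), y0,
        method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        args=(grid, p, eps, bc_mode),
        jac_sparsity=_jac_sparsity(grid.n_nodes),
    )
    if not sol.success:
        t_last = float(sol.t[-1]) if sol.t.size else 0.0
        state_last = (State.from_vector(sol.y[:, -1], grid.n_nodes)
                      if sol.t.size else state0)
        raise IntegrationError(
            f"stiff integration failed at t={t_last:.6g}: {sol.message}",
            t_last=t_last, state_last=state_last)
    states = [State.from_vector(sol.y[:, i], grid.n_nodes)
              for i in range(sol.y.shape[1])]
    meta = {
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "eps": eps,
        "bc_mode": bc_mode,
        "n_nodes": grid.n_nodes,
        "nfev": int(sol.nfev),
        "njev": int(sol.njev),
        "nlu": int(sol.nlu),
    }
    return Trajectory(times=sol.t, states=states, grid=grid, params=p,
                      solver_meta=meta)


def richardson_order(coarse: np.ndarray, mid: np.ndarray,
                     fine: np.ndarray) -> float:
    """Observed spatial order from one profile on three nested grids.

    The grids must be uniform refinements (N, 2N-1, 4N-3 nodes) so that every
    coarse node is shared. The order is log2 of the ratio of successive
    max-norm differences on shared nodes; a non-monotone error triple raises.
    """
    coarse = np.asarray(coarse, dtype=float)
    mid = np.asarray(mid, dtype=float)
    fine = np.asarray(fine, dtype=float)
    if len(mid) != 2 * len(coarse) - 1 or len(fine) != 2 * len(mid) - 1:
        raise ValueError(
            f"grids are not nested refinements: {len(coarse)}, {len(mid)}, {len(fine)}")
    e1 = float(np.max(np.abs(mid[::2] - coarse)))
    e2 = float(np.max(np.abs(fine[::2] - mid)))
    if e2 <= 0.0 or e1 <= e2:
        raise ValueError(
            f"error triple is not monotonically decreasing (e1={e1:.3e}, "
            f"e2={e2:.3e}); refine further or tighten solver tolerances")
    return float(np.log2(e1 / e2))
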