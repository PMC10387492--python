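"""Abundance-structured population dynamics of CAR T cells and target cells.

Cells are binned by per-cell protein copy number: ``T[i]`` counts CAR T cells
whose receptor abundance falls in the i-th bin of a CAR grid, ``U[j]`` counts
target cells whose antigen abundance falls in the j-th bin of an antigen
grid.  Bin identity is inherited at division (daughters keep the mother's
abundance), so there is no flux between bins and the dynamics reduce to the
coupled ODE system

    dU_j/dt = r U_j - (sum_i lam[i, j] T_i) U_j
    dT_i/dt = (sum_j rho[i, j] U_j) T_i - delta T_i

where ``lam[i, j] = lambda_c * C(R_i, H_j)`` and
``rho[i, j] = rho_c * C(R_i, H_j)`` are per-day rates built from the
steady-state signalling-complex abundance ``C`` of the chosen kinetic
variant (``C0`` for NKP, ``C_N`` for KP), ``r`` is the target replication
rate and ``delta`` the CAR-T death rate (both day^-1, both 0 by default).

Binding steady states are evaluated first, in unit-free copy numbers, so the
per-second kinetic rates never meet the per-day response constants; time in
this module is measured in days throughout.

Percent lysis follows the standard cytotoxicity-assay convention: the lysed
fraction is measured against an effector-free control culture grown for the
same time, ``100 * (1 - U_total(t) / (U_total(0) * exp(r t)))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import lognorm

from .kinetics import (
    BindingParams,
    KPParams,
    ResponseParams,
    kp_active_complex,
    nkp_complex,
)

__all__ = [
    "AbundanceGrid",
    "StructuredPopulation",
    "PopulationParams",
    "SubpopulationRates",
    "Trajectory",
    "discretize_lognormal",
    "rate_tables",
    "integrate",
    "integrate_arrays",
    "percent_lysis",
    "car_moments",
    "subpopulation_rates",
]


@dataclass(frozen=True)
class AbundanceGrid:
    """A binning of per-cell copy numbers.

    Centers use the geometric mean of the bin edges, matching log-spaced
    histogram conventions for flow-cytometry-like data.
    """

    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be a 1-D array of length >= 2")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if edges[0] < 0:
            raise ValueError("bin_edges must be nonnegative")
        object.__setattr__(self, "bin_edges", edges)

    @classmethod
    def log_spaced(cls, mu_log: float, sigma_log: float, n_bins: int = 100,
                   span: float = 6.0) -> "AbundanceGrid":
        """Log-spaced grid covering ``mu_log ± span*sigma_log`` (natural log)."""
        if sigma_log <= 0:
            raise ValueError("sigma_log must be positive")
        lo = mu_log - span * sigma_log
        hi = mu_log + span * sigma_log
        return cls(np.exp(np.linspace(lo, hi, n_bins + 1)))

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return np.sqrt(e[:-1] * e[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def nearest_bin(self, value: float) -> int:
        """Index of the bin whose center is closest (in log space) to value."""
        if value <= 0:
            raise ValueError("abundance must be positive")
        return int(np.argmin(np.abs(np.log(self.bin_centers) - np.log(value))))


@dataclass(frozen=True)
class StructuredPopulation:
    """State of the two interacting populations at one instant (time in days)."""

    grid_R: AbundanceGrid
    grid_H: AbundanceGrid
    T: np.ndarray
    U: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        U = np.asarray(self.U, dtype=float)
        if T.shape != (self.grid_R.n_bins,):
            raise ValueError("T length must match the CAR grid")
        if U.shape != (self.grid_H.n_bins,):
            raise ValueError("U length must match the antigen grid")
        if np.any(T < 0) or np.any(U < 0):
            raise ValueError("cell counts must be nonnegative")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "U", U)


@dataclass(frozen=True)
class PopulationParams:
    """Kinetic and demographic parameters of the coupled system.

    ``r`` (target replication) and ``delta`` (CAR-T death) default to 0: the
    in-vitro assays modelled here are short and their fits are fully
    determined without them.  Set ``model_variant="NKP"`` to drive rates from
    the bare bound complex; ``"KP"`` (requires ``kp``) to drive them from the
    proofread end complex.
    """

    binding: BindingParams
    resp: ResponseParams
    kp: KPParams | None = None
    r: float = 0.0
    delta: float = 0.0
    model_variant: Literal["NKP", "KP"] = "KP"

    def __post_init__(self) -> None:
        if self.r < 0 or self.delta < 0:
            raise ValueError("r and delta must be nonnegative")
        if self.model_variant not in ("NKP", "KP"):
            raise ValueError(f"unknown model variant {self.model_variant!r}")
        if self.model_variant == "KP" and self.kp is None:
            raise ValueError("KP variant requires KPParams")


@dataclass(frozen=True)
class SubpopulationRates:
    """Per-CAR-bin lysis/proliferation rates at a fixed antigen level."""

    R_centers: np.ndarray
    c_lysis: np.ndarray    # lam[R, H_bar] * T_R, target cells/day toward that bin
    c_prolif: np.ndarray   # rho[R, H_bar] * U_{H_bar}, day^-1


def discretize_lognormal(mu_log: float, sigma_log: float, total_cells: float,
                         grid: AbundanceGrid, max_outside: float = 0.01,
                         strict: bool = True) -> np.ndarray:
    """Bin a lognormal abundance distribution onto ``grid``.

    ``mu_log`` and ``sigma_log`` parameterise the natural log of abundance.
    Bin mass is the lognormal CDF difference across the edges; the vector is
    normalised to sum exactly to ``total_cells``.  If more than
    ``max_outside`` of the probability mass falls outside the grid the call
    raises (``strict=True``) or proceeds after renormalising.
    """
    if sigma_log <= 0:
        raise ValueError("sigma_log must be positive")
    if total_cells < 0:
        raise ValueError("total_cells must be nonnegative")
    dist = lognorm(s=sigma_log, scale=np.exp(mu_log))
    cdf = dist.cdf(grid.bin_edges)
    mass = np.diff(cdf)
    covered = mass.sum()
    if 1.0 - covered > max_outside:
        msg = (f"grid covers only {covered:.4f} of the lognormal mass "
               f"(mu_log={mu_log:.3g}, sigma_log={sigma_log:.3g})")
        if strict:
            raise ValueError(msg)
    if covered <= 0:
        raise ValueError("grid covers none of the distribution")
    return total_cells * mass / covered


def rate_tables(grid_R: AbundanceGrid, grid_H: AbundanceGrid,
                params: PopulationParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-day lysis and proliferation rate matrices over the two grids.

    Returns ``(lam, rho)`` of shape ``(n_R, n_H)`` with
    ``lam[i, j] = lambda_c * C(R_i, H_j)`` and likewise for ``rho``, where
    ``C`` is the steady-state complex of the configured model variant.
    """
    R = grid_R.bin_centers[:, None]
    H = grid_H.bin_centers[None, :]
    if params.model_variant == "KP":
        C = kp_active_complex(R, H, params.binding, params.kp)
    else:
        C = nkp_complex(R, H, params.binding)
    return params.resp.lambda_c * C, params.resp.rho_c * C


def _rhs_factory(lam: np.ndarray, rho: np.ndarray, r: float, delta: float,
                 n_R: int):
    def rhs(_t, y):
        T = y[:n_R]
        U = y[n_R:]
        kill = lam.T @ T            # per-H-bin lysis rate, day^-1
        grow = rho @ U              # per-R-bin proliferation rate, day^-1
        return np.concatenate(((grow - delta) * T, (r - kill) * U))
    return rhs


def _rk4(rhs, y0: np.ndarray, times: np.ndarray, n_steps: int) -> np.ndarray:
    """Fixed-step classical RK4 over the full time span, sampled at times."""
    t_end = times[-1]
    if t_end == 0:
        return np.tile(y0, (times.size, 1))
    h = t_end / n_steps
    t_nodes = np.linspace(0.0, t_end, n_steps + 1)
    y = y0.astype(float).copy()
    out = np.empty((times.size, y0.size))
    # record by linear interpolation between RK4 nodes
    ys = np.empty((n_steps + 1, y0.size))
    ys[0] = y
    for k in range(n_steps):
        t = t_nodes[k]
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ys[k + 1] = y
    for m, t in enumerate(times):
        idx = min(int(t / h), n_steps - 1)
        frac = (t - t_nodes[idx]) / h
        out[m] = (1 - frac) * ys[idx] + frac * ys[idx + 1]
    return out


def integrate_arrays(T0: np.ndarray, R_centers: np.ndarray,
                     U0: np.ndarray, H_centers: np.ndarray,
                     params: PopulationParams, times: Sequence[float],
                     method: str = "RK45", rtol: float = 1e-8,
                     atol: float = 1e-6, n_steps: int = 200,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the structured ODEs on raw abundance arrays.

    The workhorse behind :func:`integrate`; also used directly where the
    target population is a concatenation of several sub-populations (e.g.
    healthy + tumour mixtures) sharing one effector pool.

    ``method`` is any adaptive ``solve_ivp`` method (default RK45 at
    ``rtol=1e-8``) or ``"rk4"`` for a fixed-step classical Runge–Kutta
    integrator with ``n_steps`` steps, which trades error control for a
    deterministic flop count (used in fitting loops).

    Returns ``(T_traj, U_traj)`` with shapes ``(n_times, n_R)`` and
    ``(n_times, n_H)``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] < 0 or np.any(np.diff(times) < 0):
        raise ValueError("times must be nondecreasing and start at >= 0")
    T0 = np.asarray(T0, dtype=float)
    U0 = np.asarray(U0, dtype=float)
    R = np.asarray(R_centers, dtype=float)[:, None]
    H = np.asarray(H_centers, dtype=float)[None, :]
    if params.model_variant == "KP":
        C = kp_active_complex(R, H, params.binding, params.kp)
    else:
        C = nkp_complex(R, H, params.binding)
    lam = params.resp.lambda_c * C
    rho = params.resp.rho_c * C
    rhs = _rhs_factory(lam, rho, params.r, params.delta, T0.size)
    y0 = np.concatenate((T0, U0))

    if method == "rk4":
        ys = _rk4(rhs, y0, times, n_steps)
    else:
        sol = solve_ivp(rhs, (0.0, float(times[-1]) if times[-1] > 0 else 1e-12),
                        y0, t_eval=times, method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message} "
                               f"(last good t = {sol.t[-1] if sol.t.size else 0})")
        ys = sol.y.T
    ys = np.clip(ys, 0.0, None)   # clip solver-tolerance negatives
    return ys[:, :T0.size], ys[:, T0.size:]


@dataclass(frozen=True)
class Trajectory:
    """Time-resolved solution of the structured population ODEs."""

    times: np.ndarray                 # days
    T: np.ndarray                     # (n_times, n_R)
    U: np.ndarray                     # (n_times, n_H)
    grid_R: AbundanceGrid
    grid_H: AbundanceGrid
    params: PopulationParams

    def index_of(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[i], t, rtol=0, atol=1e-9):
            raise ValueError(f"time {t} not in trajectory")
        return i

    def state_at(self, t: float) -> StructuredPopulation:
        i = self.index_of(t)
        return StructuredPopulation(self.grid_R, self.grid_H,
                                    self.T[i], self.U[i], time=float(t))

    def to_frame(self):
        """Tidy (time, axis, bin_center, cells) table."""
        import pandas as pd

        rows = []
        for name, grid, mat in (("CAR", self.grid_R, self.T),
                                ("antigen", self.grid_H, self.U)):
            centers = grid.bin_centers
            for ti, t in enumerate(self.times):
                rows.append(pd.DataFrame({
                    "time": t, "axis": name,
                    "bin_center": centers, "cells": mat[ti]}))
        return pd.concat(rows, ignore_index=True)


def integrate(pop0: StructuredPopulation, params: PopulationParams,
              times: Sequence[float], method: str = "RK45",
              rtol: float = 1e-8, atol: float = 1e-6,
              n_steps: int = 200) -> Trajectory:
    """Propagate a structured population; see :func:`integrate_arrays`."""
    times = np.asarray(times, dtype=float)
    T_traj, U_traj = integrate_arrays(
        pop0.T, pop0.grid_R.bin_centers, pop0.U, pop0.grid_H.bin_centers,
        params, times, method=method, rtol=rtol, atol=atol, n_steps=n_steps)
    return Trajectory(times, T_traj, U_traj, pop0.grid_R, pop0.grid_H, params)


def percent_lysis(traj: Trajectory, t: float) -> float:
    """Percent of targets lysed by time ``t`` versus an effector-free control.

    The control culture has no CAR T cells and grows exponentially at the
    target replication rate, so
    ``lysis = 100 * (1 - U_total(t) / (U_total(0) * exp(r t)))``.
    """
    i = traj.index_of(t)
    u0 = traj.U[0].sum()
    if u0 == 0:
        return 0.0
    control = u0 * np.exp(traj.params.r * t)
    return 100.0 * (1.0 - traj.U[i].sum() / control)


def car_moments(pop: StructuredPopulation,
                log_scale: bool = False) -> tuple[float, float]:
    """T-weighted (mean, variance) of CAR abundance over bin centers.

    ``log_scale=True`` returns moments of the natural log of abundance,
    for direct comparison with lognormal fit parameters.
    """
    w = pop.T
    total = w.sum()
    if total <= 0:
        raise ValueError("empty CAR-T population")
    x = pop.grid_R.bin_centers
    if log_scale:
        x = np.log(x)
    mean = float(np.dot(w, x) / total)
    var = float(np.dot(w, (x - mean) ** 2) / total)
    return mean, var


def subpopulation_rates(pop: StructuredPopulation, params: PopulationParams,
                        H_bar: float) -> SubpopulationRates:
    """Lysis/proliferation contributions of each CAR subpopulation.

    At the antigen level nearest ``H_bar``: ``c_lysis[i] = lam[i, j] * T_i``
    is the rate at which the i-th CAR bin removes targets of that antigen
    level, and ``c_prolif[i] = rho[i, j] * U_j`` is the per-cell growth rate
    that bin receives from those targets.
    """
    j = pop.grid_H.nearest_bin(H_bar)
    lam, rho = rate_tables(pop.grid_R, pop.grid_H, params)
    return SubpopulationRates(
        R_centers=pop.grid_R.bin_centers,
        c_lysis=lam[:, j] * pop.T,
        c_prolif=rho[:, j] * pop.U[j],
    )
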