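"""Design-space exploration of CAR constructs by two-objective optimisation.

The in-silico assay co-cultures one effector population with a 1:1 (or other
ratio) mixture of healthy and tumour target cells that differ only in their
antigen abundance distributions (healthy ~10^4.5, tumour ~10^6.9 copies/cell
by default, each lognormal with SD 0.3 in log10 units).  After ``tau`` days
the two conflicting objectives

    f1 = % lysis of healthy cells        (minimise)
    f2 = 1 / (% lysis of tumour cells)   (minimise)

are evaluated.  Design variables are, depending on scenario, the CAR
unbinding rate ``k_off`` at fixed dissociation constant ``K_D`` (with
``k_on = k_off / K_D``), and/or the synNotch induction threshold ``K_H`` and
sharpness ``n_H``.

The front is computed either by a seeded NSGA-II (non-dominated sorting
genetic algorithm: fast non-dominated sort, crowding distance, binary
tournament selection, SBX crossover, polynomial mutation) or by a
deterministic grid search followed by a non-dominated filter — the latter
doubles as the brute-force oracle for the former.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd

from .kinetics import BindingParams, KPParams, ResponseParams
from .population import AbundanceGrid, PopulationParams, discretize_lognormal, integrate_arrays
from .synthetic import LN10, TABLE_DEFAULTS, SynNotchParams, synnotch_induced_mean

__all__ = [
    "AssayDesign",
    "DesignSpace",
    "ParetoResult",
    "mixed_assay",
    "objectives",
    "non_dominated_mask",
    "pareto_front",
    "F2_SENTINEL",
]

#: f2 value reported when tumour lysis is numerically zero
F2_SENTINEL = 1e6

Scenario = Literal["constitutive_koff_sweep", "synnotch_koff_sweep",
                   "synnotch_hill_sweep"]


@dataclass(frozen=True)
class AssayDesign:
    """The mixed healthy/tumour in-silico cytotoxicity assay.

    Antigen distribution means are given as log10 copies; the SD is in
    log10 units (default 0.3, narrow enough that the two populations do not
    overlap appreciably).
    """

    n_targets: float = 20_000.0
    healthy_fraction: float = 0.5
    n_cart: float = 10_000.0
    duration: float = 5.0                  # days
    healthy_mu_log10: float = 4.5
    tumor_mu_log10: float = 6.9
    sigma_log10: float = 0.3
    n_bins_R: int = 40
    n_bins_H: int = 32

    def __post_init__(self) -> None:
        if not 0.0 <= self.healthy_fraction <= 1.0:
            raise ValueError("healthy_fraction must be in [0, 1]")
        if self.n_targets <= 0 or self.duration <= 0:
            raise ValueError("counts and duration must be positive")
        if self.n_cart < 0:
            raise ValueError("n_cart must be nonnegative")

    @property
    def sigma_log(self) -> float:
        return self.sigma_log10 * LN10

    @property
    def tumor_mean_copies(self) -> float:
        return 10.0 ** self.tumor_mu_log10


@dataclass(frozen=True)
class DesignSpace:
    """Decision variables and fixed kinetics of one optimisation scenario.

    ``K_D_copies`` is the (fixed) dissociation constant in molecules/cell;
    ``k_on`` is always derived as ``k_off / K_D``.  The signalling and
    response parameters default to the reference calibrated set.
    """

    scenario: Scenario
    K_D_copies: float
    koff_range: tuple[float, float] = (1e-5, 1e-2)      # s^-1
    nH_range: tuple[float, float] = (1.0, 8.0)
    KH_range: tuple[float, float] = (1e3, 5e7)          # copies
    k_off_fixed: float | None = None
    theta: Mapping[str, float] = field(
        default_factory=lambda: dict(TABLE_DEFAULTS))

    def __post_init__(self) -> None:
        if self.K_D_copies <= 0:
            raise ValueError("K_D_copies must be positive")
        for name in ("koff_range", "nH_range", "KH_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must satisfy 0 < lo < hi")
        if self.scenario == "synnotch_hill_sweep" and self.k_off_fixed is None:
            raise ValueError("hill sweep requires k_off_fixed")

    @property
    def variable_names(self) -> tuple[str, ...]:
        if self.scenario == "synnotch_hill_sweep":
            return ("n_H", "K_H")
        return ("k_off",)

    def bounds_internal(self) -> tuple[np.ndarray, np.ndarray]:
        """Optimizer-space bounds (log10 for k_off and K_H)."""
        if self.scenario == "synnotch_hill_sweep":
            lo = np.array([self.nH_range[0], np.log10(self.KH_range[0])])
            hi = np.array([self.nH_range[1], np.log10(self.KH_range[1])])
        else:
            lo = np.array([np.log10(self.koff_range[0])])
            hi = np.array([np.log10(self.koff_range[1])])
        return lo, hi

    def decode(self, x: np.ndarray) -> dict[str, float]:
        """Map an optimizer-space point to named design variables."""
        if self.scenario == "synnotch_hill_sweep":
            return {"n_H": float(x[0]), "K_H": float(10.0 ** x[1])}
        return {"k_off": float(10.0 ** x[0])}


def _effector_distribution(space: DesignSpace, design: AssayDesign,
                           variables: Mapping[str, float],
                           ) -> tuple[float, float]:
    """Initial CAR lognormal (mu_log, sigma_log) for the scenario.

    SynNotch effectors are induced by the tumour antigen level (induction is
    keyed to the tumour cells' mean antigen abundance); constitutive
    effectors use the calibrated constitutive distribution.
    """
    theta = space.theta
    if space.scenario == "constitutive_koff_sweep":
        return theta["mu_c"], theta["sigma_R"]
    p = SynNotchParams(
        mu_s=theta["mu_s"],
        K_H=variables.get("K_H", theta["K_H"]),
        n_H=variables.get("n_H", theta["n_H"]),
        sigma_R=theta["sigma_R_synN"])
    mu = synnotch_induced_mean(design.tumor_mean_copies, p)
    if mu <= 0:        # induction fully off: no CAR expression to speak of
        mu = 1e-6
    return mu, theta["sigma_R_synN"]


def mixed_assay(design: AssayDesign, params: PopulationParams,
                car_mu_log: float, car_sigma_log: float,
                method: str = "rk4", n_steps: int = 200,
                rtol: float = 1e-8) -> tuple[float, float]:
    """Run the mixed assay; returns (% healthy lysed, % tumour lysed) at tau.

    Healthy and tumour targets are tracked as separate abundance-structured
    vectors sharing the single effector population; percent lysis for each
    group follows the effector-free-control convention.
    """
    sig = design.sigma_log
    grid_R = AbundanceGrid.log_spaced(car_mu_log, car_sigma_log,
                                      design.n_bins_R)
    mu_h = design.healthy_mu_log10 * LN10
    mu_t = design.tumor_mu_log10 * LN10
    grid_h = AbundanceGrid.log_spaced(mu_h, sig, design.n_bins_H)
    grid_t = AbundanceGrid.log_spaced(mu_t, sig, design.n_bins_H)
    n_healthy = design.healthy_fraction * design.n_targets
    n_tumor = design.n_targets - n_healthy
    T0 = discretize_lognormal(car_mu_log, car_sigma_log, design.n_cart,
                              grid_R)
    U0_h = discretize_lognormal(mu_h, sig, n_healthy, grid_h)
    U0_t = discretize_lognormal(mu_t, sig, n_tumor, grid_t)
    H_centers = np.concatenate((grid_h.bin_centers, grid_t.bin_centers))
    U0 = np.concatenate((U0_h, U0_t))
    times = np.array([0.0, design.duration])
    _, U_traj = integrate_arrays(T0, grid_R.bin_centers, U0, H_centers,
                                 params, times, method=method,
                                 n_steps=n_steps, rtol=rtol)
    nh = grid_h.n_bins
    out = []
    for sl, n0 in ((slice(0, nh), n_healthy), (slice(nh, None), n_tumor)):
        if n0 == 0:
            out.append(0.0)
            continue
        control = n0 * np.exp(params.r * design.duration)
        out.append(100.0 * (1.0 - U_traj[-1, sl].sum() / control))
    return out[0], out[1]


def objectives(lysis_pair: tuple[float, float]) -> tuple[float, float]:
    """Map (healthy %, tumour %) lysis to the two minimised objectives."""
    healthy, tumor = lysis_pair
    f2 = 1.0 / tumor if tumor > 1.0 / F2_SENTINEL else F2_SENTINEL
    return healthy, f2


def _make_evaluator(space: DesignSpace, design: AssayDesign,
                    method: str, n_steps: int,
                    ) -> Callable[[np.ndarray], tuple[float, float, float, float]]:
    theta = space.theta

    def evaluate(x: np.ndarray):
        variables = space.decode(x)
        k_off = variables.get("k_off", space.k_off_fixed)
        binding = BindingParams(k_off=k_off, K_D=space.K_D_copies)
        params = PopulationParams(
            binding=binding,
            resp=ResponseParams(lambda_c=theta["lambda_c"],
                                rho_c=theta["rho_c"]),
            kp=KPParams(k_p=theta["k_p"], N=theta["N"]),
            model_variant="KP")
        mu, sigma = _effector_distribution(space, design, variables)
        healthy, tumor = mixed_assay(design, params, mu, sigma,
                                     method=method, n_steps=n_steps)
        f1, f2 = objectives((healthy, tumor))
        return f1, f2, healthy, tumor

    return evaluate


def non_dominated_mask(F: np.ndarray) -> np.ndarray:
    """Boolean mask of the non-dominated rows of an (n, 2) objective array.

    Brute-force O(n^2) dominance filter (both objectives minimised); ties
    collapse to a single representative so the front never contains
    duplicate objective vectors dominating each other trivially.
    """
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        if not mask[i]:
            continue
        for j in range(n):
            if i == j:
                continue
            if (F[j] <= F[i]).all() and (F[j] < F[i]).any():
                mask[i] = False
                break
            if j < i and mask[j] and (F[j] == F[i]).all():
                mask[i] = False
                break
    return mask


# ---------------------------------------------------------------------------
# NSGA-II machinery


def _fast_non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    n = F.shape[0]
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            i_dom = (F[i] <= F[j]).all() and (F[i] < F[j]).any()
            j_dom = (F[j] <= F[i]).all() and (F[j] < F[i]).any()
            if i_dom:
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif j_dom:
                dominated_by[j].append(i)
                domination_count[i] += 1
    fronts = []
    current = np.flatnonzero(domination_count == 0)
    while current.size:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(set(nxt)), dtype=int)
    return fronts


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    for k in range(m):
        order = np.argsort(F[:, k])
        d[order[0]] = d[order[-1]] = np.inf
        span = F[order[-1], k] - F[order[0], k]
        if span <= 0:
            continue
        d[order[1:-1]] += (F[order[2:], k] - F[order[:-2], k]) / span
    return d


def _sbx_crossover(p1, p2, lo, hi, rng, eta=15.0, prob=0.9):
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    for k in range(p1.size):
        if rng.random() > 0.5 or p1[k] == p2[k]:
            continue
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else \
            (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        c1[k] = 0.5 * ((1 + beta) * p1[k] + (1 - beta) * p2[k])
        c2[k] = 0.5 * ((1 - beta) * p1[k] + (1 + beta) * p2[k])
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _polynomial_mutation(x, lo, hi, rng, eta=20.0, prob=None):
    y = x.copy()
    prob = prob if prob is not None else 1.0 / x.size
    for k in range(x.size):
        if rng.random() > prob:
            continue
        u = rng.random()
        delta = (2 * u) ** (1 / (eta + 1)) - 1 if u < 0.5 else \
            1 - (2 * (1 - u)) ** (1 / (eta + 1))
        y[k] = x[k] + delta * (hi[k] - lo[k])
    return np.clip(y, lo, hi)


@dataclass
class ParetoResult:
    """Outcome of a front computation.

    ``front`` and ``evaluated`` are DataFrames with the decision variables,
    the objectives ``f1``/``f2`` and the raw ``pct_healthy``/``pct_tumor``
    lysis columns; ``front`` rows are mutually non-dominated.
    """

    front: pd.DataFrame
    evaluated: pd.DataFrame
    meta: dict

    def to_csv(self, path) -> None:
        self.front.to_csv(path, index=False)


def pareto_front(space: DesignSpace, design: AssayDesign | None = None,
                 seed: int = 0, mode: str = "nsga2",
                 population: int = 40, generations: int = 60,
                 n_grid: int = 50, method: str = "rk4",
                 n_steps: int = 200) -> ParetoResult:
    """Compute the Pareto front over a design space.

    ``mode="nsga2"`` runs the seeded evolutionary optimiser;
    ``mode="grid"`` evaluates a deterministic (log-spaced) grid of
    ``n_grid`` points per variable and applies the non-dominated filter —
    exact for 1-D sweeps up to grid resolution, and the test oracle for the
    evolutionary mode.
    """
    design = design or AssayDesign()
    lo, hi = space.bounds_internal()
    evaluate = _make_evaluator(space, design, method, n_steps)

    if mode == "grid":
        axes = [np.linspace(lo[k], hi[k], n_grid) for k in range(lo.size)]
        mesh = np.meshgrid(*axes, indexing="ij")
        X = np.stack([m.ravel() for m in mesh], axis=1)
    elif mode == "nsga2":
        rng = np.random.default_rng(seed)
        X = _run_nsga2(evaluate, lo, hi, rng, population, generations)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for x in X:
        f1, f2, healthy, tumor = evaluate(x)
        rows.append({**space.decode(x), "f1": f1, "f2": f2,
                     "pct_healthy": healthy, "pct_tumor": tumor})
    evaluated = pd.DataFrame(rows).drop_duplicates(
        subset=list(space.variable_names))
    F = evaluated[["f1", "f2"]].to_numpy()
    front = evaluated[non_dominated_mask(F)].sort_values("f1")
    meta = {"scenario": space.scenario, "mode": mode, "seed": seed,
            "population": population, "generations": generations,
            "n_grid": n_grid, "K_D_copies": space.K_D_copies}
    return ParetoResult(front.reset_index(drop=True),
                        evaluated.reset_index(drop=True), meta)


def _run_nsga2(evaluate, lo, hi, rng, population, generations) -> np.ndarray:
    """Standard NSGA-II loop; returns the final population (decision space)."""
    if population % 2:
        population += 1
    X = lo + (hi - lo) * rng.random((population, lo.size))
    F = np.array([evaluate(x)[:2] for x in X])
    for _ in range(generations):
        fronts = _fast_non_dominated_sort(F)
        rank = np.empty(population, dtype=int)
        for fi, front in enumerate(fronts):
            rank[front] = fi
        crowd = np.empty(population)
        for front in fronts:
            crowd[front] = _crowding_distance(F[front])

        def tournament():
            i, j = rng.integers(population, size=2)
            if rank[i] < rank[j]:
                return i
            if rank[j] < rank[i]:
                return j
            return i if crowd[i] >= crowd[j] else j

        children = []
        while len(children) < population:
            p1, p2 = X[tournament()], X[tournament()]
            c1, c2 = _sbx_crossover(p1, p2, lo, hi, rng)
            children.append(_polynomial_mutation(c1, lo, hi, rng))
            children.append(_polynomial_mutation(c2, lo, hi, rng))
        CX = np.array(children[:population])
        CF = np.array([evaluate(x)[:2] for x in CX])
        # environmental selection on the combined pool
        AX = np.vstack((X, CX))
        AF = np.vstack((F, CF))
        fronts = _fast_non_dominated_sort(AF)
        keep: list[int] = []
        for front in fronts:
            if len(keep) + front.size <= population:
                keep.extend(front.tolist())
            else:
                d = _crowding_distance(AF[front])
                order = front[np.argsort(-d)]
                keep.extend(order[: population - len(keep)].tolist())
                break
        X, F = AX[keep], AF[keep]
    return X
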