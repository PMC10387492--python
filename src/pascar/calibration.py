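"""Parameter estimation for the structured CAR-T cytotoxicity model.

The observables of an in-vitro cytotoxicity assay are, per experimental
condition (target antigen level x CAR affinity x cell numbers): the percent
lysis of target cells at the assay endpoint, and the mean and variance of
CAR abundance across the surviving effector population at the same time.
Estimation minimises the weighted cost

    sum_conditions [ (lysis_obs - lysis_mod)^2 / eta_lysis^2
                   + (mu_R_obs - mu_R_mod)^2 / eta_R^2
                   + (var_R_obs - var_R_mod)^2 / eta_R2^2 ]

by damped least squares (scipy's trust-region-reflective least_squares on
the standardized residual vector, with rate parameters fit in log10 space),
optionally from multiple starts.  Model variants are compared with

    AIC = n [ln(SSR/n) + ln(2 pi) + 1] + 2 k

where n counts scalar observations and k free parameters.  Confidence
intervals use the usual residual/Jacobian asymptotics; parameter
correlations are probed with a nonparametric bootstrap that resamples
conditions with replacement and refits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinetics import (
    BindingParams,
    KPParams,
    ResponseParams,
    kp_active_complex,
    nkp_complex,
)
from .population import (
    AbundanceGrid,
    PopulationParams,
    discretize_lognormal,
    integrate_arrays,
)

__all__ = [
    "AssayCondition",
    "AssayDataset",
    "FitSpec",
    "FitResult",
    "SimOptions",
    "simulate_condition",
    "cost",
    "residual_vector",
    "fit",
    "aic",
    "confidence_intervals",
    "bootstrap_correlations",
]

#: model parameters the fitting layer understands, with their default
#: optimizer transform ("log10" for scale parameters, "linear" otherwise)
PARAM_TRANSFORMS: dict[str, str] = {
    "lambda_c": "log10",
    "rho_c": "log10",
    "k_p": "log10",
    "N": "linear",
    "mu_c": "linear",
    "sigma_R": "linear",
    "mu_s": "linear",
    "sigma_R_synN": "linear",
    "K_H": "log10",
    "n_H": "linear",
}

OBSERVABLES = ("lysis", "car_mean", "car_var")


@dataclass(frozen=True)
class AssayCondition:
    """One co-culture condition of a cytotoxicity assay.

    ``her2_mu_log``/``her2_sigma_log`` parameterise the natural log of the
    target antigen abundance distribution.  Affinity is carried as
    ``k_off`` (s^-1) and ``K_D_copies`` (molecules/cell); ``k_on`` follows.
    """

    key: str
    car_type: str                 # "constitutive" | "synnotch"
    k_off: float
    K_D_copies: float
    her2_mu_log: float
    her2_sigma_log: float
    n_cart: float = 10_000.0
    n_targets: float = 20_000.0
    duration: float = 3.0         # days

    @property
    def binding(self) -> BindingParams:
        return BindingParams(k_off=self.k_off, K_D=self.K_D_copies)


@dataclass
class AssayDataset:
    """Observations and weights for a set of assay conditions.

    ``observations`` is indexed by condition key with columns
    ``lysis, car_mean, car_var, eta_lysis, eta_car_mean, eta_car_var``.
    """

    conditions: tuple[AssayCondition, ...]
    observations: pd.DataFrame
    truth: dict[str, float] | None = None   # attached by synthetic generators

    def __post_init__(self) -> None:
        keys = [c.key for c in self.conditions]
        if len(set(keys)) != len(keys):
            raise ValueError("condition keys must be unique")
        missing = set(keys) - set(self.observations.index)
        if missing:
            raise ValueError(f"observations missing for conditions {missing}")
        etas = self.observations[
            ["eta_lysis", "eta_car_mean", "eta_car_var"]]
        if (etas <= 0).any().any():
            raise ValueError("all weights eta must be positive")

    @property
    def n_observations(self) -> int:
        return 3 * len(self.conditions)

    def subset(self, keys: Sequence[str]) -> "AssayDataset":
        """Dataset restricted to (possibly repeated) condition keys.

        Repeats are kept — this is what a bootstrap resample of conditions
        produces — by suffixing duplicate keys.
        """
        by_key = {c.key: c for c in self.conditions}
        conds, rows, idx = [], [], []
        seen: dict[str, int] = {}
        for k in keys:
            n = seen.get(k, 0)
            seen[k] = n + 1
            new_key = k if n == 0 else f"{k}#rep{n}"
            c = by_key[k]
            conds.append(AssayCondition(
                key=new_key, car_type=c.car_type, k_off=c.k_off,
                K_D_copies=c.K_D_copies, her2_mu_log=c.her2_mu_log,
                her2_sigma_log=c.her2_sigma_log, n_cart=c.n_cart,
                n_targets=c.n_targets, duration=c.duration))
            rows.append(self.observations.loc[k])
            idx.append(new_key)
        obs = pd.DataFrame(rows)
        obs.index = pd.Index(idx, name=self.observations.index.name)
        return AssayDataset(tuple(conds), obs, truth=self.truth)

    def to_csv(self, path) -> None:
        cond_cols = pd.DataFrame(
            [{"key": c.key, "car_type": c.car_type, "k_off": c.k_off,
              "K_D_copies": c.K_D_copies, "her2_mu_log": c.her2_mu_log,
              "her2_sigma_log": c.her2_sigma_log, "n_cart": c.n_cart,
              "n_targets": c.n_targets, "duration": c.duration}
             for c in self.conditions]).set_index("key")
        cond_cols.join(self.observations).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "AssayDataset":
        df = pd.read_csv(path, index_col="key")
        conds = tuple(
            AssayCondition(key=str(k), car_type=row["car_type"],
                           k_off=row["k_off"], K_D_copies=row["K_D_copies"],
                           her2_mu_log=row["her2_mu_log"],
                           her2_sigma_log=row["her2_sigma_log"],
                           n_cart=row["n_cart"], n_targets=row["n_targets"],
                           duration=row["duration"])
            for k, row in df.iterrows())
        obs = df[["lysis", "car_mean", "car_var",
                  "eta_lysis", "eta_car_mean", "eta_car_var"]]
        return cls(conds, obs)


@dataclass(frozen=True)
class SimOptions:
    """Discretisation and integration settings for fitting simulations.

    Modest grids and a fixed-step RK4 keep a single cost evaluation cheap
    and smooth in the parameters (no adaptive step-count jitter), which is
    what a derivative-based optimizer wants.
    """

    n_bins_R: int = 24
    n_bins_H: int = 20
    span: float = 6.0
    method: str = "rk4"
    n_steps: int = 120
    rtol: float = 1e-8


def _initial_car_distribution(cond: AssayCondition,
                              theta: Mapping[str, float]) -> tuple[float, float]:
    """Initial CAR lognormal (mu_log, sigma_log) for a condition.

    Constitutive effectors use (mu_c, sigma_R).  SynNotch effectors derive
    their mean from a Hill function of the condition's antigen level
    (threshold K_H, sharpness n_H, plateau mu_s) with spread sigma_R_synN.
    """
    if cond.car_type == "constitutive":
        return theta["mu_c"], theta["sigma_R"]
    if cond.car_type == "synnotch":
        from .synthetic import SynNotchParams, synnotch_induced_mean

        p = SynNotchParams(mu_s=theta["mu_s"], K_H=theta["K_H"],
                           n_H=theta["n_H"],
                           sigma_R=theta["sigma_R_synN"])
        mu_H = float(np.exp(cond.her2_mu_log))
        return synnotch_induced_mean(mu_H, p), theta["sigma_R_synN"]
    raise ValueError(f"unknown car_type {cond.car_type!r}")


def simulate_condition(cond: AssayCondition, theta: Mapping[str, float],
                       model_variant: str = "KP",
                       sim: SimOptions = SimOptions(),
                       ) -> dict[str, float]:
    """Simulate one assay condition; returns lysis %, day-end CAR moments."""
    mu_R0, sigma_R0 = _initial_car_distribution(cond, theta)
    grid_R = AbundanceGrid.log_spaced(mu_R0, sigma_R0, sim.n_bins_R, sim.span)
    grid_H = AbundanceGrid.log_spaced(cond.her2_mu_log, cond.her2_sigma_log,
                                      sim.n_bins_H, sim.span)
    T0 = discretize_lognormal(mu_R0, sigma_R0, cond.n_cart, grid_R)
    U0 = discretize_lognormal(cond.her2_mu_log, cond.her2_sigma_log,
                              cond.n_targets, grid_H)
    kp = None
    if model_variant == "KP":
        kp = KPParams(k_p=theta["k_p"], N=theta["N"])
    params = PopulationParams(
        binding=cond.binding,
        resp=ResponseParams(lambda_c=theta["lambda_c"], rho_c=theta["rho_c"]),
        kp=kp, model_variant=model_variant,
        r=theta.get("r", 0.0), delta=theta.get("delta", 0.0))
    times = np.array([0.0, cond.duration])
    T_traj, U_traj = integrate_arrays(
        T0, grid_R.bin_centers, U0, grid_H.bin_centers, params, times,
        method=sim.method, rtol=sim.rtol, n_steps=sim.n_steps)
    u0, ut = U_traj[0].sum(), U_traj[-1].sum()
    control = u0 * np.exp(params.r * cond.duration)
    lysis = 100.0 * (1.0 - ut / control)
    w = T_traj[-1]
    x = grid_R.bin_centers
    total = w.sum()
    mean = float(np.dot(w, x) / total)
    var = float(np.dot(w, (x - mean) ** 2) / total)
    return {"lysis": float(lysis), "car_mean": mean, "car_var": var}


def _simulate_batch(conditions: Sequence[AssayCondition],
                    theta: Mapping[str, float], model_variant: str,
                    sim: SimOptions) -> list[dict[str, float]]:
    """All conditions in one vectorized fixed-step RK4 sweep.

    Conditions share the grid sizes of ``sim``, so their states stack into
    (n_cond, n_R) / (n_cond, n_H) arrays and the coupled ODEs advance for
    every condition simultaneously (one einsum per rate term per stage).
    Durations may differ; each condition integrates in its own rescaled
    time.  Numerically identical to per-condition RK4 at the same step
    count.
    """
    from scipy.special import ndtr

    C = len(conditions)
    nR, nH = sim.n_bins_R, sim.n_bins_H
    T0 = np.empty((C, nR))
    U0 = np.empty((C, nH))
    lam = np.empty((C, nR, nH))
    centers_R = np.empty((C, nR))
    r = theta.get("r", 0.0)
    delta = theta.get("delta", 0.0)
    kp = KPParams(k_p=theta["k_p"], N=theta["N"]) \
        if model_variant == "KP" else None

    def log_grid(mu, sigma, n):
        # edges in log space spanning mu +/- span*sigma; lognormal bin mass
        log_edges = np.linspace(mu - sim.span * sigma,
                                mu + sim.span * sigma, n + 1)
        centers = np.exp(0.5 * (log_edges[:-1] + log_edges[1:]))
        cdf = ndtr((log_edges - mu) / sigma)
        mass = np.diff(cdf)
        return centers, mass / mass.sum()

    for ci, cond in enumerate(conditions):
        mu_R0, sigma_R0 = _initial_car_distribution(cond, theta)
        R_centers, R_mass = log_grid(mu_R0, sigma_R0, nR)
        H_centers, H_mass = log_grid(cond.her2_mu_log, cond.her2_sigma_log,
                                     nH)
        T0[ci] = cond.n_cart * R_mass
        U0[ci] = cond.n_targets * H_mass
        centers_R[ci] = R_centers
        R = R_centers[:, None]
        H = H_centers[None, :]
        if model_variant == "KP":
            Cmat = kp_active_complex(R, H, cond.binding, kp)
        else:
            Cmat = nkp_complex(R, H, cond.binding)
        lam[ci] = Cmat
    lam_c, rho_c = theta["lambda_c"], theta["rho_c"]
    lam_t = lam_c * lam
    rho_t = rho_c * lam

    T = T0.copy()
    U = U0.copy()
    durations = np.array([c.duration for c in conditions])
    h = durations / sim.n_steps        # per-condition step, days

    def derivs(T, U):
        kill = np.einsum("cij,ci->cj", lam_t, T)
        grow = np.einsum("cij,cj->ci", rho_t, U)
        return (grow - delta) * T, (r - kill) * U

    hT = h[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(sim.n_steps):
            k1T, k1U = derivs(T, U)
            k2T, k2U = derivs(T + hT / 2 * k1T, U + hT / 2 * k1U)
            k3T, k3U = derivs(T + hT / 2 * k2T, U + hT / 2 * k2U)
            k4T, k4U = derivs(T + hT * k3T, U + hT * k3U)
            T = T + hT / 6 * (k1T + 2 * k2T + 2 * k3T + k4T)
            U = U + hT / 6 * (k1U + 2 * k2U + 2 * k3U + k4U)
    T = np.clip(T, 0.0, None)
    U = np.clip(U, 0.0, None)

    out = []
    with np.errstate(invalid="ignore", over="ignore"):
        for ci, cond in enumerate(conditions):
            control = U0[ci].sum() * np.exp(r * cond.duration)
            lysis = 100.0 * (1.0 - U[ci].sum() / control)
            w = T[ci]
            x = centers_R[ci]
            total = w.sum()
            mean = float(np.dot(w, x) / total)
            var = float(np.dot(w, (x - mean) ** 2) / total)
            out.append({"lysis": float(lysis), "car_mean": mean,
                        "car_var": var})
    return out


def residual_vector(theta: Mapping[str, float], dataset: AssayDataset,
                    model_variant: str = "KP",
                    sim: SimOptions = SimOptions()) -> np.ndarray:
    """Standardized residuals, 3 per condition (lysis, CAR mean, CAR var)."""
    res = np.empty(dataset.n_observations)
    obs = dataset.observations
    try:
        if sim.method == "rk4":
            preds = _simulate_batch(dataset.conditions, theta, model_variant,
                                    sim)
        else:
            preds = [simulate_condition(c, theta, model_variant, sim)
                     for c in dataset.conditions]
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"simulation failed: {exc}") from exc
    for i, cond in enumerate(dataset.conditions):
        pred = preds[i]
        row = obs.loc[cond.key]
        res[3 * i] = (pred["lysis"] - row["lysis"]) / row["eta_lysis"]
        res[3 * i + 1] = (pred["car_mean"] - row["car_mean"]) / row["eta_car_mean"]
        res[3 * i + 2] = (pred["car_var"] - row["car_var"]) / row["eta_car_var"]
    return res


def cost(theta: Mapping[str, float], dataset: AssayDataset,
         model_variant: str = "KP",
         sim: SimOptions = SimOptions()) -> float:
    """The weighted sum-of-squares objective (see module docstring)."""
    r = residual_vector(theta, dataset, model_variant, sim)
    return float(np.dot(r, r))


def aic(SSR: float, n: int, k: int) -> float:
    """Akaike information criterion ``n[ln(SSR/n) + ln(2 pi) + 1] + 2k``."""
    if SSR <= 0:
        raise ValueError("SSR must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * (np.log(SSR / n) + np.log(2.0 * np.pi) + 1.0) + 2.0 * k


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``free`` maps parameter names to (lower, upper) bounds in natural units;
    ``fixed`` pins the rest.  Scale parameters are optimised in log10 space
    (see ``PARAM_TRANSFORMS``).  ``multistart`` > 1 adds random restarts
    drawn log-uniform/uniform within the bounds; the best local minimum is
    kept.  Deterministic given ``seed``.
    """

    free: Mapping[str, tuple[float, float]]
    fixed: Mapping[str, float] = field(default_factory=dict)
    model_variant: str = "KP"
    start: Mapping[str, float] | None = None
    multistart: int = 1
    seed: int = 0
    sim: SimOptions = SimOptions()
    max_nfev: int | None = None
    xtol: float = 1e-10
    ftol: float = 1e-10

    def __post_init__(self) -> None:
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {overlap}")
        for name in self.free:
            if name not in PARAM_TRANSFORMS:
                raise ValueError(f"unknown parameter {name!r}")


@dataclass
class FitResult:
    """Estimates and diagnostics of one fit."""

    estimates: dict[str, float]
    free_names: tuple[str, ...]
    ssr: float
    n: int
    k: int
    aic: float
    success: bool
    residuals: np.ndarray
    jacobian: np.ndarray            # in transformed (optimizer) coordinates
    internal: np.ndarray            # estimates in transformed coordinates
    spec: FitSpec
    ci: dict[str, tuple[float, float]] | None = None
    message: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "estimates": self.estimates,
            "ci": self.ci,
            "ssr": self.ssr, "n": self.n, "k": self.k, "aic": self.aic,
            "success": self.success, "message": self.message,
            "model_variant": self.spec.model_variant,
            "seed": self.spec.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _to_internal(name: str, value: float) -> float:
    return np.log10(value) if PARAM_TRANSFORMS[name] == "log10" else value


def _from_internal(name: str, value: float) -> float:
    return 10.0 ** value if PARAM_TRANSFORMS[name] == "log10" else value


def _theta_from_vector(z: np.ndarray, spec: FitSpec) -> dict[str, float]:
    theta = dict(spec.fixed)
    for name, zi in zip(spec.free, z):
        theta[name] = _from_internal(name, zi)
    return theta


def fit(dataset: AssayDataset, spec: FitSpec) -> FitResult:
    """Minimise the weighted cost; damped least squares with restarts."""
    names = tuple(spec.free)
    k = len(names)
    n = dataset.n_observations
    if k >= n:
        raise ValueError(f"{k} free parameters but only {n} observations")
    lo = np.array([_to_internal(m, spec.free[m][0]) for m in names])
    hi = np.array([_to_internal(m, spec.free[m][1]) for m in names])

    def residuals_z(z):
        res = residual_vector(_theta_from_vector(z, spec), dataset,
                              spec.model_variant, spec.sim)
        # explosive parameter regions (fixed-step overflow) are mapped to
        # large finite residuals so the optimizer retreats instead of dying
        return np.nan_to_num(res, nan=1e8, posinf=1e8, neginf=-1e8)

    rng = np.random.default_rng(spec.seed)
    starts = []
    if spec.start is not None:
        starts.append(np.array([_to_internal(m, spec.start[m]) for m in names]))
    else:
        starts.append(0.5 * (lo + hi))
    while len(starts) < spec.multistart:
        starts.append(lo + (hi - lo) * rng.random(k))

    best = None
    for z0 in starts:
        z0 = np.clip(z0, lo, hi)
        try:
            sol = optimize.least_squares(
                residuals_z, z0, bounds=(lo, hi), method="trf",
                x_scale="jac", xtol=spec.xtol, ftol=spec.ftol,
                max_nfev=spec.max_nfev)
        except RuntimeError:
            continue
        ssr = 2.0 * sol.cost
        if best is None or ssr < best[0]:
            best = (ssr, sol)
    if best is None:
        raise RuntimeError("all fit starts failed")
    ssr, sol = best
    estimates = _theta_from_vector(sol.x, spec)
    result = FitResult(
        estimates=estimates, free_names=names, ssr=float(ssr), n=n, k=k,
        aic=aic(ssr, n, k), success=bool(sol.success),
        residuals=sol.fun, jacobian=sol.jac, internal=sol.x, spec=spec,
        message=sol.message)
    result.ci = confidence_intervals(result)
    return result


def confidence_intervals(result: FitResult, level: float = 0.95,
                         ) -> dict[str, tuple[float, float]]:
    """Asymptotic per-parameter CIs from the final Jacobian.

    ``z_hat +/- t_{n-k, 1-a/2} * sqrt(diag(SSR/(n-k) * (J'J)^-1))`` in the
    optimizer's transformed coordinates; the interval endpoints are then
    mapped back through the (monotone) transform, so coverage is preserved.
    Parameters whose Jacobian column is degenerate get infinite intervals.
    """
    J = result.jacobian
    dof = result.n - result.k
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = result.ssr / dof
    JTJ = J.T @ J
    tq = stats.t.ppf(0.5 + level / 2.0, dof)
    try:
        cov = s2 * np.linalg.inv(JTJ)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(result.k, np.inf)
    ci: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(result.free_names):
        z = result.internal[i]
        if not np.isfinite(se[i]):
            ci[name] = (-np.inf, np.inf) if PARAM_TRANSFORMS[name] != "log10" \
                else (0.0, np.inf)
            continue
        lo_z, hi_z = z - tq * se[i], z + tq * se[i]
        ci[name] = (_from_internal(name, lo_z), _from_internal(name, hi_z))
    return ci


def bootstrap_correlations(dataset: AssayDataset, spec: FitSpec,
                           n_boot: int = 200, seed: int = 0,
                           max_fail_fraction: float = 0.2,
                           ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Pearson correlations between parameters across bootstrap refits.

    Conditions are resampled with replacement; each resampled dataset is
    refit starting from the full-data optimum.  Returns ``(r, p, n_failed)``
    as parameter-by-parameter DataFrames.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    base = fit(dataset, spec)
    start = {m: base.estimates[m] for m in base.free_names}
    rng = np.random.default_rng(seed)
    keys = [c.key for c in dataset.conditions]
    names = base.free_names
    draws = []
    n_failed = 0
    for _ in range(n_boot):
        resampled = dataset.subset(list(rng.choice(keys, size=len(keys))))
        boot_spec = FitSpec(free=spec.free, fixed=spec.fixed,
                            model_variant=spec.model_variant, start=start,
                            multistart=1, seed=spec.seed, sim=spec.sim,
                            max_nfev=spec.max_nfev, xtol=spec.xtol,
                            ftol=spec.ftol)
        try:
            res = fit(resampled, boot_spec)
        except RuntimeError:
            n_failed += 1
            continue
        draws.append([res.estimates[m] for m in names])
    if n_failed > max_fail_fraction * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap refits failed")
    arr = np.asarray(draws)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.std(arr[:, i]) == 0 or np.std(arr[:, j]) == 0:
                rij, pij = 0.0, 1.0
            else:
                rij, pij = stats.pearsonr(arr[:, i], arr[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=names, columns=names)
    pdf = pd.DataFrame(p, index=names, columns=names)
    return rdf, pdf, n_failed
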