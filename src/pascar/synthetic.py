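"""Synthetic flow-cytometry-like inputs and calibration datasets.

Everything the pipeline consumes can be generated here with a known ground
truth: lognormal single-cell abundance samples and histograms, healthy/tumour
antigen mixtures, Hill-induced CAR expression for synNotch effectors,
moment interpolation across antigen levels, and full cytotoxicity-assay
datasets (percent lysis + day-3 CAR moments with weights) for parameter
recovery and coverage studies.

Log-base bookkeeping is explicit: a :class:`DistributionSpec` records whether
its mean/SD parameterise the natural log or the base-10 log of abundance and
converts on request.  Flow-cytometry axes are conventionally log10 while the
calibrated model parameters are natural-log moments; nothing here assumes a
base silently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    OBSERVABLES,
    AssayCondition,
    AssayDataset,
    SimOptions,
    simulate_condition,
)

__all__ = [
    "DistributionSpec",
    "SynNotchParams",
    "MomentTable",
    "NoiseModel",
    "sample_abundances",
    "make_mixture",
    "histogram_frame",
    "fit_lognormal",
    "synnotch_induced_mean",
    "interpolate_moments",
    "constitutive_conditions",
    "generate_assay_dataset",
    "TABLE_DEFAULTS",
]

LN10 = np.log(10.0)

#: Reference parameter set used as the default ground truth of synthetic
#: studies: proofreading chain of ~7 steps with k_p ~ 7e-3 s^-1, per-complex
#: response constants of order 1e-8/day, constitutive CAR distribution with
#: natural-log mean ~7.36 and SD ~0.47, and a sharp synNotch induction
#: threshold near 2.5e5 antigens/cell.
TABLE_DEFAULTS: dict[str, float] = {
    "lambda_c": 2.09e-8,
    "rho_c": 5.31e-9,
    "k_p": 0.0074,
    "N": 7.1961,
    "mu_c": 7.3589,
    "sigma_R": 0.4672,
    "mu_s": 6.5367,
    "sigma_R_synN": 1.1257,
    "K_H": 2.46e5,
    "n_H": 3.8795,
}

#: reference CAR affinities in copy-number units (K_D converted from 17.6,
#: 210 and 1.9 nM with the calibrated factor; see pascar.units)
AFFINITIES: dict[str, dict[str, float]] = {
    "high": {"k_off": 9.0e-5, "K_D_copies": 2.39},
    "low": {"k_off": 6.8e-4, "K_D_copies": 28.47},
    "highest": {"k_off": 2.2e-5, "K_D_copies": 0.258},
}

#: log10 target-antigen levels of the reference constitutive assay panel
HER2_LEVELS_LOG10: tuple[float, ...] = (4.7, 5.2, 5.7, 6.2, 6.9)

#: natural-log SD of target antigen abundance (0.3 in log10 units)
HER2_SIGMA_LOG: float = 0.3 * LN10


@dataclass(frozen=True)
class DistributionSpec:
    """Lognormal abundance distribution with an explicit log base."""

    mu_log: float
    sigma_log: float
    n_cells: int = 10_000
    base: str = "natural"          # "natural" | "10"

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be positive")
        if self.base not in ("natural", "10"):
            raise ValueError("base must be 'natural' or '10'")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")

    def natural(self) -> "DistributionSpec":
        """The same distribution with natural-log parameters."""
        if self.base == "natural":
            return self
        return DistributionSpec(self.mu_log * LN10, self.sigma_log * LN10,
                                self.n_cells, "natural")


@dataclass(frozen=True)
class SynNotchParams:
    """Hill induction of CAR expression by target antigen level.

    The induced mean CAR abundance (on the same log scale as ``mu_s``) is
    ``mu_s * mu_H**n_H / (mu_H**n_H + K_H**n_H)`` — an off/on switch around
    the threshold ``K_H`` (copies) with sharpness ``n_H``.
    """

    mu_s: float
    K_H: float
    n_H: float
    sigma_R: float

    def __post_init__(self) -> None:
        if self.K_H <= 0:
            raise ValueError("K_H must be positive")
        if self.n_H < 0:
            raise ValueError("n_H must be nonnegative")
        if self.sigma_R <= 0:
            raise ValueError("sigma_R must be positive")


def sample_abundances(spec: DistributionSpec,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw per-cell copy numbers from a lognormal spec; reproducible."""
    rng = np.random.default_rng(seed)
    nat = spec.natural()
    return rng.lognormal(mean=nat.mu_log, sigma=nat.sigma_log,
                         size=spec.n_cells)


def histogram_frame(values: np.ndarray, n_bins: int = 100,
                    ) -> pd.DataFrame:
    """Log-spaced histogram in the (bin_lo, bin_hi, count) CSV layout."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("abundances must be positive")
    edges = np.exp(np.linspace(np.log(values.min()) - 1e-9,
                               np.log(values.max()) + 1e-9, n_bins + 1))
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                         "count": counts})


def fit_lognormal(hist: pd.DataFrame) -> tuple[float, float]:
    """Natural-log (mu, sigma) from a (bin_lo, bin_hi, count) histogram.

    Moment-matches the log of the geometric bin centers, the standard quick
    estimate for flow-like log-binned data.
    """
    centers = np.log(np.sqrt(hist["bin_lo"] * hist["bin_hi"]))
    w = hist["count"].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("histogram is empty")
    mu = float(np.average(centers, weights=w))
    var = float(np.average((centers - mu) ** 2, weights=w))
    return mu, float(np.sqrt(var))


def make_mixture(healthy: DistributionSpec, tumor: DistributionSpec,
                 ratio: float, total: int,
                 seed: int | np.random.Generator = 0,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Labeled healthy/tumour antigen sample and its pooled histogram.

    ``ratio`` is the healthy fraction of ``total`` cells.  Returns
    ``(sample, histogram)`` where ``sample`` has columns
    ``abundance, label``.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_healthy = int(round(ratio * total))
    n_tumor = total - n_healthy
    parts = []
    for spec, n, label in ((healthy, n_healthy, "healthy"),
                           (tumor, n_tumor, "tumor")):
        if n == 0:
            continue
        vals = sample_abundances(replace(spec, n_cells=n), rng)
        parts.append(pd.DataFrame({"abundance": vals, "label": label}))
    sample = pd.concat(parts, ignore_index=True)
    return sample, histogram_frame(sample["abundance"].to_numpy())


def synnotch_induced_mean(mu_H: float, p: SynNotchParams) -> float:
    """Induced mean CAR (log scale) for a target antigen level ``mu_H``.

    Evaluated as ``mu_s / (1 + (K_H/mu_H)**n_H)``, which is overflow-safe
    for large antigen levels and sharp Hill coefficients.
    """
    if mu_H < 0:
        raise ValueError("mu_H must be nonnegative")
    if mu_H == 0:
        return 0.0 if p.n_H > 0 else p.mu_s / 2.0
    log_ratio = p.n_H * (np.log(p.K_H) - np.log(mu_H))
    if log_ratio > 700:          # exp would overflow; induction fully off
        return 0.0
    return p.mu_s / (1.0 + np.exp(log_ratio))


@dataclass(frozen=True)
class MomentTable:
    """(mean, variance) of log abundance at a set of log10 antigen levels."""

    levels_log10: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels_log10, dtype=float)
        m = np.asarray(self.means, dtype=float)
        v = np.asarray(self.variances, dtype=float)
        if not (lv.shape == m.shape == v.shape) or lv.ndim != 1:
            raise ValueError("levels, means, variances must be 1-D and equal length")
        if not np.all(np.diff(lv) > 0):
            raise ValueError("levels must be strictly increasing")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(v))):
            raise ValueError("moments must be finite")
        object.__setattr__(self, "levels_log10", lv)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "variances", v)


def interpolate_moments(table: MomentTable,
                        level_log10: float) -> tuple[float, float]:
    """Piecewise-linear (mean, variance) at an intermediate antigen level."""
    lv = table.levels_log10
    if not lv[0] <= level_log10 <= lv[-1]:
        raise ValueError(
            f"level {level_log10} outside table range [{lv[0]}, {lv[-1]}]")
    return (float(np.interp(level_log10, lv, table.means)),
            float(np.interp(level_log10, lv, table.variances)))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise scales for the three assay observables.

    ``lysis_sd`` is in percentage points; the CAR-moment scales are relative
    to the simulated value (flow moments are multiplicative-error limited).
    Setting all three to 0 gives a noise-free dataset; the recorded weights
    then fall back to unit-order floors so the cost stays well defined.
    """

    lysis_sd: float = 3.0
    car_mean_rel_sd: float = 0.05
    car_var_rel_sd: float = 0.15

    def scales(self, truth_obs: Mapping[str, float]) -> dict[str, float]:
        return {
            "lysis": self.lysis_sd,
            "car_mean": self.car_mean_rel_sd * abs(truth_obs["car_mean"]),
            "car_var": self.car_var_rel_sd * abs(truth_obs["car_var"]),
        }


def constitutive_conditions(
        levels_log10: Sequence[float] = HER2_LEVELS_LOG10,
        her2_sigma_log: float = HER2_SIGMA_LOG,
        affinities: Mapping[str, Mapping[str, float]] = AFFINITIES,
        n_cart: float = 10_000.0, n_targets: float = 20_000.0,
        duration: float = 3.0) -> tuple[AssayCondition, ...]:
    """The reference constitutive assay panel (36 scalar observations).

    High- and low-affinity CARs at every antigen level, plus the highest
    affinity CAR (K_D = 1.9 nM in molar units) at two intermediate levels:
    12 conditions x 3 observables = 36.  At least three distinct unbinding
    rates are required here — with only two, (k_p, N, lambda_c, rho_c) have
    an exact one-dimensional degeneracy because every rate enters the
    dynamics as ``lambda_c * alpha(k_off)**N`` (and likewise for rho_c), so
    two k_off values constrain only two of those three scale directions.
    """
    conds = []
    for aff_name, aff in affinities.items():
        if aff_name == "highest":
            levels = [lv for lv in (5.2, 6.2) if lv in levels_log10] or \
                list(levels_log10)[:2]
        else:
            levels = list(levels_log10)
        for level in levels:
            conds.append(AssayCondition(
                key=f"{aff_name}_her2_{level:g}", car_type="constitutive",
                k_off=aff["k_off"], K_D_copies=aff["K_D_copies"],
                her2_mu_log=level * LN10, her2_sigma_log=her2_sigma_log,
                n_cart=n_cart, n_targets=n_targets, duration=duration))
    return tuple(conds)


def generate_assay_dataset(truth: Mapping[str, float],
                           conditions: Sequence[AssayCondition] | None = None,
                           noise: NoiseModel = NoiseModel(),
                           seed: int = 0,
                           model_variant: str = "KP",
                           sim: SimOptions = SimOptions(),
                           n_replicates: int = 100,
                           ) -> AssayDataset:
    """Simulate an assay panel at known truth and attach noisy observations.

    Each condition is simulated once at ``truth``; the recorded observation
    is the truth value plus one Gaussian draw at the noise model's scale,
    and the weights ``eta**2`` are estimated as the sample SD of
    ``n_replicates`` further replicate draws — mimicking how replicate
    wells/histograms would be used to weight a real dataset.
    """
    if conditions is None:
        conditions = constitutive_conditions()
    rng = np.random.default_rng(seed)
    rows = {}
    for cond in conditions:
        pred = simulate_condition(cond, truth, model_variant, sim)
        sds = noise.scales(pred)
        row = {}
        for name in OBSERVABLES:
            s = sds[name]
            value = pred[name] + (s * rng.standard_normal() if s > 0 else 0.0)
            if s > 0:
                reps = pred[name] + s * rng.standard_normal(n_replicates)
                eta = float(np.std(reps, ddof=1))
            else:
                # noise-free: unit-order floors keep the cost well defined
                eta = 1.0 if name == "lysis" else max(0.01 * abs(pred[name]), 1.0)
            row[name] = value
            row[f"eta_{name}"] = eta
        rows[cond.key] = row
    obs = pd.DataFrame.from_dict(rows, orient="index")
    obs.index.name = "key"
    return AssayDataset(tuple(conditions), obs, truth=dict(truth))
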