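"""Receptor–ligand binding kinetics with and without kinetic proofreading.

A CAR T cell carrying ``R`` receptor copies conjugates with a target cell
carrying ``H`` antigen (e.g. HER2) copies.  Free receptor and ligand bind at
rate ``k_on`` and the complex unbinds at ``k_off``.  Two signalling variants
are supported:

* **NKP** (no kinetic proofreading): T-cell output is proportional to the
  steady-state abundance ``C0`` of the bound complex, the smaller root of
  ``C**2 - (R + H + K_D) C + R H = 0``.
* **KP** (kinetic proofreading): the bound complex must survive ``N``
  sequential first-order modifications at rate ``k_p`` before producing the
  active end complex ``C_N``; unbinding at any stage resets the chain.  At
  steady state ``C_N = C0 * alpha**N`` with ``alpha = k_p / (k_off + k_p)``,
  and the unmodified bound pool is ``C0_KP = C0 / beta`` with
  ``beta = 1 + k_p / k_off``.

Proofreading introduces a waiting time ``tau_w ~ 1/k_p`` that a complex must
outlive (``1/k_off > tau_w``) to signal productively, which is what lets the
KP variant discriminate ligand affinities that the NKP variant cannot.

All abundances are copies per cell (molecules/cell); binding and modification
rates are per second.  The per-day lysis/proliferation constants live in
:class:`ResponseParams` and are applied downstream by the population layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BindingParams",
    "KPParams",
    "ResponseParams",
    "SteadyStateComplexes",
    "nkp_complex",
    "kp_c0",
    "kp_active_complex",
    "steady_state_complexes",
    "kp_chain_oracle",
    "response_rates",
    "params_to_json",
    "params_from_json",
]

#: seconds per day; applied exactly once, when population dynamics combine
#: per-second binding steady states with per-day response constants.
SECONDS_PER_DAY = 86_400.0

_KD_REL_TOL = 1e-9


@dataclass(frozen=True)
class BindingParams:
    """Receptor–ligand binding parameters in per-cell copy-number units.

    Any two of ``k_on`` ((molecules/cell)^-1 s^-1), ``k_off`` (s^-1) and
    ``K_D`` (molecules/cell) determine the third through ``K_D = k_off/k_on``;
    supplying all three is allowed but they must be consistent.
    """

    k_on: float | None = None
    k_off: float | None = None
    K_D: float | None = None

    def __post_init__(self) -> None:
        k_on, k_off, K_D = self.k_on, self.k_off, self.K_D
        given = {n: v for n, v in
                 (("k_on", k_on), ("k_off", k_off), ("K_D", K_D))
                 if v is not None}
        if len(given) < 2:
            raise ValueError(
                "BindingParams needs at least two of k_on, k_off, K_D")
        for name, value in given.items():
            if value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")
        if k_on is None:
            # K_D = 0 is the infinite-affinity limit; closed forms only
            # need K_D so an infinite k_on is acceptable there
            object.__setattr__(
                self, "k_on", np.inf if K_D == 0 else k_off / K_D)
        elif k_off is None:
            object.__setattr__(self, "k_off", k_on * K_D)
        elif K_D is None:
            if k_on == 0:
                raise ValueError("cannot derive K_D from k_on = 0")
            object.__setattr__(self, "K_D", k_off / k_on)
        else:
            # all three supplied: enforce K_D * k_on = k_off
            lhs, rhs = K_D * k_on, k_off
            scale = max(abs(lhs), abs(rhs), 1e-300)
            if abs(lhs - rhs) > _KD_REL_TOL * scale:
                raise ValueError(
                    f"inconsistent parameters: K_D*k_on = {lhs:.6g} "
                    f"but k_off = {rhs:.6g}")


@dataclass(frozen=True)
class KPParams:
    """Proofreading chain parameters.

    ``k_p`` is the per-step modification rate (s^-1) and ``N`` the number of
    steps; ``N`` may be non-integer in the closed forms (continuous best-fit
    values are typical) even though the mechanistic chain is discrete.
    """

    k_p: float
    N: float

    def __post_init__(self) -> None:
        if self.k_p < 0:
            raise ValueError(f"k_p must be nonnegative, got {self.k_p}")
        if self.N < 0:
            raise ValueError(f"N must be nonnegative, got {self.N}")

    def alpha(self, k_off: float) -> float:
        """Per-step survival probability ``k_p / (k_off + k_p)``."""
        if self.k_p == 0:
            return 0.0 if k_off > 0 else 1.0
        return self.k_p / (k_off + self.k_p)

    def beta(self, k_off: float) -> float:
        """Bound-pool amplification ``1 + k_p / k_off``."""
        if self.k_p == 0:
            return 1.0
        if k_off == 0:
            raise ValueError("beta undefined: k_off = 0 with k_p > 0")
        return 1.0 + self.k_p / k_off

    @property
    def tau_w(self) -> float:
        """Proofreading waiting-time scale ``1/k_p`` in seconds."""
        if self.k_p == 0:
            return np.inf
        return 1.0 / self.k_p


@dataclass(frozen=True)
class ResponseParams:
    """Linear response constants mapping complex abundance to cell rates.

    ``lambda_c``: target-cell lysis rate per signalling complex (day^-1).
    ``rho_c``: CAR-T proliferation rate per signalling complex (day^-1).
    """

    lambda_c: float
    rho_c: float

    def __post_init__(self) -> None:
        if self.lambda_c < 0 or self.rho_c < 0:
            raise ValueError("response constants must be nonnegative")


@dataclass(frozen=True)
class SteadyStateComplexes:
    """Steady-state complex abundances for one (R, H) pair, molecules/cell."""

    C0_nkp: float
    C0_kp: float
    total_bound: float
    CN: float


def _check_rh(R, H) -> None:
    if np.any(np.asarray(R) < 0) or np.any(np.asarray(H) < 0):
        raise ValueError("copy numbers R and H must be nonnegative")


def nkp_complex(R, H, binding: BindingParams):
    """Steady-state bound-complex abundance ``C0(R, H, K_D)``.

    The smaller root of ``C**2 - (R+H+K_D) C + R H = 0``, i.e.

        C0 = (R + H + K_D)/2 * (1 - sqrt(1 - 4 R H / (R + H + K_D)**2))

    evaluated in the multiply-by-conjugate form ``2 R H / (s + sqrt(...))``
    to avoid catastrophic cancellation when ``4 R H << s**2``.  Accepts
    scalars or broadcastable arrays; result lies in ``[0, min(R, H)]``.
    """
    _check_rh(R, H)
    R = np.asarray(R, dtype=float)
    H = np.asarray(H, dtype=float)
    K_D = float(binding.K_D)
    s = R + H + K_D
    if np.any(s == 0):
        raise ValueError("R, H and K_D cannot all be zero")
    radicand = np.clip(s * s - 4.0 * R * H, 0.0, None)
    c0 = 2.0 * R * H / (s + np.sqrt(radicand))
    c0 = np.minimum(c0, np.minimum(R, H))  # guard roundoff at the boundary
    return float(c0) if c0.ndim == 0 else c0


def kp_c0(R, H, binding: BindingParams, kp: KPParams):
    """Unmodified bound complex under proofreading: ``C0 / beta``."""
    beta = kp.beta(binding.k_off)
    c0 = nkp_complex(R, H, binding)
    return c0 / beta


def kp_active_complex(R, H, binding: BindingParams, kp: KPParams):
    """Active end-complex abundance ``C_N = C0_KP * beta * alpha**N``.

    Algebraically equal to ``nkp_complex(R, H) * alpha**N``.
    """
    alpha = kp.alpha(binding.k_off)
    c0 = nkp_complex(R, H, binding)
    return c0 * alpha ** kp.N


def steady_state_complexes(R: float, H: float, binding: BindingParams,
                           kp: KPParams) -> SteadyStateComplexes:
    """All steady-state complex pools for a single (R, H) pair."""
    c0 = nkp_complex(R, H, binding)
    beta = kp.beta(binding.k_off)
    return SteadyStateComplexes(
        C0_nkp=c0,
        C0_kp=c0 / beta,
        total_bound=c0,
        CN=c0 * kp.alpha(binding.k_off) ** kp.N,
    )


def kp_chain_oracle(R: float, H: float, binding: BindingParams, kp: KPParams,
                    horizon: float = 1e7, tol: float = 1e-9,
                    rtol: float = 1e-10) -> np.ndarray:
    """Brute-force mass-action steady state of the full proofreading chain.

    Integrates the (N+1)-complex system — free R/H bind at ``k_on``, every
    ``C_i`` unbinds to free R + H at ``k_off``, ``C_i -> C_{i+1}`` at ``k_p``
    for ``i < N`` — until the derivatives settle, then polishes the fixed
    point of the same mass-action right-hand side with a Newton-type root
    solve.  Returns the vector ``[C_0 .. C_N]``.  Serves as the independent
    check on the closed forms; requires integer ``N``.

    Parameters
    ----------
    horizon : float
        Maximum integration time in seconds.
    tol : float
        Settling criterion for the integration phase:
        ``max |dC/dt| < tol * rate_scale * max(C, 1)`` where ``rate_scale``
        is the slowest relevant rate (so the criterion is time-scale
        invariant); the root polish then tightens the state to solver
        precision.

    Raises
    ------
    RuntimeError
        If neither the integrator nor the polish reaches a steady state.
    """
    if kp.N != int(kp.N):
        raise ValueError(f"oracle requires integer N, got {kp.N}")
    n = int(kp.N)
    k_on, k_off, k_p = binding.k_on, binding.k_off, kp.k_p

    def rhs(_t, c):
        bound = c.sum()
        flux_in = k_on * (R - bound) * (H - bound)
        dc = np.empty_like(c)
        for i in range(n + 1):
            step_out = k_p * c[i] if i < n else 0.0
            step_in = k_p * c[i - 1] if i > 0 else flux_in
            dc[i] = step_in - step_out - k_off * c[i]
        return dc

    # equilibration is limited by the slowest positive rate in the chain
    rates = [x for x in (k_off, k_p, k_on * (R + H + binding.K_D)) if x > 0]
    if not rates:
        raise ValueError("all rates zero; no dynamics to integrate")
    tau = 1.0 / min(rates)

    c = np.zeros(n + 1)
    t_end = min(tau, horizon)
    converged = False
    while t_end <= horizon:
        sol = solve_ivp(rhs, (0.0, t_end), c, method="LSODA",
                        rtol=rtol, atol=1e-14)
        if not sol.success:
            raise RuntimeError(f"chain integration failed: {sol.message}")
        c_new = sol.y[:, -1]
        scale = max(c_new.max(initial=0.0), 1e-300)
        if np.max(np.abs(c_new - c)) < tol * scale:
            c = c_new
            converged = True
            break
        c = c_new
        if t_end == horizon:
            break
        t_end = min(2.0 * t_end, horizon)

    from scipy.optimize import root

    polish = root(lambda x: rhs(0.0, x), c, method="hybr",
                  options={"xtol": 1e-13})
    if polish.success:
        cand = polish.x
        floor = -1e-9 * max(cand.max(initial=0.0), 1.0)
        if np.all(cand >= floor) and \
                np.max(np.abs(rhs(0.0, np.clip(cand, 0.0, None)))) <= \
                np.max(np.abs(rhs(0.0, c))):
            c = np.clip(cand, 0.0, None)
            converged = True
    if not converged:
        raise RuntimeError(
            "proofreading chain did not reach steady state within horizon "
            f"{horizon:g} s (max |dC/dt| = "
            f"{np.max(np.abs(rhs(0.0, c))):.3g})")
    return c


def params_to_json(binding: BindingParams, kp: KPParams | None = None,
                   resp: ResponseParams | None = None, path=None) -> str:
    """Serialize a parameter set as JSON with explicit unit fields."""
    import json

    payload = {
        "binding": {
            "k_on": {"value": binding.k_on,
                     "unit": "(molecules_per_cell)^-1 per_second"},
            "k_off": {"value": binding.k_off, "unit": "per_second"},
            "K_D": {"value": binding.K_D, "unit": "molecules_per_cell"},
        }
    }
    if kp is not None:
        payload["proofreading"] = {
            "k_p": {"value": kp.k_p, "unit": "per_second"},
            "N": {"value": kp.N, "unit": "steps"},
        }
    if resp is not None:
        payload["response"] = {
            "lambda_c": {"value": resp.lambda_c,
                         "unit": "per_day per_complex"},
            "rho_c": {"value": resp.rho_c, "unit": "per_day per_complex"},
        }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def params_from_json(source) -> tuple[BindingParams, KPParams | None,
                                      ResponseParams | None]:
    """Inverse of :func:`params_to_json`; ``source`` is a path or JSON str."""
    import json
    import os

    if isinstance(source, str) and not os.path.exists(source):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    b = payload["binding"]
    binding = BindingParams(k_on=b["k_on"]["value"],
                            k_off=b["k_off"]["value"],
                            K_D=b["K_D"]["value"])
    kp = resp = None
    if "proofreading" in payload:
        p = payload["proofreading"]
        kp = KPParams(k_p=p["k_p"]["value"], N=p["N"]["value"])
    if "response" in payload:
        r = payload["response"]
        resp = ResponseParams(lambda_c=r["lambda_c"]["value"],
                              rho_c=r["rho_c"]["value"])
    return binding, kp, resp


def response_rates(C: float, resp: ResponseParams) -> tuple[float, float]:
    """Per-cell-pair (lysis, proliferation) rates in day^-1.

    Linear in the signalling complex abundance ``C`` — pass ``C0`` for the
    NKP variant or ``C_N`` for the KP variant.
    """
    if np.any(np.asarray(C) < 0):
        raise ValueError("complex abundance must be nonnegative")
    return resp.lambda_c * C, resp.rho_c * C
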