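"""First-passage simulators for conflict diffusion models with within-trial boundary shifts.

Two generative models are implemented:

* a standard two-boundary drift diffusion model (DDM) with separate drift
  rates per congruency condition, and
* a diffusion model of conflict (DMC) in which a transient, gamma-shaped
  automatic activation is superimposed on a constant controlled drift,
  producing fast errors on incongruent trials.

Both models can be extended with a congruency-dependent step change of the
decision boundary ("boundary shift") occurring at a noisy time measured from
the onset of evidence accumulation.  Non-decision time and the shift time
vary trial by trial (zero-truncated normal).

Scaling conventions
-------------------
DDM parameters follow the classic small-noise convention: evidence units
with diffusion coefficient ``sigma = 0.1`` and time in seconds.  DMC
parameters follow the conflict-model literature: evidence units with
``sigma = 4`` per sqrt-millisecond, controlled drift ``mu_c`` in units per
millisecond, but all *time* fields of the parameter object (``t_peak``,
``t0_mean``, ``shift_time_mean``, ...) are expressed in seconds for a
uniform API.  The simulator converts internally; both coefficients are
plain fields and may be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.special import ndtr, ndtri

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
CONGRUENCIES = (CONGRUENT, INCONGRUENT)

#: classic DDM diffusion coefficient (evidence units per sqrt-second)
SIGMA_DDM = 0.1
#: conventional DMC diffusion coefficient (evidence units per sqrt-millisecond)
SIGMA_DMC = 4.0

_MS_PER_S = 1000.0


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DDMShiftParams:
    """Standard DDM with per-congruency drifts and optional boundary shift.

    Geometry: evidence starts at ``z_rel * a`` between a lower boundary at 0
    and an upper (correct) boundary at ``a``.  A shift of size
    ``shift_delta_*`` changes the boundary *separation*, applied
    symmetrically about the start point, at a per-trial shift time.
    """

    a: float
    v_congruent: float
    v_incongruent: float
    t0_mean: float
    t0_sd: float = 0.0
    z_rel: float = 0.5
    shift_delta_congruent: float = 0.0
    shift_delta_incongruent: float = 0.0
    shift_time_mean: float = 0.0
    shift_time_sd: float = 0.0
    sigma: float = SIGMA_DDM

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if not 0.0 < self.z_rel < 1.0:
            raise ValueError("z_rel must lie in (0, 1)")
        if self.t0_mean < 0 or self.t0_sd < 0:
            raise ValueError("non-decision time parameters must be >= 0")
        if self.shift_time_mean < 0 or self.shift_time_sd < 0:
            raise ValueError("shift time parameters must be >= 0")
        for d in (self.shift_delta_congruent, self.shift_delta_incongruent):
            if self.a + d <= 0:
                raise ValueError("a + shift_delta must stay > 0 (boundaries may not cross)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def drift(self, congruency: str) -> float:
        return self.v_congruent if congruency == CONGRUENT else self.v_incongruent

    def shift_delta(self, congruency: str) -> float:
        return (self.shift_delta_congruent if congruency == CONGRUENT
                else self.shift_delta_incongruent)


@dataclass(frozen=True)
class DMCShiftParams:
    """Diffusion model of conflict with optional boundary shift.

    Geometry: evidence starts at 0 with boundaries at ``+b`` (correct) and
    ``-b``.  The automatic activation has amplitude ``zeta`` (> 0; its sign
    is set by congruency: toward the correct boundary on congruent trials,
    toward the error boundary on incongruent trials), peak latency
    ``t_peak`` (seconds) and shape ``alpha``.  ``mu_c`` is in evidence units
    per millisecond, per the conflict-model convention.
    """

    b: float
    mu_c: float
    zeta: float
    t_peak: float
    t0_mean: float
    alpha: float = 2.0
    t0_sd: float = 0.0
    shift_delta_congruent: float = 0.0
    shift_delta_incongruent: float = 0.0
    shift_time_mean: float = 0.0
    shift_time_sd: float = 0.0
    sigma: float = SIGMA_DMC

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("boundary b must be > 0")
        if self.alpha <= 1:
            raise ValueError("alpha must be > 1")
        if self.t_peak <= 0:
            raise ValueError("t_peak must be > 0")
        if self.zeta < 0:
            raise ValueError("zeta is an amplitude and must be >= 0")
        if self.t0_mean < 0 or self.t0_sd < 0:
            raise ValueError("non-decision time parameters must be >= 0")
        if self.shift_time_mean < 0 or self.shift_time_sd < 0:
            raise ValueError("shift time parameters must be >= 0")
        for d in (self.shift_delta_congruent, self.shift_delta_incongruent):
            if self.b + d <= 0:
                raise ValueError("b + shift_delta must stay > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def shift_delta(self, congruency: str) -> float:
        return (self.shift_delta_congruent if congruency == CONGRUENT
                else self.shift_delta_incongruent)


DEFAULT_DDM = DDMShiftParams(a=0.15, v_congruent=0.30, v_incongruent=0.20,
                             t0_mean=0.30, t0_sd=0.03)
DEFAULT_DMC = DMCShiftParams(b=75.0, mu_c=0.5, zeta=20.0, t_peak=0.04,
                             t0_mean=0.30, t0_sd=0.03)


@dataclass
class TrialOutcome:
    """Outcome of one simulated trial."""

    rt: float           # seconds, NaN when censored without a crossing
    response: int       # +1 upper/correct, -1 lower/error, 0 no crossing
    censored: bool


@dataclass
class SimResult:
    """Vectorized batch of trial outcomes."""

    rt: np.ndarray        # seconds; NaN where no boundary was hit
    response: np.ndarray  # int8: +1 correct, -1 error, 0 none
    censored: np.ndarray  # bool

    def __len__(self) -> int:
        return self.rt.shape[0]

    @property
    def valid(self) -> np.ndarray:
        return ~self.censored

    def accuracy(self) -> float:
        """Proportion correct among non-censored trials."""
        v = self.valid
        if not v.any():
            return float("nan")
        return float(np.mean(self.response[v] == 1))

    def correct_rt(self) -> np.ndarray:
        return self.rt[self.valid & (self.response == 1)]

    def signed_rt(self) -> np.ndarray:
        """Non-censored RTs with error responses negated (joint CDF encoding)."""
        v = self.valid
        return self.rt[v] * self.response[v]


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------

def automatic_drift(t, zeta: float, t_peak: float, alpha: float = 2.0):
    """Time course of the automatic drift contribution (units per unit time).

    Derivative of the expected gamma-shaped automatic activation
    ``E[Xa](t) = zeta * (t/t_peak)**(alpha-1) * exp(-(alpha-1)(t-t_peak)/t_peak)``,
    i.e. the pulse integrates to an activation that peaks at exactly ``zeta``
    when ``t = t_peak``.  Works in any consistent time unit.
    """
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    if t_peak <= 0:
        raise ValueError("t_peak must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("t must be > 0")
    am1 = alpha - 1.0
    activation = zeta * (t_arr / t_peak) ** am1 * np.exp(-am1 * (t_arr - t_peak) / t_peak)
    out = activation * am1 * (1.0 / t_arr - 1.0 / t_peak)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def boundary_at(t, base: float, shift_delta: float, shift_time: float):
    """Boundary value over time: ``base`` before ``shift_time``, then ``base + shift_delta``."""
    if base <= 0:
        raise ValueError("base boundary must be > 0")
    if base + shift_delta <= 0:
        raise ValueError("base + shift_delta must stay > 0")
    t_arr = np.asarray(t, dtype=float)
    out = np.where(t_arr < shift_time, base, base + shift_delta)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def truncnorm_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Quantile function of a normal truncated at zero (lower tail removed).

    Used so trial-level noise draws can be held fixed (common random
    numbers) while location/scale change during optimization.
    """
    u = np.asarray(u, dtype=float)
    if sd <= 0:
        return np.full_like(u, float(mean))
    p0 = ndtr(-mean / sd)
    return mean + sd * ndtri(p0 + u * (1.0 - p0))


# ---------------------------------------------------------------------------
# Euler-Maruyama first-passage kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fp_kernel(seed, drift, sig_sqdt, dt, x0, up0, lo0, d_up, d_lo,
               shift_steps, n_steps):  # pragma: no cover - exercised via wrapper
    n = shift_steps.shape[0]
    dec = np.empty(n)
    resp = np.zeros(n, dtype=np.int8)
    np.random.seed(seed)
    chunk = 128  # noise drawn in blocks; much faster than scalar draws
    for i in range(n):
        x = x0
        ss = shift_steps[i]
        up = up0
        lo = lo0
        k = 0
        done = False
        while k < n_steps and not done:
            m = min(chunk, n_steps - k)
            eps = np.random.standard_normal(m)
            for j in range(m):
                kk = k + j
                if kk >= ss:
                    up = up0 + d_up
                    lo = lo0 + d_lo
                x += drift[kk] * dt + sig_sqdt * eps[j]
                if x >= up:
                    resp[i] = 1
                    dec[i] = (kk + 1) * dt
                    done = True
                    break
                if x <= lo:
                    resp[i] = -1
                    dec[i] = (kk + 1) * dt
                    done = True
                    break
            k += m
        if resp[i] == 0:
            dec[i] = np.nan
    return dec, resp


def _drift_profile(params, congruency: str, n_steps: int, dt: float) -> np.ndarray:
    """Per-step drift in evidence units per second (evaluated at step midpoints)."""
    if isinstance(params, DDMShiftParams):
        return np.full(n_steps, params.drift(congruency), dtype=float)
    if isinstance(params, DMCShiftParams):
        t_mid = (np.arange(n_steps) + 0.5) * dt
        sign = 1.0 if congruency == CONGRUENT else -1.0
        auto = automatic_drift(t_mid, sign * params.zeta, params.t_peak, params.alpha) \
            if params.zeta != 0 else np.zeros(n_steps)
        return params.mu_c * _MS_PER_S + np.asarray(auto, dtype=float)
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def _geometry(params, congruency: str):
    """(x0, up0, lo0, d_up, d_lo, sigma_per_sqrt_s) for the kernel."""
    delta = params.shift_delta(congruency)
    if isinstance(params, DDMShiftParams):
        # centre the walk on the start point; separation change is symmetric
        up0 = params.a * (1.0 - params.z_rel)
        lo0 = -params.a * params.z_rel
        return 0.0, up0, lo0, delta / 2.0, -delta / 2.0, params.sigma
    up0 = params.b
    lo0 = -params.b
    sigma_s = params.sigma * math.sqrt(_MS_PER_S)
    return 0.0, up0, lo0, delta, -delta, sigma_s


def simulate_condition(params, congruency: str, n: int, rng,
                       dt: float = 0.001, deadline: float = 3.0) -> SimResult:
    """Simulate ``n`` first-passage trials of one congruency condition.

    ``rng`` may be a ``numpy.random.Generator`` or an integer seed; the same
    seed yields a byte-identical result.  RTs include the per-trial
    non-decision time.  Trials whose RT exceeds ``deadline`` (or that never
    cross a boundary) are flagged censored.
    """
    if congruency not in CONGRUENCIES:
        raise ValueError(f"unknown congruency {congruency!r}")
    if n <= 0:
        raise ValueError("n must be >= 1")
    if dt <= 0 or deadline <= 0:
        raise ValueError("dt and deadline must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    n_steps = int(math.ceil(deadline / dt))
    drift = _drift_profile(params, congruency, n_steps, dt)
    x0, up0, lo0, d_up, d_lo, sigma = _geometry(params, congruency)

    # draw streams in a fixed order so seeds align across model variants
    u_t0 = rng.random(n)
    u_shift = rng.random(n)
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    t0 = truncnorm_ppf(u_t0, params.t0_mean, params.t0_sd)
    delta = params.shift_delta(congruency)
    if delta == 0.0:
        shift_steps = np.full(n, n_steps + 1, dtype=np.int64)  # never fires
    else:
        st = truncnorm_ppf(u_shift, params.shift_time_mean, params.shift_time_sd)
        shift_steps = np.maximum(np.floor(st / dt), 0).astype(np.int64)

    dec, resp = _fp_kernel(kernel_seed, drift, sigma * math.sqrt(dt), dt,
                           x0, up0, lo0, d_up, d_lo, shift_steps, n_steps)
    rt = dec + t0
    censored = (resp == 0) | (rt > deadline)
    return SimResult(rt=rt, response=resp, censored=censored)


def simulate_trial(params, congruency: str, rng, dt: float = 0.001,
                   deadline: float = 3.0) -> TrialOutcome:
    """Simulate a single trial (convenience wrapper over :func:`simulate_condition`)."""
    res = simulate_condition(params, congruency, 1, rng, dt=dt, deadline=deadline)
    return TrialOutcome(rt=float(res.rt[0]), response=int(res.response[0]),
                        censored=bool(res.censored[0]))


def without_shift(params):
    """Copy of ``params`` with the boundary-shift machinery disabled."""
    return replace(params, shift_delta_congruent=0.0, shift_delta_incongruent=0.0,
                   shift_time_mean=0.0, shift_time_sd=0.0)
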