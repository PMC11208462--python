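"""Lumped (0D) outlet and rheology models.

Three pieces support the hemodynamic stage:

* the three-element Windkessel (RCR) outlet model

  .. math:: \\frac{dP}{dt} = R_p\\frac{dQ}{dt}
            + \\frac{1}{R_d C}\\bigl[(R_p + R_d)Q - P\\bigr]

  integrated with the explicit Euler scheme (the update used when such a
  model is coupled to a 3D solver), with dQ/dt from centred periodic
  differences;

* the Carreau shear-thinning viscosity law
  μ(γ̇) = μ∞ + (μ0 − μ∞)[1 + (λγ̇)²]^{(n−1)/2};

* outlet total-resistance assignment for a prescribed flow division,
  with the proximal fraction fixed at R_p/R_T = 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import StabilityError

__all__ = [
    "RCRParams",
    "FlowWaveform",
    "BloodProperties",
    "RCRResult",
    "simulate_rcr",
    "carreau_viscosity",
    "assign_outlet_resistances",
]


@dataclass
class RCRParams:
    """Three-element Windkessel parameters (SI: Pa·s/m³ and m³/Pa)."""

    R_p: float
    R_d: float
    C: float

    def __post_init__(self) -> None:
        if self.R_p <= 0 or self.R_d <= 0 or self.C <= 0:
            raise ValueError("RCR parameters must be positive")

    @property
    def R_T(self) -> float:
        return self.R_p + self.R_d

    @classmethod
    def from_total(
        cls, R_T: float, C: float, proximal_fraction: float = 0.2
    ) -> "RCRParams":
        """Split a total resistance using the standard R_p/R_T = 0.2."""
        return cls(R_p=proximal_fraction * R_T, R_d=(1 - proximal_fraction) * R_T, C=C)


@dataclass
class FlowWaveform:
    """Flow-rate samples (m³/s) at uniform instants over one period (s)."""

    q: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        if self.q.ndim != 1 or len(self.q) < 16:
            raise ValueError("waveform needs ≥ 16 uniform samples")
        if self.period <= 0:
            raise ValueError("period must be positive")

    def resample(self, dt: float) -> np.ndarray:
        """Periodic linear interpolation onto a uniform dt grid (one period)."""
        n = int(round(self.period / dt))
        t = np.arange(n) * dt
        ts = np.arange(len(self.q) + 1) * (self.period / len(self.q))
        qs = np.append(self.q, self.q[0])
        return np.interp(t, ts, qs)

    @property
    def mean(self) -> float:
        return float(self.q.mean())


@dataclass
class BloodProperties:
    """Blood density and Carreau constants (defaults: adult human blood)."""

    rho: float = 1060.0  # kg/m³
    mu0: float = 0.056  # Pa·s, zero-shear viscosity
    mu_inf: float = 0.00345  # Pa·s, infinite-shear viscosity
    lam: float = 3.313  # s, relaxation time
    n: float = 0.3568  # power-law index

    def __post_init__(self) -> None:
        if not self.mu0 > self.mu_inf > 0:
            raise ValueError("need mu0 > mu_inf > 0")
        if not 0 < self.n < 1:
            raise ValueError("power-law index must lie in (0, 1)")


@dataclass
class RCRResult:
    """One converged period of the RCR pressure response."""

    times: np.ndarray  # s, within one period
    pressure: np.ndarray  # Pa
    converged: bool
    n_cycles_run: int

    @property
    def pulse_pressure(self) -> float:
        return float(self.pressure.max() - self.pressure.min())

    @property
    def mean_pressure(self) -> float:
        return float(self.pressure.mean())


def simulate_rcr(
    params: RCRParams,
    waveform: FlowWaveform,
    dt: float = 1e-3,
    n_cycles: int = 10,
    p0: float | None = None,
    convergence_tol: float = 1e-3,
) -> RCRResult:
    """Explicit-Euler trajectory of the RCR model; returns the last period.

    dQ/dt uses centred periodic differences on the dt grid.  Integration
    runs until consecutive cycles agree (max |ΔP| < ``convergence_tol`` ×
    pulse pressure) or ``n_cycles`` is exhausted.  Divergence raises a
    :class:`StabilityError` naming the explicit-Euler limit dt < 2·R_d·C.
    """
    if dt > waveform.period / 16:
        raise ValueError("dt must be ≤ period/16")
    q = waveform.resample(dt)
    n = len(q)
    dqdt = (np.roll(q, -1) - np.roll(q, 1)) / (2.0 * dt)
    rp, rd, c = params.R_p, params.R_d, params.C
    inv_tau = 1.0 / (rd * c)
    p = params.R_T * waveform.mean if p0 is None else float(p0)
    scale = max(abs(params.R_T * np.abs(q).max()), abs(p), 1.0)
    prev_cycle = None
    cycle = np.empty(n)
    converged = False
    ran = 0
    for cyc in range(n_cycles):
        ran = cyc + 1
        for i in range(n):
            cycle[i] = p
            p = p + dt * (rp * dqdt[i] + inv_tau * ((rp + rd) * q[i] - p))
            if not np.isfinite(p) or abs(p) > 1e6 * scale:
                raise StabilityError(
                    f"explicit Euler diverged at dt={dt:g} s; "
                    f"stability requires dt < 2·R_d·C = {2 * rd * c:g} s"
                )
        if prev_cycle is not None:
            pulse = max(cycle.max() - cycle.min(), 1e-300)
            if np.abs(cycle - prev_cycle).max() < convergence_tol * pulse:
                converged = True
                break
        prev_cycle = cycle.copy()
    return RCRResult(
        times=np.arange(n) * dt,
        pressure=cycle.copy(),
        converged=converged,
        n_cycles_run=ran,
    )


def rcr_transfer_function(params: RCRParams, omega: float) -> complex:
    """Analytic P̂/Q̂ of the RCR model at angular frequency ω (rad/s)."""
    return params.R_p + params.R_d / (1.0 + 1j * omega * params.R_d * params.C)


def carreau_viscosity(
    shear_rate: np.ndarray | float, props: BloodProperties | None = None
) -> np.ndarray | float:
    """Carreau dynamic viscosity (Pa·s) at shear rate γ̇ (1/s).

    Monotone non-increasing, bounded in [μ∞, μ0]; negative shear rates are
    a domain error.
    """
    props = props or BloodProperties()
    g = np.asarray(shear_rate, float)
    if np.any(g < 0):
        raise ValueError("shear rate must be ≥ 0")
    mu = props.mu_inf + (props.mu0 - props.mu_inf) * (
        1.0 + (props.lam * g) ** 2
    ) ** ((props.n - 1.0) / 2.0)
    return float(mu) if np.isscalar(shear_rate) else mu


def assign_outlet_resistances(
    flow_fractions: Sequence[float],
    total_flow: float,
    mean_pressure: float,
    time_constant: float = 1.0,
    proximal_fraction: float = 0.2,
) -> list[RCRParams]:
    """RCR parameter sets achieving a prescribed steady flow division.

    Under a common pressure source, outlet i carries the fraction f_i of
    ``total_flow`` when R_T,i = P_ref / (f_i · Q_total); the proximal share
    is R_p = 0.2·R_T and the compliance follows from the distal time
    constant τ = R_d·C (default 1.0 s, a typical systemic decay time).
    """
    fr = np.asarray(flow_fractions, float)
    if np.any(fr <= 0):
        raise ValueError("flow fractions must be positive")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("flow fractions must sum to 1")
    if total_flow <= 0 or mean_pressure <= 0:
        raise ValueError("total flow and reference pressure must be positive")
    out = []
    for f in fr:
        r_t = mean_pressure / (f * total_flow)
        r_d = (1 - proximal_fraction) * r_t
        out.append(
            RCRParams(R_p=proximal_fraction * r_t, R_d=r_d, C=time_constant / r_d)
        )
    return out
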