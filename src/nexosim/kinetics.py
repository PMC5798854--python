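"""Protein production, templated misfolding and adaptive clearance.

Each neuronal section holds two concentration fractions, normal ``Cn`` and
pathogenic ``Cp``, bounded by ``Cn + Cp <= C_max = 1``.  Per timestep:

* production adds a stochastic amount to the soma only, drawn from
  ``N(R_P, R_P^2)`` (mean and standard deviation both equal to the rate,
  i.e. coefficient of variation 1), truncated at zero;
* misfolding converts ``b = R_M * Cn * Cp`` from the normal to the pathogenic
  pool in every section, a mass-action product law validated against the
  particle-level oracle in :mod:`nexosim.particles`;
* clearance removes a stochastic amount drawn around an *adaptive* mean
  ``mu = R_C * ln(1 + (e - 1) * C / C_norm)``, which equals the nominal rate
  exactly at the normal concentration level and vanishes at zero.

The single-compartment point model couples the three processes in one volume
and is used to study loss of the normal/pathogenic equilibrium as the
misfolding rate varies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "adaptive_clearance_rate",
    "rate_draw",
    "production_step",
    "misfold_step",
    "clearance_step",
    "PointModelResult",
    "point_model_run",
    "FIG_EQUILIBRIUM_PARAMS",
]

_E_MINUS_1 = math.e - 1.0


def adaptive_clearance_rate(C, R_C, C_norm):
    """Mean clearance rate ``mu = R_C * ln(1 + (e-1) C / C_norm)``.

    Satisfies ``mu(0) = 0`` and ``mu(C_norm) = R_C`` exactly, so clearance
    holds concentrations near their normal level while adapting up or down
    with the current burden.
    """
    if np.any(np.asarray(C_norm) <= 0):
        raise ValueError("normal concentration level must be positive")
    return R_C * np.log1p(_E_MINUS_1 * np.asarray(C) / C_norm)


def rate_draw(rng, mean):
    """Draw from N(mean, mean^2) elementwise (coefficient of variation 1).

    Draws are *not* truncated: a negative draw is the net outcome of the
    step's molecular fluctuations and keeps the long-run mean exactly at the
    nominal rate.  (One-sided truncation would inflate both production and
    clearance by the same ~8% factor and shift the misfolding-rate stability
    boundary of the point model.)  Concentrations are floored at zero after
    application instead.
    """
    mean = np.asarray(mean, dtype=float)
    return rng.normal(mean, mean)


def production_step(Cn, Cp, alive, soma_index, R_Pn, R_Pp, rng):
    """Add produced protein to the soma of every living neuron (in place).

    One draw per neuron per species is consumed regardless of life state so
    that the random stream stays aligned across runs (common random numbers);
    dead neurons simply discard their draw.  Dendrite and axon receive
    nothing.
    """
    n = alive.size
    a_n = rate_draw(rng, np.full(n, R_Pn))
    a_p = rate_draw(rng, np.full(n, R_Pp))
    soma_alive = soma_index[alive]
    Cn[soma_alive] = np.maximum(Cn[soma_alive] + a_n[alive], 0.0)
    Cp[soma_alive] = np.maximum(Cp[soma_alive] + a_p[alive], 0.0)
    return a_n, a_p


def misfold_step(Cn, Cp, R_M):
    """Convert ``b = R_M * Cn * Cp`` from normal to pathogenic (in place).

    Applies to every section including those of dead neurons (templating does
    not need cellular machinery); conserves ``Cn + Cp`` exactly.
    """
    b = R_M * Cn * Cp
    Cn -= b
    Cp += b
    return b


def clearance_step(Cn, Cp, alive_sections, R_Cn, R_Cp, C_nn, C_pn, rng):
    """Remove cleared protein from sections of living neurons (in place).

    Draws are ``N(mu, mu^2)`` capped above at the available concentration
    (clearance cannot remove more than is present); negative draws are kept
    so the mean removal stays exactly ``mu`` away from the boundary.  Both
    species always consume a draw (stream alignment); dead sections are
    masked out.
    """
    mu_n = adaptive_clearance_rate(Cn, R_Cn, C_nn)
    mu_p = adaptive_clearance_rate(Cp, R_Cp, C_pn)
    q_n = np.minimum(rng.normal(mu_n, mu_n), Cn)
    q_p = np.minimum(rng.normal(mu_p, mu_p), Cp)
    Cn[alive_sections] -= q_n[alive_sections]
    Cp[alive_sections] -= q_p[alive_sections]
    return q_n, q_p


#: single-compartment equilibrium experiment protocol
FIG_EQUILIBRIUM_PARAMS = dict(
    Cn0=0.05, Cp0=0.01, C_nn=0.05, C_pn=0.01,
    R_Pn=4e-4, R_Cn=4e-4, R_Pp=0.8e-4, R_Cp=0.8e-4,
)


@dataclass
class PointModelResult:
    """Trajectory of the single-compartment model."""

    t: np.ndarray
    Cn: np.ndarray
    Cp: np.ndarray
    loss_time: int | None  # first step with Cp > threshold, None if never
    params: dict

    @property
    def equilibrium_lost(self) -> bool:
        return self.loss_time is not None


def point_model_run(R_M, *, Cn0=0.05, Cp0=0.01, C_nn=0.05, C_pn=0.01,
                    R_Pn=4e-4, R_Cn=4e-4, R_Pp=0.8e-4, R_Cp=0.8e-4,
                    horizon=200_000, loss_threshold=0.5, seed=0,
                    record_stride=1) -> PointModelResult:
    """Run the single-compartment production/misfolding/clearance model.

    Production, misfolding and clearance are applied in that order each
    timestep.  The equilibrium is declared *lost* at the first step where the
    pathogenic concentration exceeds ``loss_threshold`` (a runaway criterion;
    with ``C_max = 1`` the default 0.5 marks unambiguous divergence).

    Returns the (optionally strided) trajectory and the loss time in steps.
    """
    rng = np.random.default_rng(seed)
    # N(m, m^2) == m * (1 + eps) with eps ~ N(0, 1): pre-draw the eps stream
    eps = rng.standard_normal((horizon, 4))
    Cn, Cp = float(Cn0), float(Cp0)
    ts, cns, cps = [0], [Cn], [Cp]
    loss_time = None
    for t in range(horizon):
        e0, e1, e2, e3 = eps[t]
        Cn = max(Cn + R_Pn * (1.0 + e0), 0.0)
        Cp = max(Cp + R_Pp * (1.0 + e1), 0.0)
        b = R_M * Cn * Cp
        Cn -= b
        Cp += b
        mu_n = R_Cn * math.log1p(_E_MINUS_1 * Cn / C_nn)
        mu_p = R_Cp * math.log1p(_E_MINUS_1 * Cp / C_pn)
        Cn -= min(mu_n * (1.0 + e2), Cn)
        Cp -= min(mu_p * (1.0 + e3), Cp)
        if (t + 1) % record_stride == 0:
            ts.append(t + 1)
            cns.append(Cn)
            cps.append(Cp)
        if Cp > loss_threshold:
            loss_time = t + 1
            break
    params = dict(R_M=R_M, Cn0=Cn0, Cp0=Cp0, C_nn=C_nn, C_pn=C_pn,
                  R_Pn=R_Pn, R_Cn=R_Cn, R_Pp=R_Pp, R_Cp=R_Cp,
                  horizon=horizon, loss_threshold=loss_threshold, seed=seed)
    return PointModelResult(np.array(ts), np.array(cns), np.array(cps),
                            loss_time, params)


def equilibrium_loss_times(R_M, seeds, **kwargs) -> np.ndarray:
    """Loss times for one misfolding rate across several seeds.

    Runs that never lose equilibrium within the horizon are reported as the
    horizon (right-censored), which is conservative for ordering comparisons.
    """
    out = []
    for s in seeds:
        res = point_model_run(R_M, seed=s, record_stride=10_000, **kwargs)
        out.append(res.loss_time if res.loss_time is not None
                   else res.params["horizon"])
    return np.array(out)
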