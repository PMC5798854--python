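"""Neuronal toxicity accumulation, the firing-threshold toxic effect, and death.

Toxicity ``txc`` accrues each step by an exponential function of the mean
total protein concentration over the neuron's three sections,

    txc += 0.001 * (exp(10 * mean_j(Cn_j + Cp_j)) - 1),

is clamped at 1, and is monotone non-decreasing.  The formula deliberately
includes the normal protein pool: any protein burden is damaging, pathogenic
protein simply accumulates past normal levels.  A neuron dies at the first
step its toxicity reaches 1; after death only misfolding and diffusion out
of its sections continue.

The toxic effect couples toxicity to excitability by shifting the firing
threshold, ``Vth_adapt = +/- k * txc`` (positive: loss of function, firing
suppressed; negative: gain of function, hyperexcitability).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "toxicity_increment",
    "update_toxicity",
    "toxic_threshold_shift",
    "death_check",
]

TOXICITY_SCALE = 0.001
TOXICITY_EXPONENT = 10.0


def toxicity_increment(Cn, Cp):
    """Per-neuron increment from flat section concentration arrays (3N)."""
    total = np.asarray(Cn) + np.asarray(Cp)
    mean3 = total.reshape(-1, 3).mean(axis=1)
    return TOXICITY_SCALE * np.expm1(TOXICITY_EXPONENT * mean3)


def update_toxicity(txc, Cn, Cp, alive):
    """Accumulate toxicity for living neurons (in place); clamp at 1."""
    inc = toxicity_increment(Cn, Cp)
    txc[alive] = np.minimum(txc[alive] + inc[alive], 1.0)
    return txc


def toxic_threshold_shift(txc, mode: str, gain: float = 10.0):
    """Threshold shift ``Vth_adapt`` (mV) from toxicity.

    ``mode='increase'`` raises thresholds (loss of function),
    ``mode='decrease'`` lowers them (gain of function).
    """
    if mode == "increase":
        return gain * np.asarray(txc)
    if mode == "decrease":
        return -gain * np.asarray(txc)
    raise ValueError(f"unknown toxic-effect mode {mode!r}")


def death_check(txc, alive, t, death_order, death_times):
    """Record deaths at step ``t`` and update the alive mask (in place).

    Neurons whose toxicity reached 1 this step die together; ties within a
    step are broken by ascending neuron id so the death order is total.
    Returns the ids that died this step.
    """
    dying = np.nonzero(alive & (txc >= 1.0))[0]  # nonzero() is id-ascending
    for i in dying:
        death_order.append(int(i))
        death_times[i] = t
    alive[dying] = False
    return dying
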