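"""Adaptive-threshold leaky integrate-and-fire engine.

The protein machinery needs two things from electrophysiology: spike events
(to trigger synaptic protein transfer) and a firing threshold that toxicity
can shift.  A conductance-level cortical model is deliberately out of scope;
instead each neuron is a leaky integrator with a per-type parameter preset
(RS regular, IB burst-prone via a depolarized reset, FS fast, LTS
low-threshold), Poisson background drive, and delta-synapse coupling scaled
by synaptic strength (excitatory depolarizing, inhibitory hyperpolarizing).

A neuron fires when its potential reaches ``Vth + Vth_adapt``, where
``Vth_adapt`` is the toxicity-driven shift: positive shifts silence the cell
(toxic loss of function), negative shifts make it hyperexcitable (toxic gain
of function).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import EXCITATORY, Network

__all__ = ["TypeParams", "TYPE_PRESETS", "SpikingEngine", "firing_frequency"]


@dataclass(frozen=True)
class TypeParams:
    """LIF parameters for one cell type (mV, ms)."""

    tau_m: float     # membrane time constant
    v_threshold: float
    v_reset: float
    refractory: float  # ms


#: per-type presets; IB's high reset leaves it near threshold after a spike,
#: producing doublet/burst firing
TYPE_PRESETS = {
    "RS": TypeParams(tau_m=20.0, v_threshold=-50.0, v_reset=-65.0, refractory=2.0),
    "IB": TypeParams(tau_m=15.0, v_threshold=-52.0, v_reset=-56.0, refractory=1.0),
    "FS": TypeParams(tau_m=10.0, v_threshold=-48.0, v_reset=-70.0, refractory=0.5),
    "LTS": TypeParams(tau_m=18.0, v_threshold=-53.0, v_reset=-65.0, refractory=1.5),
}

V_REST = -65.0  # mV


class SpikingEngine:
    """Vectorized spiking dynamics for one network.

    Parameters
    ----------
    net:
        The network (synapse strengths become coupling weights, signed by the
        presynaptic type).
    background_rate:
        Poisson event rate per neuron, events/ms.
    background_amp:
        Depolarization per background event, mV.
    synaptic_gain:
        Postsynaptic potential per unit synaptic strength, mV.
    """

    def __init__(self, net: Network, *, background_rate: float = 0.5,
                 background_amp: float = 3.0, synaptic_gain: float = 2.0):
        n = net.n_neurons
        self.n = n
        self.background_rate = background_rate
        self.background_amp = background_amp
        self.synaptic_gain = synaptic_gain
        self.tau_m = np.empty(n)
        self.v_threshold = np.empty(n)
        self.v_reset = np.empty(n)
        self.refractory = np.empty(n)
        for i, typ in enumerate(net.cell_type):
            p = TYPE_PRESETS[str(typ)]
            self.tau_m[i] = p.tau_m
            self.v_threshold[i] = p.v_threshold
            self.v_reset[i] = p.v_reset
            self.refractory[i] = p.refractory
        sign = np.where(net.excitatory[net.pre], 1.0, -1.0)
        # W[pre, post]: summed signed strength
        self.W = sp.csr_matrix(
            (sign * net.strength, (net.pre, net.post_neuron)), shape=(n, n))
        self.reset_state()

    def reset_state(self) -> None:
        self.v = np.full(self.n, V_REST)
        self.vth_adapt = np.zeros(self.n)
        self.refrac_until = np.zeros(self.n)
        self.last_spikes = np.zeros(self.n, dtype=bool)
        self.spike_times: list = []
        self.spike_ids: list = []

    def step(self, t_ms: float, dt: float, rng, alive=None) -> np.ndarray:
        """Advance one step of length ``dt`` ms; returns the spike mask.

        The Poisson background draw is consumed every step for every neuron
        regardless of life state, keeping random streams aligned across
        parameter variations.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if alive is None:
            alive = np.ones(self.n, dtype=bool)
        events = rng.poisson(self.background_rate * dt, self.n)
        self.v += (V_REST - self.v) * (dt / self.tau_m)
        self.v += events * self.background_amp
        if self.last_spikes.any():
            self.v += self.synaptic_gain * (
                self.W.T @ self.last_spikes.astype(float))
        self.v[~alive] = V_REST
        can_fire = alive & (t_ms >= self.refrac_until)
        spikes = can_fire & (self.v >= self.v_threshold + self.vth_adapt)
        if spikes.any():
            self.v[spikes] = self.v_reset[spikes]
            self.refrac_until[spikes] = t_ms + self.refractory[spikes]
            ids = np.nonzero(spikes)[0]
            self.spike_ids.append(ids)
            self.spike_times.append(np.full(ids.size, t_ms))
        self.last_spikes = spikes
        return spikes

    def spike_log(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes so far as (times_ms, neuron_ids) arrays."""
        if not self.spike_ids:
            return np.empty(0), np.empty(0, dtype=np.int64)
        return (np.concatenate(self.spike_times),
                np.concatenate(self.spike_ids))


def save_spike_log(spike_times, spike_ids, path) -> None:
    """Write the spike log as TSV (time_ms, neuron_id)."""
    import pandas as pd

    pd.DataFrame({"time_ms": np.asarray(spike_times, dtype=float),
                  "neuron_id": np.asarray(spike_ids, dtype=np.int64)}
                 ).to_csv(path, sep="\t", index=False)


def firing_frequency(spike_times, spike_ids, window_ms: float,
                     group) -> float:
    """Mean firing rate in Hz of ``group`` over the trailing window.

    ``window_ms`` is the window length; spikes with time >= (t_max -
    window_ms) are counted.  Rate = spikes / window / group size, converted
    to Hz.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    group = np.asarray(group)
    if group.size == 0:
        raise ValueError("empty neuron group")
    spike_times = np.asarray(spike_times, dtype=float)
    spike_ids = np.asarray(spike_ids)
    if spike_times.size == 0:
        return 0.0
    t_hi = spike_times.max()
    in_win = spike_times >= t_hi - window_ms
    count = np.isin(spike_ids[in_win], group).sum()
    return float(count) / window_ms * 1000.0 / group.size
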