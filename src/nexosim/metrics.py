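"""Breakdown-pattern metrics: SSG, survival regressions, Dice convergence, ASY, TTNB.

A completed simulation is summarized by its *death order* (the permutation of
neuron ids sorted by death time) and a toxicity trace.  From these we
compute:

* **SSG** (synaptic strength gradient): incoming minus outgoing total
  synaptic strength per neuron; high-SSG "bottleneck" neurons receive much
  and project little.
* **Survival characteristics**: the R^2 of an ordinary least-squares
  regression of death time on SSG or on GDS (hop distance to the seed).
* **Dice convergence**: for two runs, ``D(n)`` is the overlap fraction of
  the first-``n`` dead sets; the time to convergence ``tc`` is the earliest
  death-count fraction after which ``D`` stays at or above a threshold
  ``t_conv`` (0.8 by default).
* **CONV matrix**: mean ``tc`` between groups of runs sharing a parameter
  value.
* **ASY**: maximum over time of the across-neuron standard deviation of
  toxicity (asymmetry of damage).
* **TTNB**: time to network breakdown, the step at which the last neuron
  dies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import Network

__all__ = [
    "RunRecord",
    "ssg",
    "survival_regression",
    "dice_curve",
    "time_to_convergence",
    "conv_matrix",
    "asymmetry",
    "ttnb",
    "RegressionResult",
]

T_CONV_DEFAULT = 0.8


@dataclass
class RunRecord:
    """Outcome of one simulation run.

    ``death_times`` holds ``inf`` for neurons still alive at the horizon; the
    death order lists dead neurons by (time, id).  The toxicity trace is
    sampled every ``trace_stride`` steps (row ``m`` is step
    ``trace_steps[m]``).
    """

    run_id: str
    params: dict
    n_neurons: int
    death_times: np.ndarray          # per neuron, steps; inf if censored
    death_order: np.ndarray          # ids of dead neurons in death order
    trace_steps: np.ndarray          # step index of each trace row
    toxicity_trace: np.ndarray       # (T, N)
    horizon: int
    spike_counts: np.ndarray | None = None   # (T, N) spikes per trace window
    saturation_events: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def censored(self) -> bool:
        """True if any neuron survived to the horizon."""
        return bool(np.isinf(self.death_times).any())

    def death_order_frame(self, net: Network | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "rank": np.arange(1, self.death_order.size + 1),
            "neuron_id": self.death_order,
            "t": self.death_times[self.death_order].astype(int),
        })
        if net is not None:
            df["column"] = net.column[self.death_order]
            df["layer"] = net.layer[self.death_order]
            df["type"] = [str(t) for t in net.cell_type[self.death_order]]
        return df


def ssg(net: Network, convention: str = "incoming_minus_outgoing") -> np.ndarray:
    """Synaptic strength gradient per neuron.

    The default convention (matching the verbal definition: presynaptic
    strengths minus postsynaptic strengths) is incoming minus outgoing;
    ``convention='outgoing_minus_incoming'`` flips the sign.  The SSG sums to
    zero over any network.
    """
    incoming = np.zeros(net.n_neurons)
    outgoing = np.zeros(net.n_neurons)
    np.add.at(incoming, net.post_neuron, net.strength)
    np.add.at(outgoing, net.pre, net.strength)
    if convention == "incoming_minus_outgoing":
        return incoming - outgoing
    if convention == "outgoing_minus_incoming":
        return outgoing - incoming
    raise ValueError(f"unknown SSG convention {convention!r}")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def survival_regression(values, death_times) -> RegressionResult:
    """OLS of death time on a per-neuron predictor (SSG or GDS).

    Only neurons that died and have a finite predictor enter the fit; at
    least three such points and a non-degenerate predictor are required.
    """
    values = np.asarray(values, dtype=float)
    death_times = np.asarray(death_times, dtype=float)
    ok = np.isfinite(values) & np.isfinite(death_times)
    x, y = values[ok], death_times[ok]
    if x.size < 3:
        raise ValueError("need at least 3 dead neurons with finite predictor")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue) ** 2, n=int(x.size))


def _check_universe(order_a, order_b):
    a = np.asarray(order_a)
    b = np.asarray(order_b)
    if a.size != b.size or not np.array_equal(np.sort(a), np.sort(b)):
        raise ValueError("death orders must cover the same neuron universe")
    return a, b


def dice_curve(order_a, order_b) -> np.ndarray:
    """Overlap curve ``D(n) = |first-n(a) & first-n(b)| / n`` for n = 1..N.

    Both arguments must be permutations of the same neuron set.  Symmetric in
    its arguments; ``D(N) = 1``.
    """
    a, b = _check_universe(order_a, order_b)
    n = a.size
    rank_a = np.empty(n, dtype=np.int64)
    rank_b = np.empty(n, dtype=np.int64)
    # map ids to dense ranks (ids need not be 0..N-1)
    ids = np.sort(a)
    pos_a = np.searchsorted(ids, a)
    pos_b = np.searchsorted(ids, b)
    rank_a[pos_a] = np.arange(n)
    rank_b[pos_b] = np.arange(n)
    joint = np.maximum(rank_a, rank_b)  # neuron is in both first-n sets iff joint < n
    counts = np.bincount(joint, minlength=n).cumsum()
    return counts / np.arange(1, n + 1)


def time_to_convergence(d_curve, t_conv: float = T_CONV_DEFAULT) -> float:
    """Earliest fraction n/N with ``D(m) >= t_conv`` for all m >= n.

    Returns the fraction in (0, 1].  Because ``D(N) = 1`` for complete runs,
    a valid answer always exists for ``t_conv <= 1``.
    """
    d = np.asarray(d_curve, dtype=float)
    n = d.size
    below = np.nonzero(d < t_conv)[0]
    if below.size == 0:
        return 1.0 / n
    first = below[-1] + 1  # 0-based index of first n in the stable suffix
    if first >= n:
        raise ValueError("Dice curve never stabilizes above the threshold")
    return (first + 1) / n


def _pair_tc(rec_a: RunRecord, rec_b: RunRecord, t_conv: float) -> float:
    return time_to_convergence(
        dice_curve(rec_a.death_order, rec_b.death_order), t_conv)


def conv_matrix(groups: dict, t_conv: float = T_CONV_DEFAULT) -> pd.DataFrame:
    """Mean time-to-convergence between groups of runs.

    ``groups`` maps a label to a list of :class:`RunRecord`.  Entry (i, j) is
    the mean ``tc`` over all cross pairs; within a group, self-pairs are
    excluded (they would contribute the degenerate ``1/N``).  Censored runs
    are dropped from all pairings.  The result is symmetric.
    """
    labels = list(groups)
    complete = {k: [r for r in v if not r.censored] for k, v in groups.items()}
    for k, v in complete.items():
        if not v:
            raise ValueError(f"group {k!r} has no complete (uncensored) runs")
    cache: dict = {}

    def tc_of(ra, rb):
        key = (id(ra), id(rb)) if id(ra) < id(rb) else (id(rb), id(ra))
        if key not in cache:
            cache[key] = _pair_tc(ra, rb, t_conv)
        return cache[key]

    out = np.zeros((len(labels), len(labels)))
    for i, gi in enumerate(labels):
        for j, gj in enumerate(labels[i:], start=i):
            pairs = [
                (ra, rb)
                for ra, rb in itertools.product(complete[gi], complete[gj])
                if ra is not rb
            ]
            if not pairs:
                raise ValueError(
                    f"no valid run pairs between groups {gi!r} and {gj!r}")
            val = float(np.mean([tc_of(ra, rb) for ra, rb in pairs]))
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=labels, columns=labels)


def asymmetry(toxicity_trace) -> float:
    """ASY: max over time of the across-neuron toxicity standard deviation.

    Sample standard deviation (N - 1 divisor); requires at least 2 neurons.
    """
    trace = np.atleast_2d(np.asarray(toxicity_trace, dtype=float))
    if trace.shape[1] < 2:
        raise ValueError("asymmetry needs at least 2 neurons")
    return float(trace.std(axis=1, ddof=1).max())


def ttnb(record: RunRecord) -> float | None:
    """Time to network breakdown: step of the last death, or None if censored."""
    if record.censored:
        return None
    return float(record.death_times.max())


def run_summary(record: RunRecord, net: Network | None = None,
                seed_neuron: int | None = None) -> dict:
    """One-row metric summary (TTNB, ASY, and survival R^2 when computable)."""
    from .network import geodesic_distance_to_seed

    out = {
        "run_id": record.run_id,
        "ttnb": ttnb(record),
        "asy": asymmetry(record.toxicity_trace),
        "censored": record.censored,
        "saturation_events": record.saturation_events,
    }
    if net is not None:
        try:
            out["ssg_r2"] = survival_regression(
                ssg(net), record.death_times).r_squared
        except ValueError:
            out["ssg_r2"] = np.nan
        if seed_neuron is not None:
            try:
                gds = geodesic_distance_to_seed(net, seed_neuron)
                out["gds_r2"] = survival_regression(
                    gds, record.death_times).r_squared
            except ValueError:
                out["gds_r2"] = np.nan
    return out
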