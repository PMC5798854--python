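"""Per-timestep orchestrator coupling protein kinetics, spread, spiking and death.

One simulation step applies, in a fixed order: production -> misfolding ->
clearance -> passive diffusion -> active transport -> spiking substep ->
spike-triggered synaptic transfer -> toxic threshold effect -> toxicity
update -> death check.  The order is load-bearing: intermediate
concentrations feed each subsequent operator within the same step.

After a neuron dies, only misfolding inside it and diffusion out of it
continue: production, clearance, active transport, synaptic transfer and
spiking stop, and passive diffusion no longer delivers protein into its
sections (would-be inflow stays at the source).

Randomness is split into independent substreams per process (production,
clearance, spiking), all derived from one master seed, so that toggling one
mechanism leaves the draws of the others untouched -- the common-random-number
contract that the directional comparisons rely on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import kinetics, toxicity
from .metrics import RunRecord
from .network import SOMA, Network, NetworkConfig, build_network
from .spiking import SpikingEngine
from .spread import build_spread_operators, settle_flows, synaptic_transfer_flows

__all__ = [
    "SeedSpec",
    "SimulationConfig",
    "Simulation",
    "run_simulation",
    "SimulationInvariantError",
]

#: transfer/toxic-effect menu: (f_st, threshold mode)
TRANSFER_MODES = {
    "off_increase": (0.0, "increase"),
    "low_increase": (1.0, "increase"),
    "high_decrease": (1.0, "decrease"),
}


@dataclass(frozen=True)
class SeedSpec:
    """Where the pathogenic seed goes.

    ``kind='all'``: every section starts at the regime's baseline
    concentrations; the ``variant`` only re-keys the random streams (three
    such variants emulate replicate whole-network seedings).
    ``kind='single'``: additionally add ``extra_cp`` of pathogenic protein to
    the soma of one neuron of the given layer/type in the first column.
    """

    kind: str = "all"
    variant: int = 1
    layer: int | None = None
    cell_type: str | None = None
    extra_cp: float = 0.5
    column: int = 0

    def label(self) -> str:
        if self.kind == "all":
            return f"All-{self.variant}"
        return f"L{self.layer}{self.cell_type}"


@dataclass
class SimulationConfig:
    """Full configuration of one run.

    The eight varied parameters are ``connectivity_seed``, ``solubility``,
    ``seed``, ``R_M``, ``sigma_z`` (None disables passive diffusion),
    ``f_at``, ``transfer_mode`` and ``p_intercolumnar``; the remaining fields
    are the common settings shared by every simulation.
    """

    network: NetworkConfig = field(default_factory=NetworkConfig)
    connectivity_seed: int = 0
    solubility: str = "soluble"              # 'soluble' | 'insoluble'
    seed: SeedSpec = field(default_factory=SeedSpec)
    R_M: float = 0.08
    sigma_z: float | None = 50.0
    f_at: float = 0.0
    transfer_mode: str = "off_increase"
    p_intercolumnar: float = 1.0
    # common settings
    f_pd: float = 0.05
    R_Pn: float = 2e-4
    R_Cn: float = 2e-4
    R_Pp: float = 2e-5
    R_Cp: float = 2e-5
    C_nn: float = 0.01
    C_pn: float = 0.01
    dt: float = 0.025                        # ms
    t_sig: float = 1e-6
    toxic_gain: float = 10.0                 # mV threshold shift at txc = 1
    insoluble_R_Pp: float = 0.0              # 'negligible' production
    insoluble_Cp0: float = 1e-4
    soluble_Cp0: float = 0.01
    Cn0: float = 0.01
    horizon: int = 30_000
    trace_stride: int = 20
    stop_when_all_dead: bool = True

    def __post_init__(self):
        if self.solubility not in ("soluble", "insoluble"):
            raise ValueError(f"unknown solubility {self.solubility!r}")
        if self.transfer_mode not in TRANSFER_MODES:
            raise ValueError(f"unknown transfer mode {self.transfer_mode!r}")

    @property
    def f_st(self) -> float:
        return TRANSFER_MODES[self.transfer_mode][0]

    @property
    def toxic_mode(self) -> str:
        return TRANSFER_MODES[self.transfer_mode][1]

    @property
    def effective_R_Pp(self) -> float:
        return self.R_Pp if self.solubility == "soluble" else self.insoluble_R_Pp

    @property
    def effective_R_Cp(self) -> float:
        # insoluble pathogenic protein cannot be cleared
        return self.R_Cp if self.solubility == "soluble" else 0.0

    @property
    def Cp0(self) -> float:
        return self.soluble_Cp0 if self.solubility == "soluble" \
            else self.insoluble_Cp0

    def param_tuple(self) -> dict:
        """The eight varied parameters, for run bookkeeping."""
        return {
            "connectivity_seed": self.connectivity_seed,
            "solubility": self.solubility,
            "seed": self.seed.label(),
            "R_M": self.R_M,
            "sigma_z": self.sigma_z,
            "f_at": self.f_at,
            "transfer_mode": self.transfer_mode,
            "p_intercolumnar": self.p_intercolumnar,
        }


class SimulationInvariantError(RuntimeError):
    """A state invariant was violated; carries a diagnostic dump."""

    def __init__(self, message: str, dump: dict):
        super().__init__(message)
        self.dump = dump


def _mask_rows(F: sp.csr_matrix, keep_row: np.ndarray) -> sp.csr_matrix:
    coo = F.tocoo()
    keep = keep_row[coo.row]
    return sp.csr_matrix((coo.data[keep], (coo.row[keep], coo.col[keep])),
                         shape=F.shape)


class Simulation:
    """State and stepping logic for one configured run."""

    def __init__(self, config: SimulationConfig, master_seed: int,
                 network: Network | None = None):
        self.config = config
        self.master_seed = int(master_seed)
        if network is None:
            netcfg = dataclasses.replace(
                config.network, p_intercolumnar=config.p_intercolumnar)
            network = build_network(netcfg, config.connectivity_seed)
        self.net = network
        n = self.net.n_neurons
        self.ops = build_spread_operators(
            self.net, sigma_z=config.sigma_z, f_pd=config.f_pd,
            f_at=config.f_at, f_st=config.f_st, t_sig=config.t_sig)
        self.engine = SpikingEngine(self.net)

        # independent substreams; the seed-all variant re-keys all of them
        ss = np.random.SeedSequence([self.master_seed, config.seed.variant])
        kids = ss.spawn(3)
        self.rng_production = np.random.default_rng(kids[0])
        self.rng_clearance = np.random.default_rng(kids[1])
        self.rng_spiking = np.random.default_rng(kids[2])

        # protein state
        self.Cn = np.full(self.net.n_sections, config.Cn0)
        self.Cp = np.full(self.net.n_sections, config.Cp0)
        self.seed_neuron: int | None = None
        if config.seed.kind == "single":
            cand = self.net.neurons_of(layer=config.seed.layer,
                                       cell_type=config.seed.cell_type,
                                       column=config.seed.column)
            if cand.size == 0:
                raise ValueError(
                    f"seed population L{config.seed.layer}"
                    f"{config.seed.cell_type} absent from network")
            self.seed_neuron = int(cand[0])
            k = 3 * self.seed_neuron + SOMA
            room = 1.0 - (self.Cn[k] + self.Cp[k])
            self.Cp[k] += min(config.seed.extra_cp, room)
        elif config.seed.kind != "all":
            raise ValueError(f"unknown seed kind {config.seed.kind!r}")

        # health
        self.alive = np.ones(n, dtype=bool)
        self.alive_sections = np.ones(self.net.n_sections, dtype=bool)
        self.txc = np.zeros(n)
        self.death_order: list = []
        self.death_times = np.full(n, np.inf)
        self.t = 0
        self.saturation_events = 0
        self.soma_index = np.arange(n) * 3 + SOMA
        self._volumes = self.net.sec_volume
        self._refresh_operator_masks()

        # traces
        self._trace_steps: list = [0]
        self._trace_txc: list = [self.txc.copy()]
        self._trace_spikes: list = [np.zeros(n, dtype=np.int32)]
        self._window_spikes = np.zeros(n, dtype=np.int64)

    def _refresh_operator_masks(self) -> None:
        dead_sections = ~self.alive_sections
        self._F_diff = self.ops.diffusion_flows_excluding(dead_sections)
        if self.ops.F_at is not None:
            self._F_at = _mask_rows(self.ops.F_at, self.alive_sections)
        else:
            self._F_at = None

    def _apply_flows(self, F: sp.csr_matrix) -> None:
        V = self._volumes
        x_n = self.Cn * V
        x_p = self.Cp * V
        x_n, x_p, n_sat = settle_flows(x_n, x_p, F, V)
        self.Cn = x_n / V
        self.Cp = x_p / V
        self.saturation_events += n_sat

    # -- individual processes (applied in self.process_order) ---------------

    def _process_production(self) -> None:
        cfg = self.config
        kinetics.production_step(
            self.Cn, self.Cp, self.alive, self.soma_index,
            cfg.R_Pn, cfg.effective_R_Pp, self.rng_production)

    def _process_misfolding(self) -> None:
        kinetics.misfold_step(self.Cn, self.Cp, self.config.R_M)

    def _process_clearance(self) -> None:
        cfg = self.config
        kinetics.clearance_step(
            self.Cn, self.Cp, self.alive_sections,
            cfg.R_Cn, cfg.effective_R_Cp, cfg.C_nn, cfg.C_pn,
            self.rng_clearance)

    def _process_diffusion(self) -> None:
        if self._F_diff is not None:
            self._apply_flows(self._F_diff)

    def _process_transport(self) -> None:
        if self._F_at is not None:
            self._apply_flows(self._F_at)

    def _process_spiking_transfer(self) -> None:
        cfg = self.config
        spikes = self.engine.step(self.t * cfg.dt, cfg.dt,
                                  self.rng_spiking, self.alive)
        self._window_spikes += spikes
        flows = synaptic_transfer_flows(self.ops, spikes & self.alive,
                                        self.net.n_sections)
        if flows is not None:
            self._apply_flows(flows)

    #: protein/spiking process order within a step; the trailing toxicity /
    #: death block is fixed.  Exposed so the order contract is testable.
    process_order = ("production", "misfolding", "clearance", "diffusion",
                     "transport", "spiking_transfer")

    def step(self) -> np.ndarray:
        """Advance one timestep; returns the ids that died this step."""
        cfg = self.config
        self.t += 1
        for name in self.process_order:
            getattr(self, f"_process_{name}")()
        self.engine.vth_adapt = toxicity.toxic_threshold_shift(
            self.txc, cfg.toxic_mode, cfg.toxic_gain)
        toxicity.update_toxicity(self.txc, self.Cn, self.Cp, self.alive)
        dying = toxicity.death_check(self.txc, self.alive, self.t,
                                     self.death_order, self.death_times)
        if dying.size:
            for i in dying:
                self.alive_sections[3 * i:3 * i + 3] = False
            self._refresh_operator_masks()
        self._check_invariants()
        if self.t % cfg.trace_stride == 0:
            self._trace_steps.append(self.t)
            self._trace_txc.append(self.txc.copy())
            self._trace_spikes.append(self._window_spikes.astype(np.int32))
            self._window_spikes[:] = 0
        return dying

    def _check_invariants(self) -> None:
        total = self.Cn + self.Cp
        if (self.Cn.min() < -1e-9 or self.Cp.min() < -1e-9
                or total.max() > 1.0 + 1e-6):
            dump = {
                "t": self.t,
                "Cn_min": float(self.Cn.min()),
                "Cp_min": float(self.Cp.min()),
                "total_max": float(total.max()),
                "worst_section": int(np.argmax(total)),
            }
            raise SimulationInvariantError(
                f"concentration invariant violated at step {self.t}: {dump}",
                dump)

    def run(self, run_id: str | None = None) -> RunRecord:
        """Step until the horizon (or until every neuron is dead)."""
        cfg = self.config
        while self.t < cfg.horizon:
            self.step()
            if cfg.stop_when_all_dead and not self.alive.any():
                break
        if self.t % cfg.trace_stride != 0:  # flush the trailing window
            self._trace_steps.append(self.t)
            self._trace_txc.append(self.txc.copy())
            self._trace_spikes.append(self._window_spikes.astype(np.int32))
        order = np.array(self.death_order, dtype=np.int64)
        rid = run_id or f"run-s{self.master_seed}"
        return RunRecord(
            run_id=rid,
            params=cfg.param_tuple(),
            n_neurons=self.net.n_neurons,
            death_times=self.death_times.copy(),
            death_order=order,
            trace_steps=np.array(self._trace_steps),
            toxicity_trace=np.array(self._trace_txc),
            horizon=cfg.horizon,
            spike_counts=np.array(self._trace_spikes),
            saturation_events=self.saturation_events,
            meta={"master_seed": self.master_seed,
                  "seed_neuron": self.seed_neuron},
        )


def run_simulation(config: SimulationConfig, master_seed: int,
                   run_id: str | None = None,
                   network: Network | None = None) -> RunRecord:
    """Convenience wrapper: build, run, and summarize one simulation."""
    return Simulation(config, master_seed, network=network).run(run_id)
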