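"""Factorial sweep harness: enumerate the 8-parameter design and run subsets.

The full design crosses two connectivity instances, two solubility regimes,
seventeen seed placements (three whole-network replicates plus the fourteen
single-neuron layer/type classes), two misfolding rates, three diffusion
speeds, three active-transport strengths, three synaptic-transfer/toxic
modes and three spread selectivities: 2*2*17*2*3*3*3*3 = 11016 runs.

Sweeps group runs into the H-sets (one set per menu value, 35 for the full
design) and summarize each parameter's effect as the CONV matrix of mean
pairwise times to convergence plus per-run metrics (TTNB, ASY, SSG R^2,
GDS R^2).  Subset designs are first-class: restricting any menu shrinks the
design and its H-sets consistently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import SeedSpec, SimulationConfig, run_simulation
from .metrics import RunRecord, conv_matrix, run_summary
from .network import NetworkConfig, build_network

__all__ = [
    "SweepDesign",
    "default_seed_menu",
    "enumerate_design",
    "config_for_point",
    "run_sweep",
    "SweepResult",
]


def default_seed_menu(network: NetworkConfig | None = None) -> tuple:
    """The seed menu: three whole-network variants + one single-neuron seed
    per non-empty (layer, type) population of the column composition."""
    network = network or NetworkConfig()
    menu = [SeedSpec(kind="all", variant=v) for v in (1, 2, 3)]
    menu += [SeedSpec(kind="single", layer=lay, cell_type=typ)
             for lay, typ in network.seedable_populations()]
    return tuple(menu)


@dataclass
class SweepDesign:
    """The eight parameter menus; the design is their Cartesian product."""

    connectivity_seeds: tuple = (0, 1)
    solubilities: tuple = ("soluble", "insoluble")
    seeds: tuple = ()                     # filled from the network if empty
    misfolding_rates: tuple = (0.08, 0.09)
    diffusion_speeds: tuple = (None, 50.0, 500.0)
    transport_fractions: tuple = (0.0, 0.0001, 0.001)
    transfer_modes: tuple = ("off_increase", "low_increase", "high_decrease")
    selectivities: tuple = (0.01, 1.0, 100.0)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if not self.seeds:
            self.seeds = default_seed_menu(self.network)

    @property
    def menus(self) -> dict:
        return {
            "connectivity_seed": self.connectivity_seeds,
            "solubility": self.solubilities,
            "seed": self.seeds,
            "R_M": self.misfolding_rates,
            "sigma_z": self.diffusion_speeds,
            "f_at": self.transport_fractions,
            "transfer_mode": self.transfer_modes,
            "p_intercolumnar": self.selectivities,
        }

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self.menus.values()]))

    @property
    def n_h_sets(self) -> int:
        return sum(len(v) for v in self.menus.values())

    def restrict(self, **kwargs) -> "SweepDesign":
        """A copy with some menus narrowed, e.g. ``restrict(R_M=(0.09,))``."""
        rename = {
            "connectivity_seed": "connectivity_seeds",
            "solubility": "solubilities",
            "seed": "seeds",
            "R_M": "misfolding_rates",
            "sigma_z": "diffusion_speeds",
            "f_at": "transport_fractions",
            "transfer_mode": "transfer_modes",
            "p_intercolumnar": "selectivities",
        }
        updates = {rename.get(k, k): tuple(v) for k, v in kwargs.items()}
        return replace(self, **updates)


def enumerate_design(design: SweepDesign) -> list:
    """All parameter points in lexicographic menu order, with stable ids."""
    menus = design.menus
    keys = list(menus)
    points = []
    for idx, combo in enumerate(itertools.product(*menus.values())):
        point = dict(zip(keys, combo))
        point["run_id"] = f"d{idx:05d}"
        points.append(point)
    return points


def config_for_point(point: dict, design: SweepDesign,
                     **overrides) -> SimulationConfig:
    """Materialize one design point into a full SimulationConfig."""
    return SimulationConfig(
        network=design.network,
        connectivity_seed=point["connectivity_seed"],
        solubility=point["solubility"],
        seed=point["seed"],
        R_M=point["R_M"],
        sigma_z=point["sigma_z"],
        f_at=point["f_at"],
        transfer_mode=point["transfer_mode"],
        p_intercolumnar=point["p_intercolumnar"],
        **overrides,
    )


def h_sets(points: list) -> dict:
    """Group run ids by shared menu value: one H-set per (parameter, value)."""
    out: dict = {}
    for point in points:
        for key in ("connectivity_seed", "solubility", "seed", "R_M",
                    "sigma_z", "f_at", "transfer_mode", "p_intercolumnar"):
            val = point[key]
            label = f"{key}={val.label() if isinstance(val, SeedSpec) else val}"
            out.setdefault(label, []).append(point["run_id"])
    return out


def save_conv_heatmap(conv: pd.DataFrame, path) -> None:
    """Render the CONV matrix as a heatmap PNG (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.5 * len(conv) + 3,) * 2)
    im = ax.imshow(conv.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(conv)), conv.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(conv)), conv.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="mean time to convergence")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class SweepResult:
    records: dict                 # run_id -> RunRecord
    summary: pd.DataFrame         # one row per run
    conv: pd.DataFrame | None     # H-set CONV matrix (None if not computable)
    failed: dict                  # run_id -> exception string


def run_sweep(design: SweepDesign, *, replicate_seeds=(0,),
              config_overrides: dict | None = None, t_conv: float = 0.8,
              compute_conv: bool = True, progress: bool = False) -> SweepResult:
    """Execute every design point (x replicate master seeds) and summarize.

    Failed runs are quarantined with their diagnostics and excluded from the
    CONV computation.  Networks are cached per (connectivity seed,
    selectivity) so each instance is built once.
    """
    points = enumerate_design(design)
    overrides = config_overrides or {}
    records: dict = {}
    failed: dict = {}
    rows = []
    net_cache: dict = {}
    iterator = points
    if progress:
        from tqdm import tqdm
        iterator = tqdm(points, desc="sweep")
    for point in iterator:
        for rep in replicate_seeds:
            rid = f"{point['run_id']}-r{rep}"
            cfg = config_for_point(point, design, **overrides)
            net_key = (cfg.connectivity_seed, cfg.p_intercolumnar)
            if net_key not in net_cache:
                netcfg = replace(design.network,
                                 p_intercolumnar=cfg.p_intercolumnar)
                net_cache[net_key] = build_network(netcfg,
                                                   cfg.connectivity_seed)
            try:
                rec = run_simulation(cfg, master_seed=rep, run_id=rid,
                                     network=net_cache[net_key])
            except Exception as exc:  # quarantine, keep sweeping
                failed[rid] = repr(exc)
                continue
            records[rid] = rec
            summ = run_summary(rec, net_cache[net_key],
                               rec.meta.get("seed_neuron"))
            summ.update({k: (v.label() if isinstance(v, SeedSpec) else v)
                         for k, v in point.items() if k != "run_id"})
            summ["design_id"] = point["run_id"]
            summ["replicate"] = rep
            rows.append(summ)
    summary = pd.DataFrame(rows)

    conv = None
    if compute_conv and records:
        groups: dict = {}
        for label, rids in h_sets(points).items():
            recs = [records[f"{rid}-r{rep}"]
                    for rid in rids for rep in replicate_seeds
                    if f"{rid}-r{rep}" in records]
            recs = [r for r in recs if not r.censored]
            if recs:
                groups[label] = recs
        # CONV needs at least two groups and pairable runs
        try:
            if len(groups) >= 2:
                conv = conv_matrix(groups, t_conv=t_conv)
        except ValueError:
            conv = None
    return SweepResult(records=records, summary=summary, conv=conv,
                       failed=failed)
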