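"""Multi-column cortical network substrate.

The simulated tissue is a set of ``K`` cortical columns, each containing the
same mixture of layers (2, 4, 5, 6) and cell types (excitatory regular-spiking
RS and intrinsically-bursting IB; inhibitory fast-spiking FS and low-threshold
spiking LTS).  Every neuron is reduced to three cylindrical *sections* --
dendrite, soma, axon -- with diameter ``D``, length ``L``, base area
``R = pi (D/2)^2`` and volume ``V = L * R``.  Synapses are directed edges from
a presynaptic axon to a postsynaptic section with a non-negative strength
``r``; an absent synapse is simply not stored.

Connectivity is generated synthetically from a (pre-type, post-type) density
matrix, scaled down for inter-columnar pairs, so that the statistical shape of
a columnar microcircuit (dense local wiring, sparse long-range projection) is
reproduced without importing any external connectome table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "CELL_TYPES",
    "EXCITATORY",
    "INHIBITORY",
    "DENDRITE",
    "SOMA",
    "AXON",
    "SectionGeometry",
    "NetworkConfig",
    "Network",
    "build_network",
    "section_adjacency",
    "geodesic_distance_to_seed",
    "save_network",
    "load_network",
    "test_network_config",
]

CELL_TYPES = ("RS", "IB", "FS", "LTS")
EXCITATORY = frozenset({"RS", "IB"})
INHIBITORY = frozenset({"FS", "LTS"})

#: section indices within a neuron (flat index k = 3*i + j)
DENDRITE, SOMA, AXON = 0, 1, 2
SECTION_NAMES = ("dendrite", "soma", "axon")

#: weight of the intracellular dendrite<->soma<->axon diffusion edges
INTRACELLULAR_WEIGHT = 20.0


@dataclass(frozen=True)
class SectionGeometry:
    """Cylindrical section: diameter and length in um, derived area/volume."""

    diameter: float
    length: float

    def __post_init__(self):
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("section diameter and length must be positive")

    @property
    def base_area(self) -> float:
        """Base area R = pi (D/2)^2 in um^2."""
        return math.pi * (self.diameter / 2.0) ** 2

    @property
    def volume(self) -> float:
        """Volume V = L * R in um^3."""
        return self.length * self.base_area


#: default section geometry (um), uniform across cell types, config-overridable
DEFAULT_GEOMETRY = {
    "dendrite": SectionGeometry(diameter=2.0, length=150.0),
    "soma": SectionGeometry(diameter=20.0, length=20.0),
    "axon": SectionGeometry(diameter=1.0, length=300.0),
}

#: per-column (layer, type, count) composition summing to 470 neurons.
#: IB cells are restricted to the deep layers, leaving 14 non-empty
#: layer x type populations (the seedable single-neuron classes).
DEFAULT_COMPOSITION = (
    (2, "RS", 100), (2, "FS", 25), (2, "LTS", 25),
    (4, "RS", 100), (4, "FS", 25), (4, "LTS", 25),
    (5, "RS", 40), (5, "IB", 30), (5, "FS", 10), (5, "LTS", 10),
    (6, "RS", 35), (6, "IB", 25), (6, "FS", 10), (6, "LTS", 10),
)

#: default connection probability by presynaptic type (inhibitory cells make
#: denser local contacts), expanded to a full (pre, post) matrix.
DEFAULT_DENSITY_BY_PRE = {"RS": 0.08, "IB": 0.08, "FS": 0.25, "LTS": 0.25}


def _full_density_matrix(densities) -> dict:
    """Expand shorthand density specs to a full (pre, post) -> density dict."""
    if densities is None:
        densities = DEFAULT_DENSITY_BY_PRE
    out = {}
    for pre in CELL_TYPES:
        for post in CELL_TYPES:
            if (pre, post) in densities:
                out[(pre, post)] = float(densities[(pre, post)])
            elif pre in densities and not isinstance(densities.get(pre), dict):
                out[(pre, post)] = float(densities[pre])
            elif pre in densities:
                out[(pre, post)] = float(densities[pre].get(post, 0.0))
            else:
                out[(pre, post)] = 0.0
    return out


@dataclass
class NetworkConfig:
    """Parameters of the synthetic connectivity generator.

    Attributes
    ----------
    n_columns:
        Number of cortical columns ``K``.
    composition:
        Per-column ``(layer, cell_type, count)`` tuples; identical across
        columns.
    densities:
        Connection densities in [0, 1].  Accepts a full ``(pre, post)`` dict,
        or a per-pre-type shorthand.
    inter_column_scale:
        Multiplier applied to densities for inter-columnar pairs.
    strength_range:
        Uniform range for synaptic strengths ``r``.
    p_intercolumnar:
        Protein spread selectivity ``p`` attached to inter-columnar synapses
        (intra-columnar and intracellular edges have ``p = 1``).
    geometry:
        Mapping section name -> :class:`SectionGeometry`.
    """

    n_columns: int = 3
    composition: tuple = DEFAULT_COMPOSITION
    densities: dict | None = None
    inter_column_scale: float = 0.1
    strength_range: tuple = (0.5, 1.5)
    p_intercolumnar: float = 1.0
    geometry: dict = field(default_factory=lambda: dict(DEFAULT_GEOMETRY))

    @property
    def neurons_per_column(self) -> int:
        return sum(c for _, _, c in self.composition)

    @property
    def n_neurons(self) -> int:
        return self.n_columns * self.neurons_per_column

    def density_matrix(self) -> dict:
        return _full_density_matrix(self.densities)

    def validate(self) -> None:
        if self.n_columns < 1:
            raise ValueError("need at least one column")
        for lay, typ, cnt in self.composition:
            if typ not in CELL_TYPES:
                raise ValueError(f"unknown cell type {typ!r}")
            if cnt < 0:
                raise ValueError("negative population count")
        if self.neurons_per_column <= 0:
            raise ValueError("composition sums to zero neurons per column")
        for key, d in self.density_matrix().items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"density {key} = {d} outside [0, 1]")
        lo, hi = self.strength_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid strength range")

    def seedable_populations(self) -> list:
        """Non-empty (layer, type) classes, in composition order."""
        seen, out = set(), []
        for lay, typ, cnt in self.composition:
            if cnt > 0 and (lay, typ) not in seen:
                seen.add((lay, typ))
                out.append((lay, typ))
        return out


def test_network_config(neurons_per_column: int = 10, **kwargs) -> NetworkConfig:
    """A reduced 3-column network for fast experimentation.

    The default yields 30 neurons (3 columns x 10) with denser wiring so the
    graph stays connected at small size.
    """
    if neurons_per_column == 10:
        comp = (
            (2, "RS", 2), (2, "FS", 1),
            (4, "RS", 2), (4, "LTS", 1),
            (5, "RS", 1), (5, "IB", 1),
            (6, "RS", 1), (6, "FS", 1),
        )
    else:
        # scale the default composition proportionally (crude but adequate)
        total = sum(c for _, _, c in DEFAULT_COMPOSITION)
        comp = tuple(
            (lay, typ, max(1, round(cnt * neurons_per_column / total)))
            for lay, typ, cnt in DEFAULT_COMPOSITION
        )
    kwargs.setdefault("densities", {"RS": 0.35, "IB": 0.35, "FS": 0.5, "LTS": 0.5})
    kwargs.setdefault("inter_column_scale", 0.3)
    return NetworkConfig(composition=comp, **kwargs)


class Network:
    """Realized network instance (arrays indexed by neuron / flat section).

    Neurons are 0-indexed internally; the flat section index of neuron ``i``,
    section ``j`` (0 = dendrite, 1 = soma, 2 = axon) is ``k = 3 i + j``.
    Synapses are stored as parallel arrays sorted by (pre neuron, post neuron,
    post section); the presynaptic section is always the axon.
    """

    def __init__(self, config, column, layer, cell_type,
                 sec_diameter, sec_length,
                 pre, post_neuron, post_section, strength):
        self.config = config
        self.column = np.asarray(column, dtype=np.int64)
        self.layer = np.asarray(layer, dtype=np.int64)
        self.cell_type = np.asarray(cell_type, dtype=object)
        self.n_neurons = self.column.size
        self.n_sections = 3 * self.n_neurons
        # section geometry, flat arrays of length 3N
        self.sec_diameter = np.asarray(sec_diameter, dtype=float)
        self.sec_length = np.asarray(sec_length, dtype=float)
        self.sec_area = np.pi * (self.sec_diameter / 2.0) ** 2
        self.sec_volume = self.sec_length * self.sec_area
        # synapse arrays
        self.pre = np.asarray(pre, dtype=np.int64)
        self.post_neuron = np.asarray(post_neuron, dtype=np.int64)
        self.post_section = np.asarray(post_section, dtype=np.int64)
        self.strength = np.asarray(strength, dtype=float)
        self.intercolumnar = self.column[self.pre] != self.column[self.post_neuron]
        #: per-synapse spread selectivity p
        self.selectivity = np.where(
            self.intercolumnar, float(config.p_intercolumnar), 1.0
        )
        self.excitatory = np.isin(self.cell_type, list(EXCITATORY))

    @property
    def n_synapses(self) -> int:
        return self.pre.size

    def section_index(self, neuron: int, section: int) -> int:
        return 3 * int(neuron) + int(section)

    def neurons_of(self, layer=None, cell_type=None, column=None) -> np.ndarray:
        """Ids of neurons matching the given (optional) class selectors."""
        mask = np.ones(self.n_neurons, dtype=bool)
        if layer is not None:
            mask &= self.layer == layer
        if cell_type is not None:
            mask &= self.cell_type == cell_type
        if column is not None:
            mask &= self.column == column
        return np.nonzero(mask)[0]

    def neuron_graph(self, directed: bool = True) -> nx.DiGraph:
        """Neuron-level synapse graph (parallel synapses collapsed)."""
        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(range(self.n_neurons))
        for a, b, r in zip(self.pre, self.post_neuron, self.strength):
            a, b = int(a), int(b)
            if g.has_edge(a, b):
                g[a][b]["r"] += float(r)
            else:
                g.add_edge(a, b, r=float(r))
        return g

    def neuron_table(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_neurons):
            row = {
                "id": i,
                "column": int(self.column[i]),
                "layer": int(self.layer[i]),
                "type": str(self.cell_type[i]),
            }
            for j, name in enumerate(SECTION_NAMES):
                k = 3 * i + j
                row[f"{name}_D"] = self.sec_diameter[k]
                row[f"{name}_L"] = self.sec_length[k]
            rows.append(row)
        return pd.DataFrame(rows)

    def synapse_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pre_neuron": self.pre,
            "pre_section": np.full(self.n_synapses, AXON, dtype=np.int64),
            "post_neuron": self.post_neuron,
            "post_section": self.post_section,
            "r": self.strength,
        })


def build_network(config: NetworkConfig, rng_seed: int) -> Network:
    """Sample a network instance from the generator config.

    Deterministic for a given ``rng_seed``: blocks of (column pair, pre type,
    post type) are visited in a fixed order and each potential edge is an
    independent Bernoulli draw with the block's density.  Excitatory axons
    contact dendrites, inhibitory axons contact somas; autapses are excluded.
    """
    config.validate()
    rng = np.random.default_rng(rng_seed)

    column, layer, cell_type = [], [], []
    for col in range(config.n_columns):
        for lay, typ, cnt in config.composition:
            column.extend([col] * cnt)
            layer.extend([lay] * cnt)
            cell_type.extend([typ] * cnt)
    column = np.array(column)
    layer = np.array(layer)
    cell_type = np.array(cell_type, dtype=object)
    n = column.size

    geom = config.geometry
    sec_diameter = np.empty(3 * n)
    sec_length = np.empty(3 * n)
    for j, name in enumerate(SECTION_NAMES):
        sec_diameter[j::3] = geom[name].diameter
        sec_length[j::3] = geom[name].length

    dens = config.density_matrix()
    lo, hi = config.strength_range
    pre_ids, post_ids, post_secs, strengths = [], [], [], []
    for c_pre in range(config.n_columns):
        for c_post in range(config.n_columns):
            scale = 1.0 if c_pre == c_post else config.inter_column_scale
            for t_pre in CELL_TYPES:
                srcs = np.nonzero((column == c_pre) & (cell_type == t_pre))[0]
                if srcs.size == 0:
                    continue
                target_sec = DENDRITE if t_pre in EXCITATORY else SOMA
                for t_post in CELL_TYPES:
                    dsts = np.nonzero((column == c_post) & (cell_type == t_post))[0]
                    d = dens[(t_pre, t_post)] * scale
                    if dsts.size == 0 or d <= 0.0:
                        continue
                    hit = rng.random((srcs.size, dsts.size)) < d
                    if c_pre == c_post and t_pre == t_post:
                        np.fill_diagonal(hit, False)  # no autapses
                    a, b = np.nonzero(hit)
                    if a.size == 0:
                        continue
                    pre_ids.append(srcs[a])
                    post_ids.append(dsts[b])
                    post_secs.append(np.full(a.size, target_sec))
                    strengths.append(rng.uniform(lo, hi, a.size))

    if pre_ids:
        pre = np.concatenate(pre_ids)
        post = np.concatenate(post_ids)
        psec = np.concatenate(post_secs)
        r = np.concatenate(strengths)
        order = np.lexsort((psec, post, pre))
        pre, post, psec, r = pre[order], post[order], psec[order], r[order]
    else:
        pre = post = psec = np.empty(0, dtype=np.int64)
        r = np.empty(0)

    return Network(config, column, layer, cell_type,
                   sec_diameter, sec_length, pre, post, psec, r)


def section_adjacency(net: Network) -> sp.csr_matrix:
    """Section-level weighted directed adjacency (3N x 3N).

    Intracellular chain edges dendrite<->soma<->axon carry the fixed weight
    ``w = 20`` in both directions; each synapse contributes a directed
    axon -> postsynaptic-section edge of weight ``r``.
    """
    n = net.n_sections
    base = np.arange(net.n_neurons) * 3
    rows = np.concatenate([
        base + DENDRITE, base + SOMA, base + SOMA, base + AXON,
        3 * net.pre + AXON,
    ])
    cols = np.concatenate([
        base + SOMA, base + DENDRITE, base + AXON, base + SOMA,
        3 * net.post_neuron + net.post_section,
    ])
    w = np.concatenate([
        np.full(4 * net.n_neurons, INTRACELLULAR_WEIGHT),
        net.strength,
    ])
    return sp.csr_matrix((w, (rows, cols)), shape=(n, n))


def geodesic_distance_to_seed(net: Network, seed_neuron: int,
                              directed: bool = True) -> np.ndarray:
    """Hop distance GDS from the seeded neuron on the synapse graph.

    Distances follow synapse direction (anterograde) by default; pass
    ``directed=False`` to ignore edge direction.  Unreachable neurons get
    ``inf``.
    """
    if not 0 <= seed_neuron < net.n_neurons:
        raise ValueError(f"invalid seed neuron id {seed_neuron}")
    g = net.neuron_graph(directed=directed)
    lengths = nx.single_source_shortest_path_length(g, int(seed_neuron))
    gds = np.full(net.n_neurons, np.inf)
    for node, dist in lengths.items():
        gds[node] = dist
    return gds


def save_network(net: Network, directory) -> None:
    """Write neuron and synapse tables (TSV) plus the generator config (YAML)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    net.neuron_table().to_csv(directory / "neurons.tsv", sep="\t", index=False)
    net.synapse_table().to_csv(directory / "synapses.tsv", sep="\t", index=False)
    cfg = asdict(net.config)
    cfg["geometry"] = {k: {"diameter": v.diameter, "length": v.length}
                       for k, v in net.config.geometry.items()}
    cfg["composition"] = [list(t) for t in net.config.composition]
    if cfg["densities"] is not None:
        cfg["densities"] = {
            (k if isinstance(k, str) else "->".join(k)): v
            for k, v in net.config.densities.items()
        }
    with open(directory / "network.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def load_network(directory) -> Network:
    """Rebuild a :class:`Network` from :func:`save_network` output."""
    directory = Path(directory)
    with open(directory / "network.yaml") as fh:
        cfg = yaml.safe_load(fh)
    cfg["geometry"] = {k: SectionGeometry(**v) for k, v in cfg["geometry"].items()}
    cfg["composition"] = tuple(tuple(t) for t in cfg["composition"])
    if cfg.get("densities") is not None:
        cfg["densities"] = {
            (tuple(k.split("->")) if "->" in k else k): v
            for k, v in cfg["densities"].items()
        }
    if cfg.get("strength_range") is not None:
        cfg["strength_range"] = tuple(cfg["strength_range"])
    config = NetworkConfig(**cfg)
    neurons = pd.read_csv(directory / "neurons.tsv", sep="\t")
    syn = pd.read_csv(directory / "synapses.tsv", sep="\t")
    n = len(neurons)
    sec_diameter = np.empty(3 * n)
    sec_length = np.empty(3 * n)
    for j, name in enumerate(SECTION_NAMES):
        sec_diameter[j::3] = neurons[f"{name}_D"].to_numpy()
        sec_length[j::3] = neurons[f"{name}_L"].to_numpy()
    return Network(
        config,
        neurons["column"].to_numpy(), neurons["layer"].to_numpy(),
        neurons["type"].to_numpy(dtype=object),
        sec_diameter, sec_length,
        syn["pre_neuron"].to_numpy(), syn["post_neuron"].to_numpy(),
        syn["post_section"].to_numpy(), syn["r"].to_numpy(),
    )
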