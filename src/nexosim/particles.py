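"""Particle-level Brownian misfolding oracle.

The compartmental model treats templated misfolding as a mass-action product
law, ``b = R_M * Cn * Cp``.  This module provides the ground truth that law
is checked against: discrete protein molecules diffusing in a cube, where a
normal molecule converts to the pathogenic conformer whenever it comes
within a contact radius of one.  Fitting the product surface to the grid of
converted fractions produced here validates the functional form (and its
fitted scale plays the role of ``R_M``).

Box side, step size and contact radius are arbitrary-unit model choices (the
claim under test is the *shape* of the response surface, not its scale);
counts are mapped to concentration fractions by dividing by a nominal
capacity.  The defaults keep the box dilute -- mass-action kinetics is a
dilute-limit law, so the contact radius is sized so that even at the top of
the default count grid only a modest fraction of normal molecules meets a
pathogenic one -- while counts are large enough that the Monte-Carlo noise
of the converted fraction stays small relative to the surface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["ParticleBox", "run_box", "misfold_grid", "fit_product_model",
           "DEFAULT_GRID_COUNTS"]

#: default 8-point count menu for the validation grid (dilute up to
#: concentration 0.08 at the default capacity)
DEFAULT_GRID_COUNTS = tuple(range(6, 49, 6))


@dataclass(frozen=True)
class ParticleBox:
    """Cube geometry and Brownian dynamics parameters (arbitrary units)."""

    side: float = 1.0
    step_sd: float = 0.02      # per-axis Gaussian displacement per step
    contact_radius: float = 0.0125
    n_steps: int = 1000
    capacity: int = 600        # count -> concentration divisor

    def __post_init__(self):
        if self.side <= 0 or self.step_sd < 0 or self.contact_radius < 0:
            raise ValueError("box parameters must be positive")
        if self.n_steps < 0 or self.capacity <= 0:
            raise ValueError("n_steps and capacity must be positive")


@dataclass
class BoxResult:
    n_normal0: int
    n_pathogenic0: int
    n_converted: int
    box: ParticleBox

    @property
    def converted_fraction(self) -> float:
        """Concentration of normal protein that misfolded (count/capacity)."""
        return self.n_converted / self.box.capacity


def _reflect(pos: np.ndarray, side: float) -> np.ndarray:
    # reflecting walls: fold positions back into [0, side]
    pos = np.abs(pos)
    pos = side - np.abs(side - pos % (2 * side))
    return pos


def run_box(n_normal: int, n_pathogenic: int, box: ParticleBox = ParticleBox(),
            seed: int = 0) -> BoxResult:
    """Simulate the cube and return how much normal protein converted.

    Both species take independent Gaussian steps each iteration (reflecting
    walls).  After each step, every normal molecule within the contact radius
    of any pathogenic molecule converts; conversions are resolved
    synchronously, so a newly converted molecule only templates from the next
    step onward.  Particle count is conserved and conversion is one-way.
    """
    if n_normal < 0 or n_pathogenic < 0:
        raise ValueError("particle counts must be non-negative")
    rng = np.random.default_rng(seed)
    n_total = n_normal + n_pathogenic
    pos = rng.uniform(0, box.side, size=(n_total, 3))
    pathogenic = np.zeros(n_total, dtype=bool)
    pathogenic[n_normal:] = True
    converted = 0
    if n_normal == 0 or n_pathogenic == 0:
        return BoxResult(n_normal, n_pathogenic, 0, box)
    for _ in range(box.n_steps):
        pos = _reflect(pos + rng.normal(0, box.step_sd, size=pos.shape),
                       box.side)
        normal_idx = np.nonzero(~pathogenic)[0]
        if normal_idx.size == 0:
            break
        dist = cdist(pos[normal_idx], pos[pathogenic])
        hit = (dist <= box.contact_radius).any(axis=1)
        if hit.any():
            pathogenic[normal_idx[hit]] = True
            converted += int(hit.sum())
    return BoxResult(n_normal, n_pathogenic, converted, box)


def misfold_grid(normal_counts, pathogenic_counts,
                 box: ParticleBox = ParticleBox(), n_seeds: int = 10,
                 seed: int = 0) -> pd.DataFrame:
    """Converted-fraction surface over a grid of initial counts.

    Each grid cell is the mean over ``n_seeds`` replicate boxes.  Returns a
    frame with initial concentrations ``Cn0``, ``Cp0`` and the mean
    ``converted`` concentration.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    cells = list(itertools.product(normal_counts, pathogenic_counts))
    child_seeds = ss.spawn(len(cells))
    for (nn, np_), cell_ss in zip(cells, child_seeds):
        reps = [
            run_box(nn, np_, box, seed=s).converted_fraction
            for s in cell_ss.generate_state(n_seeds)
        ]
        rows.append({
            "Cn0": nn / box.capacity,
            "Cp0": np_ / box.capacity,
            "converted": float(np.mean(reps)),
        })
    return pd.DataFrame(rows)


def fit_product_model(grid: pd.DataFrame) -> tuple[float, float]:
    """Least-squares scale fit of ``R_M * Cn0 * Cp0`` to the oracle surface.

    Returns ``(R_M_hat, r_squared)``.  The grid must span at least a 4x4
    design with variation in both axes.
    """
    if grid["Cn0"].nunique() < 4 or grid["Cp0"].nunique() < 4:
        raise ValueError("need at least a 4x4 grid to fit the product model")
    x = (grid["Cn0"] * grid["Cp0"]).to_numpy()
    y = grid["converted"].to_numpy()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("degenerate grid (all-zero products)")
    r_m = float(x @ y) / denom
    resid = y - r_m * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return r_m, r2
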