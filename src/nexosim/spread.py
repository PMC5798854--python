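"""Protein spread operators: passive diffusion, active transport, synaptic transfer.

All three mechanisms move *amounts* (concentration times section volume)
between sections and are applied identically to normal and pathogenic
protein.

Passive diffusion is Brownian: the fraction of a section's content that
crosses one of its boundaries per step is the tail mass ``y = Phi(-L/(2
sigma_z))`` of a centred normal with standard deviation ``sigma_z`` (the
diffusion speed).  The one-hop fraction towards a particular neighbour is

    z = y * min(R_src, R_dst) / R_src * w * p

with ``w = 20`` for intracellular boundaries, ``w = r`` (synaptic strength)
across synapses, and ``p`` the protein's selectivity for inter-columnar
routes.  Because protein can travel several hops per step, one-hop fractions
are propagated recursively (re-pushing any received mass above a
significance threshold ``t_sig``) into *geodesic coefficients* ``d``: per
source section, a probability distribution over where a unit of mobile mass
settles.  The diffusion matrix ``M`` mixes ``d`` with the mobile fraction
``f_pd``; rows sum to one, so total amount is conserved.

Active transport moves amounts along the intracellular dendrite-soma-axon
chain with an anterograde bias (15.4% anterograde, 73% stationary, 11.6%
retrograde, scaled by ``f_at``).  Synaptic transfer releases a fraction of
the axon's content onto postsynaptic sections when the neuron fires,
distributed in proportion to ``p * r`` across its outgoing synapses.

Every operator respects the concentration cap ``Cn + Cp <= 1``: inflow that
would overfill a section is scaled back proportionally and the residue stays
at its source (see :func:`settle_flows`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm

from .network import AXON, DENDRITE, SOMA, Network, section_adjacency

__all__ = [
    "boundary_fraction",
    "neighbour_fraction",
    "build_z_matrix",
    "geodesic_coefficients",
    "diffusion_matrix",
    "settle_flows",
    "active_transport_fractions",
    "SpreadOperators",
    "build_spread_operators",
    "ANTEROGRADE_P",
    "STAY_P",
    "RETROGRADE_P",
]

#: direction probabilities for active transport (anterograde / stay / retrograde)
ANTEROGRADE_P, STAY_P, RETROGRADE_P = 0.154, 0.73, 0.116
assert abs(ANTEROGRADE_P + STAY_P + RETROGRADE_P - 1.0) < 1e-12

#: fraction of an axon's content released per action potential (scaled by f_st)
SPIKE_RELEASE_P = 0.154


def boundary_fraction(L, sigma_z):
    """Fraction ``y = Phi(-L/(2 sigma_z))`` diffusing past a section boundary.

    The section's content is centred at its midpoint; after one Brownian step
    of standard deviation ``sigma_z`` the mass beyond a boundary at distance
    ``L/2`` is the normal tail integral.  ``y -> 0.5`` as ``L -> 0`` and
    decreases with section length, increases with diffusion speed.
    """
    sigma_z = np.asarray(sigma_z, dtype=float)
    if np.any(sigma_z <= 0):
        raise ValueError("diffusion speed sigma_z must be positive")
    return norm.cdf(-np.asarray(L, dtype=float) / (2.0 * sigma_z))


def neighbour_fraction(y, R_src, R_dst, w, p):
    """One-hop fraction ``z = y * min(R_src, R_dst)/R_src * w * p``.

    The area ratio accounts for the two transverse dimensions (protein can
    only pass through the shared cross-section); ``w`` weights intracellular
    versus synaptic boundaries and ``p`` is the spread selectivity.
    """
    R_src = np.asarray(R_src, dtype=float)
    R_dst = np.asarray(R_dst, dtype=float)
    if np.any(R_src <= 0) or np.any(R_dst <= 0):
        raise ValueError("section base areas must be positive")
    return np.asarray(y) * np.minimum(R_src, R_dst) / R_src * w * p


def build_z_matrix(net: Network, sigma_z: float, row_cap: float = 1.0) -> sp.csr_matrix:
    """One-hop diffusion fractions z as a sparse (3N x 3N) matrix.

    Edges follow :func:`nexosim.network.section_adjacency`; synaptic edges
    additionally carry the per-edge selectivity ``p``.  Rows whose outflow
    exceeds ``row_cap`` are rescaled to it, guaranteeing the recursive push
    of :func:`geodesic_coefficients` converges.
    """
    adj = section_adjacency(net).tocoo()
    rows, cols, w = adj.row, adj.col, adj.data
    # per-edge selectivity: 1 intracellularly and within a column, p across
    same_neuron = (rows // 3) == (cols // 3)
    syn_p = np.where(
        net.column[rows // 3] != net.column[cols // 3],
        float(net.config.p_intercolumnar), 1.0,
    )
    p = np.where(same_neuron, 1.0, syn_p)
    y = boundary_fraction(net.sec_length[rows], sigma_z)
    z = neighbour_fraction(y, net.sec_area[rows], net.sec_area[cols], w, p)
    Z = sp.csr_matrix((z, (rows, cols)), shape=(net.n_sections, net.n_sections))
    return cap_rows(Z, row_cap)


def cap_rows(Z: sp.csr_matrix, row_cap: float = 1.0) -> sp.csr_matrix:
    """Rescale any row whose sum exceeds ``row_cap`` down to it."""
    Z = Z.tocsr(copy=True)
    sums = np.asarray(Z.sum(axis=1)).ravel()
    scale = np.where(sums > row_cap, row_cap / np.maximum(sums, 1e-300), 1.0)
    Z = sp.diags(scale) @ Z
    return Z.tocsr()


def geodesic_coefficients(Z: sp.csr_matrix, t_sig: float = 1e-6,
                          max_iter: int = 10_000) -> sp.csr_matrix:
    """Propagate one-hop fractions into per-source settlement distributions.

    For every source section a unit of mass is pushed to its neighbours by
    ``z``; any section receiving more than ``t_sig`` re-pushes that mass
    (keeping the ``1 - sum(z)`` remainder), until all travelling parcels are
    below threshold and settle where they are.  Rows of the result are exact
    probability distributions (they are renormalized against the tiny float
    drift of repeated sparse products).

    Raises ``RuntimeError`` if the push has not converged after ``max_iter``
    sweeps, which indicates un-capped ``z`` rows.
    """
    n = Z.shape[0]
    retain = 1.0 - np.asarray(Z.sum(axis=1)).ravel()  # kept when re-pushing
    retain = np.clip(retain, 0.0, 1.0)
    active = sp.identity(n, format="csr")
    settled = sp.csr_matrix((n, n))
    for _ in range(max_iter):
        if active.nnz == 0:
            break
        data = active.data
        big = data > t_sig
        if not big.any():
            settled = settled + active
            break
        small_part = active.copy()
        small_part.data = np.where(big, 0.0, data)
        small_part.eliminate_zeros()
        big_part = active.copy()
        big_part.data = np.where(big, data, 0.0)
        big_part.eliminate_zeros()
        # travelling mass settles its retention share, pushes the rest
        settled = settled + small_part + big_part @ sp.diags(retain)
        active = (big_part @ Z).tocsr()
    else:
        raise RuntimeError(
            "geodesic push did not converge; z rows are probably not capped")
    settled = settled.tocsr()
    row_sums = np.asarray(settled.sum(axis=1)).ravel()
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise RuntimeError("geodesic coefficient rows failed to conserve mass")
    return (sp.diags(1.0 / row_sums) @ settled).tocsr()


def diffusion_matrix(d: sp.csr_matrix, f_pd: float) -> sp.csr_matrix:
    """Mix geodesic coefficients with the mobile fraction ``f_pd``.

    ``M[src, dst] = f_pd * d[src, dst]`` off-diagonal and
    ``1 - f_pd + f_pd * d[src, src]`` on the diagonal; every row sums to 1.
    Applying ``M`` maps amounts at sources to amounts at destinations
    (``x_new = M.T @ x``), conserving the total.
    """
    if not 0.0 <= f_pd <= 1.0:
        raise ValueError("f_pd must lie in [0, 1]")
    n = d.shape[0]
    M = (f_pd * d + sp.diags(np.full(n, 1.0 - f_pd))).tocsr()
    row_sums = np.asarray(M.sum(axis=1)).ravel()
    if np.any(np.abs(row_sums - 1.0) > 1e-9):
        raise ValueError("diffusion matrix rows must sum to 1")
    return M


def _offdiag_fractions(M: sp.csr_matrix) -> sp.csr_matrix:
    off = M.tocoo(copy=True)
    keep = off.row != off.col
    return sp.csr_matrix((off.data[keep], (off.row[keep], off.col[keep])),
                         shape=M.shape)


def settle_flows(x_n, x_p, F: sp.csr_matrix, V, max_rounds: int = 16):
    """Apply fractional flows to two amount vectors with a capacity cap.

    ``F[src, dst]`` is the fraction of the source's amount moved to ``dst``
    (off-diagonal only; the remainder stays).  Destinations whose resulting
    total concentration ``(x_n + x_p)/V`` would exceed 1 have their inflow
    scaled back proportionally (same factor for both species and all
    contributors); the residue returns to its source.  The scale-back factors
    are resolved by a short fixed-point iteration because returned residue
    raises retention, which can tighten other sections' capacity.

    Total amount of each species is conserved exactly by construction.
    Returns ``(x_n_new, x_p_new, n_saturated)``.
    """
    flows_n = F.multiply(x_n[:, None]).tocsr()
    flows_p = F.multiply(x_p[:, None]).tocsr()
    out_n = np.asarray(flows_n.sum(axis=1)).ravel()
    out_p = np.asarray(flows_p.sum(axis=1)).ravel()
    in_n = np.asarray(flows_n.sum(axis=0)).ravel()
    in_p = np.asarray(flows_p.sum(axis=0)).ravel()
    keep_n = x_n - out_n
    keep_p = x_p - out_p

    total = keep_n + keep_p + in_n + in_p
    if not np.any(total > V * (1.0 + 1e-12)):
        return keep_n + in_n, keep_p + in_p, 0

    n = x_n.size
    alpha = np.ones(n)
    inflow = in_n + in_p
    for _ in range(max_rounds):
        # residue returned to sources under the current scale-back
        ret_n = keep_n + flows_n @ (1.0 - alpha)
        ret_p = keep_p + flows_p @ (1.0 - alpha)
        total = ret_n + ret_p + alpha * inflow
        over = total > V * (1.0 + 1e-12)
        if not over.any():
            break
        space = np.maximum(V - (ret_n + ret_p), 0.0)
        new_alpha = np.where(
            (inflow > 0) & over,
            np.minimum(alpha, space / np.maximum(inflow, 1e-300)),
            alpha,
        )
        if np.allclose(new_alpha, alpha, rtol=0, atol=1e-15):
            break
        alpha = new_alpha
    ret_n = keep_n + flows_n @ (1.0 - alpha)
    ret_p = keep_p + flows_p @ (1.0 - alpha)
    n_sat = int(np.count_nonzero(alpha < 1.0))
    return ret_n + alpha * in_n, ret_p + alpha * in_p, n_sat


def save_coo(matrix: sp.spmatrix, path) -> None:
    """Dump a sparse operator as text coordinate triplets (row col value)."""
    coo = matrix.tocoo()
    with open(path, "w") as fh:
        fh.write("row\tcol\tvalue\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{v!r}\n")


def active_transport_fractions(net: Network, f_at: float) -> sp.csr_matrix:
    """Intracellular transport fractions for one step (off-diagonal only).

    Anterograde hops (dendrite->soma, soma->axon) carry ``f_at * 0.154`` of
    the section's amount, retrograde hops (soma->dendrite, axon->soma)
    ``f_at * 0.116``; the rest stays put.  Mass is conserved within each
    neuron.
    """
    if not 0.0 <= f_at <= 1.0:
        raise ValueError("f_at must lie in [0, 1]")
    n = net.n_sections
    base = np.arange(net.n_neurons) * 3
    rows = np.concatenate([base + DENDRITE, base + SOMA,
                           base + SOMA, base + AXON])
    cols = np.concatenate([base + SOMA, base + AXON,
                           base + DENDRITE, base + SOMA])
    frac = np.concatenate([
        np.full(2 * net.n_neurons, f_at * ANTEROGRADE_P),
        np.full(2 * net.n_neurons, f_at * RETROGRADE_P),
    ])
    F = sp.csr_matrix((frac, (rows, cols)), shape=(n, n))
    F.eliminate_zeros()
    return F


@dataclass
class SpreadOperators:
    """Precomputed spread machinery for one network and parameter set.

    ``Z`` one-hop fractions, ``d`` geodesic coefficients, ``M`` the diffusion
    matrix, ``F_diff`` its off-diagonal fraction form used by
    :func:`settle_flows`, ``F_at`` the active-transport fractions, and the
    per-synapse spike-release fractions ``g`` (grouped by presynaptic neuron
    via ``axon_edge_ptr``).
    """

    Z: sp.csr_matrix | None
    d: sp.csr_matrix | None
    M: sp.csr_matrix | None
    F_diff: sp.csr_matrix | None
    F_at: sp.csr_matrix | None
    g: np.ndarray              # per-synapse release fraction (sorted by pre)
    syn_post_index: np.ndarray  # flat section index of each synapse target
    syn_pre: np.ndarray
    f_pd: float
    f_at: float
    f_st: float
    sigma_z: float | None
    t_sig: float

    def diffusion_flows_excluding(self, blocked_dst: np.ndarray) -> sp.csr_matrix | None:
        """Off-diagonal diffusion fractions with inflow to blocked sections removed.

        Blocked (dead) destinations receive nothing; the would-be inflow stays
        at its source via the implicit retention of :func:`settle_flows`.
        """
        if self.F_diff is None:
            return None
        if not blocked_dst.any():
            return self.F_diff
        F = self.F_diff.tocoo(copy=True)
        keep = ~blocked_dst[F.col]
        return sp.csr_matrix((F.data[keep], (F.row[keep], F.col[keep])),
                             shape=F.shape)


def build_spread_operators(net: Network, *, sigma_z, f_pd, f_at, f_st,
                           t_sig: float = 1e-6) -> SpreadOperators:
    """Assemble all spread operators for a network and parameter setting.

    ``sigma_z=None`` disables passive diffusion entirely (no ``M``).
    """
    if sigma_z is not None:
        Z = build_z_matrix(net, sigma_z)
        d = geodesic_coefficients(Z, t_sig)
        M = diffusion_matrix(d, f_pd)
        F_diff = _offdiag_fractions(M)
    else:
        Z = d = M = F_diff = None
    F_at = active_transport_fractions(net, f_at) if f_at > 0 else None

    # spike release: g = 0.154 * f_st * p*r / sum(p*r) over the axon's synapses
    pr = net.selectivity * net.strength
    totals = np.zeros(net.n_neurons)
    np.add.at(totals, net.pre, pr)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(totals[net.pre] > 0,
                     SPIKE_RELEASE_P * f_st * pr / totals[net.pre], 0.0)
    syn_post = 3 * net.post_neuron + net.post_section
    return SpreadOperators(Z=Z, d=d, M=M, F_diff=F_diff, F_at=F_at,
                           g=g, syn_post_index=syn_post, syn_pre=net.pre.copy(),
                           f_pd=f_pd, f_at=f_at, f_st=f_st,
                           sigma_z=sigma_z, t_sig=t_sig)


def synaptic_transfer_flows(ops: SpreadOperators, spiking: np.ndarray,
                            n_sections: int) -> sp.csr_matrix | None:
    """Fraction matrix for spike-triggered release this step, or None.

    ``spiking`` is a boolean per-neuron mask of neurons that fired (and are
    alive).  Only their axons release; each outgoing synapse carries its
    precomputed fraction ``g``.
    """
    if ops.f_st == 0.0 or not spiking.any():
        return None
    sel = spiking[ops.syn_pre]
    if not sel.any():
        return None
    rows = 3 * ops.syn_pre[sel] + AXON
    cols = ops.syn_post_index[sel]
    return sp.csr_matrix((ops.g[sel], (rows, cols)),
                         shape=(n_sections, n_sections))
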