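# Methods

`nexosim` simulates the accumulation, spread and toxic effects of a
prion-like pathogenic protein on a small spiking neural network of cortical
columns, and measures the breakdown patterns the combination produces.
This note records the model, its assumptions, the parameters that matter,
and the numerical choices behind the implementation.

## Substrate: the column network

The tissue is `K = 3` cortical columns of 470 neurons each (`N = 1410`),
every neuron belonging to a layer (2, 4, 5, 6) and one of four
electrophysiological types: excitatory regular-spiking (RS) and
intrinsically-bursting (IB), inhibitory fast-spiking (FS) and low-threshold
spiking (LTS).  A neuron is reduced to three cylindrical *sections* —
dendrite (j=1), soma (j=2), axon (j=3) — with diameter `D`, length `L`,
base area `R = π(D/2)²` and volume `V = L·R`.  Defaults (µm): dendrite
L=150 D=2, soma L=20 D=20, axon L=300 D=1, uniform across types and
overridable per config.  These values are model choices sized like typical
cortical neurites; only ratios of areas and volumes enter the dynamics.

Connectivity is sampled from a per-(pre-type, post-type) Bernoulli density
matrix (defaults: excitatory axons contact 8% of potential targets,
inhibitory 25%, both scaled ×0.1 across columns), with uniform strengths
`r ∈ [0.5, 1.5]`, excitatory axons contacting dendrites and inhibitory
axons contacting somas, and no autapses.  The per-column composition
restricts IB cells to layers 5 and 6, leaving exactly 14 non-empty
layer×type populations; together with three whole-network seed replicates
this yields the 17-entry seed menu of the factorial design.  Two shipped
connectivity seeds stand in for "two random instances" of the wiring.

The per-neuron **synaptic strength gradient** SSG = (sum of incoming r) −
(sum of outgoing r) follows the verbal definition ("presynaptic minus
postsynaptic strengths"); a config switch (`convention=`) provides the
opposite sign convention.  **GDS** is the hop distance from the seeded neuron, computed on the
directed synapse graph (anterograde, matching the spread bias); an
undirected variant is a flag.

## Protein kinetics

Each section holds two concentration fractions, normal `Cn` and pathogenic
`Cp`, with `Cn + Cp ≤ C_max = 1`. Per timestep and per species:

* **Production** adds `a ~ N(R_P, R_P²)` to the soma only (dendrite and
  axon produce nothing).
* **Misfolding** converts `b = R_M · Cn · Cp` from normal to pathogenic in
  every section — a mass-action product law validated against the particle
  oracle below.  Misfolding continues after cellular death.
* **Clearance** removes `q ~ N(μ, μ²)` with the adaptive mean
  `μ = R_C · ln(1 + (e−1) C / C_norm)`, which equals the nominal rate
  exactly at the normal level (`μ(C_norm) = R_C`) and vanishes at zero.

All stochastic rate draws have coefficient of variation 1 (`N(m, m²)` read
as mean `m`, standard deviation `m`).  Draws are **not** truncated at zero:
one-sided truncation would inflate both production and clearance means by
the same factor `E[max(X,0)]/m ≈ 1.083`, which (because misfolding is not
similarly inflated) shifts the point model's stability boundary in `R_M` by
about 8% and destroys the documented sensitivity of the equilibrium
experiment.  Instead, negative draws are kept as net molecular
fluctuations, production is floored so concentrations stay non-negative,
and clearance draws are capped at the available concentration.  Away from
the `C = 0` boundary the realized means are exactly the nominal rates.

### The single-compartment equilibrium experiment

One volume with production, misfolding and clearance only
(`Cn0 = C_nn = 0.05`, `Cp0 = C_pn = 0.01`, `R_Pn = R_Cn = 4e−4`,
`R_Pp = R_Cp = 0.8e−4`).  The *equilibrium is lost* at the first step where
`Cp` exceeds a runaway criterion, 0.5·C_max by default (configurable; the
criterion only needs to mark unambiguous divergence, since past the
deterministic separatrix `Cp` grows without return).

The deterministic drift field has a saddle-node bifurcation between
`R_M = 0.0622` and `0.0626`: below it a stable equilibrium with partially
depleted `Cn` exists and only noise can (very slowly) escape it; above it
the equilibrium is metastable and loss is certain.  This is why loss times
are acutely sensitive to the third decimal of `R_M`, and why the default
experiment grid brackets the bifurcation with 0.0622 / 0.0624 / 0.0626
(a rate like 0.622, three orders of magnitude past the bifurcation, loses
equilibrium almost immediately and is not an interesting setting).

## Spread

All three mechanisms move *amounts* `x = C · V` and apply identically to
both species.

**Passive diffusion.**  The fraction of a section's content crossing a
boundary per step is the Gaussian tail `y = Φ(−L/(2σ_z))`: after one
Brownian displacement of standard deviation `σ_z` from the section's
midpoint, that is exactly the mass lying beyond a boundary at distance
`L/2`.  The one-hop fraction toward a neighbour is
`z = y · min(R_src, R_dst)/R_src · w · p` with `w = 20` intracellularly,
`w = r` across synapses, and `p` the inter-columnar selectivity.  Because
protein can travel several hops per step, one-hop fractions are propagated
into geodesic coefficients `d`: per source, push a unit of mass by `z`,
re-push any mass a section received above `t_sig = 1e−6` (keeping the
`1 − Σz` remainder), until every travelling parcel has settled.  Rows of
`z` are rescaled to sum ≤ 1 beforehand — the push cannot converge
otherwise.  The diffusion matrix is `M = (1 − f_pd)·I + f_pd·D` with rows
summing to one; applying `x ← Mᵀx` conserves total amount to machine
precision.  Concentrations are recovered by dividing amounts by the
destination volume, the only dimensionally consistent reading.

**Active transport** moves `f_at·0.154` of a section's amount anterograde
(dendrite→soma→axon), `f_at·0.116` retrograde, per step, the remainder
staying put — the published tau motility budget (15.4% anterograde / 73%
stationary / 11.6% retrograde) scaled by the transport fraction and applied
to all sections for want of dendrite/soma-specific rates.

**Synaptic transfer.**  When a neuron fires, its axon releases
`0.154 · f_st` of its content, distributed over its outgoing synapses in
proportion to `p·r`; the transferred amount lands in the postsynaptic
section (dendrite or soma).  Without spikes, or with `f_st = 0`, nothing
moves.  The un-transferred remainder stays in the axon: transfer and
transport both carry an explicit self-retention term so that, with
production/misfolding/clearance disabled, total protein amount is an exact
invariant of all three spread operators combined (verified to 1e−9 over
10⁴ steps; in practice machine precision).

**Capacity cap.**  Any operator's inflow that would push a destination past
`Cn + Cp = 1` is scaled back proportionally (same factor for both species
and all contributors) and the residue stays at its source; the scale-back
factors are resolved by a short fixed-point iteration because returned
residue tightens other sections' headroom.  Saturation events are counted
on the run record.

**Death rule.**  After a neuron dies, only misfolding inside it and
diffusion *out* of its sections continue; diffusion into it is disabled
(the would-be inflow stays at the source), and its production, clearance,
transport, transfer and spiking stop.

## Spiking and toxicity

The electrophysiology only needs to supply spike events and a threshold
that toxicity can move, so neurons are leaky integrate-and-fire units with
per-type presets (IB's depolarized reset produces doublets; FS is fast and
low-threshold; LTS sits between), Poisson background drive (0.5 events/ms,
3 mV each) and delta synapses (±2 mV per unit strength, signed by the
presynaptic type).  Baseline firing rates are not calibrated to any
particular dataset; only relative changes under threshold shifts are
meaningful.

Toxicity accrues as `txc += 0.001·(exp(10·mean_j(Cn_j + Cp_j)) − 1)`,
clamped at 1, monotone by construction.  The formula deliberately includes
the normal pool: a network with only baseline protein (total 0.02 per
section) still degenerates, on a timescale of ~4.5·10³ steps, and
pathogenic accumulation shortens that.  The toxic effect shifts the firing
threshold by `±k·txc` with `k = 10 mV` at full toxicity — sign per mode
(increase = loss of function, decrease = gain of function); the magnitude
is a model choice, as only the direction is specified by the underlying
hypotheses.  Death occurs at the first step `txc = 1`; simultaneous deaths
are ordered by ascending neuron id so the death order is total (required
by the Dice metrics).  Timesteps are `dt = 0.025` ms of nominal
electrophysiological time; protein updates share the same clock.

## Breakdown metrics

* `D(n)` — overlap of the first-`n` dead sets of two runs, `n = 1..N`.
* `tc` — smallest `n/N` such that `D(m) ≥ t_conv = 0.8` for all `m ≥ n`
  (exists whenever both runs complete, since `D(N) = 1`).
* `CONV` — mean `tc` over cross pairs of run groups sharing a parameter
  value; self-pairs are excluded inside a group (they would contribute the
  degenerate `1/N`), censored runs are excluded everywhere.
* `ASY` — max over time of the across-neuron sample standard deviation
  (N−1 divisor) of toxicity, taken on the stored trace (default stride 20
  steps).
* `TTNB` — step of the last death; censored if any neuron survives the
  horizon.
* Survival characteristics — OLS `R²` of death time on SSG or GDS over
  neurons that died with finite predictor.

## The misfolding particle oracle

Discrete molecules diffuse in a unit cube (per-axis Gaussian steps,
sd 0.02, reflecting walls, 1000 steps); a normal molecule converts when it
comes within the contact radius of a pathogenic one, synchronously per
step, so a convert templates from the next step onward.  Counts map to
concentrations via a nominal capacity (600).  The defaults keep the box
**dilute**: contact radius 0.0125 and the default count grid 6..48 mean at
most ~a third of normal molecules meet a pathogenic one even at the grid
corner.  Mass-action `b = R_M·Cn·Cp` is a dilute-limit law — with a much
larger radius the oracle saturates (it measures depletion of the normal
pool, not an encounter rate) and no scale of the product can fit it.
Counts are large enough that Monte-Carlo noise stays small against the
surface; the scale fit of `R_M·Cn0·Cp0` to the 8×8 grid (10 seeds/cell)
attains `R² ≈ 0.95`.

## The factorial design

Eight menus: 2 connectivity instances × 2 solubility regimes × 17 seeds ×
2 misfolding rates (0.08, 0.09) × 3 diffusion speeds (off, 50, 500) ×
3 transport fractions (0, 1e−4, 1e−3) × 3 transfer/toxic modes (off +
threshold increase, on + increase, on + decrease) × 3 selectivities (0.01,
1, 100) = 11016 runs.  Common settings: `f_pd = 0.05`,
`R_Pn = R_Cn = 2e−4`, `R_Pp = R_Cp = 2e−5`, `C_nn = C_pn = 0.01`,
`t_conv = 0.8`.  The insoluble regime zeroes pathogenic clearance and
production and starts from `Cp = 1e−4` instead of 0.01; single-neuron
seeds add `Cp = 0.5` (a config default — only "extra pathogenic protein"
is prescribed) to one soma in column 1.  H-sets (one per menu value, 35
for the full design) are derived from whatever design is run, so subset
sweeps get consistent smaller CONV matrices.

## What the synthetic generators do and do not show

The connectivity generator reproduces the *statistical shape* of a columnar
microcircuit — dense local wiring, sparse projections, type-dependent
targets — not any measured connectome; conclusions are about the model
class, not a specific tissue.  The spiking engine produces plausible
rate changes under threshold shifts, not calibrated cortical dynamics, so
firing-frequency magnitudes are qualitative.  Directional findings
(e.g. higher misfolding rate shortens survival, insolubility increases
damage asymmetry, any spread selectivity accelerates convergence of the
death order) are checked on a reduced 30-neuron, 3-column network with 5
replicate seeds under common random numbers; problem sizes for the test
suite (30 neurons, 10⁴-step conservation horizons, 8×8 oracle grids,
11-seed equilibrium batches) were chosen so each property is resolved with
comfortable margins at interactive runtimes.

## Numerical and design choices

* Per-process RNG substreams (production, clearance, spiking) are spawned
  from one master seed, so toggling one mechanism leaves the others' draws
  untouched — the common-random-number contract behind every directional
  comparison.  "Seed All 1/2/3" re-keys all substreams.
* The geodesic push compares the *aggregate* mass a section received in a
  propagation wave against `t_sig` (parcels merge), and the resulting rows
  are renormalized against the ~1e−12 float drift of repeated sparse
  products.
* Flat section index `k = 3(i−1) + j`; intracellular weight 20; the
  three-section mean in the toxicity formula is hard-required (section
  counts other than 3 are rejected by construction).
* Degenerate inputs fail loudly: zero-variance survival predictors, empty
  groups, mismatched death-order universes, non-positive geometry and
  densities outside [0, 1] all raise `ValueError`.

## Known limitations

No aggregate-size classes, oligomer intermediates, chaperones, glia,
extracellular or exosomal routes, and no synapse-level degeneration — the
death unit is the neuron.  Electrophysiology is deliberately reduced; Table
1-style magnitudes and full-scale (1410-neuron, 11016-run) reproductions
are supported by the code but beyond interactive scale, and only effect
*directions* are asserted by the test suite.
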