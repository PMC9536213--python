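# Methods

`tcsim` reconstructs, at desk scale, the machinery of a probabilistically
wired somatosensory thalamocortical model: cortical cells in a layered
cylinder wired by distance-dependent probability rules fitted from stochastic
connectome instances; a 29-class synapse registry with Tsodyks–Markram (TM)
short-term plasticity; a six-population thalamic circuit with
footprint-truncated and divergence wiring; a clock-driven network engine with
replay support; and line-source local field potentials (LFPs).

## Geometry and placement

The cortical column is a cylinder of height 2,082 um and radius 210 um, with
layer thicknesses L1 165, L2/3 502, L4 190, L5 525, L6 700 um.  Depth is the
y axis, zero at the pia and increasing downward.  Cells are placed uniformly
within their layer's disc slice; the radius is sampled by inverse CDF
(r = R * sqrt(u)) so density is uniform over area.  The thalamus is a stack
of 420 x 420 um boxes below the column: the three reticular (RTN) sectors
(outer 78, middle 78, inner 156 um) above the relay nuclei VPL (156), VPM
(156) and POm (312 um).  POm's cell density is halved to discount its
M1-projecting cells, which do not reach S1.  The vertical gap between column
and thalamic stack is configurable and irrelevant to wiring, which only uses
horizontal (XZ) distances.

The default count table (31,346 cells over 13 populations) mirrors the layer
proportions of the source microcircuit (L1 smallest, L6 largest); per-me-type
counts within a layer are synthetic, as the original per-type census is
external data.  The packaged me-type roster is likewise a representative
subset of the standard layer_mtype_etype naming scheme, chosen so that every
ordered pair of roster names resolves to exactly one registry class.

## Distance-dependent connectivity

Connection probabilities are estimated per pathway over ordered cell pairs,
binned by XZ distance (bin centres 25, 75, ..., 375 um, half-width 25 um),
averaged across stochastic connectome instances (seven by default), and
fitted by unweighted least squares with three families:

- exponential `p(d) = A exp(-d/lambda)`;
- exponential with linear saturation `p(d) = min(p_sat, A exp(-d/lambda))`
  — the simplest two-regime reading of a "saturating exponential": a decaying
  exponential whose short-range values are capped at a fitted ceiling.  An
  alternative reading (linear ramp to a breakpoint, then exponential decay)
  is possible; the form is a config-selectable strategy;
- gaussian `p(d) = A exp(-(d-mu)^2 / 2 sigma^2)` with a non-negative centre
  offset, since some pathways peak away from zero lateral offset.

Bins with no sampled pairs are excluded from the objective rather than
imputed.  Two refinements matter in practice.  First, each bin is fitted at
its *mean pair distance* rather than its nominal centre: pair density grows
roughly linearly with distance, so the centre overstates short-range
probabilities (for the 0-50 um bin the effective abscissa is near 33 um);
without this correction binned exponential data systematically masquerades
as saturated.  Second, selection applies a parsimony rule: the minimal-SSE
family sets a benchmark, and among families within 30% of it the one with
fewest parameters wins (remaining ties break exponential < exp_linsat <
gaussian).  The margin absorbs the spurious SSE advantage a free extra
parameter earns on sampling noise, while a structurally wrong family
overshoots it by orders of magnitude.  Fitted curves are clipped to [0, 1]
when evaluated.  Synapses per connection are drawn as 1 + Poisson(mean - 1),
which matches the pathway's mean count with support >= 1.

## Synapse registry

The 29 connection classes are packaged as a TSV mirroring the source table:
s-type (facilitating E1/I1, depressing E2/I2, pseudo-linear E3/I3), p-type,
peak conductance g_syn, decay constant tau_decay, and the TM parameters U, D,
F, each as mean +/- sd, plus a textual pre:post cell-type rule.  The rule
grammar supports layer tokens (`L6`), m-type sets (`DBC-LBC-NBC-SBC`),
e-type sets (`(bAC cAC bNAC dNAC)`), bracketed unions, `or` alternation
(including alternatives that share the following alternative's target side),
and `Exc`/`Excitatory`/`Inhibitory` wildcards.  Lookup picks the most
specific match (count of constrained layer/m-type/e-type tokens across both
sides), breaking ties by the highest class index; the class's E/I letter
must agree with the presynaptic identity.  Per-synapse parameters are normal
draws truncated below at 1% of the mean (U additionally capped at 1), so
kinetics can never go non-positive.

All synapses share a 0.2 ms rise time; conductances are dual-exponential
difference kernels normalized so the peak equals the sampled g_syn
(peak normalization, since the table labels g_syn a peak conductance).

### Calcium-dependent state switching

The in-vitro state is extracellular calcium cao = 2.0 mM; the in-vivo-like
state lowers cao to 1.2 mM and multiplies U by a per-connection dependence
class: steep 0.25 (pyramidal->pyramidal and pyramidal->distal-targeting
DBC/BTC/MC/BP), shallow 0.75 (pyramidal->proximal-targeting
LBC/NBC/SBC/ChC), intermediate 0.50 (everything else).  Only the range
0.25–0.75 is constrained by the source; the assignment of endpoints to the
steep/shallow classes and the midpoint to intermediate is this package's
choice and is config-overridable.

## Short-term plasticity

The deterministic TM map keeps per-synapse utilization u and resources R.
On a spike after interval dt: u <- U + u (1-U) exp(-dt/F) (facilitation
applied before release, so the first spike of a train releases exactly U);
R recovers as R <- 1 + (R+ - 1) exp(-dt/D) where R+ is the post-release
level R(1-u).  The released fraction u*R scales the conductance.  Closed
forms used as test oracles: the periodic-drive fixed point
u* = U / (1-(1-U)e^(-ISI/F)), R* = (1-e^(-ISI/D)) / (1-(1-u*)e^(-ISI/D)),
and the pure-depression/pure-facilitation limits F->0, D->0.  Each synaptic
contact of a multi-synapse connection keeps its own TM state.

## Neuron models

The morpho-electrical diversity of the source model is out of scope; cells
are single-compartment:

- **Cortical**: adaptive exponential integrate-and-fire, one adapting
  excitatory set (C 200 pF, g_L 10 nS, E_L -70 mV, V_T -50, Delta_T 2 mV,
  a 2 nS, b 40 pA, tau_w 150 ms) and one fast-spiking inhibitory set
  (C 100 pF, Delta_T 0.5 mV, no adaptation).
- **Thalamic**: integrate-and-fire plus a low-threshold calcium current
  I_T = g_T m_inf(V)^2 h (E_Ca - V) with instantaneous activation and slow
  voltage-dependent inactivation h (time constant interpolating between a
  hyperpolarized and a depolarized value through a sigmoid).  Relay cells
  rest near -60 mV, reticular cells near -80 mV; both produce rebound bursts
  after release from hyperpolarization, abolished when g_T = 0, and tonic
  regular spiking under depolarizing drive.  The source publication gives no
  equations or constants for its thalamic cells, so all kinetic constants
  here are calibrated to those stated behaviours, not transcribed values.

Integration is fixed-step (default dt 0.1 ms): exponential-Euler relaxation
for gating/adaptation, forward Euler for the voltage, threshold crossing
refined by linear interpolation within the step (which makes first-spike
latencies converge well below dt under refinement).  Non-finite states abort
the run with the offending cell named.

## Circuit assembly

Cortical recurrent wiring is Bernoulli per ordered pair with p(d_xz) from
the fitted rule; the class comes from the registry lookup, synapse counts
from the pathway mean, parameters sampled per contact.  Intrathalamic wiring
uses three strategies: (1) relay<->RTN-sector projections with
p = p0 exp(-d/lambda) truncated at the footprint radius in XZ and at 10% of
it in depth (printed footprint *diameters* are halved to radii; lambda
defaults to the radius since only proportionality is stated); (2) the same
within each RTN sector (radius 264.63 um); (3) fixed-divergence wiring with
no spatial constraint for every POm edge.  Because the thalamic populations
are stacked, an absolute depth difference can never satisfy the 10%
constraint between two different boxes; depth for footprint wiring is
therefore measured topologically, as each cell's offset from the top of its
own box, which reduces to the absolute difference within one box.  First-
order nuclei keep one preferred RTN sector (VPL-outer, VPM-middle); POm
projects diffusely across all sectors, consistent with the less organized
reticular innervation of higher-order nuclei (the zone mapping is config
data).  Receptors: RTN->RTN GABA_A; RTN->relay an equal-weight GABA_A +
GABA_B pair, realized as two contacts each carrying half the conductance
(GABA_B kinetics are config-defined, not source-constrained); relay->RTN and
all excitatory edges AMPA.

Corticothalamic feedback originates from L5_TTPC2 and L6_TPC_L4 only:
exactly 30 presynaptic sources per first-order thalamic cell, sampled
without replacement within 50 um XZ (fewer candidates: take all, log), and a
divergence rule to POm.  Thalamocortical input uses a per-me-type
convergence table (the packaged default is a synthetic fixture, as the
original values are figure-only data); inhibitory targets' convergence is
scaled by (83/775)/(4779/26567) ~= 0.595, rounded half-to-even, and every
connection carries 9 synapses with class-25 (E2) parameters.  Synaptic
delays are 1 ms within a structure and 2 ms between structures (the source
states none).  Background drive is 10 independent Poisson generators per
cell delivering quantal excitatory/inhibitory conductances; rates and
quantal sizes are free calibration parameters (grid-searched).

## Simulation engine

Clock-driven, fully vectorized over cells.  Conductances are maintained per
(receptor, decay-constant) channel as pairs of decaying exponentials;
synapses are grouped onto the channel of their class-mean decay constant
(the per-synapse sampled kinetics remain available in the connectome tables
and drive the standalone PSP protocol).  Spikes propagate through a ring
buffer binned by dt, one slot per delay step; TM states advance lazily at
presynaptic spikes.  Replay cells emit fixed trains instead of being
integrated, which implements the hybrid scheme: any subset of cells can be
simulated in full while the rest replay recorded activity, so the detailed
subset sees exactly the source run's presynaptic input.  Everything is
deterministic given the config seed.  Scaled-down columns compensate the
reduced in-degree by multiplying synaptic conductances by the inverse scale
(config-overridable).

## Desk-scale study circuits and their dynamics

Two preset networks (module `presets`) define the standard conditions used
by the tests and the reproduction script; sizes were chosen to keep a full
run in minutes on one CPU:

- the thalamic network at 10% scale (727 cells).  Background-driven relay
  firing excites RTN; RTN bursts deliver mixed GABA_A/GABA_B inhibition;
  relay T-currents de-inactivate during the inhibition and fire rebound
  bursts, closing a loop that self-organizes into theta-range (~6 Hz)
  rhythmic bursting, carried mainly by the divergence-coupled POm/RTN loop.
- the cortical column at 5% scale (1,567 cells), built end-to-end through
  the generate->bin->average->fit->select pipeline from known ground-truth
  rules, with registry synapses and TM plasticity on recurrent edges.  With
  depression enabled, recurrent excitation ignites population bursts that
  self-terminate as resources deplete and recur on the depression-recovery
  timescale (D ~ 671 ms for the dominant E2 classes), i.e. slow synchronous
  bursting near 1 Hz.  Applying the low-calcium U scaling weakens recurrent
  release and shifts the column toward the asynchronous in-vivo-like state,
  which is measured as a strict drop in the synchrony index.

What the synthetic generator does *not* emulate: morphology-dependent
synapse placement, per-type electrophysiology, conduction-distance delays,
and the true per-pathway census of the source connectome.  Passing tests
therefore demonstrate correctness of the machinery and the stated emergent
regimes at desk scale, not quantitative fidelity to the full 31,346-cell
model.

## Local field potentials

The line-source approximation assigns each segment's transmembrane current
uniformly along its axis in a homogeneous ohmic medium (sigma = 0.3 mS/mm,
frequency-independent); the electrode potential is the closed-form
logarithmic integral, summed over segments, with a 1 um minimum-distance
clamp.  Units are nA, um, mS/mm -> uV.  Point neurons carry no spatial
current distribution, so for LFP work each detailed cell is given a
synthetic two-segment vertical cable (somatic sink, dendritic return) with
enforced zero net current — the minimal dipole consistent with synaptically
dominated extracellular signals; this is a deliberate departure from
full-morphology currents, and printed full-scale amplitudes are out of
reach by construction.  Spectra use Welch periodograms; the expected
qualitative signatures (single peak for a sine, flat white-noise spectrum,
negative log-log slope for network fixtures, far-field 1/r^2 dipole decay)
are asserted in the tests.

## Analysis

Population rates are spikes/cell/s over a window excluding the 1,000 ms
transient.  ISI CV is sd/mean of the inter-spike intervals per cell,
excluding (and counting) cells with fewer than three spikes.  The population
rate is binned at 5 ms for spectra; the synchrony index is
1 - var(shuffled)/var(observed) of that binned rate, clipped to [0, 1]
(0 for independent Poisson-like firing, 1 for lockstep); no specific
synchrony statistic is prescribed by the source, so this normalized-variance
form is the package's documented choice.  Population bursts are detected as
upward crossings of a smoothed-rate threshold (30% of peak) with a
refractory separation; the burst frequency is 1000 / median inter-onset
interval.

## Numerical choices and limitations

- dt 0.1 ms default; halving dt changes population spike counts by < 5%
  under frozen input and shifts single-cell spike times by < 0.1 ms.
- Conductance-channel grouping by class-mean tau_decay trades per-synapse
  kinetic diversity in the network engine for O(channels x cells) state.
- The engine delivers spikes at step boundaries (delays rounded to >= 1
  step); recorded spike times are interpolated within the step.
- Ties in best-fit selection are resolved on SSE rounded to 12 decimals so
  that exact-zero ties are deterministic across platforms.
- Stochastic vesicle release, NMDA voltage dependence, minicolumn
  substructure and peripheral (lemniscal) afferents are out of scope.
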