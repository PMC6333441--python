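# Methods

`piriform` simulates a layer II/III piriform-cortex (PCx) pyramidal neuron as
a compartmental cable model and reproduces, in silico, the stimulation
protocols used to study NMDA-spike-mediated amplification and combination
selectivity of olfactory (LOT) and intracortical (IC) synaptic input.  This
note records the model, its assumptions, the defaults and why they were
chosen, and what the synthetic components do and do not capture.

## Electrical model

The cell is a tree of cylindrical sections discretized into iso-potential
compartments (default maximum compartment length 4.6 µm, hard cap 19 µm).
Each compartment obeys

    C_i dV_i/dt = −g_L,i (V_i − E_L) − I_chan,i − I_syn,i + Σ_j g_ij (V_j − V_i) + I_inj,i

with specific membrane resistance Rm = 25,000 Ω·cm², axial resistivity
Ra = 100 Ω·cm, specific capacitance Cm = 1 µF/cm², and resting/leak
potential −70 mV.  Axial coupling conductances g_ij follow the standard
half-compartment series-resistance rule; the soma is a single isopotential
cylinder with length = diameter = 16.24 µm (lateral area π·L·d ≈ 829 µm²)
and no internal axial resistance.

Integration is backward Euler with an exact O(n) symmetric elimination
ordered along the tree (children before parents), unconditionally stable
for the stiff coupled system.  Default step dt = 0.025 ms; on the standard
test stimulus the somatic peak changes by < 0.5% when dt is halved, and
against the analytic RC charging curve the scheme shows the expected
first-order convergence.  Ionic and synaptic conductances enter the
diagonal implicitly; gating variables and the NMDA magnesium factor are
advanced with the previous step's voltage (staggered update), which keeps
each step a single linear solve while those factors change slowly relative
to dt.  Voltage clamp is an ideal series conductance of 10 mS at the
clamped compartment (series error < 10⁻⁴ mV at 100 pA).

## Voltage-gated channels

The soma carries fast Na (g = 1000 mS/cm², E = +50 mV), delayed-rectifier K
(500 mS/cm²) and a slow non-inactivating K conductance (20 mS/cm²), both K
reversing at −87 mV, for spike generation and spike-frequency adaptation.
Dendrites are passive apart from synaptic conductances; channel placement
is a configuration option.

The rate functions are the canonical squid-axon forms with the model's
−70 mV rest mapped onto the canonical −65 mV frame, plus per-channel
depolarizing shifts (Na +10 mV, Kdr +20 mV) chosen so that the resting
state is stable under the high somatic densities: at −70 mV the combined
channel current is below the leak-current scale, and a suprarheobase
current step elicits repetitive firing with lengthening inter-spike
intervals.  The slow K gate is first-order with a Boltzmann steady state
(midpoint −25 mV, slope 6 mV) and τ = 100 ms; its build-up during firing
produces the adaptation.  These kinetics are a modelling choice — only the
conductance densities and reversal potentials are constrained — and all
shift/midpoint parameters are configurable.

Protocol simulations run with a passive soma: every measured quantity is a
subthreshold EPSP or a clamp current, and somatic action potentials would
contaminate the peak/area measures.  The channel set is used by the
spiking/adaptation demonstrations and remains available in the run
configuration.

## Synapses

Excitatory synapses combine AMPA (instantaneous rise, τ_decay = 1.5 ms,
unitary 1 nS) and NMDA (τ_rise = 2 ms, τ_decay = 80 ms, unitary 2 nS)
conductances reversing at 0 mV; inhibition is GABA-A (instantaneous rise,
τ_decay = 7 ms, unitary 2 nS, E_rev = −70 mV).  The NMDA conductance is
multiplied by the magnesium-block factor

    g(V) = 1 / (1 + 0.25 e^(−0.08 V)),

evaluated at the local compartment potential — the sole source of the
regenerative dendritic nonlinearity.  In the Ohmic-NMDA control the factor
is frozen at V = −70 mV for the whole simulation, removing regenerativity
while preserving the kinetic waveform.  Dual-exponential waveforms are
normalized to unit peak, so a full release reaches exactly the unitary
conductance; release events superpose additively and the NMDA factor
multiplies the summed conductance.

"Unitary conductance" is read as the conductance of a full-pool release;
each vesicle contributes g_unit/5.  A configuration switch
(`g_unit_per_vesicle`) selects the alternative per-vesicle reading.

### Stochastic vesicular release

Each signal-bearing synapse owns a pool of 5 vesicles.  At every
presynaptic spike the number released is Binomial(available, Pr = 0.1);
emptied slots refill independently with memoryless rate 100 s⁻¹.  Release
depends only on the presynaptic train, so it is pre-sampled before
integration from one independent random substream per synapse — results
are bit-reproducible for a fixed seed and unaffected by synapse ordering.

### Presynaptic drive

Odor-like excitatory trains: onset 100 ± 6 ms, inter-spike intervals
8 ± 5 ms (floored at 0.1 ms, which biases the realized mean slightly
upward), spike count 5 ± 3 (all normal draws; count rounded and clipped at
zero).  Inhibitory trains follow 10 ms later (onset 110 ± 6 ms) with
10 ± 3 spikes.  Background activity is 100 AMPA-only excitatory plus 20
GABA-A inputs placed uniformly over the apical membrane, each firing
homogeneous Poisson at 10 Hz, unique per trial.

### Release-model scope and inhibitory weight

Two populations do not use the stochastic pool:

* **Background synapses** deliver their full unitary conductance at each
  Poisson event.  They stand for the aggregate in-vivo bombardment, and
  with the printed kinetics this reproduces the ~11 mV tonic somatic
  depolarization; with Pr = 0.1 stochastic release the same population
  depolarizes the cell only ~3 mV.
* **Odor-driven inhibitory synapses** keep stochastic release but carry a
  conductance weight of 2× the unitary value (~1 nS mean delivered per
  presynaptic spike).  The model's inhibitory strength is otherwise
  unconstrained; this weight is the value at which feedforward inhibition
  meaningfully opposes dispersed excitatory drive while single-glomerulus
  responses remain net-depolarizing, i.e. odor inhibition is co-tuned with
  odor excitation.  It is fixed once as `INHIBITORY_SCALE` and exposed in
  the configuration.

### Unitary-input calibration

The conductance scale of a single excitatory presynaptic cell is set by
secant iteration so that its mean peak somatic voltage-clamp EPSC at rest
is 30 pA (±10%), the unitary LOT strength; the associated current-clamp
EPSP is ~1 mV.  Means are taken over release successes (≥1 vesicle), the
convention for unitary-event amplitudes, applied identically to EPSC and
EPSP.  The calibrated scale applies to every excitatory presynaptic cell
(signal and, through the unitary background event, effectively the
background too).

## Synthetic morphology

The reconstructed cells behind the model are unpublished; the generator
emulates their printed summary statistics — soma area 829 µm², total
apical dendritic length within 2238–2516 µm, 400–650 compartments at the
default discretization — with a *balanced tufted tree*: three primary
apical dendrites, each a trunk that bifurcates twice into four terminal
branches (12 terminals in total), with every root-to-tip path of one
primary reaching the same tip extent (primary 0: ≥350 µm; all others
≥340 µm, with a small jitter).  Section lengths at each level are solved
from the length budget so the balance holds exactly; sibling lengths are
jittered in a compensating way.

Balance matters scientifically: the pairing and glomerular protocols
compare same-branch, sister-branch and different-branch input placements at
*matched* path distances and on branches of comparable geometry, as the
paired-electrode experiments did.

Diameters taper by branch order — trunk 3.0 µm, child 2.2 µm, terminal
1.5 µm.  This specific regime was chosen for its integration physics: the
somatic-EPSC calibration inflates synaptic conductance in proportion to
dendritic attenuation, so a uniformly thin tree turns every calibrated
synapse into an NMDA-spike igniter and erases the clustered-versus-
dispersed distinction, while a very thick distal tree pushes the
per-branch threshold beyond the glomerular input counts.  A stout proximal
backbone (high somatic transfer, moderate calibration scale) with thin
terminal branches (high local impedance) puts the per-branch NMDA-spike
ignition threshold at several convergent calibrated inputs: one input
stays subthreshold, a six-input glomerulus is near threshold, and twelve
to twenty clustered inputs ignite reliably.  Branch-order statistics and
diameters of the real cells are unknown; all shape parameters are
configurable and the defaults are one fixed choice, not a fit to any
acceptance quantity.

Zone classification by path distance: perisomatic ≤ 100 µm, LOT ≥ 250 µm
(configurable; matching the distal stimulation sites), IC in between.

## Protocols and measurement conventions

Stimulus intensity is the number of co-activated calibrated synapses at a
site (the electrical stimulation intensity of the experiments has no model
unit); each fires a burst of 3 pulses at 50 Hz unless driven by odor-like
trains.  Synapses at a site are spread over ~20–30 µm of the branch.
Responses are measured against a 50 ms pre-stimulus baseline over a 300 ms
response window (3× the NMDA decay constant plus the burst; the original
analysis windows are unstated).  Peak and area use the baseline-subtracted
trace; trapezoidal integration; negative excursions included.

Threshold detection fits a four-parameter logistic to mean peak versus
intensity, compared against a straight line by AIC; the fitted inflection
is the threshold intensity and the mean peak at the largest intensity
below it is the threshold voltage.  In the pairing protocol a strong
same-branch bias can wash out the paired curve's sigmoid; the paired
threshold then falls back to the interpolated intensity at which the
paired curve reaches the unpaired threshold voltage.

The bias input mirrors the experiments: burst-activated synapses at a
second site, count tuned to a ~3.8 mV somatic EPSP, with an optional
temporal shift.  Percent threshold reduction is
100·(θ_unpaired − θ_paired)/θ_unpaired.

Clustered-versus-dispersed trials keep presynaptic trains identical
between arms (only placements differ) and share per-synapse release
substreams; glomerular trials keep every synapse present in every
condition, with inactive glomeruli given empty trains, so that release
streams stay aligned across background-only, single and paired conditions.
Pairing nonlinearity is the ratio of background-subtracted paired response
area to the sum of background-subtracted single-response areas; trials
with near-zero expected linear area (< 10 mV·ms) are excluded and counted
rather than clipped.  The glomerular protocol's odor-unselective
inhibition (24 synapses) is placed entirely in the LOT band (feedforward):
both stated placement options are LOT band and perisomatic, and
perisomatic inhibition on the ~11 mV-depolarized background directly
hyperpolarizes the somatic trace, driving single-glomerulus areas negative
and leaving the nonlinearity ratio undefined on most trials.  The
clustered/dispersed protocol keeps its stated 50/50 feedforward/feedback
split.

## What the synthetic data does and does not capture

The generator reproduces the printed morphometry and the integration
regime described above, not the anatomy of any real cell: no basal
dendrites, no spines, no 3D embedding beyond a synthetic planar layout for
SWC export, and branch-order statistics that are a stand-in.  Passing
tests therefore demonstrate the *mechanism* — branch-local regenerative
NMDA integration, its threshold structure, and its consequences for
clustered drive and input combinations — under one plausible morphology,
not quantitative predictions for reconstructed piriform cells.
Experimental quantities measured on real neurons (e.g. the 46.55%
same-branch threshold reduction) are reproduced as orderings and
magnitude relations, not as point values.

## Numerical choices and degenerate inputs

* dt default 0.025 ms; dt is validated to (0, 0.1] ms.
* Compartment count per section = ceil(length / max_seg_len); compartments
  within a section share one length, so lengths always sum exactly.
* Events at time t enter the solver at step round(t/dt), aligning stimulus
  onsets across dt choices.
* Non-finite voltages abort integration with the failure time.
* Release sampling clips counts at pool size by construction; empty trains
  and zero-rate Poisson backgrounds are valid and produce no events.
* The logistic threshold fit refuses curves with fewer than 4 intensities
  and reports "no spike" when the sigmoid does not beat a line by AIC.

## Known limitations

* No calcium dynamics, no voltage-gated dendritic channels by default, no
  synaptic plasticity, no network interactions.
* The inhibitory weight and the background release convention are
  modelling decisions constrained only indirectly (see above); both are
  single parameters in the configuration.
* Somatic spike-based readout of odor responses is out of scope; all
  protocol measures are subthreshold.
* The HH rate functions are canonical-shifted stand-ins; absolute
  rheobase and spike shape are not calibrated to data.
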