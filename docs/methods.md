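# Methods

## Model overview

`taxisim` treats the chemotaxis signaling pathway as the controller of a
closed sensorimotor loop: a static 2-D ligand field sets the input, a
receptor stage converts ligand concentration to occupancy
u = [L]/([L] + K_L), the controller converts occupancy to [CheY-P], a
stochastic two-state motor converts [CheY-P] to run/tumble decisions,
and movement closes the loop by changing the ligand the cell sees. Each
stage is an independent module with a small, typed surface; the
simulator composes them.

## Pathway models

**Designed three-molecule pathways.** Receptor activity u drives a slow
messenger v (dv/dt = c_v·u − d_v·v) and, together with v, sets the
CheY phosphorylation balance. Three wirings are provided:

- *positive*: dy/dt = k_phos·v·(Y_T − y) − k_dephos·u·y. The direct
  (fast) arm and the v-mediated (slow) arm act in opposite directions;
  at steady state the two arm gains cancel for every u because
  phosphorylation and dephosphorylation speeds stay proportional — a
  feedback-free "asymmetric clamp" whose equilibrium output
  y* = Y_T·k_phos·(c_v/d_v)/(k_phos·(c_v/d_v) + k_dephos)
  is independent of the input. Equivalently, the linearization has
  H(0) = 0: robust perfect adaptation without integral feedback.
- *negative*: phosphorylation/dephosphorylation roles of u and v
  swapped; equally adaptive, opposite response sign.
- *pseudo*: v dephosphorylates CheY-P against a constant basal
  autophosphorylation k_auto·(Y_T − y); no opposing fast arm, hence a
  non-adaptive low-pass response. The basal rate is the simplest
  closure that leaves the variant with a well-defined operating point.

Production of v is linear in u; a saturating production law would break
the exact steady-state proportionality of the two arms that makes the
adaptation robust.

**Default parameters.** No canonical rate set exists for these designed
pathways, so defaults are fixed by the operating point the rest of the
model assumes, identically for every variant: equilibrium
[CheY-P] = 2.71 µM (20% tumble bias) at reference occupancy u* = 0.5
with Y_T = 6 µM; messenger deactivation d_v = 0.02 s⁻¹ (the down
cut-off of the linearization, the optimal value from the controller
scans); and CheY-equation relaxation rate k_phos·v* + k_dephos·u* =
5 s⁻¹ (the up cut-off, fast enough that the motor time scale, not the
pathway, limits the response). With k_phos = 1 µM⁻¹s⁻¹ this gives
c_v = 0.090333 µM/s and k_dephos = 5.48333 s⁻¹ for the positive and
pseudo variants; the negative wiring meets the same three targets with
the two arm strengths swapped (c_v = 0.109667, k_dephos = 4.51667), and
the pseudo variant's k_auto = 1.86021 s⁻¹ pins its operating point to
the same 2.71 µM at u* = 0.5 so that the three variants start with
identical motility. K_L defaults to 1 µM (no canonical value; at the
reference field it places the start position mid-slope of the occupancy
curve). All values are configurable.

**Universal network.** An n-molecule activation/deactivation model,
dy_i/dt = (y_it − y_i)(C_ii + C_i·u + Σ_{j≠i} C_ij·y_j)
− y_i(D_ii + D_i·u + Σ_{j≠i} D_ij·y_j), for systematic design. The
designed pathways embed in it exactly except for the v-production term,
which is zeroth-order in v — the infinite-pool limit of the universal
form; the provided embedding uses a v pool of 10¹⁵ µM, making the
mismatch ≲ 10⁻¹⁴ for states of order unity.

## Linearization and frequency analysis

Equilibria are found by damped Newton iteration (backtracking on the
residual norm, convergence at ‖F‖ ≤ 10⁻¹⁰(1 + ‖x‖), 100-iteration cap
with the last residual reported on failure). Jacobians are central
finite differences with per-component steps of 10⁻⁶·max(|x_j|, 1);
analytic Jacobians of the designed pathways serve as test oracles
rather than as the implementation, so the same code path handles any
user model. State space → transfer function uses the standard
C(sI − A)⁻¹B + D expansion (scipy's `ss2tf`); numerator coefficients
below 10⁻⁹ of the leading scale are scrubbed to exact zeros so that
structural DC zeros of adaptive pathways survive floating point. Bode
tables default to 200 log-spaced points over [10⁻⁴, 10³] s⁻¹, with
magnitudes in dB and unwrapped phase in degrees. All frequencies in the
package are angular (s⁻¹); sources that quote the optimal down cut-off
as "0.01–0.02 Hz" alongside rate constants in s⁻¹ are read as using the
two unit names loosely, and this package does not convert by 2π.

Filter classification: *band-pass* iff |H(0)| ≤ 10⁻⁹ × peak gain and
H is strictly proper (decays at high frequency); *low-pass* iff |H(0)|
equals the peak (rel. 10⁻⁶) and the sampled magnitude is non-increasing;
anything else (pure gains, high-pass, resonant shapes) is *other*.
Unstable transfer functions are rejected.

## Controller filters

The canonical low-pass H(s) = Aω₀/(s + ω₀) and band-pass
H(s) = Ks/((s + ω₁)(s + ω₂)) are normalized so that the *peak* Bode
magnitude is exactly A: K = A(ω₁ + ω₂), peak at ω = √(ω₁ω₂). The rank-4
band-pass squares the rank-2 form (same cut-offs and peak, ±40 dB/decade
skirts), K₄ = A(ω₁ + ω₂)². Time stepping uses the
controllable-canonical realization advanced by zero-order-hold
discretization, which is exact for piecewise-constant input — the
controller contributes no integration error at the 0.5 s motor step.

Sign convention: for attractant chemotaxis the realized response is
subtracted from the 2.71 µM baseline, so rising occupancy lowers
[CheY-P] and suppresses tumbling; the repellent convention adds it.
[CheY-P] is clipped below at 0 after adding the baseline; large
excursions are in any case flattened by the motor's near-all-or-none
Hill response.

Step timing: τ₂ (response time) is the time from the stimulus to
half-peak on the rising side, τ₁ (adaptation time) the time to half-peak
on the falling side, both linearly interpolated between samples. The
half-rise convention for τ₂ is a choice (1/e and similar conventions
differ by tens of percent on the fast side); the reported reference
values are τ₁ ≈ 36 s and τ₂ ≈ 0.135 s for (A=16, ω₁=0.02, ω₂=5),
consistent with the published ~40 s and ~0.16 s at that convention's
tolerance.

## Motor

CW (tumble) bias is a Hill function of [CheY-P],
bias = c^h/(c^h + K^h) with K = 3.1 µM and h = 10.3, the calibration
derived from single-motor dose-response measurements; it places the
2.71 µM baseline at a 20.02% CW bias. The motor holds its state for
0.5 s; the next state is a Bernoulli draw with p(tumble) = bias —
memoryless per step, the simplest chain whose stationary CW occupancy
equals the bias exactly. An optional persistence parameter scales both
transition probabilities equally, adding autocorrelation while
preserving the stationary law.

## Environment and movement

Fields are static Gaussian shapes on an unbounded plane: a ridge
("mountain", L₀·exp(−(x/r)²)) or a radial peak
(L₀·exp(−(x² + y²)/r²)), defaults L₀ = 2 µM, r = 2 mm; concentrations
decay to nothing well inside any plausible plate, so no boundaries are
modeled. Cells run at 0.02 mm/s; a tumbling cell stays in place and
redraws its heading uniformly on [0, 2π). The uniform redraw is the
largest fidelity gap versus real cells, whose tumble deflection is
forward-biased (~68° mean); a wrapped-normal deflection of configurable
width is available as an alternative. Per 0.5 s step the order is:
move or reorient according to the current motor state; read [L] at the
end-of-interval position; advance the controller over the interval
(ZOH for LTI controllers; fixed-step RK4 with 10 substeps for the
nonlinear designed pathways, whose integration error is far below the
motor stochasticity); draw the next motor state from the fresh
[CheY-P]. Computing [CheY-P] at the end-of-interval position, rather
than the start, halves the sensing delay and is what the simulated
cells' published behavior implies.

LTI controllers take as input the occupancy *deviation* from the
occupancy at the population's start position, where the controller
state is initialized at equilibrium (zero internal state). For
band-pass controllers the reference is immaterial (H(0) = 0); for
low-pass controllers it pins the unstimulated operating point to the
start position, which reproduces the characteristic non-adaptive
pathology: hyperactivity above the reference level, tumble-trapping
below it. Designed-pathway controllers carry their own [CheY-P] state
and need no baseline or sign bookkeeping; their states start at the
closed-form equilibrium for the initial occupancy. Initial headings are
uniform; initial motor states are drawn from the stationary law at the
initial [CheY-P]. All randomness flows from one integer seed through a
single PCG64 generator; equal seeds give bit-identical records.

## Metrics

The chemotactic effect is the mean local [L] over all agents and all
recorded times in the final 50 s window (population mean of ~100
samples per agent at the 0.5 s stride), averaging out motor noise while
reflecting both climb speed and crest-holding. Box-plot summaries use
linearly interpolated quartiles (the inclusive order-statistics
convention used by mainstream plotting) with whiskers at the most
extreme data within 1.5 IQR of the box. Parameter scans run 100 agents
per grid point with 3 seed replicates under common random numbers —
the same seed triple at every grid point — so that across-grid
comparisons are not dominated by seed noise; single-run scans are what
the original protocol used, and replicate averaging is this package's
disclosed refinement.

## What the simulations do and do not show

The simulator's conditions are the study conditions: Gaussian fields,
point release at (1.4, 0) or (3.5, 0) mm, 100–2000 agents, 1000 s at
0.5 s resolution. Passing tests show that the implemented loop
reproduces the published quantitative anchors (motor calibration,
band-pass ≥ 1.9 µM endpoint, low-pass ≈ 1.6 µM comparator, τ₁/τ₂
timing, scan shapes) under these idealizations. They do not speak to
receptor-cluster gain and adaptation kinetics of real cells, rotational
diffusion during runs, variable run speeds, cell–cell interactions, or
ligand consumption — none of which are modeled. The low-pass
comparator's endpoint sits at the low edge of its published band
(≈1.44 µM vs "about 1.6"), which is consistent with the reorientation
idealization noted above.

## Numerical choices and degenerate inputs

- Newton equilibrium: damping halves the step up to 40 times; failure
  raises with the last residual attached.
- A = 0 controllers realize a null system (zero output, valid state),
  reducing the simulation to the motor-only null model.
- ω = 0 frequency response of an adaptive (H(0) = 0) system reports a
  −∞ dB sentinel rather than raising.
- Zero-height boxes (IQR = 0) collapse the whisker fences onto the
  median; all non-median values become outliers, per the 1.5·IQR rule.
- Duration must be an integer multiple of dt; record strides always
  include the final step so the last-window statistic is well defined.
- τ₁ extraction raises if the trajectory ends before the falling
  half-peak crossing (adaptation not yet complete).

## Known limitations

Uniform tumble reorientation (above); static fields without
consumption or diffusion; linear-in-u messenger production in the
designed pathways; the motor chain is memoryless at 0.5 s unless a
persistence is supplied; no spatial PDE for the population density —
all population statements are Monte-Carlo.
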