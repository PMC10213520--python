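# Methods

## The model

The cortical sheet is the complex plane.  Neural activity is represented
at the mesoscopic scale by synaptic flux φ_i(t) of small cell groups
(mixed excitatory/inhibitory pools), evolving as damped, coupled,
stochastically driven linear oscillators:

    φ̈_i + D_i φ̇_i + N_i² φ_i = Σ_j K_ij φ_j(t − τ_ij) + ξ_i(t).

The drive ξ is white in time; "spatially diffusing" noise is realized by
correlating the per-group increments with an isotropic Gaussian kernel of
scale `diffusion_length` over group positions, and an optional first-order
low-pass of cutoff `bandwidth` stands in for the finite bandwidth of the
drive.  Conduction delays are quantized to the nearest integration step
and served from a ring buffer.  Integration is semi-implicit
Euler–Maruyama on the first-order companion system; with the noise off it
matches the matrix-exponential solution of the linear system to ~1e-4
relative error at the default steps (verified in the test suite against
closed-form and `expm` oracles).

Key consequence used throughout: when couplings are bidirectionally
symmetric and positive and the field is noise-driven, the in-phase mode
has the lowest effective stiffness, carries the most stationary energy,
and the population shows zero-lag synchrony.  A canonical
"synchronous-equilibrium" network (symmetric positive couplings within the
E and within the I populations, symmetric negative couplings between
them) realizes the full ground-state signature: E–E and I–I
cross-correlograms peak at zero lag while E–I pairs peak at about half the
dominant oscillation period.

### Eigenmodes and modal energies

Mode frequencies and dampings are read off the eigenvalues of the
companion matrix (λ = −damping/2 ± i·frequency).  Modal energies project
the trajectory onto the orthonormal eigenvectors of the symmetrized
stiffness matrix S = diag(N²) − K and time-average kinetic plus potential
energy per mode; for symmetric coupling the energy decomposition is exact.
Over the simplex of energy splits the Gibbs free energy F = U − τS, with
entropy S = −Σ (U_i/U) ln(U_i/U), is minimized exactly at equipartition —
the package adopts the physically standard entropy sign, under which the
stated minimization holds.

## Free-energy measures

**Auto minus cross (F = A − C).**  A is the population sum of
peak-normalized pulse autocorrelations — one per non-degenerate group —
and C sums, over ordered group pairs, the maximum Pearson-normalized
cross-correlation within a finite lag window ±τ_max (default: one dominant
oscillation period).  The raw doubly-integrated cross-correlation of
stationary series diverges; the windowed peak is a bounded estimator that
preserves the ordering "more synchrony ⇒ larger C ⇒ smaller F".  Constant
series are excluded from A and C with a logged count.  During growth runs
the recorded quantity of interest is **F per ordered pair**,
F/(m(m−1)): apoptosis changes the number of live cells m, and the
per-pair form is the population-size-free scale on which minimization
continues as cells are eliminated.

Because the max-over-lags estimator has a positive noise floor
(≈ max of ~T/τ_corr correlated estimates), trend detection needs epochs
long enough that true synchrony exceeds that floor; the growth engine's
default epoch length (60 time units ≈ 10 natural periods) was chosen for
that reason.

**Accuracy minus complexity.**  For each candidate dimension k, a
k-factor Gaussian model of the inter-group correlation matrix
(maximum-likelihood factor analysis with heteroscedastic uniquenesses,
Σ_k = ΛΛ′ + Ψ) is fitted and the criterion

    α(k) = −2 lnL(k) + 2 d(k),     d(k) = pk − k(k−1)/2 + p,

is minimized; d(k) counts the model's free parameters (loadings modulo
rotation, plus uniquenesses).  A unit-per-dimension penalty cannot
satisfy model-order recovery at realistic sample sizes — the sample
eigenvalue spread alone buys far more than one likelihood unit per
dimension — so the parameter-count form, the standard reading of the
Akaike criterion for this model class, is used.  Exactly duplicated
series are collapsed before fitting (they carry no information and make
the covariance singular); a residually rank-deficient correlation matrix
is ridge-regularized with a logged value.  The criterion recovers planted
k ∈ {1..5} at signal-to-noise 10 with p = 40–50 groups and n = 4000–5000
samples, and selects k ≤ 1 on pure noise.

**Correlogram conventions.**  Positive lag means the second series lags
the first.  The dominant period is estimated from Welch spectra with
quadratic peak interpolation; when E/I labels are available it is
estimated from the class-mean difference (mean E minus mean I series) —
the coordinate in which the E–I oscillation lives and which common
broadband drive cancels out of.  For signature detection the series are
block-averaged to ~8 bins per period first, the standard correlogram
binning that makes "zero-lag" a well-posed bin.

## Map geometry

The global→local projection is
p = chirality · p′ (P−p0)ⁿ / |P−p0|ⁿ⁻¹ + p0 with even n: modulus scales
by |p′|, azimuth is multiplied by n.  The printed form of the rotation
constant in the source material is corrupted; p′ is implemented as a free
complex constant with default argument +90° (the rotation imposed by the
arc-of-circle presynaptic geometry: the arcs of radius X radiating from
the map center meet the center perpendicular to their radial direction)
and modulus set by the local-map/global-reach ratio.  Chirality is the
overall ± sign; adjacent maps with **opposite chirality and the same p′**
join with zero OP discontinuity across the shared border (verified
numerically to 1e-6), producing the linear zones/saddles between
neighboring pinwheels.

OP(p) = chirality · (arg(p−p0) − arg(p′))/n in degrees mod 180.  For
n = 2 one circuit of azimuth covers exactly 180° of OP with winding
number 1.  The two sheets of the inverse map are antipodes — the Moebius
double cover; injectivity of the projection onto a k-sheet antipodally
identified network is checked by enumeration over sampled directions, and
the smallest even exponent that is 1:1 on two sheets is n = 2.  For
n > 2 only the k = n sheet identification ships; the cross-linking
topology of higher exponents is not canonical.

Delays use the distance to the actual local target point |P − p| (not to
the map center); this makes the circumferential/radial temporal-frequency
argument exact: sources at constant global radius keep near-equal delays
(high local event rate), radially arranged sources accumulate delay
differences (low rate).  The contrast is measured as mean event rate of
the arrival train for equal-length circumferential and radial paths; it
exceeds 1 for finite conduction velocity and tends to 1 as ν → ∞.

## Growth engine

**Initialization.**  Uniform random positions; a fraction of excitatory
cells are long-axon patch cells (inhibitory cells never are).  Directed
links appear independently with probability proportional to a softened
(exponent 0.3, capped) presynaptic axonal density at the pair distance,
scaled to mean `sparsity`; softening keeps the two directions effectively
independent so reciprocal pairs start at ~sparsity², i.e. the scaffold is
almost entirely unidirectional.

**Plasticity.**  Three time scales per directed contact (existing links
and their reverses):

- fast efficacy ε: dε/dt = (ε₀−ε)/τ_f + a_f·coincidence − a_d·rate·ε,
  clipped to [0, ε_max] — facilitation by coincident activity, rate
  depression, recovery to baseline;
- slow gain g: dg/dt = η·pre·post·(post−θ), with dθ/dt = (post²−θ)/τ_θ —
  the sliding-threshold rule with floating negative feedback; the engine
  initializes θ at the homeostatic fixed point of the normalized rates
  and uses a small η so the rule contributes selectivity without a
  systematic gain drift;
- structure ρ: dρ/dt = c·kernel·max(gε−b, 0) − λρ, with a stronger λ
  under disuse, saturation at ρ_max, and absorption to exactly zero after
  a grace period below a floor.  The growth kernel is
  min(long-axon, short-axon density) at the pair distance — bidirectional
  contact is limited by the lesser axonal reach — which peaks exactly at
  the density-crossing distance X (closed form verified against
  bisection), plus a floor so coincident non-X contacts consolidate at a
  reduced rate.

Plasticity sees rates normalized to the population mean (homeostatic
scaling), making the rules invariant to overall amplitude drift.

**Coupling and stability.**  Effective weights w = ρgε convert to the
oscillator coupling K through a fixed factor calibrated once at
initialization (so consolidation genuinely increases total coupling),
with inter-group coupling restricted to excitatory links — the long-range
links between groups are excitatory, and the rotational E↔I coupling
otherwise dominates the spectrum with imaginary eigenvalues that cap
stable coupling far below what symmetric excitatory networks sustain.
Each epoch K is scaled back, if necessary, to the largest multiple whose
companion eigenvalues all remain in the stable half-plane with a margin:
for an eigenvalue k of K the condition is |k−q| + Re(k−q) ≤ 2(cD/2)²
with q = N² − D²/4.  Complex (asymmetric) spectra cap early; as the
weights symmetrize, the admissible coupling grows — the mechanism by
which symmetrization itself increases synchrony and lowers F.

**Apoptosis.**  A cell's survival trace is an exponential average of its
rate times (1 + mean positive zero-lag correlation with connected
partners) — engagement in synchronous oscillation.  Cells are eliminated
when their trace is both below the round's quantile and below an energy
floor of 0.75× the live median; the relative floor means a uniform
population removes nobody and a strict majority can never be culled in
one round.  Removal events trigger synaptic upscaling of the survivors
(the coupling conversion is rescaled so the field's effective coupling is
continuous across the removal).  The apoptotic wave runs over the first
60% of the run, matching its developmental character, after which the
surviving scaffold consolidates.

**Default study conditions.**  150–200 cells (20% inhibitory, 30% of E
cells patch), sparsity 0.05, an 8×8 cortical frame with X ≈ 0.80,
natural period 2π, damping 0.15, 60-time-unit epochs at dt = 0.1,
150–300 epochs.  At these sizes a full run takes a few seconds on one
CPU, and ten-seed ensembles reproduce the expected trends: weight
asymmetry falls below half its initial value, the reciprocal-pair
fraction rises toward 1, per-pair F = A − C decreases, and surviving
patch-cell clusters sit at modal spacing within 25% of X (KDE mode of
nearest-cluster distances after single-linkage clustering at X/2).

**Postnatal refinement** operates on one local map.  The test substrate is
a constructed developed field (`make_local_map_field`): local E cells on
rings about the center, inhibitory partners interleaved, patch cells
projecting reciprocally everywhere, all contacts consolidated, with a
~15% residue of one-way links.  Stimulus arrivals (projected with
conduction delays) deposit activity on nearby cells — narrowly for
short-axon cells, over a wide radius for patch cells, whose activity
reflects map-wide integration by their long axons.  Co-variation is
judged on time-coarsened rates (a moving stimulus activates the cells it
sweeps sequentially, so cells driven by the same sweep co-vary at the
sweep timescale).  Two processes act per epoch:

- Hebbian consolidation of gain between co-activated short-axon E cells —
  under repeated circumferential sweeps this breaks the antenatal
  rotational symmetry, raising the circumferential/radial weight ratio
  relative to a diffuse-noise control;
- presynapse reallocation on the patch↔local exchange: when the
  coincidence of a patch–local pair exceeds threshold *persistently*
  (an exponential average of epoch-wise exceedances — unstructured drive
  lights up different pairs each epoch and never accumulates), a fraction
  of the connectivity shifts to the target's nearest inhibitory partner,
  replacing zero-lag synchronous links by mutually cancelling zero-error
  couplings.  The motif census over angular sectors then shows
  symmetric-E→I (zero-error) pairs appearing under structured drive and
  an unchanged census under the diffuse control.

## Motif classification and Markov blankets

Pairs of groups are classified by three binary features of their flux
exchange: majority target class (E vs I), directional symmetry
(threshold 0.2 on |φ_ij−φ_ji|/(φ_ij+φ_ji)), and peak-correlation lag
(floor 2 steps), yielding the four elementary types (symmetric E→E;
symmetric E→I zero-error; asymmetric E→I cross-inhibition; asymmetric
lagged E→E).  Exchanges below a flux floor are unclassified.  On
generated motifs with moderate noise the per-class recall exceeds 0.9.

Zero-error residuals compare, per local cell, the histogram of its
backward-predicted global event times (local times minus conduction
delay) with the actual global events at its target:
residual = Σ|h_pred − h_act| / Σ(h_pred + h_act) ∈ [0, 1], zero iff the
prediction is exact, invariant to common time shifts.  Blanket members
are cells with residual ≤ tolerance (default 5% of mean activity);
membership is nested in the tolerance.  Whether the members also form a
graph separator between interior and exterior is reported as a separate
fact, checked by connected-component analysis after node removal — the
two properties coincide on planted constructions but neither implies the
other in general.

## What the synthetic data does and does not show

All inputs are generated: seeded sparse networks, Gaussian white noise,
parametric stimuli (moving points, arcs, radial segments, line sweeps,
diffuse noise), and constructed motif/factor fixtures with known ground
truth.  The generators emulate the *structure* of the developmental
story — sparse unidirectional beginnings, diffuse antenatal drive,
structured postnatal input — not the biophysics: there are no spiking
dynamics, no laminar anatomy, no conductances, no biochemical apoptosis
pathways, and stimulus statistics are caricatures (single moving points,
not natural scenes).  Passing tests therefore demonstrate the internal
consistency of the mechanism — that the stated selection rules produce
the stated anatomical and dynamical signatures under the stated
conditions — not that real cortex develops this way.

## Numerical choices and limitations

- dt guard: dt·max(N) < 0.5; growth runs use dt = 0.1 at N = 1.
- Unstable configurations warn and log rather than raise (the growth
  engine's stability-aware scaling avoids them by construction).
- Correlation estimates are clipped to [−1, 1]; degenerate series are
  flagged, excluded, and counted.
- Ties in apoptosis survive (strict inequality); the energy floor is
  relative to the live median.
- The F-trend and signature statistics are stochastic; tests assert
  ensemble statements (e.g., ≥ 8/10 seeds) at sizes chosen so a run
  completes in seconds.
- The asymmetry index is computed on direct (monosynaptic) weights; a
  two-step path-sum option is not implemented.
- For n > 2 exponents only the n-sheet identification is provided.
- The CLI covers the common workflows; programmatic use through the
  library modules is the primary interface.
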