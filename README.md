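# mesocortex

A simulator of mesoscopic cortical self-organization, for computational
neuroscientists studying how orderly cortical anatomy — superficial patch
cells tiling the surface, orientation-preference (OP) pinwheels, and
like-to-like lateral connections — can emerge from synchrony-maximizing
synaptic selection in a noise-driven neural field.

The package implements, as tested code:

- **A stochastic coupled-oscillator neural field.**  Each oscillator is a
  small group of excitatory and inhibitory cells obeying

  `φ̈_i + D_i φ̇_i + N_i² φ_i = Σ_j K_ij φ_j + ξ_i(t)`,

  with damping `D`, natural frequency `N`, coupling `K`, and spatially
  diffuse white-noise drive `ξ`.  Bidirectionally symmetric coupling under
  diffuse noise drives the field to zero-lag synchronous equilibrium.
- **Free-energy measures.**  The auto-minus-cross form `F = A − C` over
  pulse correlations (with the E/I decomposition
  `C = C_ee + C_ii + C_ei,ie`), the accuracy-minus-complexity form
  (a minimized Akaike criterion over k-factor Gaussian models of the
  inter-group correlation matrix), and the Gibbs modal form
  `F = U − τS` with `S = −Σ (U_i/U) ln(U_i/U)`, minimized exactly at
  energy equipartition.
- **Growth by selection.**  Antenatal development from a sparse, almost
  entirely unidirectional random scaffold: short-term facilitation and
  depression, slow sliding-threshold gain (BCM-style), structural growth
  weighted by axonal density overlap (which peaks at the crossing distance
  `X` of long- and short-axon density profiles), and apoptosis of cells
  that fail to engage in synchronous oscillation.  Reciprocity rises,
  directional asymmetry of flux and weights falls, and `F = A − C` falls.
- **Pinwheel map geometry.**  The angle-doubling projection
  `p = ±p′(P−p0)ⁿ/|P−p0|ⁿ⁻¹ + p0` from the global cortical frame onto
  Moebius-strip-like local maps, its inverse, delayed stimulus projection
  and motor back-projection, the circumferential/radial temporal-frequency
  contrast, and interareal superposition.
- **Motifs and Markov blankets.**  Classification of inter-group flux
  exchanges into four elementary motif types, and detection of zero-error
  cells — where forward and backward flows cancel — which form a Markov
  blanket between a local map and the surrounding field.

## Worked example

Render the OP pinwheel of one local map and verify its geometry:

```python
from mesocortex import map_geometry as mg

spec = mg.LocalMapSpec(p0=0j, p_prime=0.5j, n=2)   # 90°-rotated, half-scale map
print(mg.op_circuit_coverage(spec, n_samples=360))  # 180.0
print(mg.op_circuit_winding(spec))                  # 1
print(mg.arc_tangent_rotation(0.8, 0.6))            # 89.99999999990436 (≈ 90°)
print(mg.smallest_injective_exponent())             # 2
```

One full 360° circuit of azimuth about the map center covers the OP range
of exactly 180° with winding number 1 (a pinwheel singularity); the
arc-of-circle presynaptic geometry rotates the projection by 90°; and the
smallest even angle exponent that projects 1:1 onto the antipodally
identified two-sheet (Moebius) local network is n = 2.

Run a small antenatal growth simulation from the shell:

```bash
mesocortex grow --cells 120 --epochs 120 --seed 0 --out runs
```

which prints, among other metrics,

```json
{
  "F_per_pair_first_quarter": -0.4265053761987666,
  "F_per_pair_last_quarter": -0.610473241113432,
  "weight_asymmetry_initial": 0.8595988538681948,
  "weight_asymmetry_final": 0.18240112719863819,
  "reciprocal_fraction_initial": 0.14040114613180515,
  "reciprocal_fraction_final": 1.0,
  "live_cells_final": 81
}
```

free energy per ordered pair falls as the field synchronizes, the
directional asymmetry of effective synaptic weights collapses (the
initially one-way scaffold becomes reciprocal), and the weakly engaged
cells have been eliminated.  Other subcommands: `simulate`, `opmap`,
`metrics`, `fixtures`, `accept` (see `mesocortex --help`).

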