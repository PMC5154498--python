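# protomem

Analysis of the spatio-temporal organization of G-protein-coupled receptor
(GPCR) protomers in multi-component coarse-grained membranes — and a
synthetic trajectory generator with planted ground truth that makes every
analysis stage testable without running molecular dynamics.

## Who this is for

Computational biophysicists studying how lipid composition and receptor
conformation shape receptor oligomerization in Martini-style coarse-grained
simulations of plasma-membrane models (mixed PC/PE/SM/CHOL/GM/PS/PI/PIP/PA/
CER/DAG/LPC bilayers hosting arrays of rigid protomers such as the μ-opioid
receptor).  The package takes bead trajectories (GRO frames or a compact
frame stack, nm units, xy-periodic boxes) plus a structured topology sidecar,
and computes:

* **Lipid order fields** — per-tail order angle χ = arccos(|v_z|/‖v‖) of the
  linker→terminal-tail vector, folded into [0, π/2] (0 = ordered, π/2 =
  lying flat), averaged on a 0.175 nm grid; cholesterol orientation with a
  three-zone split of the bilayer (middle zone 1.6 nm thick).
* **Bilayer thickness maps** — per-bin gap between the two leaflets' first
  linker beads (GL1/AM1), non-flipping lipids only, plus the thickness–order
  correlation.
* **Receptor-centered lipid densities** — normalized 50×50 maps of 0.2 nm
  bins around monomeric protomers (COM ≥ 5 nm from every other receptor),
  aligned to the COM→TM1 direction; per-residue lipid contact probabilities;
  helix-azimuth order/thickness profiles within 3.125 nm of the COM;
  protomer tilt (θ, φ).
* **Pair profiles** — membrane order/thickness between two protomers as a
  function of their separation r and the lipid position d along the line of
  centers, restricted to |n| < r₀ = 1.7 nm and d ∈ [r₀, r − r₀], with
  interface windows Ω_α = [α₀ ± π/6] and a line-of-centers occlusion filter.
* **Lipid kinetics** — helix residence times (1.2 nm sidechain cutoff),
  flip-flop event detection with hysteresis and rates in s⁻¹, z-vs-distance
  densities, and a cholesterol kinetic network: contact-fingerprint
  microstates, a reversible Markov state model, 8 kinetic macrostates, and
  transition-path-theory flux pathways between the two leaflet bulks.
* **Dimer interfaces** — residue contact maps (backbone beads within
  0.8 nm), the ≥10-residues-per-side dimer rule, interface names listing
  helices with ≥3 contacting residues (e.g. "TM1,2,H8/TM5"), k-means
  clustering of contact maps under the ordering-minimized Tr(ΔᵀΔ) metric,
  monomer counting, oligomer (trimer) detection, interface RMSD after Kabsch
  superposition, and a Bayesian multinomial–Poisson posterior over interface
  frequencies (flat Normal(0, 100) priors on log λ_j, MCMC with split-R̂
  convergence control, 95% credible intervals).

The synthetic generator (`protomem.generator`) plants all of these signals —
composition, order field, SM–order coupling, flip rates, dimer interface
library — so recovery can be asserted against exact ground truth.

## A worked example

```python
import protomem as pm

params = pm.GeneratorParams(patch_nm=20.0, n_proteins=4, n_frames=400, seed=5)
topology, frame0 = pm.build_system(params)
traj, truth = pm.simulate(topology, frame0, params)

events = pm.detect_flips(traj, topology, "CHOL")
est = pm.flip_rate(events, traj, topology, "CHOL")
print(f"CHOL flip rate {est.rate_per_s/1e6:.2f}e6 1/s")
```

Running `python examples/05_flip_kinetics.py` (which executes exactly this
analysis plus residence times) prints:

```
CHOL: 863 crossings -> rate 7.26e6 1/s (planted 7.23e6)
DAG: 9 crossings -> rate 5.64e6 1/s (planted 6.34e6)
ground-truth CHOL events: 863, detected: 863 (the detector reproduces the planted event log exactly)
CHOL residence at TM6: 5.97 ns over 333 dwells
z-vs-min-distance density: (50, 60) histogram, sum = 1.0000
```

The first lines say the flip-flop detector recovers the planted leaflet-
crossing rate (7.23×10⁶ s⁻¹ for cholesterol) within sampling error, and that
every detected event matches the generator's event log one-for-one.  The
remaining `examples/` scripts walk through each capability the same way:
order/thickness fields (`02`), receptor-centered densities and contact
hotspots (`03`), pair profiles (`04`), the cholesterol kinetic network
(`06`), and dimer-interface statistics (`07`).

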