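# Methods

This note documents the models, conventions and numerical choices behind
`protomem`, in the spirit of a methods section: what each quantity is, which
knobs matter, what the synthetic generator does and does not emulate, and
where the design was genuinely open.

## Coordinate and geometry conventions

All coordinates are nm.  Boxes are orthorhombic and periodic in x and y
only; z is never wrapped.  The minimum-image displacement therefore searches
the 9 in-plane images.  Centers of mass are unweighted bead means
(coarse-grained beads are treated as equal mass; no mass table is defined at
this resolution), unwrapped about the first bead of the selection before
averaging.  Protein COMs use backbone beads only by default (configurable):
sidechain beads are asymmetrically distributed and would bias the center.

The instantaneous bilayer midplane — the z = 0 datum of every analysis — is
the mean z of all lipid reference beads: the sterol hydroxyl (ROH) bead for
cholesterol, otherwise the first linker bead (GL1 or AM1).

## Lipid order

The order metric is the folded angle χ = arccos(|v_z|/‖v‖) between the
membrane normal and each tail's linker→terminal-bead vector (ROH→final bead
for cholesterol), one sample per tail per lipid.  Folding (the |v_z|) is
forced by the metric's range ending at π/2: both leaflets then share one
scale, with 0 a fully extended tail and π/2 one lying in the plane.  This
deliberately replaces the traditional P2 segmental order parameter — it is
cheaper and applies unchanged to sterols.  Flip-flopping species (CHOL, CER,
DAG) are excluded from order and thickness fields because they change
leaflet mid-average.

Cholesterol orientation is resolved by bilayer zone: the middle of the
bilayer is taken 1.6 nm thick, so |z − midplane| < 0.8 nm is the middle zone
and the rest splits into upper/lower headgroup regions by sign.

## Gridded fields

Order and thickness accumulate on square bins of 0.175 nm; receptor-centered
densities on 50×50 bins of 0.2 nm.  Mean-field bins with no samples are
*missing* (NaN), never zero; density maps normalize to 1 over occupied bins.
Samples outside a box-spanning grid wrap periodically; receptor-centered
maps instead clip to their 10×10 nm footprint, since a centered map has no
periodic meaning beyond half the patch.  Thickness is (mean upper-leaflet
first-linker z) − (mean lower-leaflet z) per bin, leaflets assigned per
frame by the reference bead's side of the midplane; bins missing either
leaflet are missing.

Receptor-frame alignment: each frame is translated to the protomer COM and
rotated so the COM→TM1-COM xy projection points along +x.  The same
reference direction defines the azimuth origin of the helix profiles, the
tilt direction φ, and the pair-profile orientation angles, so all
receptor-frame quantities are mutually consistent.  Free-receptor density
maps use only frames in which the protomer is monomeric (COM ≥ 5 nm from
every other protein COM, boundary inclusive).

The helix-azimuth profile bins lipids laterally within 3.125 nm of the COM
into 5° azimuth sectors (default); the x-axis is geometric azimuth with the
helix-COM azimuths emitted as tick marks, and replica averages carry
standard errors with the n−1 denominator.  The cholesterol–residue contact
cutoff for contact-probability maps is 0.7 nm (a standard CG contact
distance, configurable and recorded in output).

Protomer tilt: the principal axis is the dominant eigenvector of the
backbone-bead covariance of the transmembrane bundle (TM1–TM7), oriented
+z; loops, termini and the in-plane H8 are excluded because they skew the
axis of an idealized bundle by several degrees.  θ is the angle from the
membrane normal; φ the signed angle from the COM→TM1 projection to the tilt
direction, reported as 0 when the axis is vertical.

## Pair profiles

For an ordered protomer pair (1, 2) at separation r, the axis v_d points
from protomer 1 toward protomer 2 and d is measured from protomer 1's COM
(the origin choice is stated in output metadata; the mirrored ordering is
also accumulated, making symmetric-window profiles symmetric under
d → r − d).  Orientations α, β are the signed angles from the axis toward
the partner to each protomer's reference direction; windows are
[α₀ ± π/6].  The presets α₀ = 0 (TM1,2,H8 face) and α₀ = −3π/4 (TM5,6 face)
are honored by the generator's protein template, whose TM5/TM6 helices sit
at internal azimuths +155°/+115°.  Samples require |n| < r₀ and
r₀ ≤ d ≤ r − r₀ with r₀ = 1.7 nm (average protomer radius), and frames with
any third COM within r₀ of the COM–COM segment are excluded.  The local
thickness entering the profile is the gridded thickness field sampled at the
lipid position (recomputing a lipid-centered patch per sample was the
alternative; the field lookup is cheaper and consistent with the maps).
Default bins: r in 0.25 nm steps over [3, 12] nm, d in 0.25 nm steps.

## Flip-flop kinetics

Events use the three-zone scheme with hysteresis: a molecule commits to a
headgroup zone when it enters one, and an event is recorded at the first
frame it reaches the zone opposite its last committed one; middle-zone
excursions that return do not count.  Rates are events per molecule-second
(rate = Σ events / (N_molecules × T)), per replica, reported as the replica
mean ± standard error; the per-molecule-time denominator is an explicit
convention (a per-system-time rate would differ by N).  Simulation time is
used as-is — no coarse-grained "effective time" speed-up factor is applied;
any conversion is the user's.  Zero-event runs report rate 0 with the
one-sided 95% Poisson bound 3/denominator.  Residence times at a helix are
maximal runs of frames with the reference bead within 1.2 nm of any of the
helix's sidechain beads; a single out-frame ends a dwell (no gap tolerance).

## Cholesterol kinetic network

Each cholesterol is fingerprinted per frame by its binary residue-contact
vector (ROH within 0.7 nm of a backbone bead of that residue on any
protomer) concatenated with a one-hot bilayer-zone indicator.  Distinct
fingerprints become microstates directly when at most `n_micro` (default
100) exist; otherwise k-means clusters the distinct fingerprints weighted by
multiplicity (identical to clustering all samples, far cheaper).
Microstates with fewer than 10 transition counts merge into their nearest
retained centroid; the chain restricts to its largest strongly connected
set with a warning.  The transition matrix is the detailed-balance
symmetrized estimate T = rownorm((C + Cᵀ)/2), which satisfies detailed
balance exactly with π ∝ the symmetrized row sums.

Macrostates (default 8) come from spectral lumping: k-means on the leading
eigenvector components, with two stabilizations that matter in practice —
eigenvector columns are normalized in the π-weighted norm and microstates
are π-weighted in the k-means objective, so the kinetically dominant leaflet
bulks drive the partition instead of rare contact states whose π^{-1/2}
scaling would otherwise dominate.  (A hidden-Markov refinement would be a
drop-in alternative; its hyperparameters are not pinned down here, so the
spectral method is the contractual one.)  Committors solve the standard
linear system, the net reactive flux is f⁺_ij = max(0, f_ij − f_ji) with
f_ij = π_i q⁻_i T_ij q⁺_j, and pathways are extracted by iterative
bottleneck (widest-path) decomposition, each pathway reported with its flux
fraction.

Lag time: the default is 5 frames, but the generator's flip transit makes
the zone sequence non-Markov below ~3 transit times (the classic recrossing
artifact inflates the slow implied timescale by ~2× at lag 1); implied
timescales converge by lag ≈ 20 frames, which the tests and the acceptance
script use.  Choosing the lag from an implied-timescale convergence plot is
standard MSM practice and the lag is recorded in the model.

## Dimer interfaces

A contact is two backbone beads within 0.8 nm (minimum image); a dimer
needs ≥ 10 contacting residues on *each* protomer; an interface name lists,
per side, the helices with ≥ 3 contacting residues in TM1…TM7, H8 order,
sides joined by "/" (a side where no helix reaches 3 falls back to its
largest-contact helix and is flagged).  Side order is canonicalized: the
side whose lowest-index contacting helix is smaller goes first, ties broken
by conformation (inactive first) then protomer id.  Contact-map
dissimilarity is Tr(ΔᵀΔ) minimized over the two protomer orderings — for
binary maps a Hamming distance, hence a true metric.  k-means runs on the
canonicalized vectorized maps with k chosen by silhouette over k ∈ [2, 12]
(the number of clusters is not an observable; silhouette is the selection
rule), and clusters sharing a majority interface name merge for reporting.

Interface frequencies use the multinomial–Poisson factorization:
X_j ~ Poisson(λ_j), p_j = λ_j/Σλ, with Normal(0, sd 100) priors on
γ_j = log λ_j.  The posteriors of the γ_j are independent, which the sampler
exploits: componentwise adaptive random-walk Metropolis, 4 chains,
Robbins–Monro step adaptation during warm-up, split-R̂ < 1.05 enforced (a
failure raises with diagnostics).  Intervals are equal-tailed at 95% by
default (the level is configurable).  Calibration is asserted by a
200-replication coverage simulation (95% ± 4%).

Interface RMSD superposes the matched interface-helix backbone beads of the
full dimer by least squares (Kabsch, SVD with reflection guard) and reports
RMSD in Å (nm × 10); CG backbone beads stand in for Cα.

Oligomers are connected components of the protein graph whose edges are
detected dimers; components of ≥ 3 members are reported with per-edge
interface names and protomer subscripts (A, B, C…).

## The synthetic generator

`build_system`/`simulate` emulate the *statistics* of coarse-grained
receptor-array trajectories, not their physics.  What is planted, and the
default study conditions:

* **Geometry**: protomers on a regular grid with independent random
  z-rotations, 16 by default, in a 50×50 nm (low receptor density) or
  25×25 nm (high density) patch; per-leaflet lipid counts follow area
  densities of 1.28/1.20 nm⁻², giving 3200/3000 upper/lower lipids at low
  density and 800/750 at high density (protein:lipid ≈ 1:200 and 1:100).
* **Composition** (upper leaflet): 30% CHOL, 5% GM, 0.7% CER, 1.0% LPC,
  0.4% DAG, remainder PC/PE/SM; (lower): 30% CHOL, 19% charged
  (PS/PI/PA 1.5%/PIP 1.6%), 0.1% CER, 0.5% DAG, remainder PC/PE/SM.
  Species counts use largest-remainder rounding (deterministic).
* **Protein template**: an idealized 8-helix bundle, one backbone + one
  sidechain bead per residue (residues 65–352), TM helices as near-vertical
  bead columns on a 1.3 nm circle (TM3 interior), H8 an in-plane arm, the
  internal frame normalized so the lab rotation angle equals the COM→TM1
  reference direction.  The active conformation swings TM6 outward.  No
  crystal coordinates are involved; every analysis consumes bead positions
  and helix maps only.
* **Dynamics**: lipids take Brownian xy steps (D = 0.01 nm²/ns) with a
  Metropolis exclusion from 2.0 nm protein footprints (a lipid caught
  inside a footprint when a binding event snaps protomers together may
  still step outward); each lipid's order angle relaxes (τ = 5 ns,
  stationary sd 0.12 rad) toward a planted mean field — baseline 0.6 rad,
  plus a static membrane-wide Gaussian random field (sd 0.05 rad,
  correlation 3 nm) emulating the spontaneous ordered/disordered domains a
  heterogeneous membrane develops, plus Gaussian bumps (correlation length
  1.5 nm) of −0.10/−0.12/−0.12 rad at TM1/TM5/TM6 and +0.12 at TM4,
  emulating order induction at some helices and disorder at others; linker
  depth couples to the same field (0.3 nm/rad), making ordered regions
  thicker.
* **SM–order coupling**: sphingomyelin is placed and moves under a
  Metropolis weight exp(−c·(m − m̄)/0.1) with c = 0.6 by default, tilting
  SM density toward ordered regions monotonically in c; c = 0 is exactly
  unbiased.  At the default, SM occupies below-mean-χ grid bins with
  probability ≈ 0.6 at desk-scale sampling while other classes stay at the
  occupancy baseline — the qualitative ordered-region enrichment of
  sphingolipids, made large enough to clear sampling noise at the small
  patch sizes the tests use (the measured fraction depends on the
  background-field amplitude and the number of independent SM positions).
* **Flip-flop**: per-molecule Poisson schedules at planted rates — CHOL
  7.23×10⁶ s⁻¹ and DAG 6.34×10⁶ s⁻¹ (low-receptor-density conditions), CER
  0 (its crossings are too rare at these timescales) — with a 2-frame
  linear z transit through the midplane; intermediate waypoints are
  compressed inside the middle zone so midplane fluctuations cannot move
  the committed crossing frame, and the realized event log (continuous
  event times and committed frames) is emitted as ground truth that the
  detector reproduces exactly.
* **Dimerization**: a planted interface library — TM1,2,H8/TM1,2,H8 (α₀ =
  β₀ = 0), TM1,2,H8/TM5,6 (0, −3π/4) and TM5,6/TM5,6 (−3π/4, −3π/4), bound
  COM distance 3.2 nm, capture radius 4.5 nm with ±π/6 orientation windows,
  k_on = 0.1 ns⁻¹, k_off = 0 (formed interfaces do not dissociate, matching
  the emulated regime).  Bound pairs snap to the exact pose and stop
  diffusing; the realized poses satisfy the ≥10-contact dimer rule and the
  interface detector recovers the planted names.  Explicit `planted_bonds`
  build static dimers or linear trimers from frame 0.

What the generator does **not** emulate: forces and energetics (no
elastic network, no lipid–protein enthalpy), membrane undulations and
curvature, correlated collective lipid motion, solvent and ions, realistic
bead chemistry, and protein-mediated changes to flip *mechanism* (flips are
scheduled, so protein-bound flip pathways arise only through geometry, not
energetics).  Passing tests therefore demonstrate that the analyses recover
planted statistical structure exactly or within stated error — not that the
analyses would be similarly well-behaved against all artifacts of real
trajectories (e.g., undulation-induced apparent thickness variation).

## Numerical details and degenerate inputs

Empty bins are missing, never zero; empty dwell distributions have an
undefined mean and are flagged; a single-bin thickness–order table reports
r = NaN; zero reactive flux yields an empty pathway list with a warning;
zero-length tail vectors give NaN order angles (skipped downstream).  GRO
I/O is fixed-width with 3-decimal nm positions; parse errors name the
1-based line; NaN or field-overflow positions are refused on write.  The
frame stack is a single JSON header line plus little-endian float32
positions.  Every stochastic component (generator, k-means seeds, MCMC)
takes an explicit integer seed; identical seeds give bit-identical output.

## Problem sizes used by the tests and the acceptance script

The bundled statistical checks run on deliberately modest problems chosen
for tight ground-truth control: flip statistics on a protein-free sterol
membrane (≈390 CHOL × 3000 ns ≈ 1.2×10⁶ molecule-frames, ≈5700 events);
the acceptance pipeline on a 25 nm patch with 16 receptors for 1200 ns; the
Bayesian coverage on 200 replications of n = 200 multinomial draws.  These
sizes give standard errors comfortably inside the asserted tolerances while
keeping the full suite to a few minutes on one CPU.

## Known limitations

Microstate k-means on binary fingerprints is geometric, not kinetic; rare
long-lived contact states can still appear as slow modes of the microstate
chain (they are real features of the generated dynamics, but they compete
with the leaflet-exchange mode for the top of the spectrum in
protein-dense systems).  The HMM refinement of the macrostates is not
implemented, only the spectral lumping.  The pair-profile thickness uses
the trajectory-average field rather than an instantaneous local estimate,
which damps any time correlation between protomer approach and local
thinning.  Replica standard errors assume independent replicas; frames
within a replica are autocorrelated and the per-frame sample counts
overstate the effective n.
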