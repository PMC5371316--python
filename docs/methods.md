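# Methods

## The problem

Intrinsically disordered protein regions (IDRs) often carry short segments
with *transient* helical structure — populated a few tens of percent of the
time — that act as molecular recognition elements. Estimating that per-segment
helical population is the core task this package addresses. The strategy:
split the region into 10-residue segments, sample each segment's
conformational ensemble along a helicity reaction coordinate with umbrella
sampling and replica exchange, reconstruct the free-energy profile with WHAM,
and integrate the helical basin. An independent NMR route estimates the same
populations from Cα/Cβ secondary chemical shifts.

## Reaction coordinate

The helicity coordinate is a distance RMSD over the Cα(j)–Cα(j+3) pairs:

    R = sqrt( (1/N) Σ_i (d_i − d_i,0)² ),   d_i,0 = 0.5 nm for every pair.

R = 0 is the fully helical segment; increasing R is progressive unwinding.
Sampling is restrained with V(R) = ½ k0 (R − R0)², k0 in kJ·mol⁻¹·nm⁻².
The analytic gradient of R is singular at R = 0 (square root of a sum of
squares); `drmsd_squared_gradient` provides the regular gradient of R² for
callers that need a force at the origin.

## Coarse-grained peptide model

All-atom molecular dynamics in explicit water is replaced by a Cα-trace
model sampled by Metropolis Monte Carlo. The representation is deliberately
minimal — the analysis pipeline, not the force field, is the product — but
it preserves every quantity the analysis consumes:

| term | form | default |
|---|---|---|
| virtual bond | fixed | 0.38 nm |
| pseudo-bond angle | harmonic, ½k(θ−θ₀)² | θ₀ = 91°, k = 400 kBT/rad² |
| pseudo-dihedral | two Gaussian wells (σ = 15°): helical at +48° of depth h_j, extended at −170° of depth 0.9 kBT | h_j from sequence |
| contacts (\|i−j\| ≥ 4) | −ε_c inside 0.62 nm; harmonic soft core inside 0.40 nm (k = 200 kBT/nm²) | ε_c per variant |

Geometry calibration: with bond 0.38 nm and angle 91°, a helical dihedral
of +48° reproduces the 0.50 nm i,i+3 reference distance to 2×10⁻⁴ nm and
puts the i,i+4 distance at 0.598 nm — inside the 0.62 nm contact cutoff, so
an ideal n-mer helix has exactly n−4 surrogate H-bonds (e.g. 6 for a
10-mer), while i,i+5 (0.86 nm) stays outside. The angle stiffness and well
width were set so that the geometric helicity criterion (below) reads an
ideal helix as 100% helical, a 6 kBT well as >80% time-averaged helicity,
and a well-free chain as <5% — the dynamic range the pipeline needs.

Energies are in units of kBT at a 300 K reference; sampling at another
temperature scales the model part of the Metropolis exponent by 300/T, so
ensembles flatten (mean energy rises) with temperature as they must.

Per-residue well depths come from the amino-acid sequence: h_j =
5 kBT × helix_scale × w(aa_j), where w is a packaged intrinsic
helix-propensity weight in [0, 1] derived from an experimental
helix-propensity free-energy scale (Ala = 1; Gly ≈ 0; Pro = 0).

### Water-model surrogates

Four named presets stand in for four water force fields. They differ only
in the helix multiplier and the contact depth; their *only* contract is
qualitative ordering — helix stabilisation V-TIP4P-ws ≥ V-TIP3P >
V-TIP4P-s > V-TIP4P-D, with V-TIP4P-D the most expanded (lowest ε_c) and
V-TIP3P the most compact. No quantitative mapping from water model to
stabilisation is published, so none is encoded.

| preset | helix_scale | ε_c (kBT) |
|---|---|---|
| V-TIP4P-ws | 1.15 | 0.8 |
| V-TIP3P | 1.00 | 1.2 |
| V-TIP4P-s | 0.70 | 0.8 |
| V-TIP4P-D | 0.30 | 0.1 |

### Monte Carlo moves

One sweep = one attempted dihedral move per pseudo-dihedral (rotation of the
chain tail about the bond axis; 25% of proposals redrawn uniformly on the
circle so the sampler hops between wells) plus ⌊(n−3)/2⌋ crankshaft moves
(rotation of two interior residues about the i→i+3 axis, which is what lets
bond angles relax). All moves preserve bond lengths exactly. Per-replica
random streams derive from (seed, window index), so adding windows never
perturbs existing streams. The numerical hot path (energy, dRMSD, rotations)
is JIT-compiled; a NumPy reference implementation of the energy is kept as
the behavioural contract in the test suite.

## Umbrella sampling with replica exchange

Twelve windows span R0 = 0.0 … 0.5 nm, endpoint-inclusive (spacing 0.5/11
nm). The restraint force constant is k0 = 1000 kJ·mol⁻¹·nm⁻² by default
— a package choice sized so that at 300 K the window widths
σ = √(kBT/k0) ≈ 0.05 nm comfortably overlap the 0.045 nm spacing.
Neighbour swaps use the Hamiltonian-replica-exchange criterion on
bias energies only (the shared model energy cancels), alternating even/odd
pairs, every `exchange_interval` sweeps (default 500; the scaled-down
study runs use 100 to keep the swap count meaningful at shorter trajectory
lengths).

## WHAM and helical populations

Binned self-consistent WHAM in log space (bin width 0.01 nm, tolerance
1e-7 on the window free energies in kT, max 10⁵ iterations), profile
reported over [min R0 − 0.05, max R0 + 0.1] nm. Bins without counts are
undefined (NaN), never interpolated; disconnected window histograms raise an
error naming the gap. Uncertainty is a Bayesian bootstrap over window sample
weights with Dirichlet weights drawn **per contiguous block of 50 samples**:
per-sample weights ignore trajectory autocorrelation and produce
overconfident intervals (verified against matched long unbiased runs).

The helical state is R < 0.15 nm — the conventional boundary at which
average helicity drops through 50% in this kind of calibration — and its
population is the Boltzmann weight of that region,
with the boundary bin split proportionally. kB = 0.0083144621
kJ·mol⁻¹·K⁻¹, T = 300 K.

Convergence is checked by splitting every window's trajectory into four
contiguous quarters, running WHAM per quarter, and comparing quarters 2–4
(the first quarter carries relaxation from the helical start): converged
when the maximum pairwise |ΔF| < 0.5 kBT over bins that are defined *and
hold ≥ 100 samples* in every compared quarter. Without the occupancy floor
the criterion keys on shot noise in barely-visited bins.

## Ensemble metrics

**Helicity.** DSSP needs backbone N/C/O atoms a Cα trace does not have.
Residue j counts as helical when its pseudo-dihedral (atoms j−1…j+2) lies
in [30°, 80°] and, where defined, d(j, j+3) ∈ [0.44, 0.56] nm. Terminal
residues without full geometric context are excluded from the denominator.
Calibration: ideal helix → 1.0, extended chain → 0.0. The
helicity-versus-R curve (0.02 nm bins) reports where linear interpolation
crosses 0.5; on this model that crossing sits near 0.10 nm — the 0.15 nm
state boundary above is retained as the protocol value, and populations are
monotone in that choice.

**Compaction.** Radius of gyration with unit masses; the H-bond surrogate
counts pairs with sequence separation ≥ 4 closer than 0.62 nm. Salt-bridge
level detail is out of reach at Cα resolution.

**Clustering.** Greedy neighbour-count (Daura-style) clustering under a
pairwise least-RMSD cutoff (default 0.1 nm, configurable) after Kabsch
superposition restricted to proper rotations. Ties
break to the lowest structure index; clusters are reported by decreasing
size. Dominance analysis scores, per significant cluster (> 100 structures)
and per variant, the variant's share of members: dominated above 80%,
neglected below 1%, else neutral, with the variant's global share reported
as the uniform-contribution baseline.

## NMR secondary-shift propensity (SSP)

Secondary shifts are observed minus random-coil reference per nucleus
(packaged Wishart-style random-coil table; glycine has no Cβ; proline rows
are flagged). The raw propensity is ΔδCα − ΔδCβ in ppm; a 3-residue
centred moving average that skips missing entries stands in for the
neighbour correction of the ncSPC web tool (whose exact weights are not
published); dividing by the packaged full-helix difference of 3.5 ppm
(+3.1 Cα, −0.4 Cβ) gives a fractional propensity clipped to [−1, 1].
Region helicity against a helix-stabilised (TFE-like) reference is the
ratio of region-mean propensities, clipped to [0, 1].

With 0.1 ppm shift noise the per-residue estimator has an irreducible sd of
0.1·√2/√3/3.5 ≈ 0.023, so per-residue recovery is quoted as mean absolute
error (≈ 0.018); region means average 10–30 residues and recover
populations to a few parts in a thousand.

## Synthetic data: what it emulates and what it does not

The generator plays two roles. (i) Conformational ensembles with tunable
per-residue helix propensity and compaction stand in for all-atom MD in
four water models: they reproduce helix–coil two-state behaviour along R,
sequence-dependent propensity, compaction-vs-extension contrast between
presets, and overlapping umbrella windows. They do **not** reproduce
absolute free energies, side-chain chemistry (salt bridges), solvent
structure, or kinetics — so passing tests demonstrate that the *analysis
stack* (restrained sampling → WHAM → populations → clustering → dominance)
is correct and internally consistent, not that any particular water model
is right. (ii) Shift tables built from a known population profile plus
Gaussian noise stand in for assigned experimental spectra; they encode the
two-state secondary-shift model exactly, so round trips test the SSP
arithmetic, not chemical-shift prediction.

The packaged 111-residue sequence (positions 380–490) is a synthetic
stand-in for the Axin-1 region with the same architecture — helix-prone
blocks at 390–420 and 460–480 with Arg/Glu spacings at 401/404, 403/410
and 412/420, a coil-prone linker between — and is labelled synthetic in
the FASTA header and loader docstring.

## Problem sizes used by the packaged studies

The test suite and the acceptance script run the study at desk scale: 12
windows × 1500–4000 MC sweeps per (segment, variant) cell, 30–60 k steps
for 1-D toy Hamiltonians, 40 k sweeps for unbiased reference runs, 200-block
bootstrap resamples. These sizes were chosen so every estimate's bootstrap
interval is small compared to the effects being asserted (verified across
seeds), and the full 11-segment two-variant scan completes in about two
minutes.

## Known limitations

- The Cα model's helicity boundary (R = 0.15 nm) is a protocol constant,
  not re-derived per sequence; the measured 50% crossing on this model is
  nearer 0.10 nm.
- Variant presets are ordinal, not calibrated: comparisons between presets
  are meaningful as orderings only.
- The random-coil shift table and full-helix offsets are packaged constants;
  any other reference set can be supplied, and absolute SSP values inherit
  whatever bias the reference carries.
- WHAM assumes decorrelated samples within bins; the block bootstrap
  compensates in the uncertainty but not in the point estimate.
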