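# Methods

## The model

`chromocg` simulates chromosomes as semi-flexible self-avoiding walks on a
face-centered-cubic (fcc) lattice with periodic boundary conditions,
following the stored-length lattice-polymer tradition: each lattice site
may hold at most two monomers, and only if they are consecutive along the
chain. A doubly occupied site stores one unit of contour length, which is
what lets the chain reptate locally and keeps the dynamics efficient in
dense, topologically constrained conditions while preserving connectivity,
excluded volume and strand non-crossability. The fcc embedding uses
integer triples (i, j, k) with even coordinate sum on a cubic grid of
spacing b/√2, so the 12 nearest-neighbor offsets are the permutations of
(±1, ±1, 0) and periodic wrapping is plain integer arithmetic.

Dynamics are kinetic Monte Carlo: one Monte-Carlo step (MCS) is N trial
moves; a trial picks a monomer and one of its 12 neighbor sites uniformly,
rejects geometrically illegal moves (occupancy or connectivity violations),
and otherwise accepts with the Metropolis probability min(1, e^(−ΔE)).
Temperature is fixed at 1; all energies are in units of k_BT. Because
KMC transition rates are Poissonian, the simulation clock is proportional
to real time; the proportionality constant is fixed a posteriori by the
MSD amplitude calibration described below.

The Hamiltonian has two terms:

* **Bending**: E(θ) = κ(1 − cos θ) per angle between two consecutive
  *non-zero* bonds. A zero-length (stored-length) bond carries no bending
  energy and decorrelates the angle chain. We deliberately use the
  κ(1 − cos θ) convention (not κ/2): it is the convention under which the
  closed-form κ ↔ l_k/b mapping below is exact, and that mapping is what
  calibrates every coarse-grained model in the package. The two
  conventions differ only by a factor-of-two relabeling of κ.
* **Epigenomic copolymer coupling**: U[e(i), e(j)] for every unordered
  monomer pair |i − j| ≥ 2 occupying nearest-neighbor lattice sites, with
  e(i) the chromatin state of monomer i. The case of interest is the
  homotypic matrix U = E_i·I (same-state attraction E_i < 0, states
  active / HP1 / PcG / black). Bonded pairs (|i − j| = 1) are excluded by
  default — for a homotypic matrix they would only add a state-independent
  offset — but an `include_bonded_pairs` flag provides the other reading.

## Coarse-graining calculus

The physical identity of a chromosome model is carried by two
dimensionless numbers: the lattice volume fraction and the entanglement
ratio L/L_e, where the entanglement length follows the melt relation
L_e = l_k (c/(ρ_k l_k³))² with c ≈ 19 and ρ_k the Kuhn-segment density.
Coarse-graining by a factor n while conserving the box volume (fcc site
volume b³/√2, double occupancy allowed) and L/L_e yields

    b    = (√2 · n · Φ / ρ_FS)^(1/3),
    l_k/b = ((b₀/L_e0) · n · c² / Φ²)^(1/3),

with ρ_FS the density in fine-scale monomers and Φ the lattice volume
fraction, which acts as the control knob (equivalently one may prescribe
the Kuhn size N_k = ν·l_k/b; the package inverts the relation either way).

Two normalization caveats are deliberate, documented behavior rather than
bugs:

* Evaluating the entanglement relation literally with c = 19 and the
  reference nucleosomal fiber (ν₀ = 200 bp, b₀ = 10.6 nm, l_k0 = 55.4 nm)
  underestimates the published entanglement sizes by a constant factor
  ≈ 1.6–1.8. The presets therefore carry the published N_e values
  (920 / 285 / 102 kbp for yeast / fly / mammal) as explicit calibration
  anchors, and the relation is used only for its exact ρ⁻² scaling.
  A preset without an anchor falls back to the raw relation and warns.
* The fine-scale volume fraction Φ₀ = ρ_FS·b₀³/√2 computed from
  b₀ = 10.6 nm differs slightly from the published 0.043/0.023 (which
  imply b₀ ≈ 11.1 nm). Φ₀ is cosmetic output; the solver consumes ρ_FS
  directly, so nothing downstream depends on the choice.

### Stiffness mapping

For the fcc stored-length chain the Boltzmann average of cos θ over the
12 successor directions (multiplicities 1, 4, 2, 4, 1 for
cos θ = 1, ½, 0, −½, −1) has a closed form, and with
x = (12/13)⟨cos θ⟩ the Kuhn ratio is l_k/b = (1 + x)/(1 − x): 1 at κ = 0,
approaching the hard ceiling of 25 as κ → ∞ (the 12/13 factor is the
stored-length fraction). The numerical inverse (Brent, tolerance 1e−13)
turns a requested l_k/b into κ; requests at or above 25 raise an
unreachable-rigidity error rather than silently clipping. The phantom
mean squared end-to-end distance

    ⟨R_e²⟩ = (12/13) b² [ (N−1)(1+x)/(1−x) − 2x(1−x^(N−1))/(1−x)² ]

is used as the Rouse-scale estimator for fit windows; its x → 0 limit is
taken analytically. The test suite checks it against an exact Markov
sampling oracle: a 13-state bond chain in which each bond is zero with
probability 1/13 and otherwise Boltzmann-tilted relative to the last
non-zero bond. That chain has ⟨u_i·u_j⟩ = (12/13) b² x^|i−j| exactly, the
correlation structure the closed form sums.

## Box size and initial states

Given a target Φ, the box edge S is the integer minimizing
|N/(4S³) − Φ|; the *realized* Φ is then fed back into the geometry solver
so that b, l_k and κ always describe the lattice actually simulated.
Production runs start from "hedgehog" configurations: a short straight
central scaffold grown by repeatedly inserting monomers at sites adjacent
to (or, as stored length, coincident with) both ends of a randomly chosen
bond. Insertions into zero-length bonds are refused — splitting a
co-located pair would strand them as a non-consecutive double occupancy —
and, because every insertion is local, the growth cannot thread the chain
through itself, so the start is knot-free by construction (no knot
invariant is computed). The scaffold shape and length (a straight path of
min(N, 2S) sites through the box center) are free choices; nothing
downstream depends on them beyond knot-freeness. A straight-`line`
initializer (with stored-length doubling when the chain exceeds the box
traverse) and a `random_collapse` grower (potentially knotted, the control
case for reptation) are provided for tests and comparisons.

## Observables

All structural and dynamical observables use *unfolded* coordinates, so
chains may extend beyond the periodic box. Monomer and center-of-mass
MSDs (g1, g3) average over monomers, up to 500 time origins per lag on the
snapshot grid, and replicas; errors are standard deviations of the
replica-mean (overlapping-origin correlation is absorbed at the replica
level). Distance moments ⟨R²(s)⟩ and σ²(s), and the contact probability
P_c(s) (strict inequality, distance < d_c) are averaged over snapshots in
a stated MCS window. Exponents always come from least-squares fits on
log-log coordinates over *declared* windows recorded in the output.

Two window rules are fixed package-wide:

* **g1 intermediate-time window**: from the Kuhn-equilibration lag (first
  lag with g1 ≥ l_k²) to the Rouse-time estimate (last lag with
  g1 ≤ ⟨R_e²⟩/6, the phantom gyration-radius scale). Below the lower edge
  the semi-flexible t^0.75 regime contaminates the fit; beyond the upper
  edge center-of-mass diffusion takes over.
* **Structural fit window** (P_c(s), ⟨R²(s)⟩): s from max(8, 4·l_k/b)
  monomers up to the box-crossing scale — the last separation whose
  ⟨R²(s)⟩ stays below the squared box edge — capped at one decade. Below
  a few Kuhn segments the correlation hole and lattice discreteness
  steepen P_c well beyond its asymptotic law (the same reason the g1
  window starts at the Kuhn scale); beyond the box scale periodic-image
  artifacts and vanishing contact counts corrupt the tail.

Contact thresholds default to d_c = √2·b (the fcc cubic-cell edge, which
evaluates to the 163 nm used for 10-kbp-resolution contact maps) and
d = 2√2·b (≈ 325 nm at that resolution) for pair kinetics; the
nucleosomal-scale reference conventionally uses a fixed 55 nm instead.

**Time mapping.** The simulation clock is anchored to experiment by
matching g1 (in μm²) to the typical measured amplitude 0.01·t^0.5
μm²·s^(−1/2): the estimator minimizes the log-space misfit over the
declared window, which reduces to an amplitude match at the window's
geometric midpoint. When the measured local exponent differs from 0.5 the
mapping is still an amplitude match; the local exponent is attached to the
result so the mismatch is visible rather than hidden.

## Epigenome decoration

Monomers take one of four merged chromatin states (the two euchromatic
classes of the five-state fly annotation merge into "active"; HP1, PcG and
black heterochromatin stay separate). Annotations are 0-based half-open
BED; each ν-bp monomer takes the state of largest base-pair overlap, and
uncovered monomers default to "black" with a warning.

The synthetic-epigenome generator emulates the block-domain structure of
the Kc167 annotation without requiring a download: domain states follow a
uniform no-immediate-repeat walk over the states, and state i draws
geometric domain lengths with mean K·p_i·L̄ (K states, target frequencies
p_i, overall mean domain length L̄). This makes the per-monomer state
frequencies exactly p_i in expectation, keeps the overall mean domain
length at L̄, and gives the prevalent black state the longest domains, as
in the real annotation. Defaults: p = (0.35, 0.07, 0.10, 0.48) for
(active, HP1, PcG, black), approximating the genomic shares of the merged
states, and L̄ = 10 monomers (100 kbp at 10-kbp resolution, the scale of
fly epigenomic domains). What the generator does *not* reproduce: the
empirical domain-length tail (real domains are broader than geometric),
correlations between neighboring domain types, and chromosome-specific
composition. Tests passing on synthetic epigenomes therefore validate the
machinery (binning, state bookkeeping, contact statistics), not any
biological claim about a particular locus.

Copolymer observables: windowed contact maps (KD-tree pair search, bin
aggregation, diagonal = 1 at single-monomer binning), P_intra/P_inter/P_c
split by state identity (their pair-count-weighted combination equals P_c
identically, which the suite asserts), per-band time courses of
⟨P_intra/P_c⟩ and ⟨P_inter/P_c⟩ (default bands 10–100 kbp, 100 kbp–1 Mbp,
1–10 Mbp; kinetics-grade runs record every 100 MCS), and pair-contact
kinetics: τ_first (first crossing below d, censored and reported as such
if absent — never imputed), τ_c (maximal runs below d) and τ_s (gaps
between runs), which satisfy τ_first + Στ_c + Στ_s + trailing = span
exactly. A map-correlation utility (Pearson over matched off-diagonal
upper-triangle entries) supports comparison against external maps but the
package ships no experimental data.

## Problem sizes used in the shipped checks

The package's own validation runs at desk scale, chosen so the full suite
and the reproduction script each complete comfortably on one CPU:

* Weakly entangled ("yeast-like") conditions: N = 512 at realized
  Φ = 512/(4·18³) ≈ 0.022, l_k/b = 5, 8 replicas × 10⁶ MCS, snapshots
  every 100 MCS, hedgehog starts, seeds 1..8. This yields the
  intermediate-time g1 exponent ≈ 0.5 (Rouse), near-linear ⟨R²(s)⟩ and a
  P_c decade near s^(−3/2): at this density the N = 512 chain overlaps its
  periodic images, so excluded volume is screened and near-ideal
  statistics emerge above the Kuhn scale.
* Isolated flexible chain: N = 512, κ = 0, Φ ≈ 0.004 (S = 32),
  4 replicas × 10⁶ MCS: P_c decade near s^(−2), the isolated-SAW law.
* Strongly entangled check (reduced size): the fly 10-kbp level
  (Φ ≈ 0.98, L/L_e = 70) at N = 2000 for 2 × 2·10⁵ MCS, asserting only
  the qualitative signature (intermediate-time g1 exponent < 0.5); the
  full crumpled-globule phenomenology needs chain lengths and trajectory
  counts far beyond a desk run.
* Copolymer toys: N = 120–160 four-state block chains at Φ ≈ 0.5–0.6 for
  2–3·10⁴ MCS, asserting sign-level microphase signatures (block-diagonal
  map enrichment, P_intra/P_c > 1 > P_inter/P_c, monotone slow-down of g1
  with deeper E_i) rather than quantitative transition locations.

## Numerical choices and degenerate inputs

* Energies are tracked incrementally during KMC and audited against a
  full recomputation on a configurable cadence; a drift beyond 1e−6 kT
  aborts the run with the offending state. Double precision keeps the
  drift orders of magnitude below that over 10⁷ MCS.
* The κ ↔ l_k/b inverse uses Brent with κ-tolerance 1e−13; the map is
  strictly monotone so bracketing is trivial.
* Single-monomer chains have no bonds or angles: every proposal is legal
  and accepted, giving the exact free-walk MSD of b² per MCS (a test
  anchor).
* Moves are proposed uniformly (monomer, then one of 12 directions);
  illegal proposals count as rejected trials, so acceptance rates are
  comparable across densities.
* The KD-tree contact search shrinks its radius by a relative 1e−9 to
  realize the strict `distance < d_c` convention on a lattice where
  squared distances are integers.
* Replica k of an ensemble uses seed = base + k; analysis stages are
  seedless and deterministic.

## Known limitations

* The equilibrium-structure checks exploit periodic-image screening in a
  small box as a stand-in for a true melt of long chains; finite-N and
  finite-box corrections leave the measured exponents a few percent off
  their asymptotic values (bands in the tests reflect this).
* The dilute flexible chain does *not* follow the phantom closed form:
  self-avoidance swells ⟨R_e²⟩ by tens of percent at N ≤ 16 and more
  beyond. The suite asserts the swelling (and its growth with N) rather
  than pretending the correction is negligible; the closed form is
  recovered under melt screening within 10%.
* The isolated-chain contact probability decays with the interior-pair
  SAW exponent ≈ −2.25 at N = 512 when contacts are counted at the
  nearest-neighbor radius √2·b — measurably steeper than the idealized
  s^(−2) law, which is recovered (≈ −1.97) only under a wider contact
  radius (the 55 nm fine-scale convention). The corresponding shipped
  check asserts the idealized band and is expected to sit at its edge;
  the exponent's dependence on the contact-radius convention is a real
  feature of the observable, not a defect of the estimator.
* Quantitative drosophila results (Hi-C correlation, glass-transition
  location near E_i ≈ −0.25, absolute contact lifetimes) require the
  full-scale ensembles and external data and are out of scope here; the
  package provides the machinery and validates its identities and
  qualitative signatures.
* Knot-freeness of hedgehog starts is guaranteed by construction, not
  verified algorithmically.
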