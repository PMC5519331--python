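# Methods

This note documents the models, conventions and numerical choices behind
`chapdock`, and what the synthetic test systems do and do not establish.

## Rigid-body coarse-grained model

Each binding partner is a rigid body with one bead per residue at the Cα
position.  The inter-body energy is a sum over bead pairs of

* a **contact term**: attractive pairs (ε<sub>ij</sub> < 0) interact through
  a Lennard-Jones-like well of depth |ε<sub>ij</sub>| with minimum at
  σ<sub>ij</sub> = (σ<sub>i</sub> + σ<sub>j</sub>)/2; repulsive pairs
  (ε<sub>ij</sub> > 0) through a barrier form |ε|[(σ/r)¹² − 2(σ/r)⁶ + 2] for
  r ≤ σ and −|ε|[(σ/r)¹² − 2(σ/r)⁶] beyond, positive at contact and decaying
  to zero;
* a **screened Coulomb term** C·q<sub>i</sub>q<sub>j</sub>·e^(−r/λ_D)/(ε_r·r)
  with C = 332.0637 kcal·Å/mol·e².  Charges are D/E = −1, K/R = +1,
  H = +0.5 (configurable; the histidine protonation state at neutral pH is
  genuinely ambiguous).  Defaults λ_D = 10 Å (≈100 mM ionic strength) and
  ε_r = 80.

All interactions are plainly truncated (not shifted) at 30 Å.  The shipped
ε/σ table (`data/synthetic_contact_params.tsv`) is a **synthetic** default —
a hydrophobicity-product combination rule, ε_ij = −λ·h_i·h_j + e₀ with
λ = 0.6 kcal/mol, e₀ = 0.2 kcal/mol — not a fitted statistical potential.
It gives qualitatively sensible behavior (hydrophobic attraction, polar
repulsion, charge complementarity) and is exercised by the toy-complex tests;
quantitative affinity predictions for real systems require a user-supplied
parameterization, which the loader accepts with its λ/e₀ scaling knobs.

## Replica-exchange Monte Carlo

One body is held fixed (without loss of generality for rigid bodies); the
other undergoes Metropolis moves in a periodic cubic box under the
minimum-image convention: rigid translations uniform in a sphere, or
rotations by a quaternion perturbation with normally distributed angle, each
chosen with probability ½.  Default ladder: 20 temperatures geometrically
spaced over 200–395 K; 2×10⁶ steps per replica recorded every 100.
Configuration swaps between a random neighbor pair are attempted every 100
steps with the standard criterion min{1, exp[(β_i − β_j)(E_i − E_j)]}.

Move magnitudes adapt toward ~30% acceptance during a discarded burn-in
phase (default one tenth of the run, capped at 5000 steps) and are frozen
for production, keeping the production chain a fixed-parameter Markov chain
that satisfies detailed balance.  Energies are stored in kcal/mol; thresholds
quoted in k_BT refer to a 300 K reference.

**Bound state and K_d.**  A pose is bound when at least one inter-body Cα
pair is within 8 Å *and* the total energy is ≤ −2 k_BT (both configurable).
For one copy of each partner in volume V, K_d = (1 − P_b)²/(P_b·N_A·V).
The estimate is averaged over several box volumes (the study protocol uses
five; the synthetic validation uses three) with the standard error over
boxes as uncertainty.  The bound fraction is read from the ladder
temperature closest to 300 K.  Note the finite-size caveat: the
K_d(V) relation is volume-independent only while the bound statistical
weight is small against the free volume (P_b ≲ 0.1); the validation systems
are chosen in that regime.

**Validation.**  The sampler is validated against the hard-core/square-well
toy, whose configurational integral is closed-form:
P_b = V_b·e^(βε)/(V_b·e^(βε) + V_free) with
V_b = (4π/3)(r_well³ − r_core³).  The acceptance suite requires agreement
within 3 standard errors (block-averaged over 20 blocks) at every box size
and a weighted-least-squares slope of K_d vs V consistent with zero.
Problem sizes (3 boxes × 2 replicas × 3×10⁵ steps) were chosen so the Monte
Carlo error is a few percent — small enough to be meaningful, large
enough to keep the whole validation in minutes on one CPU.

## Orientational analysis

Inertia frames use equal bead masses.  Axes are ordered by *decreasing*
moment of inertia (I₁ = largest moment).  Eigenvector signs are fixed by
making each axis's largest-magnitude component positive, with the third axis
then set by right-handedness — this makes frames reproducible across runs,
and all Euler-angle values are reported in this convention.  Frames with two
moments equal within 10⁻⁶ relative are rejected as degenerate.

Spherical coordinates of the ligand center of mass take I₁ as the polar
axis (Φ = 0 along I₁) and azimuth Ω = atan2(v·I₃, v·I₂).  The Euler angles
between frames J and K are

* Θ = asin(I₁ᴶ·I₂ᴷ),
* Ω = atan2(I₂ᴶ·I₂ᴷ/cosΘ, −I₃ᴶ·I₂ᴷ/cosΘ),
* Ψ = atan2(I₁ᴶ·I₃ᴷ/cosΘ, I₁ᴶ·I₁ᴷ/cosΘ),

with gimbal lock (|I₁ᴶ·I₂ᴷ| = 1) flagged and the joint angle Ω+Ψ reported.
`euler_to_matrix` inverts the map exactly away from gimbal lock, which the
test suite uses as a round-trip oracle (10⁻⁶-degree agreement on 1000 random
orientations).  The identity orientation gives Θ = 0 but Ω = 90° under this
convention — published angle maps can only be compared bin-for-bin when the
polar-axis convention is stated.

Free-energy surfaces are −k_BT·ln of the normalized 2-D histogram
(default 5° bins), min-shifted to zero; empty bins are reported as NaN
("no data"), never as +∞.  Binding modes come from neighbor-count (Daura)
clustering: the pose with the most neighbors within the cutoff becomes a
center, it and its neighbors are removed, and the step repeats; ties break
toward the lowest pose index, so the result is deterministic given the pose
ordering.  The metric is ligand-only Cα RMSD in the common receptor frame —
the receptor is rigid and identically placed in every pose, so no
superposition is needed and ligand RMSD isolates the binding-mode geometry.
The gap between the two largest modes is −k_BT·ln(p₂/p₁) in kcal/mol.
Labeling modes (e.g. by where a functional loop points) is left to
inspection of the cluster centers.

## Direct coupling analysis

Sequences are encoded over 21 states (20 amino acids + gap; nonstandard
letters map to gap with a warning).  Sequence weights are
w_i = 1/|{j: identity(i,j) ≥ 0.9}| with identity counted over **all**
columns including gaps (configurable); N_eff = Σw_i, so duplicating every
row leaves N_eff unchanged.

The Potts model is fitted by the **asymmetric pseudo-likelihood** method:
each column's conditional distribution given the rest of the row is an
independent multinomial logistic regression, minimized with L-BFGS
(gradient tolerance 10⁻⁵) on the weighted negative log-likelihood
(normalized by Σw) plus L2 penalties λ_h Σh² + λ_J ΣJ², defaults
λ_h = λ_J = 0.01.  Per-column estimates are symmetrized
J_ij(a,b) ← (J_ij(a,b) + J_ji(b,a))/2.

Scores: each 21×21 coupling block is shifted to the zero-sum gauge before
taking the Frobenius norm (the norm runs over the full block, gap state
included).  The average-product correction is applied **per segment pair**:
for an inter-segment pair the row/column/grand means run over the
inter-segment block only, which absorbs the different positional
conservation profiles of the two families; intra-segment blocks use the
standard APC with the diagonal excluded.  A fully conserved alignment
produces a uniform raw-score matrix whose APC correction is identically
zero — the raw Frobenius norms themselves do not vanish (the conditional
fits absorb the conservation), which is exactly the positional bias APC
exists to remove.  Inter-segment scores are renormalized as
S̃ = S/|min S^inter|·(1 + N/N_eff); a `variant="divide"` switch implements
the alternative 1/(1 + N/N_eff) reading of this convention, since both
appear in the literature — the multiplicative form is the default.  The
renormalization is monotone and never changes the ranking.

**Random paralog matching.**  Within each organism present in both
families, sequences are paired uniformly at random without replacement until
the smaller family is exhausted; leftovers stay unpaired, and every source
sequence appears in at most one row (avoiding the combinatorial dilution an
all-pairs concatenation would cause).  Organisms with exactly one sequence
per family are therefore paired deterministically and enter every
realization.  One master seed spawns independent per-realization seeds.
Each realization runs the full pipeline (match → weights → fit → Frobenius →
APC → renormalize) and records the inter-segment pairs with S̃ > 0.8; a
pair's **selection frequency** is the fraction of realizations selecting it.
The production protocol uses 1000 realizations; the synthetic validation
uses 50, which already separates planted pairs (frequency 1.0) from matching
noise (< 0.2) at its scale.

**Surface filtering.**  Per-residue SASA is computed with the Shrake–Rupley
rolling-probe algorithm (biotite implementation, ProtOr united-atom radii,
hydrogens excluded) on a user-supplied full-atom structure; a Cα-only trace
is rejected.  Normalized values divide by an average per-residue-type SASA
table (configurable).  Two filter modes: *stop-at-first-buried* walks the
ranked predictions and truncates at the first pair containing a residue with
SASA < 1 Å²; *discard-buried* drops only the offending pairs.  Both are
exposed because both selection protocols are in use.

An **empirical inter-protein score** — the mean of the four strongest
inter-segment APC scores, averaged over realizations — is provided for
cross-family comparisons.

## Trajectory metrics

dRMS(t) is the root-mean-square change over all inter-body Cα pair distances
relative to the reference frame; it is invariant under rigid transformations
of whole frames.  The angular deviation θ(t) is the angle between the mobile
body's largest-moment inertia axis at t and at the reference, after
least-squares (Kabsch) superposition of the reference body onto its
reference coordinates with the transform applied to both bodies.  Because an
inertia axis is a director (sign-free), each frame's axis is flipped to keep
a positive dot product with the previous frame's axis; θ then covers
(90°, 180°] only when the trajectory is sampled finely enough to track the
rotation — an isolated jump of 150° is indistinguishable from 30°.  Trailing
window averages default to the last 10 ns when time metadata exists, else
the last third of frames.

## Synthetic generators

* **Square-well toy**: exact two-state thermodynamics (above); the oracle
  for the sampler and the K_d estimator.
* **Toy complexes**: bead chains with complementary charged terminal patches
  (+1 lysines vs −1 aspartates by default); ground-truth patch residues are
  recorded so docked ensembles can be scored.  Chains are mildly kinked so
  inertia tensors are non-degenerate.
* **Planted Potts alignments**: organisms draw a paralog copy count
  (default 50/30/20% for 1/2/3 copies, 300 organisms); each true pair's
  concatenated sequence is Gibbs-sampled (default 1000 burn-in sweeps;
  chains are independent, so one draw per chain suffices) from a Potts model
  with same-state couplings J₀·δ(a,b) on the planted column pairs, J₀ = 3 by
  default — strong enough that a correct pairing shows ~50% same-letter
  frequency at planted columns against a 1/21 background, the regime the
  detection pipeline is designed for.  Row order is shuffled per family and
  true partnerships are recorded only in the truth record.  The generator
  produces i.i.d. sequences given the model: it emulates paralog
  multiplicity and matching ambiguity but **not** phylogenetic correlation
  between organisms, so passing tests demonstrate correctness of the
  inference machinery, not robustness to shared-ancestry confounding in real
  alignments.
* **Two-state trajectories**: i.i.d. hopping between two rigid poses with a
  known rotation angle (about an axis perpendicular to the principal inertia
  axis, so θ equals the rotation angle exactly) and known dRMS; optional
  per-bead Gaussian noise.

## Known limitations

* The shipped contact table is a synthetic stand-in; absolute affinities for
  real proteins are parameterization-dependent.
* K_d estimation assumes the dilute regime (small bound weight per box).
* The pseudo-likelihood fit is dense (one design matrix per column); it is
  comfortable up to a few hundred columns and a few thousand effective
  sequences on one CPU, which covers paired domain alignments but not
  full-length multi-domain concatenations.
* Gimbal-locked orientations report only the joint angle Ω+Ψ.
* Clustering is O(n²) in bound poses; a seeded subsample cap is provided for
  large ensembles.
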