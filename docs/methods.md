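# Methods

This note documents the models, numerical contracts and design choices in
`mlpot`, in the spirit of a methods section: what is computed, under which
assumptions, and what the tests do and do not establish.

## Differentiation core

All model mathematics runs on `mlpot.autodiff`, a reverse-mode automatic
differentiation engine over numpy arrays. Each primitive's backward pass is
written in terms of engine ops, so gradients returned with
`create_graph=True` carry their own graph and can be differentiated again:
forces are first derivatives of the energy, and force-matching training
takes a second derivative through them. Gradient correctness is audited
against central finite differences at every level (primitives, edge
geometry, priors, full models), and the double-backward path is audited the
same way.

Two numerical conventions matter. Division and square-root adjoints use a
defined-zero convention at zero denominators, so a zero-length edge
produces a zero unit vector and zero gradient rather than NaN. Scalar
constants stay python floats inside ops, which keeps float32 graphs in
float32; `precision: 32` casts parameters and inputs, float64 is the
default and the test precision.

## Particle systems and neighbor search

A `ParticleSystem` holds positions (Å), atomic numbers, a non-decreasing
batch vector (atoms of one sample are contiguous), optional charges
(elementary-charge units) and an optional periodic box given by three row
lattice vectors. Rectangular boxes are diagonal; triclinic boxes must be in
reduced lower-triangular form with positive diagonal **and** satisfy
|bx| ≤ ax/2, |cx| ≤ ax/2, |cy| ≤ by/2. The second set of constraints is
what makes the sequential minimum-image reduction (subtract the rounded
multiple of lattice row c, then b, then a) exact for every displacement
whose true minimum image lies within the cutoff, given the validity
constraint r_c ≤ ½·min(ax, by, cz) enforced when a list is built. A
property test checks the reduction against an exhaustive 27-image oracle.

Two searches produce the same sorted pair list: an all-pairs O(N²) scan
(default below 10,000 atoms; the boundary itself goes to the cell list) and
a hash-and-sort cell list whose per-axis cell count is derived from the
cell's perpendicular widths, so one cell spans at least a cutoff even in
skewed boxes; aliased neighbor cells at small cell counts are deduplicated
explicitly. One decomposition covers all batches jointly; cross-batch
candidates are dropped at distance-check time. Open-boundary systems are
enclosed in a padded non-periodic bounding box. Both searches emit a
fixed-capacity list padded with −1 and an overflow error carrying the
required size — never a silent truncation. The default list is full
(both directions per pair), matching message passing; prior sums use the
half list (source < target) to count each pair once.

Edge vectors are rebuilt differentiably from positions as
r_tgt − r_src + shift, where the integer-combination lattice shift recorded
at search time is locally constant; the adjoint accumulates
±(g_vec + g_dist·v̂) onto the two atoms, is available both as an explicit
function and through the engine, and supports higher-order derivatives.

## Distance featurization

Every edge enters the models through the cosine cutoff envelope
φ(d) = ½(cos(πd/r_c)+1) for d ≤ r_c (zero beyond, continuous and once
differentiable at r_c) and an exponential-normal radial basis
exp(−β_k(e^{−d} − μ_k)²)·φ(d) with μ_k spaced evenly on [e^{−r_c}, 1].
The basis family is a package choice — it resolves short distances more
finely, which suits interatomic potentials — and can be made trainable
(`trainable_rbf`, off by default). Padded slots are masked to exact zero
feature rows.

## Representation models

All three models append a ghost atom internally; padded edges attach to it
with exactly-zero contributions, and edges are accumulated with a fixed
summation order (lists sorted by source, then target; sequential
`np.add.at`). Consequence, verified bit-exactly in tests: growing the list
capacity or adding the ghost atom never changes any real atom's features by
even one ulp, which is the static-shape contract.

**Tensor model.** Atoms carry channels of 3×3 matrices decomposed as
X = I + A + S. Edge geometry enters through the identity, the
skew-symmetric matrix of the unit edge vector, and its symmetric traceless
outer product, weighted by radial features and element embeddings.
Interaction layers exchange decomposed neighbor tensors and combine them
with symmetrized matrix products (XM + MX, plus a Y² term), normalize by
Frobenius norm, and mix channels linearly per component. Under a proper
rotation R features transform as X → RXRᵀ and under an improper operation
as X → RXᵀRᵀ; every operation used commutes with both, so the final scalar
invariants (component Frobenius norms) are exact under the full orthogonal
group. Zero layers means the embedding stage alone — a valid, much cheaper
model.

**Equivariant transformer.** Scalar features x and Cartesian vector
features v per atom. Attention weights are silu(Σ q_i·k_j·dk(d))·φ(d);
the value pathway is split into a scalar part and two vector gates driving
v updates along neighbor vectors and unit edge vectors; an update block
couples v back into x through the invariant inner product ⟨Uv, Wv⟩. The
distance filters for the value pathway intentionally use the raw
(non-enveloped) basis: with `vector_cutoff` off, vector updates are not
weighted by φ(d) and the potential has a finite jump when an edge crosses
r_c (legacy behaviour, kept for backward compatibility); with it on, the
value-pathway contribution is multiplied by φ(d) and the jump decays
linearly to zero. Both behaviours are asserted in tests.

**Graph network.** Continuous-filter convolutions on radial features with
residual updates of the element embeddings; invariant because only
distances are used.

Weights are drawn uniform fan-in from a generator seeded per model, so two
models built with the same config and seed predict bit-identically. Layer
equations are faithful in structure to the Cartesian-tensor and
attention-based lineages these models come from, with initialization and
normalization details chosen here.

## Output head and priors

A two-layer perceptron (C → C/2 → 1, silu) maps features to per-atom
scalars, reduced per batch segment by sum (default, extensive energies) or
mean. Priors compose around the reduction: atom-level hooks (atomref)
modify per-atom energies before it, sample-level hooks (pairwise priors)
add to per-sample energies after it, and everything is added before any
gradient is taken, so forces include all prior terms. Any object with the
two `BasePrior` hooks composes identically to the built-ins.

- **Atomref**: adds table[Zᵢ] per atom; optionally a learnable parameter
  initialized from the provided references.
- **Coulomb**: Σ sw(r)·k·qᵢqⱼ/r over the half list with
  sw(r) = ½(1 − cos(πr/r_sw)) below the switching distance and 1 beyond:
  smooth, kills the r → 0 singularity, exact Coulomb at r ≥ r_sw. The
  switch acts on the inner range only; at the outer neighbor cutoff the
  term is truncated (below).
- **ZBL**: Σ φ(r)·(k ZᵢZⱼ/r)·f(r/a) with the four-exponential universal
  screening function (coefficients 0.18175/0.50986/0.28022/0.02817,
  exponents 3.19980/0.94229/0.40290/0.20162, screening length
  a = 0.46850 Å/(Zᵢ^0.23 + Zⱼ^0.23)); f(0) equals the coefficient sum,
  0.99993 ≈ 1 at the published precision. The cosine envelope takes every
  contribution continuously to zero at the neighbor cutoff.
- **D2**: −s₆ Σ fdmp(r)·C6ᵢⱼ/r⁶ with C6ᵢⱼ = √(C6ᵢC6ⱼ),
  fdmp(r) = 1/(1+e^{−d(r/Rᵢⱼ−1)}) (d = 20, Rᵢⱼ the summed van der Waals
  radii, equal to ½ at r = Rᵢⱼ). Element tables (H–Ar; C6 in J nm⁶ mol⁻¹,
  radii in Å) ship as a versioned CSV under `mlpot/tables/` and are data,
  not code.

Units: the learned part is unit-agnostic; priors take explicit constants in
the dataset's energy unit. Bundled defaults target eV/Å/e (Coulomb constant
14.399645 eV·Å/e²; C6 conversion 10.364 eV·Å⁶ per J nm⁶ mol⁻¹).

Truncation: D2 and Coulomb are cut at the neighbor-list cutoff without
long-range corrections, leaving a discontinuity of order C6/r_c⁶ and
k·qq/r_c respectively at r_c; the ZBL term is enveloped and continuous.
This is a deliberate consequence of a strictly local neighbor engine; for
the cutoffs and charges used here the Coulomb step is the larger one
(~k·q²/r_c), and applications needing smooth electrostatics at r_c should
either extend the cutoff or taper charges externally.

## Training

Datasets are records (Z, R, y, optional forces, optional charges) with
heterogeneous atom counts, batched by concatenation with a batch index
vector (no sample padding). Loaders cover an aligned-numpy-file layout
(coords (n_conf, n_atoms, 3); one embedding vector per molecule; energies
(n_conf, 1); optional forces) matched by sorted globs, and an HDF5
group-per-molecule layout with an optional lazy mode that materializes
records on access. Splits are seed-deterministic shuffled index sets,
persisted to an index file.

The loss is λ_E·MSE(y) + λ_F·MSE(neg_dy), each term averaged over all its
elements (per-element averaging is the package's convention; per-sample
weighting is a documented alternative the framework does not prescribe).
Validation logs L1 and MSE for energies and forces; test reporting uses the
L1 pair. Logged losses are smoothed with an exponential moving average
new = α·x + (1−α)·old (default α = 0.05, first value initializes); the EMA
never touches weights. The optimizer is Adam with plateau-based learning-
rate decay on the smoothed validation loss — a runnable loop needs *an*
optimizer and this one is a package choice, fully configurable. Epoch
shuffles are drawn from rng([seed, epoch]), which makes runs bit-
reproducible and checkpoint resumption exact; checkpoints (NPZ: config,
weights, optimizer state, metric history) reload to bit-identical
predictions, and `load_model` can override the derivative flag.

A non-finite loss aborts with the epoch and batch in the message.

## Synthetic data

The generators define the conditions the tests run under. `make_cloud`
draws uniform positions in a box sized from the ideal-gas relation
density = target/( (4/3)πr_c³ ), so the realized mean neighbor count lands
within 20% of target (checked); elements come from {H, C, N, O, S}.
`make_dimer_dataset` samples two-atom conformers of a Morse potential
(depth 1, width 1.5 Å⁻¹, r₀ 1.5 Å) over r ∈ [1, 4] Å with exact analytic
forces. `make_atomref_dataset` draws random compositions with
y = Σ μ(Zᵢ) + ε (ε ~ N(0, 0.01²), 500 samples by default) and zero forces.
All generators are pure functions of (spec, seed).

What these fixtures emulate — controlled density, exact labels, smooth
potentials — is what the contracts need; what they do not emulate is real
quantum-chemistry data (conformational correlation, label noise structure,
element diversity, many-body interactions). Passing tests therefore
establish the *mechanics* (symmetries, conservation, convergence, padding,
round-trips), not chemical accuracy on external benchmark sets, which
requires large datasets and GPU-scale training outside this package's
scope.

## Problem sizes and defaults

Config defaults follow common production settings (cutoff 4.5 Å, embedding
dimension 128, 32 radial bases, 32 max neighbors per atom). Tests and the
validation script run deliberately small instances — embedding 8–32,
systems of 2–500 atoms, 60–200 training epochs on 200–500 samples — chosen
so the whole suite verifies every contract in about a minute on one CPU
core while exercising the same code paths as production-sized models.

## Known limitations

- No long-range electrostatics (Ewald/PME) and no D3/D4 dispersion.
- No neighbor-list reuse (skin buffers) across MD steps; no lower-cutoff
  annulus filtering.
- The cell list degrades with many batches (one joint decomposition means
  cross-batch candidates are checked and discarded).
- Training has no static-shape mode; batching pads nothing and relies on
  the batch vector.
- Inference throughput is numpy-bound; the package targets correctness and
  inspectability, not kernel-level performance.
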