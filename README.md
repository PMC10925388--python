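# mlpot

Modular neural-network potentials (NNPs) at desk scale, for researchers in
molecular modelling and structural bioinformatics who want a transparent,
fully inspectable implementation of the standard NNP training/inference
stack: composable equivariant representation models, physics-based priors,
a batched periodic-boundary neighbor engine with a static-shape padding
contract, and an energy/force training loop — all in numpy, on a small
reverse-mode autodiff core written for this package that supports the
double backpropagation force matching requires.

## The model

An NNP maps atomic numbers *Z*, Cartesian coordinates ***R*** (Å) and
optionally partial charges *q* to a per-sample scalar

> *y* = Σᵢ εᵢ(*Z*, *R*) + Σₚ E⁽ᵖ⁾(*Z*, *R*, *q*)

where εᵢ are learned per-atom energies (a representation model followed by a
small output head) and E⁽ᵖ⁾ are analytic prior terms. Forces are the exact
negative gradient, **F** = −∂*y*/∂***R*** (`neg_dy`), computed by automatic
differentiation through the *entire* composition — priors included — so the
force field is energy-conserving by construction.

Three representation models are provided, all message-passing networks over
a cutoff-radius neighbor graph:

- **tensornet** — per-atom channels of Cartesian rank-2 tensors
  X = I + A + S (isotropic / antisymmetric / symmetric-traceless), mixed by
  node-level 3×3 matrix products instead of Clebsch–Gordan couplings; scalar
  outputs are O(3)-invariant by construction (reflections included).
- **equivariant_transformer** — scalar + Cartesian-vector features with
  distance-gated dot-product attention. The `vector_cutoff` flag applies the
  cosine cutoff envelope φ(d) to the attention value pathway feeding vector
  updates, removing a discontinuity in the potential at the cutoff radius;
  with the flag off the legacy (discontinuous) behaviour is reproduced.
- **graph_network** — invariant continuous-filter convolutions using only
  interatomic distances.

Four priors: per-element reference energies (**atomref**, optionally
learnable), cosine-**switched Coulomb** electrostatics, **ZBL** screened
nuclear repulsion, and **D2** dispersion (−s₆ C₆ᵢⱼ fdmp(r)/r⁶) with bundled
element tables.

The neighbor engine supports open, rectangular and triclinic periodic
boundaries (minimum-image convention), arbitrary batches in one call, an
all-pairs strategy for small systems and a cell list for large ones, and a
fixed-capacity output padded with the sentinel −1 so downstream shapes are
static; padded slots attach to a ghost atom and contribute exactly zero.

## Worked example

```python
import numpy as np
from mlpot import (AssembledModel, ParticleSystem, RepresentationConfig,
                   RadialConfig, OutputConfig, AtomrefPrior, CoulombPrior,
                   ZBLPrior, D2Prior)

rng = np.random.default_rng(0)
system = ParticleSystem(
    positions=rng.uniform(0, 5, (12, 3)),            # Å
    atomic_numbers=rng.choice([1, 6, 7, 8, 16], 12),
    charges=rng.normal(0, 0.2, 12),
)
model = AssembledModel(
    RepresentationConfig(model="tensornet", embedding_dimension=32,
                         num_layers=2, radial=RadialConfig(cutoff=4.5,
                         num_rbf=16), max_z=20),
    OutputConfig(hidden_channels=16),
    priors=[AtomrefPrior(np.linspace(-1, 1, 21)),
            CoulombPrior(switching_distance=1.0),
            ZBLPrior(cutoff=4.5), D2Prior()],
    derivative=True, seed=0,
)
pred = model.predict(system)
print(pred.y, np.abs(pred.neg_dy.sum(axis=0)).max())
```

Running this (it is `examples/02_predict_energy_forces.py`) prints

```
trainable parameters: 30817
energy y = 68.677229 (energy units of the training data)
max |force| = 102.7462 energy/Å
net force per sample (translation invariance => ~0): 7.99e-15
padded (capacity x4) prediction bit-identical: True
```

The energy of an untrained model is arbitrary; the physics is in the
structure: the net force vanishes to machine precision (translation
invariance), and predictions are bit-identical for any neighbor-list
capacity (the static-shape contract). `examples/03_train_dimer.py` trains
the same architecture on a Morse-dimer dataset with a combined energy+force
loss and prints a ~5×10⁴-fold validation-loss reduction and a 1.0000
correlation between the learned and true pair potential. The other examples
cover neighbor search under triclinic boundaries and the standalone prior
terms.

## Command line

```bash
mlpot-train --conf run.yaml     # config-driven training (see mlpot/config.py)
mlpot-predict checkpoint.npz structures.xyz -o predictions
```

Every run emits its fully-resolved YAML config, a per-epoch metrics CSV,
and checkpoints that reload bit-identically with
`mlpot.training.load_model`.

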