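"""Train a small tensor-feature model on a toy dimer dataset with forces.

The dataset holds two-atom conformers of a Morse pair potential with exact
analytic forces; the loss combines energy and force mean-squared errors, so
each step differentiates through the force computation (double backward).
"""

import numpy as np

from mlpot.data import SplitSpec, make_splits
from mlpot.featurization import RadialConfig
from mlpot.fixtures import make_dimer_dataset, morse_potential
from mlpot.geometry import ParticleSystem
from mlpot.model import AssembledModel
from mlpot.outputs import OutputConfig
from mlpot.representations import RepresentationConfig
from mlpot.training import LossWeights, TrainingConfig, train_loop

dataset = make_dimer_dataset(n_samples=200, seed=0)
splits = make_splits(len(dataset), SplitSpec(160, 20, 20, seed=0))

model = AssembledModel(
    RepresentationConfig(
        model="tensornet", embedding_dimension=16, num_layers=2,
        radial=RadialConfig(cutoff=4.5, num_rbf=8), max_z=20,
    ),
    OutputConfig(hidden_channels=16),
    derivative=True,
    seed=0,
)

config = TrainingConfig(
    epochs=100, batch_size=40, learning_rate=5e-3,
    weights=LossWeights(energy=1.0, force=0.5), seed=0,
)
result = train_loop(model, dataset, splits, config)
hist = result["history"]
print(f"validation loss: {hist[0]['val_loss']:.4f} -> {hist[-1]['val_loss']:.6f} "
      f"({hist[0]['val_loss'] / hist[-1]['val_loss']:.0f}x reduction)")

# compare the learned curve against the true pair potential on held-out r
v, _ = morse_potential()
rs = np.linspace(1.1, 3.5, 9)
z = np.array([6, 8])
pred = np.array([
    model.predict(ParticleSystem([[0, 0, 0], [r, 0, 0]], z)).y[0] for r in rs
])
true = v(rs)
corr = np.corrcoef(pred, true)[0, 1]
print(f"correlation of predicted vs true V(r) on a held-out grid: {corr:.4f}")
for r, p, t in zip(rs[::4], pred[::4], true[::4]):
    print(f"  r = {r:.2f} Å   V_pred = {p:+.3f}   V_true = {t:+.3f}")
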