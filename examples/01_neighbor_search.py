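"""Batched neighbor search under periodic boundaries, two strategies.

Builds a random particle cloud with a controlled neighbor density in a
triclinic box, runs the all-pairs and the cell-list searches, and shows that
they return the identical padded pair list.
"""

import numpy as np

from mlpot.fixtures import CloudSpec, make_cloud
from mlpot.geometry import brute_force_neighbors, cell_list_neighbors, select_strategy

spec = CloudSpec(n_atoms=2000, target_neighbors=16, cutoff=3.0,
                 box_kind="triclinic", seed=0)
system = make_cloud(spec)

brute = brute_force_neighbors(system, cutoff=3.0)
cell = cell_list_neighbors(system, cutoff=3.0)

print(f"atoms: {system.n_atoms}, box kind: {system.box.kind}")
print(f"pairs found (full list): {brute.n_found}")
print(f"mean neighbors per atom: {brute.n_found / system.n_atoms:.1f} "
      f"(target {spec.target_neighbors})")
print(f"cell list returns identical pair list: "
      f"{np.array_equal(brute.pairs, cell.pairs)}")
print(f"auto strategy for 2000 atoms: {select_strategy(2000)}; "
      f"for 50000 atoms: {select_strategy(50_000)}")
# the pair list is padded with -1 beyond n_found so array shapes can be fixed
padded = brute_force_neighbors(system, cutoff=3.0, capacity=brute.n_found + 8)
print(f"padded tail entries: {padded.pairs[0, -8:].tolist()}")
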