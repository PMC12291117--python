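"""Per-monomer Rg tracking and conformational classification.

Generates a free-monomer Rg ensemble (four Gaussian conformational
states), clusters it with 1D k-means, then classifies monomers of a
drifting synthetic assembly against the fixed class boundaries and
prints how the class mix shifts as monomers extend.
"""

import numpy as np

from oligogrowth.conformers import class_fractions, cluster_free_monomer, per_monomer_rg
from oligogrowth.synth import synth_assembly_trajectory

rng = np.random.default_rng(0)
means, weights = [9.0, 11.0, 13.0, 16.0], [0.46, 0.34, 0.12, 0.08]
counts = rng.multinomial(1000, weights)
free_rg = np.concatenate([rng.normal(m, 0.3, k) for m, k in zip(means, counts)])

model = cluster_free_monomer(free_rg, k=4, seed=0)
print("free-monomer clusters (Rg, A):")
for name, c, a in zip(model.class_names, model.centroids, model.abundances):
    print(f"  {name:>9s}: centroid {c:5.2f}  abundance {a:.1%}")
print("  boundaries:", np.round(model.boundaries, 2))

frames, _ = synth_assembly_trajectory(
    14, 6, rg_drift={"kind": "monotone_rise", "rg_start": 9.5, "rg_end": 15.0}, seed=3
)
records = per_monomer_rg(frames)
fractions = class_fractions(records, model)
print("\nclass fractions per frame of the drifting assembly:")
print(fractions.round(3).to_string(index=False))
print("\nAs the generator extends monomers over time, occupancy migrates from")
print("compact toward extended and beyond - the fingerprint of assembly-driven")
print("monomer extension.")
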