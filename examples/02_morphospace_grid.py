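"""Build a PCA morphospace and its theoretical shape grid.

Samples 40 synthetic taxa, ordinates their 45-parameter harmonic vectors,
and reconstructs an evenly spaced grid of theoretical jaws over PC1-PC2
(with the 20%-of-PC1-range border), screening out self-intersecting
reconstructions — the geometrically impossible corner of morphospace.
"""

import numpy as np

from jawscape import (
    build_theoretical_grid,
    efa_decompose,
    fit_pca,
    generate_taxon_set,
    normalize_efa,
)

taxa = generate_taxon_set(40, seed=11)
matrix = np.array(
    [normalize_efa(efa_decompose(outline, 12)).flatten() for _, outline in taxa]
)
space = fit_pca(matrix, specimen_ids=[rec.taxon_id for rec, _ in taxa])
print("variance explained by PC1..PC5:",
      np.round(space.variance_explained[:5], 3))
print("(PC1 tracks length/depth ratio, PC2 dorsal concavity, as in real jaws)")

grid = build_theoretical_grid(space, n1=23, n2=21)
print(f"theoretical grid: {grid.n_nodes} nodes "
      f"({grid.pc1_values.size} x {grid.pc2_values.size})")
print(f"valid shapes: {int(grid.valid_mask.sum())}, "
      f"self-intersecting (impossible): {int((~grid.valid_mask).sum())}")
print(f"PC1 span {grid.pc1_values[0]:.3f}..{grid.pc1_values[-1]:.3f}, "
      f"PC2 span {grid.pc2_values[0]:.3f}..{grid.pc2_values[-1]:.3f}")
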