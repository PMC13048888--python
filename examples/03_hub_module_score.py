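"""Module score of the 18-gene hub panel with expression-matched controls.

The panel combines the two population markers (SPP1, POSTN), eleven
ligand-receptor genes, and five shared stress-response genes.  The score of
a cell is the mean expression of the panel minus the mean expression of
control genes sampled from the same expression bins, so it is centred near
zero for an unremarkable cell.
"""

import pandas as pd

import nichecoloc as nc

adata = nc.generate_cell_matrix(nc.ScSimParams(n_cells=400, seed=3))
nc.normalize(adata)
result = nc.module_score(adata, nc.HUB_PANEL, n_bins=24, n_ctrl=50, seed=0)

by_condition = (
    pd.Series(result.score)
    .groupby(adata.obs["condition"].to_numpy())
    .describe()[["mean", "std"]]
    .round(3)
)
print("hub-panel module score by condition:")
print(by_condition.to_string())
print(
    "\nDisease cells score higher because the generator makes the panel "
    "genes condition-responsive; control cells sit near zero, the expected "
    "value under the bin-matched control subtraction."
)
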