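"""Spot-level colocalization of two cell-type programs across a k sweep.

Generates a two-condition spatial dataset in which the SPP1-myeloid and
POSTN-fibroblast program scores share a latent spatial correlation of 0.8 in
disease samples and none in controls, then runs the full kNN colocalization
pipeline for k = 3..15.
"""

import nichecoloc as nc

params = nc.SpatialSimParams(seed=1)  # 2 samples/condition x 1,000 spots
spots = nc.generate_spot_table(params)
result = nc.k_sensitivity(
    spots, "score_SPP1_myeloid", "score_POSTN_fibroblast", keep_per_spot=False
)

cols = ["k", "odds_ratio", "ci_low", "ci_high", "p_value",
        "prop_pos_disease", "prop_pos_control"]
print(result.summary[cols].round(3).to_string(index=False))
print(
    "\nEach row is one neighborhood size k: the odds ratio compares the odds "
    "of a coloc-positive spot (coloc > 0) in disease vs control tissue, with "
    "a Woolf 95% CI and a one-sided Fisher p-value. An OR above 1 at every k "
    "means the two programs co-occur in space more often in disease, "
    "robustly across spatial scales."
)
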