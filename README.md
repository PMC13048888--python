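# nichecoloc

Spot-level spatial colocalization of two cell-type programs, with the
single-cell and multiplex-immunofluorescence statistics that surround it in
a tissue validation study — plus synthetic-data generators that let the
whole pipeline run and be validated without any external dataset.

## The problem

In fibrotic aortic disease (thoracic aortic aneurysm and related
conditions), SPP1⁺ myeloid cells and POSTN⁺ fibroblasts are thought to form
a pathogenic niche. Spot-based spatial transcriptomics can test this: after
label transfer, every spot carries prediction scores *A* (SPP1-myeloid
program) and *B* (POSTN-fibroblast program) in [0, 1]. The question is
whether high-*A* and high-*B* spots cluster *together* in space more often
in disease than in control tissue.

## The statistic

Within each sample, scores are standardized (z_A, z_B) and each spot's k
nearest neighbors (Euclidean distance, self excluded) define neighborhood
means z̄_A,k and z̄_B,k. The per-spot colocalization score is the symmetric
centered cross product

    coloc_i = z_A(i) · z̄_B,k(i) + z_B(i) · z̄_A,k(i),

positive when spot and neighborhood are concordantly enriched in both
programs. Spots with coloc > 0 are *positive*; pooling spots per condition
gives a 2×2 condition × positivity table per k, tested by a one-sided
Fisher's exact test with an odds ratio and Woolf 95% CI, across
k ∈ {3, 4, 5, 6, 8, 10, 12, 15} (a spatial-scale robustness sweep).

Around that core the package implements: single-cell QC (UMI 1,000-50,000,
300-5,000 genes, mitochondrial fraction ≤ 10%, doublet removal),
one-vs-rest Wilcoxon differential expression with BH correction, Jaccard
overlap of gene sets, the bin-matched-control module score of an 18-gene
SPP1/POSTN hub panel, one-sided per-gene rank-sum tests of the panel on
spots, and mIF ROI quantification (double-positive proportions with pooled
Fisher tests, DAPI-normalized MFI with ROI-level Mann-Whitney tests).
Synthetic generators (`generate_spot_table`, `generate_cell_matrix`,
`generate_roi_table`) produce spot tables with exactly controlled latent
correlations, count matrices with a known low-quality fraction, and ROI
cell tables with group-dependent double-positive rates.

## Worked example

```python
import nichecoloc as nc

spots = nc.generate_spot_table(nc.SpatialSimParams(seed=1))
result = nc.k_sensitivity(spots, "score_SPP1_myeloid", "score_POSTN_fibroblast")
print(result.summary.round(3))
```

Output (also `python examples/01_spatial_colocalization.py`):

```
 k  odds_ratio  ci_low  ci_high  p_value  prop_pos_disease  prop_pos_control
 3       1.527   1.347    1.731      0.0             0.600             0.496
 4       1.497   1.321    1.697      0.0             0.602             0.502
 5       1.448   1.278    1.641      0.0             0.591             0.500
 6       1.328   1.172    1.504      0.0             0.586             0.516
 8       1.443   1.273    1.635      0.0             0.593             0.502
10       1.429   1.261    1.619      0.0             0.582             0.494
12       1.452   1.282    1.645      0.0             0.581             0.488
15       1.437   1.268    1.628      0.0             0.576             0.486
```

The generator planted a latent correlation of 0.8 between the two programs
in disease samples and 0.0 in controls. Roughly 60% of disease spots but
only ~50% of control spots come out colocalization-positive, so the odds
ratio sits above 1 at every neighborhood size — the qualitative signature
of a real spatial co-enrichment, robust across scales. Each `examples/`
script demonstrates one capability the same way (QC + DEG + Jaccard, module
scores, ROI quantification, the full config-driven pipeline).

A thin CLI mirrors the library:

```sh
nichecoloc simulate --kind spots --seed 1 --out spots.tsv
nichecoloc coloc --spots spots.tsv --out coloc_summary.csv
nichecoloc run --config examples/demo_config.yaml
```

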