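"""Cell-level statistics: QC filtering, DEG selection, Jaccard overlap, and
expression-bin-matched module scores.

The container for a single-cell count matrix is an :class:`anndata.AnnData`
(cells x genes) whose ``obs`` carries the QC metadata columns
``total_counts`` (UMIs), ``n_genes`` (detected genes), ``mito_frac``,
``doublet``, ``cluster`` and ``condition``; raw counts live in ``X`` and the
log-normalized expression in ``layers["lognorm"]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .stats import bh_adjust, rank_sum_test

__all__ = [
    "QcThresholds",
    "DegThresholds",
    "GeneSet",
    "ModuleScoreResult",
    "DegResult",
    "HUB_PANEL",
    "qc_filter",
    "normalize",
    "select_degs",
    "jaccard",
    "module_score",
]

QC_META_COLUMNS = ("total_counts", "n_genes", "mito_frac", "doublet")


@dataclass(frozen=True)
class QcThresholds:
    """Cell retention bounds.

    Removal uses strict inequalities (a cell is dropped when UMI < umi_min or
    UMI > umi_max, etc.), so cells sitting exactly on a bound are retained.
    """

    umi_min: int = 1_000
    umi_max: int = 50_000
    genes_min: int = 300
    genes_max: int = 5_000
    mito_max: float = 0.10
    drop_doublets: bool = True

    def __post_init__(self):
        if self.umi_min >= self.umi_max or self.genes_min >= self.genes_max:
            raise ValueError("paired bounds must satisfy min < max")


@dataclass(frozen=True)
class DegThresholds:
    min_frac_expressing: float = 0.10
    min_abs_log2fc: float = 0.25
    max_adj_p: float = 0.05
    direction: str = "up"  # "up" | "down" | "both"

    def __post_init__(self):
        if not 0 <= self.min_frac_expressing <= 1:
            raise ValueError("min_frac_expressing must be in [0, 1]")
        if self.direction not in ("up", "down", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")


class GeneSet:
    """A named, nonempty, duplicate-free collection of gene ids."""

    def __init__(self, name: str, genes):
        genes = list(genes)
        if not genes:
            raise ValueError("gene set must be nonempty")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        self.name = name
        self.genes = frozenset(genes)
        self._order = tuple(genes)  # original order, for deterministic iteration

    def ordered(self) -> tuple[str, ...]:
        return self._order

    def __len__(self):
        return len(self.genes)

    def __contains__(self, g):
        return g in self.genes

    def __repr__(self):
        return f"GeneSet({self.name!r}, n={len(self.genes)})"


#: the 18-gene myeloid/fibroblast hub panel: the two population markers,
#: eleven ligand-receptor genes, and five shared stress-pathway genes.
HUB_PANEL = GeneSet(
    "hub18",
    [
        "SPP1", "POSTN",
        "ITGAV", "ITGB1", "ITGA8", "ITGA5", "MDK", "SDC4", "SDC2", "NCL",
        "LRP1", "ITGA6", "ITGA4",
        "GADD45B", "GADD45A", "PMEPA1", "PTX3", "IL6",
    ],
)


def _require_meta(adata: AnnData, columns) -> None:
    missing = [c for c in columns if c not in adata.obs.columns]
    if missing:
        raise ValueError(f"cell metadata missing columns: {missing}")


def qc_pass_mask(adata: AnnData, thresholds: QcThresholds | None = None) -> pd.Series:
    """Boolean per-cell retention mask under the QC thresholds."""
    t = thresholds or QcThresholds()
    _require_meta(adata, QC_META_COLUMNS)
    obs = adata.obs
    keep = (
        (obs["total_counts"] >= t.umi_min)
        & (obs["total_counts"] <= t.umi_max)
        & (obs["n_genes"] >= t.genes_min)
        & (obs["n_genes"] <= t.genes_max)
        & (obs["mito_frac"] <= t.mito_max)
    )
    if t.drop_doublets:
        keep &= ~obs["doublet"].astype(bool)
    return keep


def qc_filter(
    adata: AnnData, thresholds: QcThresholds | None = None
) -> tuple[AnnData, dict[str, int]]:
    """Remove low-quality cells; returns the filtered matrix and per-rule counts.

    A cell is removed when its UMI count or detected-gene count falls strictly
    outside the allowed range, its mitochondrial fraction strictly exceeds the
    maximum, or it is flagged as a doublet.  Boundary values are retained.
    Cell order is preserved.  An empty input returns an empty output with a
    warning rather than raising.
    """
    t = thresholds or QcThresholds()
    if adata.n_obs == 0:
        warnings.warn("qc_filter received an empty matrix", stacklevel=2)
        return adata.copy(), {}
    _require_meta(adata, QC_META_COLUMNS)
    obs = adata.obs
    removed = {
        "umi_low": int((obs["total_counts"] < t.umi_min).sum()),
        "umi_high": int((obs["total_counts"] > t.umi_max).sum()),
        "genes_low": int((obs["n_genes"] < t.genes_min).sum()),
        "genes_high": int((obs["n_genes"] > t.genes_max).sum()),
        "mito_high": int((obs["mito_frac"] > t.mito_max).sum()),
        "doublet": int(obs["doublet"].astype(bool).sum()) if t.drop_doublets else 0,
    }
    keep = qc_pass_mask(adata, t)
    removed["total_removed"] = int((~keep).sum())
    return adata[keep.to_numpy()].copy(), removed


def normalize(adata: AnnData, target_sum: float = 1e4) -> AnnData:
    """Counts-per-10k + log1p into ``layers["lognorm"]`` (in place, returned).

    Uses the scanpy implementation on a copy of the raw counts.
    """
    import scanpy as sc

    tmp = AnnData(adata.X.copy(), obs=adata.obs[[]].copy(), var=adata.var[[]].copy())
    sc.pp.normalize_total(tmp, target_sum=target_sum)
    sc.pp.log1p(tmp)
    adata.layers["lognorm"] = tmp.X
    return adata


def _dense_lognorm(adata: AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize() first: layers['lognorm'] missing")
    x = adata.layers["lognorm"]
    return x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)


@dataclass
class DegResult:
    """Full per-gene statistics plus the thresholded gene sets per group."""

    table: pd.DataFrame
    gene_sets: dict[str, GeneSet] = field(default_factory=dict)


def _log2fc(lognorm_in: np.ndarray, lognorm_out: np.ndarray) -> np.ndarray:
    """log2(mean(expm1(in)) + 1) - log2(mean(expm1(out)) + 1), per gene."""
    mean_in = np.expm1(lognorm_in).mean(axis=0)
    mean_out = np.expm1(lognorm_out).mean(axis=0)
    return np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)


def select_degs(
    adata: AnnData,
    group_by: str,
    thresholds: DegThresholds | None = None,
) -> DegResult:
    """One-vs-rest differential expression per group with BH correction.

    For each level of ``obs[group_by]`` (with >= 3 cells; smaller groups are
    excluded with a warning), genes expressed in at least
    ``min_frac_expressing`` of the in-group cells are tested with a two-sided
    Wilcoxon rank-sum test of in-group vs all other cells on the
    log-normalized expression.  p-values are BH-adjusted across the tested
    genes within each group contrast.  A gene is selected when
    |log2FC| > min_abs_log2fc and adjusted p < max_adj_p, with the sign
    constrained by ``direction`` ("up" keeps log2FC > 0).
    """
    t = thresholds or DegThresholds()
    if group_by not in adata.obs.columns:
        raise ValueError(f"unknown grouping column {group_by!r}")
    lognorm = _dense_lognorm(adata)
    counts = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    labels = adata.obs[group_by].astype(str).to_numpy()
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    genes = adata.var_names.to_numpy()

    frames = []
    gene_sets: dict[str, GeneSet] = {}
    for level in levels:
        in_mask = labels == level
        n_in = int(in_mask.sum())
        if n_in < 3:
            warnings.warn(f"group {level!r} has {n_in} cells (<3); excluded", stacklevel=2)
            continue
        out_mask = ~in_mask
        frac_in = (counts[in_mask] > 0).mean(axis=0)
        frac_out = (counts[out_mask] > 0).mean(axis=0)
        tested = frac_in >= t.min_frac_expressing
        if not tested.any():
            continue
        lfc = _log2fc(lognorm[in_mask][:, tested], lognorm[out_mask][:, tested])
        x_in, x_out = lognorm[in_mask][:, tested], lognorm[out_mask][:, tested]
        if n_in <= 25 and int(out_mask.sum()) <= 25:
            p = np.array(
                [rank_sum_test(x_in[:, j], x_out[:, j]).p_value for j in range(x_in.shape[1])]
            )
        else:
            p = _vectorized_ranksum_p(x_in, x_out)
        p_adj = bh_adjust(p)
        df = pd.DataFrame(
            {
                "group": level,
                "gene": genes[tested],
                "log2fc": lfc,
                "frac_in": frac_in[tested],
                "frac_out": frac_out[tested],
                "p_value": p,
                "p_adj": p_adj,
            }
        )
        selected = (np.abs(df["log2fc"]) > t.min_abs_log2fc) & (df["p_adj"] < t.max_adj_p)
        if t.direction == "up":
            selected &= df["log2fc"] > 0
        elif t.direction == "down":
            selected &= df["log2fc"] < 0
        df["selected"] = selected
        frames.append(df)
        hits = df.loc[selected, "gene"].tolist()
        if hits:
            gene_sets[level] = GeneSet(str(level), hits)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return DegResult(table=table, gene_sets=gene_sets)


def _vectorized_ranksum_p(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided tie-corrected asymptotic rank-sum p, all genes at once."""
    from scipy import stats as sps

    res = sps.mannwhitneyu(
        x_in, x_out, alternative="two-sided", method="asymptotic", axis=0
    )
    return np.asarray(res.pvalue, dtype=float)


def jaccard(a: GeneSet, b: GeneSet) -> float:
    """Jaccard index |a n b| / |a u b| of two gene sets (both nonempty)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("jaccard undefined for empty gene sets")
    inter = len(a.genes & b.genes)
    union = len(a.genes | b.genes)
    return inter / union


@dataclass
class ModuleScoreResult:
    score: np.ndarray  # per cell
    control_genes: dict[str, tuple[str, ...]]  # scored gene -> its sampled controls
    params: dict


def module_score(
    adata: AnnData,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    layer: str = "lognorm",
    control_genes=None,
    exclude_set_genes: bool = False,
) -> ModuleScoreResult:
    """Per-cell module score with expression-matched control genes.

    Algorithm (the standard bin/sample/subtract recipe):

    1. compute each gene's mean expression across all cells on ``layer``;
    2. order genes by that mean (ties broken by a tiny seeded jitter) and cut
       the ordering into ``n_bins`` equal-frequency bins;
    3. for each gene of the set, in the set's given order, sample ``n_ctrl``
       genes from its bin without replacement (with replacement plus a
       warning when the bin is smaller than ``n_ctrl``); the control pool is
       the union of these draws;
    4. score(cell) = mean expression of the set genes - mean expression of
       the pooled control genes.

    Sampling uses ``numpy.random.default_rng(seed)``: one jitter draw of
    length n_genes, then one ``rng.choice`` per set gene.  ``control_genes``
    overrides the pool entirely (step 3 skipped), which is how the score's
    self-cancellation property (controls == set -> score 0) is exercised.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = _dense_lognorm(adata) if layer == "lognorm" else np.asarray(adata.layers[layer])
    genes = list(adata.var_names)
    index = {g: i for i, g in enumerate(genes)}
    missing = [g for g in gene_set.ordered() if g not in index]
    if missing:
        raise ValueError(f"gene set members absent from matrix: {missing}")

    set_idx = [index[g] for g in gene_set.ordered()]
    rng = np.random.default_rng(seed)
    ctrl_record: dict[str, tuple[str, ...]] = {}

    if control_genes is not None:
        pool = [index[g] for g in control_genes]
        ctrl_record["__override__"] = tuple(control_genes)
    else:
        avg = x.mean(axis=0)
        jitter = rng.normal(scale=1e-12, size=len(genes))
        order = np.argsort(avg + jitter, kind="stable")
        bin_of = np.empty(len(genes), dtype=int)
        for b, chunk in enumerate(np.array_split(order, n_bins)):
            bin_of[chunk] = b
        bins = [np.flatnonzero(bin_of == b) for b in range(n_bins)]
        pool_set: set[int] = set()
        for g in gene_set.ordered():
            gi = index[g]
            candidates = bins[bin_of[gi]]
            if exclude_set_genes:
                candidates = candidates[~np.isin(candidates, set_idx)]
            if len(candidates) == 0:
                raise ValueError(f"no control candidates available for gene {g!r}")
            if len(candidates) < n_ctrl:
                warnings.warn(
                    f"bin of gene {g!r} has {len(candidates)} genes < n_ctrl={n_ctrl}; "
                    "sampling with replacement",
                    stacklevel=2,
                )
                draw = rng.choice(candidates, size=n_ctrl, replace=True)
            else:
                draw = rng.choice(candidates, size=n_ctrl, replace=False)
            ctrl_record[g] = tuple(genes[i] for i in draw)
            pool_set.update(int(i) for i in draw)
        pool = sorted(pool_set)

    score = x[:, set_idx].mean(axis=1) - x[:, pool].mean(axis=1)
    return ModuleScoreResult(
        score=np.asarray(score, dtype=float),
        control_genes=ctrl_record,
        params={"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed, "layer": layer},
    )
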