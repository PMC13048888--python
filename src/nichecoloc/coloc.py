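"""Spot-level kNN colocalization of two cell-type programs.

Spot-based spatial transcriptomics assigns each capture spot a per-cell-type
prediction score (from reference-based label transfer).  Given two focal
program scores A and B, colocalization at a spot is measured by combining the
spot's own standardized scores with the mean standardized scores of its k
nearest spatial neighbors:

    coloc_i = z_A(i) * mean_k(z_B) + z_B(i) * mean_k(z_A)

where z_X is the within-sample standard score of X and mean_k averages over
the spot's k nearest other spots (self excluded).  This is a symmetric,
bivariate local-Moran-style cross statistic: it is positive when a spot and
its neighborhood are jointly enriched (or jointly depleted) in both programs,
and negative for discordant spots, so "coloc > 0" is an informative
positivity threshold.  Condition differences in the frequency of positive
spots are tested with a one-sided Fisher's exact test on the pooled
condition x positivity table, and the whole analysis is swept over a list of
k values to check robustness to spatial scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .stats import FisherResult, bh_adjust, fisher_or, rank_sum_test

__all__ = [
    "DEFAULT_K_LIST",
    "ColocConfig",
    "ColocResult",
    "knn_neighbors",
    "neighborhood_means",
    "coloc_score",
    "positivity_table",
    "k_sensitivity",
    "hub_gene_spot_test",
]

DEFAULT_K_LIST = (3, 4, 5, 6, 8, 10, 12, 15)

CONDITIONS = ("disease", "control")  # first row of every 2x2 table is disease


@dataclass(frozen=True)
class ColocConfig:
    """Configuration of the colocalization sweep.

    centering="global_mean_z" standardizes each score within each sample
    before forming the cross product; "none" uses raw scores (then coloc is
    nonnegative for scores in [0,1] and the >0 threshold is nearly vacuous —
    provided for comparison only).  ``require_joint_enrichment`` additionally
    demands that a positive spot has both own z-scores above the sample mean,
    masking positives that arise from joint depletion.
    """

    k_list: tuple[int, ...] = DEFAULT_K_LIST
    centering: str = "global_mean_z"
    symmetric: bool = True
    alternative: str = "greater"
    zero_cell_correction: float = 0.5
    require_joint_enrichment: bool = False
    cmle: bool = False  # also compute conditional-MLE CIs (slow at large n)

    def __post_init__(self):
        if len(self.k_list) == 0 or any(k < 1 for k in self.k_list):
            raise ValueError("k_list must contain integers >= 1")
        if self.centering not in ("global_mean_z", "none"):
            raise ValueError(f"unknown centering {self.centering!r}")
        if self.alternative not in ("greater", "less", "two_sided"):
            raise ValueError(f"unknown alternative {self.alternative!r}")


def knn_neighbors(coords, k: int) -> np.ndarray:
    """Indices of the k nearest other points for each point (self excluded).

    Euclidean distance; distance ties are broken by ascending point index so
    the result is deterministic.  Computed within one sample only — callers
    must never mix coordinates across samples.

    Returns an (n, k) integer array.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1={k + 1} points, got {n}")
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    # partition to the k-th smallest distance, then order the (possibly
    # tie-enlarged) candidate set by (distance, index) so ties resolve to the
    # ascending original index
    kth = np.partition(dist, k - 1, axis=1)[:, k - 1]
    out = np.empty((n, k), dtype=np.intp)
    for i in range(n):
        cand = np.flatnonzero(dist[i] <= kth[i])
        order = np.lexsort((cand, dist[i, cand]))
        out[i] = cand[order[:k]]
    return out


def neighborhood_means(values, neighbors: np.ndarray) -> np.ndarray:
    """Mean of ``values`` over each point's neighbor list (self excluded)."""
    values = np.asarray(values, dtype=float)
    return values[neighbors].mean(axis=1)


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean()
    sd = values.std()
    if sd == 0:
        warnings.warn(
            "score has zero variance within a sample; coloc set to 0 there",
            stacklevel=3,
        )
        return np.zeros_like(values)
    return (values - mu) / sd


def coloc_score(a, b, neighbors: np.ndarray, cfg: ColocConfig | None = None) -> np.ndarray:
    """Per-spot colocalization of scores ``a`` and ``b`` within one sample.

    With the default centering the statistic is
    ``z_a * mean_k(z_b) + z_b * mean_k(z_a)`` (symmetric); with
    ``symmetric=False`` only the first term is used.
    """
    cfg = cfg or ColocConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[0] != neighbors.shape[0]:
        raise ValueError("scores and neighbors must be aligned")
    if cfg.centering == "global_mean_z":
        za, zb = _standardize(a), _standardize(b)
    else:
        za, zb = a, b
    coloc = za * neighborhood_means(zb, neighbors)
    if cfg.symmetric:
        coloc = coloc + zb * neighborhood_means(za, neighbors)
    return coloc


def _positive_flags(coloc, za, zb, cfg: ColocConfig) -> np.ndarray:
    pos = coloc > 0  # strict: coloc exactly 0 is negative
    if cfg.require_joint_enrichment:
        pos = pos & (za > 0) & (zb > 0)
    return pos


def positivity_table(coloc, condition) -> np.ndarray:
    """Pooled 2x2 condition x positivity table.

    Rows: (disease, control); columns: (positive, negative).  Positivity is
    strict ``coloc > 0``.
    """
    coloc = np.asarray(coloc, dtype=float)
    condition = np.asarray(condition)
    table = np.zeros((2, 2), dtype=np.int64)
    for i, cond in enumerate(CONDITIONS):
        mask = condition == cond
        if not mask.any():
            raise ValueError(f"no spots with condition {cond!r}")
        pos = int(np.count_nonzero(coloc[mask] > 0))
        table[i] = (pos, int(mask.sum()) - pos)
    return table


@dataclass
class ColocResult:
    """Output of the k-sensitivity sweep.

    ``summary`` has one row per k (pooled 2x2 counts, OR, CI, p, positive
    proportions per condition); ``per_spot`` maps k to a per-spot data frame
    with neighborhood means, coloc value and positivity; ``per_sample`` holds
    diagnostic per-sample 2x2 tables.
    """

    summary: pd.DataFrame
    per_spot: dict[int, pd.DataFrame] = field(repr=False, default_factory=dict)
    per_sample: pd.DataFrame | None = field(repr=False, default=None)
    fisher: dict[int, FisherResult] = field(repr=False, default_factory=dict)


def k_sensitivity(
    spots: pd.DataFrame,
    score_a: str,
    score_b: str,
    cfg: ColocConfig | None = None,
    keep_per_spot: bool = True,
) -> ColocResult:
    """Full colocalization pipeline (kNN -> means -> coloc -> Fisher) per k.

    ``spots`` needs columns x, y, sample_id, condition plus the two score
    columns.  kNN and standardization are computed within each sample; the
    2x2 tables pool spots across samples within condition.
    """
    cfg = cfg or ColocConfig()
    required = {"x", "y", "sample_id", "condition", score_a, score_b}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    bad = set(spots["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")

    k_max = max(cfg.k_list)
    # deterministic sample order regardless of row order
    samples = sorted(spots["sample_id"].unique())
    per_sample_data = []
    for sid in samples:
        sub = spots[spots["sample_id"] == sid]
        if sub["condition"].nunique() != 1:
            raise ValueError(f"sample {sid!r} carries more than one condition label")
        coords = sub[["x", "y"]].to_numpy(dtype=float)
        if k_max >= len(sub):
            raise ValueError(
                f"sample {sid!r} has {len(sub)} spots; max k {k_max} too large"
            )
        nbrs = knn_neighbors(coords, k_max)
        a = sub[score_a].to_numpy(dtype=float)
        b = sub[score_b].to_numpy(dtype=float)
        if cfg.centering == "global_mean_z":
            za, zb = _standardize(a), _standardize(b)
        else:
            za, zb = a, b
        per_sample_data.append((sid, sub, nbrs, a, b, za, zb))

    rows = []
    per_spot: dict[int, pd.DataFrame] = {}
    per_sample_rows = []
    fishers: dict[int, FisherResult] = {}
    cond_index = {cond: i for i, cond in enumerate(CONDITIONS)}
    for k in cfg.k_list:
        frames = []
        table = np.zeros((2, 2), dtype=np.int64)
        for sid, sub, nbrs, a, b, za, zb in per_sample_data:
            nb_k = nbrs[:, :k]
            coloc = za * neighborhood_means(zb, nb_k)
            if cfg.symmetric:
                coloc = coloc + zb * neighborhood_means(za, nb_k)
            pos = _positive_flags(coloc, za, zb, cfg)
            cond = sub["condition"].iloc[0]
            if cond not in cond_index:
                raise ValueError(f"unknown condition {cond!r} in sample {sid!r}")
            n_pos = int(pos.sum())
            table[cond_index[cond], 0] += n_pos
            table[cond_index[cond], 1] += len(sub) - n_pos
            per_sample_rows.append(
                {
                    "k": k,
                    "sample_id": sid,
                    "condition": cond,
                    "n_pos": n_pos,
                    "n_total": len(sub),
                }
            )
            if keep_per_spot:
                frames.append(
                    pd.DataFrame(
                        {
                            "spot_id": sub["spot_id"].to_numpy()
                            if "spot_id" in sub.columns
                            else sub.index.to_numpy(),
                            "sample_id": sid,
                            "condition": sub["condition"].to_numpy(),
                            "mean_a_k": neighborhood_means(a, nb_k),
                            "mean_b_k": neighborhood_means(b, nb_k),
                            "coloc": coloc,
                            "positive": pos,
                        }
                    )
                )
        if keep_per_spot:
            per_spot[k] = pd.concat(frames, ignore_index=True)
        if (table.sum(axis=1) == 0).any():
            raise ValueError("each condition needs at least one spot")
        fr = fisher_or(
            table,
            alternative=cfg.alternative,
            zero_cell_correction=cfg.zero_cell_correction,
            cmle=cfg.cmle,
        )
        fishers[k] = fr
        rows.append(
            {
                "k": k,
                "n_pos_disease": table[0, 0],
                "n_total_disease": int(table[0].sum()),
                "n_pos_control": table[1, 0],
                "n_total_control": int(table[1].sum()),
                "prop_pos_disease": table[0, 0] / table[0].sum(),
                "prop_pos_control": table[1, 0] / table[1].sum(),
                "odds_ratio": fr.odds_ratio,
                "ci_low": fr.ci_low,
                "ci_high": fr.ci_high,
                "p_value": fr.p_value,
            }
        )
    summary = pd.DataFrame(rows)
    return ColocResult(
        summary=summary,
        per_spot=per_spot,
        per_sample=pd.DataFrame(per_sample_rows),
        fisher=fishers,
    )


def hub_gene_spot_test(
    spots: pd.DataFrame,
    genes,
    expr_prefix: str = "expr_",
    alternative: str = "greater",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene one-sided rank-sum test of disease vs control spot expression.

    Expression columns are ``<expr_prefix><gene>``; values are log1p
    transformed before testing (rank tests are invariant to the monotone
    transform, but the reported medians are on the transformed scale the
    analysis plots).  Missing genes are skipped with a warning.  BH-adjusted
    p-values are reported alongside the raw ones.
    """
    if hasattr(genes, "genes"):  # accept a GeneSet
        genes = sorted(genes.genes)
    dis = spots["condition"] == "disease"
    ctl = spots["condition"] == "control"
    if not dis.any() or not ctl.any():
        raise ValueError("both conditions must be present")
    rows = []
    missing = []
    for gene in genes:
        col = f"{expr_prefix}{gene}"
        if col not in spots.columns:
            missing.append(gene)
            continue
        vals = spots[col].to_numpy(dtype=float)
        if log_transform:
            vals = np.log1p(vals)
        res = rank_sum_test(vals[dis.to_numpy()], vals[ctl.to_numpy()], alternative=alternative)
        rows.append(
            {
                "gene": gene,
                "median_disease": float(np.median(vals[dis.to_numpy()])),
                "median_control": float(np.median(vals[ctl.to_numpy()])),
                "U": res.statistic,
                "p_value": res.p_value,
            }
        )
    if missing:
        warnings.warn(f"genes missing from spot table, skipped: {missing}", stacklevel=2)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    return out
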