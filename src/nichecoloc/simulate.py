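"""Synthetic spot tables, single-cell count matrices, and segmented-cell
mIF tables with the statistical structure the downstream stages assume.

The generators emulate a two-condition tissue study:

* spatial spots carry per-program prediction scores in [0, 1] whose latent
  spatial fields are correlated within disease samples but not (or less so)
  within controls, plus sparse negative-binomial expression of a hub-gene
  panel that tracks both programs;
* single cells are negative-binomial count profiles with cluster markers,
  condition-responsive genes, and a controlled fraction of cells constructed
  to violate standard QC rules;
* mIF cells live in square regions of interest with group-dependent
  double-positive rates and lognormal marker/DAPI intensities.

Every generator is a pure function of its parameter object, whose ``seed``
drives a single ``numpy.random.default_rng`` stream, so identical parameters
reproduce identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .scstats import HUB_PANEL, QcThresholds

__all__ = [
    "SpatialSimParams",
    "ScSimParams",
    "RoiSimParams",
    "generate_spot_table",
    "generate_cell_matrix",
    "generate_roi_table",
]

CONDITIONS = ("control", "disease")

FOCAL_PROGRAMS = ("SPP1_myeloid", "POSTN_fibroblast")


def _check_prob(name, value):
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SpatialSimParams:
    """Conditions of the simulated spatial study.

    Defaults mirror the validation setting the pipeline targets: two samples
    per condition of ~1,000 spots each on a regular grid in the unit square,
    two focal programs whose smooth latent fields are correlated at
    ``rho_disease`` in disease tissue and ``rho_control`` in control tissue
    (correlation imposed exactly, before noise and squashing), and an
    18-gene hub panel whose sparse counts increase with both program scores.

    ``field_length_scale`` is in the same units as the unit-square
    coordinates (grid spacing at 1,000 spots is ~0.032; the default puts the
    latent correlation length at about one spot spacing, i.e. niche-scale
    structure at the assay's resolution limit); ``score_noise_sd`` is the SD
    of additive latent noise relative to the unit-variance field (the
    default makes the field explain ~40% of pre-squash score variance,
    reflecting noisy label transfer);
    ``hub_effect`` is the log2-expression slope per unit of (A + B);
    ``nb_dispersion`` is the negative-binomial shape (smaller = more
    overdispersed).  ``hub_condition_log2fc`` optionally plants a per-gene
    disease log2 fold change on the hub expression (scalar or one value per
    hub gene).
    """

    n_samples_per_condition: int = 2
    n_spots_per_sample: int = 1_000
    layout: str = "grid"  # "grid" | "uniform_random"
    n_programs: int = 2
    rho_control: float = 0.0
    rho_disease: float = 0.8
    field_length_scale: float = 0.03
    score_noise_sd: float = 1.2
    hub_effect: float = 1.0
    nb_dispersion: float = 1.5
    seed: int = 0
    n_field_centers: int = 150
    base_expr: float = 1.0
    hub_genes: tuple[str, ...] = tuple(HUB_PANEL.ordered())
    hub_condition_log2fc: object = None
    normalize_scores: bool = False  # force per-spot scores to sum to 1

    def __post_init__(self):
        if self.n_programs < 2:
            raise ValueError("n_programs must be >= 2")
        if self.n_spots_per_sample < 2:
            raise ValueError("n_spots_per_sample must be >= 2")
        if self.n_samples_per_condition < 1:
            raise ValueError("n_samples_per_condition must be >= 1")
        for name in ("rho_control", "rho_disease"):
            rho = getattr(self, name)
            if not -1 <= rho <= 1:
                raise ValueError(f"{name} must be in [-1, 1], got {rho}")
        if self.layout not in ("grid", "uniform_random"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.field_length_scale <= 0:
            raise ValueError("field_length_scale must be positive")

    def program_names(self) -> tuple[str, ...]:
        extras = tuple(f"program_{i + 1}" for i in range(2, self.n_programs))
        return FOCAL_PROGRAMS + extras

    def hub_lfc_vector(self) -> np.ndarray:
        lfc = self.hub_condition_log2fc
        n = len(self.hub_genes)
        if lfc is None:
            return np.zeros(n)
        arr = np.asarray(lfc, dtype=float)
        if arr.ndim == 0:
            return np.full(n, float(arr))
        if arr.shape != (n,):
            raise ValueError(
                f"hub_condition_log2fc must be scalar or length {n}, got shape {arr.shape}"
            )
        return arr


def _sample_coords(rng: np.random.Generator, n: int, layout: str) -> np.ndarray:
    if layout == "uniform_random":
        return rng.uniform(0.0, 1.0, size=(n, 2))
    m = math.ceil(math.sqrt(n))
    step = 1.0 / max(m - 1, 1)
    ii, jj = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    grid = np.column_stack([ii.ravel() * step, jj.ravel() * step])
    return grid[:n].astype(float)


def _bump_field(
    rng: np.random.Generator, coords: np.ndarray, length_scale: float, n_centers: int
) -> np.ndarray:
    """Smooth random surface: weighted sum of Gaussian bumps, standardized."""
    centers = rng.uniform(-0.1, 1.1, size=(n_centers, 2))
    weights = rng.normal(size=n_centers)
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    f = (np.exp(-d2 / (2.0 * length_scale**2)) * weights).sum(axis=1)
    sd = f.std()
    if sd == 0:  # pathological (e.g. all coords identical); keep finite
        return np.zeros(len(coords))
    return (f - f.mean()) / sd


def _correlated_pair(
    rng: np.random.Generator, coords: np.ndarray, rho: float, length_scale: float, n_centers: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two standardized fields with *exact* empirical correlation rho."""
    f_a = _bump_field(rng, coords, length_scale, n_centers)
    f_raw = _bump_field(rng, coords, length_scale, n_centers)
    # Gram-Schmidt: make the second field empirically orthogonal to the first
    resid = f_raw - (f_raw @ f_a) / max(f_a @ f_a, 1e-300) * f_a
    sd = resid.std()
    f_perp = resid / sd if sd > 0 else resid
    f_b = rho * f_a + math.sqrt(1.0 - rho**2) * f_perp
    return f_a, f_b


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; variance mu + mu^2/theta."""
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-12) / dispersion)
    return rng.poisson(lam)


def generate_spot_table(params: SpatialSimParams) -> pd.DataFrame:
    """All samples of both conditions in one long spot table.

    Columns: spot_id, x, y, sample_id, condition, one ``latent_<program>``
    and one ``score_<program>`` column per program, and one ``expr_<gene>``
    count column per hub gene (omitted when ``hub_genes`` is empty).  The
    ``latent_`` columns expose the pre-noise fields whose within-sample
    correlation between the two focal programs equals ``rho_control`` /
    ``rho_disease`` exactly.
    """
    rng = np.random.default_rng(params.seed)
    programs = params.program_names()
    lfc = params.hub_lfc_vector()
    frames = []
    for condition in CONDITIONS:
        rho = params.rho_disease if condition == "disease" else params.rho_control
        for s in range(params.n_samples_per_condition):
            sid = f"{condition}_{s + 1}"
            n = params.n_spots_per_sample
            coords = _sample_coords(rng, n, params.layout)
            f_a, f_b = _correlated_pair(
                rng, coords, rho, params.field_length_scale, params.n_field_centers
            )
            latents = {programs[0]: f_a, programs[1]: f_b}
            for extra in programs[2:]:
                latents[extra] = _bump_field(
                    rng, coords, params.field_length_scale, params.n_field_centers
                )
            data = {
                "spot_id": [f"{sid}_s{i}" for i in range(n)],
                "x": coords[:, 0],
                "y": coords[:, 1],
                "sample_id": sid,
                "condition": condition,
            }
            scores = {}
            for prog in programs:
                noise = rng.normal(scale=params.score_noise_sd, size=n)
                scores[prog] = _sigmoid(latents[prog] + noise)
            if params.normalize_scores:
                total = np.sum([scores[p] for p in programs], axis=0)
                for prog in programs:
                    scores[prog] = scores[prog] / total
            for prog in programs:
                data[f"latent_{prog}"] = latents[prog]
            for prog in programs:
                data[f"score_{prog}"] = scores[prog]
            a, b = scores[programs[0]], scores[programs[1]]
            is_disease = 1.0 if condition == "disease" else 0.0
            for g, gene in enumerate(params.hub_genes):
                log2_mu = (
                    math.log2(params.base_expr)
                    + params.hub_effect * (a + b - 1.0)
                    + lfc[g] * is_disease
                )
                mu = np.exp2(log2_mu)
                data[f"expr_{gene}"] = _nb_draw(rng, mu, params.nb_dispersion)
            frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ScSimParams:
    """Conditions of the simulated single-cell experiment.

    Cells are negative-binomial draws over a lognormal gene-mean profile
    scaled so a typical cell has ~``target_umi`` UMIs and comfortably passes
    the default QC thresholds; exactly ``ceil(frac_low_quality * n_cells)``
    cells are post-processed to violate at least one QC rule (low/high UMI,
    few detected genes, high mitochondrial content, or — for
    ``frac_doublet`` of all cells, counted inside the low-quality quota — a
    doublet flag).  Each cluster elevates its own marker genes by
    ``marker_log2fc``; disease cells elevate the condition-responsive genes
    by ``condition_effect`` (log2).  With ``include_hub_panel`` the first
    genes carry the 18-gene hub-panel names and are condition-responsive.
    """

    n_cells: int = 500
    n_genes: int = 2_000
    n_clusters: int = 3
    marker_log2fc: float = 2.0
    frac_low_quality: float = 0.0
    frac_doublet: float = 0.0
    condition_effect: float = 1.0
    seed: int = 0
    target_umi: int = 5_000
    nb_dispersion: float = 1.5
    n_markers_per_cluster: int = 20
    n_condition_genes: int = 50
    n_mito_genes: int = 13
    mito_mean_frac: float = 0.03
    include_hub_panel: bool = True

    def __post_init__(self):
        _check_prob("frac_low_quality", self.frac_low_quality)
        _check_prob("frac_doublet", self.frac_doublet)
        if self.n_clusters > self.n_cells:
            raise ValueError("n_clusters cannot exceed n_cells")
        if self.frac_doublet > self.frac_low_quality:
            raise ValueError(
                "frac_doublet cells are counted inside the low-quality quota; "
                "require frac_doublet <= frac_low_quality"
            )
        needed = (
            self.n_condition_genes
            + self.n_clusters * self.n_markers_per_cluster
            + self.n_mito_genes
        )
        if needed > self.n_genes:
            raise ValueError(f"n_genes={self.n_genes} too small for layout ({needed} reserved)")


def _gene_names(params: ScSimParams) -> list[str]:
    names = [f"gene_{i:04d}" for i in range(params.n_genes)]
    if params.include_hub_panel:
        for i, g in enumerate(HUB_PANEL.ordered()):
            names[i] = g
    for j in range(params.n_mito_genes):
        names[params.n_genes - params.n_mito_genes + j] = f"MT-{j + 1}"
    return names


def generate_cell_matrix(params: ScSimParams) -> AnnData:
    """Cells x genes AnnData with counts in ``X`` and QC metadata in ``obs``.

    ``obs`` columns: total_counts (== column sums), n_genes (== nonzero
    entries), mito_frac (share of ``MT-`` gene counts), doublet, cluster,
    condition.  ``uns["sim"]`` records which genes are cluster markers /
    condition-responsive and which cells were constructed low-quality.
    """
    rng = np.random.default_rng(params.seed)
    n_cells, n_genes = params.n_cells, params.n_genes
    qc = QcThresholds()

    mito_idx = np.arange(n_genes - params.n_mito_genes, n_genes)
    cond_idx = np.arange(params.n_condition_genes)
    marker_idx = {
        c: np.arange(
            params.n_condition_genes + c * params.n_markers_per_cluster,
            params.n_condition_genes + (c + 1) * params.n_markers_per_cluster,
        )
        for c in range(params.n_clusters)
    }

    base = rng.lognormal(mean=0.0, sigma=1.3, size=n_genes)
    base[mito_idx] = rng.lognormal(mean=0.0, sigma=0.5, size=len(mito_idx))
    non_mito = np.setdiff1d(np.arange(n_genes), mito_idx)
    base[non_mito] *= (1.0 - params.mito_mean_frac) * params.target_umi / base[non_mito].sum()
    base[mito_idx] *= params.mito_mean_frac * params.target_umi / base[mito_idx].sum()

    clusters = rng.integers(0, params.n_clusters, size=n_cells)
    condition = np.where(rng.random(n_cells) < 0.5, "disease", "control")

    n_bad = math.ceil(params.frac_low_quality * n_cells)
    n_doublet = math.ceil(params.frac_doublet * n_cells)
    bad_cells = rng.choice(n_cells, size=n_bad, replace=False) if n_bad else np.array([], int)
    modes = ["doublet"] * n_doublet
    cycle = ["low_umi", "high_mito", "low_genes", "high_umi"]
    while len(modes) < n_bad:
        modes.append(cycle[(len(modes) - n_doublet) % len(cycle)])
    mode_of = dict(zip(bad_cells.tolist(), modes))

    def cell_mean(i: int) -> np.ndarray:
        mu = base.copy()
        mu[marker_idx[clusters[i]]] *= 2.0**params.marker_log2fc
        if condition[i] == "disease":
            mu[cond_idx] *= 2.0**params.condition_effect
        return mu

    def passes(counts: np.ndarray) -> bool:
        umi = counts.sum()
        ng = np.count_nonzero(counts)
        mito = counts[mito_idx].sum() / max(umi, 1)
        return (
            qc.umi_min <= umi <= qc.umi_max
            and qc.genes_min <= ng <= qc.genes_max
            and mito <= qc.mito_max
        )

    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    doublet = np.zeros(n_cells, dtype=bool)
    for i in range(n_cells):
        mu = cell_mean(i)
        row = _nb_draw(rng, mu, params.nb_dispersion)
        for _ in range(50):
            if passes(row):
                break
            row = _nb_draw(rng, mu, params.nb_dispersion)
        else:
            raise RuntimeError("could not draw a QC-passing cell; check parameters")
        mode = mode_of.get(i)
        if mode == "doublet":
            doublet[i] = True
        elif mode == "low_umi":
            row = rng.multivariate_hypergeometric(row, 600)
        elif mode == "high_umi":
            top = int(np.argmax(np.where(np.isin(np.arange(n_genes), mito_idx), -1, row)))
            row[top] += qc.umi_max - row.sum() + int(rng.integers(1_000, 5_000))
        elif mode == "low_genes":
            keep = np.argsort(row)[-150:]
            mask = np.zeros(n_genes, dtype=bool)
            mask[keep] = True
            row = np.where(mask, row, 0)
        elif mode == "high_mito":
            row[mito_idx[0]] += math.ceil(0.2 * row.sum())
        counts[i] = row

    total = counts.sum(axis=1)
    obs = pd.DataFrame(
        {
            "total_counts": total,
            "n_genes": (counts > 0).sum(axis=1),
            "mito_frac": counts[:, mito_idx].sum(axis=1) / np.maximum(total, 1),
            "doublet": doublet,
            "cluster": pd.Categorical([f"c{c}" for c in clusters]),
            "condition": pd.Categorical(condition, categories=list(CONDITIONS)),
        },
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    var = pd.DataFrame(index=_gene_names(params))
    adata = AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    adata.uns["sim"] = {
        "marker_genes": {f"c{c}": [adata.var_names[j] for j in idx] for c, idx in marker_idx.items()},
        "condition_genes": [adata.var_names[j] for j in cond_idx],
        "low_quality_cells": [adata.obs_names[i] for i in sorted(bad_cells.tolist())],
    }
    return adata


@dataclass(frozen=True)
class RoiSimParams:
    """Conditions of the simulated mIF experiment: per group,
    ``n_rois_per_group`` square ROIs of side ``roi_side`` μm holding
    ~``cells_per_roi_mean`` segmented cells; each cell is double-positive for
    a marker pair with its group's probability, and marker/DAPI intensities
    are lognormal with a disease shift of ``mfi_lognormal_mu_shift`` on the
    log-intensity of SPP1 and POSTN."""

    n_rois_per_group: int = 15
    roi_side: float = 150.0
    cells_per_roi_mean: float = 120.0
    p_doublepos_control: float = 0.05
    p_doublepos_disease: float = 0.40
    mfi_lognormal_mu_shift: float = 0.7
    seed: int = 0

    def __post_init__(self):
        _check_prob("p_doublepos_control", self.p_doublepos_control)
        _check_prob("p_doublepos_disease", self.p_doublepos_disease)
        if self.roi_side <= 0:
            raise ValueError("roi_side must be positive")
        if self.cells_per_roi_mean <= 0:
            raise ValueError("cells_per_roi_mean must be positive")


_MARKERS = ("CD68", "SPP1", "aSMA", "POSTN")


def generate_roi_table(params: RoiSimParams) -> pd.DataFrame:
    """Segmented-cell table: cell_id, x, y (μm), roi_id, group, per-marker and
    DAPI intensities, and the four phenotype flags."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for group in CONDITIONS:
        p_dp = (
            params.p_doublepos_disease if group == "disease" else params.p_doublepos_control
        )
        shift = params.mfi_lognormal_mu_shift if group == "disease" else 0.0
        for r in range(params.n_rois_per_group):
            roi_id = f"{group}_roi{r + 1:02d}"
            x0 = (r % 5) * params.roi_side * 2.0
            y0 = (r // 5) * params.roi_side * 2.0
            n = max(1, int(rng.poisson(params.cells_per_roi_mean)))
            x = x0 + rng.uniform(0, params.roi_side, n)
            y = y0 + rng.uniform(0, params.roi_side, n)

            dp_mye = rng.random(n) < p_dp
            cd68 = dp_mye | (rng.random(n) < 0.15)
            spp1 = dp_mye | (rng.random(n) < 0.10)
            dp_fib = rng.random(n) < p_dp
            asma = dp_fib | (rng.random(n) < 0.20)
            postn = dp_fib | (rng.random(n) < 0.10)

            dapi = rng.lognormal(mean=math.log(500.0), sigma=0.25, size=n)

            def intensity(pos, shifted):
                mu_pos = math.log(800.0) + (shift if shifted else 0.0)
                return np.where(
                    pos,
                    rng.lognormal(mean=mu_pos, sigma=0.35, size=n),
                    rng.lognormal(mean=math.log(150.0), sigma=0.35, size=n),
                )

            df = pd.DataFrame(
                {
                    "cell_id": [f"{roi_id}_c{i:04d}" for i in range(n)],
                    "x": x,
                    "y": y,
                    "roi_id": roi_id,
                    "group": group,
                    "CD68": intensity(cd68, False),
                    "SPP1": intensity(spp1, True),
                    "aSMA": intensity(asma, False),
                    "POSTN": intensity(postn, True),
                    "DAPI": dapi,
                    "cd68_pos": cd68,
                    "spp1_pos": spp1,
                    "asma_pos": asma,
                    "postn_pos": postn,
                }
            )
            rows.append(df)
    return pd.concat(rows, ignore_index=True)
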