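"""Quantification of segmented multiplex-immunofluorescence cell tables.

Per square region of interest (ROI) the double-positive proportion of a
marker pair is the number of cells positive for both markers divided by all
detected cells in that ROI; group differences are tested by Fisher's exact
test on counts pooled within group (appropriate when only a handful of
sections are available).  Mean fluorescence intensity (MFI) of a marker over
the double-positive cells is normalized to the ROI's mean DAPI intensity,
and the resulting per-ROI ratios are compared between groups with a
two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import FisherResult, RankTestResult, fisher_or, rank_sum_test

__all__ = [
    "PHENOTYPE_PAIRS",
    "RoiSummary",
    "dp_proportions",
    "normalized_mfi",
    "roi_group_test",
    "summarize_rois",
    "gate_phenotypes",
]

GROUPS = ("disease", "control")  # first row of pooled tables is disease

#: marker pairs defining double positivity: myeloid (CD68+SPP1+) and
#: activated-fibroblast (aSMA+POSTN+)
PHENOTYPE_PAIRS = {
    "cd68_spp1": ("cd68_pos", "spp1_pos"),
    "asma_postn": ("asma_pos", "postn_pos"),
}

REQUIRED_COLUMNS = ("cell_id", "roi_id", "group")


def _check_cells(cells: pd.DataFrame, extra=()) -> None:
    missing = [c for c in (*REQUIRED_COLUMNS, *extra) if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    bad = set(cells["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")


def dp_proportions(
    cells: pd.DataFrame, pairs: dict[str, tuple[str, str]] | None = None
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-ROI double-positive proportions and pooled 2x2 tables per pair.

    Returns ``(per_roi, pooled)``: ``per_roi`` has one row per ROI with
    n_cells and, per pair, the double-positive count and proportion
    (denominator = all detected cells in the ROI); ``pooled`` maps each pair
    to its group x double-positive 2x2 table (rows disease, control) over all
    cells.  Empty ROIs cannot occur (a ROI exists only through its cells).
    """
    pairs = pairs or PHENOTYPE_PAIRS
    flags = [f for pair in pairs.values() for f in pair]
    _check_cells(cells, extra=flags)

    rows = []
    for roi_id, sub in cells.groupby("roi_id", sort=True, observed=True):
        n = len(sub)
        row = {"roi_id": roi_id, "group": sub["group"].iloc[0], "n_cells": n}
        for name, (f1, f2) in pairs.items():
            dp = int((sub[f1].astype(bool) & sub[f2].astype(bool)).sum())
            row[f"n_dp_{name}"] = dp
            row[f"prop_dp_{name}"] = dp / n
        rows.append(row)
    per_roi = pd.DataFrame(rows)

    pooled: dict[str, np.ndarray] = {}
    for name, (f1, f2) in pairs.items():
        dp_flag = cells[f1].astype(bool) & cells[f2].astype(bool)
        table = np.zeros((2, 2), dtype=np.int64)
        for i, g in enumerate(GROUPS):
            mask = (cells["group"] == g).to_numpy()
            table[i, 0] = int(dp_flag.to_numpy()[mask].sum())
            table[i, 1] = int(mask.sum()) - table[i, 0]
        pooled[name] = table
    return per_roi, pooled


def normalized_mfi(
    cells: pd.DataFrame,
    marker: str,
    restrict_to: tuple[str, str],
    dapi: str = "DAPI",
    dapi_over: str = "all",
) -> pd.Series:
    """Per-ROI DAPI-normalized MFI of ``marker`` over double-positive cells.

    Numerator: mean ``marker`` intensity over the ROI's cells positive for
    both ``restrict_to`` flags.  Denominator: mean DAPI intensity over all
    detected cells in that ROI (``dapi_over="all"``, default) or over the
    double-positive cells only (``"double_positive"``).  ROIs without a
    qualifying cell are excluded with a warning.
    """
    _check_cells(cells, extra=(marker, dapi, *restrict_to))
    if dapi_over not in ("all", "double_positive"):
        raise ValueError(f"unknown dapi_over {dapi_over!r}")
    out = {}
    skipped = []
    for roi_id, sub in cells.groupby("roi_id", sort=True, observed=True):
        dp = sub[restrict_to[0]].astype(bool) & sub[restrict_to[1]].astype(bool)
        if not dp.any():
            skipped.append(roi_id)
            continue
        denom_cells = sub[dp] if dapi_over == "double_positive" else sub
        mean_dapi = float(denom_cells[dapi].mean())
        if mean_dapi <= 0:
            raise ValueError(f"ROI {roi_id!r} has nonpositive mean DAPI intensity")
        out[roi_id] = float(sub.loc[dp, marker].mean()) / mean_dapi
    if skipped:
        warnings.warn(
            f"ROIs without {restrict_to} double-positive cells excluded: {skipped}",
            stacklevel=2,
        )
    return pd.Series(out, name=f"mfi_{marker.lower()}_over_dapi")


def roi_group_test(values_by_group: dict[str, "pd.Series | np.ndarray"]) -> RankTestResult:
    """Two-sided Mann-Whitney U comparing per-ROI values between two groups.

    Exact when both groups are small (full enumeration with mid-rank ties),
    normal approximation otherwise; all-tied input gives p = 1.
    """
    if set(values_by_group) != set(GROUPS):
        raise ValueError(f"expected groups {GROUPS}, got {sorted(values_by_group)}")
    dis = np.asarray(values_by_group["disease"], dtype=float)
    ctl = np.asarray(values_by_group["control"], dtype=float)
    if len(dis) == 0 or len(ctl) == 0:
        raise ValueError("need at least one ROI per group")
    return rank_sum_test(dis, ctl, alternative="two-sided")


@dataclass
class RoiSummary:
    per_roi: pd.DataFrame
    pooled_tables: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    fisher: dict[str, FisherResult] = field(default_factory=dict)
    mfi_tests: dict[str, RankTestResult] = field(default_factory=dict)


def summarize_rois(
    cells: pd.DataFrame,
    alternative: str = "greater",
    dapi_over: str = "all",
) -> RoiSummary:
    """Full mIF quantification: per-ROI proportions and MFI ratios, pooled
    Fisher odds ratios per marker pair, and group-level Mann-Whitney tests on
    the DAPI-normalized MFIs (SPP1 over CD68+SPP1+ cells, POSTN over
    aSMA+POSTN+ cells)."""
    per_roi, pooled = dp_proportions(cells)
    fisher = {name: fisher_or(table, alternative=alternative) for name, table in pooled.items()}

    mfi_tests: dict[str, RankTestResult] = {}
    for marker, pair in (("SPP1", PHENOTYPE_PAIRS["cd68_spp1"]), ("POSTN", PHENOTYPE_PAIRS["asma_postn"])):
        ratios = normalized_mfi(cells, marker, restrict_to=pair, dapi_over=dapi_over)
        col = f"mfi_{marker.lower()}_over_dapi"
        per_roi = per_roi.merge(
            ratios.rename(col), left_on="roi_id", right_index=True, how="left"
        )
        by_group = {
            g: per_roi.loc[per_roi["group"] == g, col].dropna().to_numpy() for g in GROUPS
        }
        if all(len(v) for v in by_group.values()):
            mfi_tests[marker] = roi_group_test(by_group)
    return RoiSummary(per_roi=per_roi, pooled_tables=pooled, fisher=fisher, mfi_tests=mfi_tests)


def gate_phenotypes(
    cells: pd.DataFrame,
    thresholds: dict[str, float],
    suffix: str = "_pos",
) -> pd.DataFrame:
    """Simple intensity-threshold gater (fixture helper, not a classifier).

    Adds ``<marker.lower()>_pos`` flags where intensity > threshold.
    """
    out = cells.copy()
    for marker, thr in thresholds.items():
        if marker not in out.columns:
            raise ValueError(f"marker column {marker!r} missing")
        out[f"{marker.lower()}{suffix}"] = out[marker] > thr
    return out
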