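"""End-to-end orchestration: simulate -> QC -> DEG/scores -> coloc -> ROI.

A run is described by a :class:`RunConfig` (usually loaded from YAML), and
produces CSV/TSV results plus a JSON manifest recording the config snapshot,
software version, per-stage output checksums and wall-clock times.  A single
global seed is fanned out to the stochastic stages through a counter-based
child-seed scheme (`numpy.random.SeedSequence` with a fixed per-stage spawn
key), so adding or disabling a stage never perturbs another stage's stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .coloc import ColocConfig, hub_gene_spot_test, k_sensitivity
from .roiquant import summarize_rois
from .scstats import (
    HUB_PANEL,
    DegThresholds,
    QcThresholds,
    jaccard,
    module_score,
    normalize,
    qc_filter,
    select_degs,
)
from .simulate import (
    FOCAL_PROGRAMS,
    RoiSimParams,
    ScSimParams,
    SpatialSimParams,
    generate_cell_matrix,
    generate_roi_table,
    generate_spot_table,
)

__version__ = "0.1.0"

log = logging.getLogger("nichecoloc")

# fixed stage order; each stage's child seed is derived from its position
STAGES = ("spots", "cells", "roi", "qc", "deg", "module_score", "coloc", "hub_test", "roi_quant")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31), independent across stages."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    spatial: dict = field(default_factory=dict)
    sc: dict = field(default_factory=dict)
    roi: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    deg: dict = field(default_factory=dict)
    module: dict = field(default_factory=lambda: {"n_bins": 24, "n_ctrl": 100})
    coloc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = {**{s: True for s in STAGES}, **cfg.stages}
        return cfg

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def manifest_fingerprint(manifest: dict) -> str:
    """Checksum of the deterministic part of a manifest (config + outputs)."""
    det = {"config": manifest["config"], "version": manifest["version"],
           "checksums": manifest["checksums"]}
    return hashlib.sha256(json.dumps(det, sort_keys=True).encode()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Outputs land under ``cfg.out_dir``; the manifest is also written there as
    ``manifest.json``.  A stage failure raises with the stage name attached.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = {s: bool(cfg.stages.get(s, True)) for s in STAGES}
    manifest: dict = {
        "config": cfg.snapshot(),
        "version": __version__,
        "checksums": {},
        "timings": {},
    }

    state: dict = {}

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["checksums"][stage] = {p.name: _sha256(p) for p in sorted(paths)}
        manifest["timings"][stage] = round(time.perf_counter() - t0, 3)

    def run_stage(stage: str, fn) -> None:
        if not enabled[stage]:
            log.info("stage %s disabled", stage)
            return
        t0 = time.perf_counter()
        log.info("stage %s ...", stage)
        try:
            paths = fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, paths, t0)

    def st_spots():
        params = SpatialSimParams(**{"seed": stage_seed(cfg.seed, "spots"), **cfg.spatial})
        spots = generate_spot_table(params)
        state["spots"] = spots
        p = out / "spots.tsv"
        nio.write_spot_table(spots, p)
        return [p]

    def st_cells():
        params = ScSimParams(**{"seed": stage_seed(cfg.seed, "cells"), **cfg.sc})
        adata = generate_cell_matrix(params)
        state["cells"] = adata
        d = out / "cells"
        nio.write_cell_matrix(adata, d)
        return sorted(d.iterdir())

    def st_roi():
        params = RoiSimParams(**{"seed": stage_seed(cfg.seed, "roi"), **cfg.roi})
        cells = generate_roi_table(params)
        state["roi"] = cells
        p = out / "roi_cells.csv"
        nio.write_roi_table(cells, p)
        return [p]

    def st_qc():
        adata = state["cells"]
        filtered, removed = qc_filter(adata, QcThresholds(**cfg.qc))
        normalize(filtered)
        state["cells_qc"] = filtered
        p = out / "qc_summary.json"
        p.write_text(
            json.dumps(
                {"n_input": adata.n_obs, "n_retained": filtered.n_obs, "removed": removed},
                indent=2,
            )
        )
        return [p]

    def st_deg():
        adata = state["cells_qc"]
        res = select_degs(adata, group_by="cluster", thresholds=DegThresholds(**cfg.deg))
        p1 = out / "deg_table.tsv"
        res.table.to_csv(p1, sep="\t", index=False)
        paths = [p1]
        names = sorted(res.gene_sets)
        if len(names) >= 2:
            jc = pd.DataFrame(
                [
                    {"set_a": a, "set_b": b,
                     "jaccard": jaccard(res.gene_sets[a], res.gene_sets[b])}
                    for i, a in enumerate(names)
                    for b in names[i + 1:]
                ]
            )
            p2 = out / "deg_jaccard.csv"
            jc.to_csv(p2, index=False)
            paths.append(p2)
        state["deg"] = res
        return paths

    def st_module():
        adata = state["cells_qc"]
        panel = [g for g in HUB_PANEL.ordered() if g in adata.var_names]
        if len(panel) < len(HUB_PANEL):
            log.warning("hub panel incomplete in matrix: %d/%d genes", len(panel), len(HUB_PANEL))
        from .scstats import GeneSet

        res = module_score(
            adata,
            GeneSet("hub_panel", panel),
            n_bins=int(cfg.module.get("n_bins", 24)),
            n_ctrl=int(cfg.module.get("n_ctrl", 100)),
            seed=stage_seed(cfg.seed, "module_score"),
        )
        df = pd.DataFrame(
            {
                "cell_id": adata.obs_names,
                "condition": adata.obs["condition"].astype(str),
                "cluster": adata.obs["cluster"].astype(str),
                "hub_score": res.score,
            }
        )
        p = out / "hub_module_scores.tsv"
        df.to_csv(p, sep="\t", index=False)
        return [p]

    def st_coloc():
        spots = state["spots"]
        ccfg_kwargs = dict(cfg.coloc)
        score_a = ccfg_kwargs.pop("score_a", f"score_{FOCAL_PROGRAMS[0]}")
        score_b = ccfg_kwargs.pop("score_b", f"score_{FOCAL_PROGRAMS[1]}")
        if "k_list" in ccfg_kwargs:
            ccfg_kwargs["k_list"] = tuple(ccfg_kwargs["k_list"])
        res = k_sensitivity(spots, score_a, score_b, ColocConfig(**ccfg_kwargs))
        p1 = out / "coloc_summary.csv"
        res.summary.to_csv(p1, index=False)
        p2 = out / "coloc_per_sample.csv"
        res.per_sample.to_csv(p2, index=False)
        state["coloc"] = res
        return [p1, p2]

    def st_hub_test():
        spots = state["spots"]
        genes = [g for g in HUB_PANEL.ordered() if f"expr_{g}" in spots.columns]
        table = hub_gene_spot_test(spots, genes)
        p = out / "hub_gene_tests.tsv"
        table.to_csv(p, sep="\t", index=False)
        return [p]

    def st_roi_quant():
        summary = summarize_rois(state["roi"])
        p1 = out / "roi_summary.csv"
        summary.per_roi.to_csv(p1, index=False)
        report = {
            name: {
                "table": np.asarray(summary.pooled_tables[name]).tolist(),
                "odds_ratio": fr.odds_ratio,
                "ci": [fr.ci_low, fr.ci_high],
                "p_value": fr.p_value,
            }
            for name, fr in summary.fisher.items()
        }
        report["mfi_tests"] = {
            marker: {"U": t.statistic, "p_two_sided": t.p_value}
            for marker, t in summary.mfi_tests.items()
        }
        p2 = out / "roi_tests.json"
        p2.write_text(json.dumps(report, indent=2))
        return [p1, p2]

    run_stage("spots", st_spots)
    run_stage("cells", st_cells)
    run_stage("roi", st_roi)
    if enabled["qc"] and "cells" in state:
        run_stage("qc", st_qc)
    if enabled["deg"] and "cells_qc" in state:
        run_stage("deg", st_deg)
    if enabled["module_score"] and "cells_qc" in state:
        run_stage("module_score", st_module)
    if enabled["coloc"] and "spots" in state:
        run_stage("coloc", st_coloc)
    if enabled["hub_test"] and "spots" in state:
        run_stage("hub_test", st_hub_test)
    if enabled["roi_quant"] and "roi" in state:
        run_stage("roi_quant", st_roi_quant)

    manifest["fingerprint"] = manifest_fingerprint(manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def validate_inputs(paths: dict[str, str], strict: bool = False) -> list[dict]:
    """Schema-check input files before a run.

    ``paths`` maps kind -> path, with kinds ``spot_table``, ``cell_matrix``
    (a directory holding matrix.mtx/features.tsv/barcodes.tsv/metadata.tsv)
    and ``roi_table``.  Returns one report dict per file; with
    ``strict=True`` raises on the first failure.
    """
    checkers = {
        "spot_table": nio.read_spot_table,
        "cell_matrix": nio.read_cell_matrix,
        "roi_table": nio.read_roi_table,
    }
    report = []
    for kind, path in paths.items():
        if kind not in checkers:
            raise ValueError(f"unknown input kind {kind!r}")
        entry = {"kind": kind, "path": str(path), "ok": True, "error": None}
        try:
            checkers[kind](path)
        except Exception as exc:
            entry["ok"] = False
            entry["error"] = str(exc)
            if strict:
                raise
        report.append(entry)
    return report
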