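"""Config-driven orchestration of the full analysis.

Stages: variable selection -> phi2 association -> hierarchical clustering
(with divisive and fuzzy diagnostics) -> tree cut at fixed k -> bootstrap
co-membership -> extraction/rotation grid search scored by Procrustes-aligned
Tucker congruence -> reliability (clusters and factors) -> outlier flagging
-> rule-based integration into the final named-cluster table.

Every artifact is plain delimited text or JSON, and the machine-readable
report carries no timestamps, so identical config + seed gives byte-identical
payloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import silhouette_score

from itemclust import __version__
from itemclust.association import DissimilarityMatrix, association_matrix, to_dissimilarity
from itemclust.bootstrap import bootstrap_comembership, within_cluster_summary
from itemclust.cluster import MergeTree, agglomerate, cut, diana, export_newick, fanny
from itemclust.congruence import grid_search, match_score
from itemclust.datasets import ChecklistDataset, read_dataset, select_variables, write_dataset, write_matrix
from itemclust.efa import threshold_loadings
from itemclust.reliability import cronbach_alpha, flag_outliers, integrate, reliability_report
from itemclust.simulate import SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "run", "select_k_diagnostic", "factor_partition"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end run."""

    input: str | None = None
    metadata: str | None = None
    simulate: SimulationConfig | None = None
    sections: list[int] | None = None
    min_pairs: int = 2
    dissimilarity_form: str = "one_minus"
    method: str = "ward_d2"
    k: int = 7
    boot_B: int = 1000
    boot_k: int | None = None  # defaults to k
    seed: int = 0
    extractions: list[str] = field(default_factory=lambda: ["pc", "paf"])
    rotations: list[str] = field(
        default_factory=lambda: ["none", "varimax", "quartimax", "promax", "oblimin", "cluster_target"]
    )
    m_range: list[int] = field(default_factory=lambda: [4, 5, 6, 7])
    cutoff: float = 0.35
    t_within: float = 0.10
    r_ratio: float = 2.0
    cluster_names: dict[int, str] | None = None
    diagnostics: bool = True
    k_range: list[int] | None = None
    outdir: str = "itemclust_out"

    def __post_init__(self) -> None:
        if self.input is None and self.simulate is None:
            raise ValueError("config needs either an input path or a simulate block")
        if self.boot_k is None:
            self.boot_k = self.k

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.get("simulate")
        if isinstance(sim, dict):
            raw["simulate"] = SimulationConfig(**sim)
        names = raw.get("cluster_names")
        if isinstance(names, dict):
            raw["cluster_names"] = {int(k): str(v) for k, v in names.items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        if self.simulate is not None:
            out["simulate"] = dataclasses.asdict(self.simulate)
        return out


def _matrix_hash(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(np.round(values, 12)).tobytes()).hexdigest()[:16]


def select_k_diagnostic(
    d: DissimilarityMatrix, tree: MergeTree, k_range: Sequence[int]
) -> pd.DataFrame:
    """Mean silhouette width of each tree cut; the maximizer is marked."""
    n = len(d.labels)
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    rows = []
    for k in ks:
        labels = cut(tree, k).assignment
        sil = float(silhouette_score(d.d, labels, metric="precomputed"))
        rows.append({"k": k, "mean_silhouette": sil})
    frame = pd.DataFrame(rows)
    frame["best"] = frame["mean_silhouette"] == frame["mean_silhouette"].max()
    return frame


def factor_partition(loadings, labels: Sequence[str]):
    """Hard assignment of items to their maximal-|loading| factor.

    Used to score factor-level reliability the same way cluster-level
    reliability is scored.  Returns a list of per-factor item lists.
    """
    arr = np.abs(loadings.L)
    top = np.argmax(arr, axis=1)
    return [[labels[i] for i in range(len(labels)) if top[i] == f] for f in range(loadings.m)]


def _load_input(cfg: PipelineConfig, outdir: Path) -> tuple[ChecklistDataset, dict[str, int] | None]:
    if cfg.input is not None:
        ds = read_dataset(cfg.input, metadata=cfg.metadata)
        return ds, None
    assert cfg.simulate is not None
    ds, truth = simulate_dataset(cfg.simulate)
    write_dataset(ds, outdir / "simulated_data.csv")
    pd.DataFrame(
        [{"item_id": k, "block_label": v} for k, v in truth.items()]
    ).to_csv(outdir / "simulated_truth.csv", index=False)
    return ds, truth


def run(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the machine-readable report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config": cfg.to_dict(),
        "stages": {},
        "warnings": [],
        "artifacts": [],
    }

    def emit(name: str) -> Path:
        report["artifacts"].append(name)
        return outdir / name

    stage = "load"
    try:
        ds, truth = _load_input(cfg, outdir)
        if cfg.simulate is not None:
            report["artifacts"] += ["simulated_data.csv", "simulated_truth.csv"]
        if cfg.sections:
            ds = select_variables(ds, cfg.sections)
        report["stages"]["load"] = {
            "n_subjects": ds.n_subjects,
            "n_items": ds.n_items,
            "n_missing_cells": int(ds.mask.sum()),
            "sections": sorted(ds.sections_present()),
        }

        stage = "association"
        assoc = association_matrix(ds, min_pairs=cfg.min_pairs)
        dis = to_dissimilarity(assoc, form=cfg.dissimilarity_form)
        write_matrix(assoc.to_frame(), emit("association_phi2.csv"))
        write_matrix(dis.to_frame(), emit("dissimilarity.csv"))
        report["stages"]["association"] = {
            "phi2_hash": _matrix_hash(assoc.phi2),
            "min_complete_pairs": int(assoc.n_pairs[~np.eye(ds.n_items, dtype=bool)].min()),
        }

        stage = "cluster"
        tree = agglomerate(dis, cfg.method)
        part = cut(tree, cfg.k)
        emit("dendrogram.nwk").write_text(export_newick(tree) + "\n")
        pd.DataFrame({"item_id": part.labels, "cluster": part.assignment}).to_csv(
            emit("partition.csv"), index=False
        )
        cluster_stage: dict[str, Any] = {
            "method": cfg.method,
            "k": cfg.k,
            "merge_heights": [round(h, 12) for h in tree.heights.tolist()],
            "cluster_sizes": [len(part.members(c)) for c in range(1, part.k + 1)],
        }
        if cfg.diagnostics:
            diana_part = cut(diana(dis), cfg.k)
            fuzzy = fanny(dis, cfg.k)
            cluster_stage["diana_partition"] = diana_part.as_dict()
            cluster_stage["fanny"] = {
                "objective": fuzzy.objective,
                "dunn": fuzzy.dunn,
                "converged": fuzzy.converged,
                "hardened": fuzzy.harden().as_dict(),
            }
            k_range = cfg.k_range or list(range(2, min(11, ds.n_items - 1) + 1))
            sil = select_k_diagnostic(dis, tree, k_range)
            sil.to_csv(emit("silhouette_by_k.csv"), index=False)
            cluster_stage["silhouette_best_k"] = int(sil.loc[sil["best"], "k"].iloc[0])
        report["stages"]["cluster"] = cluster_stage

        stage = "bootstrap"
        comember = None
        if cfg.boot_B > 0:
            comember = bootstrap_comembership(
                ds, cfg.method, k=cfg.boot_k or cfg.k, B=cfg.boot_B, seed=cfg.seed,
                dissimilarity_form=cfg.dissimilarity_form,
            )
            write_matrix(comember.to_frame(), emit("comembership.csv"))
            summary = within_cluster_summary(comember, part)
            summary.to_csv(emit("comembership_summary.csv"))
            report["stages"]["bootstrap"] = {
                "B": comember.B,
                "B_effective": comember.B_effective,
                "n_dropped": comember.n_dropped,
                "p_hash": _matrix_hash(comember.p),
            }
        else:
            report["warnings"].append(
                "bootstrap disabled (B=0): integration uses loading evidence only"
            )
            report["stages"]["bootstrap"] = {"B": 0}

        stage = "efa"
        grid, winner = grid_search(
            assoc, part, m_range=cfg.m_range,
            extractions=cfg.extractions, rotations=cfg.rotations, cutoff=cfg.cutoff,
        )
        grid.to_csv(emit("grid_search.csv"), index=False)
        alignment = match_score(winner, part) if winner is not None else None
        efa_stage: dict[str, Any] = {"n_combinations": len(grid)}
        if winner is not None:
            winner.to_frame().to_csv(emit("loadings.csv"))
            thresholded = threshold_loadings(winner, cfg.cutoff)
            thresholded.table.to_csv(emit("loadings_thresholded.csv"))
            efa_stage.update(
                {
                    "winner": {
                        "extraction": winner.extraction,
                        "rotation": winner.rotation,
                        "m": winner.m,
                        "diag_sum": alignment.diag_sum,
                    },
                    "cross_loading_items": thresholded.cross_loading,
                }
            )
        report["stages"]["efa"] = efa_stage

        stage = "reliability"
        cluster_alphas = reliability_report(ds, part)
        cluster_alphas.to_csv(emit("alpha_clusters.csv"), index=False)
        rel_stage: dict[str, Any] = {
            "cluster_alphas": {
                int(r["cluster"]): None if pd.isna(r["alpha"]) else round(float(r["alpha"]), 12)
                for _, r in cluster_alphas.iterrows()
            }
        }
        if winner is not None:
            factor_rows = []
            for f, items in enumerate(factor_partition(winner, ds.item_ids), start=1):
                alpha = cronbach_alpha(ds, items)[0] if len(items) >= 2 else float("nan")
                factor_rows.append(
                    {"factor": f, "n_items": len(items), "items": ";".join(items), "alpha": alpha}
                )
            factor_alphas = pd.DataFrame(factor_rows)
            factor_alphas.to_csv(emit("alpha_factors.csv"), index=False)
            rel_stage["factor_alphas"] = {
                int(r["factor"]): None if pd.isna(r["alpha"]) else round(float(r["alpha"]), 12)
                for _, r in factor_alphas.iterrows()
            }
        report["stages"]["reliability"] = rel_stage

        stage = "integration"
        flags = []
        if comember is not None:
            flags = flag_outliers(
                comember, part, winner, alignment,
                t_within=cfg.t_within, r_ratio=cfg.r_ratio,
            )
        final = integrate(ds, part, flags, winner, alignment, names=cfg.cluster_names)
        final.to_frame().to_csv(emit("final_clusters.csv"), index=False)
        final.log.to_csv(emit("reassignment_log.csv"), index=False)
        report["stages"]["integration"] = {
            "n_flagged": len(flags),
            "n_moved": int((final.log["action"] == "moved").sum()) if len(final.log) else 0,
            "final_clusters": [
                {"name": c["name"], "items": c["items"],
                 "alpha": None if pd.isna(c["alpha"]) else round(float(c["alpha"]), 12)}
                for c in final.clusters
            ],
        }
        if truth is not None:
            from sklearn.metrics import adjusted_rand_score

            truth_vec = [truth[l] for l in part.labels]
            report["stages"]["cluster"]["ari_vs_planted"] = float(
                adjusted_rand_score(truth_vec, part.assignment)
            )
    except Exception as exc:
        report["error"] = {"stage": stage, "message": str(exc)}
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    report["artifacts"].append("report.json")
    return report
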