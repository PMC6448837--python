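"""End-to-end orchestration: filter -> select -> MIC -> networks -> scores.

A single :class:`PipelineConfig` drives the whole analysis and every
intermediate artifact is written to the output directory, so each stage
can be audited from disk: filtered matrices, per-layer selection tables,
MIC matrices per layer and condition, the threshold-scan table, GraphML
networks at every scanned threshold, and the final node score table. The
run manifest (JSON) records the configuration, package versions, the
seed, and per-stage sample/feature/edge counts; replicate runs with the
same config and seed produce byte-identical manifests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .io import (
    NORMAL,
    TUMOR,
    align_samples,
    read_mirna_table,
    read_protein_table,
    write_mirna_table,
    write_protein_table,
    zero_filter,
)
from .mic import mic_matrix
from .network import (
    build_multilayer,
    recommend_threshold,
    threshold_graph,
    threshold_scan,
    write_graphml,
)
from .scoring import importance_scores, jarque_bera
from .select import select_features
from .simulate import default_spec, generate, write_fixtures

__all__ = ["PipelineConfig", "run_pipeline"]

CONDITIONS = (NORMAL, TUMOR)


@dataclass
class PipelineConfig:
    """Everything one analysis run depends on.

    Either both input paths are given, or ``synthetic`` is true and the
    reference synthetic cohort is generated from ``seed``.
    """

    mirna_path: str | None = None
    protein_path: str | None = None
    synthetic: bool = False
    out_dir: str = "micnet_run"
    seed: int = 0
    zero_filter_mode: str = "any"
    k_grid_mirna: list[int] = field(default_factory=lambda: [5, 10, 15, 20])
    k_grid_protein: list[int] = field(default_factory=lambda: [4, 8, 12])
    folds: int = 10
    n_rounds: int = 40
    # candidate-set sizes: the chosen CV rows, one generous size per layer
    rf_k_mirna: int | None = 20
    rf_k_protein: int | None = 10
    top_k_mirna: int | None = 20
    top_k_protein: int | None = 10
    n_estimators: int = 100
    wrapper_budget: int = 10
    b_exponent: float = 0.6
    mic_method: str = "auto"
    taus: list[float] = field(default_factory=lambda: [0.2, 0.35, 0.5])
    node_loss_cap: float = 0.05
    working_tau: float | None = None  # None: use recommend_threshold

    def validate(self) -> None:
        if not self.synthetic:
            for p in (self.mirna_path, self.protein_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"input file {p!r} not found (set synthetic: true to simulate)"
                    )
        if not self.taus:
            raise ValueError("taus must not be empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "micnet_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": {},
    }
    try:
        _run_stages(cfg, out, manifest)
    except Exception as exc:
        manifest["failed_stage"] = manifest.get("current_stage", "unknown")
        manifest["error"] = str(exc)
        _write_manifest(manifest, out)
        raise RuntimeError(f"pipeline failed at stage {manifest['failed_stage']}: {exc}") from exc
    manifest.pop("current_stage", None)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _run_stages(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    stages = manifest["stages"]

    manifest["current_stage"] = "load"
    if cfg.synthetic:
        mirna, protein, truth = generate(default_spec(cfg.seed))
        write_fixtures(mirna, protein, out / "inputs", truth)
    else:
        mirna = read_mirna_table(cfg.mirna_path)
        protein = read_protein_table(cfg.protein_path)
    stages["load"] = {
        "mirna": {"samples": mirna.n_samples, "features": mirna.n_features,
                  **mirna.condition_counts()},
        "protein": {"samples": protein.n_samples, "features": protein.n_features,
                    **protein.condition_counts()},
    }

    manifest["current_stage"] = "zero_filter"
    mirna_f = zero_filter(mirna, cfg.zero_filter_mode)
    protein_f = zero_filter(protein, cfg.zero_filter_mode)
    write_mirna_table(mirna_f, out / "mirna_filtered.csv")
    write_protein_table(protein_f, out / "protein_filtered.csv")
    stages["zero_filter"] = {
        "mode": cfg.zero_filter_mode,
        "mirna_features": mirna_f.n_features,
        "protein_features": protein_f.n_features,
    }

    manifest["current_stage"] = "feature_selection"
    sel = {}
    for tag, mat, k_grid, top_k, rf_k in (
        ("mirna", mirna_f, cfg.k_grid_mirna, cfg.top_k_mirna, cfg.rf_k_mirna),
        ("protein", protein_f, cfg.k_grid_protein, cfg.top_k_protein, cfg.rf_k_protein),
    ):
        rf_k = min(rf_k, mat.n_features) if rf_k is not None else None
        res = select_features(
            mat, k_grid=k_grid, folds=cfg.folds, n_rounds=cfg.n_rounds,
            top_k=min(top_k, mat.n_features) if top_k is not None else None,
            seed=cfg.seed, select_k=rf_k,
            n_estimators=cfg.n_estimators, wrapper_budget=cfg.wrapper_budget,
        )
        res.cv_table.to_csv(out / f"{tag}_cv_table.csv", index=False)
        res.boosting_metrics.to_csv(out / f"{tag}_boosting_metrics.csv", index=False)
        pd.DataFrame(res.ranked_features["rf"], columns=["feature", "filter_score"]).to_csv(
            out / f"{tag}_rf_ranking.csv", index=False
        )
        pd.DataFrame(res.ranked_features["xgb"], columns=["feature", "gain"]).to_csv(
            out / f"{tag}_xgb_ranking.csv", index=False
        )
        sel[tag] = res
    stages["feature_selection"] = {
        tag: {
            "rf_selected": len(sel[tag].rf_selected),
            "xgb_selected": len(sel[tag].xgb_selected),
            "union": len(sel[tag].selected_union),
            "features": sel[tag].selected_union,
        }
        for tag in sel
    }

    manifest["current_stage"] = "align"
    mirna_c = mirna_f.subset_features(sel["mirna"].selected_union)
    protein_c = protein_f.subset_features(sel["protein"].selected_union)
    mirna_al, protein_al = align_samples(mirna_c, protein_c)
    stages["align"] = {"paired_samples": mirna_al.n_samples}

    manifest["current_stage"] = "mic"
    intra = {}
    cross = {}
    for condition in CONDITIONS:
        for tag, mat in (("miRNA", mirna_c), ("protein", protein_c)):
            sub = mat.restrict_condition(condition)
            micm = mic_matrix(sub, b_exponent=cfg.b_exponent, method=cfg.mic_method)
            micm.to_csv(out / f"mic_{tag.lower()}_{condition}.csv")
            intra[(tag, condition)] = micm
        a = mirna_al.restrict_condition(condition)
        b = protein_al.restrict_condition(condition)
        xm = mic_matrix(a, b, b_exponent=cfg.b_exponent, method=cfg.mic_method)
        xm.to_csv(out / f"mic_cross_{condition}.csv")
        cross[condition] = xm
    stages["mic"] = {
        f"{tag}_{condition}": {"features": len(m.row_features), "n_samples": m.n_samples}
        for (tag, condition), m in intra.items()
    }

    manifest["current_stage"] = "threshold_scan"
    scan = threshold_scan(intra, cfg.taus)
    scan.table.to_csv(out / "threshold_scan.csv", index=False)
    scan.curves.to_csv(out / "threshold_curves.csv", index=False)
    if cfg.working_tau is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau = recommend_threshold(scan, cfg.node_loss_cap)
    else:
        tau = cfg.working_tau
    stages["threshold_scan"] = {
        "taus": list(map(float, sorted(cfg.taus))),
        "working_tau": float(tau),
        "table": scan.table.to_dict(orient="records"),
    }

    manifest["current_stage"] = "networks"
    nets: dict = {}
    net_counts = {}
    for t in sorted(set(cfg.taus) | {tau}):
        for condition in CONDITIONS:
            mn = threshold_graph(intra[("miRNA", condition)], t, "miRNA", condition)
            pn = threshold_graph(intra[("protein", condition)], t, "protein", condition)
            mln = build_multilayer(mn, pn, cross[condition], t)
            write_graphml(mln, out / f"network_{condition}_tau{t:.2f}.graphml")
            nets[(t, condition)] = mln
            net_counts[f"{condition}_tau{t:.2f}"] = {
                "mirna_edges": mn.n_edges,
                "protein_edges": pn.n_edges,
                "cross_edges": mln.n_cross_edges,
            }
    stages["networks"] = net_counts

    manifest["current_stage"] = "scoring"
    table = importance_scores(nets[(tau, NORMAL)], nets[(tau, TUMOR)])
    table.to_csv(out / "node_scores.csv", index=False)
    diag = {}
    for layer in ("miRNA", "protein"):
        signed = table.loc[table["layer"] == layer, "b_signed_diff"].to_numpy()
        if len(signed) >= 8 and np.ptp(signed) > 0:
            stat, p = jarque_bera(signed)
            diag[layer] = {"jb_statistic": round(stat, 6), "jb_pvalue": round(p, 6)}
        else:
            diag[layer] = {"jb_statistic": None, "jb_pvalue": None}
    top = table.groupby("layer", sort=True).head(5)
    stages["scoring"] = {
        "working_tau": float(tau),
        "jarque_bera": diag,
        "top_nodes": {
            layer: top.loc[top["layer"] == layer, "node"].tolist()
            for layer in ("miRNA", "protein")
        },
    }
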