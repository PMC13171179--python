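"""End-to-end pipeline orchestration and the run manifest.

Stages: preprocess -> (k sweep or fixed k) -> k-NN graph -> (latent-dimension
evaluation or fixed d) -> GAE training -> graph reconstruction -> Louvain ->
validation -> SHAP diagnosis -> PCA baseline -> optional stability analysis.
Every stage writes its artifact under the output directory and the manifest
records the full configuration (including every defaulted parameter and all
derived sub-seeds), artifact paths, and wall times, so a run can be
reproduced bit-identically from the manifest alone.

Sub-seeds are derived from the master seed by fixed offsets so each stage is
also individually reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baseline import baseline_report
from .community import louvain, reconstruct_graph, validate
from .diagnosis import diagnose
from .dimension import evaluate_dims, select_dim
from .gae import GAEConfig, train
from .graph import graph_summary, knn_graph, select_k, sweep_k
from .preprocessing import TraitTable, preprocess
from .stability import assess_stability, stability_run

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (master seed + offset)
STAGE_SEEDS = {
    "sweep": 1, "gae": 2, "louvain": 3, "shap": 4, "baseline": 5,
    "stability": 6,
}


@dataclass
class PipelineConfig:
    outdir: str = "morphograph_run"
    seed: int = 0
    k: int | None = None                # fixed k; None -> sweep
    k_range: tuple[int, int] = (3, 10)
    sweep_replicates: int = 20
    latent_dim: int | None = None       # fixed d; None -> evaluate
    d_range: tuple[int, int] | None = None
    t_threshold: float = 0.9
    loss_tol: float = 0.01
    epochs: int = 1000
    lr0: float = 0.008
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 250
    dropout: float = 0.15
    pos_weight: float | str = "auto"
    tau: float | str = "auto"
    cluster_mode: str = "weighted"
    best_of: int = 1
    top_n: int = 10
    n_estimators: int = 100
    run_stability: bool = False
    stability_sizes: tuple[int, ...] = (5, 10, 15, 20)
    stability_max_subsets: int = 200


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, name: str, seconds: float, outputs: dict,
               **info) -> None:
        self.stages[name] = {
            "wall_time_s": round(seconds, 3),
            "outputs": outputs,
            **info,
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "version": self.version,
             "stages": self.stages, "warnings": self.warnings},
            indent=2, default=str,
        ))


def run_pipeline(table: TraitTable, config: PipelineConfig) -> RunManifest:
    """Execute all stages on a validated trait table; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    seed = config.seed

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                self.seconds = time.perf_counter() - self.t0
                return False

        return _Timer()

    try:
        with stage("preprocess") as t:
            cm = preprocess(table)
            corrected_path = out / "corrected_matrix.csv"
            cm.to_frame().to_csv(corrected_path)
        manifest.record("preprocess", t.seconds,
                        {"corrected_matrix": str(corrected_path)},
                        n_specimens=len(cm.specimen_ids),
                        n_traits=len(cm.trait_names))

        if config.k is None:
            with stage("sweep_k") as t:
                report = sweep_k(cm, range(config.k_range[0], config.k_range[1] + 1),
                                 n_replicates=config.sweep_replicates,
                                 seed=seed + STAGE_SEEDS["sweep"])
                k = select_k(report)
                sweep_path = out / "k_sweep.csv"
                report.table.to_csv(sweep_path, index=False)
            manifest.record("sweep_k", t.seconds, {"k_sweep": str(sweep_path)},
                            selected_k=k)
        else:
            k = config.k
            manifest.record("sweep_k", 0.0, {}, selected_k=k, skipped=True)

        with stage("graph") as t:
            g = knn_graph(cm, k)
            edge_path = out / "knn_edges.txt"
            with open(edge_path, "w") as fh:
                for i, j, w in g.edge_list():
                    fh.write(f"{i} {j} {w}\n")
            ids_path = out / "node_ids.csv"
            pd.DataFrame({"node": range(len(cm.specimen_ids)),
                          "specimen_id": cm.specimen_ids}).to_csv(
                ids_path, index=False)
        manifest.record("graph", t.seconds,
                        {"edges": str(edge_path), "node_ids": str(ids_path)},
                        **graph_summary(g))

        gcfg = GAEConfig(
            d=config.latent_dim or 8, epochs=config.epochs, lr0=config.lr0,
            lr_decay_factor=config.lr_decay_factor,
            lr_decay_every=config.lr_decay_every, dropout=config.dropout,
            pos_weight=config.pos_weight, seed=seed + STAGE_SEEDS["gae"],
        )
        if config.latent_dim is None:
            d_lo, d_hi = config.d_range or (1, len(cm.trait_names))
            with stage("select_dim") as t:
                dim_report = evaluate_dims(cm, g, range(d_lo, d_hi + 1),
                                           config=gcfg, k=k)
                d = select_dim(dim_report, t_threshold=config.t_threshold,
                               loss_tol=config.loss_tol)
                dim_path = out / "dimension_report.csv"
                dim_report.table.to_csv(dim_path, index=False)
            manifest.record("select_dim", t.seconds,
                            {"dimension_report": str(dim_path)}, selected_d=d)
            gcfg = GAEConfig(**{**asdict(gcfg), "d": d})
        else:
            d = config.latent_dim
            manifest.record("select_dim", 0.0, {}, selected_d=d, skipped=True)

        with stage("train") as t:
            emb, a_hat, trace = train(cm, g, gcfg)
            z_path = out / "latent_embedding.csv"
            pd.DataFrame(emb.Z, index=cm.specimen_ids).to_csv(z_path)
            trace_path = out / "training_trace.csv"
            pd.DataFrame({"epoch": range(len(trace.loss)), "loss": trace.loss,
                          "lr": trace.lr}).to_csv(trace_path, index=False)
        manifest.record("train", t.seconds,
                        {"embedding": str(z_path), "trace": str(trace_path)},
                        final_loss=trace.final_loss, d=d)

        with stage("cluster") as t:
            wg = reconstruct_graph(a_hat, tau=config.tau,
                                   mode=config.cluster_mode)
            part = louvain(wg, seed=seed + STAGE_SEEDS["louvain"],
                           best_of=config.best_of)
            part_path = out / "partition.csv"
            pd.DataFrame({"specimen_id": cm.specimen_ids,
                          "cluster": part.labels}).to_csv(part_path,
                                                          index=False)
        manifest.record("cluster", t.seconds, {"partition": str(part_path)},
                        n_communities=part.n_communities, Q=part.q)

        taxonomy = cm.species if cm.species is not None else ["na"] * len(
            cm.specimen_ids)
        with stage("validate") as t:
            report = validate(wg, part, taxonomy)
            val_path = out / "validation.json"
            val_path.write_text(json.dumps({
                "Q": report.q,
                "q_threshold_passed": report.q_threshold_passed,
                "nmi_vs_taxonomy": report.nmi_vs_taxonomy,
            }, indent=2))
            cont_path = out / "contingency.csv"
            report.contingency.to_csv(cont_path)
        manifest.record("validate", t.seconds,
                        {"validation": str(val_path),
                         "contingency": str(cont_path)},
                        Q=report.q, nmi=report.nmi_vs_taxonomy)

        with stage("explain") as t:
            diag = diagnose(cm, part, n_estimators=config.n_estimators,
                            top_n=config.top_n,
                            seed=seed + STAGE_SEEDS["shap"])
            diag_path = out / "shap_diagnosis.csv"
            diag.to_frame().to_csv(diag_path, index=False)
        manifest.record("explain", t.seconds, {"diagnosis": str(diag_path)})

        with stage("baseline") as t:
            base = baseline_report(cm, taxonomy,
                                   seed=seed + STAGE_SEEDS["baseline"])
            base_path = out / "baseline.json"
            base_path.write_text(json.dumps({
                "n_components_95": base.n_components_95,
                "best_k": base.best_k,
                "silhouette_by_k": base.silhouette_by_k,
                "Q_baseline": base.Q_baseline,
                "nmi_vs_taxonomy": base.nmi_vs_taxonomy,
            }, indent=2))
            labels_path = out / "baseline_labels.csv"
            pd.DataFrame({"specimen_id": cm.specimen_ids,
                          "cluster": base.labels}).to_csv(labels_path,
                                                          index=False)
        manifest.record("baseline", t.seconds,
                        {"report": str(base_path), "labels": str(labels_path)},
                        best_k=base.best_k, Q=base.Q_baseline)

        if config.run_stability:
            with stage("stability") as t:
                sizes = [s for s in config.stability_sizes
                         if 2 <= s <= table.n_traits]
                srep = stability_run(
                    table, sizes, mode="graph", knn_k=k,
                    max_subsets=config.stability_max_subsets,
                    seed=seed + STAGE_SEEDS["stability"],
                )
                verdict = assess_stability(srep, part.n_communities)
                stab_path = out / "stability.csv"
                srep.table.to_csv(stab_path, index=False)
                verdict_path = out / "stability_verdict.json"
                verdict_path.write_text(json.dumps(verdict, indent=2))
            manifest.record("stability", t.seconds,
                            {"report": str(stab_path),
                             "verdict": str(verdict_path)}, **verdict)
        else:
            manifest.record("stability", 0.0, {}, skipped=True)
    except Exception as exc:
        manifest.warnings.append(f"pipeline aborted: {exc}")
        manifest.write(out / "manifest.json")
        raise

    manifest.write(out / "manifest.json")
    return manifest
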