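"""Batch orchestration: datasets x methods with isolated output directories.

Each (dataset, method) pair runs the full chain — moderated statistics,
global-graph edge scores, change-point HES thresholds, DEG selection, the
KO-gene subnetwork, enrichment, knockout ground truth, and ROC metrics —
and writes its artifacts into a directory named after the pair.  Pairs are
independent (no shared mutable state), so a batch is order-independent;
failures are recorded per pair and do not abort the batch.  Every output
directory embeds the serialized configuration and the derived seed, making
any run reproducible from its own artifacts.
"""

from __future__ import annotations

import json
import traceback
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import benchmark as bench
from . import enrich
from .benchmark import GroundTruth
from .enrich import MethodSpec, format_deg_pct
from .expression import (
    ExpressionDataset,
    compute_edge_scores,
    derive_hes_thresholds,
    detect_changepoint,
    extract_ko_subnetwork,
    fit_gene_stats,
    read_expression,
    select_degs,
)
from .kgml import PathwayGraph, build_global_graph, load_collection, write_graphml

__all__ = [
    "DatasetSpec",
    "RunConfig",
    "derive_seed",
    "run_single",
    "run_batch",
    "format_report",
]


@dataclass
class DatasetSpec:
    """One dataset: file locations plus the knockout gene(s)."""

    dataset_id: str
    matrix: str
    design: str
    ko_genes: list[str]

    def load(self) -> ExpressionDataset:
        return read_expression(
            self.matrix, self.design, self.ko_genes, self.dataset_id
        )


@dataclass
class RunConfig:
    """Configuration of a batch run (serialized verbatim into each output)."""

    collection_dir: str
    datasets: list[DatasetSpec]
    methods: list[MethodSpec]
    out_root: str
    hes: str = "HES1"
    alpha: float = 0.005
    evidence_alpha: float = 0.05
    roc_p_field: str = "pG"
    call_p_field: str = "pGFdr"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "collection_dir": str(self.collection_dir),
            "datasets": [
                {
                    "dataset_id": d.dataset_id,
                    "matrix": str(d.matrix),
                    "design": str(d.design),
                    "ko_genes": list(d.ko_genes),
                }
                for d in self.datasets
            ],
            "methods": [m.to_dict() for m in self.methods],
            "out_root": str(self.out_root),
            "hes": self.hes,
            "alpha": self.alpha,
            "evidence_alpha": self.evidence_alpha,
            "roc_p_field": self.roc_p_field,
            "call_p_field": self.call_p_field,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        datasets = [DatasetSpec(**ds) for ds in d["datasets"]]
        methods = []
        for m in d["methods"]:
            if isinstance(m, str):
                methods.append(MethodSpec(method_id=m))
            else:
                methods.append(MethodSpec(**m))
        keys = {
            k: d[k]
            for k in (
                "hes",
                "alpha",
                "evidence_alpha",
                "roc_p_field",
                "call_p_field",
                "seed",
            )
            if k in d
        }
        return cls(
            collection_dir=d["collection_dir"],
            datasets=datasets,
            methods=methods,
            out_root=d["out_root"],
            **keys,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def derive_seed(seed: int, dataset_id: str, method_id: str) -> int:
    """Stable per-pair seed below 2**31."""
    return zlib.crc32(f"{seed}:{dataset_id}:{method_id}".encode()) % (2**31)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sanitize(obj):
    """Make numpy scalars / NaN JSON-friendly and deterministic."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_single(
    config: RunConfig,
    dataset_id: str,
    method_id: str,
    *,
    collection: Sequence[PathwayGraph] | None = None,
    dataset: ExpressionDataset | None = None,
) -> Path:
    """Run the full chain for one (dataset, method) pair.

    Writes the DEG table, edge-score table, HES summary, KO subnetwork,
    enrichment results, ROC table and a machine-readable ``summary.json``
    into ``out_root/<dataset_id>/<method_id>/``.  Any stage error is
    recorded in ``run.log`` (downstream stages skipped); the directory
    always contains the serialized config and the derived seed.
    """
    outdir = Path(config.out_root) / dataset_id / method_id
    outdir.mkdir(parents=True, exist_ok=True)
    pair_seed = derive_seed(config.seed, dataset_id, method_id)
    _json_dump(
        {"config": config.to_dict(), "pair_seed": pair_seed}, outdir / "config.json"
    )
    log_lines: list[str] = []
    summary: dict = {
        "dataset_id": dataset_id,
        "method_id": method_id,
        "seed": pair_seed,
        "hes": config.hes,
        "alpha": config.alpha,
    }
    try:
        if collection is None:
            collection = load_collection(config.collection_dir)
        if dataset is None:
            spec = next(
                d for d in config.datasets if d.dataset_id == dataset_id
            )
            dataset = spec.load()
        mspec = next(m for m in config.methods if m.method_id == method_id)
        mspec = MethodSpec(**{**mspec.to_dict(), "seed": pair_seed})

        with warnings.catch_warnings():
            warnings.simplefilter("always")
            stats_df = fit_gene_stats(dataset)
        stats_df.reset_index(names="gene").to_csv(
            outdir / "gene_stats.tsv", sep="\t", index=False
        )

        graph = build_global_graph(collection)
        scores = compute_edge_scores(stats_df, graph)
        scores.to_csv(outdir / "edge_scores.tsv", sep="\t", index=False)
        log_lines.append(f"skipped unmeasured edges: {scores.attrs['n_skipped']}")

        cp = detect_changepoint(scores["score"].to_numpy())
        hes = derive_hes_thresholds(scores, cp)
        _json_dump(hes.to_dict(), outdir / "hes.json")
        threshold = hes.get(config.hes)
        degs = select_degs(scores, threshold, stats_df, threshold_label=config.hes)
        degs.reset_index(names="gene").to_csv(
            outdir / "degs.tsv", sep="\t", index=False
        )
        dist = scores[["score"]].copy()
        dist["hes1"], dist["hes2"], dist["hes3"] = hes.hes1, hes.hes2, hes.hes3
        dist.to_csv(outdir / "score_distribution.csv", index=False)

        subnet = extract_ko_subnetwork(degs, graph)
        write_graphml(subnet, outdir / "subnetwork.graphml")
        summary["n_degs"] = int(len(degs))
        summary["hes_thresholds"] = hes.to_dict()

        results = enrich.run_method(
            mspec, collection=collection, stats_df=stats_df, degs=degs
        )
        enrich.write_results(results, outdir / "results.tsv")
        summary["n_pathways"] = int(len(results))

        truth = bench.build_ground_truth(collection, dataset.ko_genes)
        counts = bench.classify_confusion(
            results, truth, config.alpha, config.call_p_field
        )
        metrics = bench.compute_metrics(counts)
        curve = bench.build_roc(results, truth, config.roc_p_field)
        pd.DataFrame(
            {
                "threshold": curve.thresholds,
                "specificity": curve.specificity,
                "sensitivity": curve.sensitivity,
            }
        ).to_csv(outdir / "roc_curve.csv", index=False)
        youden_p, youden_pt = bench.youden_threshold(curve)
        youden_counts = bench.classify_confusion(
            results, truth, min(max(youden_p, 1e-300), 1 - 1e-12), config.roc_p_field
        ) if np.isfinite(youden_p) else None
        summary["confusion"] = counts.to_dict()
        summary["metrics_at_alpha"] = metrics
        summary["roc"] = {
            "auc": curve.auc,
            "pAUC_SP": bench.partial_auc(curve, "SP"),
            "pAUC_SE": bench.partial_auc(curve, "SE"),
            "pAUC_SP_corrected": bench.partial_auc(curve, "SP", corrected=True),
            "pAUC_SE_corrected": bench.partial_auc(curve, "SE", corrected=True),
            "youden_p": youden_p if np.isfinite(youden_p) else None,
            "youden_specificity": youden_pt[0],
            "youden_sensitivity": youden_pt[1],
        }
        if youden_counts is not None:
            summary["metrics_at_youden"] = bench.compute_metrics(youden_counts)
        if results["pNDE"].notna().any():
            table, intercept = bench.evidence_plot_data(
                results, alpha=config.evidence_alpha
            )
            table.to_csv(outdir / "evidence_plot.csv", index=False)
            summary["evidence_line_intercept"] = intercept
        _json_dump({"metrics": _sanitize(metrics), "counts": counts.to_dict()},
                   outdir / "metrics.json")
        summary["status"] = "ok"
    except Exception as exc:  # fault isolation: record, do not propagate
        summary["status"] = "error"
        summary["error"] = f"{type(exc).__name__}: {exc}"
        log_lines.append(traceback.format_exc())
    _json_dump(_sanitize(summary), outdir / "summary.json")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def run_batch(config: RunConfig) -> Path:
    """Run every dataset x method pair, then aggregate.

    Writes per-pair directories plus ``stats_long.tsv`` (dataset, method,
    metric, value), ``wilcoxon.tsv`` pairwise comparisons, and
    ``batch.log``; partial failures are enumerated, not fatal.
    """
    out_root = Path(config.out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    collection = load_collection(config.collection_dir)
    failures: list[str] = []
    records: list[dict] = []
    for dspec in config.datasets:
        try:
            dataset = dspec.load()
        except Exception as exc:
            failures.append(f"{dspec.dataset_id}: {type(exc).__name__}: {exc}")
            continue
        for mspec in config.methods:
            outdir = run_single(
                config,
                dspec.dataset_id,
                mspec.method_id,
                collection=collection,
                dataset=dataset,
            )
            summary = json.loads((outdir / "summary.json").read_text())
            if summary.get("status") != "ok":
                failures.append(
                    f"{dspec.dataset_id}/{mspec.method_id}: {summary.get('error')}"
                )
                continue
            roc = summary["roc"]
            values = dict(summary["metrics_at_youden"]) if "metrics_at_youden" in summary else {}
            values.update(
                {
                    "AUC": roc["auc"],
                    "pAUC_SP": roc["pAUC_SP"],
                    "pAUC_SE": roc["pAUC_SE"],
                    "p_threshold": roc["youden_p"],
                }
            )
            for metric, value in values.items():
                records.append(
                    {
                        "dataset": dspec.dataset_id,
                        "method": mspec.method_id,
                        "metric": metric,
                        "value": value,
                    }
                )
    long = pd.DataFrame(records)
    long.to_csv(out_root / "stats_long.tsv", sep="\t", index=False)
    if (
        not long.empty
        and long["method"].nunique() >= 2
        and long["dataset"].nunique() >= 2
    ):
        summary_tbl, wilcoxon = bench.aggregate_benchmark(long)
        summary_tbl.to_csv(out_root / "stats_summary.tsv", sep="\t", index=False)
        wilcoxon.to_csv(out_root / "wilcoxon.tsv", sep="\t", index=False)
    (out_root / "batch.log").write_text(
        "\n".join(failures) + ("\n" if failures else "no failures\n")
    )
    return out_root


def format_report(
    results: pd.DataFrame,
    truth: GroundTruth | None = None,
    *,
    alpha: float = 0.005,
    p_field: str = "pGFdr",
) -> str:
    """Human-readable ranked pathway table.

    Columns mirror the standard knockout-pathway report: rank order,
    pathway id and name, Activated/Inhibited status, pSize, "NDE (pct)"
    with percent = round(100*NDE/pSize, 2), the adjusted p, and — when a
    ground truth is given — the TPKO/FNKO call at ``alpha``.
    """
    header = ["Order", "Pathway ID", "Pathway Name", "Status", "pSize", "DEGs (%)", p_field]
    if truth is not None:
        header.append("Call")
    lines = ["\t".join(header)]
    for order, (_, row) in enumerate(results.iterrows(), start=1):
        p = row.get(p_field, float("nan"))
        nde = int(row["NDE"]) if pd.notna(row.get("NDE")) else 0
        psize = int(row["pSize"]) if pd.notna(row.get("pSize")) else 0
        cells = [
            str(order),
            str(row["pathway_id"]),
            str(row.get("name", "")),
            str(row.get("status", "NA")),
            str(psize),
            format_deg_pct(nde, psize),
            f"{p:.6g}" if pd.notna(p) else "NA",
        ]
        if truth is not None:
            is_ko = truth.get(row["pathway_id"], False)
            called = pd.notna(p) and p < alpha
            if is_ko:
                call = "TPKO" if called else "FNKO"
            else:
                call = "FPKO" if called else "TNKO"
            cells.append(call)
        lines.append("\t".join(cells))
    return "\n".join(lines)
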