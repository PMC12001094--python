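"""End-to-end analysis pipeline and results serialization.

For every gene set: size gate and pre-filters, candidate-model fitting and
AIC/LRT selection, Benjamini-Hochberg correction across all fitted sets,
then — for significant sets — benchmark dose and trend-change doses with
subsampling-bootstrap confidence intervals, and optional k-means clustering
of divergent gene subgroups with a per-cluster refit.

Per-pathway work is independent; with ``n_workers > 1`` pathways are
distributed over processes, with per-pathway random seeds derived
deterministically from the global seed and the pathway name, so parallel
and serial runs produce identical results tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cluster import ClusterAssignment, cluster_genes, split_geneset
from .datasets import DoseResponseDataset, GeneSet, GeneSetCollection
from .model import FittedPathwayModel, adjust_pvalues, fit_pathway
from .preprocess import FilterConfig, TransformedDataset, transform_dataset
from .thresholds import (
    BootstrapResult,
    ThresholdEstimate,
    bootstrap_ci,
    compute_bmd,
    compute_tcds,
    summarize_thresholds,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PathwayResult", "PipelineResult", "run_pipeline",
           "results_table", "write_results", "pathway_seed"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; serialized alongside the results."""

    omics_type: str = "counts"
    alpha: float = 0.05
    z: float = 1.0
    n_boot: int = 1000
    boot_fraction: float = 0.6
    log10_dose: bool = False
    clustering: bool = False
    filters: FilterConfig = field(default_factory=FilterConfig)
    grid_size: int = 200
    spline_degree: int = 3
    seed: int = 42
    n_workers: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def pathway_seed(global_seed: int, name: str) -> int:
    """Deterministic per-pathway seed independent of scheduling order."""
    return (zlib.crc32(f"{global_seed}:{name}".encode()) ^ global_seed) & 0x7FFFFFFF


@dataclass
class PathwayResult:
    """One row of the results table plus its full per-pathway detail."""

    name: str
    id: str | None
    n_genes: int
    status: str                      # "ok" | "filtered" | "skipped" | "unfit"
    filter_decisions: list = field(default_factory=list)
    model: FittedPathwayModel | None = None
    bmd: ThresholdEstimate | None = None
    tcds: list[ThresholdEstimate] = field(default_factory=list)
    bootstrap: BootstrapResult | None = None
    clusters: ClusterAssignment | None = None
    cluster_results: list["PathwayResult"] = field(default_factory=list)
    is_cluster: bool = False
    parent: str | None = None

    @property
    def significant(self) -> bool:
        return (
            self.model is not None
            and self.model.best.kind != "null"
            and self.model.adjusted_p is not None
            and not np.isnan(self.model.adjusted_p)
        )


def _fit_one(
    transformed: TransformedDataset,
    geneset: GeneSet,
    config: RunConfig,
) -> PathwayResult:
    from .preprocess import apply_filters

    n_genes = len(geneset.intersect(transformed.features))
    decisions = apply_filters(transformed, geneset, config.filters)
    if not all(d.keep for d in decisions):
        return PathwayResult(
            name=geneset.name, id=geneset.id, n_genes=n_genes,
            status="filtered", filter_decisions=decisions,
        )
    try:
        fitted = fit_pathway(
            transformed, geneset, alpha=config.alpha,
            degree=config.spline_degree, grid_size=config.grid_size,
        )
    except (ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("pathway %s unfit: %s", geneset.name, exc)
        return PathwayResult(
            name=geneset.name, id=geneset.id, n_genes=n_genes,
            status="unfit", filter_decisions=decisions,
        )
    return PathwayResult(
        name=geneset.name, id=geneset.id, n_genes=n_genes,
        status="ok", filter_decisions=decisions, model=fitted,
    )


def _thresholds_one(
    transformed: TransformedDataset,
    geneset: GeneSet,
    result: PathwayResult,
    config: RunConfig,
) -> PathwayResult:
    """BMD/TCD + bootstrap + optional clustering for a significant pathway."""
    fitted = result.model
    curve = fitted.pathway_curve
    sd = fitted.best.sigma_resid
    result.bmd = compute_bmd(curve, sd=sd, z=config.z)
    result.tcds = compute_tcds(curve)
    seed = pathway_seed(config.seed, geneset.name)
    boot = bootstrap_ci(
        transformed, geneset, fitted.best, result.bmd, result.tcds,
        z=config.z, n_boot=config.n_boot, fraction=config.boot_fraction,
        seed=seed, grid_size=config.grid_size,
    )
    result.bootstrap = boot
    if boot.bmd is not None:
        result.bmd = boot.bmd
    result.tcds = boot.tcds if boot.tcds else result.tcds
    if config.clustering and len(fitted.best.genes) >= 3:
        assignment = cluster_genes(
            fitted.best.random_effects_frame(), seed=seed,
            k_max=min(6, len(fitted.best.genes) - 1),
        )
        result.clusters = assignment
        if assignment.k > 1:
            for derived in split_geneset(
                GeneSet(name=geneset.name, members=frozenset(fitted.best.genes),
                        description=geneset.description, id=geneset.id),
                assignment,
            ):
                if len(derived) < 2:
                    continue
                sub = _fit_one(
                    transformed, derived,
                    dataclasses.replace(config, clustering=False,
                                        filters=dataclasses.replace(
                                            config.filters, enable_invariant=False,
                                            enable_antagonistic=False,
                                            enable_pc1=False,
                                            min_set_size=2)),
                )
                sub.is_cluster = True
                sub.parent = geneset.name
                if sub.model is not None and sub.model.best.kind != "null":
                    c = sub.model.pathway_curve
                    sub.bmd = compute_bmd(c, sd=sub.model.best.sigma_resid, z=config.z)
                    sub.tcds = compute_tcds(c)
                result.cluster_results.append(sub)
    return result


@dataclass
class PipelineResult:
    """All pathway results plus the transformed dataset and summaries."""

    results: list[PathwayResult]
    transformed: TransformedDataset
    config: RunConfig
    summary: dict = field(default_factory=dict)

    @property
    def significant(self) -> list[PathwayResult]:
        return [
            r for r in self.results
            if r.significant and r.model.adjusted_p < self.config.alpha
        ]


def run_pipeline(
    dataset: DoseResponseDataset,
    genesets: GeneSetCollection,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on an aligned dataset and gene-set collection."""
    config = config or RunConfig(omics_type=dataset.omics_type)
    transformed = transform_dataset(dataset, use_log10=config.log10_dose)
    ordered = list(genesets)
    parallel = Parallel(n_jobs=config.n_workers, backend="loky") \
        if config.n_workers > 1 else None

    if parallel is not None:
        results = parallel(
            delayed(_fit_one)(transformed, gs, config) for gs in ordered
        )
    else:
        results = [_fit_one(transformed, gs, config) for gs in ordered]

    fitted = [r for r in results if r.status == "ok"]
    if not fitted:
        raise RuntimeError("no gene set passed the filters and was fitted")
    adj = adjust_pvalues([r.model.lrt_p for r in fitted])
    for r, a in zip(fitted, adj):
        r.model.adjusted_p = float(a)

    by_name = {gs.name: gs for gs in ordered}
    todo = [
        r for r in fitted
        if r.model.best.kind != "null" and r.model.adjusted_p < config.alpha
    ]
    if parallel is not None:
        done = parallel(
            delayed(_thresholds_one)(transformed, by_name[r.name], r, config)
            for r in todo
        )
        done_map = {r.name: r for r in done}
        results = [done_map.get(r.name, r) for r in results]
    else:
        for r in todo:
            _thresholds_one(transformed, by_name[r.name], r, config)

    sig = [
        r for r in results
        if r.status == "ok" and r.model.best.kind != "null"
        and r.model.adjusted_p < config.alpha
    ]
    bmds = [r.bmd.dose for r in sig if r.bmd is not None]
    tcd1s = [r.tcds[0].dose for r in sig if r.tcds]
    summary = {
        "n_pathways": len(results),
        "n_fitted": len(fitted),
        "n_significant": len(sig),
        "thresholds": summarize_thresholds(bmds, tcd1s, transformed.dose_scale),
    }
    return PipelineResult(results=results, transformed=transformed,
                          config=config, summary=summary)


def _nat(scale, x):
    return None if x is None else float(scale.to_natural(np.asarray([x]))[0])


def results_table(pipeline: PipelineResult) -> pd.DataFrame:
    """The per-pathway results table (doses in natural units)."""
    scale = pipeline.transformed.dose_scale
    rows = []
    for r in pipeline.results:
        all_rows = [r] + r.cluster_results
        for rr in all_rows:
            m = rr.model
            row = {
                "geneset": rr.name if not rr.is_cluster else rr.name,
                "id": rr.id or "",
                "n_genes": rr.n_genes,
                "status": rr.status,
                "is_cluster": rr.is_cluster,
                "parent": rr.parent or "",
                "best_model": m.best.kind if m else "",
                "p": m.lrt_p if m else np.nan,
                "adj_p": (m.adjusted_p if m and m.adjusted_p is not None else np.nan),
                "aic": m.best.aic if m else np.nan,
                "log_likelihood": m.best.log_likelihood if m else np.nan,
                "rmse": m.rmse if m else np.nan,
                "bmd": _nat(scale, rr.bmd.dose) if rr.bmd else np.nan,
                "bmd_lo": _nat(scale, rr.bmd.ci_low) if rr.bmd else np.nan,
                "bmd_hi": _nat(scale, rr.bmd.ci_high) if rr.bmd else np.nan,
                "tcd1": _nat(scale, rr.tcds[0].dose) if rr.tcds else np.nan,
                "tcd1_lo": _nat(scale, rr.tcds[0].ci_low) if rr.tcds else np.nan,
                "tcd1_hi": _nat(scale, rr.tcds[0].ci_high) if rr.tcds else np.nan,
                "n_tcds": len(rr.tcds),
                "tcd_types": ";".join(t.tcd_type for t in rr.tcds),
                "k_clusters": rr.clusters.k if rr.clusters else np.nan,
            }
            rows.append(row)
    df = pd.DataFrame(rows)
    return df


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _pathway_json(r: PathwayResult, scale) -> dict:
    d = {
        "geneset": r.name,
        "id": r.id,
        "n_genes": r.n_genes,
        "status": r.status,
        "filters": [
            {"filter": f.filter, "keep": f.keep, "statistic": f.statistic,
             "reason": f.reason}
            for f in r.filter_decisions
        ],
    }
    if r.model is not None:
        m = r.model
        d["best_model"] = m.best.kind
        d["p"] = m.lrt_p
        d["adj_p"] = m.adjusted_p
        d["aic"] = m.best.aic
        d["rmse"] = m.rmse
        d["sigma_resid"] = m.best.sigma_resid
        d["selection_trace"] = m.selection_trace
        d["skipped"] = m.skipped
        d["random_effects"] = {
            g: row.tolist()
            for g, row in zip(m.best.genes, m.best.fit.random_effects)
        }
    if r.bmd is not None:
        d["bmd"] = r.bmd.natural(scale)
    d["tcds"] = [t.natural(scale) for t in r.tcds]
    if r.bootstrap is not None:
        d["bootstrap"] = {
            "n_boot": r.bootstrap.n_boot,
            "fraction": r.bootstrap.fraction,
            "n_failed_fit": r.bootstrap.n_failed_fit,
            "n_bmd_undefined": r.bootstrap.n_bmd_undefined,
        }
    if r.clusters is not None:
        d["clusters"] = {
            "k": r.clusters.k,
            "labels": r.clusters.labels,
            "silhouette_by_k": r.clusters.silhouette_by_k,
            "dominant_cluster": r.clusters.dominant_cluster,
        }
    if r.cluster_results:
        d["cluster_fits"] = [_pathway_json(c, scale) for c in r.cluster_results]
    return _jsonable(d)


def write_results(pipeline: PipelineResult, out_dir: str | Path) -> Path:
    """Write results.tsv/.csv, per-pathway JSON sidecars and run_config.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise OSError(f"cannot write to {out}")
    df = results_table(pipeline)
    df.to_csv(out / "results.tsv", sep="\t", index=False)
    df.to_csv(out / "results.csv", index=False)
    scale = pipeline.transformed.dose_scale
    for r in pipeline.results:
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in r.name)
        with open(out / f"pathway_{safe}.json", "w", encoding="utf-8") as fh:
            json.dump(_pathway_json(r, scale), fh, indent=1, allow_nan=True)
    with open(out / "run_config.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(pipeline.config.to_dict()), fh, indent=1)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(pipeline.summary), fh, indent=1)
    return out
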