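"""End-to-end pipeline: preprocess -> bicluster -> enrich -> learn -> merge
-> evaluate, with file-based interchange at every stage boundary so external
biclustering results can be substituted.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .matrix import (ExpressionMatrix, PreprocessConfig, filter_genes,
                     knn_impute, read_expression_tsv, write_expression_tsv)
from .bicluster import (BiclusterSet, CCParams, ISAParams, KMeansParams,
                        OPSMParams, bicluster_stats, cc_bicluster,
                        import_external_biclusters, isa_bicluster,
                        kmeans_as_biclusters, opsm_bicluster, write_biclusters)
from .enrichment import (percent_enriched, read_annotations,
                         write_comparison_tsv)
from .bayesnet import (BDeConfig, SearchConfig, learn_subnetworks,
                       merge_subnetworks)
from .network import GeneNetwork, read_network, write_network
from .evaluation import (modified_reclassify, topology_stats,
                         write_evaluation_tsv)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    expression: str
    annotations: str | None = None
    gold_network: str | None = None
    gold_directed: bool = False
    output_dir: str = "bicgrn_out"
    rng_seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    significance_levels: list[float] = field(default_factory=lambda: [0.05, 0.01, 0.001])
    filtered_comparison: bool = False
    algorithms: dict[str, dict] = field(default_factory=dict)
    external_biclusters: dict[str, str] = field(default_factory=dict)
    bde: BDeConfig | None = None
    search: SearchConfig = field(default_factory=SearchConfig)

    def __post_init__(self) -> None:
        if self.bde is None:
            self.bde = BDeConfig(levels=self.preprocess.discretization_levels)
        if not self.algorithms and not self.external_biclusters:
            raise ValueError("at least one algorithm (or external result) must be enabled")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        bde_raw = raw.pop("bde", None)
        bde = BDeConfig(levels=pre.discretization_levels, **bde_raw) if bde_raw else None
        search = SearchConfig(**raw.pop("search", {}))
        return cls(preprocess=pre, bde=bde, search=search, **raw)


def _run_algorithm(name: str, params: dict, m: ExpressionMatrix,
                   seed: int) -> BiclusterSet:
    key = name.lower()
    if key == "cc":
        return cc_bicluster(m, CCParams(rng_seed=seed, **params))
    if key == "isa":
        return isa_bicluster(m, ISAParams(rng_seed=seed, **params))
    if key == "opsm":
        return opsm_bicluster(m, OPSMParams(**params))
    if key in ("kmeans", "k-means"):
        return kmeans_as_biclusters(m, KMeansParams(rng_seed=seed, **params))
    raise ValueError(f"unknown algorithm {name!r}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every enabled stage and write results plus a run manifest.

    Outputs (per algorithm): bicluster file, merged network TSV; plus the
    all-algorithms union network ("ALL"), the enrichment comparison TSV,
    standard and modified evaluation TSVs, topology TSV and manifest.json.
    Reruns with the same config and seed are byte-identical.
    """
    t0 = time.time()
    outputs: dict[str, str] = {}   # filename -> content written at the end
    manifest: dict = {
        "version": __version__,
        "rng_seed": cfg.rng_seed,
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append(name)

    # --- preprocess -------------------------------------------------------
    try:
        stage("read_expression")
        m = read_expression_tsv(cfg.expression)
        stage("impute")
        m = knn_impute(m, cfg.preprocess.knn_k)
        stage("filter")
        m = filter_genes(m, cfg.preprocess)
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    manifest["matrix_shape"] = list(m.shape)

    # --- biclustering -----------------------------------------------------
    sets: dict[str, BiclusterSet] = {}
    try:
        stage("bicluster")
        for i, (name, params) in enumerate(sorted(cfg.algorithms.items())):
            sets[name] = _run_algorithm(name, dict(params), m,
                                        seed=cfg.rng_seed + 1000 * (i + 1))
        for name, path in sorted(cfg.external_biclusters.items()):
            sets[name] = import_external_biclusters(path, m)
    except Exception as exc:
        raise PipelineError("bicluster", str(exc)) from exc
    manifest["bicluster_counts"] = {k: len(v) for k, v in sets.items()}
    manifest["bicluster_stats"] = {
        k: vars(bicluster_stats(v)) for k, v in sets.items()
    }

    # --- enrichment comparison -------------------------------------------
    if cfg.annotations:
        try:
            stage("enrich")
            annotations = read_annotations(cfg.annotations, set(m.gene_ids))
            report = percent_enriched(sets, annotations, cfg.significance_levels,
                                      filtered=cfg.filtered_comparison)
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc
    else:
        report = None

    # --- learning + merging ----------------------------------------------
    networks: dict[str, GeneNetwork] = {}
    try:
        stage("learn")
        for name, bset in sorted(sets.items()):
            dags = learn_subnetworks(m, bset, cfg.preprocess, cfg.bde, cfg.search)
            networks[name] = merge_subnetworks(dags)
        stage("merge")
        all_edges = set().union(*(n.edges for n in networks.values())) \
            if networks else set()
        all_universe = set().union(*(n.gene_universe for n in networks.values())) \
            if networks else set()
        networks["ALL"] = GeneNetwork(all_edges, all_universe)
    except Exception as exc:
        raise PipelineError("learn", str(exc)) from exc
    manifest["edge_counts"] = {k: len(v) for k, v in sorted(networks.items())}

    # --- evaluation -------------------------------------------------------
    reports = {}
    topo = {}
    if cfg.gold_network:
        try:
            stage("evaluate")
            gold = read_network(cfg.gold_network, directed=cfg.gold_directed)
            universe = set(gold.gene_universe) | set().union(
                *(n.gene_universe for n in networks.values())
            )
            for name, net in sorted(networks.items()):
                reports[name] = modified_reclassify(net, gold, universe)
            stage("topology")
            for name, net in sorted(networks.items()):
                if net.edges:
                    topo[name] = vars(topology_stats(net))
            topo["gold"] = vars(topology_stats(gold))
        except Exception as exc:
            raise PipelineError("evaluate", str(exc)) from exc

    # --- write everything at once (no partial outputs on failure) ---------
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(m, outdir / "expression_preprocessed.tsv")
    for name, bset in sorted(sets.items()):
        write_biclusters(bset, outdir / f"biclusters_{name}.txt")
    for name, net in sorted(networks.items()):
        write_network(net, outdir / f"network_{name}.tsv")
    if report is not None:
        write_comparison_tsv(report, outdir / "comparison.tsv")
    if reports:
        write_evaluation_tsv(reports, outdir / "evaluation.tsv", modified=False)
        write_evaluation_tsv(reports, outdir / "evaluation_modified.tsv", modified=True)
        manifest["evaluation"] = {
            name: {"auroc": r.auroc, "aupr": r.aupr,
                   "modified_auroc": r.modified_auroc,
                   "fp_to_tp": r.fp_to_tp, "tn_to_fn": r.tn_to_fn}
            for name, r in sorted(reports.items())
        }
    if topo:
        manifest["topology"] = topo
    manifest["wall_time_s"] = round(time.time() - t0, 3)
    manifest["outputs"] = sorted(
        p.name for p in outdir.iterdir() if p.name != "manifest.json"
    )
    with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
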