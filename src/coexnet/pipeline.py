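"""End-to-end orchestration: config in, result bundle out.

``run_pipeline`` executes the full chain — load, probe collapse, sample
QC, optional cell-fraction estimation, network construction and module
detection, eigengene-trait association with bootstrap CIs and BH-FDR,
GS/MM and hub-gene selection, subsampling stability, external-partition
overlap and hub-set over-representation — and writes every artifact to the
output directory together with a JSON manifest of file hashes, parameters
and versions.  Stages whose optional inputs are missing are skipped with a
logged notice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, preprocess, validation
from .association import gs_mm_test
from .model import CoexpressionNetwork, ModuleTraitModel
from .network import NetworkParams

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Paths and parameters of a full pipeline run."""

    expression: str
    traits: str | None = None
    covariates: str | None = None
    probe_map: str | None = None
    cell_reference: str | None = None
    external_partitions: dict[str, str] = field(default_factory=dict)
    gene_sets: str | None = None          # GMT
    out_dir: str = "coexnet_results"
    seed: int = 0
    orientation: str = "genes_in_rows"
    network: NetworkParams = field(default_factory=NetworkParams)
    outlier_threshold: float = -5.0
    # association
    alpha: float = 0.05
    bootstrap_B: int = 1000
    gs_min: float = 0.3
    mm_min: float = 0.8
    cluster_k: int = 2
    adjusted: bool = True
    # validation
    stability_iterations: int = 50
    stability_fraction: float = 0.8
    overlap_correction: str = "bonferroni"
    run_stability: bool = True


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    net = NetworkParams(**raw.pop("network", {}))
    assoc = raw.pop("association", {})
    val = raw.pop("validation", {})
    rename_assoc = {"alpha": "alpha", "bootstrap_B": "bootstrap_B",
                    "gs_min": "gs_min", "mm_min": "mm_min",
                    "cluster_k": "cluster_k", "adjusted": "adjusted"}
    rename_val = {"iterations": "stability_iterations",
                  "sample_fraction": "stability_fraction",
                  "correction": "overlap_correction",
                  "run_stability": "run_stability"}
    kwargs = dict(raw)
    for k, v in assoc.items():
        kwargs[rename_assoc[k]] = v
    for k, v in val.items():
        kwargs[rename_val[k]] = v
    return PipelineConfig(network=net, **kwargs)


@dataclass
class ResultBundle:
    """Paths of every artifact written by a pipeline run."""

    out_dir: Path
    manifest: dict

    def path(self, name: str) -> Path:
        return self.out_dir / name


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    stage = "load"

    def write(df: pd.DataFrame, name: str, **kw) -> None:
        p = out / name
        df.to_csv(p, sep="\t", float_format="%.10g", **kw)
        files.append(p)

    try:
        expr = io.load_expression(config.expression, config.orientation)
        if config.probe_map:
            stage = "collapse_probes"
            expr = io.collapse_probes(expr, io.load_probe_map(config.probe_map))

        stage = "sample_qc"
        qc = preprocess.sample_connectivity_z(
            expr, threshold=config.outlier_threshold)
        write(qc.z_k.to_frame(), "sample_qc.tsv")

        covariates = (io.load_trait_table(config.covariates)
                      if config.covariates else None)
        if config.cell_reference:
            stage = "cell_fractions"
            ref = io.load_expression(config.cell_reference)
            fractions = preprocess.estimate_cell_fractions(expr, ref)
            write(fractions, "cell_fractions.tsv")
            if covariates is not None:
                covariates = covariates.join(
                    fractions.iloc[:, :-1], how="left")  # drop one: sum-to-1

        stage = "network"
        net = CoexpressionNetwork(
            expr, config.network,
            outlier_threshold=config.outlier_threshold).fit()
        io.write_module_assignment(net.assignment, out / "module_assignment.tsv")
        files.append(out / "module_assignment.tsv")
        write(net.eigengenes, "eigengenes.tsv")
        (out / "network_summary.txt").write_text(net.summary() + "\n")
        files.append(out / "network_summary.txt")

        assoc = None
        if config.traits and net.n_modules > 0:
            stage = "association"
            traits = io.load_trait_table(config.traits)
            assoc = ModuleTraitModel(
                net, traits, covariates, adjusted=config.adjusted
            ).fit(alpha=config.alpha, bootstrap_B=config.bootstrap_B,
                  seed=config.seed, gs_min=config.gs_min,
                  mm_min=config.mm_min, cluster_k=config.cluster_k)
            write(assoc.correlation_matrix(), "module_trait_r.tsv")
            write(assoc.table, "module_trait_stats.tsv", index=False)
            (out / "association_summary.txt").write_text(assoc.summary() + "\n")
            files.append(out / "association_summary.txt")

            if len(assoc.significant_modules) >= 2:
                stage = "hub_genes"
                interest = assoc.trait_of_interest()
                mm = net.module_membership()
                rows = []
                for m in assoc.significant_modules:
                    gs, _ = assoc.gene_statistics(interest[m])
                    try:
                        r, p = gs_mm_test(gs, mm, net.assignment, m)
                        rows.append((m, interest[m], r, p))
                    except ValueError as exc:
                        logger.warning("GS-MM test skipped for %s: %s", m, exc)
                if rows:
                    write(pd.DataFrame(rows, columns=["module", "trait",
                                                      "r", "p"]),
                          "gs_mm_tests.tsv", index=False)
                tree = assoc.cluster_modules()
                write(tree.clusters.to_frame(), "module_clusters.tsv")
                hub_sets = assoc.hub_gene_sets()
                for hub in hub_sets:
                    write(hub.table, f"hub_genes_cluster{hub.cluster_id}.tsv",
                          index=False)
                if config.gene_sets:
                    stage = "enrichment"
                    gmt = io.load_gmt(config.gene_sets)
                    universe = set(net.assignment.index)
                    for hub in hub_sets:
                        if not hub.genes:
                            continue
                        enr = validation.ora_enrichment(
                            set(hub.genes) & universe, gmt, universe)
                        write(enr, f"enrichment_cluster{hub.cluster_id}.tsv",
                              index=False)
                else:
                    logger.info("no GMT provided; enrichment stage skipped")

        if config.run_stability and net.n_modules > 0:
            stage = "stability"
            stab = net.stability(n_iter=config.stability_iterations,
                                 sample_fraction=config.stability_fraction,
                                 seed=config.seed)
            write(stab.gene_consistency.to_frame(), "gene_consistency.tsv")
            write(stab.module_stability.to_frame(), "module_stability.tsv")

        if config.external_partitions:
            stage = "external_overlap"
            for name, path in config.external_partitions.items():
                external = io.load_module_assignment(path)
                overlap = net.external_overlap(
                    external, correction=config.overlap_correction)
                overlap.insert(0, "study", name)
                write(overlap, f"overlap_{name}.tsv", index=False)
        else:
            logger.info("no external partitions provided; overlap stage skipped")
    except Exception as exc:
        partial = {"status": "failed", "failed_stage": stage,
                   "error": str(exc),
                   "files": {p.name: _sha256(p) for p in files if p.exists()}}
        (out / "manifest.json").write_text(json.dumps(partial, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    params = dataclasses.asdict(config)
    manifest = {
        "status": "ok",
        "files": {p.name: _sha256(p) for p in files},
        "params": params,
        "seed": config.seed,
        "versions": {"coexnet": __version__, "python": platform.python_version()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return ResultBundle(out_dir=out, manifest=manifest)
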