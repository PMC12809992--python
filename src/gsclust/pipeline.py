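"""End-to-end session orchestration from a YAML configuration.

A config describes one full pass — read, convert, filter, optional PPI
load, distance computation, clustering, summaries, report — and every
intermediate is written with a sidecar so the run can be resumed, shared or
reproduced exactly (fixed seeds give byte-identical distance matrices,
clusterings and, with the timestamp disabled, reports).

Config schema (sections and keys)::

    input:
      path: enrichment table / GMT file          [required]
      format: table | gmt                        (default table)
      source_tool: clusterprofiler | ...         (optional converter)
      gene_delimiter: ","                        (optional)
    filter:
      min_size: 1
      max_size: 199
    ppi:
      path: edge table
      score_scale: 1000
    distance:
      metric: jaccard | dice | kappa | meetmin | pmm | go   [required]
      alpha: 1.0
      obo: ontology file (required for metric go)
    cluster:
      algorithm: louvain | markov | pam | fuzzy  [required]
      tau: 0.5
      k / inflation / thresholds / seed ...
    report:
      out_dir: output directory                  [required]
      highlighted: [ids...]
      timestamp: false
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import genesets
from .clustering import ClusteringParams, cluster, write_clustering
from .distances import MetricParams, distance_matrix, write_distance_matrix
from .exceptions import ParameterError
from .ontology import load_obo
from .ppi import load_ppi_edges
from .report import SessionRecord, now_timestamp, render_report
from .summarize import cluster_term_frequencies

logger = logging.getLogger(__name__)

_SECTIONS = {"input", "filter", "ppi", "distance", "cluster", "report"}
_CLUSTER_KEYS = set(ClusteringParams().__dict__)


def _validate(config: dict) -> None:
    problems = []
    unknown = set(config) - _SECTIONS
    if unknown:
        problems.append(f"unknown sections: {sorted(unknown)}")
    if "input" not in config or "path" not in config.get("input", {}):
        problems.append("input.path is required")
    dist = config.get("distance", {})
    if "metric" not in dist:
        problems.append("distance.metric is required")
    if dist.get("metric") == "pmm" and "path" not in config.get("ppi", {}):
        problems.append("distance.metric=pmm requires ppi.path")
    if dist.get("metric") == "go" and "obo" not in dist:
        problems.append("distance.metric=go requires distance.obo")
    clu = config.get("cluster", {})
    if "algorithm" not in clu:
        problems.append("cluster.algorithm is required")
    bad_keys = set(clu) - _CLUSTER_KEYS
    if bad_keys:
        problems.append(f"unknown cluster keys: {sorted(bad_keys)}")
    if "report" not in config or "out_dir" not in config.get("report", {}):
        problems.append("report.out_dir is required")
    if problems:
        raise ParameterError("invalid configuration: " + "; ".join(problems))


def run_session(config_path: str | Path) -> SessionRecord:
    """Execute a full session described by a YAML config; returns the record."""
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text())
    if not isinstance(config, dict):
        raise ParameterError("configuration must be a YAML mapping")
    _validate(config)

    out_dir = Path(config["report"]["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # --- input
    inp = config["input"]
    logger.info("stage input: reading %s", inp["path"])
    if inp.get("format", "table") == "gmt":
        collection = genesets.read_gmt(inp["path"])
    elif inp.get("source_tool"):
        frame = pd.read_csv(inp["path"], sep=None, engine="python")
        collection = genesets.convert_enrichment_output(frame, inp["source_tool"])
    else:
        collection = genesets.read_geneset_table(
            inp["path"], gene_delimiter=inp.get("gene_delimiter")
        )

    # --- filter
    filt = config.get("filter", {})
    if filt:
        logger.info("stage filter: %s", filt)
        collection = genesets.filter_by_size(
            collection,
            min_size=filt.get("min_size", 0),
            max_size=filt.get("max_size", float("inf")),
        )
    genesets.write_geneset_table(collection, out_dir / "collection.tsv")
    artifacts["collection"] = str(out_dir / "collection.tsv")

    # --- optional resources
    ppi = None
    if "path" in config.get("ppi", {}):
        logger.info("stage ppi: loading %s", config["ppi"]["path"])
        ppi = load_ppi_edges(
            config["ppi"]["path"], score_scale=config["ppi"].get("score_scale", 1000)
        )
    dist_cfg = config["distance"]
    dag = load_obo(dist_cfg["obo"]) if "obo" in dist_cfg else None

    # --- distance
    metric_params = MetricParams(
        metric=dist_cfg["metric"], alpha=dist_cfg.get("alpha", 1.0)
    )
    logger.info("stage distance: metric=%s", metric_params.metric)
    dm = distance_matrix(collection, metric_params, ppi=ppi, dag=dag)
    write_distance_matrix(dm, out_dir / "distances.tsv")
    artifacts["distances"] = str(out_dir / "distances.tsv")

    # --- cluster
    cp = ClusteringParams(**config["cluster"])
    logger.info("stage cluster: algorithm=%s", cp.algorithm)
    clustering = cluster(dm, cp)
    write_clustering(clustering, out_dir / "clusters.tsv")
    artifacts["clusters"] = str(out_dir / "clusters.tsv")

    # --- summaries
    descriptions = {s.id: s.description or "" for s in collection}
    freqs = cluster_term_frequencies(clustering, descriptions)
    freq_rows = [
        {"cluster_id": cid, "token": tok, "count": cnt}
        for cid, pairs in freqs.items()
        for tok, cnt in pairs
    ]
    pd.DataFrame(freq_rows, columns=["cluster_id", "token", "count"]).to_csv(
        out_dir / "cluster_terms.tsv", sep="\t", index=False
    )
    artifacts["cluster_terms"] = str(out_dir / "cluster_terms.tsv")

    # --- report
    rep = config["report"]
    session = SessionRecord(
        collection=collection,
        distance=dm,
        clustering=clustering,
        input_descriptor={
            "source file": str(inp["path"]),
            "converter": inp.get("source_tool", "none"),
            "filter bounds": f"[{filt.get('min_size', 0)}, {filt.get('max_size', 'inf')}]",
        },
        highlighted=tuple(rep.get("highlighted", [])),
        artifacts=artifacts,
        timestamp=now_timestamp() if rep.get("timestamp", False) else None,
    )
    logger.info("stage report: rendering HTML")
    render_report(session, out_dir / "report.html")
    session.artifacts["report"] = str(out_dir / "report.html")
    return session
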