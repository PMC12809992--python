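"""Clustering of gene sets from a distance matrix.

Four complementary algorithms are offered:

* Louvain community detection on the threshold graph (edges where distance
  < tau, weighted by similarity 1 - d);
* Markov clustering (MCL): expansion/inflation iterations on the
  column-stochastic similarity matrix until idempotence, clusters read from
  the attractor structure;
* PAM (k-medoids, BUILD + SWAP) on the raw distance matrix, with the number
  of clusters chosen by mean silhouette when not supplied;
* DAVID-style fuzzy clustering: similarity-neighbourhood seeds filtered by a
  within-seed agreement fraction, then multiple-linkage merging — members
  may belong to several clusters.

All algorithms are deterministic given the same input and seed; gene sets
that end up in no cluster are retained as singleton clusters flagged
"unclustered" so downstream summaries account for every input set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .distances import DistanceMatrix
from .exceptions import ParameterError

logger = logging.getLogger(__name__)

ALGORITHMS = ("louvain", "markov", "pam", "fuzzy")


@dataclass(frozen=True)
class ClusteringParams:
    """Algorithm selection and tuning knobs.

    tau is the graph distance threshold (strict: an edge is drawn when
    d < tau). The fuzzy thresholds mirror the DAVID defaults of 0.5 for
    similarity, membership and linkage.
    """

    algorithm: str = "louvain"
    tau: float = 0.5
    inflation: float = 2.0
    expansion: int = 2
    prune: float = 1e-5
    max_iter: int = 100
    k: int | None = None
    sim_threshold: float = 0.5
    membership_threshold: float = 0.5
    linkage_threshold: float = 0.5
    min_seed_size: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(
                f"unknown algorithm {self.algorithm!r}; choose from {', '.join(ALGORITHMS)}"
            )
        for name in ("tau", "sim_threshold", "membership_threshold", "linkage_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.inflation <= 1:
            raise ParameterError("MCL inflation must be > 1")
        if self.expansion < 2:
            raise ParameterError("MCL expansion must be >= 2")

    def to_jsonable(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class Clustering:
    """A partition or overlapping grouping of gene-set identifiers."""

    clusters: tuple[tuple[str, ...], ...]
    mode: str  # "partition" | "overlapping"
    labels: tuple[str, ...]
    params: ClusteringParams
    unclustered: tuple[str, ...] = ()
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(len(c) == 0 for c in self.clusters):
            raise ParameterError("clusters must be non-empty")
        members = [m for c in self.clusters for m in c]
        if self.mode == "partition":
            if len(set(members)) != len(members):
                raise ParameterError("partition clusters must be disjoint")
            if set(members) != set(self.labels):
                raise ParameterError("partition must cover exactly the label set")
        else:
            if not set(members) <= set(self.labels):
                raise ParameterError("cluster members must come from the label set")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, float]:
        """Label -> cluster index; partition mode only."""
        if self.mode != "partition":
            raise ParameterError("membership vector is defined for partitions only")
        out: dict[str, int] = {}
        for idx, cluster in enumerate(self.clusters):
            for m in cluster:
                out[m] = idx
        return out

    def label_vector(self) -> np.ndarray:
        """Integer cluster labels in the order of ``self.labels``."""
        memb = self.membership()
        return np.array([memb[lbl] for lbl in self.labels], dtype=int)


def _ordered_clusters(groups: list[set[str]], labels: tuple[str, ...]) -> tuple:
    """Deterministic cluster order: by lowest member index, members in label order."""
    pos = {lbl: i for i, lbl in enumerate(labels)}
    ordered = [tuple(sorted(g, key=pos.__getitem__)) for g in groups if g]
    ordered.sort(key=lambda c: pos[c[0]])
    return tuple(ordered)


def build_threshold_graph(dm: DistanceMatrix, tau: float) -> nx.Graph:
    """Similarity graph: edge (i, j) iff d(i, j) < tau, weight 1 - d.

    All labels are present as nodes even when isolated, so community
    detection can emit singleton clusters for them.
    """
    if not 0.0 <= tau <= 1.0:
        raise ParameterError("tau must lie in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(dm.labels)
    n = len(dm)
    for i in range(n):
        for j in range(i + 1, n):
            d = dm.values[i, j]
            if d < tau:
                g.add_edge(dm.labels[i], dm.labels[j], weight=1.0 - d)
    return g


def louvain_cluster(dm: DistanceMatrix, params: ClusteringParams) -> Clustering:
    """Seeded Louvain modularity communities of the threshold graph."""
    graph = build_threshold_graph(dm, params.tau)
    communities = nx.community.louvain_communities(
        graph, weight="weight", seed=params.seed
    )
    return Clustering(
        clusters=_ordered_clusters([set(c) for c in communities], dm.labels),
        mode="partition",
        labels=dm.labels,
        params=params,
    )


def markov_cluster(dm: DistanceMatrix, params: ClusteringParams) -> Clustering:
    """Markov clustering on the threshold-restricted similarity matrix.

    Self-loops of weight 1 are added, columns are normalized to stochastic,
    and expansion (matrix power) alternates with inflation (elementwise
    power + renormalization) and pruning of small entries until the matrix
    is numerically idempotent. Attractors (nonzero diagonal) define the
    clusters; a node attracted by several attractors is resolved to the
    lowest-index cluster so the result stays a partition.
    """
    graph = build_threshold_graph(dm, params.tau)
    n = len(dm)
    index = {lbl: i for i, lbl in enumerate(dm.labels)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        i, j = index[a], index[b]
        m[i, j] = m[j, i] = data["weight"]
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(params.max_iter):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = np.power(m, params.inflation)
        m[m < params.prune] = 0.0
        col_sums = m.sum(axis=0, keepdims=True)
        col_sums[col_sums == 0] = 1.0  # pruned-out column: leave as zero column
        m /= col_sums
        if m.shape == prev.shape and np.max(np.abs(m - prev)) < 1e-8:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not reach idempotence within max_iter=%d", params.max_iter)

    attractors = [i for i in range(n) if m[i, i] > params.prune]
    assigned: dict[int, int] = {}
    groups: list[set[str]] = []
    for a in attractors:
        members = {j for j in range(n) if m[a, j] > params.prune} | {a}
        new = {j for j in members if j not in assigned}
        if not new:
            continue
        idx = len(groups)
        groups.append({dm.labels[j] for j in new})
        for j in new:
            assigned[j] = idx
    for j in range(n):  # nodes attracted by nothing become singletons
        if j not in assigned:
            groups.append({dm.labels[j]})
    return Clustering(
        clusters=_ordered_clusters(groups, dm.labels),
        mode="partition",
        labels=dm.labels,
        params=params,
        info={"mcl_converged": converged},
    )


# --- PAM ----------------------------------------------------------------------


def _pam_assign_cost(values: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    d = values[:, medoids]
    assign = np.argmin(d, axis=1)  # argmin ties -> lowest medoid position
    return assign, float(d[np.arange(len(values)), assign].sum())


def _pam_run(values: np.ndarray, k: int) -> tuple[list[int], np.ndarray]:
    """Classic BUILD + SWAP k-medoids; ties broken to the lowest index."""
    n = len(values)
    # BUILD: first medoid minimizes total distance, then greedy gain
    medoids = [int(np.argmin(values.sum(axis=1)))]
    while len(medoids) < k:
        best_c, best_cost = -1, np.inf
        current = values[:, medoids].min(axis=1)
        for c in range(n):
            if c in medoids:
                continue
            cost = float(np.minimum(current, values[:, c]).sum())
            if cost < best_cost - 1e-15:
                best_c, best_cost = c, cost
        medoids.append(best_c)
    medoids.sort()
    _, cost = _pam_assign_cost(values, medoids)
    # SWAP until no improvement
    improved = True
    while improved:
        improved = False
        best = (cost, None)
        for mi, m in enumerate(medoids):
            for c in range(n):
                if c in medoids:
                    continue
                trial = medoids[:mi] + [c] + medoids[mi + 1 :]
                _, t_cost = _pam_assign_cost(values, trial)
                if t_cost < best[0] - 1e-12:
                    best = (t_cost, sorted(trial))
        if best[1] is not None:
            cost, medoids = best[0], best[1]
            improved = True
    assign, _ = _pam_assign_cost(values, medoids)
    return medoids, assign


def pam_cluster(dm: DistanceMatrix, params: ClusteringParams) -> Clustering:
    """Partitioning Around Medoids on the distance matrix.

    When ``params.k`` is not given, k is chosen to maximize the mean
    silhouette over k in [2, min(n - 1, 20)] (ties to the smaller k).
    """
    n = len(dm)
    k = params.k
    if k is not None:
        if not 1 <= k <= n:
            raise ParameterError(f"k={k} outside [1, {n}]")
        medoids, assign = _pam_run(dm.values, k)
    else:
        best = (-np.inf, None, None)
        for kk in range(2, min(n - 1, 20) + 1):
            medoids, assign = _pam_run(dm.values, kk)
            if len(set(assign.tolist())) < 2:
                continue
            score = silhouette_score(dm.values, assign, metric="precomputed")
            if score > best[0] + 1e-12:
                best = (score, medoids, assign)
        if best[1] is None:
            raise ParameterError("silhouette search failed; supply k explicitly")
        medoids, assign = best[1], best[2]
    groups: list[set[str]] = [set() for _ in medoids]
    for i, a in enumerate(assign):
        groups[a].add(dm.labels[i])
    return Clustering(
        clusters=_ordered_clusters(groups, dm.labels),
        mode="partition",
        labels=dm.labels,
        params=params,
        info={"medoids": [dm.labels[m] for m in medoids]},
    )


# --- fuzzy --------------------------------------------------------------------


def _seed_quality(sim: np.ndarray, members: list[int], threshold: float) -> float:
    """Fraction of off-diagonal within-seed pairs at or above the threshold."""
    pairs = 0
    good = 0
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            pairs += 1
            if sim[members[a], members[b]] >= threshold:
                good += 1
    return good / pairs if pairs else 1.0


def fuzzy_cluster(dm: DistanceMatrix, params: ClusteringParams) -> Clustering:
    """DAVID-style fuzzy clustering with overlapping membership.

    Stage 1 builds one candidate seed per gene set from its similarity
    neighbourhood (S >= sim_threshold) and keeps seeds that are large enough
    and internally coherent (fraction of within-seed similar pairs >=
    membership_threshold). Stage 2 repeatedly merges seeds whose shared
    member fraction |X ∩ Y| / min(|X|, |Y|) reaches linkage_threshold,
    scanning lowest-index-first until a pass makes no merge. Gene sets left
    out become singleton clusters flagged unclustered.
    """
    sim = 1.0 - dm.values
    n = len(dm)
    seeds: list[set[int]] = []
    for i in range(n):
        members = [i] + [j for j in range(n) if j != i and sim[i, j] >= params.sim_threshold]
        if len(members) < params.min_seed_size:
            continue
        if _seed_quality(sim, members, params.sim_threshold) >= params.membership_threshold:
            cand = set(members)
            if cand not in seeds:
                seeds.append(cand)

    merged = True
    while merged:
        merged = False
        for a in range(len(seeds)):
            for b in range(a + 1, len(seeds)):
                x, y = seeds[a], seeds[b]
                if len(x & y) / min(len(x), len(y)) >= params.linkage_threshold:
                    seeds[a] = x | y
                    del seeds[b]
                    merged = True
                    break
            if merged:
                break

    covered = set().union(*seeds) if seeds else set()
    groups = [{dm.labels[i] for i in s} for s in seeds]
    unclustered = tuple(dm.labels[i] for i in range(n) if i not in covered)
    for lbl in unclustered:
        groups.append({lbl})
    return Clustering(
        clusters=_ordered_clusters(groups, dm.labels),
        mode="overlapping",
        labels=dm.labels,
        params=params,
        unclustered=unclustered,
    )


def cluster(dm: DistanceMatrix, params: ClusteringParams) -> Clustering:
    """Dispatch to the algorithm named in ``params.algorithm``."""
    return {
        "louvain": louvain_cluster,
        "markov": markov_cluster,
        "pam": pam_cluster,
        "fuzzy": fuzzy_cluster,
    }[params.algorithm](dm, params)


# --- serialization ------------------------------------------------------------


def write_clustering(clustering: Clustering, path: str | Path) -> None:
    """TSV (geneset_id, cluster_id, flag) + JSON params sidecar.

    Overlapping members produce repeated geneset_id rows; unclustered
    singletons carry the flag "unclustered".
    """
    path = Path(path)
    rows = []
    flagged = set(clustering.unclustered)
    for idx, members in enumerate(clustering.clusters):
        for m in members:
            flag = "unclustered" if (m in flagged and len(members) == 1) else ""
            rows.append({"geneset_id": m, "cluster_id": idx, "flag": flag})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "mode": clustering.mode,
                "params": clustering.params.to_jsonable(),
                "info": clustering.info,
            },
            indent=1,
            sort_keys=True,
        )
    )


def read_clustering(path: str | Path) -> Clustering:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"geneset_id": str, "flag": str})
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    groups: dict[int, set[str]] = {}
    flagged = []
    for _, row in frame.iterrows():
        groups.setdefault(int(row["cluster_id"]), set()).add(row["geneset_id"])
        if isinstance(row.get("flag"), str) and row["flag"] == "unclustered":
            flagged.append(row["geneset_id"])
    labels = tuple(dict.fromkeys(frame["geneset_id"]))
    raw = meta["params"]
    raw.pop("info", None)
    params = ClusteringParams(**{k: v for k, v in raw.items()})
    return Clustering(
        clusters=_ordered_clusters([groups[k] for k in sorted(groups)], labels),
        mode=meta["mode"],
        labels=labels,
        params=params,
        unclustered=tuple(flagged),
        info=meta.get("info", {}),
    )
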