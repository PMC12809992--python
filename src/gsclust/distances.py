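"""Pairwise gene-set distance metrics and labeled distance matrices.

Three families of metrics are provided, all mapping a pair of gene sets to
a dissimilarity in [0, 1]:

* set-based — Jaccard, Sorensen-Dice, Cohen's kappa, Meet-Min — which depend
  only on the overlap structure of the two gene lists;
* hybrid — the PPI-weighted Meet-Min score (pMM), which credits non-shared
  genes of the smaller set for their strongest interaction into the other
  set, scaled by a balancing factor alpha;
* semantic — the Wang graph-based measure on an ontology DAG, where each
  term's similarity derives from edge-discounted contributions of shared
  ancestors.

For sets A, B with intersection I = |A ∩ B|:

    jaccard  d = 1 - I / |A ∪ B|
    dice     d = 1 - 2I / (|A| + |B|)
    meetmin  d = 1 - I / min(|A|, |B|)
    kappa    d = clamp(1 - κ, 0, 1) with κ the chance-corrected agreement of
             the two membership indicators over a gene universe
    pmm      d = 1 - [ I + α · Σ_{g in S\\L} max_w(g, L) ] / |S|
             where S is the smaller set, L the larger, and max_w the
             strongest PPI weight from g into L

The Meet-Min family divides by the smaller set size, so a small pathway
nested in a large one scores as highly similar — the behaviour wanted when
summarizing redundant enrichment output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ResourceError
from .genesets import GeneSet, GeneSetCollection
from .ontology import GODag
from .ppi import PPINetwork

logger = logging.getLogger(__name__)

SET_METRICS = ("jaccard", "dice", "kappa", "meetmin")
METRICS = SET_METRICS + ("pmm", "go")

#: values within this distance of 0 or 1 are snapped to the boundary
_SNAP = 1e-12


@dataclass(frozen=True)
class MetricParams:
    """Parameters governing a distance metric.

    Parameters
    ----------
    metric:
        One of ``jaccard``, ``dice``, ``kappa``, ``meetmin``, ``pmm``, ``go``.
    alpha:
        Balancing factor of the pMM interaction term (>= 0, default 1).
    universe:
        Gene background for kappa; defaults to the union of the collection.
    semantic_method:
        Only ``wang`` is implemented.
    w_isa, w_partof:
        Wang contribution factors for is_a (0.8) and part_of (0.6) edges.
    """

    metric: str = "jaccard"
    alpha: float = 1.0
    universe: frozenset[str] | None = None
    semantic_method: str = "wang"
    w_isa: float = 0.8
    w_partof: float = 0.6

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ParameterError(
                f"unknown metric {self.metric!r}; choose from {', '.join(METRICS)}"
            )
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if not (0 < self.w_isa < 1 and 0 < self.w_partof < 1):
            raise ParameterError("edge contribution factors must lie in (0, 1)")
        if self.semantic_method != "wang":
            raise ParameterError("only the 'wang' semantic method is supported")
        if self.universe is not None:
            object.__setattr__(self, "universe", frozenset(self.universe))

    def to_jsonable(self) -> dict:
        d = {
            "metric": self.metric,
            "alpha": self.alpha,
            "semantic_method": self.semantic_method,
            "w_isa": self.w_isa,
            "w_partof": self.w_partof,
        }
        if self.universe is not None:
            d["universe_size"] = len(self.universe)
        return d


def _snap(value: float) -> float:
    if -_SNAP < value < 0.0:
        return 0.0
    if 1.0 < value < 1.0 + _SNAP:
        return 1.0
    return value


def set_distance(a: GeneSet, b: GeneSet, params: MetricParams) -> float:
    """Set-based distance between two gene sets under ``params.metric``."""
    sa, sb = a.gene_set, b.gene_set
    inter = len(sa & sb)
    union = len(sa | sb)
    metric = params.metric
    if metric == "jaccard":
        d = 1.0 - inter / union
    elif metric == "dice":
        d = 1.0 - 2.0 * inter / (len(sa) + len(sb))
    elif metric == "meetmin":
        d = 1.0 - inter / min(len(sa), len(sb))
    elif metric == "kappa":
        universe = params.universe if params.universe is not None else sa | sb
        if not universe >= sa | sb:
            raise ParameterError("kappa universe must contain both gene sets")
        n = len(universe)
        n11 = inter
        n10 = len(sa - sb)
        n01 = len(sb - sa)
        n00 = n - union
        po = (n11 + n00) / n
        pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / n**2
        if pe == 1.0:
            logger.warning("degenerate kappa universe (Pe = 1); using exact-match rule")
            return 0.0 if sa == sb else 1.0
        kappa = (po - pe) / (1.0 - pe)
        d = min(max(1.0 - kappa, 0.0), 1.0)
    else:
        raise ParameterError(
            f"{metric!r} is not a set-based metric; use pmm_distance / "
            "go_semantic_distance or distance_matrix"
        )
    return _snap(d)


def pmm_distance(
    a: GeneSet, b: GeneSet, ppi: PPINetwork, params: MetricParams
) -> float:
    """PPI-weighted Meet-Min distance.

    The smaller set S (ties broken to the first argument) is scored against
    the larger set L: shared genes count fully, and every non-shared gene of
    S contributes its strongest interaction weight into L, scaled by alpha.
    With an empty network this reduces exactly to the Meet-Min distance.
    """
    if len(a) <= len(b):
        small, large = a, b
    else:
        small, large = b, a
    ss, sl = small.gene_set, large.gene_set
    inter = len(ss & sl)
    bonus = sum(ppi.max_weight_to_set(g, sl) for g in ss - sl)
    d = 1.0 - (inter + params.alpha * bonus) / len(ss)
    return _snap(min(max(d, 0.0), 1.0))


# --- Wang semantic distance ---------------------------------------------------


def _wang_svalues(term: str, dag: GODag, params: MetricParams) -> dict[str, float]:
    """Edge-discounted contribution of each ancestor of ``term``.

    S(term) = 1; walking child->parent edges multiplies by the edge factor
    (is_a 0.8, part_of 0.6 by default); an ancestor reachable along several
    paths keeps the maximum product.
    """
    weights = {"is_a": params.w_isa, "part_of": params.w_partof}
    svalues: dict[str, float] = {term: 1.0}
    # breadth-first relaxation; factors < 1 guarantee convergence on a DAG
    frontier = [term]
    while frontier:
        nxt: list[str] = []
        for child in frontier:
            for parent, relation in dag.parents(child):
                cand = svalues[child] * weights[relation]
                if cand > svalues.get(parent, 0.0):
                    svalues[parent] = cand
                    nxt.append(parent)
        frontier = nxt
    return svalues


def go_semantic_distance(
    term_a: str, term_b: str, dag: GODag, params: MetricParams
) -> float:
    """Wang semantic distance between two ontology terms: 1 - sim.

    sim sums the S-value contributions of shared ancestors, normalized by
    the total semantic value of both terms. Terms in disconnected components
    share no ancestors and are maximally distant.
    """
    for term in (term_a, term_b):
        if term not in dag:
            raise ParameterError(f"term {term!r} is not in the ontology")
    if term_a == term_b:
        return 0.0
    sa = _wang_svalues(term_a, dag, params)
    sb = _wang_svalues(term_b, dag, params)
    shared = set(sa) & set(sb)
    if not shared:
        logger.warning(
            "terms %s and %s share no ancestors (disconnected components)",
            term_a,
            term_b,
        )
        return 1.0
    sim = sum(sa[u] + sb[u] for u in shared) / (sum(sa.values()) + sum(sb.values()))
    return _snap(min(max(1.0 - sim, 0.0), 1.0))


# --- matrices -----------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Labeled symmetric matrix of pairwise gene-set distances in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray
    params: MetricParams = field(default_factory=MetricParams)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ParameterError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        # snap float fuzz before enforcing the invariants
        self.values[(self.values > -_SNAP) & (self.values < 0)] = 0.0
        self.values[(self.values > 1) & (self.values < 1 + _SNAP)] = 1.0
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ParameterError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ParameterError("distance matrix diagonal must be exactly 0")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ParameterError("distances must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(
    collection: GeneSetCollection,
    params: MetricParams,
    ppi: PPINetwork | None = None,
    dag: GODag | None = None,
) -> DistanceMatrix:
    """All pairwise distances for a collection under one metric.

    The pMM metric requires ``ppi``; the semantic metric requires ``dag``
    and interprets set ids as ontology term ids. Values are independent of
    computation order.
    """
    metric = params.metric
    if metric == "pmm" and ppi is None:
        raise ResourceError("metric 'pmm' requires a PPI network")
    if metric == "go" and dag is None:
        raise ResourceError("metric 'go' requires an ontology DAG")
    if metric == "kappa" and params.universe is None:
        params = replace(params, universe=collection.universe)

    sets = collection.sets
    n = len(sets)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if metric in SET_METRICS:
                d = set_distance(sets[i], sets[j], params)
            elif metric == "pmm":
                d = pmm_distance(sets[i], sets[j], ppi, params)
            else:
                d = go_semantic_distance(sets[i].id, sets[j].id, dag, params)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=collection.ids, values=values, params=params)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """TSV with label header row/column, plus a JSON params sidecar."""
    path = Path(path)
    dm.to_frame().to_csv(path, sep="\t", float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(dm.params.to_jsonable(), indent=1, sort_keys=True))


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    params = MetricParams()
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        params = MetricParams(
            metric=meta.get("metric", "jaccard"),
            alpha=meta.get("alpha", 1.0),
            semantic_method=meta.get("semantic_method", "wang"),
            w_isa=meta.get("w_isa", 0.8),
            w_partof=meta.get("w_partof", 0.6),
        )
    return DistanceMatrix(
        labels=tuple(str(c) for c in frame.columns),
        values=frame.values,
        params=params,
    )
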