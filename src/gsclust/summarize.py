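"""Interpretive summaries: heatmap ordering, bipartite membership graphs,
and per-cluster term-frequency tables for word clouds."""

from __future__ import annotations

import logging
import re
from collections import Counter
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .clustering import Clustering
from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

#: Standard English stopwords plus pathway-description boilerplate; callers
#: may extend or replace the list.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be by for from has have in into is it its of on or
    that the to via was were will with within without
    process processes regulation positive negative pathway pathways response
    activity signaling involved mediated dependent""".split()
)

_TOKEN = re.compile(r"[a-z0-9]+")
_MIN_TOKEN_LEN = 3


def order_for_heatmap(dm: DistanceMatrix) -> list[int]:
    """Leaf order of average-linkage hierarchical clustering on the matrix.

    Returns a permutation of row indices that places similar gene sets next
    to each other; reordering the matrix by it preserves symmetry and values.
    """
    n = len(dm)
    if n == 1:
        return [0]
    condensed = squareform(dm.values, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return hierarchy.leaves_list(linkage).tolist()


def build_bipartite_graph(clustering: Clustering) -> nx.Graph:
    """Bipartite graph of gene sets vs clusters, one edge per membership.

    Node names are namespaced ("geneset::X", "cluster::3") so a gene-set id
    can never collide with a cluster id; overlapping members therefore have
    degree above 1, and flagged singletons keep their own cluster node.
    """
    g = nx.Graph()
    flagged = set(clustering.unclustered)
    for lbl in clustering.labels:
        g.add_node(f"geneset::{lbl}", bipartite="geneset", label=lbl)
    for idx, members in enumerate(clustering.clusters):
        is_unclustered = len(members) == 1 and members[0] in flagged
        g.add_node(
            f"cluster::{idx}",
            bipartite="cluster",
            size=len(members),
            flag="unclustered" if is_unclustered else "",
        )
        for m in members:
            g.add_edge(f"geneset::{m}", f"cluster::{idx}")
    return g


def tokenize(text: str, stopwords: Iterable[str] = DEFAULT_STOPWORDS) -> list[str]:
    stop = set(stopwords)
    return [
        t
        for t in _TOKEN.findall(text.lower())
        if len(t) >= _MIN_TOKEN_LEN and t not in stop
    ]


def cluster_term_frequencies(
    clustering: Clustering,
    descriptions: Mapping[str, str],
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
) -> dict[int, list[tuple[str, int]]]:
    """Token counts of member descriptions, per cluster.

    Descriptions are lowercased, punctuation-stripped, stopword- and
    short-token-filtered; counts are sorted by frequency then alphabetically
    (the table behind a word-cloud view). An empty description supply gives
    an empty result with a warning.
    """
    if not any(descriptions.get(lbl) for lbl in clustering.labels):
        logger.warning("no gene-set descriptions available; word counts are empty")
        return {}
    out: dict[int, list[tuple[str, int]]] = {}
    for idx, members in enumerate(clustering.clusters):
        counter: Counter[str] = Counter()
        for m in members:
            text = descriptions.get(m)
            if text:
                counter.update(tokenize(text, stopwords))
        out[idx] = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return out


def reorder_matrix(dm: DistanceMatrix, order: list[int]) -> np.ndarray:
    """The matrix values permuted by a heatmap order (rows and columns)."""
    idx = np.asarray(order)
    return dm.values[np.ix_(idx, idx)]
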