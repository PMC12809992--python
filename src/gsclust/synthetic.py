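"""Seeded synthetic fixtures: planted gene-set collections, interaction
networks with within-group signal, and toy ontology DAGs.

The planted-collection model mimics a redundant enrichment result: each of
``n_clusters`` functional themes owns a disjoint pool of genes, and every
member set draws a core fraction of its genes from its theme's pool and the
rest from a shared background. Theme pools give within-group overlap (and,
via the synthetic interaction network, within-group connectivity) while the
background supplies realistic cross-group noise. Everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .genesets import GeneSet, GeneSetCollection
from .ontology import GODag
from .ppi import PPINetwork

#: Canonical fixture used throughout tests and the examples:
#: 5 themes x 6 sets of 25 genes, 80% drawn from 60-gene theme pools,
#: 300 background genes, fixed seed.
DEFAULT_SPEC_KWARGS = dict(
    n_clusters=5,
    sets_per_cluster=6,
    set_size=25,
    core_fraction=0.8,
    pool_size=60,
    background_size=300,
    seed=20240601,
)

#: Default synthetic-PPI regime: dense strong edges inside theme pools,
#: sparse weak edges elsewhere.
DEFAULT_PPI_KWARGS = dict(w_in=0.9, p_in=0.3, w_out=0.2, p_out=0.01, seed=11)


@dataclass(frozen=True)
class PlantedCollectionSpec:
    """Parameters of the planted-cluster gene-set generator."""

    n_clusters: int
    sets_per_cluster: int
    set_size: int
    core_fraction: float
    pool_size: int
    background_size: int
    seed: int

    def __post_init__(self) -> None:
        for name in (
            "n_clusters",
            "sets_per_cluster",
            "set_size",
            "pool_size",
            "background_size",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.core_fraction <= 1:
            raise ParameterError("core_fraction must lie in (0, 1]")
        if self.set_size > self.pool_size + self.background_size:
            raise ParameterError("set_size exceeds available genes")


def default_spec() -> PlantedCollectionSpec:
    return PlantedCollectionSpec(**DEFAULT_SPEC_KWARGS)


def _gene_names(n: int, offset: int = 0) -> list[str]:
    # synthetic identifiers; the G-prefix + zero padding avoids any
    # accidental collision with real gene identifier spaces
    return [f"G{i:06d}" for i in range(offset, offset + n)]


def generate_planted_collection(
    spec: PlantedCollectionSpec,
) -> tuple[GeneSetCollection, dict[str, int], dict[str, list[str]]]:
    """Sample a collection with planted cluster structure.

    Returns the collection, the true cluster label per set id, and the
    per-cluster gene pools (needed by the synthetic PPI generator).
    """
    rng = np.random.default_rng(spec.seed)
    n_core = round(spec.core_fraction * spec.set_size)
    n_bg = spec.set_size - n_core
    if n_core > spec.pool_size or n_bg > spec.background_size:
        raise ParameterError("requested more genes than the pools provide")

    pools: dict[str, list[str]] = {}
    offset = 0
    for c in range(spec.n_clusters):
        pools[f"C{c}"] = _gene_names(spec.pool_size, offset)
        offset += spec.pool_size
    background = _gene_names(spec.background_size, offset)

    sets: list[GeneSet] = []
    labels: dict[str, int] = {}
    for c in range(spec.n_clusters):
        pool = pools[f"C{c}"]
        for m in range(spec.sets_per_cluster):
            core = rng.choice(pool, size=n_core, replace=False).tolist()
            extra = rng.choice(background, size=n_bg, replace=False).tolist()
            set_id = f"S{c:02d}_{m:02d}"
            sets.append(
                GeneSet(
                    id=set_id,
                    genes=tuple(core + extra),
                    description=f"synthetic theme {c} member {m}",
                )
            )
            labels[set_id] = c
    collection = GeneSetCollection(
        sets=tuple(sets),
        metadata={s.id: {"description": s.description} for s in sets},
    )
    return collection, labels, pools


def generate_synthetic_ppi(
    collection: GeneSetCollection,
    labels: dict[str, int],
    pools: dict[str, list[str]],
    w_in: float = 0.9,
    p_in: float = 0.3,
    w_out: float = 0.2,
    p_out: float = 0.01,
    seed: int = 0,
) -> PPINetwork:
    """Interaction network enriched within the planted gene pools.

    Every unordered pair of genes inside one cluster pool gets an edge of
    weight ``w_in`` with probability ``p_in``; every other pair of universe
    genes gets weight ``w_out`` with probability ``p_out``.
    """
    for v in (w_in, w_out):
        if not 0 <= v <= 1:
            raise ParameterError("edge weights must lie in [0, 1]")
    for v in (p_in, p_out):
        if not 0 <= v <= 1:
            raise ParameterError("edge probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    net = PPINetwork(
        provenance={
            "source": "synthetic",
            "w_in": w_in,
            "p_in": p_in,
            "w_out": w_out,
            "p_out": p_out,
            "seed": seed,
        }
    )
    pool_of: dict[str, str] = {}
    for name, genes in pools.items():
        for g in genes:
            pool_of[g] = name
    universe = sorted(collection.universe | set(pool_of))
    for i, a in enumerate(universe):
        for b in universe[i + 1 :]:
            same_pool = pool_of.get(a) is not None and pool_of.get(a) == pool_of.get(b)
            p, w = (p_in, w_in) if same_pool else (p_out, w_out)
            if p > 0 and w > 0 and rng.random() < p:
                net.add_edge(a, b, w)
    return net


def generate_toy_dag(depth: int, branching: int) -> GODag:
    """Rooted is_a tree of the given depth and branching factor.

    Term ids encode their path from the root ("T", "T.0", "T.0.1", ...), so
    the DAG is acyclic by construction.
    """
    if depth < 1 or branching < 1:
        raise ParameterError("depth and branching must be >= 1")
    dag = GODag()
    dag.add_term("T")
    frontier = ["T"]
    for _ in range(depth):
        nxt = []
        for parent in frontier:
            for b in range(branching):
                child = f"{parent}.{b}"
                dag.add_edge(child, parent, relation="is_a")
                nxt.append(child)
        frontier = nxt
    return dag


def canonical_fixture(
    ppi_seed: int | None = None,
) -> tuple[GeneSetCollection, dict[str, int], PPINetwork]:
    """The frozen default instance: planted collection + informative PPI."""
    collection, labels, pools = generate_planted_collection(default_spec())
    kwargs = dict(DEFAULT_PPI_KWARGS)
    if ppi_seed is not None:
        kwargs["seed"] = ppi_seed
    ppi = generate_synthetic_ppi(collection, labels, pools, **kwargs)
    return collection, labels, ppi
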