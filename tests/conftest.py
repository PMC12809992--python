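import pytest

from gsclust.clustering import ClusteringParams
from gsclust.distances import MetricParams, distance_matrix
from gsclust.genesets import GeneSet, GeneSetCollection
from gsclust.synthetic import canonical_fixture


@pytest.fixture(scope="session")
def canonical():
    """The frozen planted fixture: (collection, planted labels, informative PPI)."""
    return canonical_fixture()


@pytest.fixture(scope="session")
def pmm_matrix(canonical):
    collection, _, ppi = canonical
    return distance_matrix(collection, MetricParams(metric="pmm"), ppi=ppi)


@pytest.fixture(scope="session")
def planted_clustering(canonical):
    """The planted labels expressed as a partition Clustering."""
    from gsclust.clustering import Clustering

    collection, labels, _ = canonical
    k = max(labels.values()) + 1
    clusters = tuple(
        tuple(s.id for s in collection if labels[s.id] == c) for c in range(k)
    )
    return Clustering(
        clusters=clusters,
        mode="partition",
        labels=collection.ids,
        params=ClusteringParams(),
    )


@pytest.fixture
def small_collection():
    return GeneSetCollection(
        sets=(
            GeneSet(id="S1", genes=("a", "b", "c"), description="alpha beta"),
            GeneSet(id="S2", genes=("b", "c", "d"), description="beta gamma"),
            GeneSet(id="S3", genes=("x", "y"), description="other"),
        ),
        metadata={"S1": {"description": "alpha beta", "padj": 0.01}},
    )
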