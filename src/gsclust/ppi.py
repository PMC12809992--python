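"""Weighted protein-protein interaction networks.

Edge weights live in [0, 1]; STRING combined scores (0-1000) are rescaled by
``score_scale`` on load. Lookups for absent genes or pairs return exactly 0,
which makes the PPI-weighted distance degrade gracefully to its overlap-only
counterpart on sparse networks.
"""

from __future__ import annotations

import json
import logging
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .exceptions import ConnectivityError, FormatError

logger = logging.getLogger(__name__)

STRING_COLUMNS = ("protein1", "protein2", "combined_score")


@dataclass
class PPINetwork:
    """Undirected weighted gene-gene interaction graph.

    ``provenance`` records where the network came from (source, version,
    score threshold) so that distance matrices can state their inputs.
    """

    provenance: dict[str, object] = field(default_factory=dict)
    _weights: dict[frozenset[str], float] = field(default_factory=dict)
    _nodes: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._weights)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError("self-loops are not allowed")
        if not 0.0 <= weight <= 1.0:
            raise ValueError(f"weight {weight} outside [0, 1]")
        key = frozenset((a, b))
        # duplicate pairs keep the strongest evidence
        self._weights[key] = max(weight, self._weights.get(key, 0.0))
        self._nodes.update((a, b))

    def weight(self, a: str, b: str) -> float:
        """Edge weight between ``a`` and ``b``; 0 for absent pairs/nodes."""
        if a == b:
            return 0.0
        return self._weights.get(frozenset((a, b)), 0.0)

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for key, w in self._weights.items():
            a, b = sorted(key)
            yield a, b, w

    def max_weight_to_set(self, gene: str, target: Iterable[str]) -> float:
        """Strongest interaction between ``gene`` and any member of ``target``.

        Returns 0 when the gene is absent from the network, the target is
        empty, or no edge exists (the vacuous-max convention).
        """
        if gene not in self._nodes:
            return 0.0
        best = 0.0
        for t in target:
            w = self.weight(gene, t)
            if w > best:
                best = w
        return best


def max_weight_to_set(ppi: PPINetwork, gene: str, target: Iterable[str]) -> float:
    """Module-level alias for :meth:`PPINetwork.max_weight_to_set`."""
    return ppi.max_weight_to_set(gene, target)


def network_from_frame(
    frame: pd.DataFrame, score_scale: float = 1000.0, provenance: dict | None = None
) -> PPINetwork:
    if frame.shape[1] < 3:
        raise FormatError("PPI table needs two identifier columns and a score column")
    if frame.empty:
        raise FormatError("PPI table has no rows")
    net = PPINetwork(provenance=dict(provenance or {}))
    self_loops = 0
    cols = list(frame.columns[:3])
    for row_number, (a, b, score) in enumerate(
        frame[cols].itertuples(index=False), start=1
    ):
        try:
            s = float(score)
        except (TypeError, ValueError):
            raise FormatError(
                f"non-numeric interaction score {score!r} at row {row_number}"
            ) from None
        a, b = str(a), str(b)
        if a == b:
            self_loops += 1
            continue
        w = min(max(s / score_scale, 0.0), 1.0)
        net.add_edge(a, b, w)
    if self_loops:
        logger.warning("dropped %d self-interaction row(s)", self_loops)
    net.provenance.setdefault("score_scale", score_scale)
    net.provenance["self_loops_dropped"] = self_loops
    return net


def load_ppi_edges(
    path: str | Path,
    score_scale: float = 1000.0,
    provenance: dict | None = None,
) -> PPINetwork:
    """Load a 3-column edge table (STRING detailed-scores dialect or generic).

    Scores are divided by ``score_scale`` (default 1000, the STRING
    combined-score convention) and clamped to [0, 1]. Duplicate pairs are
    collapsed keeping the maximum weight; self-pairs are dropped and counted.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python")
    prov = {"source": str(path)}
    prov.update(provenance or {})
    return network_from_frame(frame, score_scale=score_scale, provenance=prov)


def write_ppi_edges(net: PPINetwork, path: str | Path) -> None:
    rows = sorted(net.edges())
    frame = pd.DataFrame(rows, columns=["protein1", "protein2", "weight"])
    frame.to_csv(path, sep="\t", index=False)


_STRING_URL = (
    "https://stringdb-downloads.org/download/protein.links.v{version}/"
    "{taxon}.protein.links.v{version}.txt.gz"
)


def fetch_interactions(
    taxon: int,
    version: str,
    score_threshold: int,
    cache_dir: str | Path,
    timeout: float = 60.0,
) -> PPINetwork:
    """Fetch a STRING interaction table, caching it locally.

    The first call downloads and writes a TSV cache plus a JSON provenance
    sidecar under ``cache_dir``; later calls with the same (taxon, version,
    threshold) read the cache without touching the network. Offline with a
    cold cache raises :class:`ConnectivityError` naming the cache file to
    pre-populate.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    stem = f"string_{taxon}_v{version}_min{score_threshold}"
    cache_file = cache_dir / f"{stem}.tsv"
    sidecar = cache_dir / f"{stem}.json"
    provenance = {
        "source": "STRING",
        "taxon": taxon,
        "version": version,
        "score_threshold": score_threshold,
    }
    if not cache_file.exists():
        url = _STRING_URL.format(version=version, taxon=taxon)
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                payload = resp.read()
        except (urllib.error.URLError, OSError) as exc:
            raise ConnectivityError(
                f"cannot download STRING interactions and no cache at {cache_file}; "
                "pre-populate that file (columns protein1, protein2, combined_score) "
                "to run offline"
            ) from exc
        import gzip
        import io

        text = gzip.decompress(payload).decode()
        frame = pd.read_csv(io.StringIO(text), sep=r"\s+")
        frame = frame[frame.iloc[:, 2] >= score_threshold]
        frame.to_csv(cache_file, sep="\t", index=False)
        sidecar.write_text(json.dumps(provenance, indent=1, sort_keys=True))
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    provenance["cache_file"] = str(cache_file)
    return load_ppi_edges(cache_file, provenance=provenance)
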