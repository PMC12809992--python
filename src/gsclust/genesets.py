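"""Gene sets and gene-set collections: reading, conversion, filtering, writing.

The central input contract is a table with two columns named ``Genesets``
and ``Genes``: one row per gene set, genes concatenated with a delimiter.
Outputs of common enrichment tools (topGO, clusterProfiler, ReactomePA,
enrichR, fgsea) are normalized onto the same contract by
:func:`convert_enrichment_output`. Collections round-trip through GMT and
JSON and can be size-filtered before distance computation.

Gene identifiers are opaque, case-sensitive strings; no identifier mapping
is attempted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .exceptions import FormatError, ParameterError

logger = logging.getLogger(__name__)

#: Auto-detection order for gene delimiters. First delimiter that splits a
#: majority of rows into >1 token wins; an explicit argument overrides.
DELIMITER_CANDIDATES = (",", "/", ";", None)  # None = any whitespace

GENESETS_COLUMN = "Genesets"
GENES_COLUMN = "Genes"


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene identifiers.

    Parameters
    ----------
    id:
        Non-empty identifier, unique within a collection (e.g. a GO term id).
    genes:
        Ordered unique gene identifiers; at least one, none empty.
    description:
        Optional free-text label (e.g. the GO term name).
    """

    id: str
    genes: tuple[str, ...]
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("gene set id must be a non-empty string")
        if not self.genes:
            raise FormatError(f"gene set {self.id!r} has no genes")
        if any(not g for g in self.genes):
            raise FormatError(f"gene set {self.id!r} contains an empty gene identifier")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"gene set {self.id!r} contains duplicate genes")
        object.__setattr__(self, "genes", tuple(self.genes))

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of :class:`GeneSet` with per-set metadata.

    ``metadata`` maps set ids to records of extra columns carried along from
    the source table (description, adjusted p-value, ...); keys are always a
    subset of the member ids. ``universe`` is derived: the exact union of
    all member gene lists.
    """

    sets: tuple[GeneSet, ...]
    metadata: dict[str, dict[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = tuple(self.sets)
        ids = [s.id for s in self.sets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate gene set ids: {dupes}")
        extra = set(self.metadata) - set(ids)
        if extra:
            raise FormatError(f"metadata keys not matching any set id: {sorted(extra)}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sets)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.genes)
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.id == set_id:
                return s
        raise KeyError(set_id)

    def subset(self, ids: Iterable[str]) -> "GeneSetCollection":
        """Collection restricted to ``ids``, preserving the original order."""
        keep = set(ids)
        sets = tuple(s for s in self.sets if s.id in keep)
        meta = {s.id: dict(self.metadata[s.id]) for s in sets if s.id in self.metadata}
        return GeneSetCollection(sets=sets, metadata=meta)


def _split_genes(raw: object, delimiter: str | None) -> list[str]:
    text = "" if raw is None or (isinstance(raw, float) and math.isnan(raw)) else str(raw)
    tokens = text.split() if delimiter is None else text.split(delimiter)
    return [t.strip() for t in tokens if t.strip()]


def _detect_delimiter(values: Sequence[object]) -> str | None:
    for cand in DELIMITER_CANDIDATES:
        multi = sum(1 for v in values if len(_split_genes(v, cand)) > 1)
        if multi > len(values) / 2:
            return cand
    return None  # whitespace split is the safe fallback (single-token rows)


def _dedupe(genes: Sequence[str], set_id: str) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    dropped = 0
    for g in genes:
        if g in seen:
            dropped += 1
        else:
            seen.add(g)
            out.append(g)
    if dropped:
        logger.warning("gene set %r: dropped %d duplicate gene(s)", set_id, dropped)
    return out


def collection_from_frame(
    frame: pd.DataFrame, gene_delimiter: str | None = None
) -> GeneSetCollection:
    """Build a collection from a ``Genesets``/``Genes`` data frame.

    Non-required columns are preserved as per-set metadata. Rows whose gene
    list is empty after parsing are dropped with a warning.
    """
    for col in (GENESETS_COLUMN, GENES_COLUMN):
        if col not in frame.columns:
            raise FormatError(f"required column {col!r} is missing")
    if frame.empty:
        raise FormatError("input table has no rows")

    delim = gene_delimiter
    if delim is None:
        delim = _detect_delimiter(list(frame[GENES_COLUMN]))

    extra_cols = [c for c in frame.columns if c not in (GENESETS_COLUMN, GENES_COLUMN)]
    sets: list[GeneSet] = []
    metadata: dict[str, dict[str, object]] = {}
    for _, row in frame.iterrows():
        set_id = str(row[GENESETS_COLUMN]).strip()
        genes = _dedupe(_split_genes(row[GENES_COLUMN], delim), set_id)
        if not genes:
            logger.warning("dropping empty gene set %r", set_id)
            continue
        meta = {c: row[c] for c in extra_cols if not pd.isna(row[c])}
        description = meta.get("description")
        sets.append(
            GeneSet(
                id=set_id,
                genes=tuple(genes),
                description=str(description) if description is not None else None,
            )
        )
        if meta:
            metadata[set_id] = meta
    if not sets:
        raise FormatError("no non-empty gene sets in the input table")
    return GeneSetCollection(sets=tuple(sets), metadata=metadata)


def read_geneset_table(
    path: str | Path, gene_delimiter: str | None = None
) -> GeneSetCollection:
    """Read a delimited table with ``Genesets`` and ``Genes`` columns.

    The table separator (comma vs tab) is sniffed by pandas; the
    gene-delimiter inside the ``Genes`` column is auto-detected unless given.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path} is empty")
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    return collection_from_frame(frame, gene_delimiter=gene_delimiter)


def write_geneset_table(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to the two-column contract (TSV, ',' genes)."""
    rows = []
    for s in collection:
        row: dict[str, object] = {
            GENESETS_COLUMN: s.id,
            GENES_COLUMN: ",".join(s.genes),
        }
        row.update(collection.metadata.get(s.id, {}))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- converters --------------------------------------------------------------

#: source tool -> (id column, genes column, gene delimiter, metadata column map)
_CONVERTER_MAPS: dict[str, dict[str, object]] = {
    "clusterprofiler": {
        "id": "ID",
        "genes": "geneID",
        "delim": "/",
        "meta": {"Description": "description", "p.adjust": "padj"},
    },
    "reactomepa": {
        "id": "ID",
        "genes": "geneID",
        "delim": "/",
        "meta": {"Description": "description", "p.adjust": "padj"},
    },
    "fgsea": {
        "id": "pathway",
        "genes": "leadingEdge",
        "delim": None,  # auto-detect: leadingEdge serializations vary
        "meta": {"padj": "padj"},
    },
    "enrichr": {
        "id": "Term",
        "genes": "Genes",
        "delim": ";",
        "meta": {"Adjusted.P.value": "padj"},
    },
    "topgo": {
        "id": "GO.ID",
        "genes": None,  # topGO summary tables carry no gene lists
        "delim": None,
        "meta": {"Term": "description"},
    },
}

SUPPORTED_TOOLS = tuple(sorted(_CONVERTER_MAPS))


def convert_enrichment_output(
    table: pd.DataFrame,
    source_tool: str,
    gene_map: Mapping[str, Sequence[str]] | None = None,
) -> GeneSetCollection:
    """Normalize a tool-specific enrichment table to the Genesets/Genes contract.

    Parameters
    ----------
    table:
        Raw result table with the tool's documented column names.
    source_tool:
        One of ``topgo``, ``clusterprofiler``, ``reactomepa``, ``enrichr``,
        ``fgsea``.
    gene_map:
        Required for ``topgo`` only: mapping from term id to its gene list,
        because topGO summary tables do not include per-term genes.
    """
    tool = source_tool.lower()
    if tool not in _CONVERTER_MAPS:
        raise ParameterError(
            f"unknown source tool {source_tool!r}; supported: {', '.join(SUPPORTED_TOOLS)}"
        )
    spec = _CONVERTER_MAPS[tool]
    id_col = spec["id"]
    if id_col not in table.columns:
        raise FormatError(f"{tool} output must contain column {id_col!r}")

    out = pd.DataFrame()
    out[GENESETS_COLUMN] = table[id_col].astype(str)
    if tool == "topgo":
        if gene_map is None:
            raise ParameterError(
                "topgo conversion requires gene_map (term id -> gene list): "
                "topGO summary tables carry no gene lists"
            )
        missing = [t for t in out[GENESETS_COLUMN] if t not in gene_map]
        if missing:
            raise FormatError(f"gene_map lacks entries for terms: {missing}")
        out[GENES_COLUMN] = [",".join(gene_map[t]) for t in out[GENESETS_COLUMN]]
        delim: str | None = ","
    else:
        genes_col = spec["genes"]
        if genes_col not in table.columns:
            raise FormatError(f"{tool} output must contain column {genes_col!r}")
        raw = table[genes_col]
        # fgsea leadingEdge may arrive as actual lists when built in memory
        out[GENES_COLUMN] = [
            ",".join(str(g) for g in v) if isinstance(v, (list, tuple)) else v
            for v in raw
        ]
        delim = "," if any(isinstance(v, (list, tuple)) for v in raw) else spec["delim"]

    for src, dst in spec["meta"].items():
        if src in table.columns:
            out[dst] = table[src].values
    return collection_from_frame(out, gene_delimiter=delim)


# --- filtering ----------------------------------------------------------------


def filter_by_size(
    collection: GeneSetCollection,
    min_size: int = 0,
    max_size: int | float = math.inf,
) -> GeneSetCollection:
    """Keep only sets with ``min_size <= |genes| <= max_size`` (inclusive).

    Removing all sets with 200 or more genes is expressed as
    ``max_size=199``. Metadata and ordering of survivors are preserved and
    the universe is recomputed.
    """
    if min_size > max_size:
        raise ParameterError(f"min_size ({min_size}) exceeds max_size ({max_size})")
    keep = [s.id for s in collection if min_size <= len(s) <= max_size]
    if not keep:
        raise ParameterError(
            f"size filter [{min_size}, {max_size}] removed every gene set; "
            "revise the thresholds"
        )
    return collection.subset(keep)


# --- GMT ----------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, genes...)."""
    sets: list[GeneSet] = []
    metadata: dict[str, dict[str, object]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, description, *genes = fields
            clean = [g.strip() for g in genes]
            if any(not g for g in clean):
                logger.warning("%s:%d: dropped empty gene token(s)", path, lineno)
                clean = [g for g in clean if g]
            clean = _dedupe(clean, name)
            if not clean:
                logger.warning("dropping empty gene set %r", name)
                continue
            desc = None if description in ("", "NA") else description
            sets.append(GeneSet(id=name, genes=tuple(clean), description=desc))
            if desc is not None:
                metadata[name] = {"description": desc}
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(sets=tuple(sets), metadata=metadata)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; missing descriptions become ``NA``."""
    with open(path, "w") as fh:
        for s in collection:
            desc = s.description if s.description else "NA"
            fh.write("\t".join([s.id, desc, *s.genes]) + "\n")


# --- JSON ---------------------------------------------------------------------


def collection_to_json(collection: GeneSetCollection, path: str | Path) -> None:
    payload = {
        "sets": [
            {"id": s.id, "description": s.description, "genes": list(s.genes)}
            for s in collection
        ],
        "metadata": {
            k: {c: _jsonable(v) for c, v in rec.items()}
            for k, rec in collection.metadata.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def collection_from_json(path: str | Path) -> GeneSetCollection:
    payload = json.loads(Path(path).read_text())
    sets = tuple(
        GeneSet(id=rec["id"], genes=tuple(rec["genes"]), description=rec["description"])
        for rec in payload["sets"]
    )
    return GeneSetCollection(sets=sets, metadata=payload.get("metadata", {}))


def _jsonable(v: object) -> object:
    try:
        json.dumps(v)
        return v
    except TypeError:
        return str(v)
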