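"""Self-contained HTML session reports.

The report documents an exploration session: the input collection, every
parameter chosen (metric, alpha, thresholds, seeds), the distance heatmap,
the cluster graph, the cluster membership table and any highlighted genes
or gene sets. Figures are embedded as base64 PNG so the single file can be
shared as-is; with the timestamp disabled, rendering is byte-reproducible.
"""

from __future__ import annotations

import base64
import datetime
import io
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
from jinja2 import Template

from .clustering import Clustering, build_threshold_graph
from .distances import DistanceMatrix
from .exceptions import ParameterError
from .genesets import GeneSetCollection
from .summarize import build_bipartite_graph, order_for_heatmap, reorder_matrix

_LINK_TEMPLATES = (
    ("GO:", "https://amigo.geneontology.org/amigo/term/{id}"),
    ("R-", "https://reactome.org/content/detail/{id}"),
    ("map", "https://www.kegg.jp/entry/{id}"),
)


def external_link(set_id: str) -> str | None:
    """Static database hyperlink inferred from an id prefix, if any."""
    for prefix, template in _LINK_TEMPLATES:
        if set_id.startswith(prefix):
            return template.format(id=set_id)
    return None


@dataclass
class SessionRecord:
    """Everything needed to render a report of one exploration session."""

    collection: GeneSetCollection
    distance: DistanceMatrix
    clustering: Clustering
    input_descriptor: dict = field(default_factory=dict)
    highlighted: tuple[str, ...] = ()
    artifacts: dict[str, str] = field(default_factory=dict)
    timestamp: str | None = None

    def parameter_table(self) -> list[tuple[str, str]]:
        rows = [("distance metric", self.distance.params.metric)]
        rows += [
            (f"distance {k}", str(v))
            for k, v in self.distance.params.to_jsonable().items()
            if k != "metric"
        ]
        rows += [
            (f"clustering {k}", str(v))
            for k, v in self.clustering.params.to_jsonable().items()
        ]
        return rows


def _fig_to_base64(fig) -> str:
    buf = io.BytesIO()
    # empty metadata keeps the PNG byte-stable across matplotlib runs
    fig.savefig(buf, format="png", dpi=100, metadata={"Software": None})
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def _heatmap_png(dm: DistanceMatrix) -> str:
    order = order_for_heatmap(dm)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(reorder_matrix(dm, order), cmap="viridis", vmin=0, vmax=1)
    ax.set_title(f"pairwise {dm.params.metric} distance")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="distance")
    return _fig_to_base64(fig)


def _cluster_graph_png(dm: DistanceMatrix, clustering: Clustering) -> str:
    graph = build_threshold_graph(dm, clustering.params.tau)
    memb: dict[str, int] = {}
    for idx, members in enumerate(clustering.clusters):
        for m in members:
            memb.setdefault(m, idx)
    pos = nx.spring_layout(graph, seed=0)
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = [memb.get(n, -1) for n in graph.nodes]
    nx.draw_networkx(
        graph,
        pos=pos,
        ax=ax,
        node_color=colors,
        cmap="tab20",
        node_size=80,
        with_labels=False,
        width=0.5,
    )
    ax.set_axis_off()
    ax.set_title(f"threshold graph (tau={clustering.params.tau}), colored by cluster")
    return _fig_to_base64(fig)


_TEMPLATE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>gene-set clustering session report</title>
<style>
body { font-family: sans-serif; margin: 2em; max-width: 70em; }
table { border-collapse: collapse; margin: 1em 0; }
td, th { border: 1px solid #999; padding: 0.3em 0.6em; text-align: left; }
.missing { color: #a00; }
</style></head>
<body>
<h1>Gene-set clustering session report</h1>
{% if timestamp %}<p>Generated: {{ timestamp }}</p>{% endif %}

<h2>Input</h2>
<table>
{% for key, value in input_rows %}<tr><th>{{ key }}</th><td>{{ value }}</td></tr>
{% endfor %}
</table>

<h2>Parameters</h2>
<table>
{% for key, value in parameter_rows %}<tr><th>{{ key }}</th><td>{{ value }}</td></tr>
{% endfor %}
</table>

<h2>Distance heatmap</h2>
<img src="data:image/png;base64,{{ heatmap }}" alt="distance heatmap">

<h2>Cluster graph</h2>
<img src="data:image/png;base64,{{ cluster_graph }}" alt="cluster graph">

<h2>Cluster membership</h2>
<table>
<tr><th>cluster</th><th>size</th><th>members</th></tr>
{% for idx, size, members in cluster_rows %}
<tr><td>{{ idx }}</td><td>{{ size }}</td><td>{{ members }}</td></tr>
{% endfor %}
</table>

<h2>Highlighted items</h2>
{% if highlight_rows %}
<table>
<tr><th>id</th><th>status</th></tr>
{% for hid, status, cls in highlight_rows %}
<tr><td>{{ hid }}</td><td class="{{ cls }}">{{ status }}</td></tr>
{% endfor %}
</table>
{% else %}<p>none</p>{% endif %}

<h2>Input gene sets</h2>
<table>
<tr><th>id</th><th>description</th><th>size</th><th>link</th></tr>
{% for sid, desc, size, link in set_rows %}
<tr><td>{{ sid }}</td><td>{{ desc }}</td><td>{{ size }}</td>
<td>{% if link %}<a href="{{ link }}">{{ link }}</a>{% endif %}</td></tr>
{% endfor %}
</table>
</body></html>
"""
)


def render_report(session: SessionRecord, out_path: str | Path) -> Path:
    """Render a session into one self-contained HTML file.

    Raises when a referenced artifact path does not exist; highlighted ids
    absent from the input are annotated rather than fatal. With
    ``session.timestamp`` left as None the output is byte-identical across
    runs.
    """
    for name, p in session.artifacts.items():
        if not Path(p).exists():
            raise ParameterError(f"referenced artifact {name!r} is missing: {p}")

    known = set(session.collection.ids) | set(session.collection.universe)
    highlight_rows = []
    for hid in session.highlighted:
        if hid in known:
            highlight_rows.append((hid, "present in input", ""))
        else:
            highlight_rows.append((hid, "not found in input", "missing"))

    input_rows = list(session.input_descriptor.items())
    input_rows.append(("gene sets", len(session.collection)))
    input_rows.append(("gene universe", len(session.collection.universe)))
    input_rows += [(f"artifact: {k}", v) for k, v in sorted(session.artifacts.items())]

    html = _TEMPLATE.render(
        timestamp=session.timestamp,
        input_rows=input_rows,
        parameter_rows=session.parameter_table(),
        heatmap=_heatmap_png(session.distance),
        cluster_graph=_cluster_graph_png(session.distance, session.clustering),
        cluster_rows=[
            (idx, len(members), ", ".join(members))
            for idx, members in enumerate(session.clustering.clusters)
        ],
        highlight_rows=highlight_rows,
        set_rows=[
            (s.id, s.description or "", len(s), external_link(s.id))
            for s in session.collection
        ],
    )
    out_path = Path(out_path)
    out_path.write_text(html)
    return out_path


def now_timestamp() -> str:
    return datetime.datetime.now().isoformat(timespec="seconds")
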