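"""Plot-ready datasets and renderers for enrichment results.

Each visualization is split into two stages: a pure *data* builder that
turns an :class:`~koenrich.enrichment.EnrichmentTable` into a serializable
:class:`PlotDataset` (testable against golden payloads, reproducible given
the layout seed), and :func:`render`, which draws the dataset with
matplotlib and writes a static PNG and/or a self-contained interactive-free
HTML document embedding the image and the payload JSON.  KGML pathway
diagrams are painted directly from KEGG's pathway XML, with enriched KO
nodes filled red.
"""

from __future__ import annotations

import base64
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from lxml import etree
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotation_io import normalize_ko
from .enrichment import EnrichmentTable
from .pathway_map import Term2Gene

__all__ = [
    "PlotDataset",
    "KGMLFormatError",
    "bar_lollipop_data",
    "heatmap_matrix",
    "treeplot_clustering",
    "cnet_graph",
    "upset_intersections",
    "pubmed_trend_data",
    "highlight_kgml",
    "render",
]

DEFAULT_TOP_N = 20
DEFAULT_LAYOUT_SEED = 0


class KGMLFormatError(ValueError):
    """The KGML file is not well-formed pathway XML."""


@dataclass
class PlotDataset:
    """One visualization's data: kind tag, payload, and styling context."""

    kind: str
    payload: dict
    styling: dict = field(default_factory=dict)

    def to_json(self) -> str:
        """Canonical serialization used for golden/determinism tests."""
        return json.dumps(
            {"kind": self.kind, "payload": self.payload, "styling": self.styling},
            sort_keys=True,
            separators=(",", ":"),
        )


def _styling(table: EnrichmentTable, by: str, extra: dict | None = None) -> dict:
    alpha = table.thresholds.get("alpha_padj" if by == "padj" else "alpha_p", 0.05)
    out = {"by": by, "alpha": alpha}
    if extra:
        out.update(extra)
    return out


def bar_lollipop_data(
    table: EnrichmentTable,
    top_n: int = DEFAULT_TOP_N,
    *,
    kind: str = "barplot",
    by: str = "padj",
) -> PlotDataset:
    """Top-n pathways with -log10(adjusted p), fold enrichment and gene count."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if kind not in ("barplot", "lollipop"):
        raise ValueError(f"kind must be 'barplot' or 'lollipop', got {kind!r}")
    records = [
        {
            "pathway_id": r.pathway_id,
            "pathway_name": r.pathway_name,
            "neg_log10_padj": -float(np.log10(r.p_adjusted)),
            "fold_enrichment": r.fold_enrichment,
            "count": r.k,
        }
        for r in table.records[:top_n]
    ]
    return PlotDataset(kind=kind, payload={"records": records}, styling=_styling(table, by))


def heatmap_matrix(table: EnrichmentTable, *, by: str = "padj") -> PlotDataset:
    """Binary gene x pathway membership matrix over the table's records."""
    if not table.records:
        raise ValueError("heatmap requires at least one record")
    pathways = [r.pathway_id for r in table.records]
    genes = sorted({g for r in table.records for g in r.genes})
    gene_index = {g: i for i, g in enumerate(genes)}
    matrix = [[0] * len(pathways) for _ in genes]
    for j, r in enumerate(table.records):
        for g in r.genes:
            matrix[gene_index[g]][j] = 1
    payload = {
        "genes": genes,
        "pathways": pathways,
        "pathway_names": [r.pathway_name for r in table.records],
        "matrix": matrix,
    }
    return PlotDataset(kind="heatmap", payload=payload, styling=_styling(table, by))


def treeplot_clustering(table: EnrichmentTable, *, by: str = "padj") -> PlotDataset:
    """Average-linkage dendrogram of terms under 1 - Jaccard gene-set distance."""
    if len(table.records) < 2:
        raise ValueError("not enough terms: treeplot needs at least 2 records")
    sets = [frozenset(r.genes) for r in table.records]
    m = len(sets)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            union = len(sets[i] | sets[j])
            jac = len(sets[i] & sets[j]) / union if union else 1.0
            dist[i, j] = dist[j, i] = 1.0 - jac
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    payload = {
        "labels": [r.pathway_name for r in table.records],
        "pathway_ids": [r.pathway_id for r in table.records],
        "merges": [
            [int(a), int(b), round(float(h), 12), int(c)]
            for a, b, h, c in linkage.tolist()
        ],
    }
    return PlotDataset(kind="treeplot", payload=payload, styling=_styling(table, by))


def cnet_graph(
    table: EnrichmentTable,
    top_n: int = DEFAULT_TOP_N,
    *,
    seed: int = DEFAULT_LAYOUT_SEED,
    by: str = "padj",
) -> PlotDataset:
    """Bipartite pathway-gene network with a seeded force-directed layout."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    records = table.records[:top_n]
    graph = nx.Graph()
    for r in records:
        graph.add_node(r.pathway_id, kind="pathway", size=r.k, label=r.pathway_name)
        for g in r.genes:
            graph.add_node(g, kind="gene", size=1, label=g)
            graph.add_edge(r.pathway_id, g)
    pos = nx.spring_layout(graph, seed=seed) if graph.number_of_nodes() else {}
    payload = {
        "nodes": [
            {
                "id": node,
                "type": data["kind"],
                "size": data["size"],
                "label": data["label"],
            }
            for node, data in sorted(graph.nodes(data=True))
        ],
        "edges": sorted([sorted(e) for e in graph.edges()]),
        "positions": {
            node: [round(float(x), 6), round(float(y), 6)]
            for node, (x, y) in sorted(pos.items())
        },
        "layout_seed": seed,
    }
    return PlotDataset(kind="cnet", payload=payload, styling=_styling(table, by))


def upset_intersections(
    table: EnrichmentTable, top_n: int = DEFAULT_TOP_N, *, by: str = "padj"
) -> PlotDataset:
    """Exclusive intersection pattern counts over the top-n pathways' gene sets.

    Standard UpSet semantics: each gene is counted in exactly one pattern,
    the full combination of sets that contain it, so pattern counts
    partition the union of the gene sets.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    records = table.records[:top_n]
    sets = {r.pathway_id: frozenset(r.genes) for r in records}
    pattern_counts: dict[tuple[str, ...], int] = {}
    for gene in sorted({g for s in sets.values() for g in s}):
        pattern = tuple(sorted(pid for pid, s in sets.items() if gene in s))
        pattern_counts[pattern] = pattern_counts.get(pattern, 0) + 1
    patterns = [
        {"sets": list(p), "count": c}
        for p, c in sorted(
            pattern_counts.items(), key=lambda item: (-item[1], item[0])
        )
    ]
    payload = {
        "set_ids": [r.pathway_id for r in records],
        "set_names": [r.pathway_name for r in records],
        "set_sizes": {pid: len(s) for pid, s in sorted(sets.items())},
        "patterns": patterns,
    }
    return PlotDataset(kind="upset", payload=payload, styling=_styling(table, by))


def pubmed_trend_data(
    term_to_year_counts: Mapping[str, Mapping[int, int]]
) -> PlotDataset:
    """Publication-count time series per term; counts are injected by the
    caller (this module never touches the network).  Missing years stay
    missing so renderers draw gaps, not zeros."""
    series = {}
    for term in sorted(term_to_year_counts):
        counts = term_to_year_counts[term]
        for year, c in counts.items():
            if c < 0:
                raise ValueError(
                    f"negative publication count for {term!r} in {year}"
                )
        series[term] = [[int(y), int(counts[y])] for y in sorted(counts)]
    return PlotDataset(kind="pubmed_trend", payload={"series": series})


# --------------------------------------------------------------------------
# KGML pathway diagrams


def _parse_kgml(path: Path) -> list[dict]:
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise KGMLFormatError(f"cannot parse KGML {path}: {exc}") from exc
    entries = []
    for entry in tree.getroot().iter("entry"):
        graphics = entry.find("graphics")
        if graphics is None:
            continue
        kos = set()
        for token in (entry.get("name") or "").split():
            if token.lower().startswith("ko:"):
                try:
                    kos.add(normalize_ko(token))
                except ValueError:
                    continue
        try:
            geom = {
                "x": float(graphics.get("x")),
                "y": float(graphics.get("y")),
                "w": float(graphics.get("width", 46)),
                "h": float(graphics.get("height", 17)),
            }
        except (TypeError, ValueError):
            continue
        entries.append(
            {
                "kos": kos,
                "label": (graphics.get("name") or "").split(",")[0],
                "shape": graphics.get("type", "rectangle"),
                **geom,
            }
        )
    if not entries:
        raise KGMLFormatError(
            f"cannot render {path}: KGML has no graphics blocks"
        )
    return entries


def highlight_kgml(
    kgml_path: str | Path,
    enriched_genes: Iterable[str],
    t2g_provenance: Term2Gene | Mapping[tuple[str, str], set[str]],
    out_path: str | Path,
    format: str = "png",
) -> int:
    """Render a pathway diagram from KGML, filling enriched KO nodes red.

    An entry is highlighted when its KO set intersects the KOs carried by
    the enriched genes (taken from the term2gene provenance).  Returns the
    number of highlighted entries.
    """
    if format not in ("png", "svg"):
        raise ValueError(f"format must be 'png' or 'svg', got {format!r}")
    provenance = (
        t2g_provenance.provenance
        if isinstance(t2g_provenance, Term2Gene)
        else t2g_provenance
    )
    enriched = set(enriched_genes)
    enriched_kos: set[str] = set()
    for (pid, gene), kos in provenance.items():
        if gene in enriched:
            enriched_kos.update(kos)

    entries = _parse_kgml(Path(kgml_path))
    width = max(e["x"] + e["w"] for e in entries) + 40
    height = max(e["y"] + e["h"] for e in entries) + 40
    fig, ax = plt.subplots(figsize=(max(width / 96, 4), max(height / 96, 3)))
    highlighted = 0
    for e in entries:
        hit = bool(e["kos"] & enriched_kos)
        if hit:
            highlighted += 1
        face = "#d62728" if hit else "#c7e9c0"
        rect = plt.Rectangle(
            (e["x"] - e["w"] / 2, e["y"] - e["h"] / 2),
            e["w"],
            e["h"],
            facecolor=face,
            edgecolor="black",
            linewidth=0.5,
        )
        ax.add_patch(rect)
        if e["label"]:
            ax.text(
                e["x"],
                e["y"],
                e["label"],
                ha="center",
                va="center",
                fontsize=5,
                color="white" if hit else "black",
            )
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # KGML origin is top-left
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(str(out_path), format=format, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return highlighted


# --------------------------------------------------------------------------
# Rendering


def _empty_axes(ax, message: str) -> None:
    ax.text(0.5, 0.5, message, ha="center", va="center", transform=ax.transAxes)
    ax.axis("off")


def _fig_barplot(ds: PlotDataset):
    fig, ax = plt.subplots(figsize=(8, 6))
    records = ds.payload["records"]
    if not records:
        _empty_axes(ax, "no pathways pass the significance filter")
        return fig
    names = [r["pathway_name"] for r in records][::-1]
    vals = [r["neg_log10_padj"] for r in records][::-1]
    ax.barh(names, vals, color="#1f77b4")
    ax.set_xlabel("-log10(adjusted P)")
    ax.set_title("Enriched pathways")
    fig.tight_layout()
    return fig


def _fig_lollipop(ds: PlotDataset):
    fig, ax = plt.subplots(figsize=(8, 6))
    records = ds.payload["records"]
    if not records:
        _empty_axes(ax, "no pathways pass the significance filter")
        return fig
    names = [r["pathway_name"] for r in records][::-1]
    folds = [r["fold_enrichment"] for r in records][::-1]
    sizes = [20 + 8 * r["count"] for r in records][::-1]
    ax.hlines(range(len(names)), 0, folds, color="grey", linewidth=1)
    ax.scatter(folds, range(len(names)), s=sizes, color="#d62728", zorder=3)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("fold enrichment")
    ax.set_title("Enriched pathways")
    fig.tight_layout()
    return fig


def _fig_heatmap(ds: PlotDataset):
    matrix = np.asarray(ds.payload["matrix"])
    fig, ax = plt.subplots(figsize=(8, 6))
    if matrix.size == 0:
        _empty_axes(ax, "empty membership matrix")
        return fig
    ax.imshow(matrix, aspect="auto", cmap="Blues", interpolation="nearest")
    ax.set_xticks(range(len(ds.payload["pathways"])))
    ax.set_xticklabels(ds.payload["pathway_names"], rotation=90, fontsize=6)
    ax.set_yticks(range(len(ds.payload["genes"])))
    ax.set_yticklabels(ds.payload["genes"], fontsize=5)
    ax.set_title("Gene membership across enriched pathways")
    fig.tight_layout()
    return fig


def _fig_treeplot(ds: PlotDataset):
    fig, ax = plt.subplots(figsize=(8, 6))
    linkage = np.asarray(ds.payload["merges"], dtype=float)
    hierarchy.dendrogram(
        linkage, labels=ds.payload["labels"], orientation="left", ax=ax
    )
    ax.set_xlabel("1 - Jaccard distance (average linkage)")
    ax.set_title("Hierarchical clustering of enriched terms")
    fig.tight_layout()
    return fig


def _fig_cnet(ds: PlotDataset):
    fig, ax = plt.subplots(figsize=(8, 8))
    nodes = ds.payload["nodes"]
    if not nodes:
        _empty_axes(ax, "no pathways pass the significance filter")
        return fig
    graph = nx.Graph()
    for node in nodes:
        graph.add_node(node["id"], **node)
    graph.add_edges_from(ds.payload["edges"])
    pos = {n: xy for n, xy in ds.payload["positions"].items()}
    pw = [n["id"] for n in nodes if n["type"] == "pathway"]
    genes = [n["id"] for n in nodes if n["type"] == "gene"]
    sizes = {n["id"]: n["size"] for n in nodes}
    nx.draw_networkx_edges(graph, pos, ax=ax, alpha=0.4)
    nx.draw_networkx_nodes(
        graph, pos, nodelist=genes, node_size=30, node_color="#2ca02c", ax=ax
    )
    nx.draw_networkx_nodes(
        graph,
        pos,
        nodelist=pw,
        node_size=[120 + 40 * sizes[p] for p in pw],
        node_color="#ff7f0e",
        ax=ax,
    )
    nx.draw_networkx_labels(
        graph, pos, labels={p: graph.nodes[p]["label"] for p in pw}, font_size=7, ax=ax
    )
    ax.set_title("Pathway-gene network")
    ax.axis("off")
    return fig


def _fig_upset(ds: PlotDataset):
    patterns = ds.payload["patterns"]
    set_ids = ds.payload["set_ids"]
    fig = plt.figure(figsize=(9, 6))
    if not patterns:
        ax = fig.add_subplot(111)
        _empty_axes(ax, "no pathways pass the significance filter")
        return fig
    gs = fig.add_gridspec(2, 1, height_ratios=[2, 1], hspace=0.05)
    ax_bar = fig.add_subplot(gs[0])
    ax_dot = fig.add_subplot(gs[1], sharex=ax_bar)
    xs = range(len(patterns))
    ax_bar.bar(xs, [p["count"] for p in patterns], color="#1f77b4")
    ax_bar.set_ylabel("exclusive intersection size")
    plt.setp(ax_bar.get_xticklabels(), visible=False)
    for x, p in enumerate(patterns):
        members = set(p["sets"])
        for y, sid in enumerate(set_ids):
            filled = sid in members
            ax_dot.plot(
                x,
                y,
                "o",
                color="black" if filled else "#dddddd",
                markersize=6,
            )
        ys = [set_ids.index(s) for s in p["sets"]]
        if len(ys) > 1:
            ax_dot.plot([x, x], [min(ys), max(ys)], color="black", linewidth=1)
    ax_dot.set_yticks(range(len(set_ids)))
    ax_dot.set_yticklabels(ds.payload["set_names"], fontsize=6)
    ax_dot.set_xticks(list(xs))
    ax_dot.invert_yaxis()
    fig.suptitle("Pathway gene-set intersections")
    return fig


def _fig_pubmed_trend(ds: PlotDataset):
    fig, ax = plt.subplots(figsize=(8, 6))
    series = ds.payload["series"]
    if not series:
        _empty_axes(ax, "no trend data")
        return fig
    for term, pts in series.items():
        years = [p[0] for p in pts]
        counts = [p[1] for p in pts]
        full = list(range(min(years), max(years) + 1))
        lookup = dict(zip(years, counts))
        ax.plot(
            full,
            [lookup.get(y, np.nan) for y in full],
            marker="o",
            label=term,
        )
    ax.set_xlabel("year")
    ax.set_ylabel("publications")
    ax.legend(fontsize=7)
    ax.set_title("Publication trends")
    fig.tight_layout()
    return fig


_FIG_BUILDERS = {
    "barplot": _fig_barplot,
    "lollipop": _fig_lollipop,
    "heatmap": _fig_heatmap,
    "treeplot": _fig_treeplot,
    "cnet": _fig_cnet,
    "upset": _fig_upset,
    "pubmed_trend": _fig_pubmed_trend,
}

_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>{title}</title></head>
<body>
<h1>{title}</h1>
<!-- layout-seed: {seed} -->
<img alt="{title}" src="data:image/png;base64,{image}"/>
<script type="application/json" id="plot-payload">
{payload}
</script>
</body>
</html>
"""


def render(
    dataset: PlotDataset,
    out_basename: str | Path,
    formats: Iterable[str] = ("png", "html"),
) -> list[Path]:
    """Write the dataset as PNG and/or self-contained HTML; returns paths."""
    formats = list(formats)
    if not formats:
        raise ValueError("at least one output format is required")
    unknown = set(formats) - {"png", "html"}
    if unknown:
        raise ValueError(f"unsupported format(s): {sorted(unknown)}")
    if dataset.kind not in _FIG_BUILDERS:
        raise ValueError(f"no renderer for plot kind {dataset.kind!r}")
    fig = _FIG_BUILDERS[dataset.kind](dataset)
    written: list[Path] = []
    base = Path(out_basename)
    png_bytes: bytes | None = None
    if "png" in formats or "html" in formats:
        buf = io.BytesIO()
        fig.savefig(buf, format="png", dpi=120)
        png_bytes = buf.getvalue()
    if "png" in formats:
        path = base.with_suffix(".png")
        path.write_bytes(png_bytes)
        written.append(path)
    if "html" in formats:
        path = base.with_suffix(".html")
        seed = dataset.payload.get("layout_seed", DEFAULT_LAYOUT_SEED)
        path.write_text(
            _HTML_TEMPLATE.format(
                title=f"{dataset.kind}",
                seed=seed,
                image=base64.b64encode(png_bytes).decode("ascii"),
                payload=dataset.to_json(),
            ),
            encoding="utf-8",
        )
        written.append(path)
    plt.close(fig)
    return written
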