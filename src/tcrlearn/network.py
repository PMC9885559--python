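"""Per-sample repertoire similarity graphs.

Each sample's distinct clonotype sequences become nodes; an undirected edge
joins two sequences whose Levenshtein (unit-cost edit) distance is between 1
and a threshold (default 2).  Six topological summaries of the resulting
graph form the network feature row: node count, edge count, density, mean
local clustering coefficient, transitivity, and number of connected
components.  The edge count is what repertoire-network figures often call
the "number of arrows".
"""

from __future__ import annotations

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, DegenerateSampleError, ResourceError
from .io import FeatureTable, RepertoireMatrix

GRAPH_FEATURE_NAMES = (
    "n_nodes", "n_edges", "density", "avg_clustering", "transitivity", "n_components",
)

DEFAULT_THRESHOLD = 2
DEFAULT_NODE_CAP = 50_000


def levenshtein(u: str, v: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not u or not v:
        raise ConfigurationError("Levenshtein distance requires non-empty strings")
    return edlib.align(u, v, task="distance")["editDistance"]


def within_threshold(u: str, v: str, t: int) -> bool:
    """Whether ``levenshtein(u, v) <= t``.

    A length-difference prefilter skips the banded alignment when the gap
    alone exceeds the threshold.
    """
    if t < 1:
        raise ConfigurationError(f"threshold must be >= 1, got {t}")
    if abs(len(u) - len(v)) > t:
        return False
    return edlib.align(u, v, task="distance", k=t)["editDistance"] != -1


def build_graph(clonotypes, counts=None, threshold: int = DEFAULT_THRESHOLD,
                node_cap: int = DEFAULT_NODE_CAP) -> nx.Graph:
    """Build one sample's repertoire graph.

    Parameters
    ----------
    clonotypes : sequence of str
        The sample's distinct clonotype sequences (nodes).
    counts : sequence of int, optional
        Clone counts, stored as the ``count`` node attribute for export.
    threshold : int
        Edge iff ``1 <= levenshtein(u, v) <= threshold``.
    node_cap : int
        Hard cap on node count; exceeding it raises a ResourceError
        (subsample upstream), never a silent truncation.
    """
    nodes = list(dict.fromkeys(clonotypes))
    if len(nodes) == 0:
        raise DegenerateSampleError("cannot build a graph with no clonotypes")
    if len(nodes) > node_cap:
        raise ResourceError(
            f"{len(nodes)} nodes exceeds the cap of {node_cap}; "
            "subsample the repertoire or raise node_cap"
        )
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(sorted(nodes))
    if counts is not None:
        cmap = dict(zip(clonotypes, counts))
        nx.set_node_attributes(g, {n: int(cmap[n]) for n in nodes}, "count")
    # bucket by length: only pairs within `threshold` length units can connect
    by_len: dict[int, list[str]] = {}
    for n in sorted(nodes):
        by_len.setdefault(len(n), []).append(n)
    lengths = sorted(by_len)
    for li in lengths:
        for lj in (l for l in lengths if li <= l <= li + threshold):
            a, b = by_len[li], by_len[lj]
            for i, u in enumerate(a):
                vs = b[i + 1:] if li == lj else b
                for v in vs:
                    if within_threshold(u, v, threshold):
                        g.add_edge(u, v)
    return g


def graph_features(g: nx.Graph) -> dict:
    """The six topological summaries of one repertoire graph."""
    n = g.number_of_nodes()
    return {
        "n_nodes": n,
        "n_edges": g.number_of_edges(),
        "density": nx.density(g) if n > 1 else 0.0,
        "avg_clustering": nx.average_clustering(g) if n > 0 else 0.0,
        "transitivity": nx.transitivity(g),
        "n_components": nx.number_connected_components(g),
    }


class NetworkFeatures(BaseEstimator, TransformerMixin):
    """Transformer computing the six network features per sample."""

    def __init__(self, threshold: int = DEFAULT_THRESHOLD,
                 node_cap: int = DEFAULT_NODE_CAP):
        self.threshold = threshold
        self.node_cap = node_cap

    def fit(self, X: RepertoireMatrix, y=None):
        if self.threshold < 1:
            raise ConfigurationError(f"threshold must be >= 1, got {self.threshold}")
        self.feature_names_out_ = list(GRAPH_FEATURE_NAMES)
        return self

    def transform(self, X: RepertoireMatrix) -> FeatureTable:
        rows = []
        for i, sid in enumerate(X.sample_ids):
            mask = X.counts[i] > 0
            seqs = [c for c, m in zip(X.clonotypes, mask) if m]
            try:
                g = build_graph(seqs, counts=X.counts[i][mask],
                                threshold=self.threshold, node_cap=self.node_cap)
            except (DegenerateSampleError, ResourceError) as e:
                raise type(e)(f"sample {sid!r}: {e}") from e
            rows.append(graph_features(g))
        data = pd.DataFrame(rows, index=X.sample_ids, dtype=float)
        return FeatureTable(
            data=data,
            labels=X.labels.copy(),
            provenance={c: "network" for c in data.columns},
            label_column_name=X.label_column_name,
        )


def network_features(m: RepertoireMatrix, threshold: int = DEFAULT_THRESHOLD,
                     node_cap: int = DEFAULT_NODE_CAP) -> FeatureTable:
    """One network feature row per sample; labels carried through."""
    return NetworkFeatures(threshold=threshold, node_cap=node_cap).fit(m).transform(m)


def export_graph(g: nx.Graph, path, fmt: str = "auto") -> None:
    """Write a repertoire graph as an edge list (TSV, isolated nodes included
    as single-column lines) or GraphML; ``fmt="auto"`` picks by extension."""
    path = str(path)
    if fmt == "auto":
        fmt = "graphml" if path.endswith(".graphml") else "edgelist"
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in g.edges():
                fh.write(f"{u}\t{v}\n")
            for n in nx.isolates(g):
                fh.write(f"{n}\n")
    else:
        raise ConfigurationError(f"unknown graph format {fmt!r}")


def import_graph(path, fmt: str = "auto") -> nx.Graph:
    """Read a graph written by :func:`export_graph`."""
    path = str(path)
    if fmt == "auto":
        fmt = "graphml" if path.endswith(".graphml") else "edgelist"
    if fmt == "graphml":
        return nx.read_graphml(path)
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) == 2:
                g.add_edge(parts[0], parts[1])
    return g
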