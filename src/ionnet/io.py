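"""Network and table exports (Cytoscape-loadable SIF and GraphML)."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd


def edges_to_graph(edges: pd.DataFrame, significant_only: bool = True) -> nx.Graph:
    """Build an undirected graph from an edge table (one (group, time) cell).

    Edge attributes: scc, sign ("positive"/"negative"), significant.
    """
    g = nx.Graph()
    sub = edges[edges["significant"]] if significant_only else edges
    nodes = sorted(set(edges["element_a"]) | set(edges["element_b"]))
    g.add_nodes_from(nodes)
    for row in sub.itertuples():
        if row.scc != row.scc:      # NaN: undefined correlation, no edge
            continue
        g.add_edge(row.element_a, row.element_b, scc=float(row.scc),
                   sign="positive" if row.scc >= 0 else "negative",
                   significant=bool(row.significant))
    return g


def write_sif(edges: pd.DataFrame, path: str | Path,
              significant_only: bool = True) -> Path:
    """Simple interaction format: ``elementA corr elementB`` per edge."""
    g = edges_to_graph(edges, significant_only)
    path = Path(path)
    lines = [f"{a}\tcorr\t{b}" for a, b in sorted(g.edges())]
    # isolated nodes still appear so Cytoscape shows the full panel
    connected = {n for e in g.edges() for n in e}
    lines += sorted(n for n in g.nodes() if n not in connected)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_graphml(edges: pd.DataFrame, path: str | Path,
                  significant_only: bool = True) -> Path:
    g = edges_to_graph(edges, significant_only)
    path = Path(path)
    nx.write_graphml(g, path)
    return path


def write_tsv(df: pd.DataFrame, path: str | Path, **meta) -> Path:
    """Write a TSV with provenance recorded in ``# key: value`` header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
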