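"""Degree analysis, hub calling, pair counting and key-lncRNA ranking.

Hubs are nodes whose degree reaches a threshold (default 5, matching the
published hub tables where degree-5 nodes are listed).  For each lncRNA,
the first-order pairs are its incident lncRNA-miRNA edges and the
second-order pairs are the miRNA-mRNA edges of its miRNA partners, each
such edge counted once per incident selected miRNA; their total ranks
the key lncRNAs and equals the edge count of the lncRNA's extracted
subnetwork.
"""

from __future__ import annotations

import warnings
from importlib import resources

import networkx as nx
import pandas as pd


def degree_table(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree table with type and fold-change annotations."""
    rows = [(n, int(graph.degree[n]),
             graph.nodes[n].get("type", ""),
             graph.nodes[n].get("fold_change", float("nan")))
            for n in graph.nodes]
    df = pd.DataFrame(rows, columns=["node_id", "degree", "node_type", "fold_change"])
    return df.sort_values(["degree", "node_id"],
                          ascending=[False, True]).reset_index(drop=True)


def hub_table(degrees: pd.DataFrame, threshold: int = 5) -> pd.DataFrame:
    """Apply the hub threshold (degree >= threshold) to a degree table."""
    hubs = degrees.loc[degrees["degree"] >= threshold]
    return hubs.sort_values(["degree", "node_id"],
                            ascending=[False, True]).reset_index(drop=True)


def hub_nodes(graph: nx.Graph, threshold: int = 5) -> pd.DataFrame:
    """Hub nodes of a built graph, sorted by degree desc then id."""
    return hub_table(degree_table(graph), threshold=threshold)


def hub_type_counts(hubs: pd.DataFrame) -> dict[str, int]:
    return hubs["node_type"].value_counts().to_dict()


def pair_counts(graph: nx.Graph) -> pd.DataFrame:
    """First/second relationship-pair counts per lncRNA.

    n_first = number of miRNA partners of the lncRNA (its degree);
    n_second = sum over those miRNAs of their mRNA partner counts, each
    mi-m edge counted once per incident selected miRNA.
    """
    rows = []
    for n, data in graph.nodes(data=True):
        if data.get("type") != "lnc":
            continue
        mirnas = [u for u in graph.neighbors(n)
                  if graph.nodes[u].get("type") == "mi"]
        n_first = len(mirnas)
        n_second = sum(
            sum(1 for v in graph.neighbors(mu)
                if graph.nodes[v].get("type") == "m")
            for mu in mirnas)
        rows.append((n, n_first, n_second, n_first + n_second))
    df = pd.DataFrame(rows, columns=["lnc_id", "n_first", "n_second", "total"])
    return df.sort_values(["n_first", "total", "lnc_id"],
                          ascending=[False, False, True]).reset_index(drop=True)


def rank_key_lncrnas(pair_count_table: pd.DataFrame, hubs: pd.DataFrame | None = None,
                     k: int = 3) -> list[str]:
    """Top-k lncRNAs by (n_first desc, total desc, id asc).

    When a hub table is supplied the ranking is restricted to hub lncRNAs.
    Asking for more lncRNAs than exist returns them all with a warning.
    """
    tbl = pair_count_table
    if hubs is not None:
        hub_lncs = set(hubs.loc[hubs["node_type"] == "lnc", "node_id"])
        tbl = tbl.loc[tbl["lnc_id"].isin(hub_lncs)]
    tbl = tbl.sort_values(["n_first", "total", "lnc_id"],
                          ascending=[False, False, True])
    if k > len(tbl):
        warnings.warn(f"asked for k={k} key lncRNAs but only {len(tbl)} available",
                      RuntimeWarning, stacklevel=2)
    return list(tbl["lnc_id"].head(k))


def extract_subnetwork(graph: nx.Graph, lnc_id: str) -> nx.Graph:
    """Subnetwork of one lncRNA: itself, its miRNAs, and their mRNAs.

    Keeps only the L-mu edges of the chosen lncRNA and the mu-M edges of
    its miRNA set; other lncRNAs' attachments to those miRNAs are dropped.
    """
    if lnc_id not in graph:
        raise KeyError(f"unknown lncRNA {lnc_id!r}")
    mirnas = [u for u in graph.neighbors(lnc_id)
              if graph.nodes[u].get("type") == "mi"]
    sub = nx.Graph()
    sub.add_node(lnc_id, **graph.nodes[lnc_id])
    for mu in mirnas:
        sub.add_node(mu, **graph.nodes[mu])
        sub.add_edge(lnc_id, mu, **graph.edges[lnc_id, mu])
        for v in graph.neighbors(mu):
            if graph.nodes[v].get("type") == "m":
                sub.add_node(v, **graph.nodes[v])
                sub.add_edge(mu, v, **graph.edges[mu, v])
    return sub


# -- published reference tables (GSE37425 PCOS ceRNA network) --------------

def load_reference_hub_table() -> pd.DataFrame:
    """Published hub-node degree table of the PCOS ceRNA network."""
    with resources.files("cernet.data").joinpath("gse37425_hub_degrees.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_pair_counts() -> pd.DataFrame:
    """Published per-lncRNA first/second relationship-pair counts."""
    with resources.files("cernet.data").joinpath("gse37425_lnc_pair_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
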