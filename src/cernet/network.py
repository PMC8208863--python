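"""Competing-triplet assembly and ceRNA graph construction.

A competing triplet (L, mu, M) couples a lncRNA L and an mRNA M that are
tightly coexpressed (Pearson r above a one-sided threshold, default 0.99,
with p < 0.05) and are both targets of a shared miRNA mu with which each
is negatively correlated.  Triplets are merged into a simple undirected
tripartite graph whose only edge classes are lncRNA-miRNA and miRNA-mRNA;
lncRNAs never touch mRNAs directly because the competition is mediated by
the shared miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from xml.sax.saxutils import escape

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ExpressionMatrix
from .targets import TargetPair


@dataclass
class CorrelationPair:
    id_a: str
    id_b: str
    pcc: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CompetingTriplet:
    lnc_id: str
    mi_id: str
    m_id: str
    lnc_m_pcc: float
    mi_lnc_pcc: float
    mi_m_pcc: float


def _pearson_p(r: float, n: int) -> float:
    """Two-sided p for Pearson r via t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson(x, y, id_a: str = "a", id_b: str = "b") -> CorrelationPair:
    """Pearson product-moment correlation with its t-transform p-value.

    Constant vectors make the correlation undefined; the pair is returned
    with NaN coefficient and p-value and is excluded by every downstream
    gate (strict inequalities are false for NaN).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("vectors differ in length")
    n = xv.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if xv.std() == 0.0 or yv.std() == 0.0:
        return CorrelationPair(id_a, id_b, float("nan"), float("nan"), n)
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    return CorrelationPair(id_a, id_b, r, _pearson_p(r, n), n)


def correlation_matrix(matrix: ExpressionMatrix, ids_a, ids_b):
    """All-pairs Pearson r between two id lists; returns (R, P, n).

    Vectorised over rows of the expression matrix; rows with zero variance
    get NaN correlations.
    """
    missing = [i for i in list(ids_a) + list(ids_b) if i not in matrix.values.index]
    if missing:
        raise KeyError(f"ids missing from expression matrix: {sorted(set(missing))}")
    A = matrix.values.loc[list(ids_a)].to_numpy(dtype=float)
    B = matrix.values.loc[list(ids_b)].to_numpy(dtype=float)
    n = A.shape[1]

    def _standardize(X):
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (X - mu) / sd
        Z[np.broadcast_to(sd == 0.0, Z.shape)] = np.nan
        return Z

    R = _standardize(A) @ _standardize(B).T / n
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = R * np.sqrt((n - 2) / (1.0 - R * R))
        P = 2.0 * stats.t.sf(np.abs(T), df=n - 2)
    P[np.abs(R) >= 1.0] = 0.0
    return R, P, n


def coexpression_pairs(dels, dems, matrix: ExpressionMatrix,
                       pcc_cut: float = 0.99, p_cut: float = 0.05) -> list[CorrelationPair]:
    """lncRNA x mRNA pairs with r > pcc_cut and p < p_cut (both strict).

    The coexpression gate is one-sided: competing partners co-rise, so
    only strongly positive correlations qualify.
    """
    dels, dems = list(dels), list(dems)
    if not dels or not dems:
        return []
    R, P, n = correlation_matrix(matrix, dels, dems)
    out = []
    for i, lnc in enumerate(dels):
        for j, m in enumerate(dems):
            if R[i, j] > pcc_cut and P[i, j] < p_cut:
                out.append(CorrelationPair(lnc, m, float(R[i, j]), float(P[i, j]), n))
    return out


def assemble_triplets(coexpr_pairs, lnc_targets, mrna_targets,
                      matrix: ExpressionMatrix,
                      require_negative_p: bool = False,
                      p_cut: float = 0.05) -> list[CompetingTriplet]:
    """Enumerate competing triplets over every candidate combination.

    For each coexpressed (L, M) pair and each miRNA mu targeting both,
    the triplet is kept when r(mu, L) < 0 and r(mu, M) < 0.  The default
    rule gates only the signs of the miRNA correlations; a significance
    gate on them is available via ``require_negative_p``.
    """
    lnc_by_mi: dict[str, set[str]] = {}
    for p in lnc_targets:
        lnc_by_mi.setdefault(p.target_id, set()).add(p.mirna_id)
    m_by_mi: dict[str, set[str]] = {}
    for p in mrna_targets:
        m_by_mi.setdefault(p.target_id, set()).add(p.mirna_id)

    triplets = []
    for cp in coexpr_pairs:
        shared = lnc_by_mi.get(cp.id_a, set()) & m_by_mi.get(cp.id_b, set())
        for mi in sorted(shared):
            if mi not in matrix.values.index:
                continue
            r_ml = pearson(matrix.row(mi), matrix.row(cp.id_a), mi, cp.id_a)
            r_mm = pearson(matrix.row(mi), matrix.row(cp.id_b), mi, cp.id_b)
            ok = r_ml.pcc < 0 and r_mm.pcc < 0
            if ok and require_negative_p:
                ok = r_ml.p_value < p_cut and r_mm.p_value < p_cut
            if ok:
                triplets.append(CompetingTriplet(
                    lnc_id=cp.id_a, mi_id=mi, m_id=cp.id_b,
                    lnc_m_pcc=cp.pcc, mi_lnc_pcc=r_ml.pcc, mi_m_pcc=r_mm.pcc))
    triplets.sort(key=lambda t: (t.lnc_id, t.mi_id, t.m_id))
    return triplets


def build_graph(triplets, fold_changes=None, node_types=None) -> nx.Graph:
    """Union the L-mu and mu-M edges of every triplet into a simple graph.

    Node attributes: ``type`` (lnc/mi/m) and ``fold_change`` (NaN when
    unknown); edge attribute ``kind`` is ``lnc-mi`` or ``mi-m``.
    """
    fold_changes = fold_changes or {}
    g = nx.Graph()
    for t in triplets:
        for nid, ntype in ((t.lnc_id, "lnc"), (t.mi_id, "mi"), (t.m_id, "m")):
            if not g.has_node(nid):
                g.add_node(nid, type=ntype,
                           fold_change=float(fold_changes.get(nid, float("nan"))))
        g.add_edge(t.lnc_id, t.mi_id, kind="lnc-mi")
        g.add_edge(t.mi_id, t.m_id, kind="mi-m")
    return g


def write_sif(graph: nx.Graph, path) -> None:
    """Simple-interaction-format export (Cytoscape-loadable)."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            kind = data.get("kind", "pp")
            if graph.nodes[a].get("type") == "mi" and kind == "lnc-mi":
                a, b = b, a  # keep the lncRNA first in lnc-mi rows
            if graph.nodes[b].get("type") == "mi" and kind == "mi-m":
                a, b = b, a  # keep the miRNA first in mi-m rows
            fh.write(f"{a}\t{kind}\t{b}\n")
        for n in sorted(graph.nodes):
            if graph.degree[n] == 0:
                fh.write(f"{n}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export with type, fold_change and degree node attributes."""
    g = graph.copy()
    for n in g.nodes:
        g.nodes[n]["degree"] = int(g.degree[n])
        fc = g.nodes[n].get("fold_change")
        if fc is None or (isinstance(fc, float) and np.isnan(fc)):
            g.nodes[n]["fold_change"] = 0.0
        g.nodes[n]["id_label"] = escape(str(n))
    nx.write_graphml(g, str(path), named_key_ids=True)
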