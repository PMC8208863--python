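"""Gene-set over-representation analysis of network mRNAs.

One-sided Fisher's exact test (equivalently the hypergeometric upper
tail) of a query gene list against flat gene sets (GO-style BP/MF/CC and
KEGG-style pathway collections supplied as GMT files), with
Benjamini-Hochberg adjustment, enrichment factors (k/n)/(K/N) and top-N
reporting per category.  The background universe defaults to the set of
measured mRNAs, not the genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("BP", "MF", "CC", "pathway")


@dataclass
class GeneSet:
    term_id: str
    name: str
    category: str
    members: frozenset


@dataclass
class GeneSetCollection:
    terms: list[GeneSet]
    universe: frozenset = field(default_factory=frozenset)

    def restricted(self, universe) -> "GeneSetCollection":
        """Restrict members to a universe, dropping emptied terms."""
        uni = frozenset(universe)
        kept = []
        for t in self.terms:
            members = t.members & uni
            if members:
                kept.append(GeneSet(t.term_id, t.name, t.category, members))
        return GeneSetCollection(terms=kept, universe=uni)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (term, description, tab-separated member genes).

    The description field doubles as the category label when it is one of
    BP/MF/CC/pathway; anything else is kept as-is in ``name`` with
    category ``pathway``.
    """
    terms: list[GeneSet] = []
    universe: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has no members")
            term_id, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            category = desc if desc in CATEGORIES else "pathway"
            terms.append(GeneSet(term_id, desc, category, members))
            universe |= set(members)
    return GeneSetCollection(terms=terms, universe=frozenset(universe))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for t in collection.terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k > K:
        return 0.0
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(query_genes, collection: GeneSetCollection,
           universe=None, top_n: int | None = None) -> pd.DataFrame:
    """Over-representation of a query list against a gene-set collection.

    Query genes outside the universe are dropped with a warning.  Terms
    with zero overlap are suppressed.  Rows are sorted by p ascending,
    ties by enrichment factor descending then term id; ``top_n`` keeps the
    best N terms per category.
    """
    uni = frozenset(universe) if universe is not None else collection.universe
    coll = collection.restricted(uni)
    query = frozenset(query_genes)
    dropped = query - uni
    if dropped:
        warnings.warn(f"{len(dropped)} query genes outside the universe dropped",
                      RuntimeWarning, stacklevel=2)
    query &= uni
    if not query:
        raise ValueError("query empty after restriction to the universe")
    N, n = len(uni), len(query)
    rows = []
    for t in coll.terms:
        K = len(t.members)
        k = len(query & t.members)
        if k == 0:
            continue
        factor = (k / n) / (K / N)
        rows.append((t.term_id, t.name, t.category, k, n, K, N,
                     factor, hypergeom_upper(k, n, K, N)))
    df = pd.DataFrame(rows, columns=["term_id", "name", "category", "k", "n",
                                     "K", "N", "enrichment_factor", "p_value"])
    if df.empty:
        df["bh_q"] = []
        return df
    df["bh_q"] = bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values(["p_value", "enrichment_factor", "term_id"],
                        ascending=[True, False, True]).reset_index(drop=True)
    if top_n is not None:
        df = df.groupby("category", group_keys=False, sort=False).head(top_n)
        df = df.reset_index(drop=True)
    return df


def category_counts(result: pd.DataFrame, p_cut: float = 0.05) -> dict[str, int]:
    """Number of enriched terms (p < p_cut) per category."""
    sig = result.loc[result["p_value"] < p_cut]
    return {c: int((sig["category"] == c).sum()) for c in CATEGORIES}


def dotplot_table(result: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table mirroring enrichment dot-plot axes."""
    out = result[["term_id", "name", "category", "enrichment_factor", "k"]].copy()
    out["neg_log10_p"] = -np.log10(result["p_value"].clip(lower=1e-300))
    return out.rename(columns={"k": "gene_count"})
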