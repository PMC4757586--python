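"""Target-set integration and hypergeometric functional enrichment.

Per miRNA, the working target set is (predicted by source A AND source B)
UNION experimentally validated — intersecting two prediction algorithms
trades recall for precision, and validated interactions are kept regardless.
Enrichment of a query gene set against flat category annotations uses the
hypergeometric upper tail P(X >= k) with Benjamini–Hochberg control across
the categories of each query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

PROVENANCE = ("predicted_both", "validated", "both")


@dataclass
class IntegratedTargets:
    """mirna -> {gene -> provenance}; provenance in PROVENANCE."""

    by_mirna: dict[str, dict[str, str]] = field(default_factory=dict)

    def genes(self, mirna: str) -> set[str]:
        return set(self.by_mirna.get(mirna, {}))

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.by_mirna.values():
            out |= set(genes)
        return out

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.by_mirna)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m, g, prov)
            for m, genes in sorted(self.by_mirna.items())
            for g, prov in sorted(genes.items())
        ]
        return pd.DataFrame(rows, columns=["mirna", "gene", "provenance"])


def _pairs(table: pd.DataFrame) -> dict[str, set[str]]:
    if not {"mirna", "gene"} <= set(table.columns):
        raise ValueError("target table needs 'mirna' and 'gene' columns")
    out: dict[str, set[str]] = {}
    for r in table.itertuples():
        out.setdefault(r.mirna, set()).add(r.gene)
    return out


def integrate_targets(
    pred_a: pd.DataFrame,
    pred_b: pd.DataFrame,
    validated: pd.DataFrame | None = None,
    mirnas: Iterable[str] | None = None,
) -> IntegratedTargets:
    """Per miRNA: (A intersect B) union validated, with provenance labels.

    ``mirnas`` optionally fixes the universe; miRNAs absent from every table
    get an empty set (with no error — missing evidence is not malformed input).
    """
    a = _pairs(pred_a)
    b = _pairs(pred_b)
    v = _pairs(validated) if validated is not None and len(validated) else {}
    names = set(mirnas) if mirnas is not None else set(a) | set(b) | set(v)
    result: dict[str, dict[str, str]] = {}
    for m in names:
        both = a.get(m, set()) & b.get(m, set())
        val = v.get(m, set())
        genes = {g: "predicted_both" for g in both}
        for g in val:
            genes[g] = "both" if g in genes else "validated"
        result[m] = genes
    return IntegratedTargets(by_mirna=result)


def enrich(
    query: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each category.

    For a universe of N genes, a category of K and a query of n with overlap
    k, p = P(X >= k) under Hypergeom(N, K, n).  Categories are intersected
    with the universe first; BH adjustment runs across the categories of this
    one query.  Rows are sorted by category name for determinism.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query gene set")
    if not query <= universe:
        raise ValueError("query genes outside the universe")
    rows = []
    for name in sorted(categories):
        cat = set(categories[name]) & universe
        if not cat:
            continue
        k = len(query & cat)
        rows.append((name, k, len(query), len(cat), len(universe),
                     float(hypergeom.sf(k - 1, len(universe), len(cat), len(query)))))
    df = pd.DataFrame(rows, columns=["category", "k", "n", "K", "N", "p"])
    if len(df):
        df["p"] = df["p"].clip(upper=1.0)
        df["p_adjusted"] = np.maximum(multipletests(df["p"], method=method)[1], df["p"])
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["p_adjusted"] = []
        df["significant"] = []
    return df


def enrich_per_mirna(
    targets: IntegratedTargets,
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Run ``enrich`` for every miRNA with a non-empty target set."""
    out = {}
    for m in targets.mirnas:
        genes = targets.genes(m) & set(universe)
        if genes:
            out[m] = enrich(genes, categories, universe, alpha=alpha)
    return out


def enrichment_matrix(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """miRNA x category matrix of adjusted p-values (NaN = not tested).

    Heatmap-ready; rows and columns sorted, so the matrix is invariant to the
    order results are supplied in.
    """
    if not results:
        raise ValueError("no enrichment results")
    cats = sorted({c for df in results.values() for c in df["category"]})
    mat = pd.DataFrame(np.nan, index=sorted(results), columns=cats)
    for m, df in results.items():
        for r in df.itertuples():
            mat.loc[m, r.category] = r.p_adjusted
    mat.index.name = "mirna"
    return mat
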