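"""Function prediction from TF target sets: GO-BP enrichment + clustering.

For each transcription factor, Gene Ontology Biological Process terms
enriched among its target genes are found with the upper-tail
hypergeometric test against the gene universe (Bonferroni over the terms
actually tested for that TF).  TFs are then hierarchically clustered
(average linkage on Jaccard distance of their binary enriched-term
profiles) so that factors with similar predicted functions group
together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .stats import bonferroni, hypergeom_upper_tail

__all__ = [
    "RegulatoryNetwork",
    "FunctionMatrix",
    "TermEnrichment",
    "go_enrich",
    "build_function_matrix",
    "cluster_tfs",
    "read_edge_list",
    "read_term_annotations",
]

#: Terms annotating fewer universe genes than this are not tested (noise guard).
MIN_ANNOTATED_GENES = 3


@dataclass
class RegulatoryNetwork:
    """TF -> target edges plus gene -> GO-BP annotations over a universe."""

    edges: dict[str, frozenset[str]]
    annotations: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        stray = set().union(*self.edges.values(), frozenset()) - self.universe
        if stray:
            raise ValueError(f"edge targets outside the universe: {sorted(stray)[:5]}")
        stray = set(self.annotations) - self.universe
        if stray:
            raise ValueError(f"annotated genes outside the universe: {sorted(stray)[:5]}")

    def genes_with_term(self, term: str) -> frozenset[str]:
        return frozenset(g for g, ts in self.annotations.items() if term in ts)

    @property
    def terms(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.annotations.values():
            out |= ts
        return frozenset(out)


@dataclass(frozen=True)
class TermEnrichment:
    term: str
    k: int          # annotated targets
    n: int          # targets
    K: int          # annotated universe genes
    N: int          # universe size
    p_raw: float
    p_adjusted: float


@dataclass
class FunctionMatrix:
    """Binary TF x enriched-term matrix with per-cell adjusted p-values."""

    matrix: pd.DataFrame          # bool, TFs x terms
    p_values: pd.DataFrame        # adjusted p (NaN where untested)
    threshold: float
    dendrogram_order: Optional[list[str]] = None


def go_enrich(tf: str, network: RegulatoryNetwork,
              threshold: float = 0.05,
              min_annotated: int = MIN_ANNOTATED_GENES,
              ) -> list[TermEnrichment]:
    """GO-BP term enrichment of one TF's target set.

    Terms annotating fewer than ``min_annotated`` universe genes, or none
    of the TF's targets, are not tested; Bonferroni corrects over the
    terms actually tested for this TF.  Returns all tested terms sorted
    by adjusted p (callers filter at ``threshold``).
    """
    targets = network.edges.get(tf, frozenset())
    if not targets:
        return []
    N = len(network.universe)
    n = len(targets)
    term_genes: dict[str, frozenset[str]] = {}
    for term in network.terms:
        genes = network.genes_with_term(term)
        if len(genes) < min_annotated:
            continue
        if not (genes & targets):
            continue
        term_genes[term] = genes
    results = []
    raw = []
    for term, genes in sorted(term_genes.items()):
        k = len(genes & targets)
        K = len(genes)
        raw.append((term, k, K, hypergeom_upper_tail(k, n, K, N)))
    adjusted = bonferroni([p for *_, p in raw], family_size=len(raw))
    for (term, k, K, p), padj in zip(raw, adjusted):
        results.append(TermEnrichment(term=term, k=k, n=n, K=K, N=N,
                                      p_raw=p, p_adjusted=padj))
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
    return results


def build_function_matrix(network: RegulatoryNetwork,
                          threshold: float = 0.05,
                          min_annotated: int = MIN_ANNOTATED_GENES,
                          ) -> FunctionMatrix:
    """Binary enriched-term profiles for every TF with >= 1 enriched term."""
    rows: dict[str, dict[str, float]] = {}
    for tf in sorted(network.edges):
        enr = go_enrich(tf, network, threshold, min_annotated)
        sig = {r.term: r.p_adjusted for r in enr if r.p_adjusted < threshold}
        if sig:
            rows[tf] = sig
    terms = sorted({t for sig in rows.values() for t in sig})
    tfs = sorted(rows)
    p = pd.DataFrame(np.nan, index=tfs, columns=terms)
    for tf, sig in rows.items():
        for term, padj in sig.items():
            p.loc[tf, term] = padj
    matrix = p.notna()
    return FunctionMatrix(matrix=matrix, p_values=p, threshold=threshold)


def cluster_tfs(fm: FunctionMatrix, n_clusters: Optional[int] = None,
                ) -> tuple[list[str], dict[str, int]]:
    """Average-linkage clustering of TFs on Jaccard profile distance.

    Returns the dendrogram leaf order and a flat cluster assignment
    (``n_clusters`` groups; defaults to 1 when not given).  Requires at
    least two TFs with an enriched term.  Deterministic: ties are broken
    by scipy's fixed ordering of the (alphabetically sorted) input rows.
    """
    if fm.matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 TFs with enriched terms")
    X = fm.matrix.to_numpy(dtype=bool)
    dist = pdist(X, metric="jaccard")
    dist = np.nan_to_num(dist, nan=0.0)  # all-zero rows: identical profiles
    Z = hierarchy.linkage(dist, method="average")
    order = [fm.matrix.index[i] for i in hierarchy.leaves_list(Z)]
    fm.dendrogram_order = order
    if n_clusters is None:
        n_clusters = 1
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    assignment = {tf: int(c) for tf, c in zip(fm.matrix.index, flat)}
    return order, assignment


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> dict[str, frozenset[str]]:
    """TSV with columns tf_id, target_id (header optional)."""
    edges: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "tf_id":
                continue
            tf, target = parts[0], parts[1]
            edges.setdefault(tf, set()).add(target)
    return {tf: frozenset(ts) for tf, ts in edges.items()}


def read_term_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """TSV with columns gene_id, term_id; GAF-style lines (gene in column
    2, term in column 5) are also accepted."""
    annos: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            parts = line.split("\t")
            if parts[0] == "gene_id":
                continue
            if len(parts) >= 5 and parts[4].startswith("GO:"):
                gene, term = parts[1], parts[4]  # GAF
            else:
                gene, term = parts[0], parts[1]
            annos.setdefault(gene, set()).add(term)
    return {g: frozenset(ts) for g, ts in annos.items()}
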