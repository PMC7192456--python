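"""Real-hub-gene screening within trait-significant modules.

A module's network is thresholded at a per-module edge weight; gene
degree is the number of retained incident edges; one-dimensional k-means
splits the degrees and the cluster with the highest mean is the "first
cluster"; real hubs are first-cluster genes whose |GS| and |MM| clear
inclusive thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datatypes import HubCriteria, ModuleAssignment
from .errors import ValidationError


def module_edge_list(
    weights: pd.DataFrame,
    labels: pd.Series,
    module: str,
    weight_threshold: float,
) -> pd.DataFrame:
    """Within-module undirected edges with weight strictly above threshold.

    Each unordered pair appears once, ordered (gene_a < gene_b), rows
    sorted lexicographically.
    """
    if not 0.0 <= weight_threshold <= 1.0:
        raise ValidationError("weight threshold must lie in [0, 1]")
    if module not in set(labels.values):
        raise ValidationError(f"unknown module: {module!r}")
    genes = sorted(g for g in labels.index[labels == module] if g in weights.index)
    w = weights.loc[genes, genes].values
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if w[i, j] > weight_threshold:
                rows.append((genes[i], genes[j], float(w[i, j])))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


def degree(edges: pd.DataFrame, module_genes) -> pd.Series:
    """Number of incident edges per gene; isolated genes score 0."""
    counts = pd.Series(0, index=sorted(module_genes), dtype=int)
    if len(edges):
        for col in ("gene_a", "gene_b"):
            vc = edges[col].value_counts()
            counts = counts.add(vc.reindex(counts.index, fill_value=0), fill_value=0)
    counts.name = "degree"
    return counts.astype(int)


def degree_first_cluster(degrees: pd.Series, k: int = 3, seed: int = 0) -> list[str]:
    """Genes in the highest-mean-degree cluster of a 1-D k-means split.

    If there are fewer distinct degree values than ``k``, ``k`` is
    reduced (with a warning); with a single distinct value every gene is
    returned.
    """
    values = degrees.values.astype(float)
    distinct = np.unique(values).size
    if distinct < k:
        warnings.warn(
            f"only {distinct} distinct degree value(s); reducing k from {k}",
            stacklevel=2,
        )
        k = distinct
    if k <= 1:
        return sorted(degrees.index)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(values.reshape(-1, 1))
    first = int(np.argmax(km.cluster_centers_.ravel()))
    return sorted(degrees.index[assign == first])


@dataclass(frozen=True)
class HubReport:
    """Per-gene screening outcome across all significant modules."""

    table: pd.DataFrame  # gene, module, degree, gs, mm, per-criterion flags

    def hubs(self, module: str | None = None) -> list[str]:
        t = self.table[self.table.is_hub]
        if module is not None:
            t = t[t.module == module]
        return sorted(t.index)

    def summary(self) -> str:
        lines = ["Real hub gene screen"]
        for m, grp in self.table.groupby("module"):
            lines.append(
                f"  {m:<14} genes={len(grp):<5d} first-cluster="
                f"{int(grp.in_first_cluster.sum()):<4d} hubs={int(grp.is_hub.sum())}"
            )
        lines.append(f"  total real hubs: {int(self.table.is_hub.sum())}")
        return "\n".join(lines)


def real_hub_genes(
    assignment: ModuleAssignment,
    criteria: HubCriteria,
    weights: pd.DataFrame,
    modules: list[str] | None = None,
) -> HubReport:
    """Screen significant modules for real hub genes.

    ``weights`` is the gene x gene edge-weight matrix (TOM by default in
    the pipeline).  A gene is a real hub when it lies in the first
    degree cluster AND |GS| >= gs_min AND |MM| >= mm_min.
    """
    if modules is None:
        modules = sorted(
            m
            for m in assignment.eigengenes.index
            if abs(assignment.module_trait_cor.get(m, 0.0)) > criteria.module_trait_min
        )
    rows = []
    stats = assignment.gene_stats
    for module in modules:
        genes = assignment.module_genes(module)
        thr = criteria.threshold_for(module)
        edges = module_edge_list(weights, assignment.labels, module, thr)
        if not len(edges):
            warnings.warn(
                f"module {module} has no edges above weight {thr}; empty hub set",
                stacklevel=2,
            )
        deg = degree(edges, genes)
        first = set(degree_first_cluster(deg, k=criteria.kmeans_k, seed=criteria.seed))
        for g in genes:
            abs_gs = float(stats.loc[g, "abs_gs"]) if g in stats.index else np.nan
            abs_mm = float(stats.loc[g, "abs_mm"]) if g in stats.index else np.nan
            in_first = g in first and len(edges) > 0
            pass_gs = bool(abs_gs >= criteria.gs_min)
            pass_mm = bool(abs_mm >= criteria.mm_min)
            rows.append(
                (g, module, int(deg.get(g, 0)), abs_gs, abs_mm, in_first, pass_gs, pass_mm,
                 in_first and pass_gs and pass_mm)
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "module", "degree", "abs_gs", "abs_mm",
            "in_first_cluster", "pass_gs", "pass_mm", "is_hub",
        ],
    ).set_index("gene_id")
    return HubReport(table=table)


def export_edges_tsv(edges: pd.DataFrame, path) -> None:
    """Write a 3-column TSV (source, target, weight) for network viewers."""
    out = edges.rename(columns={"gene_a": "source", "gene_b": "target"})
    out = out.sort_values(["source", "target"]).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
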