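"""Weighted gene coexpression analysis built from first principles.

The pipeline follows the standard weighted-network recipe: absolute
Pearson correlations between gene expression profiles (on log1p-FPKM by
default) are raised to a soft-threshold power chosen for approximate
scale-free topology; the resulting adjacency is converted to a
topological overlap matrix (TOM); genes are clustered by average-linkage
hierarchical clustering on 1 - TOM with a static tree cut; each module
is summarized by its eigengene (first principal component across
samples); and per-gene statistics relate expression to the trait (gene
significance, GS) and to the module eigengene (module membership, MM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .datatypes import ExpressionMatrix, ModuleAssignment
from .errors import ValidationError

# WGCNA-convention module colour order (largest module first).
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

UNASSIGNED = ModuleAssignment.UNASSIGNED


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _log_matrix(expr: ExpressionMatrix, transform: str = "log1p") -> pd.DataFrame:
    """Expression on the correlation scale, zero-variance genes dropped."""
    if transform == "log1p":
        vals = np.log1p(expr.values)
    elif transform == "raw":
        vals = expr.values.copy()
    else:
        raise ValidationError(f"unknown transform: {transform!r}")
    df = pd.DataFrame(vals, index=list(expr.gene_ids), columns=list(expr.sample_ids))
    sd = df.std(axis=1, ddof=0)
    dropped = list(df.index[sd == 0.0])
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} zero-variance gene(s) from correlation "
            f"analysis: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=3,
        )
        df = df.loc[sd > 0.0]
    return df


def _abs_cor(df: pd.DataFrame) -> np.ndarray:
    return np.abs(np.corrcoef(df.values))


def correlation_pvalue(r, n: int):
    """Two-sided p-value of the Pearson correlation t-test (df = n - 2)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return 2.0 * t_dist.sf(np.abs(t), df=n - 2)


# ---------------------------------------------------------------------------
# Soft-threshold selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SoftThresholdResult:
    table: pd.DataFrame  # power, scale_free_r2, slope, mean_connectivity
    beta: int
    r2_threshold: float


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of the log-log degree-distribution regression.

    Connectivities are binned into `n_bins` equal-width bins; empty bins
    are dropped; log10(frequency) is regressed on log10(mean connectivity
    per bin).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq, kmean = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        freq.append(mask.sum() / k.size)
        kmean.append(k[mask].mean())
    if len(freq) < 3:
        return 0.0, 0.0
    x = np.log10(kmean)
    y = np.log10(freq)
    slope, _ = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2), float(slope)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_threshold: float = 0.85,
    n_bins: int = 10,
    transform: str = "log1p",
) -> SoftThresholdResult:
    """Scale-free topology diagnostics per power and the chosen beta.

    The chosen beta is the smallest power whose fit reaches
    ``r2_threshold`` with a negative log-log slope; if none qualifies,
    the power with the largest (negative-slope) R^2 is used.
    """
    df = _log_matrix(expr, transform)
    if df.shape[0] < 30:
        raise ValidationError(f"too few genes for topology analysis: {df.shape[0]}")
    if df.shape[1] < 4:
        raise ValidationError(f"too few samples: {df.shape[1]}")
    cor = _abs_cor(df)
    rows = []
    for p in powers:
        a = cor**p
        k = a.sum(axis=1) - 1.0  # exclude self (|cor_ii| = 1)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append((int(p), r2, slope, float(k.mean())))
    table = pd.DataFrame(
        rows, columns=["power", "scale_free_r2", "slope", "mean_connectivity"]
    )
    ok = table[(table.scale_free_r2 >= r2_threshold) & (table.slope < 0)]
    if len(ok):
        beta = int(ok.power.iloc[0])
    else:
        neg = table[table.slope < 0]
        pool = neg if len(neg) else table
        beta = int(pool.power.iloc[int(np.argmax(pool.scale_free_r2.values))])
    return SoftThresholdResult(table=table, beta=beta, r2_threshold=r2_threshold)


# ---------------------------------------------------------------------------
# Adjacency and topological overlap
# ---------------------------------------------------------------------------

def adjacency(expr: ExpressionMatrix, beta: int, transform: str = "log1p") -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta with zero diagonal (genes x genes)."""
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    df = _log_matrix(expr, transform)
    a = _abs_cor(df) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=df.index, columns=df.index)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)."""
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValidationError("adjacency must be square and symmetric")
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return pd.DataFrame(tom)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def detect_modules(
    tom: pd.DataFrame, min_module_size: int = 30, merge_height: float = 0.8
) -> pd.Series:
    """Cluster genes on 1 - TOM and cut the tree at a fixed height.

    Average-linkage hierarchical clustering; clusters smaller than
    ``min_module_size`` are labelled "unassigned"; surviving modules are
    named by size rank (largest first) from the conventional colour list.
    Genes are sorted lexicographically before clustering so the result
    does not depend on input order.
    """
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    genes = sorted(tom.index)
    d = 1.0 - tom.loc[genes, genes].values
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=merge_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    # order clusters by size (desc), tie-broken by smallest member gene id
    sizes = labels.value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_module_size]
    keep.sort(key=lambda c: (-sizes[c], labels.index[labels == c].min()))
    name_map = {}
    for rank, c in enumerate(keep):
        name_map[c] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        )
    out = labels.map(lambda c: name_map.get(c, UNASSIGNED))
    out.name = "module"
    return out


# ---------------------------------------------------------------------------
# Eigengenes and trait statistics
# ---------------------------------------------------------------------------

def module_eigengene(
    expr: ExpressionMatrix, labels: pd.Series, transform: str = "log1p"
) -> pd.DataFrame:
    """First principal component of each module across samples.

    Expression is standardized per gene; the eigengene is the unit-norm
    first right-singular vector, sign-oriented so that its mean
    correlation with the module's gene profiles is non-negative.
    """
    df = _log_matrix(expr, transform)
    modules = sorted(m for m in labels.unique() if m != UNASSIGNED)
    rows = {}
    for m in modules:
        genes = [g for g in labels.index[labels == m] if g in df.index]
        if len(genes) < 2:
            raise ValidationError(f"module {m} has fewer than 2 usable genes")
        x = df.loc[genes].values
        sd = x.std(axis=1, ddof=0)
        if np.any(sd == 0):
            raise ValidationError(f"module {m} contains constant genes")
        xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        _, _, vt = np.linalg.svd(xs, full_matrices=False)
        me = vt[0]
        me = me / np.linalg.norm(me)
        cors = np.array([np.corrcoef(row, me)[0, 1] for row in xs])
        if cors.mean() < 0:
            me = -me
        rows[m] = me
    return pd.DataFrame(rows, index=list(df.columns)).T


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: Sequence[float]
) -> pd.DataFrame:
    """Pearson correlation (and two-sided p) of each eigengene with the trait."""
    trait = np.asarray(trait, dtype=float)
    if trait.std() == 0:
        raise ValidationError("trait is constant; correlations undefined")
    if trait.size != eigengenes.shape[1]:
        raise ValidationError("trait length does not match eigengene samples")
    n = trait.size
    cors = {}
    for m, me in eigengenes.iterrows():
        r = float(np.corrcoef(me.values, trait)[0, 1])
        cors[m] = (r, float(correlation_pvalue(r, n)))
    out = pd.DataFrame(cors, index=["cor", "p"]).T
    out.index.name = "module"
    return out


def significant_modules(
    module_trait: pd.DataFrame, min_abs_cor: float = 0.9
) -> list[str]:
    """Modules whose |eigengene-trait correlation| strictly exceeds the cut."""
    return sorted(module_trait.index[module_trait["cor"].abs() > min_abs_cor])


def gene_trait_statistics(
    expr: ExpressionMatrix,
    trait: Sequence[float],
    labels: pd.Series,
    eigengenes: pd.DataFrame,
    transform: str = "log1p",
) -> pd.DataFrame:
    """Per-gene GS/MM (signed and absolute) with correlation-test p-values.

    GS is the Pearson correlation of the gene's profile with the trait;
    MM is the correlation with the eigengene of the gene's own module
    (NaN for unassigned genes).
    """
    df = _log_matrix(expr, transform)
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    xs = df.values
    xs_std = (xs - xs.mean(axis=1, keepdims=True)) / xs.std(axis=1, keepdims=True)
    z_t = (trait - trait.mean()) / trait.std()
    gs = xs_std @ z_t / n
    mm = np.full(df.shape[0], np.nan)
    for m in eigengenes.index:
        me = eigengenes.loc[m].values
        z_me = (me - me.mean()) / me.std()
        mask = np.array([labels.get(g) == m for g in df.index])
        if mask.any():
            mm[mask] = xs_std[mask] @ z_me / n
    out = pd.DataFrame(
        {
            "module": [labels.get(g, UNASSIGNED) for g in df.index],
            "gs": gs,
            "abs_gs": np.abs(gs),
            "p_gs": correlation_pvalue(gs, n),
            "mm": mm,
            "abs_mm": np.abs(mm),
            "p_mm": correlation_pvalue(mm, n),
        },
        index=df.index,
    )
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# statsmodels-style facade
# ---------------------------------------------------------------------------

class WeightedCoexpressionNetwork:
    """Model object bundling the full coexpression workflow.

    ``pick_soft_threshold`` explores powers; ``fit`` runs adjacency ->
    TOM -> modules -> eigengenes -> trait statistics and returns a
    :class:`CoexpressionResults`.
    """

    def __init__(self, expr: ExpressionMatrix, transform: str = "log1p"):
        self.expr = expr
        self.transform = transform

    def pick_soft_threshold(self, powers=tuple(range(1, 21)), r2_threshold=0.85):
        return pick_soft_threshold(
            self.expr, powers=powers, r2_threshold=r2_threshold, transform=self.transform
        )

    def fit(
        self,
        beta: int | None = None,
        min_module_size: int = 30,
        merge_height: float = 0.8,
        min_abs_cor: float = 0.9,
    ) -> "CoexpressionResults":
        soft = None
        if beta is None:
            soft = self.pick_soft_threshold()
            beta = soft.beta
        adj = adjacency(self.expr, beta, transform=self.transform)
        tom = topological_overlap(adj)
        labels = detect_modules(tom, min_module_size=min_module_size, merge_height=merge_height)
        me = module_eigengene(self.expr, labels, transform=self.transform)
        mt = module_trait_correlation(me, self.expr.trait)
        stats = gene_trait_statistics(
            self.expr, self.expr.trait, labels, me, transform=self.transform
        )
        assignment = ModuleAssignment(
            labels=labels,
            eigengenes=me,
            module_trait_cor=mt["cor"],
            module_trait_p=mt["p"],
            gene_stats=stats,
        )
        return CoexpressionResults(
            network=self,
            beta=int(beta),
            soft_threshold=soft,
            adjacency=adj,
            tom=tom,
            assignment=assignment,
            min_abs_cor=min_abs_cor,
        )


@dataclass
class CoexpressionResults:
    """Fitted coexpression network: matrices, modules and statistics."""

    network: WeightedCoexpressionNetwork
    beta: int
    soft_threshold: SoftThresholdResult | None
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    assignment: ModuleAssignment
    min_abs_cor: float = 0.9

    def significant_modules(self, min_abs_cor: float | None = None) -> list[str]:
        cut = self.min_abs_cor if min_abs_cor is None else min_abs_cor
        mt = pd.DataFrame(
            {"cor": self.assignment.module_trait_cor, "p": self.assignment.module_trait_p}
        )
        return significant_modules(mt, min_abs_cor=cut)

    def summary(self) -> str:
        labels = self.assignment.labels
        sizes = labels[labels != UNASSIGNED].value_counts()
        sig = self.significant_modules()
        lines = [
            f"Weighted coexpression network (beta = {self.beta})",
            f"  genes analysed      : {labels.size}",
            f"  modules detected    : {sizes.size}",
            f"  unassigned genes    : {int((labels == UNASSIGNED).sum())}",
            f"  significant modules (|r| > {self.min_abs_cor}): {', '.join(sig) if sig else 'none'}",
        ]
        for m in sizes.index:
            r = self.assignment.module_trait_cor.get(m, float("nan"))
            lines.append(f"    {m:<14} n={sizes[m]:<5d} trait r = {r:+.3f}")
        return "\n".join(lines)
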