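"""Weighted co-expression module analysis.

The weighted network is built from per-gene expression as a = |cor|^beta
(unsigned), with the soft-threshold power beta chosen as the lowest one at
which the connectivity distribution fits a scale-free law (signed R^2 at or
above a target, 0.9 by default).  The topological overlap measure (TOM)
turns adjacency into a neighbourhood-sharing similarity; average-linkage
clustering of 1 - TOM followed by a static tree cut and iterative
eigengene merging yields modules, labelled with the conventional colour
vocabulary (turquoise, blue, brown, ... with grey = unassigned).  Module
eigengenes (first principal component of the standardised module
expression) are then correlated with clinical traits, and per-gene
summaries — gene significance (GS), module membership (MM) and
intramodular connectivity (kIM) — identify the trait-relevant hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .iolib import ExpressionDataset

logger = logging.getLogger("dynprognet")

# WGCNA's standard module colour order; grey is reserved for unassigned.
MODULE_COLOURS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]
GREY = "grey"


@dataclass
class SoftThresholdScan:
    """Result of the soft-threshold power scan."""

    powers: list[int]
    fit_r2: list[float]              # signed scale-free fit index per power
    mean_connectivity: list[float]
    chosen_beta: int
    target_r2: float
    reached_target: bool

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"power": self.powers, "fit_r2": self.fit_r2,
                             "mean_connectivity": self.mean_connectivity})


@dataclass
class ModuleAssignment:
    """Gene -> module labels plus derived module-level statistics."""

    module_of: pd.Series                      # index=gene, value=colour
    eigengenes: pd.DataFrame | None = None    # samples x modules
    module_trait_r: pd.DataFrame | None = None
    module_trait_p: pd.DataFrame | None = None
    gs: pd.DataFrame | None = None            # genes x traits, |cor|
    mm: pd.DataFrame | None = None            # genes x modules, cor
    k_im: pd.Series | None = None             # intramodular connectivity
    extras: dict = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        sizes = self.module_of[self.module_of != GREY].value_counts()
        return list(sizes.index)

    def members(self, module: str) -> list[str]:
        return list(self.module_of.index[self.module_of == module])


# ---------------------------------------------------------------------------
# Soft threshold
# ---------------------------------------------------------------------------


def adjacency_matrix(d: ExpressionDataset, beta: float) -> pd.DataFrame:
    """Unsigned weighted adjacency a_ij = |cor(x_i, x_j)|^beta, zero diagonal."""
    mat = d.values.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("all genes are constant; adjacency undefined")
    r = np.corrcoef(mat)
    r = np.nan_to_num(r, nan=0.0)             # constant genes: no co-variation
    a = np.abs(np.clip(r, -1, 1)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=d.values.index, columns=d.values.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity vector.

    Connectivity is discretised into equal-width bins; the fraction of
    genes per occupied bin is regressed as log10 p(k) on log10 mean(k).
    The index is R^2 times the negated sign of the slope, so a decaying
    (scale-free-like) degree distribution scores positive.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r ** 2 * -np.sign(slope))


def _fallback_power(n_samples: int) -> int:
    """Sample-size-based default power for unsigned networks.

    Used when no candidate power reaches the scale-free fit target, the
    standard practitioner fallback: picking the max-fit power instead
    tends to over-sharpen the adjacency and wash out module structure.
    """
    if n_samples < 20:
        return 9
    if n_samples < 30:
        return 8
    if n_samples < 40:
        return 7
    return 6


def soft_threshold_scan(d: ExpressionDataset,
                        powers: list[int] | tuple[int, ...] = tuple(range(1, 21)),
                        target_r2: float = 0.9,
                        min_mean_connectivity: float = 1.0
                        ) -> SoftThresholdScan:
    """Scan candidate powers and pick the lowest meeting the fit target.

    A power qualifies only while the mean connectivity stays at or above
    ``min_mean_connectivity``: beyond that the weighted network is
    essentially empty and the scale-free fit index becomes meaningless,
    so an apparently good fit there must not drive the choice.  If no
    qualifying power reaches the target, a sample-size-based default is
    chosen with a warning (9/8/7/6 for <20, <30, <40, >=40 samples).
    """
    if len(d.genes) < 20:
        raise ValueError("soft-threshold scan needs >= 20 genes")
    if len(d.samples) < 4:
        raise ValueError("soft-threshold scan needs >= 4 samples")
    mat = d.values.to_numpy(dtype=float)
    r = np.corrcoef(mat)
    r = np.abs(np.nan_to_num(np.clip(r, -1, 1), nan=0.0))
    np.fill_diagonal(r, 0.0)
    fits, ks = [], []
    for beta in powers:
        a = r ** beta
        k = a.sum(axis=1)
        fits.append(scale_free_fit(k))
        ks.append(float(k.mean()))
    chosen = None
    for beta, f, k in zip(powers, fits, ks):
        if f >= target_r2 and k >= min_mean_connectivity:
            chosen = beta
            break
    reached = chosen is not None
    if not reached:
        chosen = _fallback_power(len(d.samples))
        logger.warning("soft_threshold_scan: no power reaches fit R^2 >= %g; "
                       "falling back to beta=%d for n=%d samples "
                       "(max fit %.3f)", target_r2, chosen, len(d.samples),
                       max(fits))
    logger.info("soft_threshold_scan: chosen beta=%d (target %g, reached=%s)",
                chosen, target_r2, reached)
    return SoftThresholdScan(powers=list(powers), fit_r2=fits,
                             mean_connectivity=ks, chosen_beta=int(chosen),
                             target_r2=target_r2, reached_target=reached)


# ---------------------------------------------------------------------------
# TOM and module detection
# ---------------------------------------------------------------------------


def tom_matrix(adjacency: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, and TOM_ii = 1.  Entries must lie in [0, 1]; the diagonal is
    ignored (treated as zero) during the computation.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    np.fill_diagonal(a, 0.0)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengene(d: ExpressionDataset, member_genes: list[str]) -> pd.Series:
    """First principal component of the gene-standardised module submatrix.

    The returned sample vector has unit norm and is sign-oriented so that
    its average correlation with member-gene profiles is positive.
    """
    if not member_genes:
        raise ValueError("module has no member genes")
    sub = d.values.loc[member_genes].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    # orient: average correlation with members positive
    if np.mean([np.dot(row, me) for row in z]) < 0:
        me = -me
    return pd.Series(me, index=d.values.columns)


def _eigengene_frame(d: ExpressionDataset, module_of: pd.Series) -> pd.DataFrame:
    mods = [m for m in module_of.unique() if m != GREY]
    data = {m: module_eigengene(d, list(module_of.index[module_of == m]))
            for m in mods}
    return pd.DataFrame(data, index=d.values.columns)


def detect_modules(diss: np.ndarray, genes: list[str],
                   expr: ExpressionDataset | None = None,
                   min_module_size: int = 30, cut_height: float = 0.995,
                   merge_height: float = 0.25) -> ModuleAssignment:
    """Average-linkage clustering of a dissimilarity matrix into modules.

    The tree is cut statically at ``cut_height``; clusters smaller than
    ``min_module_size`` are sent to grey.  When ``expr`` is given, modules
    whose eigengenes are closer than ``merge_height`` (1 - cor) are merged
    iteratively.  Surviving modules get colour labels by decreasing size.
    """
    diss = np.asarray(diss, dtype=float)
    if diss.shape[0] != diss.shape[1]:
        raise ValueError("dissimilarity must be square")
    dsym = (diss + diss.T) / 2.0
    np.fill_diagonal(dsym, 0.0)
    z = linkage(squareform(dsym, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=pd.Index(genes, name="gene"))
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = 0                  # 0 = unassigned
    if expr is not None:
        labels = _merge_close_modules(expr, labels, merge_height)
    module_of = _colourise(labels)
    n_mod = (module_of != GREY).sum()
    logger.info("detect_modules: %d modules over %d of %d genes",
                module_of[module_of != GREY].nunique(), n_mod, len(genes))
    return ModuleAssignment(module_of=module_of)


def _merge_close_modules(d: ExpressionDataset, labels: pd.Series,
                         merge_height: float) -> pd.Series:
    """Iteratively merge module pairs whose eigengene 1-cor < merge_height."""
    labels = labels.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m != 0)
        if len(mods) < 2:
            return labels
        mes = np.vstack([
            module_eigengene(d, list(labels.index[labels == m])).to_numpy()
            for m in mods])
        cor = np.corrcoef(mes)
        dis = 1.0 - cor
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= merge_height:
            return labels
        labels[labels == mods[j]] = mods[i]


def _colourise(labels: pd.Series) -> pd.Series:
    """Numeric cluster ids -> colour names by decreasing module size."""
    sizes = labels[labels != 0].value_counts()
    name_of = {0: GREY}
    for rank, mod in enumerate(sizes.index):
        name_of[mod] = (MODULE_COLOURS[rank] if rank < len(MODULE_COLOURS)
                        else f"module{rank + 1}")
    return labels.map(name_of)


def detect_modules_from_expression(
        d: ExpressionDataset, beta: int, min_module_size: int = 30,
        cut_height: float = 0.995, merge_height: float = 0.25
) -> tuple[ModuleAssignment, pd.DataFrame]:
    """Convenience wrapper: adjacency -> TOM dissimilarity -> modules.

    Returns the assignment (with eigengenes filled in) and the adjacency.
    """
    adj = adjacency_matrix(d, beta)
    diss = 1.0 - tom_matrix(adj.to_numpy())
    assignment = detect_modules(diss, d.genes, expr=d,
                                min_module_size=min_module_size,
                                cut_height=cut_height,
                                merge_height=merge_height)
    assignment.eigengenes = _eigengene_frame(d, assignment.module_of)
    return assignment, adj


# ---------------------------------------------------------------------------
# Module-trait statistics
# ---------------------------------------------------------------------------


def _cor_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the t distribution with n-2 df."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        return np.nan, np.nan
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of each module eigengene with each trait.

    Samples missing a trait value are dropped pairwise; cells with fewer
    than 4 complete pairs or a zero-variance trait are NaN.
    """
    common = [s for s in eigengenes.index if s in traits.index]
    me = eigengenes.loc[common]
    tr = traits.loc[common]
    r = pd.DataFrame(index=me.columns, columns=tr.columns, dtype=float)
    p = pd.DataFrame(index=me.columns, columns=tr.columns, dtype=float)
    for m in me.columns:
        for t in tr.columns:
            r.loc[m, t], p.loc[m, t] = _cor_test(
                me[m].to_numpy(dtype=float), tr[t].to_numpy(dtype=float))
    return r, p


def gene_significance_and_mm(d: ExpressionDataset, traits: pd.DataFrame,
                             assignment: ModuleAssignment
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GS = |cor(gene, trait)| per gene and trait; MM = cor(gene, eigengene)."""
    if assignment.eigengenes is None:
        raise ValueError("assignment lacks eigengenes")
    common = [s for s in d.values.columns if s in traits.index]
    expr = d.values[common]
    gs = pd.DataFrame(index=expr.index, columns=traits.columns, dtype=float)
    for t in traits.columns:
        y = traits.loc[common, t].to_numpy(dtype=float)
        for g in expr.index:
            r, _ = _cor_test(expr.loc[g].to_numpy(dtype=float), y)
            gs.loc[g, t] = abs(r) if np.isfinite(r) else np.nan
    mm = pd.DataFrame(index=expr.index, columns=assignment.eigengenes.columns,
                      dtype=float)
    for m in assignment.eigengenes.columns:
        me = assignment.eigengenes.loc[d.values.columns, m].to_numpy()
        for g in expr.index:
            r, _ = _cor_test(d.values.loc[g].to_numpy(dtype=float), me)
            mm.loc[g, m] = r
    assignment.gs, assignment.mm = gs, mm
    return gs, mm


def intramodular_connectivity(adjacency: pd.DataFrame,
                              assignment: ModuleAssignment) -> pd.Series:
    """kIM(g) = sum of g's adjacency to the other members of its module.

    Grey (unassigned) genes get NaN.
    """
    k = pd.Series(np.nan, index=assignment.module_of.index, name="k_im")
    for m in assignment.modules:
        members = assignment.members(m)
        sub = adjacency.loc[members, members].to_numpy(dtype=float).copy()
        np.fill_diagonal(sub, 0.0)
        k.loc[members] = sub.sum(axis=1)
    assignment.k_im = k
    return k


def module_hub_table(assignment: ModuleAssignment, top_k: int = 10
                     ) -> pd.DataFrame:
    """Top-k genes per module by intramodular connectivity."""
    if assignment.k_im is None:
        raise ValueError("run intramodular_connectivity first")
    rows = []
    for m in assignment.modules:
        sub = assignment.k_im.loc[assignment.members(m)]
        for g, v in sub.sort_values(ascending=False).head(top_k).items():
            rows.append((m, g, v))
    return pd.DataFrame(rows, columns=["module", "gene", "k_im"])
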