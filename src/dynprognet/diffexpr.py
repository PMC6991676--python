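"""Probe collapsing, Z-score normalisation and transition-wise differential
expression.

A *dynamic* differentially expressed gene (dynamic DEG) is one that passes
the BH-FDR threshold in BOTH successive stage comparisons (stage1 vs stage2
and stage2 vs stage3), so its expression keeps shifting along the disease
course rather than changing once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iolib import ExpressionDataset

logger = logging.getLogger("dynprognet")


@dataclass
class TransitionStats:
    """Per-gene two-group t-test results for one stage transition."""

    transition: tuple[str, str]          # (earlier, later)
    table: pd.DataFrame                  # index=gene; mean_earlier, mean_later,
                                         # t_statistic, p_value, q_value

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class DynamicDegSet:
    """Genes significant in both transitions, with per-transition direction."""

    genes: list[str]
    directions: pd.DataFrame             # index=gene; dir1, dir2 in {+1,-1,0}
    alpha: float


def collapse_probes_mean(d: ExpressionDataset,
                         probe_map: dict[str, str]) -> ExpressionDataset:
    """Collapse probe rows to genes by the per-sample arithmetic mean.

    Probes absent from ``probe_map`` are dropped (count logged).
    """
    mapped = [p for p in d.values.index if p in probe_map]
    n_dropped = len(d.values.index) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes_mean: dropping %d unmapped probes", n_dropped)
    if not mapped:
        raise ValueError("no probes map to any gene")
    sub = d.values.loc[mapped]
    gene_of = pd.Series({p: probe_map[p] for p in mapped})
    collapsed = sub.groupby(gene_of).mean()
    collapsed.index = collapsed.index.astype(str)
    return d.with_values(collapsed)


def zscore_normalize(d: ExpressionDataset) -> ExpressionDataset:
    """Per-gene Z-score across all samples jointly: (x - mean) / sd, n-1 sd.

    Scaling across all samples (rather than within each stage) preserves
    between-stage mean differences for the downstream t-tests.  Genes with
    zero variance are set to all-zero and flagged in
    ``dataset.values.attrs['zero_variance_genes']``.
    """
    if d.values.shape[1] < 2:
        raise ValueError("Z-scoring needs >= 2 samples per gene")
    mat = d.values.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (mat - mean) / sd
    z[flat, :] = 0.0
    out = pd.DataFrame(z, index=d.values.index, columns=d.values.columns)
    out.attrs["zero_variance_genes"] = list(d.values.index[flat])
    if flat.any():
        logger.info("zscore_normalize: %d zero-variance genes set to 0",
                    int(flat.sum()))
    return d.with_values(out)


def ttest_transition(d: ExpressionDataset, earlier: str, later: str,
                     welch: bool = False) -> TransitionStats:
    """Two-sided two-sample t-test per gene between two stages.

    Pooled-variance (Student) by default; ``welch=True`` switches to the
    unequal-variance form.  Degenerate genes (zero pooled variance) get
    p=1 when the group means agree and p=0 otherwise.
    """
    x = d.stage_matrix(earlier).to_numpy(dtype=float)
    y = d.stage_matrix(later).to_numpy(dtype=float)
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("each stage needs >= 2 samples for a t-test")
    t, p = stats.ttest_ind(y, x, axis=1, equal_var=not welch)
    mx, my = x.mean(axis=1), y.mean(axis=1)
    # zero-variance genes: scipy returns nan
    bad = ~np.isfinite(p)
    if bad.any():
        same = np.isclose(mx[bad], my[bad])
        p = p.copy()
        t = t.copy()
        p[np.where(bad)[0][same]] = 1.0
        t[np.where(bad)[0][same]] = 0.0
        p[np.where(bad)[0][~same]] = 0.0
        t[np.where(bad)[0][~same]] = np.inf * np.sign(
            my[bad][~same] - mx[bad][~same])
    q = bh_fdr(p)
    table = pd.DataFrame(
        {"mean_earlier": mx, "mean_later": my, "t_statistic": t,
         "p_value": p, "q_value": q},
        index=d.values.index,
    )
    return TransitionStats(transition=(earlier, later), table=table)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1, returned in the
    original order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def dynamic_degs(s1: TransitionStats, s2: TransitionStats,
                 alpha: float = 0.05) -> DynamicDegSet:
    """Genes with q < alpha in both transitions, with direction codes.

    Directions come from the sign of the later-minus-earlier mean in each
    transition; no sign consistency between transitions is required.
    """
    if list(s1.table.index) != list(s2.table.index):
        if set(s1.table.index) != set(s2.table.index):
            raise ValueError("transition stats cover different gene universes")
        s2 = TransitionStats(s2.transition, s2.table.loc[s1.table.index])
    hit = (s1.table["q_value"] < alpha) & (s2.table["q_value"] < alpha)
    genes = list(s1.table.index[hit])
    d1 = np.sign(s1.table["mean_later"] - s1.table["mean_earlier"]).astype(int)
    d2 = np.sign(s2.table["mean_later"] - s2.table["mean_earlier"]).astype(int)
    directions = pd.DataFrame({"dir1": d1[hit], "dir2": d2[hit]},
                              index=pd.Index(genes, name="gene"))
    logger.info("dynamic_degs: %d of %d genes pass q < %g in both transitions",
                len(genes), len(s1.table), alpha)
    return DynamicDegSet(genes=genes, directions=directions, alpha=alpha)


def deg_result_table(s1: TransitionStats, s2: TransitionStats,
                     dyn: DynamicDegSet) -> pd.DataFrame:
    """Flat per-gene report table combining both transitions."""
    out = pd.DataFrame(index=s1.table.index)
    out.index.name = "gene"
    for i, s in ((1, s1), (2, s2)):
        out[f"t{i}"] = s.table["t_statistic"]
        out[f"p{i}"] = s.table["p_value"]
        out[f"q{i}"] = s.table["q_value"]
    out["dynamic"] = out.index.isin(dyn.genes)
    out["dir1"] = dyn.directions["dir1"].reindex(out.index).fillna(0).astype(int)
    out["dir2"] = dyn.directions["dir2"].reindex(out.index).fillna(0).astype(int)
    return out
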