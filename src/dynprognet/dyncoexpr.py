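"""Per-stage Pearson correlations and the d-PCC link statistic.

For each gene pair the Pearson correlation r is computed separately inside
each stage; the *differential* PCC of a transition is the later-stage r
minus the earlier-stage r, so d-PCC lies in [-2, 2].  A pair whose |d-PCC|
falls inside a fixed band (0.8 to 2 by default) is a differentially
co-expressed link (DL) for that transition, and a *dynamic* DL is a pair
that is a DL in both successive transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iolib import ExpressionDataset, _canon

logger = logging.getLogger("dynprognet")


@dataclass
class StageCorrelations:
    """Symmetric gene x gene Pearson matrix for one stage.

    Zero-variance genes are undefined: their rows/columns are NaN and they
    are excluded from pair statistics downstream.
    """

    stage: str
    genes: list[str]
    pcc: np.ndarray            # (G, G), NaN where undefined
    n_samples: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pcc, index=self.genes, columns=self.genes)


def pcc_matrix(d: ExpressionDataset, stage: str,
               gene_subset: list[str] | None = None,
               block_size: int = 512) -> StageCorrelations:
    """All-pairs Pearson correlation within one stage's samples.

    Computed block-wise on standardised rows so memory stays bounded for
    large gene counts.  Requires >= 3 samples in the stage.
    """
    sub = d.stage_matrix(stage)
    if gene_subset is not None:
        keep = [g for g in d.genes if g in set(gene_subset)]
        sub = sub.loc[keep]
    n = sub.shape[1]
    if n < 3:
        raise ValueError(f"stage {stage!r} has {n} samples; need >= 3")
    genes = list(sub.index)
    mat = sub.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    degenerate = sd[:, 0] == 0
    sd[degenerate] = 1.0
    z = (mat - mean) / sd                      # rows with unit population sd
    g = len(genes)
    pcc = np.empty((g, g))
    for i0 in range(0, g, block_size):
        i1 = min(i0 + block_size, g)
        pcc[i0:i1, :] = z[i0:i1] @ z.T / n
    np.clip(pcc, -1.0, 1.0, out=pcc)
    np.fill_diagonal(pcc, 1.0)
    pcc[degenerate, :] = np.nan
    pcc[:, degenerate] = np.nan
    return StageCorrelations(stage=stage, genes=genes, pcc=pcc, n_samples=n)


def dpcc(c_earlier: StageCorrelations, c_later: StageCorrelations) -> np.ndarray:
    """Elementwise later - earlier correlation difference.

    NaN wherever either stage's correlation is undefined.
    """
    if c_earlier.genes != c_later.genes:
        raise ValueError("correlation matrices cover different gene universes")
    return c_later.pcc - c_earlier.pcc


def select_dls(dp: np.ndarray, genes: list[str], low: float = 0.8,
               high: float = 2.0) -> set[tuple[str, str]]:
    """Pairs with low <= |d-PCC| <= high (closed interval), upper triangle.

    NaN (undefined) entries are never selected.
    """
    if not low < high:
        raise ValueError("need low < high")
    a = np.abs(dp)
    iu, ju = np.triu_indices(len(genes), k=1)
    vals = a[iu, ju]
    hit = (vals >= low) & (vals <= high)       # NaN compares False
    return {_canon(genes[i], genes[j])
            for i, j in zip(iu[hit], ju[hit])}


def dynamic_dls(dl1: set[tuple[str, str]],
                dl2: set[tuple[str, str]]) -> set[tuple[str, str]]:
    """Pairs that are DLs in both transitions (set intersection)."""
    return dl1 & dl2


def dynamic_link_table(d: ExpressionDataset,
                       low: float = 0.8, high: float = 2.0,
                       gene_subset: list[str] | None = None,
                       require_sign_flip: bool = False,
                       block_size: int = 512) -> pd.DataFrame:
    """Full DL analysis over the dataset's three (or more) stages.

    Returns one row per candidate pair that is a DL in at least one
    transition, with per-stage correlations, both d-PCCs and the DL /
    dynamic-DL flags.  With ``require_sign_flip`` a dynamic DL must also
    have d-PCC 1 and d-PCC 2 of opposite sign (the stricter reading of
    "rewired back and forth").
    """
    stages = d.stage_order
    if len(stages) < 3:
        raise ValueError("dynamic DLs need >= 3 ordered stages")
    cors = [pcc_matrix(d, s, gene_subset=gene_subset, block_size=block_size)
            for s in stages]
    genes = cors[0].genes
    dp1 = dpcc(cors[0], cors[1])
    dp2 = dpcc(cors[1], cors[2])
    dl1 = select_dls(dp1, genes, low, high)
    dl2 = select_dls(dp2, genes, low, high)
    union = sorted(dl1 | dl2)
    idx = {g: i for i, g in enumerate(genes)}
    rows = []
    for a, b in union:
        i, j = idx[a], idx[b]
        d1, d2 = dp1[i, j], dp2[i, j]
        is1, is2 = (a, b) in dl1, (a, b) in dl2
        dyn = is1 and is2
        if dyn and require_sign_flip:
            dyn = d1 * d2 < 0
        rows.append((a, b, *(c.pcc[i, j] for c in cors[:3]), d1, d2,
                     is1, is2, dyn))
    out = pd.DataFrame(rows, columns=[
        "geneA", "geneB", "pcc_stage1", "pcc_stage2", "pcc_stage3",
        "dpcc1", "dpcc2", "is_dl1", "is_dl2", "is_dynamic_dl"])
    logger.info("dynamic_link_table: %d DL1, %d DL2, %d dynamic DLs "
                "(|d-PCC| in [%g, %g])",
                len(dl1), len(dl2), int(out["is_dynamic_dl"].sum()), low, high)
    return out


def dynamic_dl_pairs(table: pd.DataFrame) -> set[tuple[str, str]]:
    """Canonical pair set of the dynamic DLs in a link table."""
    sub = table[table["is_dynamic_dl"]]
    return {_canon(a, b) for a, b in zip(sub["geneA"], sub["geneB"])}
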