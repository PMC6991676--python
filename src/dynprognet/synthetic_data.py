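"""Synthetic three-stage expression data with planted, recorded truth.

Every structure the pipeline hunts for can be planted here: genes whose
mean keeps shifting across both stage transitions (dynamic DEGs), gene
pairs whose correlation is rewired between stages by a chosen delta-rho
(dynamic DLs), latent-factor co-expression modules, a clinical trait tied
to one module's factor, and a background interaction table covering a
chosen fraction of the rewired pairs.  The planted truth is returned
alongside the data so recovery can be scored exactly.

The default configuration mirrors the motivating study's shape — three
ordered disease stages with cohort sizes of a few tens of samples — at a
gene count small enough for exhaustive pair analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .iolib import EdgeTable, ExpressionDataset, GeneSetCollection, _canon

logger = logging.getLogger("dynprognet")

STAGE_LABELS = ["stage1", "stage2", "stage3"]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-data generator.

    Defaults plant moderate, recoverable structure: 2-SD expression shifts
    per transition, correlation rewiring of +-1.2-1.4 between stages, four
    50-gene one-factor modules with noise sd 0.5, and a trait equal to the
    first module's factor plus noise.
    """

    n_genes: int = 500
    samples_per_stage: tuple[int, int, int] = (30, 30, 30)
    n_dynamic_de: int = 30
    de_effect: float = 2.0                     # mean shift per transition, SD units
    de_signs: tuple[int, int] = (1, 1)         # direction per transition
    n_rewired_pairs: int = 20
    rho_by_stage: tuple[float, float, float] = (0.8, -0.6, 0.6)
    n_modules: int = 4
    module_size: int = 50
    module_factor_sd: float = 1.0
    noise_sd: float = 0.5
    trait_module_index: int = 0
    trait_noise_sd: float = 0.5
    ppi_coverage: float = 1.0                  # fraction of rewired pairs in background
    ppi_n_random_edges: int = 200
    seed: int = 42

    def __post_init__(self) -> None:
        needed = (self.n_dynamic_de + 2 * self.n_rewired_pairs
                  + self.n_modules * self.module_size)
        if needed > self.n_genes:
            raise ValueError(
                f"gene budget overcommitted: {needed} planted > {self.n_genes}")
        if any(abs(r) >= 1 for r in self.rho_by_stage):
            raise ValueError("planted |rho| must be < 1")
        if not all(c >= 0 for c in (self.n_dynamic_de, self.n_rewired_pairs,
                                    self.n_modules, self.module_size)):
            raise ValueError("counts must be >= 0")
        if self.n_modules and not 0 <= self.trait_module_index < self.n_modules:
            raise ValueError("trait_module_index out of range")


@dataclass
class SyntheticTruth:
    """Record of everything the generator planted."""

    de_genes: list[str]
    de_directions: dict[str, tuple[int, int]]
    rewired_pairs: list[tuple[str, str]]
    rho_by_stage: tuple[float, float, float]
    module_of: dict[str, str] = field(default_factory=dict)  # gene -> module name
    trait_module: str | None = None
    seed: int = 0

    def module_collection(self) -> GeneSetCollection:
        sets: dict[str, set[str]] = {}
        for g, m in self.module_of.items():
            sets.setdefault(m, set()).add(g)
        return GeneSetCollection(
            sets=sets,
            descriptions={m: "planted latent-factor module" for m in sets})


def _bivariate(rng: np.random.Generator, rho: float, n: int) -> np.ndarray:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal([0.0, 0.0], cov, size=n).T


def generate(config: GeneratorConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw one synthetic dataset plus its truth record.

    Baseline expression is i.i.d. N(0,1).  Planted structures overwrite
    disjoint gene blocks: dynamic-DE genes get the configured mean shift
    added at stage 2 and again at stage 3; each rewired pair is redrawn
    per stage from a bivariate normal with that stage's planted rho
    (keeping standard-normal marginals); module genes are factor x loading
    plus noise.  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n1, n2, n3 = config.samples_per_stage
    n_samples = n1 + n2 + n3
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    stage_of = {}
    bounds = [0, n1, n1 + n2, n_samples]
    for si, stage in enumerate(STAGE_LABELS):
        for j in range(bounds[si], bounds[si + 1]):
            stage_of[samples[j]] = stage
    stage_cols = [list(range(bounds[i], bounds[i + 1])) for i in range(3)]

    mat = rng.standard_normal((config.n_genes, n_samples))

    cursor = 0
    # dynamic-DE genes: cumulative mean shifts
    de_genes = genes[cursor:cursor + config.n_dynamic_de]
    cursor += config.n_dynamic_de
    s1, s2 = config.de_signs
    for gi in range(len(de_genes)):
        row = genes.index(de_genes[gi])
        mat[row, stage_cols[1]] += s1 * config.de_effect
        mat[row, stage_cols[2]] += (s1 + s2) * config.de_effect

    # rewired pairs: replace baseline with per-stage bivariate draws
    rewired: list[tuple[str, str]] = []
    for _ in range(config.n_rewired_pairs):
        a, b = genes[cursor], genes[cursor + 1]
        cursor += 2
        ia, ib = genes.index(a), genes.index(b)
        for si, rho in enumerate(config.rho_by_stage):
            draw = _bivariate(rng, rho, len(stage_cols[si]))
            mat[ia, stage_cols[si]] = draw[0]
            mat[ib, stage_cols[si]] = draw[1]
        rewired.append(_canon(a, b))

    # latent-factor modules
    module_of: dict[str, str] = {}
    factors = rng.normal(0.0, config.module_factor_sd,
                         size=(config.n_modules, n_samples))
    for m in range(config.n_modules):
        name = f"M{m + 1}"
        members = genes[cursor:cursor + config.module_size]
        cursor += config.module_size
        loadings = rng.uniform(0.5, 1.0, size=len(members))
        for g, lo in zip(members, loadings):
            row = genes.index(g)
            mat[row] = lo * factors[m] + rng.normal(0.0, config.noise_sd,
                                                    size=n_samples)
            module_of[g] = name

    traits = None
    trait_module = None
    if config.n_modules:
        trait_module = f"M{config.trait_module_index + 1}"
        trait = (factors[config.trait_module_index]
                 + rng.normal(0.0, config.trait_noise_sd, size=n_samples))
        traits = pd.DataFrame({"trait": trait}, index=samples)

    values = pd.DataFrame(mat, index=genes, columns=samples)
    dataset = ExpressionDataset(values=values, stage_of=stage_of,
                                stage_order=list(STAGE_LABELS), traits=traits)
    truth = SyntheticTruth(
        de_genes=list(de_genes),
        de_directions={g: (s1, s2) for g in de_genes},
        rewired_pairs=rewired,
        rho_by_stage=config.rho_by_stage,
        module_of=module_of,
        trait_module=trait_module,
        seed=config.seed,
    )
    logger.info("generate: %d genes x %d samples; planted %d DE genes, "
                "%d rewired pairs, %d modules", config.n_genes, n_samples,
                len(de_genes), len(rewired), config.n_modules)
    return dataset, truth


def generate_background_ppi(truth: SyntheticTruth, config: GeneratorConfig
                            ) -> EdgeTable:
    """Background interaction table covering the planted rewired pairs.

    Includes ``ppi_coverage`` of the rewired pairs plus Erdos-Renyi random
    edges among all genes.  Confidences are Uniform(0.2, 1) so that a
    score-above-0.4 filter has something to remove.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    table = EdgeTable()
    n_keep = int(round(config.ppi_coverage * len(truth.rewired_pairs)))
    keep = rng.choice(len(truth.rewired_pairs), size=n_keep, replace=False)
    for i in sorted(keep):
        a, b = truth.rewired_pairs[i]
        table.add(a, b, float(rng.uniform(0.2, 1.0)), "planted")
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    added = 0
    while added < config.ppi_n_random_edges:
        i, j = rng.integers(0, len(genes), size=2)
        if i == j:
            continue
        before = len(table)
        table.add(genes[i], genes[j], float(rng.uniform(0.2, 1.0)), "random")
        if len(table) > before:
            added += 1
    return table


def score_recovery(truth: SyntheticTruth,
                   found_degs: set[str] | list[str] | None = None,
                   found_dls: set[tuple[str, str]] | None = None,
                   found_modules: dict[str, str] | pd.Series | None = None
                   ) -> pd.DataFrame:
    """Precision/recall of DEG and DL calls and ARI of module labels
    against the planted truth."""
    rows = []
    if found_degs is not None:
        found = set(found_degs)
        planted = set(truth.de_genes)
        tp = len(found & planted)
        rows.append(("deg_recall", tp / len(planted) if planted else np.nan))
        rows.append(("deg_precision", tp / len(found) if found else np.nan))
    if found_dls is not None:
        found_p = {_canon(a, b) for a, b in found_dls}
        planted_p = set(truth.rewired_pairs)
        tp = len(found_p & planted_p)
        rows.append(("dl_recall", tp / len(planted_p) if planted_p else np.nan))
        rows.append(("dl_precision", tp / len(found_p) if found_p else np.nan))
    if found_modules is not None:
        if isinstance(found_modules, pd.Series):
            found_modules = found_modules.to_dict()
        genes = sorted(truth.module_of)
        y_true = [truth.module_of[g] for g in genes]
        y_pred = [str(found_modules.get(g, "grey")) for g in genes]
        rows.append(("module_ari", adjusted_rand_score(y_true, y_pred)))
    return pd.DataFrame(rows, columns=["metric", "value"])
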