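"""Core data containers, run configuration and file format support.

The pipeline consumes a gene-by-sample expression matrix with an ordered
stage assignment (e.g. normal -> COPD -> SQCC+COPD), one or more background
interaction edge tables, optional per-sample clinical traits and gene-set
collections in GMT format.  Everything here is deliberately dumb plumbing:
parsing, canonicalisation and validation, no statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dynprognet")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Gene x sample expression values with an ordered stage grouping.

    Parameters
    ----------
    values
        DataFrame, rows indexed by gene (or probe) identifier, columns by
        sample identifier.
    stage_of
        Mapping sample -> stage label.  Every column of ``values`` must
        appear here with a label drawn from ``stage_order``.
    stage_order
        Ordered stage labels defining the disease progression.  Three in
        the motivating study, but any number >= 2 is accepted.
    traits
        Optional sample x trait numeric table (rows = samples).
    """

    values: pd.DataFrame
    stage_of: dict[str, str]
    stage_order: list[str]
    traits: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dups)[:5]}")
        if len(self.stage_order) != len(set(self.stage_order)):
            raise ValueError("stage_order contains repeated labels")
        known = set(self.stage_order)
        missing = [s for s in self.values.columns if s not in self.stage_of]
        if missing:
            raise ValueError(f"samples lack a stage assignment: {missing[:5]}")
        bad = {s: g for s, g in self.stage_of.items()
               if s in self.values.columns and g not in known}
        if bad:
            raise ValueError(f"stage labels outside stage_order: {bad}")

    # -- convenience accessors ------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_stage(self, stage: str) -> list[str]:
        if stage not in self.stage_order:
            raise ValueError(f"unknown stage label: {stage!r}")
        return [s for s in self.values.columns if self.stage_of[s] == stage]

    def stage_matrix(self, stage: str) -> pd.DataFrame:
        """Sub-matrix of the samples belonging to one stage."""
        return self.values[self.samples_of_stage(stage)]

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        return replace(self, values=values)

    def transitions(self) -> list[tuple[str, str]]:
        """Successive stage pairs, e.g. [(s1, s2), (s2, s3)]."""
        return list(zip(self.stage_order[:-1], self.stage_order[1:]))


def _canon(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair: lexicographically smaller symbol first."""
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeTable:
    """Undirected interaction edges with optional confidence scores.

    Pairs are stored canonically (smaller symbol first), self-loops are
    dropped and duplicates collapsed keeping the maximal confidence.
    ``sources`` records provenance tags per edge.
    """

    edges: dict[tuple[str, str], float | None] = field(default_factory=dict)
    sources: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[str, str]] | list[tuple[str, str, float]],
        source_tag: str = "",
    ) -> "EdgeTable":
        t = cls()
        for rec in pairs:
            a, b = str(rec[0]), str(rec[1])
            conf = float(rec[2]) if len(rec) > 2 and rec[2] is not None else None
            t.add(a, b, conf, source_tag)
        return t

    def add(self, a: str, b: str, confidence: float | None = None,
            source_tag: str = "") -> None:
        if a == b:
            return
        key = _canon(a, b)
        old = self.edges.get(key)
        if key not in self.edges:
            self.edges[key] = confidence
            self.sources[key] = [source_tag] if source_tag else []
        else:
            if confidence is not None and (old is None or confidence > old):
                self.edges[key] = confidence
            if source_tag and source_tag not in self.sources[key]:
                self.sources[key].append(source_tag)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _canon(*pair) in self.edges

    def confidence(self, a: str, b: str) -> float | None:
        return self.edges[_canon(a, b)]

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), c in self.edges.items():
            g.add_edge(a, b, confidence=c, sources="|".join(self.sources[(a, b)]))
        return g


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets not allowed: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    ``fdr_deg``/``fdr_deg_strict`` gate the per-transition differential
    expression calls; ``dpcc_low``/``dpcc_high`` bound |d-PCC| for a
    differentially co-expressed link; ``confidence_min`` is the strict
    lower bound applied to scored background edges.
    """

    fdr_deg: float = 0.05
    fdr_deg_strict: float = 0.01
    dpcc_low: float = 0.8
    dpcc_high: float = 2.0
    confidence_min: float = 0.4
    rng_seed: int = 42
    welch: bool = False
    ttest_on_raw: bool = False
    require_sign_flip: bool = False
    map_mode: str = "edges"           # "edges" | "nodes"
    # WGCNA-style module parameters
    powers: tuple[int, ...] = tuple(range(1, 21))
    target_r2: float = 0.9
    min_module_size: int = 30
    cut_height: float = 0.995
    merge_height: float = 0.25
    block_size: int = 512

    def __post_init__(self) -> None:
        if not (0 < self.fdr_deg <= 1):
            raise ValueError("fdr_deg must be in (0, 1]")
        if not (0 <= self.dpcc_low < self.dpcc_high <= 2):
            raise ValueError("need 0 <= dpcc_low < dpcc_high <= 2")
        if self.map_mode not in ("edges", "nodes"):
            raise ValueError("map_mode must be 'edges' or 'nodes'")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "powers" in raw:
            raw["powers"] = tuple(raw["powers"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["powers"] = list(self.powers)
        return d


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_stage_map(path: str) -> tuple[dict[str, str], list[str]]:
    """Read a two-column sample->stage TSV; stage order = first appearance."""
    stage_of: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'sample<TAB>stage'")
            sample, stage = parts[0], parts[1]
            if sample in stage_of:
                raise ValueError(f"{path}:{ln}: duplicate sample id {sample!r}")
            stage_of[sample] = stage
            if stage not in order:
                order.append(stage)
    return stage_of, order


def read_expression_tsv(
    path: str,
    stage_map: dict[str, str] | str,
    stage_order: list[str] | None = None,
    traits: pd.DataFrame | None = None,
) -> ExpressionDataset:
    """Read a gene-by-sample TSV (first column = gene id, numeric body).

    ``stage_map`` is either a sample->stage mapping or the path of a
    two-column sidecar TSV.  Samples without a stage assignment are an
    error, matching the contract that every analysed sample is staged.
    """
    if isinstance(stage_map, str):
        stage_of, inferred_order = read_stage_map(stage_map)
        stage_order = stage_order or inferred_order
    else:
        stage_of = dict(stage_map)
        if stage_order is None:
            seen: list[str] = []
            for g in stage_of.values():
                if g not in seen:
                    seen.append(g)
            stage_order = seen

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample id in header")
    values = pd.DataFrame(index=df.index.astype(str), columns=df.columns,
                          dtype=float)
    for col in df.columns:
        try:
            values[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric cell at row {bad!r}, column {col!r}"
            ) from None
    if values.isna().any().any():
        row = values.index[values.isna().any(axis=1)][0]
        col = values.columns[values.isna().any(axis=0)][0]
        raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    logger.info("read_expression_tsv: %d genes x %d samples from %s",
                len(values), values.shape[1], path)
    return ExpressionDataset(values=values, stage_of=stage_of,
                             stage_order=list(stage_order), traits=traits)


def write_expression_tsv(d: ExpressionDataset, path: str,
                         index_label: str = "gene") -> None:
    d.values.to_csv(path, sep="\t", index_label=index_label, float_format="%.12g")


def _dequote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        s = s[1:-1]
    return s


def read_series_matrix(path: str) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Parse a GEO series-matrix file.

    Returns the probe x sample value matrix and the ``!Sample_*`` metadata
    lines (key -> per-sample values, dequoted) so the caller can build a
    stage map from sample characteristics.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, *vals = line.split("\t")
                meta.setdefault(key.lstrip("!"), []).extend(_dequote(v) for v in vals)
    if not (saw_begin and saw_end):
        raise ValueError(
            f"{path}: missing series_matrix_table_begin/end markers")
    if not table_lines:
        raise ValueError(f"{path}: empty series-matrix table")
    header = [_dequote(c) for c in table_lines[0].split("\t")]
    rows = []
    index = []
    for line in table_lines[1:]:
        if not line:
            continue
        parts = line.split("\t")
        index.append(_dequote(parts[0]))
        rows.append([float("nan") if _dequote(p) in ("", "null", "NULL")
                     else float(_dequote(p)) for p in parts[1:]])
    df = pd.DataFrame(rows, index=index, columns=header[1:], dtype=float)
    logger.info("read_series_matrix: %d probes x %d samples from %s",
                len(df), df.shape[1], path)
    return df, meta


def read_edge_table(path: str, source_tag: str = "") -> EdgeTable:
    """Read a 2-3 column edge TSV (geneA, geneB[, confidence]).

    Canonicalises pairs, drops self-loops and collapses duplicates keeping
    the maximum confidence.
    """
    table = EdgeTable()
    n_raw = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: need >= 2 columns")
            conf = None
            if len(parts) >= 3 and parts[2] != "":
                conf = float(parts[2])
            table.add(parts[0], parts[1], conf, source_tag)
            n_raw += 1
    logger.info("read_edge_table: %d lines -> %d canonical edges from %s",
                n_raw, len(table), path)
    return table


def write_edge_table(t: EdgeTable, path: str) -> None:
    with open(path, "w") as fh:
        for (a, b), c in sorted(t.edges.items()):
            if c is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{c:.12g}\n")


def filter_edges_by_confidence(t: EdgeTable, min_conf: float) -> EdgeTable:
    """Keep edges with confidence strictly greater than ``min_conf``.

    Unscored edges pass unconditionally: confidence filtering applies only
    to sources that provide scores (curated-database edges carry none).
    """
    if not (0 <= min_conf <= 1):
        raise ValueError("min_conf must be in [0, 1]")
    out = EdgeTable()
    for key, conf in t.edges.items():
        if conf is None or conf > min_conf:
            out.edges[key] = conf
            out.sources[key] = list(t.sources[key])
    logger.info("filter_edges_by_confidence(> %g): %d -> %d edges",
                min_conf, len(t), len(out))
    return out


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file: name, description, genes... (tab-separated)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >= 3 fields")
            name, desc, genes = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
            sets[name] = {g for g in genes if g}
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(c: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name in c.sets:
            desc = c.descriptions.get(name, "")
            genes = "\t".join(sorted(c.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# Network / table writers
# ---------------------------------------------------------------------------


def write_network(g: nx.Graph, path: str, fmt: str = "sif",
                  relation: str = "pp") -> None:
    """Export a network as SIF, GraphML or a plain edge TSV."""
    fmt = fmt.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(_canon(a, b) for a, b in g.edges()):
                fh.write(f"{a}\t{relation}\t{b}\n")
    elif fmt == "graphml":
        h = nx.Graph()
        h.add_nodes_from(g.nodes())
        for a, b, data in g.edges(data=True):
            h.add_edge(a, b, **{k: v for k, v in data.items() if v is not None})
        nx.write_graphml(h, path)
    elif fmt in ("tsv", "edge tsv"):
        cols: list[str] = sorted({k for _, _, d in g.edges(data=True) for k in d})
        with open(path, "w") as fh:
            fh.write("geneA\tgeneB" + "".join(f"\t{c}" for c in cols) + "\n")
            for a, b in sorted(_canon(a, b) for a, b in g.edges()):
                data = g.edges[a, b]
                vals = "".join(
                    "\t" + ("" if data.get(c) is None else f"{data.get(c)}")
                    for c in cols)
                fh.write(f"{a}\t{b}{vals}\n")
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def write_table(rows: pd.DataFrame, path: str, index: bool = False,
                index_label: str | None = None) -> None:
    rows.to_csv(path, sep="\t", index=index, index_label=index_label,
                float_format="%.12g")


def write_json(obj: object, path: str) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
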