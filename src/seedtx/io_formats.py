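"""Validated in-memory containers and readers/writers for the pipeline's formats.

Everything downstream operates on log2-scale gene-level expression matrices
(genes x samples), a per-sample design table, GMT category maps, IUPAC motif
libraries and bipartite TF-function networks.  All readers validate strictly
and raise rather than coerce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TISSUES = frozenset(
    {"root", "leaf", "seedling", "ovary", "embryo", "endosperm", "seed"}
)
TREATMENTS = frozenset({"control", "cold"})

#: 15-letter IUPAC nucleotide alphabet -> the set of concrete bases matched.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class FormatError(ValueError):
    """Malformed external file (row width, non-numeric cell, bad token)."""


class ValidationError(ValueError):
    """Structurally parseable input violating a container invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities.

    Invariants: unique gene and sample ids, all values finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        self.data = df.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class SampleDesign:
    """Per-sample metadata: tissue, stage (days after fertilization),
    replicate number and treatment.

    The table is indexed by sample id; ``stage`` is nullable (vegetative
    tissues have no DAF stage).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"tissue", "replicate", "treatment"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        if "stage" not in t.columns:
            t["stage"] = pd.NA
        if t.index.has_duplicates:
            raise ValidationError("duplicate sample ids in design")
        bad_tissue = set(t["tissue"]) - TISSUES
        if bad_tissue:
            raise ValidationError(f"unknown tissue tokens: {sorted(bad_tissue)}")
        bad_trt = set(t["treatment"]) - TREATMENTS
        if bad_trt:
            raise ValidationError(f"unknown treatment tokens: {sorted(bad_trt)}")
        t["stage"] = t["stage"].astype("Int64")
        t["replicate"] = t["replicate"].astype(int)
        if (t["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be positive")
        t.index = t.index.astype(str)
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_key(self, sample: str) -> tuple:
        row = self.table.loc[sample]
        stage = None if pd.isna(row["stage"]) else int(row["stage"])
        return (row["tissue"], stage, row["treatment"])

    def groups(self) -> dict[tuple, list[str]]:
        """(tissue, stage, treatment) -> ordered sample ids."""
        out: dict[tuple, list[str]] = {}
        for sid in self.table.index:
            out.setdefault(self.group_key(sid), []).append(sid)
        return out

    def samples_for(self, tissue=None, stage=None, treatment=None) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if tissue is not None:
            tissues = {tissue} if isinstance(tissue, str) else set(tissue)
            mask &= t["tissue"].isin(tissues)
        if stage is not None:
            mask &= t["stage"] == stage
        if treatment is not None:
            mask &= t["treatment"] == treatment
        return list(t.index[mask])

    def validate_against(self, m: ExpressionMatrix) -> None:
        missing = set(m.sample_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"samples without design rows: {sorted(missing)}")


@dataclass
class CategoryMap:
    """Term id -> gene set annotations over a fixed background universe."""

    term_labels: dict[str, str]
    term_genes: dict[str, frozenset]
    background: frozenset

    def __post_init__(self) -> None:
        if not self.background:
            raise ValidationError("category map background is empty")
        self.background = frozenset(self.background)
        self.term_genes = {
            t: frozenset(g) for t, g in self.term_genes.items()
        }
        for term, genes in self.term_genes.items():
            extra = genes - self.background
            if extra:
                raise ValidationError(
                    f"term {term} has genes outside background: {sorted(extra)[:5]}"
                )

    @property
    def terms(self) -> list[str]:
        return list(self.term_genes)

    def restrict(self, background) -> "CategoryMap":
        """Intersect every term and the universe with a new background."""
        bg = frozenset(background)
        return CategoryMap(
            term_labels=dict(self.term_labels),
            term_genes={t: g & bg for t, g in self.term_genes.items()},
            background=bg,
        )


@dataclass
class MotifLibrary:
    """Named IUPAC patterns for promoter cis-element scanning."""

    patterns: dict[str, str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, pat in self.patterns.items():
            pat = pat.upper()
            bad = set(pat) - set(IUPAC_CODES)
            if bad:
                raise ValidationError(
                    f"motif {mid}: illegal IUPAC characters {sorted(bad)}"
                )
            if len(pat) < 4:
                raise ValidationError(f"motif {mid}: pattern shorter than 4 nt")
            self.patterns[mid] = pat

    def __iter__(self):
        return iter(self.patterns.items())

    def __len__(self) -> int:
        return len(self.patterns)


@dataclass
class TFNetwork:
    """Bipartite TF -> function-term graph with enrichment q on edges.

    TF nodes carry an expression-class attribute (embryo / endosperm / both /
    unclassified); term nodes carry a human-readable label.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_tf(self, tf: str, expr_class: str = "unclassified") -> None:
        self.graph.add_node(tf, kind="tf", expr_class=expr_class)

    def add_term(self, term: str, label: str = "") -> None:
        self.graph.add_node(term, kind="term", label=label or term)

    def add_edge(self, tf: str, term: str, q: float) -> None:
        if tf not in self.graph or self.graph.nodes[tf].get("kind") != "tf":
            raise ValidationError(f"edge endpoint {tf} is not a TF node")
        if term not in self.graph or self.graph.nodes[term].get("kind") != "term":
            raise ValidationError(f"edge endpoint {term} is not a term node")
        if not (0.0 < q <= 1.0):
            raise ValidationError(f"edge q-value {q} outside (0, 1]")
        self.graph.add_edge(tf, term, q=float(q))

    @property
    def tfs(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "tf"]

    @property
    def terms(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "term"]

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            if self.graph.nodes[u].get("kind") == "tf":
                out.append((u, v, d["q"]))
            else:
                out.append((v, u, d["q"]))
        return sorted(out)


# ---------------------------------------------------------------------------
# TSV expression matrix / design IO
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a tab-delimited log2 matrix: first column gene id, header row of
    sample ids, ``#`` comment lines ignored."""
    header: list[str] | None = None
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields[1:]
                continue
            if len(fields) != len(header) + 1:
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header) + 1} fields, "
                    f"got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric cell ({exc})")
    if header is None:
        raise FormatError(f"{path}: no header row found")
    df = pd.DataFrame(rows, index=gene_ids, columns=header, dtype=float)
    return ExpressionMatrix(df)


def write_expression_matrix(m: ExpressionMatrix, path, float_format="%.10g") -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_sample_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})
    return SampleDesign(df)


def write_sample_design(d: SampleDesign, path) -> None:
    d.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gene_sets(path, background) -> CategoryMap:
    """Read GMT (term, description, gene ids...); genes absent from the
    background are dropped with a logged count."""
    background = frozenset(background)
    labels: dict[str, str] = {}
    sets: dict[str, frozenset] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if not fields[0]:
                raise ValidationError(f"{path}: line {lineno}: empty term id")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: GMT needs term and description fields"
                )
            term, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            kept = frozenset(g for g in genes if g in background)
            n_dropped += len(set(genes)) - len(kept)
            labels[term] = desc
            sets[term] = kept
    if n_dropped:
        log.info("read_gene_sets: dropped %d genes outside background", n_dropped)
    return CategoryMap(term_labels=labels, term_genes=sets, background=background)


def write_gene_sets(cats: CategoryMap, path) -> None:
    with open(path, "w") as fh:
        for term in cats.terms:
            genes = sorted(cats.term_genes[term])
            label = cats.term_labels.get(term, "")
            fh.write("\t".join([term, label, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Motif library TSV: motif_id <TAB> IUPAC pattern [<TAB> description]
# ---------------------------------------------------------------------------

def read_motif_library(path) -> MotifLibrary:
    patterns: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: need id and pattern")
            patterns[fields[0]] = fields[1]
            if len(fields) > 2:
                descriptions[fields[0]] = fields[2]
    return MotifLibrary(patterns=patterns, descriptions=descriptions)


def write_motif_library(lib: MotifLibrary, path) -> None:
    with open(path, "w") as fh:
        for mid, pat in lib:
            desc = lib.descriptions.get(mid, "")
            fh.write(f"{mid}\t{pat}\t{desc}\n")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network(net: TFNetwork, fmt: str, path) -> None:
    """Export a TF-function network as Cytoscape SIF or GraphML."""
    if fmt == "sif":
        with open(path, "w") as fh:
            for tf, term, _q in net.edges():
                fh.write(f"{tf}\tannotates\t{term}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(n, **{k: str(v) for k, v in d.items()})
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, q=float(d["q"]))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r} (use 'sif' or 'graphml')")
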