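"""Reading, aligning and writing the evidence networks.

All inputs are plain delimited text: a TF->gene prior edge table, a TF-TF
interaction pair table, and a gene x sample expression matrix.  The three are
aligned onto a common TF/gene universe and turned into the raw seed networks
W0 (TF x gene prior), P0 (TF x TF cooperativity, identity plus interactions)
and C0 (gene x gene Pearson co-expression).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledBipartiteNetwork",
    "LabeledSymmetricNetwork",
    "ExpressionMatrix",
    "SeedNetworks",
    "read_pairwise_table",
    "read_expression",
    "read_network",
    "build_seed_networks",
    "write_network",
]


class ParseError(ValueError):
    """Raised when an input table cannot be parsed."""


def _check_unique(labels, what: str) -> None:
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if list(labels).count(x) > 1})
        raise ValueError(f"duplicate {what} labels: {dupes[:5]}")


@dataclass
class LabeledBipartiteNetwork:
    """A dense TF x gene weight grid with row/column labels.

    Weights are raw evidence before normalization and z-scores afterwards.
    """

    tf_labels: list[str]
    gene_labels: list[str]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.tf_labels), len(self.gene_labels)):
            raise ValueError(
                f"weight grid shape {self.weights.shape} does not match "
                f"({len(self.tf_labels)}, {len(self.gene_labels)}) labels"
            )
        _check_unique(self.tf_labels, "TF")
        _check_unique(self.gene_labels, "gene")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.tf_labels, columns=self.gene_labels)


@dataclass
class LabeledSymmetricNetwork:
    """A dense square symmetric weight grid over one set of nodes."""

    labels: list[str]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError(f"weight grid shape {self.weights.shape}, expected ({n}, {n})")
        _check_unique(self.labels, "node")
        if not np.allclose(self.weights, self.weights.T, atol=1e-8):
            raise ValueError("weight grid is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values; NaN marks missing entries."""

    gene_labels: list[str]
    sample_labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_labels), len(self.sample_labels)):
            raise ValueError("expression value shape does not match labels")
        _check_unique(self.gene_labels, "gene")

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_labels, columns=self.sample_labels)


@dataclass
class SeedNetworks:
    """The raw (or normalized) seed triple W0, P0, C0 with shared labels."""

    regulatory: LabeledBipartiteNetwork
    cooperativity: LabeledSymmetricNetwork
    coregulation: LabeledSymmetricNetwork
    normalized: bool = False

    def __post_init__(self):
        if self.cooperativity.labels != self.regulatory.tf_labels:
            raise ValueError("cooperativity labels must equal regulatory TF labels")
        if self.coregulation.labels != self.regulatory.gene_labels:
            raise ValueError("coregulation labels must equal regulatory gene labels")

    @property
    def tf_labels(self) -> list[str]:
        return self.regulatory.tf_labels

    @property
    def gene_labels(self) -> list[str]:
        return self.regulatory.gene_labels


def _sniff_delimiter(line: str) -> str | None:
    # tab beats comma beats generic whitespace
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # split on any whitespace


def read_pairwise_table(path, kind: str = "prior") -> list[tuple[str, str, float]]:
    """Read a two/three-column edge table into (source, target, weight) records.

    The third column is an optional weight (default 1.0).  Duplicate pairs
    collapse to their maximum weight.  For ``kind="ppi"`` records are
    symmetrized so both orientations are present.

    Parameters
    ----------
    path : str or Path
        Delimited text file; tab, comma or whitespace separated.
    kind : {"prior", "ppi", "gold"}
        Table role; only "ppi" changes behaviour (symmetrization).
    """
    if kind not in ("prior", "ppi", "gold"):
        raise ValueError(f"unknown table kind {kind!r}")
    records: dict[tuple[str, str], float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        delim: str | None = None
        n_rows = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            fields = [f.strip() for f in (line.split(delim) if delim else line.split())]
            fields = [f for f in fields if f != ""]
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >=2 fields, got {len(fields)}")
            src, tgt = fields[0], fields[1]
            if len(fields) >= 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: weight {fields[2]!r} is not a number"
                    ) from None
            else:
                w = 1.0
            n_rows += 1
            key = (src, tgt)
            records[key] = max(records.get(key, -math.inf), w)
            if kind == "ppi" and src != tgt:
                rkey = (tgt, src)
                records[rkey] = max(records.get(rkey, -math.inf), w)
    if n_rows == 0:
        raise ParseError(f"{path}: empty table")
    return [(s, t, w) for (s, t), w in records.items()]


def read_expression(path, na_sentinel: str = "NA") -> ExpressionMatrix:
    """Read a delimited gene x sample expression table.

    First row holds sample labels, first column gene labels.  Cells equal to
    ``na_sentinel`` become NaN and are later excluded pairwise from
    correlations.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty expression table")
        delim = _sniff_delimiter(header)
    sep = delim if delim is not None else r"\s+"
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=[na_sentinel], keep_default_na=False,
        engine="python" if delim is None else "c",
    )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene labels {dupes[:5]}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} for gene {gene!r}, "
                f"sample {col!r} (sentinel is {na_sentinel!r})"
            )
        df[col] = converted
    return ExpressionMatrix(
        gene_labels=[str(g).strip() for g in df.index],
        sample_labels=[str(s).strip() for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def build_seed_networks(
    prior_records,
    ppi_records=None,
    expression: ExpressionMatrix | None = None,
    universe: str = "intersection",
) -> SeedNetworks:
    """Align the evidence onto a common universe and build raw seed networks.

    The regulatory seed W0 takes the prior weights (0 for absent pairs); the
    cooperativity seed P0 is symmetric 0/1 with unit diagonal, so TFs with no
    interaction evidence are self-cooperating and, with no interaction table at
    all, P0 is the identity; the co-regulation seed C0 holds pairwise-complete
    Pearson correlations between gene expression profiles (identity when no
    expression is given).  Zero-variance genes get zero off-diagonal
    correlation.

    Parameters
    ----------
    universe : {"intersection", "prior-driven"}
        "intersection" keeps prior genes that also have expression;
        "prior-driven" keeps all prior nodes and zero-fills missing evidence.
    """
    if universe not in ("intersection", "prior-driven"):
        raise ValueError(f"unknown universe policy {universe!r}")
    prior_records = list(prior_records)
    if not prior_records:
        raise ValueError("prior table contributes no edges")

    tfs = sorted({s.strip() for s, _, _ in prior_records})
    genes = sorted({t.strip() for _, t, _ in prior_records})
    if expression is not None and universe == "intersection":
        expr_genes = {g for g in expression.gene_labels}
        genes = [g for g in genes if g in expr_genes]
    if not tfs or len(genes) < 2:
        raise ValueError(
            "empty universe after alignment: need at least 1 TF and 2 genes "
            f"(got {len(tfs)} TFs, {len(genes)} genes)"
        )
    tf_idx = {t: i for i, t in enumerate(tfs)}
    gene_idx = {g: j for j, g in enumerate(genes)}

    W0 = np.zeros((len(tfs), len(genes)))
    for s, t, w in prior_records:
        s, t = s.strip(), t.strip()
        if s in tf_idx and t in gene_idx:
            W0[tf_idx[s], gene_idx[t]] = max(W0[tf_idx[s], gene_idx[t]], w)

    P0 = np.eye(len(tfs))
    if ppi_records:
        for a, b, w in ppi_records:
            a, b = a.strip(), b.strip()
            if a in tf_idx and b in tf_idx and a != b:
                v = max(P0[tf_idx[a], tf_idx[b]], w)
                P0[tf_idx[a], tf_idx[b]] = v
                P0[tf_idx[b], tf_idx[a]] = v

    C0 = np.eye(len(genes))
    if expression is not None:
        if expression.n_samples < 2:
            raise ValueError("need at least 2 expression samples to compute correlations")
        expr = expression.to_frame()
        present = [g for g in genes if g in expr.index]
        if present:
            # pairwise-complete Pearson; undefined (zero-variance) pairs -> 0
            corr = expr.loc[present].T.corr(method="pearson")
            corr = corr.fillna(0.0).to_numpy()
            rows = np.array([gene_idx[g] for g in present])
            C0[np.ix_(rows, rows)] = corr
        np.fill_diagonal(C0, 1.0)

    reg = LabeledBipartiteNetwork(tfs, genes, W0)
    coop = LabeledSymmetricNetwork(tfs, P0)
    coreg = LabeledSymmetricNetwork(genes, C0)
    return SeedNetworks(reg, coop, coreg, normalized=False)


_WFMT = "%.12g"  # >= 10 significant digits for round-trip fidelity


def write_network(network, path, format: str = "edge-list") -> None:
    """Write a network as a labeled matrix grid or a deterministic edge list.

    Edge-list rows are source<TAB>target<TAB>weight, one per (source, target)
    pair including zeros, ordered source-major then target (lexicographic).
    """
    if isinstance(network, LabeledBipartiteNetwork):
        rows, cols = network.tf_labels, network.gene_labels
    elif isinstance(network, LabeledSymmetricNetwork):
        rows = cols = network.labels
    else:
        raise TypeError(f"cannot write {type(network).__name__}")
    W = network.weights
    try:
        with open(path, "w", encoding="utf-8") as fh:
            if format == "matrix":
                fh.write("\t".join(["."] + list(cols)) + "\n")
                for i, r in enumerate(rows):
                    fh.write("\t".join([r] + [_WFMT % w for w in W[i]]) + "\n")
            elif format == "edge-list":
                order_r = sorted(range(len(rows)), key=lambda i: rows[i])
                order_c = sorted(range(len(cols)), key=lambda j: cols[j])
                for i in order_r:
                    for j in order_c:
                        fh.write(f"{rows[i]}\t{cols[j]}\t{_WFMT % W[i, j]}\n")
            else:
                raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise OSError(f"failed to write network to {path}: {exc}") from exc


def read_network(path, format: str = "edge-list", symmetric: bool = False):
    """Read a network written by :func:`write_network`.

    Returns a :class:`LabeledSymmetricNetwork` when ``symmetric`` (or when the
    row and column label sets coincide in matrix format), otherwise a
    :class:`LabeledBipartiteNetwork`.
    """
    if format == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        rows = [str(r) for r in df.index]
        cols = [str(c) for c in df.columns]
        W = df.to_numpy(dtype=float)
    elif format == "edge-list":
        recs = read_pairwise_table(path, kind="gold")
        rows = sorted({s for s, _, _ in recs})
        cols = sorted({t for _, t, _ in recs})
        W = np.zeros((len(rows), len(cols)))
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: j for j, c in enumerate(cols)}
        for s, t, w in recs:
            W[ri[s], ci[t]] = w
    else:
        raise ValueError(f"unknown format {format!r}")
    if symmetric or (rows == cols):
        if rows != cols:
            raise ValueError("symmetric network requested but labels differ")
        return LabeledSymmetricNetwork(rows, W)
    return LabeledBipartiteNetwork(rows, cols, W)
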