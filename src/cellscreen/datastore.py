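"""Ingestion and normalization of expression matrices, drug-response tables,
gene sets, and gene-symbol maps.

The normalization chain for raw RNA-seq counts is median-of-ratios size
factors, then quantile normalization, then per-column scaling so that the
mean expression within every cell line equals a fixed target (1000 by
default).  Pre-normalized (e.g. RMA) matrices receive only the final scaling
step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Valid values of :attr:`ExpressionMatrix.state`.
STATES = ("raw_counts", "prenormalized", "normalized")

#: Target per-cell-line mean after scaling normalization.
SCALE_TARGET = 1000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Dense genes x cell-lines expression matrix.

    Parameters
    ----------
    genes : list of str
        Unique gene symbols, one per row.
    cell_lines : list of str
        Unique cell-line identifiers, one per column.
    values : ndarray of shape (n_genes, n_cell_lines)
        Non-negative expression values; no missing entries.
    state : {'raw_counts', 'prenormalized', 'normalized'}
        Provenance / normalization state.
    """

    genes: list[str]
    cell_lines: list[str]
    values: np.ndarray
    state: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cell_lines)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cell_lines)} cell lines"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:10]}")
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValidationError("duplicate cell-line ids")
        if np.isnan(self.values).any():
            g, c = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"missing value at gene {self.genes[g]!r}, "
                f"cell line {self.cell_lines[c]!r}"
            )
        if (self.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_lines)

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(gene) from None
        return self.values[i]

    def expression_of(self, gene: str) -> dict[str, float]:
        """Mapping cell line -> expression for one gene."""
        return dict(zip(self.cell_lines, self.row(gene)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cell_lines)


@dataclass(frozen=True)
class DrugResponseRecord:
    """One (dataset, compound, cell line) drug-response measurement."""

    dataset: str
    compound: str
    cell_line: str
    ic50: float | None = None
    audrc: float | None = None

    def __post_init__(self) -> None:
        if self.ic50 is None and self.audrc is None:
            raise ValidationError(
                f"record {self.dataset}/{self.compound}/{self.cell_line} "
                "has neither IC50 nor AUDRC"
            )
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValidationError(f"IC50 must be positive, got {self.ic50}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")


@dataclass
class SymbolMap:
    """Approved-symbol dictionary with alias resolution.

    Aliases that point at more than one approved symbol are ambiguous and
    excluded from ``alias_to_approved``.
    """

    approved: set[str]
    alias_to_approved: dict[str, str]
    ambiguous: set[str] = field(default_factory=set)

    def resolve(self, symbol: str) -> str | None:
        """Approved symbol for ``symbol``, or None when unmappable."""
        if symbol in self.approved:
            return symbol
        return self.alias_to_approved.get(symbol)


@dataclass
class MappingReport:
    """Outcome of :func:`map_symbols`."""

    renamed: dict[str, str] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)
    collisions: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression(path, state_hint: str) -> ExpressionMatrix:
    """Read a gene x cell-line expression TSV.

    First column holds gene ids, the header row holds cell-line ids, the body
    is numeric with no missing entries.
    """
    if state_hint not in ("raw_counts", "prenormalized"):
        raise ValidationError(f"state_hint must be raw_counts or prenormalized, got {state_hint!r}")
    # pandas silently renames duplicate header fields, so inspect the raw header
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ParseError(f"duplicated cell-line column name(s): {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    cell_lines = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        g, c = bad[0]
        raw = df.iat[g, c]
        if pd.isna(raw):
            raise ParseError(f"missing value at gene {genes[g]!r}, cell line {cell_lines[c]!r}")
        raise ParseError(
            f"non-numeric value {raw!r} at gene {genes[g]!r}, cell line {cell_lines[c]!r}"
        )
    return ExpressionMatrix(genes, cell_lines, numeric.to_numpy(dtype=float), state_hint)


def read_responses(path) -> list[DrugResponseRecord]:
    """Read a drug-response TSV (`dataset, compound, cell_line, ic50, audrc`).

    Empty strings are missing values; rows with neither IC50 nor AUDRC are
    dropped (not an error) and the drop count is logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"dataset": str, "compound": str, "cell_line": str})
    required = {"dataset", "compound", "cell_line", "ic50", "audrc"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"response table missing column(s): {sorted(missing)}")
    records: list[DrugResponseRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        ic50 = None if pd.isna(row.ic50) else float(row.ic50)
        audrc = None if pd.isna(row.audrc) else float(row.audrc)
        if ic50 is None and audrc is None:
            dropped += 1
            continue
        records.append(DrugResponseRecord(str(row.dataset), str(row.compound),
                                          str(row.cell_line), ic50, audrc))
    if dropped:
        logger.info("dropped %d record(s) with neither IC50 nor AUDRC", dropped)
    return records


def read_gmt(path) -> list[GeneSet]:
    """Read a Broad-dialect GMT file: name, description, tab-separated genes."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(f"GMT line {lineno} ({name}): duplicate genes deduplicated")
            if not unique:
                raise ParseError(f"GMT line {lineno} ({name}): no genes")
            sets.append(GeneSet(name, tuple(unique)))
    return sets


def read_symbol_map(path) -> SymbolMap:
    """Read an HGNC-style map TSV.

    Columns: ``approved_symbol``, ``alias_symbols`` and ``previous_symbols``
    (both pipe-separated, possibly empty).  An alias claimed by several
    approved symbols, or equal to an approved symbol itself, is ambiguous and
    dropped from the mapping.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"approved_symbol", "alias_symbols", "previous_symbols"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"symbol map missing column(s): {sorted(missing)}")
    approved = set(df["approved_symbol"])
    claims: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        for col in (row.alias_symbols, row.previous_symbols):
            for alias in filter(None, col.split("|")):
                claims.setdefault(alias, set()).add(row.approved_symbol)
    mapping, ambiguous = {}, set()
    for alias, targets in claims.items():
        if len(targets) > 1 or alias in approved:
            ambiguous.add(alias)
        else:
            mapping[alias] = next(iter(targets))
    return SymbolMap(approved=approved, alias_to_approved=mapping, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def deseq_size_factors(m: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios size factors, one per cell line.

    Reference genes are those with strictly positive counts in every cell
    line; the factor for column j is the median over reference genes of
    count(g, j) divided by the gene's geometric mean across columns.
    """
    if m.state != "raw_counts":
        raise ValidationError(f"size factors require raw counts, matrix state is {m.state!r}")
    ref = (m.values > 0).all(axis=1)
    if not ref.any():
        raise ValidationError(
            "no gene has positive counts in all cell lines; filter zero genes first"
        )
    counts = m.values[ref]
    log_geo_mean = np.log(counts).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(counts) - log_geo_mean, axis=0))
    return factors


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every column onto the common reference distribution.

    The reference is the across-column mean of the sorted columns; within a
    column, tied values all receive the mean of the reference values spanned
    by their ranks (Bolstad convention).
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValidationError("quantile_normalize: missing values not allowed")
    n, k = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(k):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # average reference values across tie groups
        sorted_col = col[order]
        start = 0
        for end in range(1, n + 1):
            if end == n or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[order[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = assigned
    return out


def scale_to_mean(values: np.ndarray, target: float = SCALE_TARGET,
                  cell_lines: list[str] | None = None) -> np.ndarray:
    """Multiply each column so its mean equals ``target``."""
    values = np.asarray(values, dtype=float)
    means = values.mean(axis=0)
    zero = np.flatnonzero(means <= 0)
    if zero.size:
        name = cell_lines[zero[0]] if cell_lines else f"column {zero[0]}"
        raise ValidationError(f"cannot scale cell line {name}: non-positive mean expression")
    return values * (target / means)


def filter_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with zero expression in strictly more than half the cell lines."""
    zeros = (m.values == 0).sum(axis=1)
    keep = zeros <= m.n_cell_lines / 2
    return replace(m, genes=[g for g, k in zip(m.genes, keep) if k], values=m.values[keep])


def normalize_pipeline(m: ExpressionMatrix, target: float = SCALE_TARGET) -> ExpressionMatrix:
    """Full normalization chain.

    Raw counts: zero-gene filter -> size-factor division -> quantile
    normalization -> scaling to ``target``.  Pre-normalized input receives the
    scaling step only.  Idempotent on already-normalized matrices.
    """
    if m.state == "raw_counts":
        m = filter_zero_genes(m)
        factors = deseq_size_factors(m)
        values = quantile_normalize(m.values / factors)
    else:
        values = m.values
    values = scale_to_mean(values, target, m.cell_lines)
    return replace(m, values=values, state="normalized")


def map_symbols(m: ExpressionMatrix, sm: SymbolMap) -> tuple[ExpressionMatrix, MappingReport]:
    """Rename gene rows to approved symbols.

    Unmappable ids pass through verbatim and are listed in the report.  When
    several rows resolve to one approved symbol, the row with the highest mean
    expression wins and the collision is reported.
    """
    report = MappingReport()
    resolved: list[str] = []
    for gene in m.genes:
        target = sm.resolve(gene)
        if target is None:
            report.unmapped.append(gene)
            resolved.append(gene)
        else:
            if target != gene:
                report.renamed[gene] = target
            resolved.append(target)
    best: dict[str, int] = {}
    groups: dict[str, list[int]] = {}
    row_means = m.values.mean(axis=1)
    for i, symbol in enumerate(resolved):
        groups.setdefault(symbol, []).append(i)
    for symbol, idx in groups.items():
        if len(idx) > 1:
            report.collisions[symbol] = [m.genes[i] for i in idx]
            idx = [max(idx, key=lambda i: (row_means[i], -i))]
        best[symbol] = idx[0]
    keep = sorted(best.values())
    out = replace(m, genes=[resolved[i] for i in keep], values=m.values[keep])
    return out, report
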