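"""Data model and readers/writers for expression matrices, gene sets and signatures.

Formats handled:

* expression matrices — plain TSV (first column = gene id, header row of
  sample ids) and GCT 1.2 (``#1.2`` version line, ``nrow\\tncol`` line,
  ``Name``/``Description`` columns);
* gene-set collections — GMT (MSigDB dialect: name, description, genes);
* Epi/Mes signature tables — TSV with columns ``gene``, ``direction``
  (``Epi``/``Mes``) and optional ``weight``.

Gene identifiers are matched by exact string after whitespace trimming; no
alias resolution is attempted. On load, gene order is canonicalized to sorted
order (documented behaviour); sample order is never changed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("emtscore")

Klass = Literal["Epi", "intermediate-Epi", "intermediate-Mes", "Mes"]
KLASSES: tuple[str, ...] = ("Epi", "intermediate-Epi", "intermediate-Mes", "Mes")


class ParseError(ValueError):
    """Raised for malformed input files; the message names the offending location."""


class CoverageError(ValueError):
    """Raised when too few signature genes are present in a matrix."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values.

    ``data`` is indexed by gene id with sample ids as columns. Values may
    contain NaN (a gene missing in one sample is excluded from that sample's
    ranking only); infinities are rejected.
    """

    data: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.data.shape[0] < 2 or self.data.shape[1] < 1:
            raise ValueError(
                f"expression matrix needs >=2 genes and >=1 sample, "
                f"got {self.data.shape[0]}x{self.data.shape[1]}"
            )
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("expression matrix contains infinite values")
        # canonical axis labels so read/write round trips compare equal
        object.__setattr__(self, "data",
                           self.data.rename_axis(index="gene", columns=None))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.columns:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self.data[sample_id]


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free collection of gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class EMTSignature:
    """Disjoint epithelial and mesenchymal gene lists with optional weights.

    Weights are non-negative provenance values from signature derivation; the
    2KS score itself is unweighted.
    """

    epi_genes: tuple[str, ...]
    mes_genes: tuple[str, ...]
    weights: Mapping[str, float] = field(default_factory=dict)
    source: str = field(default="", compare=False)  # provenance, not identity

    def __post_init__(self) -> None:
        epi, mes = set(self.epi_genes), set(self.mes_genes)
        if not epi or not mes:
            raise ValueError("both Epi and Mes gene lists must be non-empty")
        if len(epi) != len(self.epi_genes) or len(mes) != len(self.mes_genes):
            raise ValueError("duplicate genes within a signature direction")
        overlap = epi & mes
        if overlap:
            raise ValueError(
                f"genes assigned to both Epi and Mes: {sorted(overlap)}"
            )
        members = epi | mes
        for g, w in self.weights.items():
            if g not in members:
                raise ValueError(f"weight given for non-member gene {g!r}")
            if not (w >= 0):
                raise ValueError(f"negative weight for gene {g!r}")
        # normalize: every member carries an explicit weight (default 1.0) so
        # that signatures compare equal across write/read round trips
        full = {g: float(self.weights.get(g, 1.0))
                for g in (*self.epi_genes, *self.mes_genes)}
        object.__setattr__(self, "weights", full)

    def weight(self, gene: str) -> float:
        return float(self.weights.get(gene, 1.0))

    @property
    def n_genes(self) -> int:
        return len(self.epi_genes) + len(self.mes_genes)


@dataclass(frozen=True)
class ScoreResult:
    """Per-sample signed 2KS EMT score with its classification.

    A sample that fails the signature-coverage floor yields a flagged record
    (``error`` set, numeric fields None) rather than aborting a whole matrix.
    """

    sample_id: str
    emt_score: float | None
    ks_pvalue: float | None
    klass: str | None
    n_epi_used: int
    n_mes_used: int
    error: str | None = None

    def __post_init__(self) -> None:
        if self.error is not None:
            return
        if self.emt_score is None or not -1.0 <= self.emt_score <= 1.0:
            raise ValueError(f"emt_score {self.emt_score} outside [-1, +1]")
        if self.ks_pvalue is None or not 0.0 <= self.ks_pvalue <= 1.0:
            raise ValueError(f"ks_pvalue {self.ks_pvalue} outside [0, 1]")
        if self.klass not in KLASSES:
            raise ValueError(f"unknown class {self.klass!r}")
        mes_side = self.klass in ("Mes", "intermediate-Mes")
        if self.emt_score > 0 and not mes_side:
            raise ValueError("positive score with Epi-side class")
        if self.emt_score < 0 and mes_side:
            raise ValueError("negative score with Mes-side class")

    @property
    def ok(self) -> bool:
        return self.error is None


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def _finalize_matrix(df: pd.DataFrame, origin: str) -> ExpressionMatrix:
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    # non-numeric cells -> error naming row/column
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{origin}: non-numeric value {df.loc[gene, col]!r} "
                f"at gene {gene!r}, sample {col!r}"
            )
        # float() is correctly rounded (to_numeric can be 1 ulp off)
        df[col] = df[col].map(
            lambda v: np.nan if v is None or str(v).strip() == "" else float(v))
    # duplicate gene rows -> mean collapse on the log2 scale
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        logger.warning(
            "%s: %d duplicated gene id(s) collapsed by mean: %s%s",
            origin, len(dups), ", ".join(dups[:5]), "..." if len(dups) > 5 else "",
        )
        df = df.groupby(level=0, sort=False).mean()
    # drop rows that are entirely missing
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        logger.warning("%s: dropped %d entirely-missing gene row(s)",
                       origin, int(all_missing.sum()))
        df = df.loc[~all_missing]
    df = df.sort_index()  # canonical gene order; sample order untouched
    return ExpressionMatrix(df)


def read_expression(path: str | Path,
                    format: Literal["tsv", "gct"] | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    ``format=None`` infers from the file extension (``.gct`` -> GCT).
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if df.shape[1] == 0:
            raise ParseError(f"{path}: no sample columns found")
        return _finalize_matrix(df, str(path))
    if format == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(f"{path}: expected '#1.2' version line, got {version!r}")
            dims = fh.readline().strip().split("\t")
            if len(dims) < 2:
                raise ParseError(f"{path}: malformed dimension line")
            try:
                nrow, ncol = int(dims[0]), int(dims[1])
            except ValueError as exc:
                raise ParseError(f"{path}: malformed dimension line {dims!r}") from exc
            df = pd.read_csv(fh, sep="\t", dtype=str)
        if df.columns[0] != "Name" or df.columns[1] != "Description":
            raise ParseError(f"{path}: expected Name/Description columns, "
                             f"got {list(df.columns[:2])}")
        if df.shape[0] != nrow or df.shape[1] - 2 != ncol:
            raise ParseError(
                f"{path}: GCT declares {nrow} genes x {ncol} samples but file "
                f"contains {df.shape[0]} x {df.shape[1] - 2}"
            )
        df = df.drop(columns="Description").set_index("Name")
        return _finalize_matrix(df, str(path))
    raise ValueError(f"unknown format {format!r}")


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     format: Literal["tsv", "gct"] | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        matrix.data.to_csv(path, sep="\t", index_label="gene",
                           float_format="%.17g")  # exact float64 round trip
        return
    if format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = matrix.data.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name", float_format="%.17g")
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line, ``name TAB description TAB genes...``."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), "
                    f"need name, description and >=1 gene"
                )
            name = fields[0].strip()
            genes: list[str] = []
            seen: set[str] = set()
            for g in (f.strip() for f in fields[2:]):
                if not g:
                    continue
                if g in seen:
                    logger.warning("%s:%d: duplicate gene %r in set %r dropped",
                                   path, lineno, g, name)
                    continue
                seen.add(g)
                genes.append(g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name, tuple(genes)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path,
                    description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Signature tables
# ---------------------------------------------------------------------------


def read_signature(path: str | Path, source: str | None = None) -> EMTSignature:
    """Read a signature TSV (columns gene, direction, weight).

    A missing ``weight`` column defaults every weight to 1.0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "direction": str})
    for col in ("gene", "direction"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    df["gene"] = df["gene"].str.strip()
    df["direction"] = df["direction"].str.strip()
    bad_dir = ~df["direction"].isin(["Epi", "Mes"])
    if bad_dir.any():
        raise ParseError(
            f"{path}: direction must be 'Epi' or 'Mes', "
            f"got {df.loc[bad_dir, 'direction'].iloc[0]!r}"
        )
    both = set(df.loc[df["direction"] == "Epi", "gene"]) & \
        set(df.loc[df["direction"] == "Mes", "gene"])
    if both:
        raise ParseError(f"{path}: gene(s) listed with both directions: {sorted(both)}")
    if "weight" in df.columns:
        weights = {g: float(w) for g, w in zip(df["gene"], df["weight"])}
    else:
        weights = {g: 1.0 for g in df["gene"]}
    return EMTSignature(
        epi_genes=tuple(df.loc[df["direction"] == "Epi", "gene"]),
        mes_genes=tuple(df.loc[df["direction"] == "Mes", "gene"]),
        weights=weights,
        source=source if source is not None else str(path),
    )


def write_signature(sig: EMTSignature, path: str | Path) -> None:
    rows = [(g, "Epi", sig.weight(g)) for g in sig.epi_genes]
    rows += [(g, "Mes", sig.weight(g)) for g in sig.mes_genes]
    pd.DataFrame(rows, columns=["gene", "direction", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def matrix_from_arrays(gene_ids: Sequence[str], sample_ids: Sequence[str],
                       values: np.ndarray, sort_genes: bool = True) -> ExpressionMatrix:
    """Convenience constructor from raw arrays (genes x samples)."""
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=list(gene_ids), columns=list(sample_ids))
    if sort_genes:
        df = df.sort_index()
    return ExpressionMatrix(df)
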