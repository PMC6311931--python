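"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are handled internally as 0-based half-open
``[start, end)``.  GTF input (1-based, inclusive) is converted on read.
Missing values are never imputed: malformed input raises immediately with
the offending line or cell identified.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "BindingSiteRecord",
    "GeneModel",
    "PeakRecord",
    "GeneSetCollection",
    "read_binding_sites",
    "read_gene_models",
    "read_expression_table",
    "read_gene_sets",
    "read_peaks",
    "write_network",
    "read_network",
    "NETWORK_COLUMNS",
]

NETWORK_COLUMNS = ["tf", "gene", "cell_line", "probability"]


@dataclass(frozen=True)
class BindingSiteRecord:
    """A predicted TF binding site with its binding probability.

    Coordinates are 0-based half-open.
    """

    tf_id: str
    cell_line: str
    chrom: str
    start: int
    end: int
    strand: str
    probability: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"binding site {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"binding probability {self.probability} outside [0, 1]"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class GeneModel:
    """A gene with its strand-resolved TSS position(s), 0-based."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    transcript_tss_list: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.transcript_tss_list:
            self.transcript_tss_list = [self.tss]


@dataclass(frozen=True)
class PeakRecord:
    """A scored interval from a ChIP-seq experiment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: start must be < end"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. GO terms, keyed by term id."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    category: str | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> set[str]:
        return self.sets[term]

    def items(self):
        return self.sets.items()


def _fields(line: str) -> list[str]:
    # BED is tab-separated but whitespace-delimited files are common in the wild
    return line.split("\t") if "\t" in line else line.split()


def read_binding_sites(
    path: str | Path,
    cell_line: str,
    dialect: str = "bed6-prob",
    one_based: bool = False,
) -> list[BindingSiteRecord]:
    """Read predicted binding sites with probabilities from a BED-like file.

    Parameters
    ----------
    path
        File with one site per line.
    cell_line
        Cell line the file belongs to (binding-site files are per cell line).
    dialect
        Column layout. ``"bed6-prob"`` (default): chrom, start, end, tf id,
        probability, strand. ``"bed6+1"``: standard BED6 (score in column 5)
        with the probability appended as a seventh column.
    one_based
        If True, input coordinates are 1-based inclusive and converted to
        0-based half-open.
    """
    if dialect not in {"bed6-prob", "bed6+1"}:
        raise ValueError(f"unknown binding-site dialect {dialect!r}")
    prob_col = 4 if dialect == "bed6-prob" else 6
    min_cols = 6 if dialect == "bed6-prob" else 7
    records: list[BindingSiteRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = _fields(line)
            if len(cols) < min_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(cols)}"
                )
            try:
                start = int(cols[1])
                end = int(cols[2])
                prob = float(cols[prob_col])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if one_based:
                start -= 1
            try:
                records.append(
                    BindingSiteRecord(
                        tf_id=cols[3],
                        cell_line=cell_line,
                        chrom=cols[0],
                        start=start,
                        end=end,
                        strand=cols[5],
                        probability=prob,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _tss_from_interval(start: int, end: int, strand: str) -> int:
    """5' end of a 0-based half-open interval."""
    return start if strand == "+" else end - 1


def read_gene_models(path: str | Path, format: str = "bed") -> list[GeneModel]:
    """Read gene models from BED (6 or 12 column) or GTF.

    The TSS of a transcript on the + strand is its start; on the − strand it
    is ``end − 1`` (0-based).  For GTF, every ``transcript`` feature of a gene
    contributes one entry to ``transcript_tss_list``; the gene-level ``tss``
    is the 5'-most transcript TSS.
    """
    if format == "bed":
        return _read_gene_models_bed(path)
    if format == "gtf":
        return _read_gene_models_gtf(path)
    raise ValueError(f"unknown gene model format {format!r}")


def _read_gene_models_bed(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = _fields(line)
            if len(cols) < 6:
                raise ValueError(
                    f"{path}:{lineno}: gene without strand (need >= 6 BED columns)"
                )
            chrom, start, end, gene_id, _, strand = cols[:6]
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: gene {gene_id} without valid strand")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            tss = _tss_from_interval(int(start), int(end), strand)
            genes.append(GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss))
    return genes


def _read_gene_models_gtf(path: str | Path) -> list[GeneModel]:
    # keyed by gene id; transcripts accumulate TSS entries
    meta: dict[str, tuple[str, str, int]] = {}  # gene -> (chrom, strand, first tss)
    tss_lists: dict[str, list[int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = cols
            if feature not in {"transcript", "gene"}:
                continue
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: feature without valid strand")
            attr = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            # GTF is 1-based inclusive -> 0-based half-open
            start0, end0 = int(start) - 1, int(end)
            tss = _tss_from_interval(start0, end0, strand)
            if gene_id not in meta:
                meta[gene_id] = (chrom, strand, tss)
                tss_lists[gene_id] = []
                order.append(gene_id)
            if feature == "transcript":
                tss_lists[gene_id].append(tss)
    genes = []
    for gid in order:
        chrom, strand, gene_tss = meta[gid]
        # gene feature only: fall back to the gene-level interval's TSS
        tss_list = tss_lists[gid] or [gene_tss]
        # gene-level TSS = 5'-most transcript TSS
        tss = min(tss_list) if strand == "+" else max(tss_list)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                tss=tss,
                transcript_tss_list=tss_list,
            )
        )
    return genes


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a genes × cell-lines expression matrix from TSV.

    First column = gene id, header = cell lines.  Duplicate gene ids and
    non-numeric / missing cells are errors; nothing is imputed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric or missing expression value at gene {gene!r}, "
                f"cell line {col!r} in {path}"
            )
        out.iloc[:, j] = converted.to_numpy()
    return out


def read_gene_sets(path: str | Path, category: str | None = None) -> GeneSetCollection:
    """Read gene sets from GMT (term, description, gene, gene, ...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs term and description")
            term, desc, *genes = cols
            genes = [g for g in genes if g]
            if not genes:
                warnings.warn(f"{path}:{lineno}: term {term!r} has no genes; skipped")
                continue
            sets[term] = set(genes)
            descriptions[term] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, category=category)


def read_peaks(
    path: str | Path, score_column: int = 4
) -> list[PeakRecord]:
    """Read scored peaks from BED/narrowPeak.

    ``score_column`` is 0-based; default 4 is the BED score (5th column).
    Use 6 for narrowPeak's signalValue.
    """
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = _fields(line)
            if len(cols) <= score_column:
                raise ValueError(
                    f"{path}:{lineno}: no score column {score_column} "
                    f"(line has {len(cols)} columns)"
                )
            try:
                peaks.append(
                    PeakRecord(
                        chrom=cols[0],
                        start=int(cols[1]),
                        end=int(cols[2]),
                        score=float(cols[score_column]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_network(net: pd.DataFrame, path: str | Path) -> None:
    """Write a network table (tf, gene, cell_line, probability) as TSV."""
    missing = [c for c in NETWORK_COLUMNS if c not in net.columns]
    if missing:
        raise ValueError(f"network table missing columns {missing}")
    net.loc[:, NETWORK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> pd.DataFrame:
    """Read a network table written by :func:`write_network`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"tf": str, "gene": str, "cell_line": str, "probability": float},
    )
    if list(df.columns) != NETWORK_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {NETWORK_COLUMNS}, got {list(df.columns)}"
        )
    if ((df["probability"] < 0) | (df["probability"] > 1)).any():
        raise ValueError(f"{path}: probability outside [0, 1]")
    if df.duplicated(subset=["tf", "gene", "cell_line"]).any():
        raise ValueError(f"{path}: duplicate (tf, gene, cell_line) rows")
    return df
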