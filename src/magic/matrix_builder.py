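"""Build gene × ChIP-track signal matrices from narrowPeak files.

Each gene is assigned a *domain* (gene body ± flank, or a promoter window)
and, per ChIP-seq track, the maximal narrowPeak ``signalValue`` of any peak
overlapping that domain.  Genes with no overlapping peak get 0, so every
cell holds a single non-negative signal and the enrichment ECDFs downstream
always have a value per gene.

Coordinates are 0-based half-open throughout (the BED convention used by
narrowPeak files); overlap means intersection by at least 1 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: flank / promoter-window constants per domain kind, in bp
DOMAIN_KINDS = {
    "gene_1kb": {"flank": 1000},
    "gene_5kb": {"flank": 5000},
    "promoter": {"upstream": 1000, "downstream": 300},
}


class MatrixParseError(ValueError):
    """Raised for malformed matrix / annotation / narrowPeak inputs."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's transcription span: ``[tx_start, tx_end)`` on ``chrom``."""

    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(
                f"{self.symbol}: tx_start must be < tx_end "
                f"({self.tx_start} >= {self.tx_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.symbol}: unknown strand {self.strand!r}")


@dataclass(frozen=True)
class NarrowPeakRecord:
    """One line of an ENCODE narrowPeak (BED6+4) file."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal_value: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    peak_offset: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak start must be < end ({self.start} >= {self.end})")
        if self.signal_value < 0:
            raise ValueError(f"negative signalValue {self.signal_value}")


@dataclass(frozen=True)
class DomainSpec:
    """One of the three gene-domain definitions.

    ``gene_1kb`` / ``gene_5kb``: gene body plus a symmetric flank.
    ``promoter``: a strand-aware window 1 kb upstream to 300 bp downstream
    of the TSS (TSS = tx_start on '+', tx_end on '−').
    """

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(
                f"unknown domain kind {self.kind!r}; one of {sorted(DOMAIN_KINDS)}"
            )

    @property
    def upstream_bp(self) -> int:
        p = DOMAIN_KINDS[self.kind]
        return p.get("flank", p.get("upstream"))

    @property
    def downstream_bp(self) -> int:
        p = DOMAIN_KINDS[self.kind]
        return p.get("flank", p.get("downstream"))


@dataclass(frozen=True)
class TrackMeta:
    """Identity of one ChIP-seq track: the Factor and its cell line/condition."""

    factor_name: str
    description: str = ""
    engineered: bool = False

    @property
    def track_id(self) -> str:
        return f"{self.factor_name}_{self.description}" if self.description else self.factor_name


@dataclass
class MagicMatrix:
    """Gene × track table of maximal ChIP ``signalValue`` per gene domain."""

    values: pd.DataFrame  # index = gene symbols, columns = track ids
    tracks: list[TrackMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise MatrixParseError(f"duplicate gene symbol {dup!r} in matrix")
        if not self.tracks:
            self.tracks = [_track_from_id(c) for c in self.values.columns]
        if list(self.values.columns) != [t.track_id for t in self.tracks]:
            raise ValueError("track metadata does not match matrix columns")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("matrix contains negative signal values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def track_ids(self) -> list[str]:
        return list(self.values.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MagicMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.tracks == other.tracks


def _track_from_id(track_id: str) -> TrackMeta:
    factor, _, desc = track_id.partition("_")
    return TrackMeta(factor_name=factor, description=desc)


def compute_gene_domain(gene: GeneAnnotation, spec: DomainSpec) -> tuple[int, int]:
    """Half-open genomic interval of the gene's domain, clipped at 0.

    Gene-body kinds are strand-symmetric; the promoter window is anchored
    at the TSS and reflected on '−' strand genes so that "upstream" always
    means 5'-ward along the gene's own strand.
    """
    if spec.kind in ("gene_1kb", "gene_5kb"):
        flank = spec.upstream_bp
        return max(0, gene.tx_start - flank), gene.tx_end + flank
    # promoter
    if gene.strand == "+":
        tss = gene.tx_start
        return max(0, tss - spec.upstream_bp), tss + spec.downstream_bp
    tss = gene.tx_end
    return max(0, tss - spec.downstream_bp), tss + spec.upstream_bp


def max_signal_in_domain(
    peaks: Iterable[NarrowPeakRecord], domain: tuple[int, int]
) -> float:
    """Highest ``signalValue`` among peaks overlapping ``domain`` (0 if none)."""
    start, end = domain
    best = 0.0
    for p in peaks:
        if p.start < end and p.end > start:
            best = max(best, p.signal_value)
    return best


def read_narrowpeak(path: str | Path) -> list[NarrowPeakRecord]:
    """Parse a narrowPeak (BED6+4) file; malformed lines are skipped and counted."""
    records: list[NarrowPeakRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 7:
                    raise ValueError("fewer than 7 columns")
                records.append(
                    NarrowPeakRecord(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3] if len(fields) > 3 else ".",
                        score=float(fields[4]) if len(fields) > 4 else 0.0,
                        strand=fields[5] if len(fields) > 5 else ".",
                        signal_value=float(fields[6]),
                        p_value=float(fields[7]) if len(fields) > 7 else -1.0,
                        q_value=float(fields[8]) if len(fields) > 8 else -1.0,
                        peak_offset=int(fields[9]) if len(fields) > 9 else -1,
                    )
                )
            except ValueError as exc:
                skipped += 1
                logger.warning("%s line %d unreadable (%s); skipped", path, lineno, exc)
    if skipped:
        logger.warning("%s: skipped %d unreadable line(s)", path, skipped)
    return records


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation table (symbol, chrom, strand, tx_start, tx_end).

    Duplicate symbols on the same chromosome are merged to the union of
    their isoform extremes (one row per symbol); records with an unknown
    strand are rejected with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"symbol", "chrom", "strand", "tx_start", "tx_end"}
    missing = required - set(df.columns)
    if missing:
        raise MatrixParseError(f"annotation {path} missing columns {sorted(missing)}")
    genes: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        try:
            g = GeneAnnotation(
                symbol=row.symbol,
                chrom=row.chrom,
                strand=row.strand,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
            )
        except ValueError as exc:
            logger.warning("annotation record rejected: %s", exc)
            continue
        prev = genes.get(g.symbol)
        if prev is None:
            genes[g.symbol] = g
        elif prev.chrom == g.chrom and prev.strand == g.strand:
            logger.warning("duplicate symbol %s: merging isoform extremes", g.symbol)
            genes[g.symbol] = GeneAnnotation(
                g.symbol,
                g.chrom,
                g.strand,
                min(prev.tx_start, g.tx_start),
                max(prev.tx_end, g.tx_end),
            )
        else:
            # conflicting placements: keep the wider span
            logger.warning("duplicate symbol %s on different chrom/strand", g.symbol)
            if g.tx_end - g.tx_start > prev.tx_end - prev.tx_start:
                genes[g.symbol] = g
    return list(genes.values())


def read_track_manifest(path: str | Path) -> list[tuple[TrackMeta, Path]]:
    """Tab-delimited manifest: file_path, factor, description, engineered {0,1}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"file_path", "factor", "description", "engineered"}
    missing = required - set(df.columns)
    if missing:
        raise MatrixParseError(f"manifest {path} missing columns {sorted(missing)}")
    base = Path(path).parent
    out = []
    for row in df.itertuples(index=False):
        meta = TrackMeta(
            factor_name=row.factor,
            description=row.description if pd.notna(row.description) else "",
            engineered=str(row.engineered).strip() in ("1", "true", "True"),
        )
        p = Path(row.file_path)
        out.append((meta, p if p.is_absolute() else base / p))
    return out


def build_matrix(
    annotation: Sequence[GeneAnnotation],
    tracks: Sequence[tuple[TrackMeta, str | Path | Sequence[NarrowPeakRecord]]],
    spec: DomainSpec,
    include_engineered: bool = False,
) -> MagicMatrix:
    """Assemble the gene × track matrix of maximal in-domain signalValues.

    ``tracks`` pairs each :class:`TrackMeta` with either a narrowPeak file
    path or an in-memory peak list.  Engineered tracks are dropped unless
    ``include_engineered``; genes on chromosomes a track does not cover
    get 0 for that track.
    """
    if not annotation:
        raise ValueError("need at least one gene")
    retained = [
        (meta, src) for meta, src in tracks if include_engineered or not meta.engineered
    ]
    if not retained:
        raise ValueError("no tracks retained (all engineered?)")
    seen = set()
    for meta, _ in retained:
        if meta.track_id in seen:
            raise ValueError(f"duplicate track id {meta.track_id!r}")
        seen.add(meta.track_id)

    domains = [(g, compute_gene_domain(g, spec)) for g in annotation]
    genes = [g.symbol for g in annotation]
    if len(set(genes)) != len(genes):
        raise ValueError("gene symbols must be unique; merge isoforms first")

    data = np.zeros((len(genes), len(retained)))
    metas = []
    for j, (meta, src) in enumerate(retained):
        peaks = read_narrowpeak(src) if isinstance(src, (str, Path)) else list(src)
        trees: dict[str, IntervalTree] = {}
        for p in peaks:
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.signal_value)
        for i, (g, (dstart, dend)) in enumerate(domains):
            tree = trees.get(g.chrom)
            if tree is None:
                continue
            hits = tree.overlap(dstart, dend)
            if hits:
                data[i, j] = max(iv.data for iv in hits)
        metas.append(meta)

    values = pd.DataFrame(data, index=genes, columns=[m.track_id for m in metas])
    return MagicMatrix(values=values, tracks=metas)


def matrix_filename(spec: DomainSpec, include_engineered: bool = False) -> str:
    """Conventional matrix file name, e.g. ``1Kb_gene.mtx``."""
    stem = {"gene_1kb": "1Kb_gene", "gene_5kb": "5Kb_gene", "promoter": "1Kb_promoter"}[
        spec.kind
    ]
    if include_engineered:
        stem += "_with_engineered_factors"
    return stem + ".mtx"


def write_matrix(matrix: MagicMatrix, path: str | Path) -> None:
    """Write the matrix as tab-delimited text (header = track ids, col 1 = genes)."""
    matrix.values.to_csv(path, sep="\t", index_label="Gene", float_format="%.17g")


def read_matrix(path: str | Path) -> MagicMatrix:
    """Read a tab-delimited matrix file; structural faults raise MatrixParseError."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixParseError(f"{path}: empty file")
        ncol = len(header.split("\t"))
        if ncol < 2:
            raise MatrixParseError(f"{path}: header has no track columns")
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != ncol:
                raise MatrixParseError(f"{path}: ragged row at line {lineno}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise MatrixParseError(f"{path}: duplicate gene symbol {dup!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise MatrixParseError(f"{path}: non-numeric matrix cell ({exc})") from exc
    return MagicMatrix(values=values)
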