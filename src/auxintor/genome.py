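"""Genome and gene-annotation containers.

Coordinates are 1-based inclusive throughout (GFF3 convention).  BED-style
0-based half-open annotation is converted at read time via the ``dialect``
argument of :func:`read_annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import AnnotationError

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class Gene:
    """One annotated coding sequence, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeSpec:
    """Chromosome sizes plus a gene annotation.

    Parameters
    ----------
    chromosomes
        ``(name, length_bp)`` pairs.
    genes
        Gene intervals; each must lie within its chromosome and gene ids
        must be unique.
    """

    chromosomes: list[tuple[str, int]]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise AnnotationError("duplicate chromosome names")
        for name, size in self.chromosomes:
            if size < 1:
                raise AnnotationError(f"chromosome {name}: non-positive length {size}")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in lengths:
                raise AnnotationError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > lengths[g.chrom]:
                raise AnnotationError(
                    f"gene {g.gene_id}: end {g.end} beyond chromosome "
                    f"{g.chrom} length {lengths[g.chrom]}"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {name: [] for name, _ in self.chromosomes}
        for g in self.genes:
            out[g.chrom].append(g)
        return out

    def intergenic_intervals(self) -> list[tuple[str, int, int]]:
        """Maximal intervals (chrom, start, end) covered by no gene (1-based inclusive)."""
        out: list[tuple[str, int, int]] = []
        by_chrom = self.genes_by_chrom()
        for name, size in self.chromosomes:
            pos = 1
            for g in sorted(by_chrom[name], key=lambda g: (g.start, g.end)):
                if g.start > pos:
                    out.append((name, pos, g.start - 1))
                pos = max(pos, g.end + 1)
            if pos <= size:
                out.append((name, pos, size))
        return out

    @classmethod
    def from_genes(
        cls, genes: Sequence[Gene], chromosomes: Sequence[tuple[str, int]] | None = None
    ) -> "GenomeSpec":
        """Build a spec from genes alone, sizing chromosomes to the last gene."""
        if chromosomes is None:
            ends: dict[str, int] = {}
            for g in genes:
                ends[g.chrom] = max(ends.get(g.chrom, 0), g.end)
            chromosomes = list(ends.items())
        return cls(list(chromosomes), list(genes))


def tiled_genome(
    n_genes: int,
    gene_length: int = 1500,
    spacing: int = 500,
    chrom: str = "chrI",
    prefix: str = "G",
) -> GenomeSpec:
    """A synthetic single-chromosome genome of evenly spaced, equal-length genes.

    Convenient ground layout for simulations; gene ids are ``G0001``-style.
    """
    if n_genes < 0:
        raise AnnotationError("n_genes must be >= 0")
    width = max(4, len(str(n_genes)))
    genes = []
    pos = spacing + 1
    for i in range(n_genes):
        genes.append(Gene(f"{prefix}{i + 1:0{width}d}", chrom, pos, pos + gene_length - 1))
        pos += gene_length + spacing
    total = pos - 1 if n_genes else max(spacing, 1)
    return GenomeSpec([(chrom, total)], genes)


# ---------------------------------------------------------------------------
# annotation I/O

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_annotation(path: str | Path, dialect: str = "auto") -> list[Gene]:
    """Read a gene annotation.

    ``dialect`` is one of ``auto`` (sniff from the filename), ``tsv``
    (5 columns ``gene_id chrom start end strand``, 1-based inclusive),
    ``gff3``, or ``bed`` (0-based half-open, converted on read).
    """
    path = Path(path)
    if dialect == "auto":
        suffix = path.suffix.lower()
        dialect = {"gff": "gff3", "gff3": "gff3", "bed": "bed"}.get(suffix.lstrip("."), "tsv")
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect in ("tsv", "bed"):
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        if dialect == "bed":
            df = df.iloc[:, :6]
            df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"][: df.shape[1]]
            if "strand" not in df:
                df["strand"] = "."
            df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based inclusive
        else:
            if df.shape[1] < 5:
                raise AnnotationError(f"{path}: expected 5 columns, got {df.shape[1]}")
            df.columns = ANNOTATION_COLUMNS[: df.shape[1]]
        return [
            Gene(str(r.gene_id), str(r.chrom), int(r.start), int(r.end), str(r.strand))
            for r in df.itertuples()
        ]
    raise AnnotationError(f"unknown annotation dialect {dialect!r}")


def _read_gff3(path: Path) -> list[Gene]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(Gene(gene_id, feat.seqid, feat.start, feat.end, feat.strand or "."))
    return genes


def write_annotation(genes: Iterable[Gene], path: str | Path) -> None:
    """Write genes as the 5-column TSV dialect (1-based inclusive)."""
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", header=False, index=False)
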