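"""Per-gene fitness scoring from transposon insertion libraries.

A saturated transposon library is grown with and without a drug; clones whose
disrupted gene matters for growth under the drug are depleted of sequencing
reads relative to the untreated culture.  This module turns insertion tables
(chrom, position, strand, reads) into per-gene normalized log2 treated/control
scores and percentile bands, and compares score profiles between treatments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import AnnotationError, ParseError
from .genome import GenomeSpec

INSERTION_COLUMNS = ["chrom", "pos", "strand", "reads"]

#: sentinel gene id used for insertions falling in no annotated gene
INTERGENIC = "__intergenic__"

DEPLETED, NEUTRAL, ENRICHED = "depleted", "neutral", "enriched"


@dataclass
class InsertionTable:
    """Transposon insertions for one library/condition.

    ``records`` has columns ``chrom`` (str), ``pos`` (1-based int),
    ``strand`` (+/-/.), ``reads`` (int >= 0).
    """

    records: pd.DataFrame
    condition_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in INSERTION_COLUMNS if c not in self.records.columns]
        if missing:
            raise ParseError(f"insertion table missing columns: {missing}")
        self.records = self.records[INSERTION_COLUMNS].reset_index(drop=True)

    @property
    def total_reads(self) -> int:
        return int(self.records["reads"].sum())

    @property
    def n_sites(self) -> int:
        return int(self.records.drop_duplicates(["chrom", "pos"]).shape[0])

    def __len__(self) -> int:
        return len(self.records)


def read_insertion_table(path: str | Path, condition_label: str | None = None) -> InsertionTable:
    """Read a TSV insertion table (header ``chrom pos strand reads``).

    Malformed rows are rejected with an error naming the 1-based file line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    got = [c.strip() for c in df.columns]
    if got != INSERTION_COLUMNS:
        raise ParseError(f"{path}: expected header {INSERTION_COLUMNS}, got {got}")
    if df.empty:
        records = pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=int),
                                "strand": pd.Series(dtype=str), "reads": pd.Series(dtype=int)})
        return InsertionTable(records, condition_label or path.stem)

    def _to_int(col: str) -> pd.Series:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise ParseError(f"{path}, line {line}: non-integer value in column {col!r}")
        return vals.astype(int)

    pos = _to_int("pos")
    reads = _to_int("reads")
    if (pos < 1).any():
        line = int((pos < 1).idxmax()) + 2
        raise ParseError(f"{path}, line {line}: position must be >= 1")
    if (reads < 0).any():
        line = int((reads < 0).idxmax()) + 2
        raise ParseError(f"{path}, line {line}: negative read count")
    bad_strand = ~df["strand"].isin(["+", "-", "."])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 2
        raise ParseError(f"{path}, line {line}: invalid strand {df['strand'][bad_strand.idxmax()]!r}")
    records = pd.DataFrame(
        {"chrom": df["chrom"].astype(str), "pos": pos, "strand": df["strand"], "reads": reads}
    )
    return InsertionTable(records, condition_label or path.stem)


def write_insertion_table(table: InsertionTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


@dataclass
class GeneCounts:
    """Per-gene insertion-site and read tallies for one library."""

    rows: pd.DataFrame  # gene_id, n_sites, n_reads
    library_total_reads: int
    library_total_sites: int
    intergenic_reads: int = 0
    intergenic_sites: int = 0
    condition_label: str = ""

    @property
    def gene_ids(self) -> set[str]:
        return set(self.rows["gene_id"])

    def counts(self, mode: str) -> pd.Series:
        if mode == "reads":
            return self.rows.set_index("gene_id")["n_reads"]
        if mode == "sites":
            return self.rows.set_index("gene_id")["n_sites"]
        raise ValueError(f"mode must be 'reads' or 'sites', got {mode!r}")

    def library_total(self, mode: str) -> int:
        return self.library_total_reads if mode == "reads" else self.library_total_sites


def assign_insertions(table: InsertionTable, genome: GenomeSpec) -> GeneCounts:
    """Tally insertions per gene by 1-based inclusive interval membership.

    Strand-agnostic; an insertion inside several overlapping genes counts for
    each of them; insertions in no gene are tallied as intergenic.
    """
    known = set(genome.chrom_lengths)
    present = set(table.records["chrom"].unique())
    unknown = sorted(present - known)
    if unknown:
        raise AnnotationError(f"insertion table refers to unknown chromosomes: {unknown}")

    trees: dict[str, IntervalTree] = {}
    for g in genome.genes:
        trees.setdefault(g.chrom, IntervalTree())[g.start : g.end + 1] = g.gene_id

    n_reads: dict[str, int] = {gid: 0 for gid in genome.gene_ids}
    n_sites: dict[str, int] = {gid: 0 for gid in genome.gene_ids}
    inter_reads = inter_sites = 0
    # one row per distinct site: merge strands at the same position
    sites = table.records.groupby(["chrom", "pos"], as_index=False)["reads"].sum()
    for chrom, pos, reads in sites.itertuples(index=False):
        hits = trees[chrom][pos] if chrom in trees else set()
        if not hits:
            inter_reads += int(reads)
            inter_sites += 1
            continue
        for hit in hits:
            n_reads[hit.data] += int(reads)
            n_sites[hit.data] += 1

    rows = pd.DataFrame(
        {
            "gene_id": genome.gene_ids,
            "n_sites": [n_sites[g] for g in genome.gene_ids],
            "n_reads": [n_reads[g] for g in genome.gene_ids],
        }
    )
    return GeneCounts(
        rows,
        library_total_reads=table.total_reads,
        library_total_sites=len(sites),
        intergenic_reads=inter_reads,
        intergenic_sites=inter_sites,
        condition_label=table.condition_label,
    )


def score_genes(
    treated: GeneCounts,
    control: GeneCounts,
    mode: str = "reads",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Normalized log2 treated/control score per gene.

    score = log2( ((t + pc) / T) / ((c + pc) / C) ) with per-gene counts t, c
    and library totals T, C in the chosen mode.  Genes with zero counts in
    both libraries score exactly 0 (neutral).
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    if treated.gene_ids != control.gene_ids:
        diff = sorted(treated.gene_ids ^ control.gene_ids)
        raise ValueError(f"gene sets differ between libraries; symmetric difference: {diff}")
    t = treated.counts(mode)
    c = control.counts(mode).reindex(t.index)
    T = treated.library_total(mode)
    C = control.library_total(mode)
    if T <= 0 or C <= 0:
        raise ValueError("library totals must be positive to normalize")
    score = np.log2((t + pseudocount) / T) - np.log2((c + pseudocount) / C)
    score = score.where(~((t == 0) & (c == 0)), 0.0)
    out = pd.DataFrame({"gene_id": t.index, "score": score.to_numpy(), "band": NEUTRAL})
    return out.reset_index(drop=True)


def classify_percentiles(
    scores: pd.DataFrame, low_pct: float = 10, high_pct: float = 90
) -> pd.DataFrame:
    """Assign depleted/neutral/enriched bands by nearest-rank percentile cutoffs.

    Ties at a cutoff fall into the extreme band.  If the two cutoffs coincide
    (degenerate score distribution) every gene is left neutral and a warning
    is emitted.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    out = scores.copy()
    n = len(out)
    if n == 0:
        return out
    if n < 10:
        warnings.warn(f"only {n} genes; percentile bands are unreliable", stacklevel=2)
    vals = np.sort(out["score"].to_numpy())
    low_cut = vals[max(0, int(np.ceil(low_pct / 100 * n)) - 1)]
    high_cut = vals[max(0, int(np.ceil(high_pct / 100 * n)) - 1)]
    if low_cut >= high_cut:
        warnings.warn(
            "degenerate score distribution: percentile cutoffs coincide; all genes neutral",
            stacklevel=2,
        )
        out["band"] = NEUTRAL
        return out
    band = np.full(n, NEUTRAL, dtype=object)
    band[out["score"].to_numpy() <= low_cut] = DEPLETED
    band[out["score"].to_numpy() >= high_cut] = ENRICHED
    out["band"] = band
    return out


@dataclass
class ConcordanceReport:
    """Agreement between two treatments' score profiles."""

    pearson: float
    spearman: float
    depleted_both: set[str] = field(default_factory=set)
    n_genes: int = 0


def compare_treatments(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> ConcordanceReport:
    """Correlate two score profiles and intersect their bottom-decile sets."""
    ids_a, ids_b = set(scores_a["gene_id"]), set(scores_b["gene_id"])
    if ids_a != ids_b:
        raise ValueError(
            f"gene universes differ; symmetric difference: {sorted(ids_a ^ ids_b)}"
        )
    if len(ids_a) < 3:
        raise ValueError("need at least 3 genes to compute correlations")
    a = scores_a.set_index("gene_id")
    b = scores_b.set_index("gene_id").reindex(a.index)
    pear = float(stats.pearsonr(a["score"], b["score"]).statistic)
    spear = float(stats.spearmanr(a["score"], b["score"]).statistic)
    dep_a = set(a.index[a["band"] == DEPLETED])
    dep_b = set(b.index[b["band"] == DEPLETED])
    return ConcordanceReport(pear, spear, dep_a & dep_b, n_genes=len(ids_a))


def write_scores(
    scores_reads: pd.DataFrame, scores_sites: pd.DataFrame, path: str | Path
) -> None:
    """Write the combined scores TSV: gene_id, score_reads, score_sites, band.

    The band column comes from the reads-mode classification.
    """
    merged = scores_reads.rename(columns={"score": "score_reads"}).merge(
        scores_sites.rename(columns={"score": "score_sites"})[["gene_id", "score_sites"]],
        on="gene_id",
    )[["gene_id", "score_reads", "score_sites", "band"]]
    merged.to_csv(path, sep="\t", index=False)
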