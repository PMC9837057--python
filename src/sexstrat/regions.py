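"""Gene regions around transcription start sites, SNP-to-region mapping, trait filters.

A region is the closed 1-based interval ``[max(1, tss - flank), tss + flank]``
around a gene's strand-aware TSS (default flank 1 Mb, the conventional cis
window for regulatory analysis of drug-metabolism enzyme and transporter
genes).  BED input (0-based half-open) is converted at the reader boundary;
GTF gene lines are consumed as 1-based closed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import normalize_chrom
from .io_sumstats import SumStatsTable

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 1_000_000


@dataclass(frozen=True)
class GeneRegion:
    """A gene with strand-aware TSS and its closed +-flank interval."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    flank: int = DEFAULT_FLANK

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError("tss must be >= 1")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def start(self) -> int:
        return max(1, self.tss - self.flank)

    @property
    def end(self) -> int:
        return self.tss + self.flank

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == self.chrom and self.start <= pos <= self.end


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def load_gene_annotations(path, fmt: str = "bed") -> pd.DataFrame:
    """Parse gene annotations into one row per gene: gene_id, chrom, strand, tss.

    For '+' strand genes the TSS is the feature start, for '-' strand the
    feature end.  BED6 coordinates (0-based half-open) are converted to
    1-based.  Rows with an unknown strand symbol are rejected and counted.
    """
    path = Path(path)
    rows = []
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 6:
                    n_rejected += 1
                    continue
                chrom, start, end, name, _score, strand = fields[:6]
                start1, end1 = int(start) + 1, int(end)  # to 1-based closed
                gene_id = name
            elif fmt == "gtf":
                if len(fields) < 9 or fields[2] != "gene":
                    if len(fields) >= 3 and fields[2] != "gene":
                        continue  # transcripts/exons silently skipped
                    n_rejected += 1
                    continue
                chrom, _src, _feat, start, end, _score, strand, _frame, attrs = fields[:9]
                start1, end1 = int(start), int(end)
                match = _GTF_GENE_ID.search(attrs)
                if not match:
                    n_rejected += 1
                    continue
                gene_id = match.group(1)
            else:
                raise ValueError(f"unknown annotation format {fmt!r}")
            if strand not in ("+", "-"):
                n_rejected += 1
                continue
            tss = start1 if strand == "+" else end1
            rows.append((gene_id, normalize_chrom(chrom), strand, tss))
    if n_rejected:
        logger.warning("load_gene_annotations: rejected %d rows", n_rejected)
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])


def build_regions(genes: pd.DataFrame | Iterable, flank: int = DEFAULT_FLANK) -> list[GeneRegion]:
    """Closed ``[max(1, tss - flank), tss + flank]`` interval per gene."""
    if isinstance(genes, pd.DataFrame):
        records = genes.itertuples(index=False)
        return [GeneRegion(r.gene_id, normalize_chrom(r.chrom), r.strand, int(r.tss), flank)
                for r in records]
    return [GeneRegion(g["gene_id"], normalize_chrom(g["chrom"]), g["strand"],
                       int(g["tss"]), flank) for g in genes]


class RegionIndex:
    """Interval index over regions for fast point containment queries."""

    def __init__(self, regions: Sequence[GeneRegion]):
        self._trees: dict[str, IntervalTree] = {}
        for region in regions:
            tree = self._trees.setdefault(region.chrom, IntervalTree())
            # intervaltree is half-open; +1 keeps the closed right bound
            tree.addi(region.start, region.end + 1, region.gene_id)

    def query(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree[int(pos)])


def map_snps_to_regions(
    table: SumStatsTable, regions: Sequence[GeneRegion]
) -> pd.Series:
    """Per-variant list of overlapping region gene_ids (closed containment).

    Returns a Series aligned to ``table.df`` whose entries are (possibly
    empty) sorted lists of gene_ids; a variant may fall in several
    overlapping regions.
    """
    index = RegionIndex(regions)
    hits = [index.query(c, p) for c, p in zip(table.df["chrom"], table.df["pos"])]
    return pd.Series(hits, index=table.df.index, name="gene_ids")


def write_regions(regions: Sequence[GeneRegion], path) -> None:
    pd.DataFrame(
        [(r.gene_id, r.chrom, r.strand, r.tss, r.start, r.end, r.flank) for r in regions],
        columns=["gene_id", "chrom", "strand", "tss", "start", "end", "flank"],
    ).to_csv(path, sep="\t", index=False)


def read_regions(path) -> list[GeneRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [GeneRegion(r.gene_id, normalize_chrom(r.chrom), r.strand, int(r.tss), int(r.flank))
            for r in df.itertuples(index=False)]


def default_prevalence_difference(prev_m: float, prev_f: float, rel_tol: float = 0.02) -> bool:
    """True when the sexes differ in prevalence by more than ``rel_tol`` relatively.

    The published selection rule keeps case-control traits with a sex
    difference in prevalence; its printed form is not implementable literally,
    so the difference is quantified as |prev_m - prev_f| / max(prev) and the
    predicate is pluggable (see ``filter_traits``).
    """
    top = max(prev_m, prev_f)
    if top <= 0:
        return False
    return abs(prev_m - prev_f) / top > rel_tol


def filter_traits(
    meta: pd.DataFrame,
    min_cases: int = 300,
    sex_diff_predicate: Callable[[float, float], bool] = default_prevalence_difference,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the trait-selection filters to per-trait metadata.

    ``meta`` columns: trait_id, trait_type, and for binary traits
    n_cases_male, n_cases_female, n_male, n_female.  Binary traits are
    excluded when either sex has fewer than ``min_cases`` cases, when the
    prevalence predicate reports no sex difference, or when the case counts
    are missing.  Quantitative traits pass vacuously.

    Returns (kept trait_ids, decision frame with a per-trait reason).
    """
    decisions = []
    for row in meta.itertuples(index=False):
        trait_id = row.trait_id
        if row.trait_type != "binary":
            decisions.append((trait_id, True, "quantitative"))
            continue
        counts = [getattr(row, c, None) for c in
                  ("n_cases_male", "n_cases_female", "n_male", "n_female")]
        if any(c is None or (isinstance(c, float) and np.isnan(c)) for c in counts):
            decisions.append((trait_id, False, "incomplete_metadata"))
            continue
        ncm, ncf, nm, nf = (int(c) for c in counts)
        if ncm > nm or ncf > nf:
            decisions.append((trait_id, False, "incomplete_metadata"))
            continue
        if min(ncm, ncf) < min_cases:
            decisions.append((trait_id, False, "case_count"))
            continue
        if not sex_diff_predicate(ncm / nm, ncf / nf):
            decisions.append((trait_id, False, "no_prevalence_difference"))
            continue
        decisions.append((trait_id, True, "passed"))
    frame = pd.DataFrame(decisions, columns=["trait_id", "kept", "reason"])
    return frame.loc[frame["kept"], "trait_id"].tolist(), frame


def select_heritable_traits(h2: pd.Series | Mapping[str, float]) -> list[str]:
    """Trait ids with h2 strictly greater than the sample median (ties drop)."""
    s = pd.Series(h2, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least two traits to take a median")
    return s.index[s > s.median()].tolist()
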