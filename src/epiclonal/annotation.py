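"""Genomic-context annotation of loci: CpG islands and gene models.

CpG context follows the usual island / shore / shelf / open-sea nesting:
shores are the 2 kb intervals flanking each (merged) island, shelves the
next 2 kb beyond the shores, with precedence island > shore > shelf >
open sea on overlap.  Gene context uses UCSC refFlat gene models with
precedence promoter > exon > intron > intergenic and reports the signed
distance to the nearest transcription start site (negative = upstream of
the TSS, strand-aware).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import Interval, IntervalTree

logger = logging.getLogger(__name__)

ISLAND = "island"
SHORE = "shore"
SHELF = "shelf"
OPEN_SEA = "open_sea"
CPG_CATEGORIES = (ISLAND, SHORE, SHELF, OPEN_SEA)

PROMOTER = "promoter"
EXON = "exon"
INTRON = "intron"
INTERGENIC = "intergenic"
GENE_CATEGORIES = (PROMOTER, EXON, INTRON, INTERGENIC)

DEFAULT_FLANK_BP = 2000
DEFAULT_PROMOTER_UP = 1000
DEFAULT_PROMOTER_DOWN = 1000


@dataclass(frozen=True)
class GeneContext:
    label: str
    tss_distance: Optional[int]


@dataclass(frozen=True)
class Gene:
    """One refFlat transcript record (0-based half-open coordinates)."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: Tuple[Tuple[int, int], ...]

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping/adjacent (start, end) half-open intervals."""
    merged: List[List[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


class CpGIslandAnnotator:
    """Classify loci as island / shore / shelf / open sea."""

    def __init__(
        self,
        islands: Sequence[Tuple[str, int, int]],
        flank_bp: int = DEFAULT_FLANK_BP,
    ) -> None:
        self.flank_bp = flank_bp
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in islands:
            by_chrom.setdefault(chrom, []).append((start, end))
        self._island: Dict[str, IntervalTree] = {}
        self._shore: Dict[str, IntervalTree] = {}
        self._shelf: Dict[str, IntervalTree] = {}
        for chrom, raw in by_chrom.items():
            merged = merge_intervals(raw)  # merged first so shores never double-count
            island_tree = IntervalTree(Interval(s, e) for s, e in merged if e > s)
            shore_tree = IntervalTree()
            shelf_tree = IntervalTree()
            for s, e in merged:
                flanks = (
                    (shore_tree, max(0, s - flank_bp), s),
                    (shore_tree, e, e + flank_bp),
                    (shelf_tree, max(0, s - 2 * flank_bp), max(0, s - flank_bp)),
                    (shelf_tree, e + flank_bp, e + 2 * flank_bp),
                )
                for tree, fs, fe in flanks:
                    if fe > fs:  # islands near the chromosome start clip to empty
                        tree.addi(fs, fe)
            self._island[chrom] = island_tree
            self._shore[chrom] = shore_tree
            self._shelf[chrom] = shelf_tree

    def annotate(self, chrom: str, start: int, end: int) -> str:
        """CpG context of the half-open interval [start, end)."""
        for label, trees in ((ISLAND, self._island), (SHORE, self._shore), (SHELF, self._shelf)):
            tree = trees.get(chrom)
            if tree is not None and tree.overlap(start, end):
                return label
        return OPEN_SEA


def read_refflat(path) -> List[Gene]:
    """Parse UCSC refFlat gene models; malformed records are skipped with a warning."""
    genes: List[Gene] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                name, _tx_name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
                tx_start, tx_end = int(fields[4]), int(fields[5])
                exon_starts = [int(x) for x in fields[9].rstrip(",").split(",")]
                exon_ends = [int(x) for x in fields[10].rstrip(",").split(",")]
                if strand not in "+-" or len(exon_starts) != len(exon_ends):
                    raise ValueError
            except (IndexError, ValueError):
                logger.warning("%s:%d: malformed refFlat record skipped", path, lineno)
                continue
            genes.append(
                Gene(
                    name=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=tuple(zip(exon_starts, exon_ends)),
                )
            )
    return genes


class GeneAnnotator:
    """Classify loci against gene models and compute nearest-TSS distances."""

    def __init__(
        self,
        genes: Sequence[Gene],
        promoter_up: int = DEFAULT_PROMOTER_UP,
        promoter_down: int = DEFAULT_PROMOTER_DOWN,
    ) -> None:
        self.promoter_up = promoter_up
        self.promoter_down = promoter_down
        self._promoter: Dict[str, IntervalTree] = {}
        self._exon: Dict[str, IntervalTree] = {}
        self._body: Dict[str, IntervalTree] = {}
        self._tss: Dict[str, List[Tuple[int, str]]] = {}
        for gene in genes:
            tss = gene.tss
            # positions whose signed TSS distance lies in [-up, down]
            if gene.strand == "+":
                prom = (max(0, tss - promoter_up), tss + promoter_down + 1)
            else:
                prom = (max(0, tss - promoter_down), tss + promoter_up + 1)
            self._promoter.setdefault(gene.chrom, IntervalTree()).addi(*prom)
            for s, e in gene.exons:
                if e > s:
                    self._exon.setdefault(gene.chrom, IntervalTree()).addi(s, e)
            if gene.tx_end > gene.tx_start:
                self._body.setdefault(gene.chrom, IntervalTree()).addi(gene.tx_start, gene.tx_end)
            self._tss.setdefault(gene.chrom, []).append((tss, gene.strand))

    def tss_distance(self, chrom: str, point: int) -> Optional[int]:
        """Signed distance from ``point`` to the nearest TSS on ``chrom``.

        Positive downstream of the TSS in the gene's direction of
        transcription, negative upstream; None when the chromosome carries
        no gene.
        """
        sites = self._tss.get(chrom)
        if not sites:
            return None
        best = min(sites, key=lambda item: abs(point - item[0]))
        tss, strand = best
        return point - tss if strand == "+" else tss - point

    def annotate(self, chrom: str, start: int, end: int) -> GeneContext:
        """Gene context of the half-open interval [start, end)."""
        dist = self.tss_distance(chrom, start)
        for label, trees in ((PROMOTER, self._promoter), (EXON, self._exon), (INTRON, self._body)):
            tree = trees.get(chrom)
            if tree is not None and tree.overlap(start, end):
                return GeneContext(label=label, tss_distance=dist)
        return GeneContext(label=INTERGENIC, tss_distance=dist)


def context_summary(
    elocus_labels: Sequence[str],
    background_labels: Sequence[str],
    categories: Sequence[str],
) -> pd.DataFrame:
    """Per-category fractions for the elocus set vs. all covered (background) loci.

    Fractions sum to 1 within each set; an empty set yields missing (NaN)
    fractions.
    """
    def fractions(labels: Sequence[str]) -> List[float]:
        n = len(labels)
        if n == 0:
            return [float("nan")] * len(categories)
        return [sum(1 for lab in labels if lab == cat) / n for cat in categories]

    return pd.DataFrame(
        {
            "category": list(categories),
            "eloci_fraction": fractions(elocus_labels),
            "background_fraction": fractions(background_labels),
        }
    )
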