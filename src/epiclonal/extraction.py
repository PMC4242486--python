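"""Per-locus epiallele compositions from methylation-call reads.

A locus is a window of ``m`` consecutive CpG positions (default 4, giving
2**4 = 16 possible epiallele patterns); every read that covers all ``m``
CpGs of a window with unambiguous calls contributes one pattern word to
that window's tally.  Windows are slid over the per-chromosome CpG universe
(the sorted union of CpG positions observed in the input reads), so a read
covering more than ``m`` CpGs contributes to every fully-covered window.
Compositions are then filtered on per-sample coverage, intersected across
the two samples, and optionally purged of loci overlapping C>T / G>A
variants (which can mimic unmethylated / methylated calls in bisulfite
data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

if TYPE_CHECKING:  # pragma: no cover
    from .io_bismark import MethylationRead

logger = logging.getLogger(__name__)

DEFAULT_M = 4
DEFAULT_MIN_READS = 60


@lru_cache(maxsize=None)
def pattern_words(m: int = DEFAULT_M) -> Tuple[str, ...]:
    """All 2**m epiallele words in index (binary/lexicographic) order."""
    return tuple(format(i, f"0{m}b") for i in range(2**m))


def word_to_index(word: str) -> int:
    return int(word, 2)


@dataclass(frozen=True)
class EpiallelePattern:
    """A fixed-length methylation word and its index in the 2**m pattern space."""

    word: str
    index: int

    def __post_init__(self) -> None:
        if set(self.word) - {"0", "1"}:
            raise ValueError(f"pattern word must be over {{0,1}}, got {self.word!r}")
        if self.index != word_to_index(self.word):
            raise ValueError("index must be the binary value of the word")

    @classmethod
    def from_word(cls, word: str) -> "EpiallelePattern":
        return cls(word=word, index=word_to_index(word))

    @classmethod
    def from_index(cls, index: int, m: int = DEFAULT_M) -> "EpiallelePattern":
        return cls(word=format(index, f"0{m}b"), index=index)


@dataclass(frozen=True)
class Locus:
    """``m`` consecutive reference CpG positions defining one epiallele window."""

    chrom: str
    cpg_positions: Tuple[int, ...]

    def __post_init__(self) -> None:
        pos = self.cpg_positions
        if len(pos) < 2 or any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("cpg_positions must be >=2 strictly increasing coordinates")

    @property
    def m(self) -> int:
        return len(self.cpg_positions)

    @property
    def start(self) -> int:
        return self.cpg_positions[0]

    @property
    def end(self) -> int:
        return self.cpg_positions[-1]


@dataclass(frozen=True)
class SampleComposition:
    """Raw read count and per-pattern counts/proportions at one locus in one sample."""

    locus: Locus
    raw_count: int
    pattern_counts: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.pattern_counts) != 2**self.locus.m:
            raise ValueError("pattern_counts must have 2**m entries")
        if any(c < 0 for c in self.pattern_counts):
            raise ValueError("pattern counts must be nonnegative")
        if sum(self.pattern_counts) != self.raw_count:
            raise ValueError("pattern counts must sum to raw_count")

    @property
    def proportions(self) -> np.ndarray:
        counts = np.asarray(self.pattern_counts, dtype=float)
        if self.raw_count == 0:
            return counts
        return counts / self.raw_count


# ---------------------------------------------------------------------------
# locus enumeration


def cpg_universe(*read_sets: Iterable["MethylationRead"]) -> Dict[str, List[int]]:
    """Sorted union of observed CpG positions per chromosome across read sets."""
    seen: Dict[str, set] = {}
    for reads in read_sets:
        for read in reads:
            chrom_set = seen.setdefault(read.chrom, set())
            for pos, _ in read.calls:
                chrom_set.add(pos)
    return {chrom: sorted(positions) for chrom, positions in seen.items()}


def enumerate_loci(
    reads: Iterable["MethylationRead"],
    m: int = DEFAULT_M,
    universe: Optional[Dict[str, Sequence[int]]] = None,
    first_window_only: bool = False,
) -> Dict[Locus, np.ndarray]:
    """Tally epiallele patterns for every fully-covered ``m``-CpG window.

    ``universe`` fixes the CpG coordinate system (normally the union over
    both samples so window boundaries agree); without it the universe is
    built from ``reads`` alone.  A read with an ambiguous (dropped) call
    inside a window simply does not cover that window; its other windows
    are unaffected.  With ``first_window_only`` each read contributes only
    to the leftmost window it covers.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    reads = list(reads)
    if universe is None:
        universe = cpg_universe(reads)
    index_of = {
        chrom: {pos: i for i, pos in enumerate(positions)} for chrom, positions in universe.items()
    }
    n_patterns = 2**m
    tallies: Dict[Locus, np.ndarray] = {}
    for read in reads:
        chrom_index = index_of.get(read.chrom)
        if chrom_index is None:
            continue
        positions = universe[read.chrom]
        indexed = sorted(
            (chrom_index[pos], state) for pos, state in read.calls if pos in chrom_index
        )
        if len(indexed) < m:
            continue
        # maximal runs of consecutive universe indices covered by this read
        runs: List[List[Tuple[int, int]]] = [[indexed[0]]]
        for item in indexed[1:]:
            if item[0] == runs[-1][-1][0] + 1:
                runs[-1].append(item)
            else:
                runs.append([item])
        done = False
        for run in runs:
            if done:
                break
            for w in range(len(run) - m + 1):
                window = run[w : w + m]
                locus = Locus(
                    chrom=read.chrom,
                    cpg_positions=tuple(positions[i] for i, _ in window),
                )
                pattern_index = 0
                for _, state in window:
                    pattern_index = (pattern_index << 1) | state
                tally = tallies.setdefault(locus, np.zeros(n_patterns, dtype=np.int64))
                tally[pattern_index] += 1
                if first_window_only:
                    done = True
                    break
    return tallies


def build_composition(
    tallies: Dict[Locus, np.ndarray], min_reads: int = DEFAULT_MIN_READS
) -> Dict[Locus, SampleComposition]:
    """Turn tallies into compositions, dropping loci with fewer than ``min_reads`` reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    out: Dict[Locus, SampleComposition] = {}
    for locus, tally in tallies.items():
        raw = int(tally.sum())
        if raw < min_reads:
            continue
        out[locus] = SampleComposition(
            locus=locus, raw_count=raw, pattern_counts=tuple(int(c) for c in tally)
        )
    return out


def intersect_samples(
    comps1: Dict[Locus, SampleComposition], comps2: Dict[Locus, SampleComposition]
) -> List[Tuple[SampleComposition, SampleComposition]]:
    """Pair up loci that passed the coverage filter in both samples.

    The number of returned pairs is C, the denominator of the EPM summary.
    """
    shared = sorted(
        set(comps1) & set(comps2), key=lambda locus: (locus.chrom, locus.cpg_positions)
    )
    return [(comps1[locus], comps2[locus]) for locus in shared]


# ---------------------------------------------------------------------------
# SNP filtering


def read_vcf_variants(path) -> List[Tuple[str, int, str, str]]:
    """Read (chrom, pos_1based, ref, alt) tuples from an uncompressed VCF.

    Multi-allelic records are expanded; unparseable lines are skipped with a
    warning.
    """
    variants: List[Tuple[str, int, str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                chrom, pos, ref, alts = fields[0], int(fields[1]), fields[3], fields[4]
            except (IndexError, ValueError):
                logger.warning("%s:%d: unparseable variant line skipped", path, lineno)
                continue
            for alt in alts.split(","):
                variants.append((chrom, pos, ref.upper(), alt.upper()))
    return variants


def read_bed_intervals(path) -> List[Tuple[str, int, int]]:
    """Read (chrom, start, end) 0-based half-open intervals from a BED file."""
    intervals: List[Tuple[str, int, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
            except (IndexError, ValueError):
                logger.warning("%s:%d: unparseable BED line skipped", path, lineno)
    return intervals


def filter_snp_overlap(
    pairs: List[Tuple[SampleComposition, SampleComposition]],
    variants: Optional[List[Tuple[str, int, str, str]]] = None,
    exclusion_intervals: Optional[List[Tuple[str, int, int]]] = None,
) -> List[Tuple[SampleComposition, SampleComposition]]:
    """Drop loci whose CpG dyads carry bisulfite-confoundable variants.

    A C>T SNP at the C of a dyad (or a G>A SNP at the paired G) is
    indistinguishable from an unmethylated (resp. apparent) call, so any
    locus with such a variant on one of its ``m`` dyads is removed.  Other
    variant types are ignored.  ``exclusion_intervals`` (e.g. from a
    precomputed BED) remove any locus whose dyad positions they overlap.
    """
    ct_positions: set = set()
    ga_positions: set = set()
    for chrom, pos, ref, alt in variants or []:
        pos0 = pos - 1
        if ref == "C" and alt == "T":
            ct_positions.add((chrom, pos0))
        elif ref == "G" and alt == "A":
            ga_positions.add((chrom, pos0))
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end in exclusion_intervals or []:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def excluded(locus: Locus) -> bool:
        tree = trees.get(locus.chrom)
        for c_pos in locus.cpg_positions:
            g_pos = c_pos + 1  # paired G on the opposite strand
            if (locus.chrom, c_pos) in ct_positions or (locus.chrom, g_pos) in ga_positions:
                return True
            if tree is not None and (tree.overlaps_point(c_pos) or tree.overlaps_point(g_pos)):
                return True
        return False

    kept = [(c1, c2) for c1, c2 in pairs if not excluded(c1.locus)]
    removed = len(pairs) - len(kept)
    if removed:
        logger.info("SNP filter removed %d locus/loci", removed)
    return kept
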