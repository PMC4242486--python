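"""Read and write bisulfite methylation-call data and comparison results.

Input side: Bismark-style BAM/SAM alignments carrying the per-read
methylation-call string (XM tag; ``Z`` = methylated CpG, ``z`` =
unmethylated CpG, anything else ignored), plus a bundled plain-TSV read
format used by the simulator and tests.  Output side: the per-locus
comparison table (TSV), the elocus BED track and a JSON run summary.

Coordinates are 0-based half-open internally; written tables use 1-based
inclusive locus coordinates (BED stays 0-based half-open per its own
convention).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam

if TYPE_CHECKING:  # pragma: no cover
    from .entropy import ComparisonResult

logger = logging.getLogger(__name__)

FORMAT_BAM = "bam"
FORMAT_PLAIN = "plain_tsv"

METHYLATED = 1
UNMETHYLATED = 0


@dataclass(frozen=True)
class MethylationRead:
    """One sequencing read reduced to its phased CpG methylation calls.

    ``calls`` is an ordered tuple of ``(ref_cpg_position, state)`` where the
    position is the 0-based coordinate of the C of the CpG dyad on the +
    strand and state is 1 (methylated) or 0 (unmethylated).
    """

    chrom: str
    pos: int
    strand: str
    calls: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.calls]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("CpG call positions must be strictly increasing")
        if any(s not in (METHYLATED, UNMETHYLATED) for _, s in self.calls):
            raise ValueError("call states must be 0 or 1")


@dataclass
class ReadSource:
    """A sample's read file plus its format and label."""

    path: str
    format: Optional[str] = None
    sample_label: str = ""

    def __post_init__(self) -> None:
        if not self.sample_label:
            self.sample_label = Path(self.path).stem
        if not self.sample_label:
            raise ValueError("sample_label must be nonempty")
        if self.format is None:
            suffix = Path(self.path).suffix.lower()
            self.format = FORMAT_BAM if suffix in (".bam", ".sam", ".cram") else FORMAT_PLAIN
        if self.format not in (FORMAT_BAM, FORMAT_PLAIN):
            raise ValueError(f"unknown format {self.format!r}")


# ---------------------------------------------------------------------------
# parsing


def parse_reads(source: ReadSource, region=None, collapse_strands: bool = True) -> Iterator[MethylationRead]:
    """Dispatch to the BAM or plain-TSV parser based on ``source.format``."""
    if source.format == FORMAT_BAM:
        return parse_bam(source, region=region, collapse_strands=collapse_strands)
    return parse_plain(source)


def parse_bam(
    source: ReadSource,
    region=None,
    collapse_strands: bool = True,
) -> Iterator[MethylationRead]:
    """Stream methylation reads from a Bismark-style BAM/SAM file.

    Only primary, uniquely-mapped alignments with at least one CpG call are
    emitted.  CpG calls on reverse-strand alignments sit on the G of the
    dyad; with ``collapse_strands`` (default) they are shifted by -1 onto
    the + strand C so both strands address the same CpG.  Records without
    the XM tag are skipped with a counted warning.
    """
    missing_tag = 0
    with pysam.AlignmentFile(str(source.path), check_sq=False) as bam:
        if region is not None:
            records = bam.fetch(*region) if isinstance(region, tuple) else bam.fetch(region=region)
        else:
            records = bam
        for aln in records:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if not aln.has_tag("XM"):
                missing_tag += 1
                continue
            xm = aln.get_tag("XM")
            calls = []
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                symbol = xm[qpos]
                if symbol == "Z":
                    state = METHYLATED
                elif symbol == "z":
                    state = UNMETHYLATED
                else:
                    continue
                ref = rpos - 1 if (collapse_strands and aln.is_reverse) else rpos
                calls.append((ref, state))
            if not calls:
                continue
            calls.sort()
            yield MethylationRead(
                chrom=aln.reference_name,
                pos=aln.reference_start,
                strand="-" if aln.is_reverse else "+",
                calls=tuple(calls),
            )
    if missing_tag:
        logger.warning("%d alignment(s) without an XM methylation-call tag were skipped", missing_tag)


def parse_plain(source: ReadSource) -> Iterator[MethylationRead]:
    """Parse the bundled plain read format.

    Tab-separated columns: chromosome, comma-separated 0-based CpG positions,
    call word over {0,1} of equal length.  An optional fourth column carries
    the strand (default ``+``).
    """
    with open(source.path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{source.path}:{lineno}: expected >=3 tab-separated columns")
            chrom, pos_field, word = fields[0], fields[1], fields[2]
            strand = fields[3] if len(fields) > 3 else "+"
            positions = [int(p) for p in pos_field.split(",")]
            if len(positions) != len(word):
                raise ValueError(
                    f"{source.path}:{lineno}: {len(positions)} positions but call word of length {len(word)}"
                )
            calls = tuple((p, int(c)) for p, c in zip(positions, word))
            yield MethylationRead(chrom=chrom, pos=positions[0], strand=strand, calls=calls)


# ---------------------------------------------------------------------------
# writing reads


def write_plain(reads: Iterable[MethylationRead], path) -> int:
    """Write reads in the plain-TSV format; returns the number written."""
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            positions = ",".join(str(p) for p, _ in read.calls)
            word = "".join(str(s) for _, s in read.calls)
            handle.write(f"{read.chrom}\t{positions}\t{word}\t{read.strand}\n")
            n += 1
    return n


def write_bam(reads: Sequence[MethylationRead], path, reference_lengths: Optional[dict] = None) -> int:
    """Write reads as Bismark-style alignments with an XM tag.

    Reverse-strand reads are written with their calls on the G of the CpG
    dyad (position + 1) and the reverse flag set, so that parsing with
    strand collapsing round-trips to the + strand C coordinates.  The output
    is SAM or BAM depending on the file extension.
    """
    reads = list(reads)
    if reference_lengths is None:
        reference_lengths = {}
        for read in reads:
            end = read.calls[-1][0] + 2
            reference_lengths[read.chrom] = max(reference_lengths.get(read.chrom, 0), end + 1000)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in reference_lengths.items()],
    }
    mode = "w" if str(path).endswith(".sam") else "wb"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for i, read in enumerate(reads):
            shift = 1 if read.strand == "-" else 0
            positions = [p + shift for p, _ in read.calls]
            start = min(read.pos + shift, positions[0])
            length = positions[-1] - start + 1
            xm = ["."] * length
            for (pos, state) in zip(positions, (s for _, s in read.calls)):
                xm[pos - start] = "Z" if state == METHYLATED else "z"
            aln = pysam.AlignedSegment()
            aln.query_name = f"read{i}"
            aln.query_sequence = "A" * length
            aln.flag = 16 if read.strand == "-" else 0
            aln.reference_id = out.get_tid(read.chrom)
            aln.reference_start = start
            aln.mapping_quality = 42
            aln.cigarstring = f"{length}M"
            aln.set_tag("XM", "".join(xm))
            out.write(aln)
    return len(reads)


# ---------------------------------------------------------------------------
# writing comparison results

#: Fixed (non-pattern) columns of the comparison table, in order.
COMPARISON_FIXED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "reads1",
    "reads2",
    "delta_s",
    "epipoly1",
    "epipoly2",
    "delta_epipoly",
    "shift_class",
    "hamming_presence",
    "hamming_major",
]


def comparison_columns(m: int = 4) -> list[str]:
    """Full column list of the comparison TSV for word length ``m``."""
    from .extraction import pattern_words

    words = pattern_words(m)
    return COMPARISON_FIXED_COLUMNS + [f"s1_{w}" for w in words] + [f"s2_{w}" for w in words]


def comparison_frame(result: "ComparisonResult") -> pd.DataFrame:
    """Tabulate a comparison result, one row per locus covered in both samples."""
    m = result.m
    rows = []
    for comp in result.comparisons:
        locus = comp.locus
        row = {
            "chrom": locus.chrom,
            "start": locus.start + 1,  # 1-based inclusive
            "end": locus.end + 1,
            "reads1": comp.raw_count1,
            "reads2": comp.raw_count2,
            "delta_s": round(comp.delta_s, 6),
            "epipoly1": round(comp.epipoly[0], 6),
            "epipoly2": round(comp.epipoly[1], 6),
            "delta_epipoly": round(comp.delta_epipoly, 6),
            "shift_class": comp.shift_class,
            "hamming_presence": comp.hamming_presence,
            "hamming_major": comp.hamming_major,
        }
        from .extraction import pattern_words

        for stage, spectrum in (("s1", comp.spectra[0]), ("s2", comp.spectra[1])):
            for word, p in zip(pattern_words(m), spectrum):
                row[f"{stage}_{word}"] = round(100.0 * float(p), 4)
        rows.append(row)
    return pd.DataFrame(rows, columns=comparison_columns(m))


def write_comparison(result: "ComparisonResult", out_prefix) -> dict:
    """Write ``<prefix>.tsv``, ``<prefix>_eloci.bed`` and ``<prefix>_summary.json``.

    The BED track holds the eloci at the active cutoff (0-based half-open,
    score column = delta-S); the JSON summary reports the number of loci
    covered by both samples (C) and, per cutoff, the elocus count E and the
    EPM (eloci per million covered loci; null when C is zero).
    """
    out_prefix = str(out_prefix)
    paths = {
        "tsv": out_prefix + ".tsv",
        "bed": out_prefix + "_eloci.bed",
        "json": out_prefix + "_summary.json",
    }
    frame = comparison_frame(result)
    frame.to_csv(paths["tsv"], sep="\t", index=False)

    active = result.eloci_by_cutoff[result.active_cutoff]
    with open(paths["bed"], "w") as bed:
        for comp in active:
            locus = comp.locus
            bed.write(f"{locus.chrom}\t{locus.start}\t{locus.end + 1}\t{comp.delta_s:.6f}\n")

    summary = {
        "loci_covered": result.C,
        "active_cutoff": result.active_cutoff,
        "cutoffs": {
            str(cutoff): {
                "eloci": len(result.eloci_by_cutoff[cutoff]),
                "epm": result.epm_by_cutoff[cutoff],
            }
            for cutoff in sorted(result.eloci_by_cutoff, reverse=True)
        },
    }
    with open(paths["json"], "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return paths
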