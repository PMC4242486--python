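"""Combinatorial entropy statistic for epiallele composition shifts.

For one locus with per-stage normalized pattern counts ``N_{i,k}`` the
foreground entropy is the log multinomial permutation count summed over the
two stages,

    S = sum_k [ ln N_k! - sum_i ln N_{i,k}! ] ,

with factorials generalized to fractional counts through the log-gamma
function ``ln Gamma(x + 1)``.  The background entropy evaluates the same
expression at the pooled-expectation counts ``Ñ_{i,k} = N_k * N_i / N``
(pattern totals pooled across stages and redistributed proportionally),
which maximizes the stage entropies for the fixed pooled composition.  The
statistic is

    delta-S = S - S̃  <=  0 ,

zero exactly when the two stages have identical pattern proportions and
increasingly negative as the compositions diverge; a locus is an *elocus*
when delta-S falls below a cutoff alpha (default -60).  Each stage is
normalized to 100 reads, i.e. a locus total of 200 across both stages, so
delta-S is depth-free and spans 0 down to about -133.6 (two disjoint
single-pattern stages, -2 ln C(100,50)).  For large normalization totals
delta-S / (2 * norm_total) approaches minus the Jensen-Shannon divergence
of the two proportion vectors (equal weights, nats).

The EPM summary (eloci per million loci covered by both samples,
``EPM = 1e6 * E / C``) makes elocus burdens comparable across libraries of
different depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .extraction import Locus, SampleComposition
from .heterogeneity import (
    DEFAULT_BAND,
    DEFAULT_PRESENCE_CUTOFF,
    NONE,
    classify_shift,
    epipolymorphism,
    hamming_major,
    hamming_presence,
)

#: Per-stage normalization constant (locus total 200 across both stages).
DEFAULT_NORM_TOTAL = 100.0
#: Elocus cutoffs reported side by side; the first is the active default.
DEFAULT_CUTOFFS = (-60.0, -70.0, -80.0)
DEFAULT_ALPHA = -60.0


@dataclass(frozen=True)
class NormalizedComposition:
    """Pattern counts rescaled so each stage carries a fixed total."""

    norm_total: float
    norm_counts: np.ndarray

    def __post_init__(self) -> None:
        nc = np.asarray(self.norm_counts, dtype=float)
        if (nc < 0).any():
            raise ValueError("normalized counts must be nonnegative")
        if not np.isclose(nc.sum(), self.norm_total, atol=1e-9 * max(1.0, self.norm_total)):
            raise ValueError("normalized counts must sum to norm_total")
        object.__setattr__(self, "norm_counts", nc)

    @classmethod
    def from_proportions(cls, proportions, norm_total: float = DEFAULT_NORM_TOTAL):
        p = np.asarray(proportions, dtype=float)
        return cls(norm_total=norm_total, norm_counts=norm_total * p / p.sum())


def stage_entropy(norm_counts) -> float:
    """Log permutation count ``ln(N! / prod_i N_i!)`` of one stage's counts.

    Counts may be fractional (log-gamma generalization).  Zero when a single
    pattern holds all mass; maximal, for fixed total, at the uniform
    composition.
    """
    nc = np.asarray(norm_counts, dtype=float)
    if (nc < 0).any():
        raise ValueError("counts must be nonnegative")
    return float(gammaln(nc.sum() + 1.0) - gammaln(nc + 1.0).sum())


def foreground_entropy(nc1, nc2) -> float:
    """Foreground entropy S: stage entropies of the two observed compositions, summed."""
    return stage_entropy(nc1) + stage_entropy(nc2)


def background_counts(nc1, nc2) -> Tuple[np.ndarray, np.ndarray]:
    """Pooled-expectation counts ``Ñ_{i,k} = N_k * N_i / N`` for both stages."""
    a = np.asarray(nc1, dtype=float)
    b = np.asarray(nc2, dtype=float)
    pooled = a + b
    total = pooled.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    return a.sum() * pooled / total, b.sum() * pooled / total


def background_entropy(nc1, nc2) -> float:
    """Background entropy S̃: stage entropies at the pooled-expectation counts."""
    b1, b2 = background_counts(nc1, nc2)
    return stage_entropy(b1) + stage_entropy(b2)


def delta_entropy_from_proportions(p1, p2, norm_total: float = DEFAULT_NORM_TOTAL) -> float:
    """delta-S from two pattern proportion vectors at a per-stage normalization total."""
    nc1 = NormalizedComposition.from_proportions(p1, norm_total).norm_counts
    nc2 = NormalizedComposition.from_proportions(p2, norm_total).norm_counts
    return foreground_entropy(nc1, nc2) - background_entropy(nc1, nc2)


def delta_entropy(
    comp1: SampleComposition,
    comp2: SampleComposition,
    norm_total: float = DEFAULT_NORM_TOTAL,
) -> float:
    """delta-S for one locus from the two samples' raw compositions.

    Depends only on the proportion vectors and ``norm_total``, never on raw
    depth.  Nonpositive up to floating-point round-off; zero iff the
    proportions agree.
    """
    if comp1.locus != comp2.locus:
        raise ValueError("compositions must describe the same locus")
    if comp1.raw_count == 0 or comp2.raw_count == 0:
        raise ValueError("both stages must have positive coverage (pre-filter loci)")
    return delta_entropy_from_proportions(comp1.proportions, comp2.proportions, norm_total)


# ---------------------------------------------------------------------------
# per-locus comparison records


@dataclass
class LocusComparison:
    """delta-S, heterogeneity measures and full spectra for one locus."""

    locus: Locus
    s_fore: float
    s_back: float
    delta_s: float
    raw_count1: int
    raw_count2: int
    epipoly: Tuple[float, float]
    delta_epipoly: float
    hamming_presence: int
    hamming_major: int
    spectra: Tuple[np.ndarray, np.ndarray]
    shift_class: str = NONE


def compare_locus(
    comp1: SampleComposition,
    comp2: SampleComposition,
    norm_total: float = DEFAULT_NORM_TOTAL,
    presence_cutoff: float = DEFAULT_PRESENCE_CUTOFF,
) -> LocusComparison:
    """All per-locus statistics for one shared locus (shift class left unset)."""
    p1 = comp1.proportions
    p2 = comp2.proportions
    nc1 = NormalizedComposition.from_proportions(p1, norm_total).norm_counts
    nc2 = NormalizedComposition.from_proportions(p2, norm_total).norm_counts
    s_fore = foreground_entropy(nc1, nc2)
    s_back = background_entropy(nc1, nc2)
    e1 = epipolymorphism(p1)
    e2 = epipolymorphism(p2)
    return LocusComparison(
        locus=comp1.locus,
        s_fore=s_fore,
        s_back=s_back,
        delta_s=s_fore - s_back,
        raw_count1=comp1.raw_count,
        raw_count2=comp2.raw_count,
        epipoly=(e1, e2),
        delta_epipoly=e2 - e1,
        hamming_presence=hamming_presence(p1, p2, presence_cutoff),
        hamming_major=hamming_major(p1, p2),
        spectra=(p1, p2),
    )


def call_eloci(comparisons: Sequence[LocusComparison], alpha: float) -> List[LocusComparison]:
    """Loci whose delta-S falls strictly below the cutoff ``alpha``."""
    if alpha >= 0:
        raise ValueError("alpha must be negative")
    return [comp for comp in comparisons if comp.delta_s < alpha]


def compute_epm(E: int, C: int) -> float:
    """Eloci per million covered loci, ``EPM = 1e6 * E / C``."""
    if C <= 0:
        raise ValueError("EPM is undefined when no loci are covered by both samples")
    return 1e6 * E / C


@dataclass
class ComparisonResult:
    """All compared loci plus elocus/EPM summaries per cutoff."""

    comparisons: List[LocusComparison]
    C: int
    eloci_by_cutoff: Dict[float, List[LocusComparison]]
    epm_by_cutoff: Dict[float, Optional[float]]
    active_cutoff: float
    m: int = 4


def build_comparison_result(
    pairs: Sequence[Tuple[SampleComposition, SampleComposition]],
    norm_total: float = DEFAULT_NORM_TOTAL,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    active_cutoff: float = DEFAULT_ALPHA,
    band: float = DEFAULT_BAND,
    presence_cutoff: float = DEFAULT_PRESENCE_CUTOFF,
) -> ComparisonResult:
    """Score every shared locus and summarize eloci/EPM at each cutoff.

    The drift/selection/stable label is attached only to eloci at the
    active cutoff; all other loci keep the label ``none``.
    """
    cutoffs = sorted(set(list(cutoffs) + [active_cutoff]), reverse=True)
    comparisons = [
        compare_locus(c1, c2, norm_total=norm_total, presence_cutoff=presence_cutoff)
        for c1, c2 in pairs
    ]
    C = len(comparisons)
    eloci_by_cutoff = {cutoff: call_eloci(comparisons, cutoff) for cutoff in cutoffs}
    epm_by_cutoff = {
        cutoff: (compute_epm(len(eloci), C) if C > 0 else None)
        for cutoff, eloci in eloci_by_cutoff.items()
    }
    for comp in eloci_by_cutoff[active_cutoff]:
        comp.shift_class = classify_shift(comp.epipoly[0], comp.epipoly[1], band).label
    m = comparisons[0].locus.m if comparisons else 4
    return ComparisonResult(
        comparisons=comparisons,
        C=C,
        eloci_by_cutoff=eloci_by_cutoff,
        epm_by_cutoff=epm_by_cutoff,
        active_cutoff=active_cutoff,
        m=m,
    )
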