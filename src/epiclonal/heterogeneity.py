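"""Within-sample heterogeneity and between-stage shift measures.

Epipolymorphism (Landan-style ``1 - sum p_i^2``) quantifies epigenetic
heterogeneity inside one sample.  Comparing it across two stages of the same
locus classifies an epiallele shift as *drift* (heterogeneity gain),
*selection* (one epiallele sweeping toward fixation, heterogeneity loss) or
*stable*.  Two Hamming-distance comparators are provided as coarser
alternatives to the combinatorial-entropy statistic: one over pattern
presence indicators, one between the majority pattern words.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DRIFT = "drift"
SELECTION = "selection"
STABLE = "stable"
NONE = "none"

#: Default epipolymorphism stability band: changes within +/- band are "stable".
DEFAULT_BAND = 0.05
#: Default minimum proportion for a pattern to count as "present".
DEFAULT_PRESENCE_CUTOFF = 0.05


@dataclass(frozen=True)
class ShiftClass:
    """Drift/selection/stable call for one locus across two stages."""

    label: str
    delta_epipoly: float
    band: float

    def __post_init__(self) -> None:
        if self.label not in (DRIFT, SELECTION, STABLE):
            raise ValueError(f"unknown shift label {self.label!r}")


def epipolymorphism(proportions) -> float:
    """Epipolymorphism ``e = 1 - sum_i p_i**2`` of a pattern spectrum.

    Zero iff a single pattern carries all mass; maximal (``1 - 2**-m``,
    0.9375 for m=4) iff the spectrum is uniform over the 2**m patterns.
    """
    p = np.asarray(proportions, dtype=float)
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"proportions must sum to 1, got {total}")
    return float(1.0 - np.square(p).sum())


def classify_shift(e1: float, e2: float, band: float = DEFAULT_BAND) -> ShiftClass:
    """Classify an epiallele shift by the direction of the epipolymorphism change.

    ``drift`` if epipolymorphism rose by more than ``band``; ``selection`` if
    it fell by more than ``band``; ``stable`` otherwise.
    """
    delta = e2 - e1
    if delta > band:
        label = DRIFT
    elif delta < -band:
        label = SELECTION
    else:
        label = STABLE
    return ShiftClass(label=label, delta_epipoly=delta, band=band)


def hamming_presence(prop1, prop2, presence_cutoff: float = DEFAULT_PRESENCE_CUTOFF) -> int:
    """Number of patterns whose presence (proportion >= cutoff) differs between stages.

    The per-locus spectra are reduced to binary presence words over the 2**m
    patterns; the Hamming distance between those words is returned.
    """
    if not 0.0 < presence_cutoff < 1.0:
        raise ValueError("presence_cutoff must be in (0, 1)")
    p1 = np.asarray(prop1, dtype=float)
    p2 = np.asarray(prop2, dtype=float)
    return int(np.sum((p1 >= presence_cutoff) != (p2 >= presence_cutoff)))


def _major_index(p: np.ndarray) -> int:
    # np.argmax takes the first maximum, i.e. the lexicographically smallest
    # pattern word, which is the documented tie-break.
    idx = int(np.argmax(p))
    if np.sum(p == p[idx]) > 1:
        logger.warning("majority-pattern tie broken toward pattern index %d", idx)
    return idx


def hamming_major(prop1, prop2) -> int:
    """Bitwise Hamming distance between the two stages' majority pattern words.

    Ties for the majority are broken toward the lexicographically smallest
    word and logged.
    """
    i1 = _major_index(np.asarray(prop1, dtype=float))
    i2 = _major_index(np.asarray(prop2, dtype=float))
    return bin(i1 ^ i2).count("1")
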