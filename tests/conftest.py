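import numpy as np
import pytest

from epiclonal import Locus, MethylationRead, SampleComposition


def spectrum(assignments: dict, m: int = 4) -> np.ndarray:
    """Dense 2**m proportion vector from {word: fraction}."""
    dense = np.zeros(2**m)
    for word, p in assignments.items():
        dense[int(word, 2)] = p
    return dense


def composition(assignments: dict, raw_count: int = 100, m: int = 4,
                chrom: str = "chr1", start: int = 100) -> SampleComposition:
    """SampleComposition with integer pattern counts ~ raw_count * fractions."""
    counts = np.zeros(2**m, dtype=int)
    for word, p in assignments.items():
        counts[int(word, 2)] = round(p * raw_count)
    locus = Locus(chrom=chrom, cpg_positions=tuple(start + 10 * i for i in range(m)))
    return SampleComposition(locus=locus, raw_count=int(counts.sum()),
                             pattern_counts=tuple(int(c) for c in counts))


def make_read(chrom: str, positions, word: str, strand: str = "+") -> MethylationRead:
    return MethylationRead(
        chrom=chrom,
        pos=positions[0],
        strand=strand,
        calls=tuple((p, int(c)) for p, c in zip(positions, word)),
    )


# archetypal relapse-stage spectra of the two shift modes: a drift
# locus (heterogeneity gain) and a selection locus (one epiallele sweeping)
DRIFT_RELAPSE_SPECTRUM = {"1000": 0.53, "0100": 0.29, "0000": 0.11, "0001": 0.07}
SELECTION_DIAGNOSIS_SPECTRUM = {"0000": 0.45, "1100": 0.32, "0001": 0.03, "1000": 0.20}
SELECTION_RELAPSE_SPECTRUM = {"0001": 0.92, "0010": 0.08}


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
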