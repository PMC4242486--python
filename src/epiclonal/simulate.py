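"""Synthetic two-sample read panels with controlled epiallele compositions.

Each simulated locus is a window of ``m`` CpGs with a declared pattern
spectrum per stage; reads are drawn multinomially from the spectrum at the
declared coverage, so empirical proportions converge to the design spectra
at rate ~1/sqrt(coverage).  Panels engineer three kinds of loci: *null*
(same spectrum in both stages), *drift* (stage-2 spectrum spread toward
uniform, raising epipolymorphism) and *selection* (one winner pattern swept
toward fixation, lowering epipolymorphism).  The generator is fully
deterministic: every locus draws from its own RNG substream derived from
the global seed and the locus coordinates, so panels reproduce under
reordering of their loci.

The design (expected, infinite-coverage) delta-S of each locus is available
analytically from its spectra, which gives simulation tests an exact
ground truth to recover.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .entropy import DEFAULT_NORM_TOTAL, delta_entropy_from_proportions
from .extraction import DEFAULT_M, pattern_words, word_to_index
from .heterogeneity import epipolymorphism
from .io_bismark import MethylationRead

#: Per-stage read depth used for simulated loci (typical eRRBS locus depth).
DEFAULT_COVERAGE = 200


def _as_spectrum(spectrum: Union[Sequence[float], Dict[str, float]], m: int) -> np.ndarray:
    """Accept either a dense 2**m vector or a sparse {word: fraction} mapping."""
    n = 2**m
    if isinstance(spectrum, dict):
        dense = np.zeros(n)
        for word, p in spectrum.items():
            dense[word_to_index(str(word))] = float(p)
    else:
        dense = np.asarray(spectrum, dtype=float)
        if dense.shape != (n,):
            raise ValueError(f"spectrum must have {n} entries for m={m}")
    if (dense < 0).any() or abs(dense.sum() - 1.0) > 1e-6:
        raise ValueError("spectrum must be nonnegative and sum to 1 (+/- 1e-6)")
    return dense / dense.sum()


@dataclass
class LocusSpec:
    """Design of one simulated locus: spectra, coverage, and read geometry."""

    chrom: str
    cpg_positions: Tuple[int, ...]
    spectrum_stage1: np.ndarray
    spectrum_stage2: np.ndarray
    coverage_stage1: int = DEFAULT_COVERAGE
    coverage_stage2: int = DEFAULT_COVERAGE
    read_length_cpgs: Optional[int] = None  # defaults to m (one window per read)
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.cpg_positions = tuple(int(p) for p in self.cpg_positions)
        m = len(self.cpg_positions)
        self.spectrum_stage1 = _as_spectrum(self.spectrum_stage1, m)
        self.spectrum_stage2 = _as_spectrum(self.spectrum_stage2, m)
        if self.read_length_cpgs is None:
            self.read_length_cpgs = m
        if self.read_length_cpgs < m:
            raise ValueError("read_length_cpgs must cover the locus (>= m)")
        if min(self.coverage_stage1, self.coverage_stage2) < 0:
            raise ValueError("coverage must be nonnegative")

    @property
    def m(self) -> int:
        return len(self.cpg_positions)

    @property
    def span(self) -> Tuple[int, int]:
        extra = self.read_length_cpgs - self.m
        spacing = self._extra_spacing()
        return self.cpg_positions[0], self.cpg_positions[-1] + extra * spacing

    def _extra_spacing(self) -> int:
        gaps = np.diff(self.cpg_positions)
        return int(gaps.max()) if len(gaps) else 10

    def design_delta_s(self, norm_total: float = DEFAULT_NORM_TOTAL) -> float:
        """Expected delta-S at infinite coverage, from the design spectra."""
        return delta_entropy_from_proportions(
            self.spectrum_stage1, self.spectrum_stage2, norm_total
        )

    def design_epipoly(self) -> Tuple[float, float]:
        return epipolymorphism(self.spectrum_stage1), epipolymorphism(self.spectrum_stage2)


@dataclass
class PanelSpec:
    """A reproducible collection of simulated loci."""

    loci: List[LocusSpec]
    seed: int
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.allow_overlap:
            spans: Dict[str, List[Tuple[int, int]]] = {}
            for spec in self.loci:
                spans.setdefault(spec.chrom, []).append(spec.span)
            for chrom, ivals in spans.items():
                ivals.sort()
                for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                    if s2 <= e1:
                        raise ValueError(f"overlapping simulated loci on {chrom} near {s2}")


def _locus_rng(seed: int, spec: LocusSpec, stage: int) -> np.random.Generator:
    # substream keyed by locus identity so panel order does not matter
    key = f"{spec.chrom}:{','.join(map(str, spec.cpg_positions))}:{stage}".encode()
    return np.random.default_rng(np.random.SeedSequence([seed, stage, zlib.crc32(key)]))


def _stage_reads(spec: LocusSpec, stage: int, seed: int) -> List[MethylationRead]:
    rng = _locus_rng(seed, spec, stage)
    spectrum = spec.spectrum_stage1 if stage == 1 else spec.spectrum_stage2
    coverage = spec.coverage_stage1 if stage == 1 else spec.coverage_stage2
    counts = rng.multinomial(coverage, spectrum)
    m = spec.m
    extra = spec.read_length_cpgs - m
    spacing = spec._extra_spacing()
    extra_positions = [spec.cpg_positions[-1] + spacing * (i + 1) for i in range(extra)]
    reads: List[MethylationRead] = []
    for index, count in enumerate(counts):
        if count == 0:
            continue
        bits = [int(b) for b in format(index, f"0{m}b")]
        for _ in range(count):
            states = list(bits)
            positions = list(spec.cpg_positions)
            if extra:
                positions += extra_positions
                states += list(rng.integers(0, 2, size=extra))
            reads.append(
                MethylationRead(
                    chrom=spec.chrom,
                    pos=positions[0],
                    strand="+",
                    calls=tuple(zip(positions, states)),
                )
            )
    return reads


def simulate_panel(panel: PanelSpec) -> Tuple[List[MethylationRead], List[MethylationRead]]:
    """Draw both stages' read sets for a panel; deterministic given the seed."""
    reads1: List[MethylationRead] = []
    reads2: List[MethylationRead] = []
    for spec in panel.loci:
        reads1.extend(_stage_reads(spec, 1, panel.seed))
        reads2.extend(_stage_reads(spec, 2, panel.seed))
    key = lambda r: (r.chrom, r.pos, r.calls)
    return sorted(reads1, key=key), sorted(reads2, key=key)


# ---------------------------------------------------------------------------
# engineered shift designs


def make_drift_spec(
    chrom: str,
    cpg_positions: Sequence[int],
    base_spectrum,
    noise: float,
    coverage: int = DEFAULT_COVERAGE,
) -> LocusSpec:
    """Drift design: stage 2 mixes the base spectrum toward uniform.

    ``noise`` in [0, 1] is the uniform mixing weight; any positive noise on
    a non-uniform base strictly raises stage-2 epipolymorphism.  noise=0
    reproduces the base spectrum exactly (a null locus).
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")
    m = len(cpg_positions)
    base = _as_spectrum(base_spectrum, m)
    uniform = np.full(2**m, 1.0 / 2**m)
    stage2 = (1.0 - noise) * base + noise * uniform
    return LocusSpec(
        chrom=chrom,
        cpg_positions=tuple(cpg_positions),
        spectrum_stage1=base,
        spectrum_stage2=stage2,
        coverage_stage1=coverage,
        coverage_stage2=coverage,
        kind="drift" if noise > 0 else "null",
    )


def make_selection_spec(
    chrom: str,
    cpg_positions: Sequence[int],
    base_spectrum,
    winner_pattern: Union[str, int],
    final_fraction: float,
    coverage: int = DEFAULT_COVERAGE,
) -> LocusSpec:
    """Selection design: one winner pattern swept to ``final_fraction`` at stage 2.

    The remaining mass is distributed over the other patterns proportionally
    to the base spectrum, emulating a clone expanding through the bulk.
    """
    if not 0.0 < final_fraction <= 1.0:
        raise ValueError("final_fraction must be in (0, 1]")
    m = len(cpg_positions)
    base = _as_spectrum(base_spectrum, m)
    winner = word_to_index(winner_pattern) if isinstance(winner_pattern, str) else int(winner_pattern)
    stage2 = np.zeros_like(base)
    others = base.copy()
    others[winner] = 0.0
    rest = others.sum()
    if rest > 0:
        stage2 = (1.0 - final_fraction) * others / rest
    stage2[winner] = final_fraction
    return LocusSpec(
        chrom=chrom,
        cpg_positions=tuple(cpg_positions),
        spectrum_stage1=base,
        spectrum_stage2=stage2,
        coverage_stage1=coverage,
        coverage_stage2=coverage,
        kind="selection",
    )


def make_benchmark_panel(
    n_null: int = 950,
    n_drift: int = 25,
    n_selection: int = 25,
    coverage: int = DEFAULT_COVERAGE,
    seed: int = 0,
    m: int = DEFAULT_M,
    chrom: str = "chrSim",
    cpg_spacing: int = 8,
    locus_gap: int = 500,
) -> PanelSpec:
    """Benchmark panel: mostly null loci plus engineered drift and selection loci.

    Null loci draw a sparse Dirichlet spectrum (a handful of co-existing
    epialleles, as seen at typical eRRBS loci) and reuse it in both stages.
    Drift loci start from a concentrated two-epiallele spectrum and spread;
    selection loci sweep a minor pattern to 92% of the bulk, mirroring the
    archetypal relapse-stage sweeps.  Spectra are drawn from an RNG derived
    from ``seed``; read sampling later uses per-locus substreams of the
    same seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBE9C]))
    n_patterns = 2**m
    loci: List[LocusSpec] = []
    start = 1000
    total = n_null + n_drift + n_selection
    kinds = ["null"] * n_null + ["drift"] * n_drift + ["selection"] * n_selection
    rng.shuffle(kinds)
    for kind in kinds:
        positions = tuple(start + i * cpg_spacing for i in range(m))
        start = positions[-1] + locus_gap
        if kind == "null":
            support = rng.choice(n_patterns, size=rng.integers(2, 5), replace=False)
            weights = rng.dirichlet(np.full(len(support), 1.0))
            spectrum = np.zeros(n_patterns)
            spectrum[support] = weights
            spec = LocusSpec(
                chrom=chrom,
                cpg_positions=positions,
                spectrum_stage1=spectrum,
                spectrum_stage2=spectrum.copy(),
                coverage_stage1=coverage,
                coverage_stage2=coverage,
                kind="null",
            )
        elif kind == "drift":
            # concentrated ancestral spectrum scattering into new epialleles
            base = np.zeros(n_patterns)
            base[0] = 0.85
            base[1] = 0.11
            base[2] = 0.04
            stage2 = np.zeros(n_patterns)
            stage2[word_to_index("1" + "0" * (m - 1))] = 0.53
            stage2[word_to_index("01" + "0" * (m - 2))] = 0.29
            stage2[0] = 0.11
            stage2[1] = 0.07
            spec = LocusSpec(
                chrom=chrom,
                cpg_positions=positions,
                spectrum_stage1=base,
                spectrum_stage2=stage2,
                coverage_stage1=coverage,
                coverage_stage2=coverage,
                kind="drift",
            )
        else:
            # heterogeneous diagnosis-like spectrum; pattern '0..01' later sweeps
            base = np.zeros(n_patterns)
            base[0] = 0.45
            base[word_to_index("11" + "0" * (m - 2))] = 0.32
            base[1] = 0.03
            base[word_to_index("1" + "0" * (m - 1))] = 0.10
            base[2] = 0.10
            spec = make_selection_spec(
                chrom, positions, base, winner_pattern=1, final_fraction=0.92, coverage=coverage
            )
        loci.append(spec)
    return PanelSpec(loci=loci, seed=seed)


# ---------------------------------------------------------------------------
# declarative panel configs


def load_panel_config(path) -> PanelSpec:
    """Load a panel from a YAML config.

    Schema::

        seed: 7
        loci:
          - chrom: chr1
            cpg_positions: [100, 110, 125, 140]
            spectrum_stage1: {"0000": 0.9, "0001": 0.1}
            spectrum_stage2: {"1111": 1.0}
            coverage_stage1: 200
            coverage_stage2: 200

    Spectra may be sparse word->fraction mappings or dense 2**m lists.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "loci" not in raw or "seed" not in raw:
        raise ValueError(f"{path}: panel config must define 'seed' and 'loci'")
    loci = []
    for entry in raw["loci"]:
        loci.append(
            LocusSpec(
                chrom=str(entry["chrom"]),
                cpg_positions=tuple(entry["cpg_positions"]),
                spectrum_stage1=entry["spectrum_stage1"],
                spectrum_stage2=entry["spectrum_stage2"],
                coverage_stage1=int(entry.get("coverage_stage1", DEFAULT_COVERAGE)),
                coverage_stage2=int(entry.get("coverage_stage2", DEFAULT_COVERAGE)),
                read_length_cpgs=entry.get("read_length_cpgs"),
            )
        )
    return PanelSpec(loci=loci, seed=int(raw["seed"]), allow_overlap=bool(raw.get("allow_overlap", False)))
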