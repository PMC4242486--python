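# Methods

## Model

A read covering `m` adjacent CpGs phases them into one epiallele word over
{0,1}; a locus is a window of `m` consecutive CpG positions and a sample's
state at that locus is its multinomial spectrum over the 2^m words. The
shift statistic treats each stage's reads as a sequence of exchangeable
epiallele draws: the foreground entropy is the log number of distinct
orderings of the observed per-stage counts, `ln(N_k!/Π_i N_{i,k}!)` summed
over the two stages; the background entropy evaluates the same quantity at
the pooled-expectation counts `Ñ_{i,k} = N_k·N_i/N`, which is the maximal
stage-entropy configuration consistent with the pooled spectrum. Their
difference ΔS = S − S̃ is ≤ 0, equals 0 iff the two proportion vectors are
identical (then Ñ = N algebraically), is symmetric in stage order, and
depends only on proportions, never raw depth. For large normalization
totals ΔS/(2N) converges to minus the equal-weight Jensen–Shannon
divergence of the two spectra (nats); the statistic is thus a
finite-sample, permutation-counting form of a symmetric distributional
divergence. All factorials are evaluated as `ln Γ(x+1)` (scipy `gammaln`)
so the normalized, generally fractional counts need no rounding.

Assumptions worth keeping in mind: reads within a stage are treated as
independent draws from one bulk spectrum (no overlapping-mate
deduplication; each alignment counts once), and both strands of a CpG dyad
report the same underlying cytosine state (reverse-strand calls are
collapsed onto the + strand C by default; `--stranded` disables this).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `m` (`--cpgs`) | 4 | CpGs per epiallele window; 2^m patterns. 4 balances pattern resolution against the read count needed to sample the spectrum; larger m needs proportionally longer reads and deeper coverage. |
| `min_reads` | 60 | minimum raw reads per locus **per sample**; a locus must pass in both samples to be compared. |
| `norm_total` | 100 per stage | per-stage normalized read total, i.e. 200 per locus across both stages. Sets the dynamic range: the extreme two-clone swap scores −2·ln C(100,50) ≈ −133.6. |
| `alpha` (`--cutoff`) | −60 | elocus cutoff, strict `ΔS < α`; −70 and −80 are always reported alongside in the summary. |
| `band` | 0.05 | epipolymorphism stability band: eloci whose epipolymorphism changes by at most ±0.05 are called `stable` rather than drift/selection, since shifts of that size can occur without a real heterogeneity change. |
| `presence_cutoff` | 0.05 | minimum proportion for a pattern to count as "present" in the presence-Hamming comparator. |
| promoter window | −1000..+1000 bp of TSS | promoter definition for gene-context annotation; configurable because no single convention exists. |
| shore/shelf width | 2000 bp each | CpG-island flank geometry (island > shore > shelf > open sea precedence; islands merged before flanking so shores never double-count). |

Normalization note: the per-locus total of 200 is split equally, 100 per
stage. Proportions are depth-free, so the equal split is the neutral
reading of a constant-total normalization, and it is corroborated by two
checks the tests perform: the extreme swap bound (≈133.6, consistent with a
0-to-about-140 dynamic range; 200 per stage would allow ≈271) and the
magnitude of the printed selection-locus example (≈114 nats), which the
printed proportions reproduce at 100/stage but not at 200/stage. A
documented upper bound of 144 for the magnitude is not derivable from the
formulas under any per-stage split we tested; the package documents its
exact bound instead and enforces nothing at 144.

## Locus enumeration

The CpG universe per chromosome is the union of CpG positions observed in
either sample's reads (no reference FASTA needed); windows are m
*consecutive* positions of that universe. A read contributes one pattern to
every window it covers completely with unambiguous calls (sliding
windows); `--first-window-only` restricts each read to its leftmost
covered window for users who prefer disjoint read-to-window assignment.
Ambiguous call symbols never enter patterns: a read missing a call inside
a window is excluded from that window only. Because the universe is shared
across samples, a CpG observed only in sample B can split an otherwise
consecutive window in sample A — both samples always see the same window
coordinates.

Loci overlapping C>T SNPs at a window C, or G>A SNPs at the paired G, are
removed when a variant list is supplied (such variants are
indistinguishable from methylation calls in bisulfite data). Variant
calling itself is out of scope; the filter accepts a precomputed VCF site
list or a BED of exclusion intervals.

## Simulator

The generator draws, per locus and stage, `coverage` pattern words from a
declared multinomial spectrum (default 200 reads per stage, a typical
deeply covered eRRBS locus). Engineered designs: *null* (same spectrum both
stages), *drift* (stage-2 spectrum mixed toward uniform, strictly raising
epipolymorphism for any non-uniform base), *selection* (a winner pattern
swept to a declared final fraction, remaining mass redistributed
proportionally). The benchmark panel defaults to 950 null / 25 drift / 25
selection loci; the drift and selection archetypes mirror the two printed
worked examples (85/11/4 spreading to 53/29/11/7, and a 3% pattern
sweeping to 92%) and both have design |ΔS| > 80, comfortably past the −60
cutoff relative to the sampling noise at 200 reads (null loci score within
about −3 to 0).

Every locus draws from an RNG substream keyed by the global seed and the
locus coordinates, so panels are bit-reproducible and invariant under
locus reordering. Reads cover exactly one window by default
(`read_length_cpgs = m`) so tallies are analytically predictable; longer
reads exercise the sliding-window path, with the extra CpG states drawn
Bernoulli(1/2).

What the simulator does *not* emulate: bisulfite conversion failure,
sequencing error, fragment-length and coverage variation, PCR duplicates,
or linkage between neighboring windows. Passing the benchmark therefore
demonstrates correct recovery of engineered compositional shifts under
clean multinomial sampling, not robustness to real-data artifacts.

## Numerical and edge-case choices

- Strict inequality for the elocus call (`ΔS < α`); ΔS exactly at the
  cutoff is not an elocus.
- ΔS may land at ~1e-13 above zero from floating round-off; it is reported
  as computed, and invariants are asserted at 1e-6/1e-9 tolerances.
- Majority-pattern ties in the Hamming comparator break toward the
  lexicographically smallest word and are logged.
- EPM is undefined (reported as `null`) when no locus is covered by both
  samples.
- Empty inputs yield header-only tables, empty BED tracks and C = 0
  summaries rather than errors; zero-coverage compositions reaching the
  entropy layer are a programming error and raise.
- drift/selection labels are attached only to eloci at the active cutoff;
  all other loci carry `none`.
- Written tables use 1-based inclusive locus coordinates; BED output keeps
  its native 0-based half-open convention; everything internal is 0-based
  half-open.

## Test problem sizes

The default suite simulates panels of up to 1,000 loci at 200 reads per
stage (400k reads end to end) and samples 10,000 random spectrum pairs for
the nonpositivity sweep — sizes chosen so the full spectrum of engineered
effects (null, borderline, extreme) is represented while the whole suite
runs in well under a minute of compute for the property layers and a few
seconds for the end-to-end benchmark.

## Known limitations

- No statistical significance or FDR is attached to ΔS; elocus calling is
  by fixed entropy cutoff, as designed.
- The drift/selection dichotomy is a heuristic on the *direction* of the
  epipolymorphism change; mixed or compensating clonal dynamics land in
  `stable`.
- TSS distances are emitted as raw signed base pairs; any log-scale
  transform for plotting (problematic for negative distances) is left to
  the user.
- Only two-sample comparisons are supported; multi-sample designs are left
  to user scripting over pairwise runs.
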