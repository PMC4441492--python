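# Methods

## Junction model

A switch-junction amplicon is modelled as an ordered tiling of gap-free
fragments of two germline references (donor Sμ, acceptor Sγx), on either
strand, joined by seams that are blunt, microhomologous, or carry inserted
novel bases. Alignment is deliberately **gap-free**: Sanger-scale switch
junction reads are substitution-dominated, and gap-free segments keep every
decision auditable against brute-force enumeration. A read fragment
containing a true indel simply splits into two collinear segments at the
indel.

### Segmentation (seed-and-extend)

Exact k-mer seeds (k = 12 by default) against each reference and strand are
extended along their diagonal with match +1 / mismatch −3 scoring and an
X-drop of 12, trimmed to maximal-score endpoints. Segments shorter than
`min_seg_len` (20 nt, roughly four switch-repeat units) or with mismatch
fraction above `max_mismatch_rate` (0.1) are discarded. Candidate segments
from both references and strands are chained by dynamic programming:
chain score = Σ segment scores − query-overlap double counting − a
per-boundary junction penalty (12). The penalty means an extra fragment
(an extra recombination event) must improve the explanation of the read by
more than ~12 matched bases — without it, accidental ≥ 20 nt matches (e.g.
via repeat arrays) fragment clean reads. Adjacent fragments may overlap on
the read by up to 60 nt, which is how a microhomology window is covered by
both of its fragments. A valid call needs ≥ 1 donor and ≥ 1 acceptor
fragment; otherwise the read is reported *uncallable* with its partial
matches, not an exception. Reads are tried in both orientations; the
orientation whose best chain starts with a forward-strand donor fragment
wins (score, then fewer fragments, fewer mismatches, leftmost donor
breakpoint, given orientation, as deterministic tie-breaks).

### Boundary resolution

The overlap OL of a seam is defined as the length of the longest read
window spanning the breakpoint that matches **both** reference
continuations perfectly (N never matches; comparison is case-insensitive).
Operationally the two frontiers are located independently:

* donor frontier `eL` = the position maximising the cumulative gap-free
  score (+1/−3) of the read prefix along the left fragment's diagonal
  (smallest position on ties);
* acceptor frontier `sR` = the position maximising the cumulative score of
  the read suffix along the right fragment's diagonal (largest on ties).

With this scoring the frontier is exactly the end of the maximal perfect
extension whenever the seam is unambiguous, while still crossing isolated
point mutations that sit ≥ ~2 matched bases away from their neighbours.
`eL > sR` ⇒ microhomology window `[sR, eL)` with OL = `eL − sR`;
`eL == sR` ⇒ blunt; `eL < sR` ⇒ the bases between match neither reference
and are an insertion (OL is forced to 0 — a seam is insertion **xor**
microhomology, and insertion-bearing junctions are excluded from overlap
means). No single breakpoint is assigned inside a microhomology window:
the reported coordinates are the last donor-side base of the maximal donor
extension and the first acceptor-side base of the acceptor extension, i.e.
OL itself encodes the placement ambiguity. Reported coordinates are
1-based inclusive in the accession frame (`genomic_offset` + local
position); all internal arithmetic is 0-based half-open.

### Classification

*Simple* = exactly two fragments, donor then acceptor, both forward;
everything else callable is *compound*. Flags: *inversion* iff any
fragment maps to the reverse strand; *microdeletion* iff two adjacent
fragments map to the same region and strand with a reference gap in
[1, 50] nt (larger same-region gaps are intra-switch recombination events
of recombination scale; overlapping same-region intervals — duplications —
count as intra events, with no separate flag); *long microhomology* iff any
boundary OL ≥ 15 (the threshold follows the ≥ 15 bp convention for
alt-EJ-scale overlaps; configurable). Complexity = intra events +
insertions + inversions + microdeletions. A seam insertion on an otherwise
simple junction therefore scores complexity 1 while the category stays
simple; cohort summaries average complexity over compound junctions only,
so this choice does not leak into compound-junction statistics. For
compound junctions the overlap statistics score the single donor→acceptor
transition boundary (one OL per junction); intra-switch seams are reported
per boundary but not pooled into OL histograms.

## Statistics

* **Fisher exact (2×2, two-tailed)**: point-probability tail — the p-value
  sums hypergeometric probabilities of all tables with the observed margins
  whose probability does not exceed the observed table's. Implemented with
  exact integer/rational arithmetic (the emitted float is the rounding of
  an exact fraction). This is the convention of mainstream statistical
  software; tail definitions differ between packages, so small
  discrepancies against p-values computed elsewhere are possible and are a
  property of the convention, not the arithmetic.
* **Pearson χ²**: no continuity correction. Columns whose expected counts
  fall below 1 are pooled — into the adjacent higher bin for ordered OL
  histograms (the top ≥ 15 bin pools downward), or into a rest category for
  substitution spectra; df = (r−1)(c−1) after pooling. Zero-margin
  rows/columns are dropped with a warning.
* **OL histograms**: bins 0, 1, …, 14, ≥ 15 by default, aligning the top
  bin with the long-microhomology threshold.
* **Ratio normalization**: value = a/b, sd = |a/b|·√((sa/a)² + (sb/b)²)
  (relative errors in quadrature), with the zero-numerator case handled as
  sd = sa/|b|. This is the standard error-propagation contract for
  qPCR/ChIP fold-changes normalized to a control.

## SHM profiling

Clones are aligned globally to the germline reference with Biopython's
`PairwiseAligner` (match +1, mismatch −2, gap open −6, extend −1, free end
gaps, so trimmed amplicons align cleanly). Substitutions become mutation
calls; gap runs become indel records excluded from the substitution
spectrum; calls within 1 nt of an indel column are kept but flagged.
A clone under 90% identity over aligned columns is flagged unalignable and
excluded (not fatal). Frequency F = calls / (sequences × analyzed length),
i.e. per total analyzed bases (not per mutated-sequence bases).
Motif classes on the germline strand, hotspots before the coldspot:
RGYW (focal G), WRCY (focal C), WA (focal A), TW (focal T), coldspot
SYC (focal C) / GRS (focal G), with W = A/T, R = A/G, Y = C/T, S = G/C.
The complementary pattern pairs make calling strand-symmetric: a WRCY C on
one strand is an RGYW G on the other. Clonally related sequences (identical
mutation sets) can optionally be collapsed (off by default, since clonal
correction is a per-study choice).

## Synthetic data generator

The generator is the stand-in for raw junction/clone sequencing data and
defines the conditions under which the pipeline is validated.

**References**: random background (1600 nt per region by default)
interleaved with tandem arrays of switch-like repeat pentamers (GAGCT,
GGGGT; 2–6 copies per array, ~20% coverage) — repetitiveness is what makes
OL calling hard, so it is on by default. On top, one *controlled
shared-homology tract* per length 1..30 is planted in both regions with
mismatch-forced flanks, and cross-region maximal exact matches longer than
30 are broken (mutating only non-tract positions), iterating until every
tract length is present and the bound holds. These tracts are what makes
every requested overlap length realizable by construction; 30 matches the
longest overlap the analyses bin (≥ 15 is already "long").

**Junction reads** are assembled from reference pieces (~90–300 nt each,
total 300–700 nt, Sanger-amplicon scale). Boundary kinds are drawn from a
configurable mix (defaults 0.40 blunt / 0.45 microhomology / 0.15
insertion, a wild-type-like, c-NHEJ-dominated mixture; overlap lengths
geometric with p = 0.45 truncated at 30; insertion lengths geometric,
≤ 20 nt). A fraction of reads (0.15 by default) is compound, with events
drawn from intra-donor / intra-acceptor duplicating-type gaps (100–400 nt),
inversions (reverse-strand middle fragment) and microdeletions (1–50 nt
same-diagonal gaps); internal event seams are blunt, and the inter-switch
seam after an inverted fragment is blunt (shared tracts are planted
forward/forward). Two safeguards make the planted structure the *true*
structure: (1) a seam scanner verifies that the realized maximal perfect
homology at every seam equals the planted value; (2) an ambiguity check
rejects reads where the cumulative ±(1/−3) score beyond either frontier
ever returns to ≥ 0 — i.e. seams where mismatch-tolerant extension could
plausibly cross the junction. Both run under rejection sampling with a
1000-attempt cap per read (a cap hit is a configuration error, e.g. a
requested overlap longer than any shared tract). Point mutations are then
planted outside a protected window of max(5, OL + 2) nt around each seam
(so the planted boundary remains the ground truth), at a configurable rate
(0 by default; 0.02 in the robustness studies).

**SHM clone sets**: per-position substitution rates equal the target
frequency F₀ (5×10⁻³/bp by default, a germinal-center-scale load) times a
hotspot multiplier (6 at RGYW/WRCY focal positions) normalized so the mean
rate equals F₀ exactly; substitution identity follows transition:transversion
odds 2:1; optional indels (off by default, 1–3 nt when enabled).

**What the generator does not emulate**: chromatogram/basecalling noise,
PCR chimeras, clonal phylogenies, selection during affinity maturation, and
biological positional biases of breaks within switch regions (breakpoints
are uniform over the usable reference). Passing round-trip tests therefore
demonstrates correctness of the *computation* under realistic sequence
composition, not performance on real traces.

## Validation sizes and determinism

The test suite validates: boundary resolution against brute-force
perfect-extension enumeration (500 clean junctions, exact agreement);
round-trip recovery on 1000 reads per scenario (blunt-only, overlap 1–30,
insertion-only, compound; ≥ 99% clean, ≥ 95% with 2% off-seam mutations);
the Fisher test against vectorised hypergeometric enumeration over **all**
2×2 margins ≤ 30 (>10⁵ tables); χ² against the 2×2 closed form; ratio SD
against 10⁶-draw Monte Carlo; and SHM frequency recovery over 200
replicate clone sets (profiled F within 3 binomial SE of F₀ in ≥ 95% of
sets, every planted mutation recovered in indel-free sets). The
acceptance script re-runs the same measurements at moderately smaller
simulation sizes (500 reads/scenario, 100 SHM sets, Fisher margins ≤ 20),
chosen to keep a full from-scratch reproduction fast while leaving the
measured rates statistically indistinguishable from the full-size runs.
All generators are integer-RNG-seeded (`numpy` PCG64) with no float-order
dependence in sequence construction, so outputs are byte-identical across
runs and platforms; the pipeline itself is deterministic given inputs and
configuration.

## Known limitations

* Gap-free segmentation cannot represent a single fragment containing a
  true indel; it appears as two collinear fragments (counted as an intra
  event if the gap is on the reference side). Real Sanger data with
  homopolymer miscalls near a seam can therefore inflate complexity.
* Frontier search crosses point mutations by score recovery; two
  substitutions within ~3 nt of each other just outside the protected
  window can still shift a frontier. This is the dominant (<1–2%) failure
  mode in the 2%-mutation robustness study.
* The two-tailed Fisher tail convention and the χ² pooling policy are
  explicit choices; studies using different software conventions may print
  slightly different p-values for borderline tables.
* Breakpoint coordinates inside a microhomology window are intrinsically
  ambiguous; consumers must treat `left_break`/`right_break` as window
  delimiters, not as a point estimate.
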