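# Methods

## The screening procedure

The unit of evidence is one PAF record: a contiguous aligned segment
between a query assembly and a reference assembly, with query/target
coordinates (0-based half-open throughout; 1-based only in exported link
tables), strand, residue matches, block length and mapping quality.
Alignment generation itself is out of scope — any whole-genome aligner
emitting PAF works; `asm5`-style presets are the intended regime.

### Filters

A block is set aside (category *unassessed*, reason recorded) when any
of four predicates fires, checked in order:

| predicate | default | meaning |
|---|---|---|
| `query_seq_len < 3000` | 3 kbp | whole query *sequence* too short (PAF col 2, not the aligned span) |
| `block_len < 500` | 500 bp | alignment block too short |
| `mapq < 30` | 30 | ≥ 1/1000 chance of mapping error |
| `matches / block_len < 0.8` | 0.8 | identity too low |

Comparisons are strict, so a value exactly at a threshold is retained.
An optional fragmented-genome mode raises the query-sequence threshold
to 1 Mbp, the special-casing appropriate when one side of the comparison
is a highly fragmented short-read assembly.

Stacked blocks — two query blocks overlapping by more than half the
shorter one's span — would double-count query sequence, so the shorter
is set aside. The rule is applied iteratively until no offending pair
remains among survivors; each round removes the single shortest losing
block (ties: fewer matches, then a fixed lexicographic key), which makes
the outcome independent of input order. Whether transitive pile-ups
should be resolved pairwise-once or iteratively is genuinely open; the
iterative reading is implemented because it leaves a survivor set with
no residual violations.

### Classification

Labels are assigned in precedence order — debris, translocation,
inversion, relocation, congruent — and each later criterion sees only
blocks not yet labeled, so nested discrepancies are never stacked (an
inversion inside a translocated segment counts once, as translocation).

* *Dominant target* of a query chromosome: the reference sequence
  receiving the maximum summed aligned bp from it, over blocks surviving
  the debris step; ties break to the lexicographically smaller name.
* *Dominant strand* of a reference sequence: the strand with maximum
  summed bp over blocks surviving earlier steps; an exact tie is called
  forward.
* *Backbone* of a reference sequence: blocks are ordered along the query
  (order reversed within a query when the dominant strand is reverse) and
  the bp-weight-maximal subset with strictly increasing target starts is
  found by O(n²) weighted-LIS dynamic programming. Non-members are
  relocations. LIS is the standard formalization of "out of order"
  synteny; the weighting by aligned bp means a small stray block never
  displaces a heavy collinear run.

Debris is recognized from the query side by default (unplaced query
scraps aligning into reference chromosomes); a `debris_side` switch
(`query`/`reference`/`both`) covers comparisons where one assembly was
never chromosome-scaffolded. Blocks whose sequences are unplaced on both
sides can still be congruent if collinear — debris semantics require one
side to be chromosome-assigned.

### Tally and denominators

Category bp are summed query-block spans. Unassessed bp = discarded +
stacked bp. With the default `evaluated` denominator the total is the
sum of all category bp, so the table partitions exactly and percentages
sum to 100; with `assembly` the reference assembly length is the
denominator and its unaligned remainder is folded into unassessed. Full
precision is kept in JSON; the TSV prints half-up at two decimals below
10% and one above. The headline total discrepancy is the sum of the four
discrepancy-category percentages rounded to one decimal.

### Contiguity statistics

Scaffold metrics use full sequence lengths; contig metrics split
scaffolds at runs of N of length ≥ `min_gap_run` (default 10 — scaffold
gaps are typically 10–100 N; shorter runs are treated as ambiguous base
calls and neither split contigs nor count as gap bp). N50/L50 use the
inclusive crossing rule: a cumulative sum exactly equal to half the
total counts. Tools differ on both conventions, hence both are
configurable/documented.

### Regression

Per reference chromosome: discrepancy % = summed bp of
discrepancy-labeled blocks aligning to it over chromosome length;
repeat % from the merged repeat-annotation track (soft-masking in FASTA
is deliberately ignored — repeat status comes only from the track, which
decouples masking dialects from classification). Ordinary least squares
of discrepancy % on repeat % (`scipy.stats.linregress`); two-sided slope
p-value compared against Bonferroni-corrected α = 0.05 / number of
pairwise comparisons in the study; a refit without the X chromosome
probes how much the association leans on the most repeat-rich point.

## The synthetic generator

Defaults describe the study conditions used throughout the tests: a
10 Mbp truth genome of five 2 Mbp chromosomes (four autosome-like at
22–30% repeat density, one X-like at 55%), with 10 inversions, 5
translocations, 5 relocations and 5 debris fragments.

* Nucleotide composition is uniform; repeats are realized as tandem
  duplications of short random motifs (genuinely repetitive sequence,
  not just annotated intervals), placed without overlap until each
  chromosome hits its target density (realized density lands within one
  element, ≲ 0.2 points).
* Inversion sizes are log-normal with σ = 0.885 and
  μ = ln(20 000) + σ², putting the mode at exactly 20 kbp with ≈ 17.5%
  of draws above 100 kbp — the size spectrum reported for chromosome-
  scale assembly comparisons. Sizes are clamped to [5 kbp, 400 kbp].
* Debris fragments are ≥ 15 kbp (the usual Hi-C scaffolding inclusion
  threshold), keeping them distinguishable from filter-discarded noise;
  translocated/relocated segments are 20–80 kbp.
* Events are placed without overlap (1 kbp margins); overlapping
  requests are rejected rather than layered, matching the no-stacking
  accounting of the classifier.
* A relocation is only implanted where the in-place material it jumps
  over outweighs it (> 2× its length). Without this constraint the
  collinear backbone legitimately keeps the moved segment and calls the
  lighter displaced piece relocated instead — an intrinsic ambiguity of
  "out of order", not a classifier defect.
* 100 bp runs of N are inserted at every junction that is not
  truth-contiguous, exercising gap detection and gap statistics.
* The derived assembly is represented as a list of truth-genome
  segments, so idealized PAF (matches = block length, mapQ 60) is
  emitted exactly from the edit history. Fragmentation noise (default
  2 × 10⁻⁵ breakpoints/bp, i.e. ~50 kbp mean piece length) splits blocks
  at Poisson-placed breakpoints without changing covered bp; pieces that
  fall under the 500 bp block filter are the only recovery loss.

What the generator does **not** emulate: alignment errors and spurious
mappings (matches always equal block length), segmental duplication and
true biological variation between individuals, repeat-driven event
placement (events are uniform, so the generator's own comparisons show
no discrepancy-vs-repeat association — the planted-profile generators
exist for that), and realistic chromosome counts or lengths. Passing
tests therefore demonstrate the bookkeeping and the classification
semantics, not robustness to aligner artifacts on real genomes.

The chromosome-level regression behaviour is tested on separate planted
profiles: 22 chromosomes (one repeat-enriched X at 60% repeats, the rest
uniform in 25–45%) with discrepancy % = 1.0 + 0.15 × repeat % + N(0,
0.5); standard OLS theory predicts the fitted slope lies within two
standard errors of truth in ~95% of replicates, and the suite requires
≥ 90/100. A second generator confines elevated discrepancy to the X
point to verify that excluding X collapses r².

## Problem sizes and determinism

Every simulation is a pure function of its configuration (seed
included). The test suite and the acceptance script run the 10 Mbp
default conditions, 100-replicate regressions, and brute-force oracles
(exhaustive backbone enumeration at n ≤ 12, all-pairs stacking at
n ≤ 300) in well under a minute each.

## Known limitations

* Dominant targets/strands are argmaxes; a genuinely 50/50 split query
  chromosome is resolved by a deterministic tie-break rather than
  flagged.
* Debris bp are counted from query-side block spans, so an unplaced
  scrap aligning twice counts twice unless caught by stacking.
* Published comparison tables print percentages at inconsistent
  precision and a few cells are not reproducible from their own bp
  counts; re-derived values keep full precision and the printing
  convention is configurable at the report boundary.
* No attempt is made to distinguish assembly error from true structural
  variation — with two assemblies of different individuals the
  categories quantify *discrepancy*, not error.
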