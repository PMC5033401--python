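# Methods notes

## Model

A plastome single-copy region is modelled as a *linear* sequence of n
uniquely labelled, signed blocks — a signed permutation once the source
arrangement is relabelled to the identity. Linearity reflects how these
regions are analysed in practice: the LSC and SSC each sit between fixed
inverted-repeat boundaries, so rearrangements are compared per region and
whole-plastome circular arrangements are not modelled. The only event
type is the inversion of a contiguous run of whole blocks (reverse the
interval, negate every sign). Translocations, transpositions, duplications
and events that split a block are out of scope; block boundaries come from
the block-extraction step, which places them on gene boundaries.

Distances and scenarios are invariant under relabelling: d(σ, τ) equals
d(identity, σ⁻¹τ). All search code exploits this by encoding the target
in the source's identity frame (`relabel_against_reference`).

### Flip equivalence

The absolute orientation of a single-copy region between its flanking IRs
is biologically indeterminate — plastid populations carry both
orientations at equimolar frequency. With `flip_equivalence` enabled, an
arrangement and its whole-segment reverse complement F(π) (reverse the
block order, negate all signs) are treated as the same state; endpoint
checks accept either π_target or F(π_target). Since F commutes with the
reversal operation up to index reflection, the quotient distance is
min(d(σ, τ), d(σ, F(τ))), which is how both the oracle and the stochastic
search implement it. The mode defaults to off: the oriented two-event SSC
reading is primary, the one-event reading is the explicit alternative.

## Stochastic search (DIMSUM)

Each replicate is an independent random walk: events are drawn uniformly
from all n(n+1)/2 contiguous intervals (single-block flips and the full
segment included — nothing in the method's definition weights or excludes
them), applied sequentially, with the endpoint checked before the first
event and after every event. A replicate stops at its first hit or after
`max_steps` events (default 100, read as a per-walk cap); the event prefix
up to the hit is the recorded solution. Solutions are deduplicated by
exact event sequence; `hits_by_length` counts replicate hits before
deduplication, preserving both views of "all solutions reached".
`record_all_solutions=False` keeps only minimal-length solutions.

Determinism: replicate r's stream is seeded from the pair (seed, r)
(NumPy `default_rng((seed, r))`), so results are independent of execution
order and identical configurations give bit-identical results.

Implementation: walks are advanced in a vectorised engine (one int8 state
matrix over all replicates; per step, one fancy-indexing pass per interval
type). Because the draw streams do not depend on the state or the target,
one set of walks simultaneously yields, for *every* possible target, the
minimum hit length a single-target run would report (the first step at
which any replicate visits that state). `first_hit_lengths` exposes this
all-targets view; it is what makes exhaustive stochastic-vs-exact
validation over the whole n ≤ 3 space feasible, and it is the same engine
`dimsum()` itself runs on.

Default replicates: 10,000 — ample for the n ≤ 3 instances the tool
targets at the desk (the probability that no replicate finds a specific
two-event scenario is below 10⁻¹⁰⁰); published analyses with this method
used 1,000,000, and the flag accepts any count.

## Exact oracle

Breadth-first search over the full signed-permutation space (2ⁿ·n!
states) from the source, expanding all n(n+1)/2 reversals per state:
`exact_min_distance` returns the true minimum; `enumerate_minimal_scenarios`
tracks all shortest-path predecessors and backtracks every minimal event
sequence, sorted for deterministic output. The cap is n = 8
(~10.3 M states — minutes of CPU at worst; above it a `CapacityError`
advises the stochastic search). The polynomial-time signed-reversal
distance theory is deliberately not implemented: at plastome block counts
BFS is simpler, exact, and additionally enumerates scenarios. The
breakpoint bound d ≥ ⌈bp/2⌉ (adjacencies counted with two fixed terminals)
is provided as an independent diagnostic and is asserted exhaustively in
tests for n ≤ 4.

## Block extraction

Anchors are gene symbols present exactly once in each region's order —
not sequence alignments. Encoding each shared gene of the second order by
its signed position in the first, maximal runs of consecutive values are
exactly the maximal segments contiguous in both genomes with a consistent
joint orientation; each run becomes one block, labelled B1…Bk in source
coordinate order. A reversed singleton takes the sign of its strand
comparison. This is a desk-scale surrogate for sequence-level aligners:
boundaries land on gene boundaries, which is also where the named plastome
subregions (trnfM–trnE and the like) are delimited. Consequences: the
surrogate is asserted only to reproduce block-level arrangements, not
aligner output on degraded or intergenic-breakpoint cases.

## Quadripartite structure detection

The IR pair is defined as the longest pair of disjoint, *exactly*
reverse-complementary segments (the canonical structure is a perfect
repeat; no mismatch tolerance, and ambiguous N bases never match — the
complement table maps N to a sentinel that equals nothing). Detection is
seed-and-extend: k-mers (k = min(min_ir_length, 24)) of the doubled
sequence are matched against their reverse complements; matches on the
same anti-diagonal (arm1_start + arm2_end invariant) are extended
maximally in both directions, deduplicated, and filtered for circular
disjointness. Ties break on the longer larger-single-copy gap, then the
smaller start coordinate. The larger gap is the LSC; IRa is the repeat
copy immediately downstream of the LSC. Coordinates are 1-based inclusive
and may wrap; a labelled conversion to 0-based half-open BED-style rows is
separate and explicit. `min_ir_length` defaults to 1000 bp — well above
chance exact matches at plastome scale, well below real plastid IRs
(~10–30 kbp).

AT% is (A+T)/total over all bases including N, one decimal. Feature
tallies are reported both raw and with IR-duplicated (name, type) pairs
counted once, because published gene counts are ambiguous about IR
double-counting. Gene orders per region exclude boundary-straddling genes
with a warning. Intron counts are (coordinate parts − 1) of the gene's
CDS/exon structure, falling back to the gene feature; for IR-duplicated
genes the copy with the most parts is used.

## Synthetic data

The generator emulates the quadripartite layout at a reduced scale:
defaults are a 5 kbp LSC, 2 kbp IRs, 1.2 kbp SSC (10/4/4 genes), i.i.d.
uniform ACGT sequence (AT 50%, configurable), non-overlapping genes that
never straddle region boundaries, and IRb built as the exact reverse
complement of IRa with mirrored gene copies. The four junction-adjacent
single-copy bases are pinned to 'A' so the planted arms cannot extend by
chance complementarity — planted boundaries are therefore exactly
recoverable, which is what the round-trip tests assert. The optional
sibling record applies a planted k-event block-level inversion series
(default k = 2 over 5 blocks) to the LSC interior, recomputing gene
coordinates and strands, and returns the true block pair and scenario.

What passing synthetic tests do **not** show: behaviour on real data with
substitutions, indels, IR boundary shifts of a few bases, pseudogene
decay, or imperfect annotation — none of these processes are simulated.
The optional accession-based integration tests exist for that purpose and
run only when GenBank flat files are present locally.

## Numerical and degenerate-input choices

* source == target (under the configured equivalence): distance 0, one
  empty scenario, every replicate a length-0 hit.
* Event proposal includes single-block flips and the full segment;
  endpoint checked before the first event.
* Scenario and solution orderings are lexicographic by event sequence;
  reruns are bit-identical from a fixed seed everywhere (generators
  included, each with its own tagged stream).
* Block TSV signs accept ASCII '-' and U+2212 '−'; parse errors carry
  1-based line numbers.
* Equality of arrangements compares labels and signs; approximate block
  lengths are metadata and do not participate.

## Known limitations

* Inversions only; no weighting of scenarios by physical length, so all
  minimal scenarios are reported as equally parsimonious.
* The exact oracle is exponential by design; n > 8 requires the
  stochastic search, which bounds the minimum from above only.
* IR detection requires a perfect repeat; plastomes with diverged or
  heavily degraded IRs raise a no-IR error rather than a partial call.
* The two mirror readings of a two-block outcome, (+2, −1) and (−2, +1),
  cannot be distinguished from block arrangements alone; both are shipped
  as named fixture readings, and all distances agree between them.
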