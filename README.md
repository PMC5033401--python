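# dimsum-plastome

A toolkit for analysing large-scale rearrangements in plastid genomes
(plastomes). It answers the question a plastome assembler or comparative
study faces after spotting a scrambled region: *what is the shortest series
of inversions that turns one arrangement of colinear blocks into the
other, and is that series provably the most parsimonious?*

The package is aimed at researchers comparing newly assembled plastomes —
for example in the graminid Poales (grasses and their relatives), where
the large single-copy (LSC) and small single-copy (SSC) regions have
repeatedly been reshuffled by kilobase-scale inversions.

## What it does

* **Signed block arrangements.** A plastome region is an ordered list of
  locally colinear blocks, each with an orientation: a signed permutation
  π = (π₁, …, πₙ), πᵢ ∈ {±1, …, ±n}. An inversion (reversal) ρ(i, j) maps
  (…, πᵢ, …, πⱼ, …) to (…, −πⱼ, …, −πᵢ, …).
* **DIMSUM** (Detection of Inversion Modes through the Simulation of
  Unifying Mutations): a stochastic search that runs many independent
  random walks, each drawing uniform random inversions (up to 100 per
  replicate) until the target arrangement is reached, and reports every
  solution found, the shortest length, and per-length hit counts.
* **Exact parsimony oracle:** breadth-first search over the full
  signed-permutation space (2ⁿ·n! states) returns the true minimum
  d(π, σ) and enumerates *all* minimal scenarios — certifying the
  stochastic result for desk-scale block counts (n ≤ 8).
* **Flip equivalence** for SSC analyses: the SSC's absolute orientation
  between the flanking inverted repeats is biologically indeterminate, so
  an arrangement and its whole-segment reverse complement can be treated
  as the same state.
* **Colinear block extraction** from two annotated gene orders: shared
  single-copy genes are the anchors; maximal runs that are consecutive and
  consistently oriented in both genomes become blocks.
* **Quadripartite structure detection:** the longest pair of disjoint,
  exactly reverse-complementary segments of a circular sequence defines
  IRa/IRb, and the two gaps are the LSC and SSC; plus region statistics
  (lengths, AT%, feature counts) and per-gene intron counts.
* **Synthetic data:** seeded generators for arrangements, planted
  inversion histories, and quadripartite plastome records with ground
  truth, so everything is testable offline.
* The classical breakpoint bound d ≥ ⌈breakpoints / 2⌉ is available as a
  sanity diagnostic.

## Worked example

The LSC of the cattail *Typha latifolia* carries three subregions —
D-LSC3 (~0.75 kbp), D-LSC1 (~23 kbp), D-LSC2 (~5 kbp), all forward — that
the grass *Anomochloa marantoidea* carries as D-LSC2 forward followed by
D-LSC3 and D-LSC1 reverse-complemented. How many inversions does that
take?

```python
import dimsum as dm
from dimsum.fixtures import typha_vs_anomochloa_lsc

source, target = typha_vs_anomochloa_lsc()
print("source:", source)                  # +D-LSC3 +D-LSC1 +D-LSC2
print("target:", target)                  # +D-LSC2 -D-LSC3 -D-LSC1
print(dm.relabel_against_reference(source, target).values)   # (3, -1, -2)

print(dm.exact_min_distance(source, target))                 # 2
for sc in dm.enumerate_minimal_scenarios(source, target):
    print("minimal scenario:", sc)        # [2..3] -> [1..2]

res = dm.dimsum(source, target, dm.SearchConfig(replicates=10_000, seed=1))
res.exact_min = 2
print(res.summary())
```

Output of the last call:

```
replicates run      : 10000
minimum length found: 2
exact minimum (BFS) : 2
replicates hitting  : 8267 (82.7%)
  length   2: 250 hits
  ...
distinct solutions  : 7811
```

Reading: of 10,000 random walks, 8,267 reached the Anomochloa arrangement
within 100 inversions; 250 of them did it in two events, and the exact
oracle confirms two is the minimum. The unique minimal scenario inverts
blocks 2–3 (D-LSC1 + D-LSC2 together) and then blocks 1–2 — the classic
pattern of a large inversion followed by a partially overlapping second
inversion. The same machinery shows the shared Poaceae–Joinvilleaceae SSC
rearrangement needs two inversions as an oriented sequence but only one
under flip equivalence.

The same analyses run from the shell:

```bash
dimsum-plastome simulate fixtures --out fixtures/
dimsum-plastome distance fixtures/typha-anomochloa-lsc.blocks.tsv --out out/
dimsum-plastome dimsum fixtures/pojo-ssc.blocks.tsv --replicates 10000 --seed 1 --flip --out out/
dimsum-plastome structure my_plastome.fasta my_features.tsv --out out/
```

## Optional integration data

Region-statistic checks against real accessions (the *Joinvillea
ascendens* plastome KX035098 and the references NC013823, NC014062) run
automatically when the GenBank flat files are placed under
`tests/data/accessions/`; without them those tests are skipped and
everything else runs offline. See `docs/methods.md` for the model,
parameter and design notes.
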