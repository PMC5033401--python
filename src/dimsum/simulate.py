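"""Seeded generators: random arrangements, planted inversion histories, and
plastome-like records with known ground truth.

Everything is a pure function of (parameters, seed): repeated calls are
bit-identical, and each artifact comes with the ground truth needed to
score any downstream module offline.

Synthetic plastomes emulate the quadripartite layout (random single-copy
sequences, an exact reverse-complement IR pair) with evenly spaced,
non-overlapping gene features that never straddle region boundaries.
Sequences are i.i.d. uniform over ACGT (AT 50%) unless ``at_fraction`` is
set; there are no substitution or indel processes, so sequence-level realism
is not claimed — the generator exists to exercise structure detection and
block extraction, not aligners.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .arrangements import (
    InversionEvent,
    Scenario,
    SignedArrangement,
    SignedBlock,
    apply_inversion,
)
from .blocks import BlockPair
from .errors import ConfigError
from .structure import (
    CircularInterval,
    Feature,
    PlastomeRecord,
    QuadripartiteMap,
    reverse_complement,
    write_feature_tsv,
)

# stream tags keep the independent generators decoupled from one another
_TAG_ARRANGEMENT = 101
_TAG_PLANT = 102
_TAG_PLASTOME = 103
_TAG_SIBLING = 104


@dataclass(frozen=True)
class SynthParams:
    """Parameters of a synthetic plastome pair.

    Defaults give a compact desk-scale circle (5 kbp LSC, 2 kbp IRs,
    1.2 kbp SSC) with a 2-event planted inversion history over 5 LSC
    blocks — the same shape, two orders of magnitude smaller, as the
    ~150 kbp plastomes the tool targets.
    """

    n_blocks: int = 5
    k_events: int = 2
    seed: int = 0
    lsc_length: int = 5000
    ir_length: int = 2000
    ssc_length: int = 1200
    lsc_genes: int = 10
    ir_genes: int = 4
    ssc_genes: int = 4
    min_ir_length: int = 1000
    at_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_blocks", "lsc_length", "ir_length", "ssc_length",
                     "lsc_genes", "ir_genes", "ssc_genes", "min_ir_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.k_events < 0:
            raise ConfigError("k_events must be >= 0")
        if not (0.0 < self.at_fraction < 1.0):
            raise ConfigError("at_fraction must be in (0, 1)")
        if self.n_blocks > self.lsc_genes:
            raise ConfigError("n_blocks cannot exceed lsc_genes")


def random_arrangement(
    n: int, seed: int, region_name: str = "region"
) -> SignedArrangement:
    """Uniformly random signed arrangement of blocks B1..Bn."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng((seed, _TAG_ARRANGEMENT))
    order = rng.permutation(n) + 1
    signs = rng.choice((1, -1), size=n)
    return SignedArrangement(
        region_name,
        tuple(SignedBlock(f"B{k}", int(s)) for k, s in zip(order, signs)),
    )


def plant_inversions(
    arr: SignedArrangement, k: int, seed: int
) -> tuple[SignedArrangement, Scenario]:
    """Apply k uniformly random inversion events; return result and history."""
    if k < 0:
        raise ConfigError("k must be >= 0")
    rng = np.random.default_rng((seed, _TAG_PLANT))
    n = len(arr)
    intervals = [(s, e) for s in range(1, n + 1) for e in range(s, n + 1)]
    events = []
    current = arr
    for _ in range(k):
        s, e = intervals[int(rng.integers(len(intervals)))]
        ev = InversionEvent(s, e)
        events.append(ev)
        current = apply_inversion(current, ev)
    return current, Scenario(arr, tuple(events))


def _random_seq(rng: np.random.Generator, length: int, at_fraction: float) -> list[str]:
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return list(rng.choice(list("ATCG"), size=length, p=[p_at, p_at, p_gc, p_gc]))


def _place_genes(
    rng: np.random.Generator, region_len: int, n_genes: int, prefix: str, offset: int
) -> list[Feature]:
    """Evenly spaced, non-overlapping single-part genes inside one region."""
    gene_len = min(200, max(10, region_len // (2 * n_genes)))
    margin = 10
    usable = region_len - 2 * margin
    if usable < n_genes * gene_len + (n_genes - 1):
        raise ConfigError(
            f"region of {region_len} bp too short for {n_genes} genes"
        )
    feats = []
    for i in range(n_genes):
        centre = margin + int((i + 0.5) * usable / n_genes)
        start = offset + centre - gene_len // 2  # 0-based within circle
        strand = int(rng.choice((1, -1)))
        feats.append(
            Feature(f"{prefix}{i + 1:02d}", "gene", strand, ((start + 1, start + gene_len),))
        )
    return feats


@dataclass(frozen=True)
class SynthPlastome:
    """A synthetic plastome with its ground truth (and optional rearranged sibling)."""

    record: PlastomeRecord
    qmap: QuadripartiteMap
    params: SynthParams
    sibling: PlastomeRecord | None = None
    block_pair: BlockPair | None = None
    scenario: Scenario | None = None


def synth_plastome(params: SynthParams, with_sibling: bool = True) -> SynthPlastome:
    """Build a circular quadripartite record, and optionally a sibling whose
    LSC carries a known planted inversion series at block level.

    Layout: LSC | IRa | SSC | IRb, with IRb the exact reverse complement of
    IRa. The four junction-adjacent single-copy bases are pinned to 'A' so
    the planted arms cannot extend by chance complementarity, making the
    planted boundaries exactly recoverable.
    """
    rng = np.random.default_rng((params.seed, _TAG_PLASTOME))
    lsc = _random_seq(rng, params.lsc_length, params.at_fraction)
    ira = _random_seq(rng, params.ir_length, params.at_fraction)
    ssc = _random_seq(rng, params.ssc_length, params.at_fraction)
    # guard bases: an 'A' never complements an 'A', so the IR arms stop exactly
    # at the planted junctions
    lsc[0] = lsc[-1] = "A"
    ssc[0] = ssc[-1] = "A"
    lsc_s, ira_s, ssc_s = "".join(lsc), "".join(ira), "".join(ssc)
    irb_s = reverse_complement(ira_s)
    seq = lsc_s + ira_s + ssc_s + irb_s
    total = len(seq)

    l1, li, l2 = params.lsc_length, params.ir_length, params.ssc_length
    qmap = QuadripartiteMap(
        lsc=CircularInterval(1, l1, total),
        ira=CircularInterval(l1 + 1, l1 + li, total),
        ssc=CircularInterval(l1 + li + 1, l1 + li + l2, total),
        irb=CircularInterval(l1 + li + l2 + 1, total, total),
    )

    feats = []
    feats += _place_genes(rng, l1, params.lsc_genes, "lsc", 0)
    ira_feats = _place_genes(rng, li, params.ir_genes, "ir", l1)
    feats += ira_feats
    feats += _place_genes(rng, l2, params.ssc_genes, "ssc", l1 + li)
    # IRb carries mirrored copies of the IRa genes (duplicated names, as in
    # real plastomes)
    irb_start0 = l1 + li + l2
    for f in ira_feats:
        s, e = f.parts[0]
        off_s, off_e = s - 1 - l1, e - l1  # 0-based within IRa
        new_s0 = irb_start0 + (li - off_e)
        new_e0 = irb_start0 + (li - off_s)
        feats.append(Feature(f.name, f.type, -f.strand, ((new_s0 + 1, new_e0),)))
    feats.sort(key=lambda f: f.span)
    record = PlastomeRecord("synth-ref", seq, tuple(feats))

    if not with_sibling:
        return SynthPlastome(record=record, qmap=qmap, params=params)

    sibling, pair, scenario = _rearranged_sibling(record, qmap, params)
    return SynthPlastome(
        record=record, qmap=qmap, params=params,
        sibling=sibling, block_pair=pair, scenario=scenario,
    )


def _rearranged_sibling(
    record: PlastomeRecord, qmap: QuadripartiteMap, params: SynthParams
) -> tuple[PlastomeRecord, BlockPair, Scenario]:
    """Apply a planted block-level inversion series to the LSC."""
    l1 = qmap.lsc.length
    lsc_feats = [
        f for f in record.features if f.span[1] <= l1 and f.name.startswith("lsc")
    ]
    lsc_feats.sort(key=lambda f: f.span)
    n = params.n_blocks
    per = [len(lsc_feats) // n + (1 if i < len(lsc_feats) % n else 0) for i in range(n)]
    groups: list[list[Feature]] = []
    idx = 0
    for size in per:
        groups.append(lsc_feats[idx : idx + size])
        idx += size
    # chunk cut points at midpoints between adjacent gene spans; 0-based
    # half-open chunks, with fixed margins at the LSC edges so the junction
    # guard bases survive any rearrangement
    cuts = [max(1, groups[0][0].parts[0][0] - 1 - 5)]
    for g_prev, g_next in zip(groups, groups[1:]):
        prev_end0 = g_prev[-1].parts[0][1]  # 0-based exclusive end
        next_start0 = g_next[0].parts[0][0] - 1
        cuts.append((prev_end0 + next_start0) // 2)
    cuts.append(min(l1 - 1, groups[-1][-1].parts[0][1] + 5))

    chunk_bounds = list(zip(cuts, cuts[1:]))  # 0-based half-open within LSC
    source_arr = SignedArrangement(
        "LSC",
        tuple(
            SignedBlock(f"B{i + 1}", 1, hi - lo)
            for i, (lo, hi) in enumerate(chunk_bounds)
        ),
    )
    target_arr, scenario = plant_inversions(
        source_arr, params.k_events, np.random.default_rng((params.seed, _TAG_SIBLING)).integers(2**31)
    )

    seq = record.sequence
    new_lsc_parts = [seq[: cuts[0]]]
    new_feats: list[Feature] = []
    pos = cuts[0]
    for blk in target_arr.blocks:
        i = int(blk.label[1:]) - 1
        lo, hi = chunk_bounds[i]
        chunk_seq = seq[lo:hi]
        if blk.sign == 1:
            new_lsc_parts.append(chunk_seq)
            for f in groups[i]:
                s, e = f.parts[0]
                shift = pos - lo
                new_feats.append(
                    Feature(f.name, f.type, f.strand, ((s + shift, e + shift),))
                )
        else:
            new_lsc_parts.append(reverse_complement(chunk_seq))
            for f in groups[i]:
                s0, e0 = f.parts[0][0] - 1, f.parts[0][1]  # 0-based half-open
                new_s0 = pos + (hi - e0)
                new_e0 = pos + (hi - s0)
                new_feats.append(
                    Feature(f.name, f.type, -f.strand, ((new_s0 + 1, new_e0),))
                )
        pos += hi - lo
    new_lsc_parts.append(seq[cuts[-1] : l1])
    new_seq = "".join(new_lsc_parts) + seq[l1:]
    assert len(new_seq) == len(seq)

    other_feats = [f for f in record.features if f not in set(lsc_feats)]
    all_feats = tuple(sorted(new_feats + other_feats, key=lambda f: f.span))
    sibling = PlastomeRecord("synth-sib", new_seq, all_feats)

    members = {
        f"B{i + 1}": tuple(f.name for f in groups[i]) for i in range(len(groups))
    }
    pair = BlockPair(source_arr=source_arr, target_arr=target_arr, block_members=members)
    return sibling, pair, scenario


def write_synth_plastome(synth: SynthPlastome, outdir: str | Path) -> dict[str, Path]:
    """FASTA + feature TSV (+ sibling) + ground-truth JSON, for offline runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_fasta(rec: PlastomeRecord, name: str) -> Path:
        p = outdir / f"{name}.fasta"
        body = "\n".join(
            rec.sequence[i : i + 70] for i in range(0, len(rec.sequence), 70)
        )
        p.write_text(f">{rec.record_id} circular synthetic plastome\n{body}\n")
        return p

    paths["fasta"] = write_fasta(synth.record, "reference")
    paths["features"] = outdir / "reference.features.tsv"
    write_feature_tsv(synth.record.features, paths["features"])
    truth = {
        "params": dataclasses.asdict(synth.params),
        "regions": {
            name: {
                "start": synth.qmap.region(name).start,
                "end": synth.qmap.region(name).end,
            }
            for name in ("LSC", "IRa", "SSC", "IRb")
        },
    }
    if synth.sibling is not None:
        paths["sibling_fasta"] = write_fasta(synth.sibling, "sibling")
        paths["sibling_features"] = outdir / "sibling.features.tsv"
        write_feature_tsv(synth.sibling.features, paths["sibling_features"])
        truth["planted_events"] = [
            {"start": ev.start, "end": ev.end} for ev in synth.scenario.events
        ]
        truth["target_arrangement"] = [
            f"{'+' if b.sign > 0 else '-'}{b.label}"
            for b in synth.block_pair.target_arr.blocks
        ]
        truth["block_members"] = {
            k: list(v) for k, v in synth.block_pair.block_members.items()
        }
    paths["truth"] = outdir / "ground_truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
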