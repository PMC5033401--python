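"""Locally colinear blocks from two annotated gene orders.

A desk-scale surrogate for whole-genome aligners: the anchors are shared,
single-copy gene symbols rather than sequence matches, so block boundaries
fall on gene boundaries (which is where named plastome subregions such as
trnfM--trnE are delimited anyway). Shared genes are partitioned into
maximal runs that are consecutive in both orders with a consistent joint
orientation; each run becomes one signed block.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .arrangements import SignedArrangement, SignedBlock, write_blocks_tsv
from .errors import BlockTSVParseError, ConfigError, NoAnchorsError

_STRAND_TOKENS = {"+": 1, "-": -1, "−": -1, "1": 1, "-1": -1}


@dataclass(frozen=True)
class GeneOrder:
    """Ordered, stranded gene symbols for one region of one genome."""

    genome_id: str
    region_name: str
    genes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple((g, s) for g, s in self.genes))
        if not self.genes:
            raise ConfigError("gene order must be non-empty")
        for sym, strand in self.genes:
            if strand not in (1, -1):
                raise ConfigError(f"strand for {sym!r} must be +1 or -1")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class BlockPair:
    """Shared blocks of two gene orders, as matched signed arrangements.

    ``source_arr`` is the identity frame (all blocks forward, labelled
    B1..Bk in source coordinate order); ``block_members`` maps each label
    to its gene symbols in source order.
    """

    source_arr: SignedArrangement
    target_arr: SignedArrangement
    block_members: Mapping[str, tuple[str, ...]]


def restrict_to_shared(a: GeneOrder, b: GeneOrder) -> tuple[GeneOrder, GeneOrder]:
    """Drop genes not present exactly once in each order.

    Genes duplicated within a region (e.g. IR copies that leak into a
    single-copy annotation) are removed from both sides: unique anchors are
    required for a well-defined permutation.
    """
    counts_a = Counter(a.symbols)
    counts_b = Counter(b.symbols)
    shared = {
        sym for sym in counts_a
        if counts_a[sym] == 1 and counts_b.get(sym, 0) == 1
    }
    if not shared:
        raise NoAnchorsError(
            f"no shared single-copy genes between {a.genome_id!r} and {b.genome_id!r}"
        )
    ra = tuple((g, s) for g, s in a.genes if g in shared)
    rb = tuple((g, s) for g, s in b.genes if g in shared)
    return (
        GeneOrder(a.genome_id, a.region_name, ra),
        GeneOrder(b.genome_id, b.region_name, rb),
    )


def collinear_blocks(a: GeneOrder, b: GeneOrder) -> BlockPair:
    """Partition shared genes into maximal consistently-oriented runs.

    Encoding each shared gene of ``b`` by its (signed) position in ``a``,
    a maximal run with consecutive values (+i, +i+1, ... forward, or
    -j, -j+1, ... reversed) is exactly a maximal segment that is contiguous
    in both genomes with a consistent joint orientation.
    """
    ra, rb = restrict_to_shared(a, b)
    index = {sym: i + 1 for i, (sym, _) in enumerate(ra.genes)}
    a_strand = {sym: s for sym, s in ra.genes}
    svals = [index[sym] * (s * a_strand[sym]) for sym, s in rb.genes]

    runs: list[tuple[int, int]] = []  # (start_idx, end_idx) in rb, inclusive
    start = 0
    for i in range(1, len(svals)):
        if svals[i] != svals[i - 1] + 1:
            runs.append((start, i - 1))
            start = i
    runs.append((start, len(svals) - 1))

    # a-frame interval and orientation of each run
    described = []
    for lo, hi in runs:
        vals = svals[lo : hi + 1]
        sign = 1 if vals[0] > 0 else -1
        a_lo = min(abs(v) for v in vals)
        a_hi = max(abs(v) for v in vals)
        described.append((a_lo, a_hi, sign, lo))
    by_source = sorted(described)  # by a_lo: source coordinate order
    label_of = {
        (a_lo, a_hi): f"B{i + 1}" for i, (a_lo, a_hi, _, _) in enumerate(by_source)
    }

    members = {
        label_of[(a_lo, a_hi)]: tuple(ra.genes[i - 1][0] for i in range(a_lo, a_hi + 1))
        for a_lo, a_hi, _, _ in by_source
    }
    source_blocks = tuple(
        SignedBlock(label_of[(a_lo, a_hi)], 1) for a_lo, a_hi, _, _ in by_source
    )
    target_blocks = tuple(
        SignedBlock(label_of[(a_lo, a_hi)], sign)
        for a_lo, a_hi, sign, _ in sorted(described, key=lambda r: r[3])
    )
    return BlockPair(
        source_arr=SignedArrangement(a.region_name, source_blocks),
        target_arr=SignedArrangement(b.region_name, target_blocks),
        block_members=members,
    )


def read_gene_order_tsv(
    path: str | Path, genome_id: str | None = None, region_name: str = "region"
) -> GeneOrder:
    """Two-column TSV: gene symbol, strand (+/-). '#' lines are comments;
    a ``# region=...\\tgenome=...`` header, if present, names the order."""
    genes: list[tuple[str, int]] = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line.lstrip("#").split("\t"):
                key, _, val = tok.strip().partition("=")
                if key == "region":
                    region_name = val
                elif key == "genome" and genome_id is None:
                    genome_id = val
            continue
        cols = line.split("\t")
        if len(cols) < 2 or cols[1].strip() not in _STRAND_TOKENS:
            raise BlockTSVParseError("expected <symbol>\\t<+|->", lineno)
        genes.append((cols[0].strip(), _STRAND_TOKENS[cols[1].strip()]))
    if not genes:
        raise BlockTSVParseError("no gene lines found", 1)
    return GeneOrder(genome_id or str(path), region_name, tuple(genes))


def write_gene_order_tsv(order: GeneOrder, path: str | Path) -> None:
    lines = [f"# region={order.region_name}\tgenome={order.genome_id}"]
    lines += [f"{sym}\t{'+' if s > 0 else '-'}" for sym, s in order.genes]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_block_pair(
    pair: BlockPair,
    tsv_path: str | Path,
    members_json_path: str | Path | None = None,
    genome_ids: tuple[str, str] = ("source", "target"),
) -> None:
    """Block TSV plus a companion JSON mapping label -> member genes."""
    write_blocks_tsv((pair.source_arr, pair.target_arr), tsv_path, genome_ids)
    if members_json_path is not None:
        Path(members_json_path).write_text(
            json.dumps(
                {k: list(v) for k, v in pair.block_members.items()},
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
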