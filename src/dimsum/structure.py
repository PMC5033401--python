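"""Quadripartite plastome structure: IR detection, region statistics,
per-region gene orders and intron counts.

Most angiosperm plastomes are circles partitioned into a large and a small
single-copy region (LSC, SSC) separated by two inverted repeats (IRa, IRb)
that are exact reverse complements of each other. Detection here requires
*exact* reverse-complementarity (no mismatch tolerance; ambiguous ``N``
bases never match): the longest pair of disjoint reverse-complementary
segments of at least ``min_ir_length`` bp, maximally extended, defines the
partition.

Coordinates are 1-based inclusive throughout (GenBank convention); circular
intervals may wrap past the end of the sequence. An explicit, labelled
conversion to 0-based half-open BED-like rows is provided.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .blocks import GeneOrder
from .errors import (
    BlockTSVParseError,
    ConfigError,
    FeatureNotFoundError,
    InconsistencyError,
    NoInvertedRepeatError,
)

FEATURE_TYPES = ("gene", "CDS", "tRNA", "rRNA", "exon")

# complement for matching: N maps to '0' so it can never match anything
_COMP = str.maketrans("ACGTN", "TGCA0")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class Feature:
    """A typed, stranded feature with 1-based inclusive coordinate parts."""

    name: str
    type: str
    strand: int
    parts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ConfigError(f"unsupported feature type {self.type!r}")
        if self.strand not in (1, -1):
            raise ConfigError("strand must be +1 or -1")
        if not self.parts:
            raise ConfigError("feature needs at least one coordinate part")
        for s, e in self.parts:
            if not (1 <= s <= e):
                raise ConfigError(f"bad part {s}..{e}")

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.parts), max(e for _, e in self.parts)


@dataclass(frozen=True)
class PlastomeRecord:
    """A circular nucleotide sequence plus its gene features."""

    record_id: str
    sequence: str
    features: tuple[Feature, ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ConfigError("empty sequence")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ConfigError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        for f in self.features:
            if f.span[1] > len(seq):
                raise ConfigError(
                    f"feature {f.name!r} exceeds sequence length {len(seq)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_genbank(cls, path: str | Path) -> "PlastomeRecord":
        """Read a GenBank flat file (sequence and gene/CDS/tRNA/rRNA features)."""
        rec = SeqIO.read(str(path), "genbank")
        feats = []
        for f in rec.features:
            if f.type not in FEATURE_TYPES:
                continue
            quals = f.qualifiers
            name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or [""])[0]
            if not name:
                continue
            strand = -1 if f.location.strand == -1 else 1
            parts = tuple(
                (int(p.start) + 1, int(p.end)) for p in f.location.parts
            )
            feats.append(Feature(name, f.type, strand, parts))
        return cls(rec.id or rec.name, str(rec.seq), tuple(feats))

    @classmethod
    def from_fasta(
        cls, path: str | Path, features_tsv: str | Path | None = None
    ) -> "PlastomeRecord":
        rec = SeqIO.read(str(path), "fasta")
        feats = read_feature_tsv(features_tsv) if features_tsv else ()
        return cls(rec.id, str(rec.seq), tuple(feats))


def read_feature_tsv(path: str | Path) -> tuple[Feature, ...]:
    """Minimal feature dialect: name, type, strand, comma-separated start..end parts."""
    feats = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise BlockTSVParseError(
                "expected <name>\\t<type>\\t<+|->\\t<start..end[,start..end]>", lineno
            )
        name, ftype, strand_tok, parts_tok = (c.strip() for c in cols)
        if strand_tok not in ("+", "-", "−"):
            raise BlockTSVParseError(f"unknown strand token {strand_tok!r}", lineno)
        parts = []
        try:
            for tok in parts_tok.split(","):
                s, _, e = tok.partition("..")
                parts.append((int(s), int(e)))
        except ValueError:
            raise BlockTSVParseError(f"bad parts field {parts_tok!r}", lineno) from None
        try:
            feats.append(Feature(name, ftype, 1 if strand_tok == "+" else -1, tuple(parts)))
        except ConfigError as exc:
            raise BlockTSVParseError(str(exc), lineno) from None
    return tuple(feats)


def write_feature_tsv(features: tuple[Feature, ...], path: str | Path) -> None:
    lines = ["# name\ttype\tstrand\tparts"]
    for f in features:
        parts = ",".join(f"{s}..{e}" for s, e in f.parts)
        lines.append(f"{f.name}\t{f.type}\t{'+' if f.strand > 0 else '-'}\t{parts}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class CircularInterval:
    """1-based inclusive interval on a circle of ``total`` bp; wraps when end < start."""

    start: int
    end: int
    total: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.total and 1 <= self.end <= self.total):
            raise ConfigError("interval coordinates outside [1, total]")

    @property
    def length(self) -> int:
        return (self.end - self.start) % self.total + 1

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def offset_of(self, pos: int) -> int:
        """0-based offset of a 1-based position along the interval's forward direction."""
        return (pos - self.start) % self.total

    def contains_pos(self, pos: int) -> bool:
        return self.offset_of(pos) < self.length

    def contains_span(self, start: int, end: int) -> bool:
        """Whether a non-wrapping 1-based span lies fully inside."""
        if end < start:
            return False
        return (
            self.contains_pos(start)
            and self.contains_pos(end)
            and self.offset_of(start) <= self.offset_of(end)
        )

    def extract(self, seq: str) -> str:
        if self.wraps:
            return seq[self.start - 1 :] + seq[: self.end]
        return seq[self.start - 1 : self.end]

    def to_bed_interval(self) -> tuple[int, int]:
        """Explicit conversion to a 0-based half-open interval (end may exceed
        ``total`` for wrapping intervals, BED-on-circle style)."""
        return self.start - 1, self.start - 1 + self.length


@dataclass(frozen=True)
class QuadripartiteMap:
    """Circular coordinates of the four canonical plastome regions."""

    lsc: CircularInterval
    ssc: CircularInterval
    ira: CircularInterval
    irb: CircularInterval

    def region(self, name: str) -> CircularInterval:
        key = name.lower()
        if key not in ("lsc", "ssc", "ira", "irb"):
            raise ConfigError(f"unknown region {name!r}; expected LSC/SSC/IRa/IRb")
        return getattr(self, key)

    @property
    def lengths(self) -> dict[str, int]:
        return {
            "LSC": self.lsc.length,
            "SSC": self.ssc.length,
            "IRa": self.ira.length,
            "IRb": self.irb.length,
        }

    def to_bed_rows(self, record_id: str = ".") -> list[str]:
        """BED-like rows (0-based half-open), explicitly labelled as such."""
        rows = []
        for name in ("LSC", "IRa", "SSC", "IRb"):
            s0, e0 = self.region(name).to_bed_interval()
            rows.append(f"{record_id}\t{s0}\t{e0}\t{name}")
        return rows


def _circ_overlap(start1: int, start2: int, length: int, total: int) -> bool:
    return (start2 - start1) % total < length or (start1 - start2) % total < length


def find_inverted_repeat(
    rec: PlastomeRecord, min_ir_length: int = 1000
) -> QuadripartiteMap:
    """Detect the quadripartite partition of a circular plastome.

    Finds the longest pair of disjoint, exactly reverse-complementary
    segments of length >= ``min_ir_length`` on the circle (seed-and-extend
    on shared k-mers, maximal extension while exact complementarity holds).
    The larger single-copy gap becomes the LSC; IRa is the repeat copy
    immediately downstream of the LSC. Ties break first on the longer
    larger-single-copy gap, then on the smaller start coordinate.

    Raises :class:`NoInvertedRepeatError` when no such pair exists.
    """
    if min_ir_length < 1:
        raise ConfigError("min_ir_length must be >= 1")
    seq = rec.sequence
    n = len(seq)
    if min_ir_length > n // 2:
        raise NoInvertedRepeatError(
            f"min_ir_length {min_ir_length} exceeds half the sequence length"
        )
    d = seq + seq  # doubled string: circular segments are substrings
    cd = d.translate(_COMP)  # cd[y] == complement of d[y]
    k = min(min_ir_length, 24)

    kmer_pos: dict[str, list[int]] = {}
    for i in range(n):
        kmer_pos.setdefault(d[i : i + k], []).append(i)

    max_len = n // 2
    # anti-diagonal c = arm1_start + arm2_end is invariant under extension
    covered: dict[int, list[tuple[int, int]]] = {}
    candidates: list[tuple[int, int, int]] = []  # (length, a1, a2) in doubled coords

    for j in range(n):
        query = cd[j : j + k][::-1]  # reverse complement of d[j:j+k]
        for i in kmer_pos.get(query, ()):
            c = i + j + k - 1
            if any(lo <= i <= hi for lo, hi in covered.get(c, ())):
                continue
            a1, a2, length = i, j, k
            j_end = a2 + length - 1
            # extend left end of arm1 (pairs with right end of arm2)
            while (
                a1 > 0
                and j_end + 1 < 2 * n
                and length < max_len
                and d[a1 - 1] == cd[j_end + 1]
            ):
                a1 -= 1
                j_end += 1
                length += 1
            # extend right end of arm1 (pairs with left end of arm2)
            while (
                a2 > 0
                and a1 + length < 2 * n
                and length < max_len
                and d[a1 + length] == cd[a2 - 1]
            ):
                a2 -= 1
                length += 1
            covered.setdefault(c, []).append((a1, a1 + length - 1))
            if length >= min_ir_length:
                candidates.append((length, a1, a2))

    viable = []
    for length, a1, a2 in candidates:
        s1, s2 = a1 % n, a2 % n
        if s1 == s2:
            continue  # the same arm matched against itself
        if _circ_overlap(s1, s2, length, n):
            continue
        lo, hi = min(s1, s2), max(s1, s2)
        gap1 = (s2 - (s1 + length)) % n  # from end of arm1 to start of arm2
        gap2 = (s1 - (s2 + length)) % n
        if min(gap1, gap2) < 1:
            continue  # arms abut: not quadripartite
        viable.append((length, max(gap1, gap2), lo, hi, s1, s2, gap1, gap2))

    if not viable:
        raise NoInvertedRepeatError(
            f"no disjoint reverse-complementary repeat pair >= {min_ir_length} bp"
        )
    # dedupe the symmetric (arm1, arm2)/(arm2, arm1) discoveries
    best = {}
    for cand in viable:
        key = (cand[0], cand[2], cand[3])
        best[key] = cand
    length, _, _, _, s1, s2, gap1, gap2 = max(
        best.values(), key=lambda c: (c[0], c[1], -min(c[4], c[5]))
    )

    def interval(start0: int, seg_len: int) -> CircularInterval:
        return CircularInterval(start0 + 1, (start0 + seg_len - 1) % n + 1, n)

    arm1 = interval(s1, length)
    arm2 = interval(s2, length)
    gap_a = interval((s1 + length) % n, gap1)  # between arm1 and arm2
    gap_b = interval((s2 + length) % n, gap2)
    if gap1 >= gap2:
        lsc, ssc, ira, irb = gap_a, gap_b, arm2, arm1
    else:
        lsc, ssc, ira, irb = gap_b, gap_a, arm1, arm2
    return QuadripartiteMap(lsc=lsc, ssc=ssc, ira=ira, irb=irb)


def _validate_map(rec: PlastomeRecord, qmap: QuadripartiteMap) -> None:
    total = sum(qmap.lengths.values())
    if total != rec.length:
        raise InconsistencyError(
            f"map regions sum to {total} bp but record is {rec.length} bp"
        )
    ira_seq = qmap.ira.extract(rec.sequence)
    irb_seq = qmap.irb.extract(rec.sequence)
    if ira_seq != reverse_complement(irb_seq):
        raise InconsistencyError("IRa is not the reverse complement of IRb")


def region_stats(rec: PlastomeRecord, qmap: QuadripartiteMap) -> dict:
    """Length, composition and feature-count report for a mapped plastome.

    AT% is computed over all bases (N counts in the denominator only) and
    reported to one decimal. Feature counts are reported per region and in
    total, both raw and with IR-duplicated (name, type) pairs counted once —
    published gene tallies are ambiguous about IR double-counting, so both
    views are given.
    """
    _validate_map(rec, qmap)
    seq = rec.sequence
    at = seq.count("A") + seq.count("T")
    region_names = ("LSC", "IRa", "SSC", "IRb")
    counts: dict[str, dict[str, int]] = {r: {} for r in region_names}
    counts["boundary_spanning"] = {}
    for f in rec.features:
        s, e = f.span
        home = next(
            (r for r in region_names if qmap.region(r).contains_span(s, e)),
            "boundary_spanning",
        )
        counts[home][f.type] = counts[home].get(f.type, 0) + 1
    raw_totals: dict[str, int] = {}
    for per_region in counts.values():
        for t, c in per_region.items():
            raw_totals[t] = raw_totals.get(t, 0) + c
    dedup: dict[str, set[str]] = {}
    for f in rec.features:
        dedup.setdefault(f.type, set()).add(f.name)
    return {
        "record_id": rec.record_id,
        "total_length_bp": rec.length,
        "at_percent": round(100.0 * at / rec.length, 1),
        "regions": {
            r: {
                "start": qmap.region(r).start,
                "end": qmap.region(r).end,
                "length_bp": qmap.region(r).length,
            }
            for r in region_names
        },
        "feature_counts": counts,
        "feature_totals": {
            "raw": raw_totals,
            "ir_deduplicated": {t: len(names) for t, names in dedup.items()},
        },
    }


def format_stats(stats: dict) -> str:
    """Human-readable table for a region_stats report."""
    lines = [
        f"record        : {stats['record_id']}",
        f"total length  : {stats['total_length_bp']:,} bp",
        f"AT composition: {stats['at_percent']}%",
        "region   start     end      length",
    ]
    for name, r in stats["regions"].items():
        lines.append(f"{name:<6} {r['start']:>8} {r['end']:>8} {r['length_bp']:>9,} bp")
    return "\n".join(lines)


def gene_order_from_features(
    rec: PlastomeRecord, qmap: QuadripartiteMap, region: str
) -> GeneOrder:
    """Ordered gene symbols of one region, for block extraction.

    Only genes whose full span lies within the region are used; genes
    straddling a region boundary are excluded with a warning. 'gene'
    features are preferred; records annotated only with CDS/tRNA/rRNA fall
    back to those types (one entry per name).
    """
    interval = qmap.region(region)  # raises ConfigError on unknown names
    has_gene_type = any(f.type == "gene" for f in rec.features)
    wanted = ("gene",) if has_gene_type else ("CDS", "tRNA", "rRNA")
    entries = []
    seen_names: set[str] = set()
    for f in rec.features:
        if f.type not in wanted:
            continue
        s, e = f.span
        if not (interval.contains_pos(s) or interval.contains_pos(e)):
            continue
        if not interval.contains_span(s, e):
            warnings.warn(
                f"gene {f.name!r} straddles a {region} boundary; excluded",
                stacklevel=2,
            )
            continue
        if not has_gene_type and f.name in seen_names:
            continue  # multi-part CDS etc. already represented
        seen_names.add(f.name)
        entries.append((interval.offset_of(s), f.name, f.strand))
    if not entries:
        raise FeatureNotFoundError(f"no genes contained in region {region}")
    entries.sort()
    canonical = {"lsc": "LSC", "ssc": "SSC", "ira": "IRa", "irb": "IRb"}
    return GeneOrder(
        rec.record_id,
        canonical[region.lower()],
        tuple((name, strand) for _, name, strand in entries),
    )


def intron_count(rec: PlastomeRecord, gene_name: str) -> int:
    """Introns of a gene, as (number of coordinate parts - 1).

    Uses the CDS/exon structure when annotated, otherwise the gene feature;
    for IR-duplicated genes the copy with the most parts is used.
    """
    matching = [f for f in rec.features if f.name == gene_name]
    if not matching:
        raise FeatureNotFoundError(f"gene {gene_name!r} not found in {rec.record_id}")
    for types in (("CDS", "exon"), ("gene", "tRNA", "rRNA")):
        cands = [f for f in matching if f.type in types]
        if cands:
            return max(len(f.parts) for f in cands) - 1
    return max(len(f.parts) for f in matching) - 1
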