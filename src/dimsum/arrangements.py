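"""Signed block arrangements and the inversion operation.

A plastome single-copy region is modelled as a *linear* ordered list of
uniquely labelled blocks, each carrying an orientation sign (+1 forward,
-1 reverse-complemented relative to the reference frame). An inversion
event reverses a contiguous interval of whole blocks and negates every
sign inside it — the block-level image of a large-scale plastid inversion.

Regions are linear because the single-copy regions sit between fixed
inverted-repeat boundaries; whole-plastome circular arrangements are out
of scope here.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

from .errors import (
    BlockTSVParseError,
    ConfigError,
    IncomparableArrangementsError,
    InvalidEventError,
)

_SIGN_TOKENS = {"+": 1, "-": -1, "−": -1}  # accept ASCII and U+2212 minus


def _sign_char(sign: int) -> str:
    return "+" if sign > 0 else "-"


@dataclass(frozen=True)
class SignedBlock:
    """One locally colinear block with an orientation.

    Parameters
    ----------
    label : str
        Non-empty block identifier, e.g. ``"D-LSC1"``.
    sign : int
        +1 (forward) or -1 (reverse-complemented).
    approx_length_bp : int, optional
        Approximate physical size of the block in base pairs.
    """

    label: str
    sign: int
    approx_length_bp: int | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ConfigError("block label must be non-empty")
        if self.sign not in (1, -1):
            raise ConfigError(f"block sign must be +1 or -1, got {self.sign!r}")
        if self.approx_length_bp is not None and self.approx_length_bp <= 0:
            raise ConfigError("approx_length_bp must be positive when given")

    def flipped(self) -> "SignedBlock":
        return dataclasses.replace(self, sign=-self.sign)

    def __str__(self) -> str:
        return f"{_sign_char(self.sign)}{self.label}"


@dataclass(frozen=True)
class SignedArrangement:
    """An ordered, signed list of blocks for one plastome region."""

    region_name: str
    blocks: tuple[SignedBlock, ...]
    topology: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if len(self.blocks) < 1:
            raise ConfigError("an arrangement needs at least one block")
        labels = [b.label for b in self.blocks]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate block labels in {self.region_name!r}")
        if self.topology != "linear":
            raise ConfigError("only linear regions are modelled")

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[SignedBlock]:
        return iter(self.blocks)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.blocks)

    @property
    def signs(self) -> tuple[int, ...]:
        return tuple(b.sign for b in self.blocks)

    def signature(self) -> tuple[tuple[str, int], ...]:
        """Order+orientation content, ignoring length metadata."""
        return tuple((b.label, b.sign) for b in self.blocks)

    def reverse_complement(self) -> "SignedArrangement":
        """Whole-segment flip: reverse block order and negate every sign."""
        return dataclasses.replace(
            self, blocks=tuple(b.flipped() for b in reversed(self.blocks))
        )

    @classmethod
    def from_signed_ints(
        cls,
        values: Sequence[int],
        region_name: str = "region",
        labels: Sequence[str] | None = None,
        lengths: Sequence[int | None] | None = None,
    ) -> "SignedArrangement":
        """Build an arrangement from signed integers, e.g. ``(+3, -1, -2)``.

        ``labels[i]`` names the block with magnitude ``i + 1`` (defaults
        ``B1..Bn``); entry ``+k``/``-k`` places that block forward/flipped.
        """
        n = len(values)
        if labels is None:
            labels = [f"B{i}" for i in range(1, n + 1)]
        blocks = []
        for v in values:
            if v == 0 or abs(v) > n:
                raise ConfigError(f"signed value {v} out of range for n={n}")
            length = lengths[abs(v) - 1] if lengths is not None else None
            blocks.append(
                SignedBlock(labels[abs(v) - 1], 1 if v > 0 else -1, length)
            )
        return cls(region_name, tuple(blocks))

    def __str__(self) -> str:
        return " ".join(str(b) for b in self.blocks)


@dataclass(frozen=True)
class InversionEvent:
    """A contiguous block interval to reverse-and-flip (1-based, inclusive)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ConfigError(
                f"need 1 <= start <= end, got start={self.start}, end={self.end}"
            )

    def __str__(self) -> str:
        return f"[{self.start}..{self.end}]"


def apply_inversion(arr: SignedArrangement, ev: InversionEvent) -> SignedArrangement:
    """Return a new arrangement with blocks ``ev.start..ev.end`` reversed
    and sign-flipped. Pure: ``arr`` is not modified."""
    if ev.end > len(arr):
        raise InvalidEventError(
            f"event {ev} out of range for {len(arr)}-block arrangement"
        )
    blocks = list(arr.blocks)
    blocks[ev.start - 1 : ev.end] = [
        b.flipped() for b in reversed(blocks[ev.start - 1 : ev.end])
    ]
    return dataclasses.replace(arr, blocks=tuple(blocks))


@dataclass(frozen=True)
class Scenario:
    """An ordered series of inversion events applied to a source arrangement."""

    source: SignedArrangement
    events: tuple[InversionEvent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        self.replay()  # validates every step

    def __len__(self) -> int:
        return len(self.events)

    def replay(self) -> list[SignedArrangement]:
        """All intermediate arrangements, from source to terminal (inclusive)."""
        states = [self.source]
        for ev in self.events:
            states.append(apply_inversion(states[-1], ev))
        return states

    @property
    def terminal(self) -> SignedArrangement:
        return self.replay()[-1]

    def __str__(self) -> str:
        return " -> ".join(str(ev) for ev in self.events) if self.events else "(empty)"


def _check_same_labels(a: SignedArrangement, b: SignedArrangement) -> None:
    if set(a.labels) != set(b.labels):
        raise IncomparableArrangementsError(
            f"label sets differ: {sorted(set(a.labels) ^ set(b.labels))}"
        )


def arrangements_equal(
    a: SignedArrangement, b: SignedArrangement, flip_equivalence: bool = False
) -> bool:
    """Test whether two arrangements are the same block order and orientation.

    With ``flip_equivalence`` the whole-segment reverse complement of ``a``
    also counts as equal — the reading appropriate for SSC regions, whose
    absolute orientation between the flanking IRs is biologically
    indeterminate (both orientations coexist in the plastid population).
    """
    _check_same_labels(a, b)
    if a.signature() == b.signature():
        return True
    if flip_equivalence:
        return a.reverse_complement().signature() == b.signature()
    return False


@dataclass(frozen=True)
class SignedPermutation:
    """A target arrangement encoded in its source's identity frame.

    ``values[i]`` is ``+k`` when position ``i+1`` of the target carries the
    source's ``k``-th block in the source orientation, ``-k`` when flipped.
    ``labels``/``source_signs``/``lengths`` retain enough metadata to round-trip
    back to labelled arrangements.
    """

    values: tuple[int, ...]
    labels: tuple[str, ...]
    source_signs: tuple[int, ...]
    lengths: tuple[int | None, ...]
    region_name: str = "region"

    def to_arrangement(self, region_name: str | None = None) -> SignedArrangement:
        blocks = []
        for v in self.values:
            k = abs(v) - 1
            sign = self.source_signs[k] * (1 if v > 0 else -1)
            blocks.append(SignedBlock(self.labels[k], sign, self.lengths[k]))
        return SignedArrangement(region_name or self.region_name, tuple(blocks))


def relabel_against_reference(
    source: SignedArrangement, target: SignedArrangement
) -> SignedPermutation:
    """Express ``target`` as a signed permutation in ``source``'s frame.

    The source maps to the identity ``(+1, ..., +n)``; inversion distances and
    scenarios are invariant under this relabelling, so all search code works
    on the returned integer tuple.
    """
    _check_same_labels(source, target)
    code = {b.label: i + 1 for i, b in enumerate(source.blocks)}
    ref_sign = {b.label: b.sign for b in source.blocks}
    values = tuple(
        code[b.label] * (b.sign * ref_sign[b.label]) for b in target.blocks
    )
    return SignedPermutation(
        values=values,
        labels=source.labels,
        source_signs=source.signs,
        lengths=tuple(b.approx_length_bp for b in source.blocks),
        region_name=source.region_name,
    )


# ---------------------------------------------------------------------------
# Block TSV dialect
#
#   # region=<name>\tgenome=<id>
#   <label>\t<+|->\t[approx_length_bp]
#   ...
#   (blank line)
#   # region=<name>\tgenome=<id>
#   ...
#
# Two sections per file: source first, target second. '#' lines that are not
# section headers are comments.
# ---------------------------------------------------------------------------


def _parse_header(line: str) -> dict[str, str]:
    fields = {}
    for tok in line.lstrip("#").strip().split("\t"):
        if "=" in tok:
            key, _, val = tok.partition("=")
            fields[key.strip()] = val.strip()
    return fields


def read_blocks_tsv(path: str | Path) -> tuple[SignedArrangement, SignedArrangement]:
    """Read a two-section block TSV; returns ``(source, target)``."""
    sections: list[dict] = []
    current: dict | None = None
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            current = None
            continue
        if line.startswith("#"):
            fields = _parse_header(line)
            if "region" in fields:
                current = {
                    "region": fields["region"],
                    "genome": fields.get("genome", ""),
                    "blocks": [],
                    "line": lineno,
                }
                sections.append(current)
            continue  # plain comment
        if current is None:  # data line before any header: implicit section
            current = {"region": "region", "genome": "", "blocks": [], "line": lineno}
            sections.append(current)
        cols = line.split("\t")
        if len(cols) < 2:
            raise BlockTSVParseError("expected <label>\\t<+|->\\t[length]", lineno)
        label, sign_tok = cols[0].strip(), cols[1].strip()
        if sign_tok not in _SIGN_TOKENS:
            raise BlockTSVParseError(f"unknown sign token {sign_tok!r}", lineno)
        length: int | None = None
        if len(cols) >= 3 and cols[2].strip():
            try:
                length = int(cols[2].strip())
            except ValueError:
                raise BlockTSVParseError(
                    f"bad approx_length_bp {cols[2]!r}", lineno
                ) from None
        if any(b.label == label for b in current["blocks"]):
            raise BlockTSVParseError(f"duplicate label {label!r}", lineno)
        try:
            current["blocks"].append(SignedBlock(label, _SIGN_TOKENS[sign_tok], length))
        except ConfigError as exc:
            raise BlockTSVParseError(str(exc), lineno) from None
    if len(sections) != 2:
        raise BlockTSVParseError(
            f"expected exactly two block sections, found {len(sections)}",
            sections[-1]["line"] if sections else 1,
        )
    arrs = []
    for sec in sections:
        if not sec["blocks"]:
            raise BlockTSVParseError("empty block section", sec["line"])
        arrs.append(SignedArrangement(sec["region"], tuple(sec["blocks"])))
    if set(arrs[0].labels) != set(arrs[1].labels):
        raise BlockTSVParseError(
            "label sets differ between the two sections", sections[1]["line"]
        )
    return arrs[0], arrs[1]


def write_blocks_tsv(
    pair: tuple[SignedArrangement, SignedArrangement],
    path: str | Path,
    genome_ids: tuple[str, str] = ("source", "target"),
) -> None:
    lines = []
    for arr, genome in zip(pair, genome_ids):
        lines.append(f"# region={arr.region_name}\tgenome={genome}")
        for b in arr.blocks:
            cols = [b.label, _sign_char(b.sign)]
            if b.approx_length_bp is not None:
                cols.append(str(b.approx_length_bp))
            lines.append("\t".join(cols))
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
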