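"""Worked plastome rearrangement instances from the graminid Poales.

Three block-level instances, encoded from published plastome comparisons
among *Typha latifolia* (cattail; the ancestral arrangement), *Anomochloa
marantoidea* (a deeply diverging grass) and *Joinvillea ascendens*:

* LSC, Typha -> Anomochloa: three subregions D-LSC1 (~23 kbp), D-LSC2
  (~5 kbp), D-LSC3 (~0.75 kbp). Relative to Typha's order (D-LSC3,
  D-LSC1, D-LSC2, all forward) the Anomochloa arrangement is (+3, -1, -2):
  D-LSC1 inverted and laterally exchanged with D-LSC2, D-LSC3 moved to a
  reverse-complemented position between them. Minimal scenario: 2 events.

* LSC, Anomochloa -> Joinvillea: two subregions Ja-LSC1 (~33 kbp) and
  Ja-LSC2 (~19.5 kbp), laterally exchanged with exactly one of the two
  ending up reverse-complemented. The two mirror readings (-2, +1)
  (Ja-LSC1 keeps its orientation) and (+2, -1) (Ja-LSC2 restored by the
  second event, Ja-LSC1 left inverted) are both provided; they have
  identical minimal scenarios of length 2.

* SSC, shared by Poaceae and Joinvilleaceae: PoJo-SSC1 (~14 kbp) keeps its
  orientation, PoJo-SSC2 (~3 kbp) is reverse-complemented, the two
  laterally exchanged: (-2, +1). Minimal scenario: 2 events — or a single
  event under flip equivalence, since the SSC's absolute orientation
  between the flanking IRs is indeterminate.
"""
from __future__ import annotations

from pathlib import Path

from .arrangements import SignedArrangement, write_blocks_tsv

Pair = tuple[SignedArrangement, SignedArrangement]


def typha_vs_anomochloa_lsc() -> Pair:
    """Typha (source) vs Anomochloa (target) LSC block arrangements."""
    labels = ["D-LSC1", "D-LSC2", "D-LSC3"]
    lengths = [23000, 5000, 750]

    def arr(values):
        return SignedArrangement.from_signed_ints(
            values, region_name="LSC", labels=labels, lengths=lengths
        )

    source = arr([+3, +1, +2])  # Typha order: D-LSC3, D-LSC1, D-LSC2
    target = arr([+2, -3, -1])  # Anomochloa: D-LSC2, -D-LSC3, -D-LSC1
    return source, target


def anomochloa_vs_joinvillea_lsc(reading: str = "event-series") -> Pair:
    """Anomochloa (source) vs Joinvillea (target) LSC block arrangements.

    ``reading`` selects the mirror reading of the two-block outcome:
    ``"event-series"`` gives (+2, -1); ``"stated-orientations"`` gives
    (-2, +1). The two are whole-segment mirror images with identical
    minimal scenarios.
    """
    labels = ["Ja-LSC1", "Ja-LSC2"]
    lengths = [33000, 19500]

    def arr(values):
        return SignedArrangement.from_signed_ints(
            values, region_name="LSC", labels=labels, lengths=lengths
        )

    source = arr([+1, +2])
    if reading == "event-series":
        return source, arr([+2, -1])
    if reading == "stated-orientations":
        return source, arr([-2, +1])
    raise ValueError(
        f"unknown reading {reading!r}; use 'event-series' or 'stated-orientations'"
    )


def poaceae_joinvillea_ssc() -> Pair:
    """Ancestral vs Poaceae+Joinvilleaceae SSC block arrangements."""
    labels = ["PoJo-SSC1", "PoJo-SSC2"]
    lengths = [14000, 3000]

    def arr(values):
        return SignedArrangement.from_signed_ints(
            values, region_name="SSC", labels=labels, lengths=lengths
        )

    # PoJo-SSC2 reverse-complemented, PoJo-SSC1 orientation retained,
    # laterally exchanged
    return arr([+1, +2]), arr([-2, +1])


FIXTURES = {
    "typha-anomochloa-lsc": typha_vs_anomochloa_lsc,
    "anomochloa-joinvillea-lsc-event-series": lambda: anomochloa_vs_joinvillea_lsc(
        "event-series"
    ),
    "anomochloa-joinvillea-lsc-stated-orientations": lambda: anomochloa_vs_joinvillea_lsc(
        "stated-orientations"
    ),
    "pojo-ssc": poaceae_joinvillea_ssc,
}

_GENOME_IDS = {
    "typha-anomochloa-lsc": ("Typha_latifolia", "Anomochloa_marantoidea"),
    "anomochloa-joinvillea-lsc-event-series": (
        "Anomochloa_marantoidea",
        "Joinvillea_ascendens",
    ),
    "anomochloa-joinvillea-lsc-stated-orientations": (
        "Anomochloa_marantoidea",
        "Joinvillea_ascendens",
    ),
    "pojo-ssc": ("ancestral", "Poaceae_Joinvilleaceae"),
}


def write_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Materialise every worked instance as a block TSV file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, build in FIXTURES.items():
        path = outdir / f"{name}.blocks.tsv"
        write_blocks_tsv(build(), path, genome_ids=_GENOME_IDS[name])
        paths[name] = path
    return paths
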