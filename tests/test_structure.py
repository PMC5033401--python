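"""Quadripartite structure detection, region statistics, introns, parsing."""
from pathlib import Path

import numpy as np
import pytest

import dimsum as dm
from dimsum.structure import (
    CircularInterval,
    Feature,
    PlastomeRecord,
    format_stats,
    read_feature_tsv,
    reverse_complement,
    write_feature_tsv,
)

ACCESSION_DIR = Path(__file__).parent / "data" / "accessions"


@pytest.fixture(scope="module")
def synth():
    return dm.synth_plastome(dm.SynthParams(seed=42), with_sibling=False)


class TestFindInvertedRepeat:
    def test_recovers_planted_lengths(self, synth):
        qmap = dm.find_inverted_repeat(synth.record, min_ir_length=1000)
        assert qmap.lengths == {"LSC": 5000, "IRa": 2000, "SSC": 1200, "IRb": 2000}

    def test_recovers_planted_boundaries_exactly(self, synth):
        assert dm.find_inverted_repeat(synth.record, min_ir_length=1000) == synth.qmap

    def test_no_repeat_raises(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        rec = PlastomeRecord("bare", seq)
        with pytest.raises(dm.NoInvertedRepeatError):
            dm.find_inverted_repeat(rec, min_ir_length=200)

    def test_partition_conservation_and_complementarity(self, synth):
        qmap = dm.find_inverted_repeat(synth.record)
        assert sum(qmap.lengths.values()) == synth.record.length
        ira = qmap.ira.extract(synth.record.sequence)
        irb = qmap.irb.extract(synth.record.sequence)
        assert ira == reverse_complement(irb)

    def test_rotation_invariance(self):
        base = dm.synth_plastome(
            dm.SynthParams(seed=7, lsc_length=1500, ir_length=400, ssc_length=300,
                           min_ir_length=200, lsc_genes=4, ir_genes=1, ssc_genes=1,
                           n_blocks=2),
            with_sibling=False,
        )
        seq = base.record.sequence
        expected = dm.find_inverted_repeat(base.record, min_ir_length=200).lengths
        rng = np.random.default_rng(3)
        for offset in rng.integers(1, len(seq), size=10):
            rotated = PlastomeRecord("rot", seq[offset:] + seq[:offset])
            got = dm.find_inverted_repeat(rotated, min_ir_length=200).lengths
            assert got == expected

    def test_ambiguous_bases_never_match(self):
        # an IR made entirely of N must not be detected
        rng = np.random.default_rng(2)
        lsc = "".join(rng.choice(list("ACGT"), size=1000))
        ssc = "".join(rng.choice(list("ACGT"), size=300))
        rec = PlastomeRecord("enn", lsc + "N" * 400 + ssc + "N" * 400)
        with pytest.raises(dm.NoInvertedRepeatError):
            dm.find_inverted_repeat(rec, min_ir_length=200)


class TestRegionStats:
    def test_all_a_toy_circle_is_pure_at(self):
        rec = PlastomeRecord("toy", "A" * 40 + "ACGT" * 5 + "A" * 20 + "ACGT" * 5)
        # hand-built map: the two ACGT*5 stretches are reverse complements
        qmap = dm.QuadripartiteMap(
            lsc=CircularInterval(1, 40, 100),
            ira=CircularInterval(41, 60, 100),
            ssc=CircularInterval(61, 80, 100),
            irb=CircularInterval(81, 100, 100),
        )
        stats = dm.region_stats(rec, qmap)
        assert stats["total_length_bp"] == 100
        # 60 bp of pure A plus the A and T of each ACGT word: 80 of 100
        assert stats["at_percent"] == 80.0

    def test_lengths_sum_to_total(self, synth):
        stats = dm.region_stats(synth.record, synth.qmap)
        assert (
            sum(r["length_bp"] for r in stats["regions"].values())
            == stats["total_length_bp"]
        )
        assert "LSC" in format_stats(stats)

    def test_mismatched_map_rejected(self, synth):
        other = dm.synth_plastome(
            dm.SynthParams(seed=1, lsc_length=4000), with_sibling=False
        )
        with pytest.raises(dm.InconsistencyError):
            dm.region_stats(synth.record, other.qmap)

    def test_ir_genes_deduplicated_in_totals(self, synth):
        stats = dm.region_stats(synth.record, synth.qmap)
        raw = stats["feature_totals"]["raw"]["gene"]
        dedup = stats["feature_totals"]["ir_deduplicated"]["gene"]
        assert raw == dedup + synth.params.ir_genes  # each IR gene counted twice raw


class TestGeneOrder:
    def test_simple_ordering_with_strands(self):
        rec = PlastomeRecord(
            "toy",
            "A" * 100 + "ACGT" * 5 + "A" * 20 + "ACGT" * 5,
            (
                Feature("a", "gene", 1, ((10, 50),)),
                Feature("b", "gene", -1, ((60, 90),)),
            ),
        )
        qmap = dm.QuadripartiteMap(
            lsc=CircularInterval(1, 100, 160),
            ira=CircularInterval(101, 120, 160),
            ssc=CircularInterval(121, 140, 160),
            irb=CircularInterval(141, 160, 160),
        )
        go = dm.gene_order_from_features(rec, qmap, "LSC")
        assert go.genes == (("a", 1), ("b", -1))

    def test_boundary_straddler_excluded_with_warning(self):
        rec = PlastomeRecord(
            "toy",
            "A" * 160,
            (
                Feature("inside", "gene", 1, ((10, 50),)),
                Feature("straddler", "gene", 1, ((95, 110),)),
            ),
        )
        qmap = dm.QuadripartiteMap(
            lsc=CircularInterval(1, 100, 160),
            ira=CircularInterval(101, 120, 160),
            ssc=CircularInterval(121, 140, 160),
            irb=CircularInterval(141, 160, 160),
        )
        with pytest.warns(UserWarning, match="straddler"):
            go = dm.gene_order_from_features(rec, qmap, "LSC")
        assert go.symbols == ("inside",)

    def test_unknown_region_rejected(self, synth):
        with pytest.raises(dm.ConfigError):
            dm.gene_order_from_features(synth.record, synth.qmap, "IRc")

    def test_synthetic_round_trip(self, synth):
        go = dm.gene_order_from_features(synth.record, synth.qmap, "LSC")
        assert go.symbols == tuple(f"lsc{i:02d}" for i in range(1, 11))


class TestIntronCount:
    def test_single_interval_gene(self):
        rec = PlastomeRecord(
            "toy", "A" * 100, (Feature("psbA", "gene", 1, ((10, 40),)),)
        )
        assert dm.intron_count(rec, "psbA") == 0

    def test_three_exon_gene(self):
        rec = PlastomeRecord(
            "toy", "A" * 100,
            (
                Feature("clpP", "gene", 1, ((10, 80),)),
                Feature("clpP", "CDS", 1, ((10, 20), (30, 45), (60, 80))),
            ),
        )
        assert dm.intron_count(rec, "clpP") == 2

    def test_absent_gene_raises(self):
        rec = PlastomeRecord("toy", "A" * 100)
        with pytest.raises(dm.FeatureNotFoundError):
            dm.intron_count(rec, "nope")


class TestIO:
    def test_feature_tsv_round_trip(self, tmp_path):
        feats = (
            Feature("a", "gene", 1, ((10, 50),)),
            Feature("b", "CDS", -1, ((60, 70), (80, 90))),
        )
        path = tmp_path / "f.tsv"
        write_feature_tsv(feats, path)
        assert read_feature_tsv(path) == feats

    def test_genbank_round_trip_with_join_location(self, tmp_path):
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
        from Bio.SeqRecord import SeqRecord

        seq = "ATGC" * 50
        rec = SeqRecord(Seq(seq), id="toy1", name="toy1",
                        description="synthetic test record",
                        annotations={"molecule_type": "DNA", "topology": "circular"})
        loc = CompoundLocation(
            [SimpleLocation(9, 30, strand=1), SimpleLocation(49, 70, strand=1)]
        )
        rec.features.append(
            SeqFeature(loc, type="CDS", qualifiers={"gene": ["clpP"]})
        )
        rec.features.append(
            SeqFeature(SimpleLocation(99, 150, strand=-1), type="gene",
                       qualifiers={"gene": ["rbcL"]})
        )
        path = tmp_path / "toy.gb"
        SeqIO.write(rec, str(path), "genbank")

        loaded = PlastomeRecord.from_genbank(path)
        assert loaded.sequence == seq
        assert dm.intron_count(loaded, "clpP") == 1
        by_name = {f.name: f for f in loaded.features}
        assert by_name["clpP"].parts == ((10, 30), (50, 70))
        assert by_name["rbcL"].strand == -1


@pytest.mark.skipif(
    not (ACCESSION_DIR / "KX035098.gb").exists(),
    reason="optional integration data: place GenBank flat files under "
    "tests/data/accessions/ (KX035098.gb, NC013823.gb, NC014062.gb) to run",
)
class TestReferenceAccessions:
    """Optional integration checks against downloaded GenBank accessions."""

    def test_joinvillea_ascendens_structure(self):
        rec = PlastomeRecord.from_genbank(ACCESSION_DIR / "KX035098.gb")
        qmap = dm.find_inverted_repeat(rec)
        stats = dm.region_stats(rec, qmap)
        assert stats["total_length_bp"] == 149_327
        assert qmap.lengths["LSC"] == 85_526
        assert qmap.lengths["SSC"] == 12_907
        assert qmap.lengths["IRa"] == qmap.lengths["IRb"] == 25_447
        assert stats["at_percent"] == 60.4

    def test_clpp_intron_counts(self):
        typha = PlastomeRecord.from_genbank(ACCESSION_DIR / "NC013823.gb")
        anomochloa = PlastomeRecord.from_genbank(ACCESSION_DIR / "NC014062.gb")
        assert dm.intron_count(typha, "clpP") == 2
        assert dm.intron_count(anomochloa, "clpP") == 0
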