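"""Coordinate layer: annotation reading, intron extraction, variant assignment."""

import numpy as np
import pytest

from intronrank.errors import (
    BuildMismatchError,
    MalformedAnnotationError,
    NotFoundError,
    UnusableModelError,
)
from intronrank.gene_model import (
    GeneModel,
    Variant,
    assign_variant,
    extract_introns,
    introns_to_tsv,
    legacy_dhs_label,
    read_gene_model,
)

EXONS = ((100, 200), (300, 400), (500, 600))


def write_bed12(path, name="T1", strand="+"):
    # blocks encode exons (100,200),(300,400),(500,600) in 1-based inclusive
    line = (
        f"chr1\t99\t600\t{name}\t0\t{strand}\t99\t600\t0\t3\t"
        "101,101,101\t0,200,400\n"
    )
    path.write_text(line)
    return path


def write_gff3(path, exons=EXONS, strand="+", with_cds=True):
    lines = ["##gff-version 3"]
    span = (exons[0][0], exons[-1][1])
    lines.append(f"chr1\tsrc\tgene\t{span[0]}\t{span[1]}\t.\t{strand}\t.\tID=G1")
    lines.append(
        f"chr1\tsrc\tmRNA\t{span[0]}\t{span[1]}\t.\t{strand}\t.\tID=T1;Parent=G1"
    )
    for k, (s, e) in enumerate(exons, 1):
        lines.append(f"chr1\tsrc\texon\t{s}\t{e}\t.\t{strand}\t.\tID=e{k};Parent=T1")
        if with_cds:
            lines.append(f"chr1\tsrc\tCDS\t{s}\t{e}\t.\t{strand}\t0\tID=c{k};Parent=T1")
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadGeneModel:
    def test_bed12_blocks_become_one_based_exons(self, tmp_path):
        model = read_gene_model(write_bed12(tmp_path / "g.bed"), "T1", build="hg38")
        assert model.exons == EXONS
        assert model.strand == "+"
        assert (model.cds_start, model.cds_end) == (100, 600)

    def test_gff3_minus_strand_same_exons(self, tmp_path):
        model = read_gene_model(
            write_gff3(tmp_path / "g.gff3", strand="-"), "T1", build="hg38"
        )
        assert model.exons == EXONS
        assert model.strand == "-"

    def test_gff3_and_bed12_agree(self, tmp_path):
        m1 = read_gene_model(write_gff3(tmp_path / "g.gff3"), "T1")
        m2 = read_gene_model(write_bed12(tmp_path / "g.bed"), "T1")
        assert m1.exons == m2.exons

    def test_gene_id_resolves_single_transcript(self, tmp_path):
        model = read_gene_model(write_gff3(tmp_path / "g.gff3"), "G1")
        assert model.transcript_id == "T1"

    def test_overlapping_exons_rejected(self, tmp_path):
        path = write_gff3(tmp_path / "bad.gff3", exons=((100, 200), (150, 400)))
        with pytest.raises(MalformedAnnotationError):
            read_gene_model(path, "T1")

    def test_absent_id_not_found(self, tmp_path):
        with pytest.raises(NotFoundError):
            read_gene_model(write_gff3(tmp_path / "g.gff3"), "NOPE")

    def test_single_exon_unusable(self, tmp_path):
        path = write_gff3(tmp_path / "one.gff3", exons=((100, 200),))
        with pytest.raises(UnusableModelError):
            read_gene_model(path, "T1")


class TestExtractIntrons:
    def test_plus_strand_gaps(self, three_exon_model):
        introns = extract_introns(three_exon_model, {})
        assert [(i.index, i.start, i.end) for i in introns] == [
            (1, 201, 299),
            (2, 401, 499),
        ]

    def test_minus_strand_reverses_indices(self, three_exon_model_minus):
        introns = extract_introns(three_exon_model_minus, {})
        assert [(i.index, i.start, i.end) for i in introns] == [
            (1, 401, 499),
            (2, 201, 299),
        ]

    def test_27_exons_give_26_introns(self):
        exons = tuple((1000 * k, 1000 * k + 100) for k in range(1, 28))
        model = GeneModel("G", "T", "chr7", "+", exons)
        introns = extract_introns(model, {})
        assert len(introns) == 26
        assert [i.index for i in introns] == list(range(1, 27))

    def test_zero_length_gap_warns_and_preserves_index(self):
        model = GeneModel("G", "T", "chr1", "+", ((100, 200), (201, 300), (400, 500)))
        with pytest.warns(UserWarning, match="zero-length"):
            introns = extract_introns(model, {})
        assert [(i.index, i.start, i.end) for i in introns] == [(2, 301, 399)]

    def test_strand_reversal_maps_index_keeps_intervals(self, rng):
        starts = np.cumsum(rng.integers(200, 500, size=10))
        exons = tuple((int(s), int(s + 100)) for s in starts)
        plus = GeneModel("G", "T", "chr1", "+", exons)
        minus = GeneModel("G", "T", "chr1", "-", exons)
        ip = {i.index: (i.start, i.end) for i in extract_introns(plus, {})}
        im = {i.index: (i.start, i.end) for i in extract_introns(minus, {})}
        n = len(ip)
        assert set(ip.values()) == set(im.values())
        for k in ip:
            assert ip[k] == im[n + 1 - k]

    def test_default_legacy_map_applied(self):
        exons = tuple((1000 * k, 1000 * k + 100) for k in range(1, 28))
        introns = extract_introns(GeneModel("G", "T", "chr7", "+", exons))
        legacy = {i.index: i.legacy_index for i in introns if i.legacy_index}
        assert legacy == {12: 11, 24: 21, 26: 23}

    def test_exon_intron_tiling(self, three_exon_model):
        introns = extract_introns(three_exon_model, {})
        span = three_exon_model.span
        exon_len = sum(e - s + 1 for s, e in three_exon_model.exons)
        intron_len = sum(i.length_bp for i in introns)
        assert exon_len + intron_len == span[1] - span[0] + 1


class TestAssignVariant:
    def test_intronic_position(self, three_exon_model):
        introns = extract_introns(three_exon_model, {})
        v = Variant("chr1", 250, "A", "G", build="hg38")
        assert assign_variant(v, introns, three_exon_model) == 1

    def test_exonic_boundary_excluded(self, three_exon_model):
        introns = extract_introns(three_exon_model, {})
        v = Variant("chr1", 200, "A", "G", build="hg38")
        assert assign_variant(v, introns, three_exon_model) is None

    def test_build_mismatch_refused(self, three_exon_model):
        introns = extract_introns(three_exon_model, {})
        v = Variant("chr1", 250, "A", "G", build="hg19")
        with pytest.raises(BuildMismatchError):
            assign_variant(v, introns, three_exon_model)

    def test_other_chromosome_unassigned(self, three_exon_model):
        introns = extract_introns(three_exon_model, {})
        v = Variant("chr2", 250, "A", "G", build="hg38")
        assert assign_variant(v, introns, three_exon_model) is None

    def test_agrees_with_brute_force_scan(self, rng):
        starts = np.cumsum(rng.integers(150, 400, size=15))
        exons = tuple((int(s), int(s + rng.integers(50, 120))) for s in starts)
        model = GeneModel("G", "T", "chr1", "+", exons)
        introns = extract_introns(model, {})
        lo, hi = model.span
        for pos in rng.integers(lo - 50, hi + 50, size=1000):
            v = Variant("chr1", int(pos), "A", "G")
            expected = None
            for i in introns:  # independent linear interval scan
                if i.start <= pos <= i.end:
                    expected = i.index
            assert assign_variant(v, introns) == expected


class TestLegacyDhsLabel:
    @pytest.fixture
    def coding_model(self):
        return GeneModel(
            "G", "T", "chr1", "+", ((100, 200), (300, 400)), cds_start=100,
            cds_end=400,
        )

    def test_first_intron_base(self, coding_model):
        introns = extract_introns(coding_model, {})
        assert legacy_dhs_label(201, coding_model, introns) == "101 + 0.0 kb"

    def test_offset_rounds_to_one_decimal(self, coding_model):
        introns = extract_introns(coding_model, {})
        assert legacy_dhs_label(299, coding_model, introns) == "101 + 0.1 kb"

    def test_first_base_always_zero_offset(self, three_exon_model):
        introns = extract_introns(three_exon_model, {})
        for i in introns:
            label = legacy_dhs_label(i.start, three_exon_model, introns)
            assert label.endswith("+ 0.0 kb")

    def test_minus_strand_counts_from_cds_end(self):
        model = GeneModel(
            "G", "T", "chr1", "-", ((100, 200), (300, 400)), cds_start=100,
            cds_end=400,
        )
        introns = extract_introns(model, {})
        # transcription-order first exon is (300,400): 101 coding bases;
        # first intronic base in transcription order is 299
        assert legacy_dhs_label(299, model, introns) == "101 + 0.0 kb"
        assert legacy_dhs_label(201, model, introns) == "101 + 0.1 kb"

    def test_non_intronic_position_rejected(self, coding_model):
        introns = extract_introns(coding_model, {})
        with pytest.raises(ValueError, match="not intronic"):
            legacy_dhs_label(150, coding_model, introns)

    def test_position_upstream_of_cds_rejected(self):
        model = GeneModel(
            "G", "T", "chr1", "+", ((100, 200), (300, 400)), cds_start=320,
            cds_end=400,
        )
        introns = extract_introns(model, {})
        with pytest.raises(ValueError, match="upstream"):
            legacy_dhs_label(250, model, introns)


def test_intron_table_tsv_round_trip(tmp_path, three_exon_model):
    import pandas as pd

    introns = extract_introns(three_exon_model, {1: 99})
    out = tmp_path / "introns.tsv"
    df = introns_to_tsv(three_exon_model, introns, out)
    back = pd.read_csv(out, sep="\t")
    assert list(back["index"]) == [1, 2]
    assert list(back["length_bp"]) == [99, 99]
    assert back.loc[0, "legacy_index"] == 99
    assert df.shape == back.shape
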