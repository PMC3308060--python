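"""Gene report: refFlat parsing, coverage fixture, translation oracle."""

import numpy as np
import pytest

from exocap.genereport import (
    GeneModel,
    RefFlatParseError,
    coding_effect,
    effect_summary,
    gene_coverage_report,
    most_severe_effect,
    read_refflat,
    simulate_gene_models,
    write_refflat,
)
from exocap.genotype import GenotypeCall
from exocap.intervals import GenomicInterval, IntervalSet
from exocap.simulate import SimulatedGenome, array_to_seq, seq_to_array
from oracles import coding_effect_oracle


def refflat_line(gene="G1", tx="G1.1", chrom="chr1", strand="+",
                 tx_start=100, tx_end=400, cds_start=150, cds_end=350,
                 exons=((100, 200), (250, 400))):
    starts = ",".join(str(s) for s, _ in exons) + ","
    ends = ",".join(str(e) for _, e in exons) + ","
    return "\t".join([gene, tx, chrom, strand, str(tx_start), str(tx_end),
                      str(cds_start), str(cds_end), str(len(exons)),
                      starts, ends])


# ---------------------------------------------------------------------------
# refFlat I/O


def test_read_refflat_clips_exons_to_cds(tmp_path):
    path = tmp_path / "genes.refFlat"
    path.write_text(refflat_line() + "\n")
    (m,) = read_refflat(path)
    assert m.name == "G1" and m.strand == "+"
    # exon 1 clipped at cdsStart=150, exon 2 clipped at cdsEnd=350
    assert [(iv.start, iv.end) for iv in m.cds_exons] == [(150, 200), (250, 350)]
    assert m.cds_length == 150
    assert m.frame_ok


def test_read_refflat_non_coding_transcript(tmp_path):
    path = tmp_path / "g.refFlat"
    path.write_text(refflat_line(cds_start=100, cds_end=100) + "\n")
    (m,) = read_refflat(path)
    assert not m.coding
    assert m.cds_exons == []


def test_read_refflat_errors_name_line_numbers(tmp_path):
    bad_cols = tmp_path / "a.refFlat"
    bad_cols.write_text(refflat_line() + "\n" + "only\tfour\tcols\there\n")
    with pytest.raises(RefFlatParseError, match=":2:"):
        read_refflat(bad_cols)

    bad_count = tmp_path / "b.refFlat"
    line = refflat_line().split("\t")
    line[8] = "3"  # claims 3 exons, lists 2
    bad_count.write_text("\t".join(line) + "\n")
    with pytest.raises(RefFlatParseError, match="exonCount"):
        read_refflat(bad_count)

    bad_int = tmp_path / "c.refFlat"
    line = refflat_line().split("\t")
    line[4] = "xyz"
    bad_int.write_text("\t".join(line) + "\n")
    with pytest.raises(RefFlatParseError, match=":1:"):
        read_refflat(bad_int)


def test_refflat_round_trip(tmp_path):
    models = [
        GeneModel("G1", "G1.1", "chr1", "+",
                  [GenomicInterval("chr1", 150, 200), GenomicInterval("chr1", 250, 350)],
                  tx_start=150, tx_end=350),
        GeneModel("G2", "G2.1", "chr2", "-",
                  [GenomicInterval("chr2", 10, 70)], tx_start=10, tx_end=70),
    ]
    path = tmp_path / "out.refFlat"
    write_refflat(models, path)
    back = read_refflat(path)
    for a, b in zip(models, back):
        assert (a.name, a.transcript, a.chrom, a.strand) == (
            b.name, b.transcript, b.chrom, b.strand
        )
        assert [(iv.start, iv.end) for iv in a.cds_exons] == [
            (iv.start, iv.end) for iv in b.cds_exons
        ]


def test_gene_model_validation():
    with pytest.raises(ValueError, match="strand"):
        GeneModel("G", "G.1", "chr1", "x", [])
    with pytest.raises(ValueError, match="overlapping"):
        GeneModel("G", "G.1", "chr1", "+",
                  [GenomicInterval("chr1", 0, 20), GenomicInterval("chr1", 10, 30)])


# ---------------------------------------------------------------------------
# CDS coordinate mapping


def test_cds_index_round_trip_both_strands():
    exons = [GenomicInterval("chr1", 10, 16), GenomicInterval("chr1", 30, 36)]
    for strand in "+-":
        m = GeneModel("G", "G.1", "chr1", strand, list(exons))
        seen = []
        for pos in list(range(10, 16)) + list(range(30, 36)):
            ci = m.cds_index_of(pos)
            assert ci is not None
            assert m.genomic_position_of(ci) == pos
            seen.append(ci)
        assert sorted(seen) == list(range(12))
        assert m.cds_index_of(9) is None and m.cds_index_of(20) is None
    plus = GeneModel("G", "G.1", "chr1", "+", list(exons))
    minus = GeneModel("G", "G.1", "chr1", "-", list(exons))
    assert plus.cds_index_of(10) == 0
    assert minus.cds_index_of(35) == 0  # translation starts at the high end
    with pytest.raises(IndexError):
        plus.genomic_position_of(12)


# ---------------------------------------------------------------------------
# coverage report


def test_gene_coverage_hand_computed_fixture():
    """Five genes with known targeting/calling fractions."""
    models = [
        # fully targeted, fully called (60 bp)
        GeneModel("FULL", "FULL.1", "chr1", "+", [GenomicInterval("chr1", 0, 60)]),
        # two transcripts collapse to a 90-bp union, 30 bp targeted
        GeneModel("UNION", "UNION.1", "chr1", "+", [GenomicInterval("chr1", 100, 160)]),
        GeneModel("UNION", "UNION.2", "chr1", "+", [GenomicInterval("chr1", 130, 190)]),
        # untargeted gene
        GeneModel("MISSED", "MISSED.1", "chr1", "-", [GenomicInterval("chr1", 300, 360)]),
        # half targeted, quarter called
        GeneModel("HALF", "HALF.1", "chr1", "+", [GenomicInterval("chr1", 400, 480)]),
        # non-coding transcript only
        GeneModel("NC", "NC.1", "chr1", "+", []),
    ]
    target = IntervalSet.from_tuples(
        [("chr1", 0, 60), ("chr1", 100, 130), ("chr1", 400, 440)]
    )
    calls = (
        [GenotypeCall("chr1", p, "A", ("A", "A"), 60.0, 20) for p in range(0, 60)]
        + [GenotypeCall("chr1", p, "A", ("A", "A"), 60.0, 20) for p in range(400, 420)]
    )
    rows = {r.gene: r for r in gene_coverage_report(models, target, calls)}
    assert set(rows) == {"FULL", "UNION", "MISSED", "HALF", "NC"}
    assert rows["FULL"].coding_length == 60
    assert rows["FULL"].pct_targeted == pytest.approx(100.0)
    assert rows["FULL"].pct_genotyped == pytest.approx(100.0)
    assert rows["UNION"].coding_length == 90  # [100,190) union
    assert rows["UNION"].pct_targeted == pytest.approx(100 * 30 / 90)
    assert rows["UNION"].pct_genotyped == pytest.approx(0.0)
    assert rows["MISSED"].pct_targeted == pytest.approx(0.0)
    assert rows["HALF"].coding_length == 80
    assert rows["HALF"].pct_targeted == pytest.approx(50.0)
    assert rows["HALF"].pct_genotyped == pytest.approx(25.0)
    assert rows["NC"].coding_length == 0
    with pytest.raises(ValueError, match="no gene models"):
        gene_coverage_report([], target, calls)


# ---------------------------------------------------------------------------
# coding effects


def genome_from(seq):
    return SimulatedGenome({"chr1": seq_to_array(seq)})


def test_coding_effect_codon_worked_examples():
    # CDS = ATG GGA TAA; GGA->GGG is synonymous (Gly), AAA in a lysine codon:
    seq = "ATGGGATAA"
    genome = genome_from(seq)
    m = GeneModel("G", "G.1", "chr1", "+", [GenomicInterval("chr1", 0, 9)])
    # third base of GGA codon: A->G keeps glycine
    assert coding_effect((5, "A", "G"), m, genome) == "synonymous"
    # first base of GGA: G->G A A -> AGA (arginine), non-synonymous
    assert coding_effect((3, "G", "A"), m, genome) == "non-synonymous"
    # stop-loss counts as non-synonymous
    assert coding_effect((8, "A", "C"), m, genome) == "non-synonymous"
    with pytest.raises(ValueError, match="does not match genome"):
        coding_effect((5, "C", "G"), m, genome)


def test_coding_effect_outside_cds_and_bad_frame():
    seq = "TTATGGGATAACC"
    genome = genome_from(seq)
    m = GeneModel("G", "G.1", "chr1", "+", [GenomicInterval("chr1", 2, 11)])
    assert coding_effect((0, "T", "A"), m, genome) == "non-coding"
    bad = GeneModel("G", "G.1", "chr1", "+", [GenomicInterval("chr1", 2, 10)])
    with pytest.raises(ValueError, match="divisible by 3"):
        coding_effect((4, "G", "A"), bad, genome)


def test_coding_effect_matches_translation_oracle_random():
    """Random spliced minus- and plus-strand models vs the whole-CDS rebuild
    oracle, every CDS position, every alternate base."""
    rng = np.random.default_rng(21)
    letters = "ACGT"
    for _ in range(20):
        seq = "".join(letters[int(rng.integers(4))] for _ in range(120))
        genome = genome_from(seq)
        e1s = int(rng.integers(0, 20))
        e1e = e1s + 3 * int(rng.integers(2, 8))
        e2s = e1e + int(rng.integers(5, 20))
        e2e = e2s + 3 * int(rng.integers(2, 8))
        exons = [(e1s, e1e), (e2s, e2e)]
        strand = "+" if rng.random() < 0.5 else "-"
        m = GeneModel("G", "G.1", "chr1", strand,
                      [GenomicInterval("chr1", s, e) for s, e in exons])
        positions = list(range(e1s, e1e)) + list(range(e2s, e2e)) + [e1e, e2e + 1]
        for pos in positions:
            if pos >= len(seq):
                continue
            ref = seq[pos]
            for alt in letters:
                if alt == ref:
                    continue
                assert coding_effect((pos, ref, alt), m, genome) == (
                    coding_effect_oracle(seq, exons, strand, pos, alt)
                ), (seq, exons, strand, pos, alt)


def test_most_severe_effect_ranking():
    # same variant: synonymous in one transcript, non-coding in another
    seq = "ATGGGATAA"
    genome = genome_from(seq)
    syn = GeneModel("G", "G.1", "chr1", "+", [GenomicInterval("chr1", 0, 9)])
    nc = GeneModel("G", "G.2", "chr1", "+", [GenomicInterval("chr1", 0, 3)])
    assert most_severe_effect((5, "A", "G"), [syn, nc], genome) == "synonymous"
    assert most_severe_effect((3, "G", "A"), [nc, syn], genome) == "non-synonymous"


def test_effect_summary_counts():
    seq = "ATGGGATAA" + "C" * 21
    genome = genome_from(seq)
    m = GeneModel("G", "G.1", "chr1", "+", [GenomicInterval("chr1", 0, 9)])
    calls = [
        GenotypeCall("chr1", 5, "A", ("A", "G"), 90.0, 30),   # het synonymous
        GenotypeCall("chr1", 3, "G", ("A", "A"), 90.0, 30),   # hom non-synonymous
        GenotypeCall("chr1", 20, "C", ("C", "T"), 90.0, 30),  # het non-coding
        GenotypeCall("chr1", 21, "C", ("C", "C"), 90.0, 30),  # hom-ref: ignored
    ]
    out = effect_summary(calls, [m], genome)
    assert out == {
        "het_synonymous": 1, "het_non_synonymous": 0, "het_non_coding": 1,
        "hom_synonymous": 0, "hom_non_synonymous": 1, "hom_non_coding": 0,
    }


# ---------------------------------------------------------------------------
# simulated gene models


def test_simulate_gene_models_frames_and_names(small_experiment):
    design = small_experiment.design
    models = simulate_gene_models(design, exons_per_gene=3, seed=4)
    assert models
    names = [m.name for m in models]
    assert len(set(names)) == len(names)
    covered = 0
    for m in models:
        assert m.frame_ok, m.name
        assert m.cds_length % 3 == 0
        covered += len(m.cds_exons)
    # every target feature lands in exactly one gene (minus frame trimming)
    assert covered == len(design.all_targets)
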