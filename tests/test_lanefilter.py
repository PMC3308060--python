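"""Lane-level steps 1-7: worked examples, boundaries, brute-force oracles."""

import numpy as np
import pytest

from exocap.config import PipelineConfig
from exocap.lanefilter import (
    classify_pair,
    clip_adapters,
    collapse_pair,
    pair_mapping_quality,
    probe_filter,
    read_sam_mates,
    remove_duplicates,
    run_lane,
)
from exocap.intervals import IntervalSet
from exocap.simulate import (
    LibraryProfile,
    TRUSEQ_ADAPTER_R1,
    TRUSEQ_ADAPTER_R2,
    array_to_seq,
    plant_variants,
    revcomp,
    seq_to_array,
    simulate_genome,
    design_capture,
    simulate_lane,
)
from helpers import mate, pair
from oracles import dedup_oracle

RNG = np.random.default_rng(123)


def random_seq(n, rng=RNG):
    return array_to_seq(np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# step 1: adapter clipping


def test_clip_short_insert_removes_adapter():
    insert = seq_to_array(random_seq(50))
    r1 = np.concatenate([insert, seq_to_array(TRUSEQ_ADAPTER_R1)[:26]])
    r2 = np.concatenate([revcomp(insert), seq_to_array(TRUSEQ_ADAPTER_R2)[:26]])
    q1 = np.full(76, 30)
    q2 = np.full(76, 30)
    b1, nq1, b2, nq2, L, clipped = clip_adapters(
        r1, q1, r2, q2, TRUSEQ_ADAPTER_R1, TRUSEQ_ADAPTER_R2
    )
    assert clipped and L == 50
    assert np.array_equal(b1, insert)
    assert np.array_equal(b2, revcomp(insert))
    assert len(nq1) == len(nq2) == 50


def test_clip_tolerates_sequencing_errors_in_overlap():
    insert = seq_to_array(random_seq(60))
    r1 = np.concatenate([insert, seq_to_array(TRUSEQ_ADAPTER_R1)[:16]])
    r2c = insert.copy()
    r2c[10] = ord("A") if chr(r2c[10]) != "A" else ord("C")  # one mismatch
    r2 = np.concatenate([revcomp(r2c), seq_to_array(TRUSEQ_ADAPTER_R2)[:16]])
    *_clipped_reads, L, clipped = clip_adapters(
        r1, np.full(76, 30), r2, np.full(76, 30), TRUSEQ_ADAPTER_R1, TRUSEQ_ADAPTER_R2
    )
    assert clipped and L == 60


def test_no_clip_when_insert_spans_both_reads():
    """Insert 120 < 152: mates overlap mid-insert; nothing to clip but the
    insert length is still inferred."""
    insert = seq_to_array(random_seq(120))
    r1 = insert[:76].copy()
    r2 = revcomp(insert[44:].copy())
    b1, q1, b2, q2, L, clipped = clip_adapters(
        r1, np.full(76, 30), r2, np.full(76, 30), TRUSEQ_ADAPTER_R1, TRUSEQ_ADAPTER_R2
    )
    assert not clipped
    assert L == 120
    assert np.array_equal(b1, r1) and np.array_equal(b2, r2)


def test_no_clip_on_unrelated_reads():
    rng = np.random.default_rng(5)
    r1 = seq_to_array(random_seq(76, rng))
    r2 = seq_to_array(random_seq(76, rng))
    *_reads, L, clipped = clip_adapters(
        r1, np.full(76, 30), r2, np.full(76, 30), TRUSEQ_ADAPTER_R1, TRUSEQ_ADAPTER_R2
    )
    assert not clipped


def test_clip_requires_adapter_flank_verification():
    """A 12-base chance overlap with non-adapter flanks must not trigger a cut."""
    rng = np.random.default_rng(8)
    core = seq_to_array(random_seq(12, rng))
    flank1 = seq_to_array(random_seq(40, rng))  # not adapter-like
    flank2 = seq_to_array(random_seq(40, rng))
    r1 = np.concatenate([core, flank1])
    r2 = np.concatenate([revcomp(core), flank2])
    *_reads, L, clipped = clip_adapters(
        r1, np.full(52, 30), r2, np.full(52, 30), TRUSEQ_ADAPTER_R1, TRUSEQ_ADAPTER_R2
    )
    assert not clipped


# ---------------------------------------------------------------------------
# step 2: pair mapping quality


def test_pair_mapping_quality_is_min_exhaustive():
    for q1 in range(61):
        for q2 in range(61):
            assert pair_mapping_quality(q1, q2) == min(q1, q2)


# ---------------------------------------------------------------------------
# step 3: proper pairs


def fr_pair(span, start=0, chrom="chr1"):
    m1 = mate(chrom=chrom, start=start, seq="A" * 76, strand="+")
    m2 = mate(chrom=chrom, start=start + span - 76, seq="A" * 76, strand="-")
    return pair(m1, m2)


def test_classify_span_boundary_inclusive():
    assert classify_pair(fr_pair(1000)) == "proper"
    assert classify_pair(fr_pair(1001)) == "improper:span"


def test_classify_rejections():
    p = pair(mate(strand="+"), mate(chrom="chr2", start=200, strand="-"))
    assert classify_pair(p) == "improper:different-chrom"
    p = pair(mate(strand="+"), mate(start=200, strand="+"))
    assert classify_pair(p) == "improper:same-strand"
    # reverse-strand mate leftmost: mates point away from each other
    p = pair(mate(start=500, strand="+"), mate(start=0, strand="-"))
    assert classify_pair(p) == "improper:wrong-orientation"


# ---------------------------------------------------------------------------
# step 4: duplicate removal


def test_dedup_matches_brute_force_oracle():
    rng = np.random.default_rng(77)
    for _ in range(30):
        pairs = []
        for i in range(40):
            start = int(rng.choice([0, 50, 100]))
            span = int(rng.choice([150, 200]))
            quals = int(rng.integers(10, 41))
            m1 = mate(start=start, seq="C" * 76, quals=quals, strand="+")
            m2 = mate(start=start + span - 76, seq="C" * 76, quals=quals, strand="-")
            pairs.append(pair(m1, m2, name=f"p{i}"))
        retained, removed = remove_duplicates(pairs)
        assert {p.name for p in retained} == dedup_oracle(pairs)
        assert len(retained) + len(removed) == len(pairs)


def test_dedup_keeps_highest_quality_representative():
    low = pair(mate(quals=20, strand="+"), mate(start=100, quals=20, strand="-"), "low")
    high = pair(mate(quals=35, strand="+"), mate(start=100, quals=35, strand="-"), "high")
    retained, removed = remove_duplicates([low, high])
    assert [p.name for p in retained] == ["high"]
    assert [p.name for p in removed] == ["low"]


# ---------------------------------------------------------------------------
# step 5: probe filter


def test_probe_filter_overlap_boundary():
    probes = IntervalSet.from_tuples([("chr1", 100, 200)])
    # both mates overlap the probe by exactly 20 bases
    ok = pair(
        mate(start=44, seq="A" * 76, strand="+"),  # [44,120) -> 20 in probe
        mate(start=180, seq="A" * 76, strand="-"),  # [180,256) -> 20 in probe
    )
    # shift by one base: 19-base overlap fails
    bad = pair(
        mate(start=43, seq="A" * 76, strand="+"),
        mate(start=181, seq="A" * 76, strand="-"),
    )
    assert probe_filter([ok, bad], probes) == [ok]


def test_probe_filter_requires_exact_mapping_quality():
    probes = IntervalSet.from_tuples([("chr1", 0, 1000)])
    good = pair(mate(mapq=60, strand="+"), mate(start=100, mapq=60, strand="-"))
    degraded = pair(mate(mapq=60, strand="+"), mate(start=100, mapq=59, strand="-"))
    assert probe_filter([good, degraded], probes) == [good]


# ---------------------------------------------------------------------------
# step 6: overlap collapsing


def test_collapse_arithmetic_matches_per_base_oracle():
    """Overlap [20, 30): mixed agreements/disagreements, winner by summed
    overlap quality, checked base by base against a literal reimplementation."""
    rng = np.random.default_rng(4)
    for _ in range(25):
        s1 = random_seq(30, rng)
        s2 = random_seq(30, rng)
        q1 = rng.integers(5, 41, 30)
        q2 = rng.integers(5, 41, 30)
        m1 = mate(start=0, seq=s1, quals=q1, strand="+")
        m2 = mate(start=20, seq=s2, quals=q2, strand="-")
        out, dropped = collapse_pair(pair(m1, m2), quality_cap=60)
        assert dropped == 0
        assert len(out) == 2

        ov1_b, ov1_q = s1[20:], q1[20:]
        ov2_b, ov2_q = s2[:10], q2[:10]
        m1_wins = ov1_q.sum() >= ov2_q.sum()
        wb, wq, lb, lq = (
            (ov1_b, ov1_q, ov2_b, ov2_q) if m1_wins else (ov2_b, ov2_q, ov1_b, ov1_q)
        )
        exp_b, exp_q = [], []
        for k in range(10):
            if wb[k] == lb[k]:
                exp_b.append(wb[k])
                exp_q.append(min(int(wq[k]) + int(lq[k]), 60))
            elif wq[k] >= lq[k]:
                exp_b.append(wb[k])
                exp_q.append(abs(int(wq[k]) - int(lq[k])))
            else:
                exp_b.append(lb[k])
                exp_q.append(abs(int(wq[k]) - int(lq[k])))

        winner = out[0] if m1_wins else out[1]
        loser = out[1] if m1_wins else out[0]
        # winner keeps its full span with the recalibrated overlap segment
        wi = 20 - winner.start
        assert array_to_seq(winner.bases[wi : wi + 10]) == "".join(exp_b)
        assert list(winner.quals[wi : wi + 10]) == exp_q
        # loser is trimmed so the pair covers each base once
        assert len(loser.bases) == 20
        total_span = {
            (m.chrom, p) for m in out for s, e, _ in m.aligned_blocks() for p in range(s, e)
        }
        # [0,30) + [20,50) collapse to [0,50) with no base covered twice
        assert len(total_span) == 50
        assert sum(len(m.bases) for m in out) == 50


def test_collapse_tie_trims_mate2():
    q = np.full(30, 30)
    m1 = mate(start=0, seq="A" * 30, quals=q.copy(), strand="+")
    m2 = mate(start=20, seq="A" * 30, quals=q.copy(), strand="-")
    out, _ = collapse_pair(pair(m1, m2))
    assert out[0].start == 0 and len(out[0].bases) == 30  # mate1 kept whole
    assert out[1].start == 30 and len(out[1].bases) == 20  # mate2 lost its 5' 10


def test_collapse_drops_indel_reads():
    clean = mate(start=0, seq="A" * 76, strand="+")
    indel = mate(start=200, seq="A" * 76, strand="-", cigar="30M2D46M")
    out, dropped = collapse_pair(pair(clean, indel))
    assert dropped == 1
    assert [m.start for m in out] == [0]


def test_collapse_drops_fully_contained_loser():
    m1 = mate(start=0, seq="G" * 50, quals=40, strand="+")
    m2 = mate(start=10, seq="G" * 20, quals=10, strand="-")
    out, _ = collapse_pair(pair(m1, m2))
    assert len(out) == 1 and out[0].start == 0
    assert (out[0].quals[10:30] == 50).all()  # agreement: 40 + 10


def test_collapse_no_overlap_is_identity():
    m1 = mate(start=0, seq="T" * 40, strand="+")
    m2 = mate(start=100, seq="T" * 40, strand="-")
    out, dropped = collapse_pair(pair(m1, m2))
    assert dropped == 0 and len(out) == 2
    assert (out[0].quals == 30).all() and (out[1].quals == 30).all()


# ---------------------------------------------------------------------------
# whole-lane behaviour


@pytest.fixture(scope="module")
def tiny_world():
    genome = simulate_genome({"chr1": 100_000}, seed=21)
    truth = plant_variants(genome, snv_rate=1e-3, seed=22)
    design = design_capture(genome, n_targets=25, seed=23)
    return genome, truth, design


def test_dedup_removal_equals_simulator_duplicate_truth(small_experiment):
    removed = sum(r.stats.n_duplicates_removed for r in small_experiment.lane_results)
    planted = sum(lane.n_duplicates for lane in small_experiment.lanes)
    assert removed == planted


def test_zero_error_lane_reproduces_reference(tiny_world):
    genome, _truth, design = tiny_world
    no_variants = plant_variants(genome, snv_rate=0.0, seed=1)
    profile = LibraryProfile.gel(error_rate=0.0)
    lane = simulate_lane(genome, no_variants, design, profile, 600, seed=9)
    result = run_lane(lane, design, PipelineConfig())
    assert result.stats.n_pairs_final > 0
    seq = genome.sequences["chr1"]
    for m in result.mates:
        for rs, re_, ro in m.aligned_blocks():
            assert np.array_equal(m.bases[ro : ro + (re_ - rs)], seq[rs:re_])


def test_dedup_and_probe_filter_commute_on_simulated_lane(tiny_world):
    genome, truth, design = tiny_world
    profile = LibraryProfile.gel(duplicate_rate=0.15, off_probe_fraction=0.2)
    lane = simulate_lane(genome, truth, design, profile, 800, seed=31)
    R = profile.read_length
    pairs = []
    for p in lane.pairs:
        n_aln = min(R, p.insert_length)
        m1 = mate(
            chrom=p.chrom, start=p.insert_start,
            seq=array_to_seq(p.r1[:n_aln]), quals=p.q1[:n_aln],
            strand="+", mapq=p.mapq,
        )
        m2 = mate(
            chrom=p.chrom, start=p.insert_end - n_aln,
            seq=array_to_seq(revcomp(p.r2[:n_aln])), quals=p.q2[:n_aln][::-1],
            strand="-", mapq=p.mapq,
        )
        pairs.append(pair(m1, m2, name=p.name))
    proper = [p for p in pairs if classify_pair(p) == "proper"]

    a = probe_filter(remove_duplicates(proper)[0], design.probes)
    b = remove_duplicates(probe_filter(proper, design.probes))[0]
    assert [p.name for p in a] == [p.name for p in b]


def test_run_lane_from_files_matches_in_memory(tmp_path, tiny_world):
    genome, truth, design = tiny_world
    profile = LibraryProfile.gel(duplicate_rate=0.1, off_probe_fraction=0.12)
    lane = simulate_lane(genome, truth, design, profile, 800, seed=41)

    mem = run_lane(lane, design, PipelineConfig())

    r1, r2, sam = tmp_path / "r1.fq", tmp_path / "r2.fq", tmp_path / "t.sam"
    lane.write_fastq(r1, r2)
    lane.write_truth_sam(sam)
    file = run_lane((str(r1), str(r2), str(sam)), design, PipelineConfig())

    assert file.stats.n_pairs_in == mem.stats.n_pairs_in
    assert file.stats.n_proper == mem.stats.n_proper
    assert file.stats.n_after_dedup == mem.stats.n_after_dedup
    assert file.stats.n_on_probe == mem.stats.n_on_probe
    assert file.stats.n_pairs_final == mem.stats.n_pairs_final
    assert file.stats.bases_on_target == mem.stats.bases_on_target
    assert len(file.mates) == len(mem.mates)
    for a, b in zip(file.mates, mem.mates):
        assert (a.chrom, a.start, a.strand, a.cigar, a.mapq) == (
            b.chrom, b.start, b.strand, b.cigar, b.mapq
        )
        assert np.array_equal(a.bases, b.bases)
        assert np.array_equal(a.quals, b.quals)


def test_sam_round_trip(tmp_path, tiny_world):
    genome, truth, design = tiny_world
    profile = LibraryProfile.gel()
    lane = simulate_lane(genome, truth, design, profile, 300, seed=51)
    result = run_lane(lane, design, PipelineConfig())
    path = tmp_path / "filtered.sam"
    result.write_sam(path, genome.lengths)
    back = read_sam_mates(path)
    assert len(back) == len(result.mates)
    key = lambda m: (m.chrom, m.start, m.cigar, array_to_seq(m.bases))
    for a, b in zip(sorted(back, key=key), sorted(result.mates, key=key)):
        assert key(a) == key(b)
        assert np.array_equal(a.quals, b.quals)


def test_lane_stats_accounting(small_experiment):
    for res in small_experiment.lane_results:
        s = res.stats
        assert s.n_proper + sum(s.improper_reasons.values()) == s.n_pairs_in
        assert s.n_after_dedup + s.n_duplicates_removed == s.n_proper
        assert s.n_on_probe <= s.n_after_dedup
        assert s.n_pairs_final <= s.n_on_probe
        assert s.bases_on_target <= s.total_final_bases
        assert len(s.insert_lengths) == s.n_on_probe
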