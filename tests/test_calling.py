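"""ME-transcript identification: projection, gene and region assignment."""

import numpy as np
import pytest

from _oracles import (
    brute_force_projection,
    brute_force_region,
    flip_alignment,
    flip_gene,
    random_alignment,
    random_gene_model,
    random_me_projection,
)
from mesplice.calling import (
    GeneIndex,
    assign_gene,
    assign_region,
    call_me_transcripts,
    merge_repeat_fragments,
    project_to_genome,
    select_best_alignment,
)
from mesplice.model import (
    GeneModel,
    MINUS,
    PLUS,
    RepeatAnnotation,
    TranscriptAlignment,
)
from mesplice.simulate import WorldConfig, build_world, simulate_sample


def _aln(tid="t1", strand=PLUS, blocks=((0, 1000, 500),), q_len=None,
         matches=None, mismatches=0, qg=0, tg=0, chrom="chr1"):
    total = sum(b[2] for b in blocks)
    return TranscriptAlignment(
        query_id=tid, query_length=q_len or total, strand=strand,
        target_chrom=chrom, target_size=10**6,
        matches=matches if matches is not None else total,
        mismatches=mismatches, q_gap_count=qg, t_gap_count=tg,
        blocks=tuple(blocks),
    )


class TestSelectBestAlignment:
    def test_single(self):
        a = _aln()
        assert select_best_alignment([a]) is a

    def test_strict_score_order(self):
        lo = _aln(matches=300)
        hi = _aln(matches=480)
        assert select_best_alignment([lo, hi]) is hi

    def test_tie_breaks_by_position(self):
        a = _aln(blocks=((0, 5000, 500),), chrom="chr2")
        b = _aln(blocks=((0, 1000, 500),), chrom="chr2")
        c = _aln(blocks=((0, 9000, 500),), chrom="chr1")
        assert select_best_alignment([a, b, c]) is c  # chr1 < chr2
        assert select_best_alignment([a, b]) is b  # 1000 < 5000

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_best_alignment([])


class TestProjectToGenome:
    def test_single_block_offset(self):
        assert project_to_genome(_aln(), (100, 200)) == [("chr1", 1100, 1200)]

    def test_interval_in_query_gap(self):
        aln = _aln(blocks=((0, 1000, 100), (200, 2000, 100)), q_len=300)
        assert project_to_genome(aln, (110, 190)) == []

    def test_two_block_span_sizes_sum(self):
        aln = _aln(blocks=((0, 1000, 100), (100, 1400, 100)))
        out = project_to_genome(aln, (50, 150))
        assert out == [("chr1", 1050, 1100), ("chr1", 1400, 1450)]
        assert sum(e - s for _, s, e in out) == 100

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            aln = random_alignment(rng)
            lo = int(rng.integers(0, aln.query_length))
            hi = int(rng.integers(lo + 1, aln.query_length + 1))
            assert project_to_genome(aln, (lo, hi)) == brute_force_projection(
                aln, (lo, hi)
            )


def _gene(strand=PLUS, tx=(1000, 2000), cds=(1200, 1800),
          exons=((1000, 1400), (1600, 2000)), symbol="G", acc="NM_1"):
    return GeneModel(
        gene_symbol=symbol, accession=acc, chrom="chr1", strand=strand,
        tx_start=tx[0], tx_end=tx[1], cds_start=cds[0], cds_end=cds[1],
        exon_starts=tuple(s for s, _ in exons),
        exon_ends=tuple(e for _, e in exons),
    )


class TestAssignGene:
    def test_transcript_inside_gene(self):
        g = _gene()
        idx = GeneIndex([g])
        assert assign_gene([("chr1", 1000, 1400)], idx) is g

    def test_majority_exonic_overlap_wins(self):
        a = _gene(symbol="A", acc="NM_A", tx=(1000, 2000),
                  exons=((1000, 2000),), cds=(1100, 1900))
        b = _gene(symbol="B", acc="NM_B", tx=(1950, 3000),
                  exons=((1950, 3000),), cds=(2000, 2900))
        idx = GeneIndex([a, b])
        got = assign_gene([("chr1", 1100, 2000)], idx)
        assert got is a  # 900 bp vs 50 bp

    def test_intergenic_returns_none(self):
        idx = GeneIndex([_gene()])
        assert assign_gene([("chr1", 50000, 50500)], idx) is None

    def test_intronic_only_returns_none(self):
        idx = GeneIndex([_gene()])
        assert assign_gene([("chr1", 1450, 1550)], idx) is None


class TestAssignRegion:
    def test_retained_intron_inside_cds_span(self):
        g = _gene()  # intron 1400-1600 sits inside the 1200-1800 CDS span
        assert assign_region([("chr1", 1450, 1550)], g) == "cds"

    def test_minus_strand_swaps_utrs(self):
        g = _gene(strand=MINUS)
        assert assign_region([("chr1", 1000, 1100)], g) == "three_prime_utr"
        assert assign_region([("chr1", 1850, 1950)], g) == "five_prime_utr"

    def test_majority_straddling_cds_end(self):
        g = _gene(cds=(1200, 1700), exons=((1000, 2000),))
        # 60 bp in the CDS span, 40 bp in the 3' UTR span
        assert assign_region([("chr1", 1640, 1740)], g) == "cds"

    def test_noncoding_gene(self):
        g = _gene(cds=(1000, 1000))
        assert assign_region([("chr1", 1100, 1200)], g) == "noncoding_exonic"

    def test_outside_span_errors(self):
        with pytest.raises(ValueError):
            assign_region([("chr1", 5000, 5100)], _gene())

    def test_oracle_equivalence_randomized(self):
        """Majority-bp label matches a per-base brute-force vote (and the
        documented priority on ties) on randomized gene models."""
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 500:
            gene = random_gene_model(rng)
            proj = random_me_projection(rng, gene)
            try:
                expect, _ = brute_force_region(proj, gene)
            except ValueError:
                with pytest.raises(ValueError):
                    assign_region(proj, gene)
                continue
            assert assign_region(proj, gene) == expect
            checked += 1

    def test_strand_symmetry_under_genome_flip(self):
        """Mirroring the genome (and all annotations) must not change any
        region label: labels are strand-aware."""
        rng = np.random.default_rng(21)
        chrom_len = 10_000
        for _ in range(200):
            gene = random_gene_model(rng)
            proj = random_me_projection(rng, gene)
            flipped_gene = flip_gene(gene, chrom_len)
            flipped_proj = [
                (c, chrom_len - e, chrom_len - s) for c, s, e in proj
            ]
            try:
                expect = assign_region(proj, gene)
            except ValueError:
                continue
            assert assign_region(flipped_proj, flipped_gene) == expect


class TestMergeRepeatFragments:
    def _row(self, begin, end, sub="AluY", orient=PLUS, div=10.0):
        return RepeatAnnotation("t1", begin, end, sub, "SINE", "Alu",
                                div, orient, 100)

    def test_close_fragments_merge(self):
        merged = merge_repeat_fragments(
            [self._row(0, 100, div=10.0), self._row(105, 200, div=20.0)]
        )
        assert len(merged) == 1
        assert (merged[0].target_begin, merged[0].target_end) == (0, 200)
        # length-weighted divergence: (10*100 + 20*95) / 195
        assert merged[0].divergence_pct == pytest.approx(14.87, abs=0.01)

    def test_distant_or_different_do_not_merge(self):
        rows = [
            self._row(0, 100),
            self._row(115, 200),               # gap 15 >= 10
            self._row(300, 400, sub="MIRb"),   # different subfamily
            self._row(401, 500, orient=MINUS),  # different orientation
        ]
        assert len(merge_repeat_fragments(rows)) == 4


class TestCallMeTranscripts:
    def test_short_transcript_not_called(self):
        g = _gene(exons=((1000, 2000),), cds=(1100, 1900))
        idx = GeneIndex([g])
        aln = _aln(blocks=((0, 1000, 250),), q_len=250)
        me = RepeatAnnotation("t1", 10, 110, "AluY", "SINE", "Alu", 8.0)
        assert call_me_transcripts("s", {"t1": 250}, [me], [aln], idx) == []

    def test_other_class_repeat_not_called(self):
        g = _gene(exons=((1000, 2000),), cds=(1100, 1900))
        idx = GeneIndex([g])
        aln = _aln(blocks=((0, 1000, 500),))
        rep = RepeatAnnotation("t1", 10, 60, "(TA)n", "Other",
                               "Simple_repeat", 5.0)
        assert call_me_transcripts("s", {"t1": 500}, [rep], [aln], idx) == []

    def test_planted_events_recovered_exactly(self, small_world):
        sample = simulate_sample(small_world, "TLE_HS", seed=5)
        calls = call_me_transcripts(
            sample.sample_id, sample.lengths, sample.repeats,
            sample.alignments, small_world.gene_index,
        )
        truth = {t.transcript_id: t for t in sample.truth}
        assert {c.transcript_id for c in calls} == set(truth)
        for c in calls:
            t = truth[c.transcript_id]
            assert c.gene_symbol == t.gene_symbol
            assert c.region == t.region
            assert c.genome_intervals == (
                (small_world.genes[0].chrom, t.genome_start, t.genome_end),
            )
            assert c.aligned_fraction == 1.0

    def test_min_length_monotonicity(self, small_world):
        sample = simulate_sample(small_world, "TLE", seed=6)
        args = (sample.sample_id, sample.lengths, sample.repeats,
                sample.alignments, small_world.gene_index)
        counts = [
            len(call_me_transcripts(*args, min_length=m))
            for m in (0, 300, 600, 1200, 5000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_sva_called_in_default_world(self, small_world):
        """The default world plants no SVA, so no SVA call may appear."""
        for seed in range(3):
            sample = simulate_sample(small_world, "TLE_HS", seed=seed)
            calls = call_me_transcripts(
                sample.sample_id, sample.lengths, sample.repeats,
                sample.alignments, small_world.gene_index,
            )
            assert all(c.me.repeat_class != "SVA" for c in calls)
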