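"""Junction probes, read counting, assays, and ORF-impact prediction."""

import numpy as np
import pytest

from mesplice.junctions import (
    assay_gene,
    build_probes,
    compare_assay_groups,
    count_probe_pair,
    count_probe_reads,
    find_divergence_junction,
    predict_orf_impact,
    revcomp,
    spliced_mrna,
)
from mesplice.model import GeneModel
from mesplice.simulate import simulate_junction_reads


class TestFindDivergenceJunction:
    def test_identical_sequences_error(self):
        with pytest.raises(ValueError, match="identical"):
            find_divergence_junction("ACGT" * 20, "ACGT" * 20)

    def test_constructed_prefix(self):
        a = "A" * 250 + "C" * 250
        normal = a + "GGGG"
        me = a + "TTTT"
        assert find_divergence_junction(normal, me) == (500, 500)

    def test_short_common_prefix_error(self):
        with pytest.raises(ValueError, match="ambiguous"):
            find_divergence_junction("ACGTACGTAC" + "G" * 50,
                                     "ACGTACGTAC" + "T" * 50)

    def test_scn1a_like_junction_matches_truth(self, scn_fixture):
        j = find_divergence_junction(scn_fixture.normal_mrna,
                                     scn_fixture.me_transcript)
        assert j == (scn_fixture.junction_offset, scn_fixture.junction_offset)


class TestBuildProbes:
    def test_default_probes_are_20bp(self, scn_fixture):
        j = (scn_fixture.junction_offset,) * 2
        n, m = build_probes(scn_fixture.normal_mrna,
                            scn_fixture.me_transcript, j)
        assert len(n) == len(m) == 20
        assert n[:10] == m[:10] and n[10] != m[10]

    def test_tiny_flank(self):
        a = "A" * 30
        n, m = build_probes(a + "G", a + "T", (30, 30), flank=1)
        assert (n, m) == ("AG", "AT")
        assert n[1] != m[1]

    def test_insufficient_flank_errors(self):
        a = "A" * 25
        with pytest.raises(ValueError):
            build_probes(a + "G", a + "T", (25, 25), flank=10)

    def test_probes_unique_in_their_sources(self, scn_fixture):
        """Brute-force scan: the ME probe occurs exactly once in the genome
        (exon/retained-intron boundary is genomic sequence); the normal
        probe spans a splice junction, so it occurs once in the mRNA and
        never in the genome."""
        j = (scn_fixture.junction_offset,) * 2
        n, m = build_probes(scn_fixture.normal_mrna,
                            scn_fixture.me_transcript, j)
        chrom = scn_fixture.genome[scn_fixture.gene.chrom]
        assert chrom.count(m) + revcomp(chrom).count(m) == 1
        assert chrom.count(n) + revcomp(chrom).count(n) == 0
        assert scn_fixture.normal_mrna.count(n) == 1
        assert scn_fixture.me_transcript.count(m) == 1


class TestCountProbeReads:
    PROBE = "ACGTTGCAACGGTACCATGG"

    def test_no_match(self):
        assert count_probe_reads(self.PROBE, ["TTTT" * 40]) == 0

    def test_reverse_complement_counts(self):
        read = "C" * 30 + revcomp(self.PROBE) + "G" * 30
        assert count_probe_reads(self.PROBE, [read]) == 1

    def test_read_counted_once(self):
        read = self.PROBE + "AA" + self.PROBE
        assert count_probe_reads(self.PROBE, [read]) == 1

    def test_strand_symmetry_of_counting(self, scn_fixture):
        rng = np.random.default_rng(8)
        reads = [seq for _, seq in simulate_junction_reads(
            scn_fixture.normal_mrna, scn_fixture.me_transcript,
            scn_fixture.junction_offset, scn_fixture.junction_offset,
            400, 0.3, rng)]
        j = (scn_fixture.junction_offset,) * 2
        n, m = build_probes(scn_fixture.normal_mrna,
                            scn_fixture.me_transcript, j)
        flipped = [revcomp(r) for r in reads]
        assert count_probe_pair(n, m, reads) == count_probe_pair(n, m, flipped)

    def test_binomial_mixture_recovery(self, scn_fixture):
        rng = np.random.default_rng(9)
        depth, p = 2000, 0.30
        reads = [seq for _, seq in simulate_junction_reads(
            scn_fixture.normal_mrna, scn_fixture.me_transcript,
            scn_fixture.junction_offset, scn_fixture.junction_offset,
            depth, p, rng, paired=False)]
        j = (scn_fixture.junction_offset,) * 2
        n_probe, m_probe = build_probes(scn_fixture.normal_mrna,
                                        scn_fixture.me_transcript, j)
        n_count, m_count = count_probe_pair(n_probe, m_probe, reads)
        sd = np.sqrt(depth * p * (1 - p))
        assert abs(m_count - depth * p) < 3 * sd
        assert abs(n_count - depth * (1 - p)) < 3 * sd


class TestAssayGene:
    def test_rpm_and_rate_arithmetic(self, scn_fixture):
        j = scn_fixture.junction_offset
        n_probe = scn_fixture.normal_mrna[j - 10 : j + 10]
        m_probe = scn_fixture.me_transcript[j - 10 : j + 10]
        reads = [n_probe] * 90 + [m_probe] * 10
        assay = assay_gene(scn_fixture.gene, scn_fixture.normal_mrna,
                           scn_fixture.me_transcript,
                           {"s1": (reads, 10**6, "g")})
        s = assay.samples["s1"]
        assert (s.normal_count, s.me_count) == (90, 10)
        assert s.normal_rpm == 90 and s.me_rpm == 10
        assert s.me_rate == pytest.approx(0.10)

    def test_zero_me_reads(self, scn_fixture):
        j = scn_fixture.junction_offset
        reads = [scn_fixture.normal_mrna[j - 10 : j + 10]] * 5
        assay = assay_gene(scn_fixture.gene, scn_fixture.normal_mrna,
                           scn_fixture.me_transcript,
                           {"s1": (reads, 1000, "g")})
        assert assay.samples["s1"].me_rate == 0.0

    def test_no_junction_reads_undefined_rate(self, scn_fixture):
        assay = assay_gene(scn_fixture.gene, scn_fixture.normal_mrna,
                           scn_fixture.me_transcript,
                           {"s1": (["TTTT" * 40], 1000, "g")})
        assert assay.samples["s1"].me_rate is None

    def test_group_recovery_and_ttest_pattern(self, scn_fixture):
        rng = np.random.default_rng(10)
        planted = {"control": 0.11, "TLE_NC": 0.03, "TLE": 0.27}
        samples = {}
        for grp, rate in planted.items():
            for i in range(6):
                reads = [seq for _, seq in simulate_junction_reads(
                    scn_fixture.normal_mrna, scn_fixture.me_transcript,
                    scn_fixture.junction_offset, scn_fixture.junction_offset,
                    1000, rate, rng)]
                samples[f"{grp}{i}"] = (reads, len(reads), grp)
        assay = assay_gene(scn_fixture.gene, scn_fixture.normal_mrna,
                           scn_fixture.me_transcript, samples)
        for grp, rate in planted.items():
            got = np.mean([s.me_rate for s in assay.samples.values()
                           if s.group == grp])
            assert abs(got - rate) < 0.05
        res = compare_assay_groups(assay)["me_rate"]
        assert res.posthoc_test == "t"
        assert res.pairwise_p[("TLE", "TLE_NC")] < 0.001

    def test_ttest_null_on_identical_rates(self, scn_fixture):
        j = scn_fixture.junction_offset
        n_probe = scn_fixture.normal_mrna[j - 10 : j + 10]
        m_probe = scn_fixture.me_transcript[j - 10 : j + 10]
        reads = [n_probe] * 9 + [m_probe]
        samples = {f"{g}{i}": (reads, 100, g) for g in ("a", "b")
                   for i in range(3)}
        res = compare_assay_groups(assay_gene(
            scn_fixture.gene, scn_fixture.normal_mrna,
            scn_fixture.me_transcript, samples))["me_rate"]
        assert res.pairwise_p[("a", "b")] == 1.0


class TestPredictOrfImpact:
    def _toy_gene(self, intron_first_codon):
        # exon1: 24 bp CDS; intron 30 bp; exon2: 9 bp CDS + stop + 3' UTR
        exon1 = "ATGGCCGCCGCAATGGCCGCCGCA"
        intron = intron_first_codon + ("GCA" * 9)
        exon2 = "GCCGCCGCCTAAGGGGGGGGGG"
        chrom = "C" * 20 + exon1 + intron + exon2 + "C" * 20
        gene = GeneModel(
            gene_symbol="TOY", accession="NM_T", chrom="chrT", strand="+",
            tx_start=20, tx_end=20 + len(exon1) + len(intron) + len(exon2),
            cds_start=20, cds_end=20 + len(exon1) + len(intron) + 12,
            exon_starts=(20, 20 + len(exon1) + len(intron)),
            exon_ends=(20 + len(exon1),
                       20 + len(exon1) + len(intron) + len(exon2)),
        )
        return gene, {"chrT": chrom}, exon1, intron

    def test_immediate_stop_in_retained_intron(self):
        gene, genome, exon1, intron = self._toy_gene("TAA")
        me_tx = exon1 + intron  # retains intron, first retained codon = stop
        imp = predict_orf_impact(me_tx, gene, genome)
        assert imp.premature_stop
        assert imp.normal_protein_length == 11  # 24 + 9 coding bases
        assert imp.divergence_aa_pos == 8  # 24 bp of shared CDS
        assert imp.truncated_tail_aa == imp.normal_protein_length - 8

    def test_in_frame_insertion_without_stop(self):
        gene, genome, exon1, intron = self._toy_gene("GCA")
        # full retained intron (30 bp, multiple of 3, stop-free) re-enters
        # the original frame and continues into exon 2
        exon2 = spliced_mrna(gene, genome)[len(exon1):]
        me_tx = exon1 + intron + exon2
        imp = predict_orf_impact(me_tx, gene, genome)
        assert not imp.premature_stop
        assert imp.truncated_tail_aa == 0

    def test_scn1a_like_truncation(self, scn_fixture):
        imp = predict_orf_impact(scn_fixture.me_transcript, scn_fixture.gene,
                                 scn_fixture.genome)
        assert imp.normal_protein_length == 1980
        assert imp.premature_stop
        assert imp.truncated_tail_aa > 1000
        assert imp.divergence_aa_pos == 673
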