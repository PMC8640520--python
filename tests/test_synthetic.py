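"""Self-consistency of the synthetic world and its emitted files."""

import numpy as np
import pytest

from mesplice import io as mio
from mesplice.calling import call_me_transcripts
from mesplice.frequency import census_genome_mes
from mesplice.simulate import (
    GroupParams,
    WorldConfig,
    build_world,
    make_scn1a_like_fixture,
    simulate_sample,
)


class TestDeterminism:
    def test_same_seed_identical_world(self):
        a = build_world(WorldConfig(seed=42, n_genes=40))
        b = build_world(WorldConfig(seed=42, n_genes=40))
        assert a.digest() == b.digest()
        assert a.genes == b.genes
        assert a.genome_repeats == b.genome_repeats
        assert a.genome["chr1"] == b.genome["chr1"]

    def test_different_seeds_differ(self):
        a = build_world(WorldConfig(seed=1, n_genes=40))
        b = build_world(WorldConfig(seed=2, n_genes=40))
        assert a.digest() != b.digest()

    def test_same_seed_identical_sample(self, small_world):
        s1 = simulate_sample(small_world, "TLE", seed=7, sequences=True,
                             reads=True, transcripts_per_sample=100)
        s2 = simulate_sample(small_world, "TLE", seed=7, sequences=True,
                             reads=True, transcripts_per_sample=100)
        assert s1.repeats == s2.repeats
        assert s1.alignments == s2.alignments
        assert s1.sequences == s2.sequences
        assert s1.reads == s2.reads


class TestWorldStructure:
    def test_zero_genes_is_valid(self):
        w = build_world(WorldConfig(seed=0, n_genes=0))
        assert w.genes == [] and w.chrom_sizes["chr1"] > 0

    def test_census_consistency_with_genome_out(self, small_world, tmp_path):
        small_world.write(tmp_path)
        reread = mio.read_repeatmasker_out(tmp_path / "genome.fa.out")
        census = census_genome_mes(reread)
        truth = small_world.genome_census()
        assert {k: census[k] for k in truth} == truth

    def test_refgene_emission_round_trips(self, small_world, tmp_path):
        small_world.write(tmp_path)
        assert mio.read_refgene(tmp_path / "refGene.txt") == small_world.genes

    def test_no_sva_planted(self, small_world):
        assert all(r.repeat_class != "SVA" for r in small_world.genome_repeats)


class TestSimulateSample:
    def test_unknown_group_errors(self, small_world):
        with pytest.raises(ValueError):
            simulate_sample(small_world, "nope", seed=0)

    def test_zero_retention_rate_yields_no_calls(self):
        cfg = WorldConfig(seed=5, n_genes=40)
        cfg.group_params["null"] = GroupParams(
            n_samples=1, me_retention_rate=0.0)
        w = build_world(cfg)
        s = simulate_sample(w, "null", seed=1)
        calls = call_me_transcripts(s.sample_id, s.lengths, s.repeats,
                                    s.alignments, w.gene_index)
        assert calls == []

    def test_full_retention_single_gene_world(self):
        cfg = WorldConfig(seed=6, n_genes=5,
                          noncoding_gene_fraction=0.0,
                          intron_me_probability=1.0)
        cfg.group_params["all"] = GroupParams(
            n_samples=1, transcripts_per_sample=50, me_retention_rate=1.0)
        w = build_world(cfg)
        s = simulate_sample(w, "all", seed=2)
        calls = call_me_transcripts(s.sample_id, s.lengths, s.repeats,
                                    s.alignments, w.gene_index)
        assert {c.transcript_id for c in calls} == {
            t.transcript_id for t in s.truth
        }
        assert len(s.truth) == 50

    def test_region_mix_recovered(self, small_world):
        rng = np.random.default_rng(9)
        regions = []
        for i in range(12):
            s = simulate_sample(small_world, "TLE_HS", rng=rng,
                                sample_id=f"m{i}")
            calls = call_me_transcripts(s.sample_id, s.lengths, s.repeats,
                                        s.alignments, small_world.gene_index)
            regions.extend(c.region for c in calls
                           if c.region != "noncoding_exonic")
        regions = np.asarray(regions)
        n = len(regions)
        mix = small_world.config.region_mix
        for region, p in mix.items():
            got = float(np.mean(regions == region))
            se = np.sqrt(p * (1 - p) / n)
            assert abs(got - p) < 4 * se + 0.01, (region, got, p)

    def test_truth_rows_match_emitted_files(self, small_world, tmp_path):
        s = simulate_sample(small_world, "control", seed=3, sequences=True,
                            transcripts_per_sample=300)
        s.write(tmp_path)
        reread = mio.read_repeatmasker_out(
            tmp_path / f"{s.sample_id}.fa.out")
        by_tid = {r.target_id: r for r in reread}
        for t in s.truth:
            r = by_tid[t.transcript_id]
            assert (r.target_begin, r.target_end) == (t.tx_begin, t.tx_end)
            assert r.repeat_subfamily == t.subfamily
            assert r.divergence_pct == t.divergence

    def test_sub300_decoys_present_and_filtered(self, small_world):
        s = simulate_sample(small_world, "control", seed=4)
        decoy_ids = {tid for tid, ln in s.lengths.items() if ln < 300}
        assert decoy_ids
        calls = call_me_transcripts(s.sample_id, s.lengths, s.repeats,
                                    s.alignments, small_world.gene_index)
        assert decoy_ids.isdisjoint({c.transcript_id for c in calls})


class TestScnFixture:
    def test_deterministic(self, small_world):
        a = make_scn1a_like_fixture(small_world)
        b = make_scn1a_like_fixture(small_world)
        assert a.normal_mrna == b.normal_mrna
        assert a.me_transcript == b.me_transcript

    def test_geometry(self, scn_fixture):
        assert len(scn_fixture.gene.exon_starts) == 26
        assert scn_fixture.me_annotation.length == 87
        assert scn_fixture.me_annotation.repeat_subfamily == "L1PA2"
        # retained segment appears verbatim at the start of intron 17
        chrom = scn_fixture.genome[scn_fixture.gene.chrom]
        i17_start = scn_fixture.gene.exon_ends[16]
        retained = scn_fixture.me_transcript[scn_fixture.junction_offset:]
        assert chrom[i17_start : i17_start + 87] == retained

    def test_normal_mrna_matches_genome_splice(self, scn_fixture):
        from mesplice.junctions import spliced_mrna
        assert spliced_mrna(scn_fixture.gene, scn_fixture.genome) \
            == scn_fixture.normal_mrna
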