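import numpy as np
import pysam
import pytest

from mtfusion import discover, pipeline, rates, simgen
from mtfusion.seqio import RCRS_LENGTH, revcomp


class TestBuildGenome:
    def test_deterministic_and_mt_length(self, tmp_path):
        g1 = simgen.build_genome({"chr1": 50_000}, seed=7)
        g2 = simgen.build_genome({"chr1": 50_000}, seed=7)
        assert g1.contigs == g2.contigs
        assert g1.mt_len == RCRS_LENGTH
        assert g1.contigs["chr1"] != simgen.build_genome({"chr1": 50_000}, seed=8).contigs["chr1"]

    def test_gc_fraction_bound(self):
        g = simgen.build_genome({"chr1": 1_000_000}, gc=0.5, seed=3)
        s = g.contigs["chr1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert 0.49 <= gc <= 0.51

    def test_pinned_mt_reference_alleles(self):
        g = simgen.build_genome({"chr1": 10_000}, seed=1)
        for pos, base in simgen.DEFAULT_MT_REF_ALLELES.items():
            assert g.mt_seq[pos] == base

    def test_nonpositive_length_errors(self):
        with pytest.raises(ValueError):
            simgen.build_genome({"chr1": 0}, seed=1)


class TestPlantIntegration:
    def test_blunt_length_conservation(self):
        g = simgen.build_genome({"chr1": 50_000}, seed=2)
        spec = simgen.IntegrationSpec("chr1", 20_000, 1_000, 1_500, "+", (0, 0))
        derived, truth = simgen.plant_integration(g, spec)
        assert len(derived) == 50_000 + 500
        assert all(j.mh_len == 0 for j in truth.junctions)

    def test_microhomology_shares_bases(self):
        g = simgen.build_genome({"chr1": 50_000}, seed=2)
        spec = simgen.IntegrationSpec("chr1", 20_000, 1_000, 1_500, "+", (3, 0))
        derived, truth = simgen.plant_integration(g, spec)
        assert len(derived) == 50_000 + 500 - 3
        j1 = truth.junctions[0]
        assert j1.mh_len == 3
        # the homologous run matches both references at the canonical junction
        assert g.contigs["chr1"][j1.nuc_bp - 3:j1.nuc_bp] == g.mt_seq[1_000:1_003]

    def test_full_length_with_deletion(self):
        g = simgen.build_genome({"chr1": 80_000}, seed=2)
        spec = simgen.IntegrationSpec("chr1", 30_000, 7, 16_563, "+", (0, 0), deletion=20_000)
        derived, truth = simgen.plant_integration(g, spec)
        assert len(derived) == 80_000 - 20_000 + 16_556
        assert truth.junctions[0].nuc_bp == 30_000
        assert truth.junctions[1].nuc_bp == 50_000

    def test_wrapping_segment_and_negative_strand(self):
        g = simgen.build_genome({"chr1": 50_000}, seed=4)
        spec = simgen.IntegrationSpec("chr1", 25_000, 16_400, 300, "-", (0, 0))
        derived, truth = simgen.plant_integration(g, spec)
        seg_len = (300 - 16_400) % RCRS_LENGTH
        assert len(derived) == 50_000 + seg_len
        # negative strand: derived carries the reverse complement of the arc
        arc = g.mt_seq[16_400:] + g.mt_seq[:300]
        assert revcomp(arc) in derived

    def test_insertion_respects_mutual_exclusion(self):
        g = simgen.build_genome({"chr1": 50_000}, seed=5)
        with pytest.raises(ValueError):
            simgen.IntegrationSpec("chr1", 20_000, 100, 600, "+", (2, 0),
                                   insertion=("AC", "")).validate()
        spec = simgen.IntegrationSpec("chr1", 20_000, 100, 600, "+", (0, 0),
                                      insertion=("ACGT", ""))
        derived, truth = simgen.plant_integration(g, spec)
        j1 = truth.junctions[0]
        assert j1.mh_len == 0 and len(j1.insertion) == 4

    def test_overlapping_events_error(self):
        g = simgen.build_genome({"chr1": 50_000}, seed=6)
        specs = [simgen.IntegrationSpec("chr1", 20_000, 100, 600, "+", deletion=200),
                 simgen.IntegrationSpec("chr1", 20_100, 700, 1_200, "+")]
        with pytest.raises(simgen.ConstructionError):
            simgen.build_haplotype(g, "chr1", specs, g.mt_seq, "x")


class TestSimulateAlignments:
    def test_deterministic_outputs(self, tmp_path):
        cfg = simgen.ReadSimConfig(mean_depth=10, cmt=10)
        events = [simgen.IntegrationSpec("chr1", 20_000, 1_000, 1_500, "+", (1, 0))]
        a = simgen.simulate_cohort(tmp_path / "a", seed=9, cfg=cfg, events=events,
                                   genome_lengths={"chr1": 60_000})
        b = simgen.simulate_cohort(tmp_path / "b", seed=9, cfg=cfg, events=events,
                                   genome_lengths={"chr1": 60_000})
        assert a.paths["ref"].read_bytes() == b.paths["ref"].read_bytes()
        assert a.paths["tumor"].read_bytes() == b.paths["tumor"].read_bytes()
        assert a.paths["normal"].read_bytes() == b.paths["normal"].read_bytes()

    def test_zero_events_zero_discordant(self, tmp_path):
        cfg = simgen.ReadSimConfig(mean_depth=10, cmt=10)
        sim = simgen.simulate_cohort(tmp_path, seed=9, cfg=cfg, events=[],
                                     genome_lengths={"chr1": 60_000})
        scan = pipeline.scan_sample(sim.paths["tumor"], "MT")
        assert scan.pairs == []

    def test_read_count_matches_depth(self, tmp_path):
        cfg = simgen.ReadSimConfig(mean_depth=30, cmt=2)
        sim = simgen.simulate_cohort(tmp_path, seed=9, cfg=cfg, events=[],
                                     genome_lengths={"chr1": 100_000})
        n = 0
        with pysam.AlignmentFile(str(sim.paths["tumor"])) as af:
            for rec in af:
                if rec.reference_name == "chr1":
                    n += 1
        expected = 30 * 100_000 / 100   # depth * L / read_len
        assert abs(n - expected) <= 2   # two haplotype-wise roundings

    def test_depth_ratio_recovers_cmt(self, small_cohort):
        depth = rates.compute_depth_summary(str(small_cohort.paths["tumor"]), "MT")
        est = rates.estimate_cmt(depth)
        assert abs(est.cmt - 60) / 60 < 0.05

    def test_self_consistency_alignments_match_reference(self, small_cohort):
        """Error-free simulation: every aligned base equals the reference base
        (with the individual's mt polymorphisms applied to the mt contig)."""
        ref = {name: seq for name, seq in small_cohort.genome.contigs.items()}
        ref["MT"] = simgen.apply_variants(ref["MT"], simgen.DEFAULT_MT_VARIANTS)
        checked = 0
        with pysam.AlignmentFile(str(small_cohort.paths["tumor"])) as af:
            for i, rec in enumerate(af):
                if i % 37:      # spot-check a deterministic subsample
                    continue
                seq = rec.query_sequence
                qs, qe = rec.query_alignment_start, rec.query_alignment_end
                assert seq[qs:qe] == ref[rec.reference_name][rec.reference_start:rec.reference_end]
                checked += 1
        assert checked > 1000

    def test_junction_reads_are_softclipped_at_breakpoint(self, small_cohort):
        truth = small_cohort.truth
        j = truth.events[0].junctions[0]       # E1 junction 1, nuclear-left
        found = 0
        with pysam.AlignmentFile(str(small_cohort.paths["tumor"])) as af:
            for rec in af.fetch(j.contig, j.nuc_bp - 200, j.nuc_bp + 200) \
                    if af.has_index() else af:
                if rec.reference_name != j.contig:
                    continue
                ct = rec.cigartuples or []
                if ct and ct[-1][0] == 4 and rec.reference_end == j.nuc_bp:
                    found += 1
        assert found >= 3

    def test_every_somatic_junction_has_5_discordant_pairs(self, small_cohort):
        scan = pipeline.scan_sample(small_cohort.paths["tumor"], "MT")
        clusters = discover.filter_support(
            discover.cluster_pairs(scan.pairs, RCRS_LENGTH), 5)
        for e in small_cohort.truth.somatic_events():
            for j in e.junctions:
                assert any(c.contig == j.contig and c.orientation == j.orientation
                           and c.nuc_start - 600 <= j.nuc_bp <= c.nuc_end + 600
                           for c in clusters), f"no supported cluster for {j}"

    def test_germline_in_both_samples(self, small_cohort):
        for path in (small_cohort.paths["tumor"], small_cohort.paths["normal"]):
            scan = pipeline.scan_sample(path, "MT")
            g1 = next(e for e in small_cohort.truth.events if e.event_id == "G1")
            j = g1.junctions[0]
            near = [p for p in scan.pairs
                    if p.contig == j.contig and abs(p.nuc_pos - j.nuc_bp) < 600]
            assert len(near) >= 2

    def test_error_rate_injects_mismatches(self, tmp_path):
        cfg = simgen.ReadSimConfig(mean_depth=20, cmt=5, error_rate=0.05)
        sim = simgen.simulate_cohort(tmp_path, seed=9, cfg=cfg, events=[],
                                     genome_lengths={"chr1": 50_000})
        ref = sim.genome.contigs["chr1"]
        mism = total = 0
        with pysam.AlignmentFile(str(sim.paths["tumor"])) as af:
            for rec in af:
                if rec.reference_name != "chr1":
                    continue
                aln = rec.query_sequence
                refpart = ref[rec.reference_start:rec.reference_end]
                mism += sum(a != b for a, b in zip(aln, refpart))
                total += len(refpart)
        assert 0.03 < mism / total < 0.07

    def test_mapq0_region_exercised(self, tmp_path):
        cfg = simgen.ReadSimConfig(mean_depth=20, cmt=5,
                                   mapq0_regions=[("chr1", 10_000, 12_000)])
        sim = simgen.simulate_cohort(tmp_path, seed=9, cfg=cfg, events=[],
                                     genome_lengths={"chr1": 50_000})
        mapqs = set()
        with pysam.AlignmentFile(str(sim.paths["tumor"])) as af:
            for rec in af:
                if rec.reference_name == "chr1" and 10_000 <= rec.reference_start < 11_500:
                    mapqs.add(rec.mapping_quality)
        assert 0 in mapqs

    def test_tumor_fraction_bounds(self, tmp_path):
        with pytest.raises(ValueError):
            simgen.simulate_cohort(tmp_path, seed=1, events=[], tumor_fraction=0.0,
                                   genome_lengths={"chr1": 20_000})


class TestTruthSet:
    def test_tsv_roundtrip_lossless(self, small_cohort, tmp_path):
        path = tmp_path / "truth.tsv"
        small_cohort.truth.write(path)
        back = simgen.TruthSet.read(path)
        orig = small_cohort.truth
        assert [e.event_id for e in back.events] == [e.event_id for e in orig.events]
        for a, b in zip(back.junctions, orig.junctions):
            assert (a.event_id, a.side, a.contig, a.nuc_bp, a.mt_bp, a.orientation,
                    a.mh_len, a.mh_seq, a.insertion, a.germline) == \
                   (b.event_id, b.side, b.contig, b.nuc_bp, b.mt_bp, b.orientation,
                    b.mh_len, b.mh_seq, b.insertion, b.germline)

    def test_two_junctions_per_event(self, small_cohort):
        for e in small_cohort.truth.events:
            assert len(e.junctions) == 2
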