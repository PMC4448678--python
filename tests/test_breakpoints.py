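import itertools

import numpy as np
import pytest

from mtfusion import simgen
from mtfusion.breakpoints import (IntegrationEvent, Junction, check_polymorphisms,
                                  collect_candidate_reads, flag_nearby_rearrangements,
                                  pair_junctions, resolve_junction, split_align)
from mtfusion.discover import Cluster, DiscordantPair
from mtfusion.homology import measure_junction
from mtfusion.seqio import AlignedRead, MtAxis, revcomp

MT_LEN = 16_569


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _break_tie(seq, idx, other):
    """Force seq[idx] != other so a constructed split has a unique placement."""
    if seq[idx] == other:
        repl = next(b for b in "ACGT" if b != other)
        seq = seq[:idx] + repl + seq[idx + 1:]
    return seq


def _disjoint_windows(rng, cut_n, cut_m):
    """Random windows engineered so the junction (cut_n | cut_m) is unambiguous."""
    nuc_w, mt_w = rand_seq(rng, 300), rand_seq(rng, 300)
    nuc_w = _break_tie(nuc_w, cut_n, mt_w[cut_m])          # no forward extension
    mt_w = _break_tie(mt_w, cut_m - 1, nuc_w[cut_n - 1])   # no backward extension
    return nuc_w, mt_w


# ---------------------------------------------------------------------------
# split_align
# ---------------------------------------------------------------------------

class TestSplitAlign:
    def test_constructed_split_found_exactly(self):
        rng = np.random.default_rng(0)
        nuc_w, mt_w = _disjoint_windows(rng, 150, 40)
        read = nuc_w[100:150] + mt_w[40:90]
        hit = split_align(read, nuc_w, mt_w, "+-")
        assert hit is not None
        assert (hit.split_i, hit.mismatches) == (50, 0)
        assert (hit.nuc_bp, hit.mt_axis_bp) == (150, 40)
        assert hit.insertion == ""

    def test_substitutions_tolerated(self):
        rng = np.random.default_rng(1)
        nuc_w, mt_w = _disjoint_windows(rng, 150, 40)
        mt_part = list(mt_w[40:90])
        mt_part[10] = "A" if mt_part[10] != "A" else "C"
        mt_part[30] = "A" if mt_part[30] != "A" else "C"
        read = nuc_w[100:150] + "".join(mt_part)
        hit = split_align(read, nuc_w, mt_w, "+-")
        assert hit is not None
        assert (hit.split_i, hit.mismatches, hit.nuc_bp, hit.mt_axis_bp) == (50, 2, 150, 40)

    def test_reverse_complement_read_found(self):
        rng = np.random.default_rng(2)
        nuc_w, mt_w = _disjoint_windows(rng, 150, 40)
        read = revcomp(nuc_w[100:150] + mt_w[40:90])
        hit = split_align(read, nuc_w, mt_w, "+-")
        assert hit is not None and hit.read_orient == "-"
        assert (hit.nuc_bp, hit.mt_axis_bp) == (150, 40)

    def test_mt_first_orientation(self):
        rng = np.random.default_rng(3)
        nuc_w, mt_w = rand_seq(rng, 300), rand_seq(rng, 300)
        mt_w = _break_tie(mt_w, 250, nuc_w[60])            # no prefix extension
        nuc_w = _break_tie(nuc_w, 59, mt_w[249])           # no suffix back-extension
        read = mt_w[200:250] + nuc_w[60:110]
        hit = split_align(read, nuc_w, mt_w, "-+")
        assert hit is not None
        assert (hit.nuc_bp, hit.mt_axis_bp) == (60, 250)

    def test_nontemplated_gap_recovered(self):
        rng = np.random.default_rng(4)
        nuc_w, mt_w = rand_seq(rng, 300), rand_seq(rng, 300)
        ins = "ACGT"
        nuc_w = _break_tie(nuc_w, 140, ins[0])             # prefix cannot absorb the gap
        mt_w = _break_tie(mt_w, 39, ins[-1])               # suffix cannot absorb the gap
        read = nuc_w[100:140] + ins + mt_w[40:96]
        hit = split_align(read, nuc_w, mt_w, "+-")
        assert hit is not None
        assert hit.insertion == ins
        assert (hit.nuc_bp, hit.mt_axis_bp) == (140, 40)

    def test_random_reads_unresolved(self):
        rng = np.random.default_rng(5)
        nuc_w, mt_w = rand_seq(rng, 300), rand_seq(rng, 300)
        n_hits = sum(
            split_align(rand_seq(rng, 100), nuc_w, mt_w, "+-") is not None
            for _ in range(1000))
        assert n_hits == 0

    def test_too_short_read_unresolved(self):
        rng = np.random.default_rng(6)
        nuc_w, mt_w = rand_seq(rng, 300), rand_seq(rng, 300)
        assert split_align(nuc_w[0:15] + mt_w[0:15], nuc_w, mt_w, "+-") is None

    def test_matches_exhaustive_oracle(self):
        """Implementation equals brute force over split points x placements."""
        rng = np.random.default_rng(7)

        def oracle_min_mm(read, wn, wm, nuclear_first, min_seed=10, max_gap=4):
            best = None
            for ro_seq in (read, revcomp(read)):
                n = len(ro_seq)
                pre_w, suf_w = (wn, wm) if nuclear_first else (wm, wn)
                for s in range(min_seed, n - min_seed + 1):
                    for g in range(0, max_gap + 1):
                        j = s + g
                        if n - j < min_seed:
                            continue
                        pre = min(sum(a != b for a, b in zip(ro_seq[:s], pre_w[t:t + s]))
                                  for t in range(len(pre_w) - s + 1))
                        suf = min(sum(a != b for a, b in zip(ro_seq[j:], suf_w[t:t + n - j]))
                                  for t in range(len(suf_w) - (n - j) + 1))
                        if best is None or pre + suf < best:
                            best = pre + suf
            return best

        for trial in range(8):
            wn, wm = rand_seq(rng, 250), rand_seq(rng, 250)
            s = int(rng.integers(15, 40))
            a, b = int(rng.integers(0, 180)), int(rng.integers(0, 180))
            read = list(wn[a:a + s] + wm[b:b + 56 - s])
            for _ in range(int(rng.integers(0, 4))):     # sprinkle mismatches
                pos = int(rng.integers(0, len(read)))
                read[pos] = "ACGT"[(("ACGT".index(read[pos])) + 1) % 4]
            read = "".join(read)
            hit = split_align(read, wn, wm, "+-", min_seed=10, max_gap=4, max_mismatch=6)
            expect = oracle_min_mm(read, wn, wm, True)
            if expect is not None and expect <= 6:
                assert hit is not None and hit.mismatches == expect
            else:
                assert hit is None


# ---------------------------------------------------------------------------
# microhomology measurement
# ---------------------------------------------------------------------------

class TestMicrohomology:
    def test_extension_rule_example(self):
        # nuclear ...AAAC|GTTT..., mt starts GTTA...: junction reads carry AAACGTT,
        # where GTT matches both continuations -> mh 3 by the extension rule
        rng = np.random.default_rng(8)
        nuc = rand_seq(rng, 50) + "AAACGTTT" + rand_seq(rng, 50)
        b = 54   # between C and G
        mt = "GTTA" + rand_seq(rng, 100)
        mt = rand_seq(rng, 30) + mt           # anchor at 30
        axis = MtAxis(mt, "+", 30)
        if axis.base(-1) == "C":              # keep left extension at zero
            mt = mt[:29] + "A" + mt[30:]
            axis = MtAxis(mt, "+", 30)
        m = measure_junction(nuc, b, axis, 0, "L")
        assert m.mh_len == 3
        assert m.mh_seq == "GTT"
        # canonical placement assigns the homology to the nuclear side
        assert (m.nuc_bp, m.mt_axis_bp) == (57, 3)

    def test_matches_bruteforce_overlap_oracle(self):
        rng = np.random.default_rng(9)
        mt = rand_seq(rng, 400)
        for trial in range(200):
            nuc = rand_seq(rng, 120)
            b = int(rng.integers(30, 90))
            t = int(rng.integers(40, 360))
            strand = "+" if rng.integers(2) else "-"
            axis = MtAxis(mt, strand, 200)
            m = measure_junction(nuc, b, axis, t - 200, "L")
            axis_str = "".join(axis.base(i) for i in range(t - 230, t - 200 + 30))
            left_ctx, right_ctx = axis_str[:30], axis_str[30:]
            l = next((k for k in range(20) if nuc[b - 1 - k] != left_ctx[::-1][k]), 20)
            r = next((k for k in range(20) if nuc[b + k] != right_ctx[k]), 20)
            assert m.mh_len == l + r

    def test_mirror_representation_same_length(self):
        """Measuring the junction from the reverse-complement view gives the same mh."""
        rng = np.random.default_rng(10)
        mt = rand_seq(rng, 400)
        for trial in range(100):
            nuc = rand_seq(rng, 120)
            b = int(rng.integers(30, 90))
            strand = "+" if rng.integers(2) else "-"
            axis = MtAxis(mt, strand, int(rng.integers(50, 350)))
            t = int(rng.integers(-20, 20))
            m = measure_junction(nuc, b, axis, t, "L")
            flip = "-" if strand == "+" else "+"
            if strand == "+":
                anchor2 = (axis.base_pos(t) - 1) % len(mt)
            else:
                anchor2 = (axis.base_pos(t) + 1) % len(mt)
            axis2 = MtAxis(mt, flip, anchor2)
            m2 = measure_junction(revcomp(nuc), len(nuc) - b, axis2, 0, "R")
            assert m.mh_len == m2.mh_len


# ---------------------------------------------------------------------------
# junction resolution against planted truth
# ---------------------------------------------------------------------------

def _junction_reads(derived, pos, rng, n=8, rl=100):
    """Synthesize error-free reads spanning a derived-haplotype position."""
    reads = []
    for i in range(n):
        off = int(rng.integers(30, 70))
        start = pos - off
        seq = derived[start:start + rl]
        if int(rng.integers(2)):
            seq = revcomp(seq)
        reads.append(AlignedRead(qname=f"r{i}", contig="chr1", start=max(start, 0),
                                 end=max(start, 0) + rl, strand="+", mapq=60,
                                 cigar=[("M", rl)], mate_contig="chr1", mate_start=0,
                                 mate_strand="-", seq=seq))
    return reads


class TestResolveJunction:
    @pytest.mark.parametrize("mh,ins,strand", [
        ((0, 0), ("", ""), "+"),
        ((4, 0), ("", ""), "+"),
        ((0, 3), ("", ""), "-"),
        ((0, 0), ("ACGT", ""), "+"),
        ((0, 0), ("", "T"), "+"),
    ])
    def test_planted_junctions_recovered_exactly(self, mh, ins, strand):
        g = simgen.build_genome({"chr1": 40_000}, seed=21)
        spec = simgen.IntegrationSpec("chr1", 20_000, 5_000, 6_000, strand, mh, insertion=ins)
        derived, truth = simgen.plant_integration(g, spec)
        rng = np.random.default_rng(22)
        for tj in truth.junctions:
            # derived coordinate of this junction
            dpos = 20_000 if tj.side == 1 else len(derived) - (40_000 - 20_000)
            reads = _junction_reads(derived, dpos, rng)
            cluster = Cluster(contig="chr1", nuc_start=tj.nuc_bp - 200, nuc_end=tj.nuc_bp + 200,
                              mt_start=(tj.mt_bp - 100) % MT_LEN, mt_end=(tj.mt_bp + 100) % MT_LEN,
                              orientation=tj.orientation,
                              members=[DiscordantPair(f"d{i}", "chr1", tj.nuc_bp, tj.orientation[0],
                                                      60, tj.mt_bp, tj.orientation[1], 60)
                                       for i in range(6)])
            rj = resolve_junction(cluster, reads, g)
            assert rj is not None
            got = rj.junction
            assert (got.nuc_bp, got.mt_bp) == (tj.nuc_bp, tj.mt_bp)
            assert got.mh_len == tj.mh_len
            assert got.insertion == tj.insertion
            assert got.split_support >= 5

    def test_no_candidates_unresolved(self):
        g = simgen.build_genome({"chr1": 40_000}, seed=23)
        cluster = Cluster(contig="chr1", nuc_start=10_000, nuc_end=10_200,
                          mt_start=100, mt_end=300, orientation="+-", members=[])
        assert resolve_junction(cluster, [], g) is None


class TestCollectCandidates:
    def test_clipped_reads_near_cluster_collected(self, small_cohort):
        from mtfusion import pipeline
        scan = pipeline.scan_sample(small_cohort.paths["tumor"], "MT")
        tj = small_cohort.truth.events[0].junctions[0]
        cluster = Cluster(contig=tj.contig, nuc_start=tj.nuc_bp - 100, nuc_end=tj.nuc_bp + 100,
                          mt_start=(tj.mt_bp - 100) % MT_LEN, mt_end=(tj.mt_bp + 100) % MT_LEN,
                          orientation=tj.orientation)
        cand = collect_candidate_reads(scan.clipped, cluster, "MT", MT_LEN)
        assert len(cand) >= 3
        assert all(r.clipped >= 20 or r.mate_unmapped for r in cand)

    def test_distance_cutoff(self, small_cohort):
        from mtfusion import pipeline
        scan = pipeline.scan_sample(small_cohort.paths["tumor"], "MT")
        cluster = Cluster(contig="chr1", nuc_start=55_000, nuc_end=55_100,
                          mt_start=100, mt_end=200, orientation="+-")
        cand = collect_candidate_reads(scan.clipped, cluster, "MT", MT_LEN, radius=1000)
        nuclear = [r for r in cand if r.contig == "chr1"]
        assert all(54_000 <= r.end and r.start <= 56_100 for r in nuclear)


# ---------------------------------------------------------------------------
# pairing and SV flags
# ---------------------------------------------------------------------------

def make_junction(contig, nuc_bp, mt_bp, orientation, sample="s"):
    return Junction(contig=contig, nuc_bp=nuc_bp, mt_bp=mt_bp, orientation=orientation,
                    sample=sample)


class TestPairJunctions:
    def test_two_complementary_junctions_one_event(self):
        j1 = make_junction("chr1", 10_000, 2_000, "+-")
        j2 = make_junction("chr1", 10_300, 2_500, "-+")
        events = pair_junctions([j1, j2], MT_LEN)
        assert len(events) == 1
        e = events[0]
        assert len(e.junctions) == 2
        assert (e.seg_start, e.seg_end, e.seg_strand, e.seg_len) == (2_000, 2_500, "+", 500)

    def test_25_junctions_9_pairs_16_events(self):
        junctions = []
        for i in range(9):
            junctions.append(make_junction("chr1", 1_000_000 * i, 1_000 * i, "+-"))
            junctions.append(make_junction("chr1", 1_000_000 * i + 400, 1_000 * i + 300, "-+"))
        for i in range(7):
            junctions.append(make_junction("chr2", 2_000_000 * i, 120 * i, "+-"))
        events = pair_junctions(junctions, MT_LEN)
        assert len(events) == 16
        assert sum(1 for e in events if len(e.junctions) == 2) == 9

    def test_single_junction_event(self):
        events = pair_junctions([make_junction("chr1", 5_000, 100, "+-")], MT_LEN)
        assert len(events) == 1 and len(events[0].junctions) == 1
        assert events[0].seg_len is None

    def test_same_mt_strand_not_paired(self):
        j1 = make_junction("chr1", 10_000, 2_000, "+-")
        j2 = make_junction("chr1", 10_300, 2_500, "--")
        assert len(pair_junctions([j1, j2], MT_LEN)) == 2

    def test_negative_strand_arc(self):
        j1 = make_junction("chr1", 10_000, 6_000, "++")     # nuclear-left, segment '-'
        j2 = make_junction("chr1", 10_200, 5_000, "--")
        (e,) = pair_junctions([j1, j2], MT_LEN)
        assert (e.seg_start, e.seg_end, e.seg_strand, e.seg_len) == (5_000, 6_000, "-", 1_000)

    def test_wrapping_arc_length(self):
        j1 = make_junction("chr1", 10_000, 16_000, "+-")
        j2 = make_junction("chr1", 10_100, 500, "-+")
        (e,) = pair_junctions([j1, j2], MT_LEN)
        assert e.seg_len == (500 - 16_000) % MT_LEN

    def test_distance_cap(self):
        j1 = make_junction("chr1", 0, 2_000, "+-")
        j2 = make_junction("chr1", 2_000_000, 2_500, "-+")
        assert len(pair_junctions([j1, j2], MT_LEN)) == 2


class TestFlagNearbyRearrangements:
    def test_examples_and_bruteforce(self):
        rng = np.random.default_rng(30)
        events = [IntegrationEvent(f"E{i}", "chr1",
                                   [make_junction("chr1", int(p), 100, "+-")])
                  for i, p in enumerate(rng.integers(0, 5_000_000, 40))]
        svs = [("chr1", int(p)) for p in rng.integers(0, 5_000_000, 15)] + [("chr2", 1)]
        flag_nearby_rearrangements(events, svs, window=100_000)
        for e in events:
            expect = any(c == "chr1" and abs(p - e.junctions[0].nuc_bp) <= 100_000
                         for c, p in svs)
            assert e.near_sv == expect

    def test_sv_10kb_away_flagged(self):
        e = IntegrationEvent("E1", "chr1", [make_junction("chr1", 50_000, 0, "+-")])
        flag_nearby_rearrangements([e], [("chr1", 60_000)])
        assert e.near_sv

    def test_empty_sv_list_all_false(self):
        e = IntegrationEvent("E1", "chr1", [make_junction("chr1", 50_000, 0, "+-")])
        flag_nearby_rearrangements([e], [])
        assert not e.near_sv


# ---------------------------------------------------------------------------
# polymorphism concordance
# ---------------------------------------------------------------------------

class TestCheckPolymorphisms:
    def _resolved_with_variant(self, seed, error_rate=0.0):
        g = simgen.build_genome({"chr1": 40_000}, seed=31)
        variants = {15_325: "G"}
        spec = simgen.IntegrationSpec("chr1", 20_000, 15_300, 15_900, "+", (0, 0))
        derived, truth = simgen.plant_integration(g, spec, mt_variants=variants)
        rng = np.random.default_rng(seed)
        reads = _junction_reads(derived, 20_000, rng, n=12)
        if error_rate:
            for r in reads:
                s = list(r.seq)
                for k in range(len(s)):
                    if rng.random() < error_rate:
                        s[k] = "ACGT"[("ACGT".index(s[k]) + 1) % 4]
                r.seq = "".join(s)
        tj = truth.junctions[0]
        cluster = Cluster(contig="chr1", nuc_start=tj.nuc_bp - 100, nuc_end=tj.nuc_bp + 100,
                          mt_start=(tj.mt_bp - 50) % MT_LEN, mt_end=(tj.mt_bp + 50) % MT_LEN,
                          orientation=tj.orientation,
                          members=[DiscordantPair("d", "chr1", tj.nuc_bp, "+", 60, tj.mt_bp, "-", 60)])
        rj = resolve_junction(cluster, reads, g)
        assert rj is not None
        return rj, variants

    def test_planted_variant_matches(self):
        rj, variants = self._resolved_with_variant(seed=32)
        (chk,) = check_polymorphisms(rj, variants, MT_LEN)
        assert chk.status == "match" and chk.observed == "G" and chk.n_reads >= 5

    def test_variant_outside_segment_uncovered(self):
        rj, _ = self._resolved_with_variant(seed=33)
        (chk,) = check_polymorphisms(rj, {8_000: "A"}, MT_LEN)
        assert chk.status == "uncovered" and chk.observed is None

    @pytest.mark.parametrize("seed", range(40, 45))
    def test_majority_robust_to_one_percent_errors(self, seed):
        rj, variants = self._resolved_with_variant(seed=seed, error_rate=0.01)
        (chk,) = check_polymorphisms(rj, variants, MT_LEN)
        assert chk.status == "match"
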