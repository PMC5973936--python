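"""Detection: aligner behaviour, breakpoint resolution, rejection
categories, filters and recovery against simulated truth."""

import numpy as np
import pytest

from circdynamics.core_io import GenomeBundle, ReadPair, Sample, revcomp
from circdynamics.detect import (
    GenomeIndex,
    align_linear,
    detect_experiment,
    extract_anchors,
    filter_repetitive,
    junction_candidates,
)

RNG = np.random.default_rng(1234)
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def rand_seq(n, rng=RNG):
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


def make_circle_genome(circ_len=200, pre_len=300, post_len=300, strand="+",
                       rng=RNG):
    """Bare genome with one planted circle with canonical flanks."""
    pre, circ, post = rand_seq(pre_len, rng), rand_seq(circ_len, rng), \
        rand_seq(post_len, rng)
    left, right = ("AG", "GT") if strand == "+" else ("AC", "CT")
    genome = pre[:-2] + left + circ + right + post[2:]
    s, e = pre_len, pre_len + circ_len
    return genome, circ, s, e


def junction_read(circ, head=60, tail=65):
    """Transcript-sense read crossing the back-splice (plus-strand circle)."""
    return circ[-head:] + circ[:tail]


class TestAnchors:
    def test_anchor_extraction(self):
        seq = rand_seq(100)
        left, right = extract_anchors(seq, 20)
        assert left == seq[:20] and right == seq[80:]

    def test_short_read_skipped(self):
        assert extract_anchors(rand_seq(39), 20) is None

    def test_junction_read_anchors_are_head_to_tail(self):
        genome, circ, s, e = make_circle_genome()
        index = GenomeIndex(GenomeBundle({"c": genome}, []))
        r = junction_read(circ)
        left, right = extract_anchors(r, 20)
        lh = index.map_anchor(left)
        rh = index.map_anchor(right)
        assert lh and rh
        # the 5' anchor lands downstream of the 3' anchor
        assert rh[0][1] < lh[0][1]


class TestLinearAligner:
    def test_exonic_substring_maps_exact(self, small_detected):
        cfg, bundle, truth, reads, index, det = small_detected
        g = next(g for g in bundle.genes if g.gene_id == "G003")
        s, e = g.transcripts[0].exons[0]
        read = bundle.sequences[g.contig][s : s + 100]
        placements = index.map_end_to_end(read)
        assert placements and placements[0].mm == 0

    def test_spliced_junction_read_maps_via_transcript(self, small_detected):
        cfg, bundle, truth, reads, index, det = small_detected
        g = next(g for g in bundle.genes
                 if g.gene_id != "GAS00" and len(g.transcripts[0].exons) > 2)
        tseq = bundle.transcript_sequence(g, g.transcripts[0])
        ex1 = g.transcripts[0].exons[0]
        cut = ex1[1] - ex1[0]  # first splice point in transcript coords
        read = tseq[cut - 50 : cut + 50]
        placements = index.map_end_to_end(read)
        assert any(p.space == "tx" for p in placements)

    def test_backsplice_read_has_no_linear_placement(self):
        genome, circ, s, e = make_circle_genome()
        index = GenomeIndex(GenomeBundle({"c": genome}, []))
        r = junction_read(circ)
        assert index.map_end_to_end(r) == []
        # brute-force: no end-to-end placement with <= 2 mismatches exists
        arr = np.frombuffer(r.encode(), dtype=np.uint8)
        for target in (genome, revcomp(genome)):
            t = np.frombuffer(target.encode(), dtype=np.uint8)
            wins = np.lib.stride_tricks.sliding_window_view(t, len(r))
            assert (wins != arr).sum(axis=1).min() > 2

    def test_total_mapped_counts_each_mate(self):
        genome, circ, s, e = make_circle_genome()
        index = GenomeIndex(GenomeBundle({"c": genome}, []))
        pair = ReadPair("r1", genome[10:110], revcomp(genome[150:250]),
                        "I" * 100, "I" * 100)
        res = align_linear([pair], index)
        assert res.total_mapped_reads == 2

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GenomeIndex(GenomeBundle({}, []))


class TestBreakpointResolution:
    def test_exact_junction_read_accepted_at_true_coordinates(self):
        genome, circ, s, e = make_circle_genome()
        index = GenomeIndex(GenomeBundle({"c": genome}, []))
        ev, status = junction_candidates(junction_read(circ), 1, index)
        assert status == "accepted"
        assert (ev.start, ev.end, ev.strand) == (s, e, "+")

    def test_minus_strand_circle_recovered(self):
        genome, circ, s, e = make_circle_genome(strand="-")
        index = GenomeIndex(GenomeBundle({"c": genome}, []))
        # transcript-sense sequence of the minus-strand circle
        tsense = revcomp(circ)
        ev, status = junction_candidates(junction_read(tsense), 1, index)
        assert status == "accepted"
        assert (ev.start, ev.end, ev.strand) == (s, e, "-")

    def test_gt_to_gc_donor_mutation_rejected_no_gtag(self):
        genome, circ, s, e = make_circle_genome()
        mutated = genome[:e] + "GC" + genome[e + 2 :]
        index = GenomeIndex(GenomeBundle({"c": mutated}, []))
        ev, status = junction_candidates(junction_read(circ), 1, index)
        assert ev is None and status == "no_gtag"

    def test_read_with_two_mismatches_still_accepted(self):
        genome, circ, s, e = make_circle_genome()
        index = GenomeIndex(GenomeBundle({"c": genome}, []))
        r = list(junction_read(circ))
        for pos in (5, 90):
            r[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r[pos]]
        ev, status = junction_candidates("".join(r), 1, index)
        assert status == "accepted" and ev.mm == 2

    def test_three_mismatches_rejected(self):
        genome, circ, s, e = make_circle_genome()
        index = GenomeIndex(GenomeBundle({"c": genome}, []))
        r = list(junction_read(circ))
        for pos in (30, 60, 90):
            r[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r[pos]]
        ev, status = junction_candidates("".join(r), 1, index)
        assert ev is None and status == "too_many_mm"

    def test_duplicated_junction_context_rejected_ambiguous(self):
        genome, circ, s, e = make_circle_genome()
        # second full copy of AG|circle|GT elsewhere: two equal-best
        # breakpoints for the same read
        genome2 = genome + rand_seq(50) + "AG" + circ + "GT" + rand_seq(50)
        index = GenomeIndex(GenomeBundle({"c": genome2}, []))
        ev, status = junction_candidates(junction_read(circ), 1, index)
        assert ev is None and status == "ambiguous"

    def test_strand_conflict_rejected(self):
        genome, circ, s, e = make_circle_genome()
        index = GenomeIndex(GenomeBundle({"c": genome}, []))
        # mate2 presented in mate1 orientation violates dUTP strandedness
        ev, status = junction_candidates(junction_read(circ), 2, index)
        assert ev is None and status == "strand_conflict"
        ev, status = junction_candidates(revcomp(junction_read(circ)), 2,
                                         index)
        assert status == "accepted"


class TestRepetitiveFilter:
    def _detect_single(self, genome, read, extra_pairs=()):
        bundle = GenomeBundle({"c": genome}, [])
        index = GenomeIndex(bundle)
        pairs = [ReadPair("p0", read[0], read[1], "I" * len(read[0]),
                          "I" * len(read[1]))]
        pairs += list(extra_pairs)
        sample = Sample("s1", "rminus", "t0")
        det = detect_experiment({"s1": pairs}, bundle, [sample], index=index)
        return det

    def test_unique_region_call_retained(self):
        genome, circ, s, e = make_circle_genome()
        r1 = junction_read(circ)
        r2 = revcomp(circ[20:120])  # mate inside the circle, antisense
        det = self._detect_single(genome, (r1, r2))
        assert [(c.start, c.end) for c in det.calls] == [(s, e)]

    def test_multi_locus_anchor_dropped_as_repetitive(self):
        genome, circ, s, e = make_circle_genome()
        r1 = junction_read(circ)
        # plant an exact second copy of the read's left anchor far away
        genome2 = genome + rand_seq(30) + r1[:20] + rand_seq(30)
        r2 = revcomp(circ[20:120])
        det = self._detect_single(genome2, (r1, r2))
        assert det.calls == []
        assert det.rejections["s1"]["repetitive"] >= 1

    def test_duplicated_junction_sequence_dropped(self):
        genome, circ, s, e = make_circle_genome()
        junction_40mer = genome[e - 20 : e] + genome[s : s + 20]
        genome2 = genome + rand_seq(33) + junction_40mer + rand_seq(33)
        r1 = junction_read(circ, head=60, tail=65)
        r2 = revcomp(circ[20:120])
        det = self._detect_single(genome2, (r1, r2))
        assert det.calls == []
        assert det.rejections["s1"]["repetitive"] >= 1


class TestMateConsistency:
    def _run(self, genome, r1, r2):
        bundle = GenomeBundle({"c": genome}, [])
        index = GenomeIndex(bundle)
        pairs = [ReadPair("p0", r1, r2, "I" * len(r1), "I" * len(r2))]
        sample = Sample("s1", "rminus", "t0")
        return detect_experiment({"s1": pairs}, bundle, [sample], index=index)

    def test_mate_inside_circle_supports(self):
        genome, circ, s, e = make_circle_genome()
        det = self._run(genome, junction_read(circ), revcomp(circ[30:130]))
        assert len(det.calls) == 1

    def test_mate_far_downstream_rejected(self):
        genome, circ, s, e = make_circle_genome(post_len=400)
        det = self._run(genome, junction_read(circ),
                        revcomp(genome[e + 150 : e + 250]))
        assert det.calls == []
        assert det.rejections["s1"]["mate_inconsistent"] == 1

    def test_both_mates_spanning_count_once(self):
        genome, circ, s, e = make_circle_genome(circ_len=160)
        r1 = junction_read(circ, head=60, tail=65)
        r2 = revcomp(junction_read(circ, head=40, tail=85))
        det = self._run(genome, r1, r2)
        assert len(det.calls) == 1
        assert det.calls[0].junction_reads["s1"] == 1


class TestSimulatedRecovery:
    def test_recall_precision_on_small_simulation(self, small_detected):
        cfg, bundle, truth, reads, index, det = small_detected
        jt = truth.junction_reads
        covered = set(
            jt.groupby("circ_id").size()[lambda s: s >= 5].index)
        truth_keys = {t.key for t in truth.templates
                      if t.circ_id in covered}
        call_keys = {c.key for c in det.calls}
        assert truth_keys <= call_keys
        assert call_keys <= {t.key for t in truth.templates}

    def test_gtag_invariant_rechecked_from_genome(self, small_detected):
        cfg, bundle, truth, reads, index, det = small_detected
        for c in det.calls:
            assert c.check_flanks(bundle.sequences)

    def test_junction_support_conservation(self, small_detected):
        """Called junction reads never exceed simulated spanning fragments."""
        cfg, bundle, truth, reads, index, det = small_detected
        jt = truth.junction_reads
        sim_counts = jt.groupby(["circ_id", "sample_id"]).size()
        for c in det.calls:
            for sid, n in c.junction_reads.items():
                assert n <= sim_counts.get((c.circ_id, sid), 0)

    def test_span_bound_respected(self, small_detected):
        cfg, bundle, truth, reads, index, det = small_detected
        assert all(c.end - c.start <= 100_000 for c in det.calls)
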