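"""Location/base accuracy metrics, consensus calling and SV calling."""

import numpy as np
import pytest

from funnelmap import Mapper, MapParams, make_reference, simulate_reads, PROFILE_2D
from funnelmap.align import Alignment, parse_cigar
from funnelmap.evaluate import (
    base_accuracy,
    consensus_call,
    location_correct,
    summarize,
    sv_call,
    sv_match,
    SVCall,
)
from funnelmap.simulate import SVEvent, TrueOrigin, inject_svs


def mkaln(pos, cigar, strand="+", seq="", rid="r"):
    return Alignment(
        read_id=rid,
        ref_id=0,
        ref_name="ref",
        strand=strand,
        pos=pos,
        cigar=parse_cigar(cigar),
        edit_distance=0,
        seq=seq,
    )


def mktruth(start, end, strand="+", base_map=None):
    return TrueOrigin(
        ref_id=0,
        ref_name="ref",
        strand=strand,
        start=start,
        end=end,
        base_map=base_map if base_map is not None else np.arange(start, end),
    )


class TestLocationCorrect:
    def test_exact_position(self):
        assert location_correct(mkaln(1000, "100="), mktruth(1000, 1100))

    def test_clip_adjustment(self):
        # clipped 30 bases; reported pos shifted by +30 compensates exactly
        aln = mkaln(1030, "30S70=")
        assert location_correct(aln, mktruth(1000, 1100))

    def test_tolerance_boundary(self):
        assert location_correct(mkaln(1050, "100="), mktruth(1000, 1100), tol=50)
        assert not location_correct(mkaln(1051, "100="), mktruth(1000, 1100), tol=50)

    def test_strand_must_match(self):
        assert not location_correct(mkaln(1000, "100=", strand="-"), mktruth(1000, 1100))


class TestBaseAccuracy:
    def test_perfect_alignment_all_correct(self):
        aln = mkaln(500, "100=")
        correct, aligned = base_accuracy(aln, mktruth(500, 600))
        assert (correct, aligned) == (100, 100)

    def test_fully_clipped_read_contributes_nothing(self):
        aln = mkaln(500, "100S")
        assert base_accuracy(aln, mktruth(500, 600)) == (0, 0)

    def test_shifted_alignment_all_wrong(self):
        aln = mkaln(505, "100=")
        correct, aligned = base_accuracy(aln, mktruth(500, 600))
        assert (correct, aligned) == (0, 100)

    def test_oracle_per_base_comparison(self, rng):
        """CIGAR walk agrees with an explicit per-base reconstruction."""
        # truth: read of 50 bases, one insertion at 10, deletion at ref 525
        base_map = np.array(
            [500 + i for i in range(10)] + [-1] + [510 + i for i in range(10)]
            + [521 + i for i in range(29)]
        )
        truth = mktruth(500, 550, base_map=base_map)
        aln = mkaln(500, "10=1I10=1D29=")
        correct, aligned = base_accuracy(aln, truth)
        # explicit reconstruction of where the aligner placed each base
        placed = {}
        qpos, rpos = 0, 500
        for op, ln in aln.cigar:
            for _ in range(ln):
                if op in "=XM":
                    placed[qpos] = rpos
                    qpos += 1
                    rpos += 1
                elif op == "I":
                    qpos += 1
                elif op == "D":
                    rpos += 1
        expect = sum(
            1 for q, r in placed.items() if 0 <= q < len(base_map) and base_map[q] == r
        )
        assert correct == expect == 49

    def test_reverse_strand_orientation(self):
        # '-'-strand read: original read position j was simulated from
        # reference position 519 - j, and SAM order is the reverse of the
        # original read, so a perfect alignment at pos 500 places everything
        # correctly
        base_map = np.arange(519, 499, -1)
        truth = mktruth(500, 520, strand="-", base_map=base_map)
        aln = mkaln(500, "20=", strand="-")
        correct, aligned = base_accuracy(aln, truth)
        assert (correct, aligned) == (20, 20)


class TestSummarize:
    def test_count_identity(self):
        alns = {"a": [mkaln(100, "50=", rid="a")], "b": []}
        truths = {"a": mktruth(100, 150), "b": mktruth(0, 50)}
        s = summarize(alns, truths)
        assert s.mapped_reads == 1 and s.correct_reads == 1 and s.total_reads == 2
        assert s.location_precision == 1.0 and s.location_recall == 0.5
        assert s.correct_reads == round(s.location_precision * s.mapped_reads)


class TestConsensus:
    def test_unanimous_pileup_recovers_reference(self):
        ref = "ACGTACGTACGTACGTACGT"
        alns = [mkaln(0, "20=", seq=ref, rid=f"r{i}") for i in range(30)]
        cons, calls = consensus_call(alns, ref, min_cov=20)
        assert cons == ref
        assert all(c["call"] is not None for c in calls)

    def test_low_coverage_positions_uncalled(self):
        ref = "ACGTACGTAC"
        alns = [mkaln(0, "10=", seq=ref, rid=f"r{i}") for i in range(19)]
        cons, calls = consensus_call(alns, ref, min_cov=20)
        assert cons == "N" * 10

    def test_majority_deletion_dropped_from_consensus(self):
        ref = "ACGTACGTAC"
        alns = [mkaln(0, "4=2D4=", seq=ref[:4] + ref[6:], rid=f"r{i}") for i in range(25)]
        cons, _ = consensus_call(alns, ref, min_cov=20)
        assert cons == ref[:4] + ref[6:]

    def test_majority_insertion_emitted(self):
        ref = "ACGTACGTAC"
        seq = ref[:5] + "TTT" + ref[5:]
        alns = [mkaln(0, "5=3I5=", seq=seq, rid=f"r{i}") for i in range(25)]
        cons, _ = consensus_call(alns, ref, min_cov=20)
        assert cons == seq

    def test_tie_calls_reference_base(self):
        ref = "AAAA"
        half1 = [mkaln(0, "4=", seq="AAAA", rid=f"a{i}") for i in range(10)]
        half2 = [mkaln(0, "4=", seq="CAAA", rid=f"b{i}") for i in range(10)]
        cons, _ = consensus_call(half1 + half2, ref, min_cov=5)
        assert cons == "AAAA"

    def test_idempotent_on_single_repeated_read(self):
        ref = "ACGTACGTACGTACGTACGT"
        seq = ref[:10] + ref[11:]  # one deletion
        alns = [mkaln(0, "10=1D9=", seq=seq, rid=f"r{i}") for i in range(30)]
        cons, _ = consensus_call(alns, ref, min_cov=20)
        assert cons == seq

    def test_consensus_errors_fall_vs_per_read_error_rate(self):
        """A deep 2D pileup corrects per-read errors by >= 10x."""
        name, ref, _ = make_reference(20_000, seed=31)
        m = Mapper([(name, ref)])
        reads = simulate_reads(ref, 20_000 * 35 // 2500, (2000, 3000), PROFILE_2D, seed=7, ref_name=name)
        alns = []
        for rid, seq, _ in reads:
            alns.extend(a for a in m.map_read(rid, seq) if not a.secondary)
        cons, calls = consensus_call(alns, ref, min_cov=20)
        per_read_error = 0.17  # 2D preset total error per step
        errors = 0
        called = 0
        for c in calls:
            if c["call"] is None:
                continue
            if isinstance(c["pos"], int):
                called += 1
                if c["call"] != ref[c["pos"]]:
                    errors += 1  # wrong base or spurious deletion
            else:
                errors += 1  # spurious insertion between positions
        assert called > 0.8 * len(ref)  # only coverage-taper edges uncalled
        assert errors / called < per_read_error / 10


def test_consensus_fasta_round_trip(tmp_path):
    from funnelmap.evaluate import write_consensus_fasta
    from funnelmap.io_sam import read_fasta

    seq = "ACGT" * 60
    p = tmp_path / "cons.fa"
    write_consensus_fasta(str(p), "cons", seq)
    rec = next(iter(read_fasta(str(p))))
    assert rec.id == "cons" and rec.sequence == seq


class TestSvCall:
    def test_no_long_runs_no_calls(self):
        alns = [mkaln(i * 10, "200=", rid=f"r{i}") for i in range(30)]
        assert sv_call(alns, 1000) == []

    def test_clean_deletion_called(self):
        # 30 spanning reads all report a 500 bp deletion at 1000
        alns = [mkaln(800, "200=500D200=", rid=f"r{i}") for i in range(30)]
        calls = sv_call(alns, 3000)
        assert len(calls) == 1
        c = calls[0]
        assert c.kind == "deletion"
        assert c.size == 500
        assert abs(c.start - 1000) <= 25 and abs(c.end - 1500) <= 25
        assert c.n_reads == 30

    def test_minimum_read_support(self):
        alns = [mkaln(800, "200=500D200=", rid=f"r{i}") for i in range(4)]
        alns += [mkaln(0, "3000=", rid=f"bg{i}") for i in range(40)]
        assert sv_call(alns, 3000) == []

    def test_fragmented_runs_from_one_read_aggregate(self):
        # each read splits its 500 bp deletion into 300 + 200
        alns = [mkaln(800, "200=300D5=200D200=", rid=f"r{i}") for i in range(30)]
        calls = sv_call(alns, 3000)
        assert len(calls) == 1
        assert calls[0].size == 500

    def test_permutation_invariant(self, rng):
        alns = [mkaln(800, "200=500D200=", rid=f"r{i}") for i in range(30)]
        calls1 = sv_call(alns, 3000)
        perm = [alns[i] for i in rng.permutation(len(alns))]
        calls2 = sv_call(perm, 3000)
        assert [(c.kind, c.start, c.end, c.size) for c in calls1] == [
            (c.kind, c.start, c.end, c.size) for c in calls2
        ]


class TestSvMatch:
    def _truth(self, expect, mstart, mend, size):
        kind = "insertion" if expect == "deletion" else "deletion"
        return {"event": SVEvent(kind, 0, size), "mstart": mstart, "mend": mend, "expect": expect}

    def test_identical_call_matches(self):
        calls = [SVCall("deletion", 1000, 1500, 500, 10, 0.5)]
        truth = [self._truth("deletion", 1000, 1500, 500)]
        assert sv_match(calls, truth) == (1.0, 1.0, 1)

    def test_size_off_by_factor_two_rejected(self):
        calls = [SVCall("deletion", 1000, 1100, 100, 10, 0.5)]
        truth = [self._truth("deletion", 1000, 1200, 200)]
        p, r, tp = sv_match(calls, truth)
        assert tp == 0

    def test_jitter_within_margins_always_matches(self, rng):
        for _ in range(50):
            size = int(rng.integers(100, 4000))
            # start/end jitter within +/- size/10 keeps all three 25% margins
            ds = int(rng.integers(-size // 10, size // 10))
            de = int(rng.integers(-size // 10, size // 10))
            calls = [SVCall("deletion", 5000 + ds, 5000 + size + de, size + de - ds, 10, 0.5)]
            truth = [self._truth("deletion", 5000, 5000 + size, size)]
            assert sv_match(calls, truth)[2] == 1, (size, ds, de)

    def test_one_to_one_greedy(self):
        calls = [
            SVCall("deletion", 1000, 1500, 500, 10, 0.5),
            SVCall("deletion", 1010, 1510, 500, 10, 0.5),
        ]
        truth = [self._truth("deletion", 1000, 1500, 500)]
        p, r, tp = sv_match(calls, truth)
        assert tp == 1 and p == 0.5 and r == 1.0
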