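"""Final alignment engines, MAPQ, rescoring and E-values."""

import math

import numpy as np
import pytest

from funnelmap.align import (
    EValueParams,
    alignment_score,
    ambiguity_count,
    anchored_alignment,
    cigar_counts,
    evalue,
    gotoh_semiglobal,
    mapping_quality,
    myers_semiglobal,
    parse_cigar,
    query_span,
    reference_span,
)
from funnelmap.anchors import region_anchors
from funnelmap.chain import lcsk_chain
from funnelmap.refine import RegionScore
from tests.conftest import random_dna


def edit_distance_dp(read, region):
    """Plain quadratic DP for semi-global (infix) edit distance; the oracle."""
    n, m = len(read), len(region)
    prev = np.zeros(m + 1, dtype=int)  # free start gap on the region
    for i in range(1, n + 1):
        cur = np.empty(m + 1, dtype=int)
        cur[0] = i
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (read[i - 1] != region[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return int(prev.min())  # free end gap on the region


def affine_score_dp(read, region, match=5, mismatch=-4, gap_open=-8, gap_extend=-6):
    """Affine-gap semi-global DP (free region end gaps); score oracle.

    Gap cost convention: open + extend per gap base.
    """
    NEG = -(10**9)
    n, m = len(read), len(region)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iq = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in region (read consumed)
    Dq = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (region consumed)
    M[0] = [0] * (m + 1)  # free leading region gap
    for i in range(1, n + 1):
        Iq[i][0] = gap_open + gap_extend * i
        for j in range(0, m + 1):
            if j > 0:
                sub = match if read[i - 1] == region[j - 1] else mismatch
                best_prev = max(M[i - 1][j - 1], Iq[i - 1][j - 1], Dq[i - 1][j - 1])
                if best_prev > NEG:
                    M[i][j] = best_prev + sub
                Dq[i][j] = max(
                    max(M[i][j - 1], Iq[i][j - 1]) + gap_open + gap_extend,
                    Dq[i][j - 1] + gap_extend,
                )
            open_from = max(M[i - 1][j], Dq[i - 1][j])
            if open_from > NEG:
                Iq[i][j] = max(Iq[i][j], open_from + gap_open + gap_extend)
            if Iq[i - 1][j] > NEG:
                Iq[i][j] = max(Iq[i][j], Iq[i - 1][j] + gap_extend)
    return max(max(M[n]), max(Iq[n]), max(Dq[n]))  # free trailing region gap


class TestMyersSemiglobal:
    def test_identity(self, rng):
        read = random_dna(rng, 50)
        core = myers_semiglobal(read, read)
        assert core.edit_distance == 0
        assert core.cigar == [("=", 50)]
        assert core.pos == 0

    def test_single_mismatch(self):
        core = myers_semiglobal("ACGT", "AGGT")
        assert core.edit_distance == 1

    def test_read_infix_of_region(self, rng):
        region = random_dna(rng, 200)
        core = myers_semiglobal(region[60:140], region)
        assert core.edit_distance == 0
        assert core.pos == 60

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 100))
            read = random_dna(rng, n)
            region = random_dna(rng, int(rng.integers(n, 120)))
            core = myers_semiglobal(read, region)
            assert core.edit_distance == edit_distance_dp(read, region)
            assert query_span(core.cigar) == len(read)

    def test_cigar_consistent_with_edit_distance(self, rng):
        read, region = random_dna(rng, 60), random_dna(rng, 80)
        core = myers_semiglobal(read, region)
        c = cigar_counts(core.cigar)
        assert c["X"] + c["I"] + c["D"] == core.edit_distance


class TestGotohSemiglobal:
    def test_identity(self, rng):
        read = random_dna(rng, 40)
        core = gotoh_semiglobal(read, read)
        assert core.edit_distance == 0
        assert query_span(core.cigar) == 40

    def test_single_gap(self):
        core = gotoh_semiglobal("ACGTACGT", "ACGTTTACGT")
        c = cigar_counts(core.cigar)
        assert c["D"] == 2 and c["gaps"] == 1

    def test_matches_affine_dp_oracle(self, rng):
        params = EValueParams()
        for _ in range(25):
            n = int(rng.integers(5, 40))
            read = random_dna(rng, n)
            region = random_dna(rng, int(rng.integers(n, 60)))
            core = gotoh_semiglobal(read, region, params)
            got = alignment_score(core.cigar, params)
            assert got == affine_score_dp(read, region)


class TestAnchoredAlignment:
    def _chain(self, read, region):
        return lcsk_chain(region_anchors(read, region, k=6, l=9))

    def test_single_cluster_equals_plain_alignment(self, rng):
        read = random_dna(rng, 300)
        region = random_dna(rng, 50) + read + random_dna(rng, 50)
        chain = self._chain(read, region)
        anchored = anchored_alignment(read, region, chain)
        plain = myers_semiglobal(read, region)
        assert anchored.pos == plain.pos
        assert anchored.edit_distance == plain.edit_distance

    def test_reference_gap_spanned_as_single_deletion_run(self, rng):
        # region carries 500 novel bases between the two read halves
        left, right = random_dna(rng, 400), random_dna(rng, 400)
        insert = random_dna(rng, 500)
        read = left + right
        region = left + insert + right
        chain = self._chain(read, region)
        core = anchored_alignment(read, region, chain)
        d_runs = [n for op, n in core.cigar if op == "D"]
        assert d_runs, "expected a deletion run"
        assert max(d_runs) >= 450  # within 10% of the 500 bp event

    def test_small_cluster_discarded_falls_back(self, rng):
        from funnelmap.align import _cluster_anchors

        read = random_dna(rng, 2000)
        region = random_dna(rng, 60) + read[:25] + random_dna(rng, 3000)
        chain = self._chain(read, region)
        clusters = _cluster_anchors(chain, len(read), 0.45) if chain.anchors else []
        # a 25-base cluster is below both the 30-base floor and 2% of 2 kb
        assert clusters == []

    def test_query_bases_conserved(self, rng):
        read = random_dna(rng, 500)
        region = random_dna(rng, 30) + read[:200] + random_dna(rng, 700) + read[300:]
        chain = self._chain(read, region)
        core = anchored_alignment(read, region, chain)
        assert query_span(core.cigar) == len(read)


class TestAmbiguity:
    def mk_scores(self, kmers):
        out = []
        for i, k in enumerate(kmers):
            s = RegionScore(n_kmers=k)
            s.f = 1.0 - 0.01 * i  # first entry has max f
            out.append(s)
        return out

    def test_single_region(self):
        assert ambiguity_count(self.mk_scores([50]))[0] == 1

    def test_threshold_at_95_percent(self):
        n_a, sel = ambiguity_count(self.mk_scores([100, 96, 50]), F=0.05)
        assert n_a == 2 and sel == [0, 1]

    def test_f_one_counts_everything(self):
        assert ambiguity_count(self.mk_scores([100, 1, 7]), F=1.0)[0] == 3


class TestMappingQuality:
    def test_unique_mapping_caps_at_40(self):
        assert mapping_quality(1) == 40

    def test_two_way_ambiguity(self):
        assert mapping_quality(2) == 3

    def test_limit_to_zero(self):
        assert mapping_quality(10_000) == 0

    def test_invalid(self):
        with pytest.raises(ValueError):
            mapping_quality(0)


class TestScoringAndEvalue:
    def test_perfect_match_score(self):
        assert alignment_score(parse_cigar("100=")) == 500

    def test_mismatch_and_gap_arithmetic(self):
        # 97 matches, 1 mismatch, one 2 bp gap: 5*97 - 4 - 8 - 6*2 = 461
        assert alignment_score(parse_cigar("50=1X47=2I")) == 461

    def test_extended_cigar_required(self):
        with pytest.raises(ValueError):
            alignment_score(parse_cigar("100M"))

    def test_doubling_reference_length_doubles_evalue(self):
        z1 = evalue(400, 100, 10_000)
        z2 = evalue(400, 100, 20_000)
        assert z2 == pytest.approx(2 * z1)

    def test_nonpositive_score_no_significance(self):
        assert evalue(0, 100, 1000) == 100 * 1000

    def test_evalue_decreases_with_score(self):
        zs = [evalue(s, 100, 10_000) for s in (50, 100, 200, 400)]
        assert zs == sorted(zs, reverse=True)
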