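"""Final alignment, mapping quality and E-value (stage V).

The winning region is aligned with one of three engines:

* ``myers`` (default) — Myers' bit-vector edit-distance alignment, semi-global
  (whole read consumed, free gaps at the region ends), via edlib;
* ``gotoh`` — affine-gap semi-global alignment (match 5, mismatch -4, gap
  open -8, gap extend -6 by default);
* ``anchor`` — anchored mode: chained anchors are grouped into clusters
  (neighbours join when the read-gap/region-gap imbalance ``|dq - dt| /
  max(dq, dt)`` is below ``e/2``; clusters with fewer than max(30, 2% of the
  read length) bases are discarded), segments within and between clusters are
  aligned with the bit-vector engine, and read-end extensions are aligned
  without end-gap penalty.  Anchored mode lets a single alignment span a
  large insertion or deletion as one long CIGAR run.

Mapping quality follows from the ambiguity count ``N_a`` — the number of
candidate regions whose covered-kmer count is within a factor ``(1 - F)`` of
the best region's: the wrong-mapping probability is taken as
``p = max(1 - 1/N_a, 1e-4)`` and ``MAPQ = round(-10 log10 p)``, capped at 40.

Each alignment is rescored (match 5, mismatch -4, gap open -8, gap extend -6
per gap base) and a BLAST-style E-value is computed from precalculated
Gumbel parameters; it is emitted as the ``ZE`` SAM tag.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import edlib

from .anchors import Anchor
from .chain import Chain
from .refine import RegionScore

_CIG_RE = re.compile(r"(\d+)([=XIDMS])")

Cigar = list[tuple[str, int]]


@dataclass
class EValueParams:
    """Gumbel parameters and rescoring scheme for the BLAST-style E-value."""

    lam: float = 0.192
    K: float = 0.176
    match: int = 5
    mismatch: int = -4
    gap_open: int = -8
    gap_extend: int = -6


@dataclass
class AlignmentCore:
    """CIGAR + edit distance + region-local start of one alignment."""

    cigar: Cigar
    edit_distance: int
    pos: int


@dataclass
class Alignment:
    """A finished read-to-reference alignment ready for SAM output."""

    read_id: str
    ref_id: int
    ref_name: str
    strand: str
    pos: int  # 0-based leftmost reference coordinate
    cigar: Cigar
    edit_distance: int
    score: int = 0  # AS, rescored
    mapq: int = 0
    evalue: float = 0.0
    f: float = 0.0
    n_kmers: int = 0
    N_a: int = 1
    seq: str = ""  # read in reference-forward orientation
    qual: str | None = None
    secondary: bool = False


def parse_cigar(s: str) -> Cigar:
    return [(op, int(n)) for n, op in _CIG_RE.findall(s)]


def cigar_to_string(cigar: Cigar, extended: bool = True) -> str:
    if not extended:
        cigar = collapse_matches(cigar)
    return "".join(f"{n}{op}" for op, n in cigar)


def merge_cigar(cigar: Cigar) -> Cigar:
    out: Cigar = []
    for op, n in cigar:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def collapse_matches(cigar: Cigar) -> Cigar:
    """Collapse '='/'X' runs into 'M' (plain SAM dialect)."""
    return merge_cigar([("M", n) if op in "=X" else (op, n) for op, n in cigar])


def cigar_counts(cigar: Cigar) -> dict[str, int]:
    counts = {op: 0 for op in "=XIDMS"}
    for op, n in cigar:
        counts[op] += n
    counts["gaps"] = sum(1 for op, _ in cigar if op in "ID")
    counts["gap_bases"] = counts["I"] + counts["D"]
    return counts


def query_span(cigar: Cigar) -> int:
    return sum(n for op, n in cigar if op in "=XIMS")


def reference_span(cigar: Cigar) -> int:
    return sum(n for op, n in cigar if op in "=XDM")


def myers_semiglobal(read: str, region_seq: str) -> AlignmentCore:
    """Minimal edit-distance semi-global alignment (bit-vector engine).

    The whole read is consumed; gaps at the region ends are free.
    """
    if not read or not region_seq:
        raise ValueError("empty sequence")
    res = edlib.align(read.upper(), region_seq.upper(), mode="HW", task="path")
    cigar = parse_cigar(res["cigar"])
    start = res["locations"][0][0]
    return AlignmentCore(cigar=merge_cigar(cigar), edit_distance=res["editDistance"], pos=start)


def _nw(read_part: str, region_part: str) -> tuple[Cigar, int]:
    """Global (end-to-end) bit-vector alignment of two segments."""
    if not read_part and not region_part:
        return [], 0
    if not read_part:
        return [("D", len(region_part))], len(region_part)
    if not region_part:
        return [("I", len(read_part))], len(read_part)
    res = edlib.align(read_part.upper(), region_part.upper(), mode="NW", task="path")
    return parse_cigar(res["cigar"]), res["editDistance"]


def _affine_global(read_part: str, region_part: str, params: EValueParams | None = None) -> tuple[Cigar, int]:
    """Global affine-gap alignment of two segments (both fully consumed).

    Used for the between-cluster segments of anchored alignments: under pure
    edit distance the placement of a long gap run inside the segment is
    tie-degenerate, while match-rewarding affine scores pin it to the true
    breakpoints.
    """
    if not read_part or not region_part:
        return _nw(read_part, region_part)
    from Bio import Align

    params = params or EValueParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    aln = aligner.align(region_part.upper(), read_part.upper())[0]
    tblocks, qblocks = aln.aligned
    cigar: Cigar = []
    edits = 0
    prev_t, prev_q = 0, 0
    for (ts, te), (qs, qe) in zip(tblocks.tolist(), qblocks.tolist()):
        if qs > prev_q:
            cigar.append(("I", qs - prev_q))
            edits += qs - prev_q
        if ts > prev_t:
            cigar.append(("D", ts - prev_t))
            edits += ts - prev_t
        for i in range(qe - qs):
            if read_part[qs + i].upper() == region_part[ts + i].upper():
                cigar.append(("=", 1))
            else:
                cigar.append(("X", 1))
                edits += 1
        prev_t, prev_q = te, qe
    if len(read_part) > prev_q:
        cigar.append(("I", len(read_part) - prev_q))
        edits += len(read_part) - prev_q
    if len(region_part) > prev_t:
        cigar.append(("D", len(region_part) - prev_t))
        edits += len(region_part) - prev_t
    return merge_cigar(cigar), edits


def _shw(read_part: str, region_part: str) -> tuple[Cigar, int, int]:
    """Prefix-anchored extension: whole read part, free gap at region end.

    Returns (cigar, edits, region bases consumed).
    """
    if not read_part:
        return [], 0, 0
    if not region_part:
        return [("S", len(read_part))], 0, 0
    res = edlib.align(read_part.upper(), region_part.upper(), mode="SHW", task="path")
    cigar = parse_cigar(res["cigar"])
    return cigar, res["editDistance"], res["locations"][0][1] + 1


def gotoh_semiglobal(
    read: str, region_seq: str, params: EValueParams | None = None
) -> AlignmentCore:
    """Affine-gap semi-global alignment (free gaps at region ends)."""
    from Bio import Align  # heavyweight import, only needed for this mode

    if not read or not region_seq:
        raise ValueError("empty sequence")
    params = params or EValueParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    # free end gaps on the reference (target) side only
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    aln = aligner.align(region_seq.upper(), read.upper())[0]
    tblocks, qblocks = aln.aligned
    cigar: Cigar = []
    edits = 0
    pos = int(tblocks[0][0])
    prev_t, prev_q = pos, int(qblocks[0][0])
    if prev_q > 0:
        cigar.append(("I", prev_q))
        edits += prev_q
    for (ts, te), (qs, qe) in zip(tblocks.tolist(), qblocks.tolist()):
        if qs > prev_q:
            cigar.append(("I", qs - prev_q))
            edits += qs - prev_q
        if ts > prev_t:
            cigar.append(("D", ts - prev_t))
            edits += ts - prev_t
        for i in range(qe - qs):
            if read[qs + i].upper() == region_seq[ts + i].upper():
                cigar.append(("=", 1))
            else:
                cigar.append(("X", 1))
                edits += 1
        prev_t, prev_q = te, qe
    if len(read) > prev_q:
        cigar.append(("I", len(read) - prev_q))
        edits += len(read) - prev_q
    return AlignmentCore(cigar=merge_cigar(cigar), edit_distance=edits, pos=pos)


def _cluster_anchors(chain: Chain, read_len: int, e: float) -> list[list[Anchor]]:
    """Group chained anchors into colinear clusters.

    A neighbour joins the current cluster when the gap imbalance between the
    read and region coordinates, ``|dq - dt| / max(dq, dt)``, stays below
    ``e/2``; imbalances under 30 bases (below the structural-variant scale)
    always join.  Clusters with fewer than ``max(30, 0.02 * read_len)``
    exactly-matching anchor bases are discarded — counting matched bases
    rather than span, so sparse chains of chance anchors (e.g. inside novel
    sequence at a structural-variant site) do not survive as clusters.
    """
    clusters: list[list[Anchor]] = []
    for a in chain.anchors:
        if not clusters:
            clusters.append([a])
            continue
        prev = clusters[-1][-1]
        dq = a.qstart - prev.qend
        dt = a.tstart - prev.tend
        imbalance = abs(dq - dt)
        if imbalance < 30 or imbalance / max(dq, dt, 1) < e / 2:
            clusters[-1].append(a)
        else:
            clusters.append([a])
    min_bases = max(30, int(0.02 * read_len))
    return [
        cl for cl in clusters if sum(a.covered_bases for a in cl) >= min_bases
    ]


def anchored_alignment(
    read: str, region_seq: str, chain: Chain, e: float = 0.45
) -> AlignmentCore:
    """Anchor-guided alignment: clusters aligned piecewise, ends extended
    without end-gap penalty, everything concatenated into one CIGAR.

    A read-end extension whose edit fraction exceeds the expected error rate
    ``e`` is soft-clipped rather than force-aligned (it is unalignable
    sequence, e.g. a read running off a structural-variant breakpoint).
    Falls back to :func:`myers_semiglobal` when every cluster is discarded.
    """
    clusters = _cluster_anchors(chain, len(read), e)
    if not clusters:
        return myers_semiglobal(read, region_seq)
    cigar: Cigar = []
    edits = 0
    first = clusters[0][0]
    # left extension, aligned right-to-left with a free end on the region
    # side; an extension noisier than the expected error rate is unalignable
    # sequence (e.g. a read running off a structural-variant breakpoint) and
    # is soft-clipped instead of force-aligned
    head_q = read[: first.qstart]
    t_lo = max(0, first.tstart - 2 * len(head_q))
    head_cig, head_ed, head_t = _shw(head_q[::-1], region_seq[t_lo : first.tstart][::-1])
    if head_q and head_ed > e * len(head_q):
        head_cig, head_ed, head_t = [("S", len(head_q))], 0, 0
    pos = first.tstart - head_t
    cigar.extend(reversed(head_cig))
    edits += head_ed
    # alternate within-cluster and between-cluster segments; cursors guard
    # against partially overlapping neighbours consuming bases twice
    q_cur, t_cur = first.qstart, first.tstart
    for cl in clusters:
        gap_q, gap_t = max(q_cur, cl[0].qstart), max(t_cur, cl[0].tstart)
        seg_cig, seg_ed = _affine_global(read[q_cur:gap_q], region_seq[t_cur:gap_t])
        cigar.extend(seg_cig)
        edits += seg_ed
        end_q, end_t = max(gap_q, cl[-1].qend), max(gap_t, cl[-1].tend)
        seg_cig, seg_ed = _nw(read[gap_q:end_q], region_seq[gap_t:end_t])
        cigar.extend(seg_cig)
        edits += seg_ed
        q_cur, t_cur = end_q, end_t
    # right extension, clipped under the same noise rule
    tail_q = read[q_cur:]
    t_hi = min(len(region_seq), t_cur + 2 * len(tail_q))
    tail_cig, tail_ed, _ = _shw(tail_q, region_seq[t_cur:t_hi])
    if tail_q and tail_ed > e * len(tail_q):
        tail_cig, tail_ed = [("S", len(tail_q))], 0
    cigar.extend(tail_cig)
    edits += tail_ed
    cigar = merge_cigar(cigar)
    # read bases pushed beyond the region boundary become soft clips
    if cigar and cigar[0][0] == "I":
        cigar[0] = ("S", cigar[0][1])
    if cigar and cigar[-1][0] == "I":
        cigar[-1] = ("S", cigar[-1][1])
    return AlignmentCore(cigar=cigar, edit_distance=edits, pos=pos)


def ambiguity_count(scores: list[RegionScore], F: float = 0.0) -> tuple[int, list[int]]:
    """Ambiguity count ``N_a`` and the indices of near-best regions.

    Regions count as ambiguous when their covered-kmer count is at least
    ``(1 - F)`` times that of the region with the highest ``f``.
    """
    if not scores:
        raise ValueError("no regions to count")
    best = max(range(len(scores)), key=lambda i: (scores[i].f, scores[i].n_kmers))
    cut = (1.0 - F) * scores[best].n_kmers
    selected = [i for i, s in enumerate(scores) if s.n_kmers >= cut]
    return len(selected), selected


def mapping_quality(N_a: int) -> int:
    """Phred-scaled mapping quality from the ambiguity count, capped at 40."""
    if N_a < 1:
        raise ValueError("N_a must be >= 1")
    p = max(1.0 - 1.0 / N_a, 1e-4)
    return min(40, round(-10.0 * math.log10(p)))


def alignment_score(cigar: Cigar, params: EValueParams | None = None) -> int:
    """Rescore a CIGAR: match/mismatch per base, open per gap, extend per gap base."""
    params = params or EValueParams()
    c = cigar_counts(cigar)
    if c["M"] > 0:
        raise ValueError("rescoring needs an extended ('='/'X') CIGAR")
    return (
        c["="] * params.match
        + c["X"] * params.mismatch
        + c["gaps"] * params.gap_open
        + c["gap_bases"] * params.gap_extend
    )


def evalue(score: int, m: int, n: int, params: EValueParams | None = None) -> float:
    """BLAST-style E-value of a rescored alignment.

    ``m`` is the read length and ``n`` the total reference length; a
    non-positive score yields the no-significance value ``m * n``.
    """
    params = params or EValueParams()
    if score <= 0:
        return float(m) * float(n)
    bitscore = (params.lam * score - math.log(params.K)) / math.log(2.0)
    return float(m) * float(n) * 2.0 ** (-bitscore)
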