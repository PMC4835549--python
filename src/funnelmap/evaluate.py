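"""Evaluation procedures: location/base precision-recall, consensus, SV calls.

Location correctness follows the clip-adjusted criterion: the reported
alignment start, minus any leading soft/hard-clipped bases, must fall within
a tolerance (default ±50 bp) of the simulated origin, on the matching strand.
Base-level correctness checks each aligned read base against the exact
reference position it was simulated from; clipped bases are excluded from
precision and all simulated bases form the recall denominator.

Consensus is a per-position majority vote over {A, C, G, T, deletion} with
insertion events (keyed by their sequence) voted separately; positions under
a coverage floor (default 20x) are not called.

Structural variants are called from long indel runs (>= 20 bases) in spanning
alignments: positions where the supporting read fraction exceeds 15% with at
least five reads become windows, nearby windows merge (gap smaller than the
larger window), and a call matches a true event when its size is within 25%
and its endpoints within 25% of the event size.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from .align import Alignment
from .simulate import TrueOrigin


@dataclass
class EvalSummary:
    """Location and base level precision/recall over a read set."""

    total_reads: int = 0
    mapped_reads: int = 0
    correct_reads: int = 0
    aligned_bases: int = 0
    correct_bases: int = 0
    total_bases: int = 0

    @property
    def location_precision(self) -> float:
        return self.correct_reads / self.mapped_reads if self.mapped_reads else 0.0

    @property
    def location_recall(self) -> float:
        return self.correct_reads / self.total_reads if self.total_reads else 0.0

    @property
    def base_precision(self) -> float:
        return self.correct_bases / self.aligned_bases if self.aligned_bases else 0.0

    @property
    def base_recall(self) -> float:
        return self.correct_bases / self.total_bases if self.total_bases else 0.0

    def report(self) -> str:
        return (
            "metric\tvalue\n"
            f"location_precision\t{self.location_precision:.4f}\n"
            f"location_recall\t{self.location_recall:.4f}\n"
            f"base_precision\t{self.base_precision:.4f}\n"
            f"base_recall\t{self.base_recall:.4f}\n"
            f"mapped_reads\t{self.mapped_reads}\n"
            f"correct_reads\t{self.correct_reads}\n"
            f"total_reads\t{self.total_reads}\n"
        )


@dataclass
class SVCall:
    """One structural-variant call from the window-vote caller."""

    kind: str  # "insertion" | "deletion"
    start: int
    end: int
    size: int
    n_reads: int
    frac: float


def _leading_clip(aln: Alignment) -> int:
    return aln.cigar[0][1] if aln.cigar and aln.cigar[0][0] in "SH" else 0


def location_correct(aln: Alignment, truth: TrueOrigin, tol: int = 50) -> bool:
    """Clip-adjusted start within ``tol`` of the simulated origin, same strand."""
    if aln.strand != truth.strand:
        return False
    adjusted = aln.pos - _leading_clip(aln)
    return abs(adjusted - truth.start) <= tol


def base_accuracy(aln: Alignment, truth: TrueOrigin) -> tuple[int, int]:
    """(correctly placed bases, aligned bases) of one alignment.

    A read base is correct when the alignment places it at exactly the
    reference position it was simulated from.  For reverse-strand alignments
    the SAM-oriented read position ``i`` corresponds to original read
    position ``len(read) - 1 - i``.
    """
    n = len(truth.base_map)
    correct = 0
    aligned = 0
    qpos = 0
    rpos = aln.pos
    for op, ln in aln.cigar:
        if op in "=XM":
            for j in range(ln):
                orig = qpos + j if aln.strand == "+" else n - 1 - (qpos + j)
                if 0 <= orig < n and truth.base_map[orig] == rpos + j:
                    correct += 1
            aligned += ln
            qpos += ln
            rpos += ln
        elif op in "IS":
            qpos += ln
        elif op == "D":
            rpos += ln
    return correct, aligned


def summarize(
    alignments: dict[str, list[Alignment]],
    truths: dict[str, TrueOrigin],
    tol: int = 50,
) -> EvalSummary:
    """Location and base precision/recall of primary alignments vs truth."""
    s = EvalSummary()
    for rid, truth in truths.items():
        s.total_reads += 1
        s.total_bases += len(truth.base_map)
        alns = [a for a in alignments.get(rid, []) if not a.secondary]
        if not alns:
            continue
        aln = alns[0]
        s.mapped_reads += 1
        if location_correct(aln, truth, tol):
            s.correct_reads += 1
        correct, aligned = base_accuracy(aln, truth)
        s.correct_bases += correct
        s.aligned_bases += aligned
    return s


def consensus_call(
    alignments: list[Alignment], ref_seq: str, min_cov: int = 20
) -> tuple[str, list[dict]]:
    """Majority-vote consensus over a pileup of alignments to one reference.

    Per position the plurality event among {A, C, G, T, deletion} is called
    (ties conservatively resolve to the reference base); an insertion whose
    event count wins a majority of the covering reads is emitted after the
    position.  Positions with coverage below ``min_cov`` are uncalled and
    emitted as ``N``.  Returns (consensus sequence, per-position calls).
    """
    G = len(ref_seq)
    votes = np.zeros((5, G), dtype=np.int32)  # A C G T del
    cov = np.zeros(G, dtype=np.int32)
    inserts: dict[int, dict[str, int]] = {}
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for aln in alignments:
        qpos, rpos = 0, aln.pos
        for op, ln in aln.cigar:
            if op in "=XM":
                for j in range(ln):
                    b = aln.seq[qpos + j].upper()
                    if b in code and rpos + j < G:
                        votes[code[b], rpos + j] += 1
                cov[rpos : rpos + ln] += 1
                qpos += ln
                rpos += ln
            elif op == "D":
                votes[4, rpos : rpos + ln] += 1
                cov[rpos : rpos + ln] += 1
                rpos += ln
            elif op == "I":
                seq = aln.seq[qpos : qpos + ln].upper()
                inserts.setdefault(rpos, {}).setdefault(seq, 0)
                inserts[rpos][seq] += 1
                qpos += ln
            elif op in "SH":
                if op == "S":
                    qpos += ln
    out: list[str] = []
    calls: list[dict] = []
    for i in range(G):
        if cov[i] < min_cov:
            out.append("N")
            calls.append({"pos": i, "call": None, "coverage": int(cov[i])})
            continue
        col = votes[:, i]
        best = int(col.max())
        winners = [j for j in range(5) if col[j] == best]
        ref_code = code.get(ref_seq[i].upper(), -1)
        if len(winners) > 1 and ref_code in winners:
            j = ref_code  # tie: call the reference base
        else:
            j = winners[0]
        call = "ACGT-"[j]
        if j < 4:
            out.append(call)
        calls.append({"pos": i, "call": call, "coverage": int(cov[i])})
        ins = inserts.get(i + 1)
        if ins:
            seq, cnt = max(ins.items(), key=lambda kv: (kv[1], kv[0]))
            if cnt * 2 > cov[i]:
                out.append(seq)
                calls.append({"pos": i + 0.5, "call": f"+{seq}", "coverage": int(cov[i])})
    return "".join(out), calls


def sv_call(
    alignments: list[Alignment],
    ref_len: int,
    min_frac: float = 0.15,
    min_reads: int = 5,
    min_event: int = 20,
) -> list[SVCall]:
    """Window-vote structural-variant calls from indel runs in alignments.

    Insertion runs support their breakpoint position; deletion runs support
    every deleted position.  Windows of consecutive positions where the
    supporting fraction exceeds ``min_frac`` with at least ``min_reads``
    reads are emitted per type, merging windows whose gap is smaller than the
    larger of the two; the call size is the median supporting run length.
    """
    support = {"insertion": np.zeros(ref_len, np.int32), "deletion": np.zeros(ref_len, np.int32)}
    # qualifying (>= min_event) runs drive support and window detection;
    # all runs contribute to the size estimate, because the aligner may
    # fragment one event into a long run plus short leftovers
    events: dict[str, list[tuple[int, int, int, int]]] = {"insertion": [], "deletion": []}
    fragments: dict[str, list[tuple[int, int, int, int]]] = {"insertion": [], "deletion": []}
    cov = np.zeros(ref_len, np.int32)
    for ri, aln in enumerate(alignments):
        rpos = aln.pos
        for op, ln in aln.cigar:
            if op in "=XM":
                cov[rpos : rpos + ln] += 1
                rpos += ln
            elif op == "D":
                cov[rpos : rpos + ln] += 1
                fragments["deletion"].append((rpos, rpos + ln, ln, ri))
                if ln >= min_event:
                    support["deletion"][rpos : rpos + ln] += 1
                    events["deletion"].append((rpos, rpos + ln, ln, ri))
                rpos += ln
            elif op == "I":
                if rpos < ref_len:
                    fragments["insertion"].append((rpos, rpos + 1, ln, ri))
                if ln >= min_event and rpos < ref_len:
                    # breakpoint placement jitters between reads; support a
                    # +/- min_event window around the reported position
                    lo = max(0, rpos - min_event)
                    hi = min(ref_len, rpos + min_event + 1)
                    support["insertion"][lo:hi] += 1
                    events["insertion"].append((lo, hi, ln, ri))
    calls: list[SVCall] = []
    for kind in ("insertion", "deletion"):
        sup = support[kind]
        mask = (sup >= min_reads) & (sup > min_frac * np.maximum(cov, 1))
        # contiguous mask runs -> windows
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        windows = [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]
        # merge windows closer than the larger window length
        merged: list[list[int]] = []
        for s, e in windows:
            if merged and (s - merged[-1][1]) < max(e - s, merged[-1][1] - merged[-1][0]):
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            ev = [x for x in events[kind] if x[0] < e and x[1] > s]
            if not ev:
                continue
            # size estimate: for each read with a qualifying run, sum all of
            # its runs near the window (the aligner may fragment one event
            # into a long run plus sub-threshold leftovers)
            qualifying = {ri for _, _, _, ri in ev}
            lo, hi = s - min_event, e + min_event
            per_read: dict[int, int] = {ri: 0 for ri in qualifying}
            for fs, fe, ln, ri in fragments[kind]:
                if ri in qualifying and fs < hi and fe > lo:
                    per_read[ri] += ln
            size = int(statistics.median(per_read.values()))
            n_reads = int(sup[s:e].max())
            frac = float(n_reads / max(1, cov[s:e].max()))
            if kind == "insertion":
                # point event: report the midpoint of the max-support plateau
                peak = np.flatnonzero(sup[s:e] == n_reads)
                ps = pe = s + (int(peak[0]) + int(peak[-1]) + 1) // 2
            else:
                # deletion breakpoints: the edges of the threshold window
                ps, pe = s, e
            calls.append(SVCall(kind=kind, start=ps, end=pe, size=size, n_reads=n_reads, frac=frac))
    calls.sort(key=lambda c: (c.start, c.kind))
    return calls


def sv_match(
    calls: list[SVCall], truth: list[dict], margin: float = 0.25
) -> tuple[float, float, int]:
    """Greedy one-to-one matching of calls to true events.

    A call matches a truth entry of the same expected type when its size is
    within ``margin`` of the true size and both endpoints are within
    ``margin * size`` of the true positions.  Returns (precision, recall,
    true positives); truth entries are as produced by
    :func:`funnelmap.simulate.inject_svs`.
    """
    unused = list(range(len(truth)))
    tp = 0
    for call in calls:
        for ui in list(unused):
            t = truth[ui]
            ev = t["event"]
            if call.kind != t["expect"]:
                continue
            if abs(call.size - ev.size) > margin * ev.size:
                continue
            if abs(call.start - t["mstart"]) > margin * ev.size:
                continue
            if abs(call.end - t["mend"]) > margin * ev.size:
                continue
            tp += 1
            unused.remove(ui)
            break
    precision = tp / len(calls) if calls else 0.0
    recall = tp / len(truth) if truth else 0.0
    return precision, recall, tp


def write_consensus_fasta(path: str, name: str, consensus: str, width: int = 70) -> None:
    """Consensus sequence as wrapped FASTA (uncalled positions are N)."""
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(consensus), width):
            fh.write(consensus[i : i + width] + "\n")


def write_sv_bed(path: str, calls: list[SVCall]) -> None:
    """SV calls as 6-column BED-like text."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"ref\t{c.start}\t{c.end}\t{c.kind}\t{c.size}\t{c.n_reads}\n")
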