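"""Vertex-centric graph walks producing exact-match anchors (stage II).

Within a candidate region the read is turned into a *kmer mapping graph*:
vertices are the read's kmers (duplicates kept as separate vertices, unlike a
de Bruijn graph) and each vertex has directed edges to the next ``l``
vertices.  Region kmers are streamed left to right; every exact kmer hit on
the read either extends the best (longest) existing walk ending within the
last ``l`` read kmers — subject to a symmetric constraint of at most ``l``
kmers skipped on the region side — or starts a new walk.  The extra edges let
a walk jump over kmers poisoned by sequencing errors.  Walks spanning fewer
than ``min_span`` read bases are discarded; survivors become anchors.

The per-hit update is O(1): walk length, origins and coverage counters are
carried on the walk state and updated incrementally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import encode

DEFAULT_K = 6
DEFAULT_L = 9
DEFAULT_MIN_SPAN = 12


@dataclass
class WalkState:
    """State of one walk through the kmer mapping graph."""

    q_origin: int
    t_origin: int
    q_last: int
    t_last: int
    covered_bases: int
    covered_kmers: int
    k: int
    parent: "WalkState | None" = None
    consumed: bool = False

    @property
    def walk_length(self) -> int:
        """Bases covered on the read from origin to the end of the last kmer."""
        return self.q_last + self.k - self.q_origin

    @property
    def q_end(self) -> int:
        return self.q_last + self.k

    @property
    def t_end(self) -> int:
        return self.t_last + self.k

    def kmer_points(self) -> list[tuple[int, int]]:
        """(read kmer position, region kmer position) match points of the walk."""
        pts = []
        st: WalkState | None = self
        while st is not None:
            pts.append((st.q_last, st.t_last))
            st = st.parent
        return pts[::-1]


@dataclass
class Anchor:
    """An exactly-matching, near-colinear segment pair found by a graph walk.

    The read span and region span may differ by the small indels the walk
    bridged; every sampled kmer point is an exact match in both sequences.
    """

    qstart: int
    qend: int
    tstart: int
    tend: int
    covered_kmers: int
    covered_bases: int
    points: tuple[tuple[int, int], ...] = ()

    @property
    def length(self) -> int:
        return min(self.qend - self.qstart, self.tend - self.tstart)

    @property
    def intercept(self) -> int:
        return self.tstart - self.qstart


def build_read_kmer_lookup(read: str, k: int) -> dict[int, list[int]]:
    """Map every ACGT kmer of the read (packed 2-bit int) to its positions."""
    codes = encode(read)
    n = len(codes) - k + 1
    lookup: dict[int, list[int]] = {}
    if n <= 0:
        return lookup
    kmers = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        ok &= col < 4
        kmers = (kmers << 2) | col
    for i in np.flatnonzero(ok):
        lookup.setdefault(int(kmers[i]), []).append(int(i))
    return lookup


def _region_kmers(region_seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    codes = encode(region_seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    kmers = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        ok &= col < 4
        kmers = (kmers << 2) | col
    pos = np.flatnonzero(ok)
    return kmers[pos], pos


def graph_walk(
    read: str,
    region_seq: str,
    k: int = DEFAULT_K,
    l: int = DEFAULT_L,
    read_lookup: dict[int, list[int]] | None = None,
) -> list[WalkState]:
    """All maximal walks of the read's kmer mapping graph through the region.

    For each region kmer hit at read kmer position ``i`` the best predecessor
    is the longest walk ending at a read position in ``{i-l, ..., i-1}`` whose
    last region kmer is 1..l kmer positions behind the current one (ties:
    smaller read gap, then earlier read origin).  Hits with no admissible
    predecessor start new walks.
    """
    if len(read) < k or len(region_seq) < k:
        return []
    if read_lookup is None:
        read_lookup = build_read_kmer_lookup(read, k)
    kmers, tpos = _region_kmers(region_seq, k)
    # best state currently ending at each read kmer position
    states: dict[int, WalkState] = {}
    finalized: list[WalkState] = []
    for km, t in zip(kmers, tpos):
        hits = read_lookup.get(int(km))
        if not hits:
            continue
        t = int(t)
        for i in hits:
            best: WalkState | None = None
            for dq in range(1, l + 1):
                st = states.get(i - dq)
                if st is None:
                    continue
                dt = t - st.t_last
                if dt < 1 or dt > l:
                    continue
                # dq ascends, so on ties the smallest read gap wins; one state
                # per read position makes further origin tie-breaks moot
                if best is None or st.walk_length > best.walk_length:
                    best = st
            if best is not None:
                new = WalkState(
                    q_origin=best.q_origin,
                    t_origin=best.t_origin,
                    q_last=i,
                    t_last=t,
                    covered_bases=best.covered_bases + min(i - best.q_last, k),
                    covered_kmers=best.covered_kmers + 1,
                    k=k,
                    parent=best,
                )
                best.consumed = True
            else:
                new = WalkState(i, t, i, t, covered_bases=k, covered_kmers=1, k=k)
            old = states.get(i)
            if old is None or new.walk_length >= old.walk_length:
                if old is not None and not old.consumed:
                    finalized.append(old)
                states[i] = new
            elif not new.consumed:
                finalized.append(new)
    finalized.extend(st for st in states.values() if not st.consumed)
    return finalized


def filter_walks(walks: list[WalkState], min_span: int = DEFAULT_MIN_SPAN) -> list[Anchor]:
    """Drop walks spanning fewer than ``min_span`` read bases; make anchors."""
    anchors = []
    for w in walks:
        if w.walk_length < min_span:
            continue
        anchors.append(
            Anchor(
                qstart=w.q_origin,
                qend=w.q_end,
                tstart=w.t_origin,
                tend=w.t_end,
                covered_kmers=w.covered_kmers,
                covered_bases=w.covered_bases,
                points=tuple(w.kmer_points()),
            )
        )
    anchors.sort(key=lambda a: (a.qstart, a.tstart, a.qend, a.tend))
    return anchors


def region_anchors(
    read: str,
    region_seq: str,
    k: int = DEFAULT_K,
    l: int = DEFAULT_L,
    min_span: int = DEFAULT_MIN_SPAN,
    read_lookup: dict[int, list[int]] | None = None,
) -> list[Anchor]:
    """Convenience: graph walk then length filter."""
    return filter_walks(graph_walk(read, region_seq, k, l, read_lookup), min_span)
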