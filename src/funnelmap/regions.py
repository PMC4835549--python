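"""Hough-vote clustering of seed hits into candidate regions (stage I, binning).

Collinear seed hits of an error-free read lie on a 45-degree line in
(read, reference) coordinate space, so with the slope fixed at 1 only the
intercept ``c = t - q`` has to be recovered.  Every hit votes for the
intercept bin ``floor(c / (L/3))`` of its (reference, strand) accumulator,
where ``L`` is the read length; the L/3 bin width guarantees at least one
bin is fully covered by the read.  Bins with more than 75% of the maximum
vote count are expanded by one read length on each side and merged into
candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seeds import SeedHit


@dataclass
class BinArray:
    """Vote accumulators, one per (reference id, strand)."""

    bin_width: int
    counts: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    n_hits: int = 0

    def max_count(self) -> int:
        return max((int(c.max()) for c in self.counts.values() if len(c)), default=0)


@dataclass
class Region:
    """A candidate reference window selected by Hough voting.

    ``start``/``end`` are 0-based half-open on the forward reference strand;
    a region of a circular reference may wrap the origin (``wraps`` set, the
    window being ``[start, ref_len) + [0, end)``).
    """

    ref_id: int
    strand: str
    start: int
    end: int
    votes: int
    wraps: bool = False

    def length(self, ref_len: int) -> int:
        return (self.end - self.start) if not self.wraps else (ref_len - self.start + self.end)

    def extract(self, ref_seq: str) -> str:
        return ref_seq[self.start : self.end] if not self.wraps else ref_seq[self.start :] + ref_seq[: self.end]


def hough_intercept(hit: SeedHit) -> int:
    """Diagonal intercept ``c = t - q`` of a seed hit (slope fixed at 1)."""
    return hit.tpos - hit.qpos


def bin_width_for(read_len: int) -> int:
    return max(1, read_len // 3)


def vote(
    hits: list[SeedHit] | dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    read_len: int,
    ref_lens: list[int],
    smear: bool = False,
) -> BinArray:
    """Accumulate intercept votes per (reference, strand).

    ``hits`` may be a list of :class:`SeedHit` or the array form returned by
    :func:`funnelmap.seeds.collect_hit_arrays`.  Negative intercepts clamp to
    bin 0.  With ``smear`` enabled, a hit whose intercept falls within
    ``read_len/6`` of its bin's lower edge casts an extra vote in the
    next-lower bin, protecting true locations that straddle a bin boundary
    (these extra votes are not counted in ``n_hits``).
    """
    binw = bin_width_for(read_len)
    bins = BinArray(bin_width=binw)
    if isinstance(hits, list):
        arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for strand in ("+", "-"):
            sel = [h for h in hits if h.strand == strand]
            arrays[strand] = (
                np.array([h.qpos for h in sel], dtype=np.int64),
                np.array([h.tpos for h in sel], dtype=np.int64),
                np.array([h.ref_id for h in sel], dtype=np.int64),
            )
    else:
        arrays = hits
    for strand, (qpos, tpos, ref) in arrays.items():
        c = tpos - qpos
        np.maximum(c, 0, out=c)
        b = c // binw
        if smear:
            lower = (c % binw) < read_len / 6
            b = np.concatenate([b, np.maximum(b[lower] - 1, 0)])
            ref = np.concatenate([ref, ref[lower]])
        else:
            bins.n_hits += len(c)
        for rid in np.unique(ref):
            nbins = ref_lens[int(rid)] // binw + 2
            sel = ref == rid
            key = (int(rid), strand)
            cnt = np.bincount(b[sel], minlength=nbins).astype(np.int64)
            if key in bins.counts:
                bins.counts[key] += cnt
            else:
                bins.counts[key] = cnt
    if smear:
        bins.n_hits = sum(len(a[0]) for a in arrays.values())
    return bins


def _merge_intervals(iv: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Merge overlapping (start, end, votes) intervals, summing votes."""
    iv = sorted(iv)
    out: list[list[int]] = []
    for s, e, v in iv:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
            out[-1][2] += v
        else:
            out.append([s, e, v])
    return [tuple(x) for x in out]


def select_regions(
    bins: BinArray,
    read_len: int,
    ref_lens: list[int],
    circular: bool = False,
    threshold: float = 0.75,
) -> list[Region]:
    """Select bins with count > ``threshold``  x max count and expand them.

    Each selected bin becomes the window ``[bin_start - L, bin_end + L]``
    (L = read length), clipped to the reference, or wrapped when the
    reference is circular.  Overlapping windows of the same (reference,
    strand) merge into one region with summed votes.
    """
    maxc = bins.max_count()
    if maxc == 0:
        return []
    cut = threshold * maxc
    binw = bins.bin_width
    regions: list[Region] = []
    for (rid, strand), counts in bins.counts.items():
        ref_len = ref_lens[rid]
        sel = np.flatnonzero(counts > cut)
        if len(sel) == 0:
            continue
        iv = [
            (int(b) * binw - read_len, (int(b) + 1) * binw + read_len, int(counts[b]))
            for b in sel
        ]
        merged = _merge_intervals(iv)
        if not circular:
            for s, e, v in merged:
                s, e = max(0, s), min(ref_len, e)
                if s < e:
                    regions.append(Region(rid, strand, s, e, v))
            continue
        # circular: normalize windows onto the circle, splitting any that
        # cross the origin, merge linearly, then rejoin across the origin
        if any(e - s >= ref_len for s, e, _ in merged):
            votes_all = sum(v for _, _, v in merged)
            regions.append(Region(rid, strand, 0, ref_len, votes_all))
            continue
        pieces: list[tuple[int, int, int]] = []
        for s, e, v in merged:
            s_, length = s % ref_len, e - s
            if s_ + length <= ref_len:
                pieces.append((s_, s_ + length, v))
            else:  # votes attach to the first piece only
                pieces.append((s_, ref_len, v))
                pieces.append((0, s_ + length - ref_len, 0))
        linear = _merge_intervals(pieces)
        if len(linear) > 1 and linear[0][0] == 0 and linear[-1][1] == ref_len:
            head, tail_iv = linear[0], linear[-1]
            linear = linear[1:-1]
            regions.append(
                Region(rid, strand, tail_iv[0], head[1], head[2] + tail_iv[2], wraps=True)
            )
        for s, e, v in linear:
            regions.append(Region(rid, strand, s, e, v))
    regions.sort(key=lambda r: (r.ref_id, r.strand, r.start))
    return regions
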