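"""Monotone anchor chaining — LCSk with variable-length substrings (stage III).

Anchors from the graph walk need not be mutually consistent (repeats produce
crossing anchors).  The chain selects the subset that is strictly increasing
in both read and region coordinates (starts and ends, so no anchor is
contained in another's span) and maximizes the total *credited* covered
bases, where each anchor's credit is its exactly-matching base count
reduced by the larger of its read- and region-overlaps with its predecessor
(never below zero).  This is the longest-common-subsequence-in-k-substrings
formulation with the fixed substring size k replaced by each anchor's own
length.

The implementation is a quadratic dynamic program over anchors sorted by
start coordinates; anchor counts per region are small.  Ties in total credit
are broken toward the smaller region span, then the earlier anchor list, so
results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .anchors import Anchor


@dataclass
class Chain:
    """A monotone chain of anchors with per-anchor credited lengths."""

    anchors: list[Anchor] = field(default_factory=list)
    credits: list[int] = field(default_factory=list)

    @property
    def total_covered(self) -> int:
        return sum(self.credits)

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def qspan(self) -> tuple[int, int]:
        return (self.anchors[0].qstart, self.anchors[-1].qend)

    @property
    def tspan(self) -> tuple[int, int]:
        return (self.anchors[0].tstart, self.anchors[-1].tend)


def anchor_credit(prev: Anchor | None, anc: Anchor) -> int:
    """Credited bases of ``anc`` following ``prev`` (overlap-trimmed)."""
    if prev is None:
        return anc.covered_bases
    q_ov = max(0, prev.qend - anc.qstart)
    t_ov = max(0, prev.tend - anc.tstart)
    return max(0, anc.covered_bases - max(q_ov, t_ov))


def lcsk_chain(anchors: list[Anchor]) -> Chain:
    """Best monotone chain by total credited covered bases.

    Anchors may arrive unsorted, duplicated or crossing; the result is
    strictly increasing in both start coordinates.
    """
    if not anchors:
        return Chain()
    # deterministic processing order; dedup exact duplicates
    uniq = sorted(
        set((a.qstart, a.qend, a.tstart, a.tend, a.covered_kmers, a.covered_bases, a.points) for a in anchors)
    )
    ancs = [Anchor(*u) for u in uniq]
    n = len(ancs)
    score = [0] * n
    first_t = [0] * n  # chain-start tstart, for the span tie-break
    pred = [-1] * n
    for j in range(n):
        aj = ancs[j]
        best_score = anchor_credit(None, aj)
        best_first = aj.tstart
        best_pred = -1
        for i in range(j):
            ai = ancs[i]
            if (
                ai.qstart >= aj.qstart
                or ai.tstart >= aj.tstart
                or ai.qend >= aj.qend
                or ai.tend >= aj.tend
            ):
                continue
            s = score[i] + anchor_credit(ai, aj)
            # tie-breaks: smaller t-span (= larger chain-start tstart), then
            # the earlier predecessor index (lexicographically earlier list)
            if s > best_score or (
                s == best_score
                and (first_t[i] > best_first or (first_t[i] == best_first and best_pred == -1))
            ):
                best_score, best_first, best_pred = s, first_t[i], i
        score[j] = best_score
        first_t[j] = best_first
        pred[j] = best_pred
    jbest = 0
    for j in range(1, n):
        key_j = (-score[j], ancs[j].tend - first_t[j], first_t[j])
        key_b = (-score[jbest], ancs[jbest].tend - first_t[jbest], first_t[jbest])
        if key_j < key_b:
            jbest = j
    order = []
    j = jbest
    while j != -1:
        order.append(j)
        j = pred[j]
    order.reverse()
    chain = Chain()
    prev: Anchor | None = None
    for j in order:
        chain.anchors.append(ancs[j])
        chain.credits.append(anchor_credit(prev, ancs[j]))
        prev = ancs[j]
    return chain
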