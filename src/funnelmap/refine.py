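"""L1 line fit, outlier filtering and region quality scores (stage IV).

A correct chain of anchors lies near a 45-degree line in (read, region)
coordinate space; deviations from that line are indel noise.  The line is fit
under the least-absolute-deviation criterion — for slope 1 this is the
weighted median of the anchor intercepts ``t - q``, weighted by credited
anchor length.  Anchors farther than ``e * T / sqrt(2)`` from the line are
dropped (``e`` = expected error rate, default 0.45; ``T`` = read length; the
``1/sqrt(2)`` converts a reference-coordinate offset into a perpendicular
distance).  A confidence half-width ``3 * sqrt(mean(d_i^2))`` — a 3-sigma
rule on the surviving residuals — trims once more, and the survivors are
re-chained to repair gaps opened by the filtering.

The refined chain is summarized by five scores: covered kmers ``n_kmers``,
residual spread ``sigma``, matched read span ``m_len``, anchored bases
``n_cb`` and the read length.  The last four are normalized to [0, 1] and
their product ``f`` ranks the candidate regions of a read; ``n_kmers`` is
reserved for the ambiguity count behind the mapping quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .anchors import Anchor
from .chain import Chain, lcsk_chain

DEFAULT_ERROR_RATE = 0.45

#: Reference-length cap in the read-length score, so that mapping to a large
#: reference does not drive every region's score toward zero.
REFLEN_CAP = 10_000

_SQRT2 = math.sqrt(2.0)


@dataclass
class L1Fit:
    """A 45-degree L1 line and the per-anchor perpendicular residuals."""

    intercept: float
    residuals: list[float] = field(default_factory=list)
    conf: float = 0.0


@dataclass
class RegionScore:
    """The five region quality scores and their product ``f``."""

    n_kmers: int = 0
    sigma: float = 0.0
    m_len: int = 0
    n_cb: int = 0
    read_len: int = 0
    ref_len: int = 0
    norm_mlen: float = 0.0
    norm_ncb: float = 0.0
    norm_sigma: float = 0.0
    norm_readlen: float = 0.0
    f: float = 0.0


def _residual(anchor: Anchor, intercept: float) -> float:
    return abs(anchor.intercept - intercept) / _SQRT2


def fit_l1(chain: Chain) -> L1Fit:
    """Weighted-median L1 fit of the 45-degree line through a chain.

    The intercept minimizes ``sum_i w_i |c_i - c|`` over anchors with
    ``c_i = tstart_i - qstart_i`` and weights the credited lengths; the
    weighted median (lower value on ties) attains the minimum.
    """
    if not chain.anchors:
        raise ValueError("cannot fit a line through an empty chain")
    pairs = sorted(
        (a.intercept, max(1, w)) for a, w in zip(chain.anchors, chain.credits)
    )
    total = sum(w for _, w in pairs)
    acc = 0
    intercept = float(pairs[-1][0])
    for c, w in pairs:
        acc += w
        if 2 * acc >= total:
            intercept = float(c)
            break
    fit = L1Fit(intercept=intercept)
    fit.residuals = [_residual(a, intercept) for a in chain.anchors]
    return fit


def band_filter(
    chain: Chain, fit: L1Fit, e: float = DEFAULT_ERROR_RATE, read_len: int | None = None
) -> list[Anchor]:
    """Anchors within ``e * T / sqrt(2)`` (perpendicular) of the L1 line."""
    if read_len is None:
        read_len = chain.qspan[1] if chain.anchors else 0
    band = e * read_len / _SQRT2
    return [a for a, d in zip(chain.anchors, fit.residuals) if d <= band]


def confidence_refilter_and_rechain(anchors: list[Anchor], fit: L1Fit) -> Chain:
    """3-sigma-style confidence trim around the L1 line, then re-chain.

    ``conf = 3 * sqrt(mean(d_i^2))`` over the surviving anchors; anchors
    within ``conf`` of the line are chained again to repair gaps opened by
    the filtering.  No survivors yields an empty chain (region scores 0).
    """
    if not anchors:
        fit.conf = 0.0
        return Chain()
    ds = [_residual(a, fit.intercept) for a in anchors]
    conf = 3.0 * math.sqrt(sum(d * d for d in ds) / len(ds))
    fit.conf = conf
    kept = [a for a, d in zip(anchors, ds) if d <= conf]
    return lcsk_chain(kept)


def score_region(
    chain: Chain,
    read_len: int,
    ref_len: int,
    e: float = DEFAULT_ERROR_RATE,
) -> RegionScore:
    """Five quality scores of a refined chain; ``f`` = product of the four
    normalized ones (an empty chain scores 0)."""
    score = RegionScore(read_len=read_len, ref_len=ref_len)
    if not chain.anchors:
        return score
    fit = fit_l1(chain)
    score.n_kmers = sum(a.covered_kmers for a in chain.anchors)
    score.sigma = math.sqrt(
        sum(d * d for d in fit.residuals) / len(fit.residuals)
    )
    score.m_len = chain.qspan[1] - chain.qspan[0]
    score.n_cb = chain.total_covered
    score.norm_mlen = min(1.0, score.m_len / read_len) if read_len else 0.0
    score.norm_ncb = min(1.0, score.n_cb / max(1, score.m_len))
    score.norm_sigma = max(0.0, 1.0 - score.sigma / (e * read_len)) if read_len else 0.0
    score.norm_readlen = read_len / (read_len + min(ref_len, REFLEN_CAP))
    score.f = score.norm_mlen * score.norm_ncb * score.norm_sigma * score.norm_readlen
    return score


def refine_chain(
    chain: Chain, read_len: int, e: float = DEFAULT_ERROR_RATE
) -> tuple[Chain, L1Fit]:
    """Full stage-IV pass: L1 fit, band filter, confidence trim, re-chain."""
    if not chain.anchors:
        return Chain(), L1Fit(intercept=0.0)
    fit = fit_l1(chain)
    survivors = band_filter(chain, fit, e, read_len)
    refined = confidence_refilter_and_rechain(survivors, fit)
    return refined, fit
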