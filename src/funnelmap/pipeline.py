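"""The five-stage read-funneling pipeline.

Each read is funneled through progressively stricter filters: spaced-seed
lookup and Hough-vote region selection (stage I), graph-walk anchoring per
region (stage II), LCSk chaining (stage III), L1 refinement and region
scoring (stage IV), and final alignment of the best-scoring region with
mapping quality and E-value (stage V).  The :class:`Mapper` owns the
reference indexes and exposes :meth:`Mapper.map_read`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import anchors as anchors_mod
from . import regions as regions_mod
from .align import (
    Alignment,
    EValueParams,
    alignment_score,
    ambiguity_count,
    anchored_alignment,
    evalue,
    gotoh_semiglobal,
    mapping_quality,
    myers_semiglobal,
)
from ._dna import revcomp
from .chain import Chain, lcsk_chain
from .refine import DEFAULT_ERROR_RATE, RegionScore, refine_chain, score_region
from .seeds import (
    DEFAULT_POSTING_CAP,
    DEFAULT_SHAPES,
    build_index,
    collect_hit_arrays,
    parse_shape,
)

logger = logging.getLogger(__name__)


@dataclass
class MapParams:
    """Tunable parameters of the pipeline (defaults are the standard ones)."""

    shapes: tuple[str, ...] = DEFAULT_SHAPES
    k: int = 6  # stage-II continuous kmer size
    l: int = 9  # graph out-degree (max kmers jumped over)
    min_anchor_span: int = 12  # minimum walk span in read bases
    error_rate: float = DEFAULT_ERROR_RATE  # expected error rate e
    bin_threshold: float = 0.75  # Hough bin selection, fraction of max votes
    posting_cap: int = DEFAULT_POSTING_CAP
    smear: bool = True  # extra vote in the next-lower Hough bin near edges
    aligner: str = "myers"  # myers | gotoh | anchor
    ambiguity_F: float = 0.0
    evalue_cutoff: float | None = None
    circular: bool = False
    use_chaining: bool = True  # stage III+IV toggle (ablation support)
    evalue_params: EValueParams = field(default_factory=EValueParams)


@dataclass
class _Candidate:
    region: regions_mod.Region
    chain: Chain  # refined (stage IV) chain, used for scoring
    chain_lcsk: Chain  # stage-III chain; anchored alignment clusters this one,
    # so an alignment can still span a large indel that the L1 band rejects
    score: RegionScore


class Mapper:
    """Maps reads against a fixed set of reference sequences."""

    def __init__(self, references: list[tuple[str, str]], params: MapParams | None = None):
        self.params = params or MapParams()
        self.references = [(name, seq.upper()) for name, seq in references if seq]
        self.names = [name for name, _ in self.references]
        self.lengths = [len(seq) for _, seq in self.references]
        self.total_ref_len = sum(self.lengths)
        shapes = [parse_shape(p) for p in self.params.shapes]
        self.indexes = build_index(self.references, shapes)

    # -- per-read stages -------------------------------------------------

    def _candidate_regions(self, read: str) -> list[regions_mod.Region]:
        hits = collect_hit_arrays(read, self.indexes, self.params.posting_cap)
        bins = regions_mod.vote(hits, len(read), self.lengths, smear=self.params.smear)
        return regions_mod.select_regions(
            bins,
            len(read),
            self.lengths,
            circular=self.params.circular,
            threshold=self.params.bin_threshold,
        )

    def _evaluate_region(
        self,
        region: regions_mod.Region,
        read_fwd: str,
        read_rev: str,
        lookups: dict[str, dict],
    ) -> _Candidate:
        p = self.params
        read = read_fwd if region.strand == "+" else read_rev
        region_seq = region.extract(self.references[region.ref_id][1])
        ancs = anchors_mod.region_anchors(
            read,
            region_seq,
            k=p.k,
            l=p.l,
            min_span=p.min_anchor_span,
            read_lookup=lookups[region.strand],
        )
        if p.use_chaining:
            chain_lcsk = lcsk_chain(ancs)
            chain, _ = refine_chain(chain_lcsk, len(read), p.error_rate)
        else:
            # ablation: keep every anchor, no monotonicity or L1 filtering
            chain = Chain(anchors=sorted(ancs, key=lambda a: (a.qstart, a.tstart)))
            chain.credits = [a.covered_bases for a in chain.anchors]
            chain_lcsk = chain
        score = score_region(chain, len(read), self.total_ref_len, p.error_rate)
        return _Candidate(region=region, chain=chain, chain_lcsk=chain_lcsk, score=score)

    def _align_candidate(
        self, cand: _Candidate, read_fwd: str, read_rev: str
    ) -> tuple | None:
        p = self.params
        region = cand.region
        read = read_fwd if region.strand == "+" else read_rev
        region_seq = region.extract(self.references[region.ref_id][1])
        if p.aligner == "myers":
            core = myers_semiglobal(read, region_seq)
        elif p.aligner == "gotoh":
            core = gotoh_semiglobal(read, region_seq, p.evalue_params)
        elif p.aligner == "anchor":
            core = anchored_alignment(read, region_seq, cand.chain_lcsk, p.error_rate)
        else:
            raise ValueError(f"unknown aligner {p.aligner!r}")
        ref_len = self.lengths[region.ref_id]
        pos = (region.start + core.pos) % ref_len if p.circular else region.start + core.pos
        return core, pos

    # -- public API --------------------------------------------------------

    def map_read(self, read_id: str, read: str, qual: str | None = None) -> list[Alignment]:
        """Map one read; returns the primary alignment (and secondaries when
        the ambiguity factor admits near-best regions), or an empty list."""
        p = self.params
        if len(read) < max(len(s) for s in p.shapes) + 1:
            return []
        regions = self._candidate_regions(read)
        if not regions:
            return []
        read_fwd = read.upper()
        read_rev = revcomp(read_fwd)
        lookups = {
            "+": anchors_mod.build_read_kmer_lookup(read_fwd, p.k),
            "-": anchors_mod.build_read_kmer_lookup(read_rev, p.k),
        }
        cands = [self._evaluate_region(r, read_fwd, read_rev, lookups) for r in regions]
        cands = [c for c in cands if c.score.f > 0 and len(c.chain) > 0]
        if not cands:
            return []
        scores = [c.score for c in cands]
        N_a, selected = ambiguity_count(scores, p.ambiguity_F)
        mapq = mapping_quality(N_a)
        best = max(
            range(len(cands)),
            key=lambda i: (scores[i].f, scores[i].n_kmers, -cands[i].region.start),
        )
        out: list[Alignment] = []
        emit = [best] + [i for i in selected if i != best] if p.ambiguity_F > 0 else [best]
        for idx in emit:
            cand = cands[idx]
            aligned = self._align_candidate(cand, read_fwd, read_rev)
            if aligned is None:
                continue
            core, pos = aligned
            score = alignment_score(core.cigar, p.evalue_params)
            ze = evalue(score, len(read), self.total_ref_len, p.evalue_params)
            if p.evalue_cutoff is not None and ze > p.evalue_cutoff:
                continue
            out.append(
                Alignment(
                    read_id=read_id,
                    ref_id=cand.region.ref_id,
                    ref_name=self.names[cand.region.ref_id],
                    strand=cand.region.strand,
                    pos=pos,
                    cigar=core.cigar,
                    edit_distance=core.edit_distance,
                    score=score,
                    mapq=mapq,
                    evalue=ze,
                    f=cand.score.f,
                    n_kmers=cand.score.n_kmers,
                    N_a=N_a,
                    seq=read_fwd if cand.region.strand == "+" else revcomp(read_fwd),
                    qual=qual if cand.region.strand == "+" else (qual[::-1] if qual else None),
                    secondary=idx != best,
                )
            )
        return out

    def map_reads(self, reads) -> dict[str, list[Alignment]]:
        """Map an iterable of (id, seq) or (id, seq, qual) tuples."""
        out: dict[str, list[Alignment]] = {}
        for rec in reads:
            rid, seq = rec[0], rec[1]
            qual = rec[2] if len(rec) > 2 else None
            out[rid] = self.map_read(rid, seq, qual)
        return out
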