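# Methods

funnelmap maps long, error-prone reads (nanopore-like, with total error rates
up to ~35%) to a reference by funneling each read through five progressively
stricter stages.  Each stage is cheap relative to the one after it and
conservatively discards candidate placements, so that the expensive final
alignment runs on (usually) a single region.

## Stage I — gapped spaced seeding and Hough voting

**Seeding.**  The reference is indexed under two complementary spaced-seed
shapes, `1111110111111` (6-1-6) and `11110111101111` (4-1-4-1-4), both of
weight 12.  A `1` marks an inclusive base, a `0` a don't-care (DC) base; the
index key concatenates the inclusive bases only.  At lookup time each DC
position independently contributes three key layouts — skip the DC base
(tolerates a substitution), keep it (tolerates a 1 bp deletion), or skip it
together with the following base (tolerates a 1 bp insertion) — and the
Cartesian product over DC positions yields up to `3^d` deduplicated keys per
position per shape.  This makes single-base errors at DC positions invisible
to the seed, which is what lets seeding survive ~30% error rates where exact
kmers of the same weight would not.  Only the forward strand is indexed; the
read and its reverse complement are both queried, halving index size.  Keys
with more than 500 postings are skipped during lookup to bound noise votes
(the threshold below is on votes, not postings, so a cap is needed
separately; it is exposed as a parameter).

**Region selection.**  An error-free read's seed hits `(q, t)` lie on a
45-degree line `t = q + c`, so only the intercept `c = t - q` must be
recovered.  Every hit votes for the bin `floor(c / (L/3))` of a per
(reference, strand) accumulator, `L` being the read length; `L/3` guarantees
at least one bin fully covered by the read.  Indels shift the diagonal by at
most the indel length, far less than `L/3` for the events sequencing errors
produce, so true hits concentrate in one or two adjacent bins while noise
hits scatter.  Bins with more than 75% of the global maximum vote count are
expanded by one read length on each side, merged when overlapping, and
emitted as candidate regions.  A hit whose intercept falls within `L/6` of
its bin's lower edge also votes in the next-lower bin (switchable), removing
the pathology of a true location straddling a bin boundary.  Circular
references wrap regions across the origin instead of splitting them.

## Stage II — graph anchoring

Within each region the read becomes a *kmer mapping graph*: one vertex per
read kmer (`k = 6` by default, duplicates kept separate), with edges from
each vertex to its `l = 9` successors.  Region kmers are streamed left to
right; each exact hit on the read extends the longest existing walk ending
within the previous `l` read kmers — with the symmetric constraint that at
most `l` region kmers may be skipped — or starts a new walk.  The `l - 1`
extra edges let a walk jump over kmers poisoned by errors, which is the
crucial difference from exact-match chaining: with 17% per-base error about
one 6-mer in three is clean, and jumps of up to 9 kmers bridge nearly all
gaps between clean 6-mers.  Per-hit work is O(1) (the walk state carries its
origin, last positions and coverage counters).  Walks spanning fewer than 12
read bases — less than stage I's seed weight — are discarded; survivors
become *anchors* carrying their exact-match kmer count and base count.

## Stage III — chaining (LCSk with variable-length substrings)

Repeats make the anchor set non-monotone, so a maximum-credit monotone
subset is selected: strictly increasing in both read and region coordinates
(starts *and* ends — an anchor contained in another's span can never join a
chain), maximizing total credited bases, where an anchor's credit is its
matching-base count minus the larger of its read/region overlaps with its
predecessor (never below zero).  This is the longest common subsequence in
k-length substrings, with the fixed k replaced by each anchor's own length.
The implementation is a quadratic DP over sorted anchors (anchor counts per
region are tens, not thousands); an exhaustive-subset oracle in the test
suite certifies optimality on random instances.  Ties break toward the
smaller region span, then the earlier anchor list, so output is
deterministic.

## Stage IV — L1 refinement and region scoring

A correct chain hugs a 45-degree line; indel noise spreads anchors
perpendicular to it.  The line is fit by least absolute deviations, which
for slope 1 reduces to the weighted median of anchor intercepts `t - q`
(weights: credited lengths).  Anchors farther than `e * T / sqrt(2)` from the
line are cut (`e` = expected error rate, conservatively 0.45; `T` = read
length; `1/sqrt(2)` converts reference offset to perpendicular distance),
then a 3-sigma-style confidence width `3 * sqrt(mean(d_i^2))` trims once
more and the survivors are re-chained to repair the gaps filtering opened.

Each region is then scored by five quantities: covered kmers `n_kmers`,
residual spread `sigma = sqrt(mean(d_i^2))`, matched read span `m_len`,
anchored bases `n_cb`, and the read length.  The last four are normalized to
[0, 1]:

    norm_mlen    = min(1, m_len / T)
    norm_ncb     = min(1, n_cb / max(1, m_len))
    norm_sigma   = max(0, 1 - sigma / (e * T))
    norm_readlen = T / (T + min(Q, 10000))        (Q = total reference length)

and the region quality is their product `f`.  `f` only ranks the candidate
regions of one read, so `norm_readlen` — constant across a read's regions —
never changes a ranking; it is kept for boundedness.  `n_kmers` is excluded
from the product and reserved for ambiguity counting.

## Stage V — final alignment, MAPQ, E-value

The region with the highest `f` is aligned (ties: higher `n_kmers`, then
smaller coordinate).  Three engines:

* **myers** (default): Myers' bit-vector edit-distance alignment,
  semi-global — whole read consumed, free gaps at region ends (edlib).
* **gotoh**: affine-gap semi-global alignment, match 5 / mismatch -4 /
  gap open -8 / gap extend -6 per gap base.
* **anchor**: the stage-III chain is grouped into colinear clusters; a
  neighbour joins a cluster when the read/region gap imbalance
  `|dq - dt| / max(dq, dt)` is below `e/2` (imbalances under 30 bases always
  join — they are below the structural-variant scale); clusters with fewer
  than max(30, 2% of read length) exactly-matching anchor bases are dropped
  (matched bases, not span: sparse chance anchors inside novel sequence must
  not survive as clusters).  Within-cluster segments are aligned with the
  bit-vector engine; between-cluster segments use affine match-reward
  scoring (5/-4/-8/-6), because under pure edit distance the placement of a
  long indel run inside a gap segment is tie-degenerate, letting breakpoint
  edges drift, while affine scoring pins the run to the true breakpoints.
  Read ends are extended with the bit-vector engine without end-gap
  penalty — unless the extension's
  edit fraction exceeds `e`, in which case the end is soft-clipped: sequence
  noisier than the expected error rate is unalignable (typically a read
  running off a structural-variant breakpoint), and force-aligning it sheds
  spurious indel runs across the downstream reference.  Because the clusters come
  from the *pre-refinement* chain, a single alignment can span an insertion
  or deletion of kilobases as one long CIGAR run — the refined chain cannot
  serve here, since the L1 band (±`e·T`) by construction rejects the anchor
  group on the far side of any indel larger than roughly `e·T`.

**Mapping quality.**  Candidate regions whose `n_kmers` is at least
`(1 - F)` times that of the winning region are counted as ambiguous
placements (`N_a`; `F` = 0 by default, counting only ties).  The
wrong-placement probability is `p = max(1 - 1/N_a, 1e-4)` and
`MAPQ = round(-10 log10 p)`, giving the cap Q = 40 for unique placements,
Q = 3 at `N_a` = 2, and 0 in the limit.

**E-value.**  Alignments are rescored (match 5, mismatch -4, gap open -8,
gap extend -6 per gap base — the open is charged once per gap run) and
converted to a BLAST-style expectation with precalculated Gumbel parameters
(defaults lambda = 0.192, K = 0.176, configurable):
`bits = (lambda * AS - ln K) / ln 2`, `ZE = m * n * 2^-bits` with `m` the
read length and `n` the total reference length.  `ZE` is written as a SAM
tag; `-z` filters alignments above a cutoff.  Reads with no surviving region
are reported unmapped rather than force-aligned.

## Synthetic data

The read generator draws one event per step from an i.i.d. multinomial over
{match, mismatch, insertion, deletion}; insertions do not consume the
template, so insertion runs are geometric.  Presets:

| preset | mismatch | insertion | deletion | unaltered steps |
|--------|----------|-----------|----------|-----------------|
| 2D     | 5%       | 4%        | 8%       | 83%             |
| 1D     | 10%      | 5%        | 15%      | 70%             |

These bracket the published accuracy bands of complementary-strand consensus
(~80-88%) and single-strand (~65-75%) nanopore reads.  The template length is
drawn uniformly (1-5 kbp by default), the origin and strand uniformly, and
every read carries an exact per-base map from read positions to reference
positions, so evaluation can check each aligned base against the position it
was simulated from.  Reference-level mutation (SNP rate 0.0006, indel rate
0.0067, indel sizes 1-10 — a draft-assembly-like divergence) and
structural-variant injection (non-overlapping insertions/deletions, sizes
100 bp to 4 kbp) support the consensus and SV experiments.

What the generator does *not* emulate: bursty error clusters, homopolymer
bias (an option exists for deletions but is off by default), quality-value
correlation, and chimeric reads.  Placement of individual bases is therefore
easier than in real nanopore data: with i.i.d. errors an edit-distance
alignment recovers the exact simulated position of ~81% of aligned 1D-preset
bases, although only 70% of generator steps are matches.  Passing the
per-base tests consequently shows the alignment machinery is correct, not
that real-data base-level accuracy would be this high.

## Evaluation procedures

* **Location**: a read is correctly mapped when its reported start, minus
  leading clipped bases, is within ±50 bp of the simulated origin on the
  matching strand.  Precision is over mapped reads, recall over all
  simulated reads.
* **Per-base**: a read base is correctly aligned when placed at exactly the
  position it was simulated from; clipped bases are excluded from precision,
  all simulated bases form the recall denominator.
* **Consensus**: per-position majority vote over {A, C, G, T, deletion} with
  insertions voted by sequence; coverage below 20x is uncalled; ties go to
  the reference base.
* **SV calling**: indel runs >= 20 bases in spanning alignments vote
  per position (insertion support is smeared ±20 bp around the breakpoint,
  since its placement jitters between reads); windows need > 15% supporting
  fraction and >= 5 reads; windows closer than the larger window merge; the
  size estimate is the per-read sum of *all* indel runs near the window
  (the aligner may fragment one event into a long run plus short leftovers),
  median over qualifying reads.  A call matches a true event when its size
  and both endpoints are within 25% of the event size.

## Benchmark scales

The bundled benchmarks (also used by `scripts/acceptance.py`) run on one
CPU in a few minutes: mapping accuracy on a 1 Mbp genome with 200 reads per
preset; the SV experiment on a 300 kbp genome carrying the twenty standard
events at 30x with 2-10 kbp reads.  The SV caller's rules are local, so its
precision/recall do not depend on how much empty genome surrounds the
events; read lengths reach 10 kbp because a 4 kbp insertion can only be
recalled by reads that span it with anchorable flanks on both sides —
with 1-5 kbp reads, recall of the largest events is physically out of reach
at any coverage.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally; SAM output is 1-based.
Weighted medians take the lower value on ties.  An empty chain scores
`f = 0` and the region is dropped; a read whose every region drops is
unmapped.  Reads shorter than the longest shape span are unmapped.  Lookup
layouts that would run past the sequence end are omitted.  Ambiguous bases
(non-ACGT) are never indexed, never produce lookup keys, and never form
stage-II kmers.  The `=`/`X` CIGAR dialect is used internally and collapsed
to `M` on output unless `--extended-cigar` is given.  Mapping is fully
deterministic; `--seed` only affects simulation, and `--threads` is accepted
for interface compatibility while execution is sequential (reads are
independent, so output is identical by construction).

## Known limitations

Mapping to mammalian-scale references would need a leaner index (the posting
arrays are built for up to tens of Mbp).  MAPQ is derived from region-level
ambiguity only, not from alignment-score gaps.  The Gumbel parameters are
BLAST-like defaults, not fitted to the scoring scheme.  The consensus caller
is a plain plurality vote, not a base-quality-aware model.
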