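"""Desk-scale benchmark experiments reproducing the headline behaviours.

Three self-contained experiments, all driven by the synthetic-data module so
no external files are needed:

* :func:`location_benchmark` — mapping accuracy across error profiles: a
  1 Mbp random genome, 200 reads each with the 2D-like and 1D-like presets,
  location precision/recall under the clip-adjusted ±50 bp criterion and
  per-base placement accuracy.
* :func:`mapq_benchmark` — an unambiguously placed read reports the capped
  mapping quality (40).
* :func:`sv_benchmark` — structural-variant detection: a genome carrying ten
  insertions and ten deletions of 100 bp to 4 kbp, 2D-like reads at 30x
  mapped back with anchored alignment, events called by the window-vote
  caller and scored with 25% size/position margins.  The genome is 300 kbp
  (the caller's rules are local, so precision/recall do not depend on how
  much empty genome surrounds the events) and reads are 2-10 kbp so the
  largest events can be spanned with anchorable flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluate import summarize, sv_call, sv_match
from .pipeline import Mapper, MapParams
from .simulate import (
    PROFILE_1D,
    PROFILE_2D,
    SVEvent,
    inject_svs,
    make_reference,
    simulate_reads,
)

#: Structural-variant event sizes, ten insertions and ten deletions.
SV_SIZES = [100, 300, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000]


@dataclass
class LocationResult:
    precision: float  # %, over all mapped reads (both profiles)
    recall: float  # %, over all simulated reads
    base_precision_1d: float  # %, aligned bases placed exactly (1D preset)
    base_precision_2d: float  # %
    n_reads: int
    n_mapped: int


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31)


def location_benchmark(
    seed: int,
    genome_size: int = 1_000_000,
    reads_per_profile: int = 200,
    length_range: tuple[int, int] = (1000, 5000),
) -> LocationResult:
    """Map 2D-like and 1D-like read sets back to their source genome."""
    name, ref, _ = make_reference(genome_size, seed=_sub_seed(seed, 1), name="genome")
    mapper = Mapper([(name, ref)])
    summaries = {}
    for k, profile in ((2, PROFILE_2D), (3, PROFILE_1D)):
        reads = simulate_reads(
            ref,
            reads_per_profile,
            length_range,
            profile,
            seed=_sub_seed(seed, k),
            ref_name=name,
            name_prefix=f"{profile.name}_read",
        )
        alns = {rid: mapper.map_read(rid, seq) for rid, seq, _ in reads}
        summaries[profile.name] = summarize(alns, {rid: o for rid, _, o in reads})
    s2, s1 = summaries["2D"], summaries["1D"]
    mapped = s2.mapped_reads + s1.mapped_reads
    correct = s2.correct_reads + s1.correct_reads
    total = s2.total_reads + s1.total_reads
    return LocationResult(
        precision=100.0 * correct / mapped if mapped else 0.0,
        recall=100.0 * correct / total,
        base_precision_1d=100.0 * s1.base_precision,
        base_precision_2d=100.0 * s2.base_precision,
        n_reads=total,
        n_mapped=mapped,
    )


def mapq_benchmark(seed: int, genome_size: int = 100_000, read_len: int = 2000) -> dict:
    """MAPQ of an error-free read with a single candidate placement."""
    name, ref, _ = make_reference(genome_size, seed=_sub_seed(seed, 5), name="genome")
    mapper = Mapper([(name, ref)])
    start = genome_size // 3
    alns = mapper.map_read("unique_read", ref[start : start + read_len])
    if not alns:
        return {"mapq": -1, "N_a": 0}
    return {"mapq": alns[0].mapq, "N_a": alns[0].N_a}


def sv_benchmark(
    seed: int,
    genome_size: int = 300_000,
    coverage: int = 30,
    length_range: tuple[int, int] = (2000, 10_000),
) -> dict:
    """Window-vote SV detection over the twenty standard events."""
    name, ref, _ = make_reference(genome_size, seed=_sub_seed(seed, 7), name="genome")
    spacing = genome_size // 21
    events = []
    for i, size in enumerate(SV_SIZES):
        events.append(SVEvent("insertion", spacing * (2 * i + 1), size))
        events.append(SVEvent("deletion", spacing * (2 * i + 2), size))
    svref, truth = inject_svs(ref, events, seed=_sub_seed(seed, 8))
    mean_len = sum(length_range) // 2
    n_reads = coverage * genome_size // mean_len
    reads = simulate_reads(
        ref, n_reads, length_range, PROFILE_2D, seed=_sub_seed(seed, 9), ref_name=name
    )
    mapper = Mapper([("sv_genome", svref)], MapParams(aligner="anchor"))
    alignments = []
    for rid, seq, _ in reads:
        alignments.extend(a for a in mapper.map_read(rid, seq) if not a.secondary)
    calls = sv_call(alignments, len(svref))
    precision, recall, tp = sv_match(calls, truth)
    return {
        "precision": 100.0 * precision,
        "recall": 100.0 * recall,
        "tp": tp,
        "n_calls": len(calls),
        "n_reads": n_reads,
    }
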