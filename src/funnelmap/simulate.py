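"""Synthetic references and nanopore-like reads with exact ground truth.

The read error process is a per-position i.i.d. multinomial over
{match, mismatch, insertion, deletion}: at each step an insertion emits a
random base without consuming the reference, a deletion consumes a reference
base without emitting, a mismatch emits one of the three other bases and a
match copies the reference base.  Two presets bracket the accuracy bands of
single-strand ("1D", ~70% of steps unaltered) and complementary-strand
consensus ("2D", ~83%) nanopore reads:

* ``PROFILE_1D`` — 10% mismatch, 5% insertion, 15% deletion;
* ``PROFILE_2D`` — 5% mismatch, 4% insertion, 8% deletion.

Every read carries a :class:`TrueOrigin` with its reference window, strand
and a per-base map from read positions to absolute forward-reference
positions (-1 for inserted bases), so evaluation can check each aligned base
against the exact position it was simulated from.

Reference-level mutation (SNPs + short indels) and structural-variant
injection (insertions/deletions of 100 bp to several kbp) are provided for
consensus- and SV-calling experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import decode, encode, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base mismatch/insertion/deletion probabilities."""

    mismatch_rate: float
    ins_rate: float
    del_rate: float
    name: str = ""

    def __post_init__(self):
        for r in (self.mismatch_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if self.mismatch_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ValueError("rates must sum to < 1")


PROFILE_1D = ErrorProfile(0.10, 0.05, 0.15, name="1D")
PROFILE_2D = ErrorProfile(0.05, 0.04, 0.08, name="2D")
PROFILE_CLEAN = ErrorProfile(0.0, 0.0, 0.0, name="clean")


@dataclass
class TrueOrigin:
    """Ground truth for one simulated read.

    ``base_map[i]`` is the absolute forward-reference position that read base
    ``i`` was copied (or mutated) from, and -1 for inserted bases.  ``edits``
    is the generating edit string over {=, X, I, D} in reference order.
    """

    ref_id: int
    ref_name: str
    strand: str
    start: int
    end: int
    base_map: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    edits: str = ""


@dataclass(frozen=True)
class SVEvent:
    """One structural variant applied to a reference."""

    kind: str  # "insertion" | "deletion"
    pos: int  # 0-based position on the input reference
    size: int

    def __post_init__(self):
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.size <= 0:
            raise ValueError("SV size must be positive")


def _rand_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def make_reference(
    length: int, gc: float = 0.5, seed: int = 0, circular: bool = False, name: str = "ref"
) -> tuple[str, str, bool]:
    """A reproducible random reference: (name, sequence, circular flag)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return name, _rand_seq(rng, length, gc), circular


def mutate_reference(
    ref: str,
    snp_rate: float = 0.0006,
    indel_rate: float = 0.0067,
    indel_max: int = 10,
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """Mutate a reference with SNPs and short indels at the given rates.

    Emulates a draft-assembly-like divergence.  Returns the mutated sequence
    and a variant list; each variant records coordinates in both the original
    (``pos``) and the mutated (``mpos``) sequence.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    mlen = 0
    variants: list[dict] = []
    i = 0
    n = len(ref)
    while i < n:
        r = rng.random()
        if r < snp_rate:
            alt = "ACGT".replace(ref[i].upper(), "")[rng.integers(0, 3)]
            variants.append({"type": "snp", "pos": i, "mpos": mlen, "ref": ref[i], "alt": alt})
            out.append(alt)
            mlen += 1
            i += 1
        elif r < snp_rate + indel_rate:
            size = int(rng.integers(1, indel_max + 1))
            if rng.random() < 0.5:
                ins = _rand_seq(rng, size)
                variants.append({"type": "ins", "pos": i, "mpos": mlen, "alt": ins, "size": size})
                out.append(ins)
                mlen += size
            else:
                size = min(size, n - i)
                variants.append({"type": "del", "pos": i, "mpos": mlen, "ref": ref[i : i + size], "size": size})
                i += size
        else:
            out.append(ref[i])
            mlen += 1
            i += 1
    return "".join(out), variants


def inject_svs(ref: str, events: list[SVEvent], seed: int = 0) -> tuple[str, list[dict]]:
    """Apply non-overlapping structural variants to a reference.

    Returns the modified sequence and a truth list; each entry carries the
    event, its coordinates on the modified sequence (``mstart``/``mend``) and
    the event type an alignment of original-reference reads against the
    modified sequence is expected to show (an injected insertion reads as a
    deletion run and vice versa).
    """
    rng = np.random.default_rng(seed)
    events = sorted(events, key=lambda e: e.pos)
    for a, b in zip(events, events[1:]):
        span_a = a.size if a.kind == "deletion" else 0
        if a.pos + span_a > b.pos:
            raise ValueError(f"overlapping SV events at {a.pos} and {b.pos}")
    out: list[str] = []
    truth: list[dict] = []
    prev = 0
    for ev in events:
        out.append(ref[prev : ev.pos])
        mpos = sum(len(s) for s in out)
        if ev.kind == "insertion":
            out.append(_rand_seq(rng, ev.size))
            truth.append(
                {"event": ev, "mstart": mpos, "mend": mpos + ev.size, "expect": "deletion"}
            )
            prev = ev.pos
        else:
            truth.append({"event": ev, "mstart": mpos, "mend": mpos, "expect": "insertion"})
            prev = ev.pos + ev.size
    out.append(ref[prev:])
    return "".join(out), truth


def _apply_errors(
    template: str,
    profile: ErrorProfile,
    rng: np.random.Generator,
    homopolymer_bias: bool = False,
) -> tuple[str, np.ndarray, str]:
    """Run the i.i.d. error process over a template.

    With ``homopolymer_bias``, the deletion probability is doubled at
    positions repeating their predecessor and halved elsewhere, emulating
    the homopolymer-heavy deletion pattern of nanopore data; the realized
    overall deletion rate then depends on sequence composition.

    Returns (read, map from read positions to template positions, edit string).
    """
    n = len(template)
    pm, px, pi, pd = (
        1.0 - profile.mismatch_rate - profile.ins_rate - profile.del_rate,
        profile.mismatch_rate,
        profile.ins_rate,
        profile.del_rate,
    )
    # one event per step, i.i.d. multinomial over {match, mismatch, ins, del};
    # insertions do not consume the template, so the process factors into a
    # geometric insertion-run before each consuming event
    if pi > 0:
        ins_counts = rng.geometric(1.0 - pi, size=n) - 1
    else:
        ins_counts = np.zeros(n, dtype=np.int64)
    codes = encode(template)
    if homopolymer_bias:
        pd_i = np.full(n, pd * 0.5)
        pd_i[1:][codes[1:] == codes[:-1]] = pd * 2.0
        u = rng.random(n) * (1.0 - pi)
        cons = np.where(u < pd_i, 2, np.where(u < pd_i + px, 1, 0))
    else:
        cons = rng.choice(3, size=n, p=np.array([pm, px, pd]) / (1.0 - pi))
    emits = cons != 2  # deletions emit nothing
    seg_lens = ins_counts + emits
    offs = np.concatenate(([0], np.cumsum(seg_lens)))
    total = int(offs[-1])
    read_codes = np.zeros(total, dtype=np.uint8)
    tmap = np.full(total, -1, dtype=np.int64)
    idx_cons = (offs[:-1] + ins_counts)[emits]
    src = np.flatnonzero(emits)
    out_bases = codes[src].astype(np.int64)
    mism = cons[src] == 1
    out_bases[mism] = (out_bases[mism] + rng.integers(1, 4, size=int(mism.sum()))) % 4
    read_codes[idx_cons] = out_bases
    tmap[idx_cons] = src
    ins_mask = np.ones(total, dtype=bool)
    ins_mask[idx_cons] = False
    read_codes[ins_mask] = rng.integers(0, 4, size=int(ins_mask.sum()))
    # edit string in reference order: I-runs then the consuming op
    eoffs = np.concatenate(([0], np.cumsum(ins_counts + 1)))
    echars = np.full(int(eoffs[-1]), ord("I"), dtype=np.uint8)
    opmap = np.frombuffer(b"=XD", dtype=np.uint8)
    echars[eoffs[:-1] + ins_counts] = opmap[cons]
    return decode(read_codes), tmap, echars.tobytes().decode("ascii")


def simulate_reads(
    ref: str,
    n: int,
    length_range: tuple[int, int] = (1000, 5000),
    profile: ErrorProfile = PROFILE_2D,
    seed: int = 0,
    ref_id: int = 0,
    ref_name: str = "ref",
    name_prefix: str = "read",
    homopolymer_bias: bool = False,
) -> list[tuple[str, str, TrueOrigin]]:
    """Simulate reads with uniform origins, strands and template lengths.

    Returns (read id, read sequence, :class:`TrueOrigin`) triples.  The
    template length is drawn uniformly from ``length_range`` (the emitted
    read length then varies with the sampled insertions and deletions), the
    origin uniformly among windows that fit, and the strand uniformly.
    """
    if len(ref) < length_range[1]:
        raise ValueError("reference shorter than the maximum template length")
    rng = np.random.default_rng(seed)
    out = []
    for ri in range(n):
        tlen = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(0, len(ref) - tlen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        template = ref[start : start + tlen]
        if strand == "-":
            template = revcomp(template)
        read, tmap, edits = _apply_errors(template, profile, rng, homopolymer_bias)
        base_map = np.where(
            tmap >= 0,
            (start + tmap) if strand == "+" else (start + tlen - 1 - tmap),
            -1,
        )
        origin = TrueOrigin(
            ref_id=ref_id,
            ref_name=ref_name,
            strand=strand,
            start=start,
            end=start + tlen,
            base_map=base_map,
            edits=edits,
        )
        out.append((f"{name_prefix}_{ri}", read, origin))
    return out


def write_truth_tsv(path: str, reads: list[tuple[str, str, TrueOrigin]]) -> None:
    """Ground truth as TSV: read id, ref, strand, start, end, edit string."""
    with open(path, "w") as fh:
        fh.write("read_id\tref\tstrand\tstart\tend\tedits\n")
        for rid, _, origin in reads:
            fh.write(
                f"{rid}\t{origin.ref_name}\t{origin.strand}\t{origin.start}\t{origin.end}\t{origin.edits}\n"
            )
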