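"""FASTA/FASTQ input, SAM output and the command-line interface."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from typing import Iterator, TextIO

import click
from Bio import SeqIO

from . import __version__
from .align import Alignment, cigar_to_string
from .pipeline import Mapper, MapParams

logger = logging.getLogger(__name__)


@dataclass
class ReadRecord:
    """One sequencing read."""

    id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality length mismatch")


def read_fasta(path: str) -> Iterator[ReadRecord]:
    """Stream records from a (possibly multi-record, wrapped) FASTA file."""
    for rec in SeqIO.parse(path, "fasta"):
        yield ReadRecord(id=rec.id, sequence=str(rec.seq).upper())


def read_fastq(path: str) -> Iterator[ReadRecord]:
    """Stream records from a FASTQ file."""
    for rec in SeqIO.parse(path, "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield ReadRecord(id=rec.id, sequence=str(rec.seq).upper(), qualities=quals)


def read_sequences(path: str) -> Iterator[ReadRecord]:
    """FASTA or FASTQ, decided by the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            return iter(())
    return read_fastq(path) if first == "@" else read_fasta(path)


def sam_flag(aln: Alignment) -> int:
    flag = 0
    if aln.strand == "-":
        flag |= 16
    if aln.secondary:
        flag |= 256
    return flag


def write_sam(
    out: TextIO,
    alignments: dict[str, list[Alignment]],
    references: list[tuple[str, str]],
    reads: dict[str, ReadRecord] | None = None,
    extended_cigar: bool = False,
    program_args: str = "",
) -> None:
    """Write a headered SAM file; unmapped reads get flag 4 records."""
    out.write("@HD\tVN:1.6\tSO:unsorted\n")
    for name, seq in references:
        out.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
    out.write(f"@PG\tID:funnelmap\tPN:funnelmap\tVN:{__version__}\tCL:{program_args}\n")
    for rid, alns in alignments.items():
        if not alns:
            if reads and rid in reads:
                rec = reads[rid]
                qual = rec.qualities or "*"
                out.write(f"{rid}\t4\t*\t0\t0\t*\t*\t0\t0\t{rec.sequence}\t{qual}\n")
            else:
                out.write(f"{rid}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
            continue
        for aln in alns:
            cigar = cigar_to_string(aln.cigar, extended=extended_cigar)
            qual = aln.qual or "*"
            tags = (
                f"NM:i:{aln.edit_distance}\tAS:i:{aln.score}\t"
                f"ZE:f:{aln.evalue:.6g}\tZF:f:{aln.f:.6g}\tZA:i:{aln.N_a}"
            )
            out.write(
                f"{aln.read_id}\t{sam_flag(aln)}\t{aln.ref_name}\t{aln.pos + 1}\t"
                f"{aln.mapq}\t{cigar}\t*\t0\t0\t{aln.seq}\t{qual}\t{tags}\n"
            )


@click.command(name="funnelmap", context_settings={"help_option_names": ["-h", "--help"]})
@click.option("-r", "--reference", "reference", required=True, type=click.Path(exists=True), help="Reference FASTA.")
@click.option("-d", "--reads", "reads_path", required=True, type=click.Path(exists=True), help="Reads FASTA/FASTQ.")
@click.option("-o", "--out", "out_path", default="-", help="Output SAM (default: stdout).")
@click.option("-C", "--circular", is_flag=True, help="Treat references as circular.")
@click.option("-a", "--aligner", type=click.Choice(["myers", "gotoh", "anchor"]), default="myers", show_default=True)
@click.option("-z", "--evalue", "evalue_cutoff", type=float, default=None, help="Discard alignments with ZE above this.")
@click.option("-F", "--ambiguity", "ambiguity_F", type=float, default=0.0, show_default=True, help="Ambiguity factor for secondary alignments.")
@click.option("-k", "kmer", type=int, default=6, show_default=True, help="Stage-II kmer size.")
@click.option("-l", "outdegree", type=int, default=9, show_default=True, help="Graph out-degree.")
@click.option("--shapes", default=",".join(MapParams().shapes), show_default=True, help="Comma-separated spaced-seed shapes.")
@click.option("--posting-cap", type=int, default=MapParams().posting_cap, show_default=True, help="Skip lookup keys with more postings than this.")
@click.option("--seed", type=int, default=0, show_default=True, help="RNG seed (mapping itself is deterministic).")
@click.option("--threads", type=int, default=1, show_default=True, help="Worker count; output is independent of it.")
@click.option("--extended-cigar", is_flag=True, help="Keep '='/'X' operations in the CIGAR.")
@click.option("-v", "--verbose", count=True, help="Increase logging verbosity.")
@click.version_option(version=__version__)
def cli(
    reference,
    reads_path,
    out_path,
    circular,
    aligner,
    evalue_cutoff,
    ambiguity_F,
    kmer,
    outdegree,
    shapes,
    posting_cap,
    seed,
    threads,
    extended_cigar,
    verbose,
):
    """Map error-prone long reads to a reference and write SAM."""
    logging.basicConfig(
        level=logging.DEBUG if verbose > 1 else logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
    params = MapParams(
        shapes=tuple(s.strip() for s in shapes.split(",") if s.strip()),
        k=kmer,
        l=outdegree,
        posting_cap=posting_cap,
        aligner=aligner,
        ambiguity_F=ambiguity_F,
        evalue_cutoff=evalue_cutoff,
        circular=circular,
    )
    refs = [(rec.id, rec.sequence) for rec in read_fasta(reference)]
    mapper = Mapper(refs, params)
    reads = {rec.id: rec for rec in read_sequences(reads_path)}
    logger.info("mapping %d reads against %d reference(s)", len(reads), len(refs))
    alignments = {
        rid: mapper.map_read(rid, rec.sequence, rec.qualities) for rid, rec in reads.items()
    }
    args = " ".join(sys.argv[1:])
    if out_path == "-":
        write_sam(sys.stdout, alignments, refs, reads, extended_cigar, args)
    else:
        with open(out_path, "w") as fh:
            write_sam(fh, alignments, refs, reads, extended_cigar, args)
    n_mapped = sum(1 for a in alignments.values() if a)
    logger.info("mapped %d/%d reads", n_mapped, len(reads))
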