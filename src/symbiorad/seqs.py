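"""Small sequence utilities shared across the package.

All coordinates in this package are 0-based, half-open. Sequences are plain
uppercase Python strings over the alphabet A/C/G/T/N (IUPAC ambiguity codes
appear only in restriction-enzyme motifs, never in genomic sequence).
"""

from __future__ import annotations

from typing import Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Orientation-free representative: the lexicographic min of a sequence
    and its reverse complement. Used wherever loci are compared or stored
    without strand information (GBS reads come from either fragment end)."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into [(id, sequence)], order preserved."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path, reads: Iterable[tuple[str, str]]) -> None:
    """Write reads as FASTQ with constant Q40 ('I') qualities."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> Iterator[tuple[str, str]]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].strip(), seq
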