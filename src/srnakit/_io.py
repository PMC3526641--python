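"""FASTA/FASTQ helpers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["FastqRead", "read_fasta", "write_fasta", "write_fastq", "parse_fastq", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FastqRead:
    name: str
    sequence: str
    quality: str  # Sanger Phred+33

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.name}: sequence/quality length mismatch")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_fastq(reads: Iterable[FastqRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def parse_fastq(path: str) -> Iterator[FastqRead]:
    """Parse Sanger FASTQ, reporting the 1-based record index on malformed input.

    The 4-line dialect is fixed (no wrapped sequences), which lets errors
    carry the offending record index — a contract the generic parsers in
    Biopython do not provide.
    """
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            idx += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record {idx}: header missing '@'")
            if not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record {idx}: separator missing '+'")
            if not qual or len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {idx}: sequence/quality length mismatch"
                )
            yield FastqRead(header[1:].strip().split()[0], seq.upper(), qual)
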