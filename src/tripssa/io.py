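"""FASTQ/FASTA/TSV plumbing shared by the simulator and the pipeline stages."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

PLACEHOLDER_QUALITY = "I"  # Phred+33 placeholder; quality models are out of scope


def write_fastq(reads, path) -> None:
    """Write (name, sequence) pairs as 4-line FASTQ records."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{PLACEHOLDER_QUALITY * len(seq)}\n")


def read_fastq(path):
    """Yield (name, sequence) pairs from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


def read_fastq_pairs(fwd_path, rev_path):
    """Yield (fwd_sequence, rev_sequence) from two parallel FASTQ files."""
    for (_, fwd), (_, rev) in zip(read_fastq(fwd_path), read_fastq(rev_path), strict=True):
        yield fwd, rev


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
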