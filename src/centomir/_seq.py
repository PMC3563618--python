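"""Small sequence helpers shared across modules.

Sequences are handled internally as uppercase DNA strings (U normalized to
T, matching the miRBase convention of distributing mature miRNAs as RNA
while sequencers report DNA).
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTUN")


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return normalize(seq).translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    s = normalize(seq)
    if not s:
        return 0.0
    return (s.count("G") + s.count("C")) / len(s)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: normalized sequence} (order preserved)."""
    return {rec.id: normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str] | list[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seqrecs, str(path), "fasta")


def write_fastq(path, records: list[tuple[str, str, str]]) -> None:
    """Write (id, sequence, phred+33 quality string) triples as 4-line FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"sequence/quality length mismatch for {name}")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path):
    """Yield (id, sequence, phred score list) from a Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]
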