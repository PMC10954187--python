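"""Read container and FASTA/FASTQ input/output (Biopython-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MAX_PHRED = 93


@dataclass
class Read:
    """An amplicon read: bases plus per-base Phred qualities."""

    read_id: str
    bases: str
    quals: np.ndarray  # int array, one Phred value per base

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > MAX_PHRED):
            raise ValueError(f"read {self.read_id}: Phred values outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.bases)

    def mean_error_phred(self) -> float:
        """Phred-scaled mean per-base error probability, -10*log10(mean(p))."""
        if len(self.quals) == 0:
            return 0.0
        p = np.power(10.0, -self.quals / 10.0)
        return float(-10.0 * np.log10(p.mean()))


def read_fasta_single(path: str | Path, what: str = "FASTA") -> tuple[str, str]:
    """Read a single-record FASTA; returns (name, upper-cased sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{what} file {path}: expected single record, found {len(records)}"
        )
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> List[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64)
        reads.append(Read(rec.id, str(rec.seq).upper(), quals))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
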