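"""Alignment of amplicon reads to a reference, confidence filter, pileup.

Reads are aligned semi-globally (read fully consumed, reference overhang
free) with affine gap penalties on both strands; the better strand is
reported. Because standard mapping quality is poorly defined for a
two-sequence reference-choice problem, each record carries a 0-100
*confidence* derived from how much the best strand outscores the other:
``100 * (1 - second_best / best)``, clipped to [0, 100] (0 when the best
score is not positive). The pileup counts, per reference position, the
aligned A/C/G/T bases, deletions (which consume depth) and anchored
insertions; it is the substrate for both the recall statistic and the
pileup SNV caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pysam

from ._align_core import semiglobal_align, semiglobal_score
from ._seq import encode, revcomp
from .seqio import Read

READ_CONSUMING = {"M", "=", "X", "I", "S"}
REF_CONSUMING = {"M", "=", "X", "D"}


@dataclass
class AlignParams:
    match_score: int = 2
    mismatch_penalty: int = 4
    gap_open: int = 4
    gap_extend: int = 2
    min_confidence: float = 90.0
    band: int = 0  # 0 = full DP

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.mismatch_penalty < 0 or self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("penalties must be non-negative")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")


@dataclass
class AlignmentRecord:
    read_id: str
    ref_name: str
    ref_start: int
    strand: str
    cigar: List[tuple[str, int]]
    score: int
    confidence: float
    seq: str  # read bases in reference orientation
    quals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        consumed = sum(l for op, l in self.cigar if op in READ_CONSUMING)
        if consumed != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: CIGAR consumes {consumed} read bases "
                f"but sequence has {len(self.seq)}"
            )
        prev = None
        for op, l in self.cigar:
            if l <= 0:
                raise ValueError(f"read {self.read_id}: non-positive CIGAR length")
            if op == prev:
                raise ValueError(f"read {self.read_id}: adjacent CIGAR ops of same type")
            prev = op

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(l for op, l in self.cigar if op in REF_CONSUMING)

    def cigar_string(self) -> str:
        return "".join(f"{l}{op}" for op, l in self.cigar)


def _confidence(best: int, second: int) -> float:
    if best <= 0:
        return 0.0
    return float(min(100.0, max(0.0, 100.0 * (1.0 - second / best))))


def align_reads(
    reads: Sequence[Read],
    reference: str,
    params: AlignParams = AlignParams(),
    ref_name: str = "ref",
) -> List[AlignmentRecord]:
    """Best-strand semi-global alignment of each read against the reference.

    Ties prefer the + strand; among equal-scoring end positions the
    leftmost anchor is taken. Reads longer than twice the reference are
    rejected (misconfigured input, e.g. unfiltered chimeras).
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    ref_codes = encode(reference)
    out: List[AlignmentRecord] = []
    ma, mm = params.match_score, params.mismatch_penalty
    go, ge = params.gap_open, params.gap_extend
    for read in reads:
        if len(read.bases) > 2 * len(reference):
            raise ValueError(
                f"read {read.read_id} is longer than twice the reference "
                f"({len(read.bases)} vs {len(reference)}); misconfigured input"
            )
        fwd_codes = encode(read.bases)
        rc = revcomp(read.bases)
        rev_codes = encode(rc)
        s_fwd = semiglobal_score(fwd_codes, ref_codes, ma, mm, go, ge, params.band)
        s_rev = semiglobal_score(rev_codes, ref_codes, ma, mm, go, ge, params.band)
        if s_fwd >= s_rev:
            strand, codes, seq = "+", fwd_codes, read.bases
            quals = read.quals
            best, second = s_fwd, s_rev
        else:
            strand, codes, seq = "-", rev_codes, rc
            quals = read.quals[::-1]
            best, second = s_rev, s_fwd
        score, ref_start, cigar = semiglobal_align(codes, ref_codes, ma, mm, go, ge, params.band)
        out.append(
            AlignmentRecord(
                read_id=read.read_id,
                ref_name=ref_name,
                ref_start=ref_start,
                strand=strand,
                cigar=cigar,
                score=score,
                confidence=_confidence(best, second),
                seq=seq,
                quals=np.asarray(quals) if quals is not None else None,
            )
        )
    return out


def filter_alignments(
    records: Sequence[AlignmentRecord], min_confidence: float
) -> List[AlignmentRecord]:
    """Keep records whose strand-discrimination confidence is >= threshold."""
    return [r for r in records if r.confidence >= min_confidence]


@dataclass(frozen=True)
class PileupColumn:
    pos: int
    depth: int
    base_counts: dict
    del_count: int
    ins_count: int
    ref_match_fraction: Optional[float]


class Pileup:
    """Per-position base/deletion/insertion counts over a reference."""

    def __init__(self, reference: str, ref_name: str = "ref"):
        self.reference = reference
        self.ref_name = ref_name
        m = len(reference)
        self.base_counts = np.zeros((4, m), dtype=np.int64)  # rows A,C,G,T
        self.del_count = np.zeros(m, dtype=np.int64)
        self.ins_count = np.zeros(m, dtype=np.int64)
        self._ref_codes = encode(reference)

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=0) + self.del_count

    @property
    def ref_match_fraction(self) -> np.ndarray:
        """Fraction of reads matching the reference base; NaN at zero depth
        or where the reference base is N."""
        depth = self.depth
        m = len(self.reference)
        matches = np.zeros(m, dtype=np.int64)
        valid = self._ref_codes < 4
        idx = np.nonzero(valid)[0]
        matches[idx] = self.base_counts[self._ref_codes[idx], idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, matches / np.maximum(depth, 1), np.nan)
        frac = np.where(valid, frac, np.nan)
        return frac

    def __len__(self) -> int:
        return len(self.reference)

    def __getitem__(self, pos: int) -> PileupColumn:
        frac = self.ref_match_fraction[pos]
        return PileupColumn(
            pos=pos,
            depth=int(self.depth[pos]),
            base_counts={b: int(self.base_counts[i, pos]) for i, b in enumerate("ACGT")},
            del_count=int(self.del_count[pos]),
            ins_count=int(self.ins_count[pos]),
            ref_match_fraction=None if math.isnan(frac) else float(frac),
        )

    def __iter__(self):
        for pos in range(len(self)):
            yield self[pos]

    def to_tsv(self, path: str | Path) -> None:
        frac = self.ref_match_fraction
        depth = self.depth
        with open(path, "w") as fh:
            fh.write("pos_1based\tref\tdepth\tA\tC\tG\tT\tdel\tins\tmatch_fraction\n")
            for i in range(len(self)):
                mf = "NA" if math.isnan(frac[i]) else f"{frac[i]:.6f}"
                fh.write(
                    f"{i + 1}\t{self.reference[i]}\t{depth[i]}\t"
                    f"{self.base_counts[0, i]}\t{self.base_counts[1, i]}\t"
                    f"{self.base_counts[2, i]}\t{self.base_counts[3, i]}\t"
                    f"{self.del_count[i]}\t{self.ins_count[i]}\t{mf}\n"
                )


def build_pileup(records: Sequence[AlignmentRecord], reference: str, ref_name: str = "ref") -> Pileup:
    """Accumulate aligned bases, deletions and anchored insertions.

    M/=/X ops add base counts, D ops add deletions (which count toward
    depth), I ops increment the insertion count of the preceding column.
    """
    pile = Pileup(reference, ref_name)
    m = len(reference)
    for rec in records:
        rpos = rec.ref_start
        qpos = 0
        codes = encode(rec.seq)
        for op, length in rec.cigar:
            if op in ("M", "=", "X"):
                if rpos + length > m:
                    raise ValueError(
                        f"read {rec.read_id}: CIGAR extends past the reference"
                    )
                seg = codes[qpos : qpos + length]
                positions = np.arange(rpos, rpos + length)
                ok = seg < 4
                np.add.at(pile.base_counts, (seg[ok], positions[ok]), 1)
                rpos += length
                qpos += length
            elif op == "D":
                pile.del_count[rpos : rpos + length] += 1
                rpos += length
            elif op == "I":
                anchor = rpos - 1
                if 0 <= anchor < m:
                    pile.ins_count[anchor] += 1
                qpos += length
            elif op == "S":
                qpos += length
            else:
                raise ValueError(f"read {rec.read_id}: unsupported CIGAR op {op}")
        if qpos != len(rec.seq):
            raise ValueError(f"read {rec.read_id}: CIGAR inconsistent with read length")
    return pile


# ---------------------------------------------------------------------------
# SAM input/output (text SAM via pysam)

_OP_TO_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "=": 7, "X": 8}
_CODE_TO_OP = {v: k for k, v in _OP_TO_CODE.items()}


def write_sam(
    records: Sequence[AlignmentRecord], reference: str, path: str | Path, ref_name: str = "ref"
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref_name, "LN": len(reference)}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq
            if rec.quals is not None:
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(int(q) + 33) for q in rec.quals)
                )
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = rec.ref_start
            a.mapping_quality = min(60, int(round(rec.confidence * 0.6)))
            a.cigartuples = [(_OP_TO_CODE[op], l) for op, l in rec.cigar]
            a.set_tag("AS", int(rec.score))
            a.set_tag("cf", float(round(rec.confidence, 4)))
            fh.write(a)


def read_sam(path: str | Path) -> List[AlignmentRecord]:
    records: List[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            cigar = [(_CODE_TO_OP[code], l) for code, l in a.cigartuples]
            quals = (
                np.array(a.query_qualities, dtype=np.int64)
                if a.query_qualities is not None
                else None
            )
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    ref_name=a.reference_name,
                    ref_start=a.reference_start,
                    strand="-" if a.is_reverse else "+",
                    cigar=cigar,
                    score=int(a.get_tag("AS")) if a.has_tag("AS") else 0,
                    confidence=float(a.get_tag("cf")) if a.has_tag("cf") else 0.0,
                    seq=a.query_sequence,
                    quals=quals,
                )
            )
    return records
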