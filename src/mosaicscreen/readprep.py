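"""Pre-alignment read filters.

Mirrors the front of the screening pipeline: keep reads that show a
barcode near *both* ends and none internally (internal barcodes mark
artificial chimeras), rank reads by a relative quality score and keep the
top fraction, and optionally thin the read set to titrate depth
(Bernoulli per-read retention with a fixed seed, seqtk-style).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from ._seq import revcomp
from .seqio import Read

FILTER_REASONS = ("ok", "missing_barcode", "internal_barcode", "low_quality", "subsampled_out")


@dataclass
class BarcodeSpec:
    barcode_id: str
    fwd_seq: str
    rev_seq: str
    max_mismatches: int = 3
    end_window: int = 150

    def __post_init__(self) -> None:
        if not self.fwd_seq or not self.rev_seq:
            raise ValueError("barcode sequences must be non-empty")
        self.fwd_seq = self.fwd_seq.upper()
        self.rev_seq = self.rev_seq.upper()
        shortest = min(len(self.fwd_seq), len(self.rev_seq))
        if self.max_mismatches >= shortest:
            raise ValueError("max_mismatches must be smaller than the barcode length")
        if self.end_window < max(len(self.fwd_seq), len(self.rev_seq)):
            raise ValueError("end_window must be at least the barcode length")

    def all_queries(self) -> List[str]:
        qs = {self.fwd_seq, self.rev_seq, revcomp(self.fwd_seq), revcomp(self.rev_seq)}
        return sorted(qs)


@dataclass(frozen=True)
class FilterDecision:
    read_id: str
    kept: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in FILTER_REASONS:
            raise ValueError(f"unknown filter reason {self.reason!r}")
        if self.kept != (self.reason == "ok"):
            raise ValueError("kept must be true exactly when reason is 'ok'")


def _find_matches(query: str, target: str, k: int) -> List[Tuple[int, int]]:
    """(start, end) intervals where query matches target with <= k edits."""
    if len(target) < 1:
        return []
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return []
    return [(s, e + 1) for s, e in res["locations"]]


def demux_and_dechimera(
    reads: Sequence[Read], spec: BarcodeSpec
) -> tuple[List[Read], List[FilterDecision]]:
    """Keep reads with a barcode at both ends and none strictly internal.

    A read passes iff some barcode (either orientation) matches within the
    first ``end_window`` bases AND within the last ``end_window`` bases,
    and no barcode match lies entirely outside both terminal windows.
    Kept reads are trimmed of their terminal barcode segments.
    """
    kept: List[Read] = []
    decisions: List[FilterDecision] = []
    queries = spec.all_queries()
    w = spec.end_window
    for read in reads:
        n = len(read.bases)
        head = read.bases[: min(w, n)]
        tail = read.bases[max(0, n - w) :]
        tail_off = max(0, n - w)

        head_hits = [m for q in queries for m in _find_matches(q, head, spec.max_mismatches)]
        tail_hits = [
            (s + tail_off, e + tail_off)
            for q in queries
            for s, e in _find_matches(q, tail, spec.max_mismatches)
        ]
        if not head_hits or not tail_hits:
            decisions.append(FilterDecision(read.read_id, False, "missing_barcode"))
            continue

        internal = False
        if n > 2 * w:
            core = read.bases[w : n - w]
            for q in queries:
                if _find_matches(q, core, spec.max_mismatches):
                    internal = True
                    break
        if internal:
            decisions.append(FilterDecision(read.read_id, False, "internal_barcode"))
            continue

        # Earliest-ending head hit and latest-starting tail hit keep the
        # retained core maximal.
        trim_start = min(e for _, e in head_hits)
        trim_end = max(s for s, _ in tail_hits)
        if trim_end <= trim_start:
            decisions.append(FilterDecision(read.read_id, False, "missing_barcode"))
            continue
        trimmed = Read(read.read_id, read.bases[trim_start:trim_end], read.quals[trim_start:trim_end])
        kept.append(trimmed)
        decisions.append(FilterDecision(read.read_id, True, "ok"))
    return kept, decisions


def quality_rank_filter(
    reads: Sequence[Read], q_threshold: float
) -> tuple[List[Read], List[FilterDecision]]:
    """Keep reads whose relative quality percentile is >= ``q_threshold``.

    Each read is scored as -10*log10(mean per-base error probability); the
    cutoff is the ``q_threshold``-th percentile of the score distribution
    (upper interpolation), and every read scoring at or above it is kept —
    so ties are kept and the filter is monotone in the threshold.
    """
    if not (0 <= q_threshold <= 100):
        raise ValueError("q_threshold must be in [0, 100]")
    if not reads:
        return [], []
    scores = np.array([r.mean_error_phred() for r in reads])
    cutoff = float(np.quantile(scores, q_threshold / 100.0, method="higher"))
    kept, decisions = [], []
    for r, s in zip(reads, scores):
        if s >= cutoff:
            kept.append(r)
            decisions.append(FilterDecision(r.read_id, True, "ok"))
        else:
            decisions.append(FilterDecision(r.read_id, False, "low_quality"))
    return kept, decisions


def subsample(
    reads: Sequence[Read],
    proportion: float,
    seed: int = 100,
    exact: bool = False,
) -> List[Read]:
    """Seeded depth reduction, preserving read order.

    Default is Bernoulli per-read retention with probability ``proportion``
    (the semantics of seqtk-style thinning); ``exact=True`` instead keeps
    exactly round(proportion * n) reads, for deterministic fixtures.
    """
    if not (0 < proportion <= 1):
        raise ValueError("proportion must be in (0, 1]")
    if proportion == 1.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    n = len(reads)
    if exact:
        k = int(round(proportion * n))
        idx = sorted(int(i) for i in rng.choice(n, size=k, replace=False))
        return [reads[i] for i in idx]
    mask = rng.random(n) < proportion
    return [r for r, m in zip(reads, mask) if m]


def write_decisions(decisions: Iterable[FilterDecision], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tkept\treason\n")
        for d in decisions:
            fh.write(f"{d.read_id}\t{str(d.kept).lower()}\t{d.reason}\n")


def load_barcode_sheet(path: str | Path) -> List[BarcodeSpec]:
    """Read a TSV barcode sheet: barcode_id, fwd, rev[, max_mismatches, end_window]."""
    specs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            specs.append(
                BarcodeSpec(
                    barcode_id=row["barcode_id"],
                    fwd_seq=row["fwd"],
                    rev_seq=row["rev"],
                    max_mismatches=int(row.get("max_mismatches", 3)),
                    end_window=int(row.get("end_window", 150)),
                )
            )
    return specs
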