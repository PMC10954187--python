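"""Consensus-threshold reference recall with homopolymer masking.

The screen's accuracy statistic: a reference position is *recalled* when
the fraction of aligned reads matching the reference base meets or
surpasses the consensus threshold (e.g. 60%). Recall is the percentage
of reference positions recalled, optionally excluding positions inside
single-base homopolymer runs of length >= k (where nanopore error
concentrates) from both numerator and denominator. Zero-depth unmasked
positions stay in the denominator and are never recalled, so recall
drops when aggressive filtering leaves too few reads for full coverage.

``sweep_recall`` grids the statistic over relative-quality thresholds,
seeded depth subsampling proportions, consensus thresholds and mask run
lengths, re-running the quality filter -> subsample -> align -> pileup ->
recall chain per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import homopolymer_runs
from .readprep import quality_rank_filter, subsample
from .seqio import Read
from .targetalign import AlignParams, Pileup, align_reads, build_pileup, filter_alignments

#: Depth-proportion grid used for the titration sweeps, plus the full set.
DEFAULT_DEPTH_GRID = (
    0.0001, 0.0005, 0.001, 0.002, 0.003, 0.004, 0.005,
    0.01, 0.02, 0.04, 0.1, 0.2, 0.5, 0.75, 1.0,
)

DEFAULT_CONSENSUS_GRID = (50, 60, 70, 80, 90, 100)


@dataclass
class HomopolymerMask:
    """Masked intervals: maximal single-base runs of length >= k."""

    k: int
    intervals: List[tuple[int, int]]

    def positions(self, length: int) -> np.ndarray:
        mask = np.zeros(length, dtype=bool)
        for s, e in self.intervals:
            mask[s:e] = True
        return mask

    @property
    def n_masked(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def to_bed(self, path: str | Path, ref_name: str = "ref") -> None:
        with open(path, "w") as fh:
            for s, e in self.intervals:
                fh.write(f"{ref_name}\t{s}\t{e}\thp_run_ge_{self.k}\n")


def homopolymer_mask(reference: str, k: int) -> HomopolymerMask:
    """Mask exactly the positions inside maximal single-base runs >= k."""
    if k < 2:
        raise ValueError("k must be >= 2")
    intervals = [
        (start, end)
        for start, end, _ in homopolymer_runs(reference)
        if end - start >= k
    ]
    return HomopolymerMask(k, intervals)


@dataclass
class RecallResult:
    consensus_threshold: float
    quality_threshold: Optional[float]
    depth_proportion: Optional[float]
    n_positions: int
    n_masked: int
    n_zero_depth: int
    n_recalled: int

    @property
    def recall_pct(self) -> float:
        denom = self.n_positions - self.n_masked
        return 100.0 * self.n_recalled / denom if denom else float("nan")


def recall(
    pileup: Pileup,
    consensus_threshold: float,
    mask: Optional[HomopolymerMask] = None,
) -> RecallResult:
    """Count unmasked positions whose match fraction meets the threshold.

    A position is recalled iff depth > 0 and 100 * ref_match_fraction >=
    consensus_threshold ("met or surpassed", inclusive). Masked positions
    are excluded from numerator and denominator.
    """
    if not (0 < consensus_threshold <= 100):
        raise ValueError("consensus_threshold must be in (0, 100]")
    m = len(pileup)
    masked = mask.positions(m) if mask is not None else np.zeros(m, dtype=bool)
    depth = pileup.depth
    frac = pileup.ref_match_fraction
    unmasked = ~masked
    covered = unmasked & (depth > 0)
    with np.errstate(invalid="ignore"):
        recalled = covered & (100.0 * np.nan_to_num(frac, nan=-1.0) >= consensus_threshold)
    return RecallResult(
        consensus_threshold=consensus_threshold,
        quality_threshold=None,
        depth_proportion=None,
        n_positions=m,
        n_masked=int(masked.sum()),
        n_zero_depth=int((unmasked & (depth == 0)).sum()),
        n_recalled=int(recalled.sum()),
    )


def sweep_recall(
    reads: Sequence[Read],
    reference: str,
    consensus_grid: Sequence[float] = DEFAULT_CONSENSUS_GRID,
    quality_grid: Sequence[float] = (90,),
    depth_grid: Sequence[float] = DEFAULT_DEPTH_GRID,
    k_values: Sequence[Optional[int]] = (None, 4, 5),
    seed: int = 100,
    params: AlignParams = AlignParams(band=200),
) -> pd.DataFrame:
    """Recall over the full (quality, depth, consensus, k) grid.

    Alignment is performed once per (quality, depth) cell and the pileup
    reused across consensus thresholds and masks. Subsampling proportions
    below 1 use Bernoulli thinning under ``seed`` (one independent draw
    per cell, derived deterministically from the cell index).
    """
    if not consensus_grid or not quality_grid or not depth_grid:
        raise ValueError("grids must be non-empty")
    masks = {k: (homopolymer_mask(reference, k) if k else None) for k in k_values}
    rows = []
    for qi, q in enumerate(quality_grid):
        q_reads, _ = quality_rank_filter(reads, q)
        for di, prop in enumerate(depth_grid):
            try:
                cell_reads = (
                    subsample(q_reads, prop, seed=seed + 1000 * qi + di)
                    if prop < 1.0
                    else list(q_reads)
                )
                records = filter_alignments(
                    align_reads(cell_reads, reference, params),
                    params.min_confidence,
                )
                pile = build_pileup(records, reference)
            except Exception as exc:  # pragma: no cover - propagate with context
                raise RuntimeError(
                    f"sweep cell quality={q} depth={prop} failed: {exc}"
                ) from exc
            for k, mask in masks.items():
                for c in consensus_grid:
                    res = recall(pile, c, mask)
                    rows.append(
                        {
                            "quality_threshold": q,
                            "depth_proportion": prop,
                            "realized_depth": len(cell_reads),
                            "n_aligned": len(records),
                            "consensus_threshold": c,
                            "homopolymer_k": 0 if k is None else k,
                            "n_positions": res.n_positions,
                            "n_masked": res.n_masked,
                            "n_zero_depth": res.n_zero_depth,
                            "n_recalled": res.n_recalled,
                            "recall_pct": res.recall_pct,
                        }
                    )
    return pd.DataFrame(rows)
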