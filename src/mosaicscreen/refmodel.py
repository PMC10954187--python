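"""Reference model: WT/mutant locus pair and mutant determinants.

A designed edit (loxP insertion, cassette knock-in, point mutation) is
described on the *mutant* sequence as a 0-based half-open interval. A
"mutant determinant" is a subsequence of the mutant that does not occur in
the wild-type sequence on either strand; reads containing it can only
derive from an edited allele. Typical choices are a fixed-width window
around a point mutation (default 30 nt) or the whole inserted segment plus
short junction flanks for knock-ins and floxed alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import yaml

from ._seq import check_alphabet, revcomp
from .seqio import read_fasta_single, write_fasta

logger = logging.getLogger(__name__)

EDIT_CLASSES = ("insertion", "substitution", "point_mutation")


@dataclass(frozen=True)
class Edit:
    """A designed difference between WT and mutant, on mutant coordinates.

    ``wt_len`` is the length of the WT segment this edit replaced
    (0 for a pure insertion, the interval length for a same-length
    substitution, 1 for a point mutation). It lets alleles be mapped back
    to WT exactly, e.g. to model partial donor integrations.
    """

    label: str
    start: int
    end: int
    edit_class: str
    wt_len: int = -1  # -1: infer from edit_class

    def __post_init__(self) -> None:
        if self.edit_class not in EDIT_CLASSES:
            raise ValueError(f"edit {self.label}: unknown class {self.edit_class!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"edit {self.label}: bad interval [{self.start},{self.end})")
        if self.wt_len < 0:
            inferred = {
                "insertion": 0,
                "substitution": self.end - self.start,
                "point_mutation": 1,
            }[self.edit_class]
            object.__setattr__(self, "wt_len", inferred)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class EditedLocus:
    """Paired WT/designed-mutant reference with annotated edits."""

    name: str
    wt_seq: str
    mut_seq: str
    edits: List[Edit]

    def __post_init__(self) -> None:
        self.wt_seq = check_alphabet(self.wt_seq, f"{self.name} wt_seq")
        self.mut_seq = check_alphabet(self.mut_seq, f"{self.name} mut_seq")
        self.edits = sorted(self.edits, key=lambda e: e.start)
        seen = set()
        prev_end = 0
        for e in self.edits:
            if e.label in seen:
                raise ValueError(f"duplicate edit label {e.label!r}")
            seen.add(e.label)
            if e.end > len(self.mut_seq):
                raise ValueError(
                    f"edit {e.label}: interval [{e.start},{e.end}) out of bounds "
                    f"for mut_seq of length {len(self.mut_seq)}"
                )
            if e.start < prev_end:
                raise ValueError(f"edit {e.label}: overlaps previous edit")
            prev_end = e.end

    def edit(self, label: str) -> Edit:
        for e in self.edits:
            if e.label == label:
                return e
        raise KeyError(f"no edit labelled {label!r} in locus {self.name}")

    def wt_start_of(self, edit: Edit) -> int:
        """WT coordinate corresponding to ``edit.start`` on the mutant."""
        offset = 0
        for e in self.edits:
            if e.start >= edit.start:
                break
            offset += e.wt_len - (e.end - e.start)
        return edit.start + offset

    def revert_edit(self, label: str) -> str:
        """Mutant sequence with one edit replaced by its WT segment."""
        e = self.edit(label)
        ws = self.wt_start_of(e)
        wt_segment = self.wt_seq[ws : ws + e.wt_len]
        return self.mut_seq[: e.start] + wt_segment + self.mut_seq[e.end :]

    def validate_consistency(self) -> None:
        """Check that reverting every edit reconstructs wt_seq exactly."""
        seq = self.mut_seq
        for e in sorted(self.edits, key=lambda x: x.start, reverse=True):
            ws = self.wt_start_of(e)
            seq = seq[: e.start] + self.wt_seq[ws : ws + e.wt_len] + seq[e.end :]
        if seq != self.wt_seq:
            raise ValueError(
                f"locus {self.name}: reverting all annotated edits does not "
                "reconstruct wt_seq; check edit intervals and wt_len values"
            )


DETERMINANT_MODES = ("point_mutation", "insert")


@dataclass(frozen=True)
class Determinant:
    """A mutant-exclusive subsequence used to partition reads."""

    label: str
    seq: str
    start: int
    end: int
    mode: str

    @property
    def mut_interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DeterminantSet:
    determinants: List[Determinant]
    require_all: bool = True

    def __post_init__(self) -> None:
        labels = [d.label for d in self.determinants]
        if len(set(labels)) != len(labels):
            raise ValueError("determinant labels must be unique")

    def __iter__(self):
        return iter(self.determinants)

    def __len__(self) -> int:
        return len(self.determinants)

    def to_fasta(self, path: str | Path) -> None:
        write_fasta([(d.label, d.seq) for d in self.determinants], path)

    def to_bed(self, path: str | Path, ref_name: str) -> None:
        with open(path, "w") as fh:
            for d in self.determinants:
                fh.write(f"{ref_name}\t{d.start}\t{d.end}\t{d.label}\n")


def load_locus(
    wt_fasta: str | Path, mut_fasta: str | Path, annotations: str | Path
) -> EditedLocus:
    """Load an EditedLocus from two single-record FASTAs and a YAML annotation.

    The YAML file has keys ``name`` and ``edits``, the latter a list of
    ``{label, start, end, class, wt_len?}`` entries on mutant coordinates.
    """
    _, wt_seq = read_fasta_single(wt_fasta, "WT FASTA")
    _, mut_seq = read_fasta_single(mut_fasta, "mutant FASTA")
    with open(annotations) as fh:
        ann = yaml.safe_load(fh)
    edits = [
        Edit(
            label=str(e["label"]),
            start=int(e["start"]),
            end=int(e["end"]),
            edit_class=str(e["class"]),
            wt_len=int(e.get("wt_len", -1)),
        )
        for e in ann.get("edits", [])
    ]
    locus = EditedLocus(str(ann["name"]), wt_seq, mut_seq, edits)
    locus.validate_consistency()
    return locus


def _wt_exclusive(candidate: str, wt_seq: str, wt_rc: str) -> bool:
    return candidate not in wt_seq and candidate not in wt_rc


def _make_exclusive(
    locus: EditedLocus, label: str, start: int, end: int, wt_rc: str, mode: str
) -> Determinant:
    """Extend [start, end) symmetrically until absent from WT on both strands."""
    m = len(locus.mut_seq)
    while True:
        cand = locus.mut_seq[start:end]
        if _wt_exclusive(cand, locus.wt_seq, wt_rc):
            return Determinant(label, cand, start, end, mode)
        if start == 0 and end == m:
            raise ValueError(
                f"determinant for edit {label!r} cannot be made WT-exclusive "
                "within reference bounds"
            )
        start = max(0, start - 1)
        end = min(m, end + 1)


def derive_determinants(
    locus: EditedLocus,
    mode: str = "insert",
    window: int = 30,
    flank: int = 15,
    seed_edits: Optional[Sequence[str]] = None,
) -> DeterminantSet:
    """Derive one mutant determinant per designed edit.

    mode="point_mutation": a ``window``-length subsequence of the mutant
    centered on each point edit (truncated, not shifted, at reference ends).
    mode="insert": the whole inserted/substituted segment plus ``flank`` bp
    of junction context on each side — wide enough flanks that two inserts
    sharing an identical core (e.g. the two loxP sites of a floxed design)
    are still distinguished by their junction context at the scan stage.
    Any candidate that still occurs in WT
    (either strand) is extended symmetrically until exclusive, or an error
    is raised when the whole mutant sequence is reached.
    """
    if mode not in DETERMINANT_MODES:
        raise ValueError(f"unknown determinant mode {mode!r}")
    if window < 1:
        raise ValueError("window must be >= 1")
    if not locus.edits:
        raise ValueError(f"locus {locus.name}: no edits to derive determinants from")
    edits = locus.edits
    if seed_edits is not None:
        edits = [locus.edit(lbl) for lbl in seed_edits]

    wt_rc = revcomp(locus.wt_seq)
    m = len(locus.mut_seq)
    out: List[Determinant] = []
    for e in edits:
        if mode == "point_mutation":
            if e.edit_class != "point_mutation":
                continue
            center = e.start
            start = center - (window - 1) // 2
            end = start + window
            if start < 0 or end > m:
                logger.warning(
                    "determinant window for edit %s truncated at reference end", e.label
                )
            start, end = max(0, start), min(m, end)
        else:
            if e.edit_class not in ("insertion", "substitution"):
                continue
            start = max(0, e.start - flank)
            end = min(m, e.end + flank)
        out.append(_make_exclusive(locus, e.label, start, end, wt_rc, mode))
    if not out:
        raise ValueError(
            f"locus {locus.name}: no edits compatible with determinant mode {mode!r}"
        )
    return DeterminantSet(out)


@dataclass(frozen=True)
class DeterminantCheck:
    label: str
    present_in_mut: bool
    absent_from_wt: bool
    absent_from_wt_revcomp: bool

    @property
    def ok(self) -> bool:
        return self.present_in_mut and self.absent_from_wt and self.absent_from_wt_revcomp


@dataclass
class VerificationReport:
    checks: List[DeterminantCheck]

    @property
    def passed(self) -> bool:
        return all(c.ok for c in self.checks)


def verify_determinants(dset: DeterminantSet, locus: EditedLocus) -> VerificationReport:
    """Exhaustive substring verification of every determinant's exclusivity."""
    wt_rc = revcomp(locus.wt_seq)
    checks = [
        DeterminantCheck(
            label=d.label,
            present_in_mut=locus.mut_seq[d.start : d.end] == d.seq and d.seq in locus.mut_seq,
            absent_from_wt=d.seq not in locus.wt_seq,
            absent_from_wt_revcomp=d.seq not in wt_rc,
        )
        for d in dset
    ]
    return VerificationReport(checks)
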