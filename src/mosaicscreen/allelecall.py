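"""Determinant-based read partitioning, variant calling and classification.

The decision layer of the screen: reads are scanned for mutant
determinants by local alignment (both strands); reads hitting every
required determinant form the "Passed reads" set, which is aligned to
the designed mutant reference to (a) measure consensus recall, (b) call
in-cis SNVs from the pileup and (c) detect large indel/duplication
signatures from per-read CIGARs. The sample is then classified:

- NO_CONFORMING_ALLELE  — no read carries all determinants
- INSUFFICIENT_DATA     — too few passed reads to judge
- CORRECT_WITH_CIS_VARIANT — passed reads carry an SNV/SV (or recall of
  the mutant reference is imperfect outside homopolymer runs)
- CORRECT_ALLELE_PRESENT — passed reads recall the mutant reference
  perfectly at the configured consensus threshold

The SNV caller and the CIGAR SV detector are deliberately simple
pileup/CIGAR stand-ins for external consensus-polishing and SV callers;
they are screen output, not inferential statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import edlib
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import yaml

from ._align_core import semiglobal_align as semiglobal_align_codes
from ._seq import encode, revcomp
from .readprep import (
    BarcodeSpec,
    FilterDecision,
    demux_and_dechimera,
    quality_rank_filter,
    subsample,
    write_decisions,
)
from .recallstats import HomopolymerMask, RecallResult, homopolymer_mask, recall
from .refmodel import Determinant, DeterminantSet, EditedLocus, derive_determinants, load_locus
from .seqio import Read, read_fastq
from .targetalign import (
    AlignParams,
    AlignmentRecord,
    Pileup,
    align_reads,
    build_pileup,
    filter_alignments,
    write_sam,
)

CLASSIFICATIONS = (
    "CORRECT_ALLELE_PRESENT",
    "CORRECT_WITH_CIS_VARIANT",
    "NO_CONFORMING_ALLELE",
    "INSUFFICIENT_DATA",
)


@dataclass(frozen=True)
class DeterminantHit:
    read_id: str
    determinant: str
    identity: float
    coverage: float
    read_interval: tuple[int, int]
    strand: str


@dataclass
class PartitionedReads:
    passed: List[str]
    failed: List[str]
    hits: Dict[str, List[DeterminantHit]]

    @property
    def n_passed(self) -> int:
        return len(self.passed)


def _infix_scan(det_codes: np.ndarray, target_codes: np.ndarray, params: AlignParams):
    """Determinant-global (infix) alignment of the determinant within a read.

    The determinant is consumed end to end (read overhang free), so a
    trimmed local hit cannot masquerade as full containment: every
    determinant base either aligns (match/mismatch/gap column) or falls
    outside the read bounds (terminal insertion, counted as uncovered).
    """
    score, ref_start, cigar = semiglobal_align_codes(
        det_codes,
        target_codes,
        params.match_score,
        params.mismatch_penalty,
        params.gap_open,
        params.gap_extend,
    )
    # terminal I ops at the read bounds are determinant overhang
    head_over = (
        cigar[0][1] if cigar and cigar[0][0] == "I" and ref_start == 0 else 0
    )
    ref_len = sum(l for op, l in cigar if op in ("M", "D"))
    tail_over = (
        cigar[-1][1]
        if len(cigar) > 1
        and cigar[-1][0] == "I"
        and ref_start + ref_len == target_codes.shape[0]
        else 0
    )
    matches = columns = 0
    qpos, rpos = 0, ref_start
    for idx, (op, length) in enumerate(cigar):
        terminal = (idx == 0 and op == "I" and head_over) or (
            idx == len(cigar) - 1 and op == "I" and tail_over
        )
        if op == "M":
            for k in range(length):
                if (
                    det_codes[qpos + k] == target_codes[rpos + k]
                    and det_codes[qpos + k] < 4
                ):
                    matches += 1
            columns += length
            qpos += length
            rpos += length
        elif op == "I":
            if not terminal:
                columns += length
            qpos += length
        elif op == "D":
            columns += length
            rpos += length
    target_end = rpos
    return {
        "score": score,
        "matches": matches,
        "columns": columns,
        "overhang": head_over + tail_over,
        "target_start": ref_start,
        "target_end": target_end,
    }


def scan_determinants(
    read: Read,
    determinant: Determinant,
    min_identity: float = 0.80,
    min_coverage: float = 0.90,
    params: AlignParams = AlignParams(),
) -> Optional[DeterminantHit]:
    """Scan a read for a mutant determinant by infix alignment, both strands.

    The whole determinant is aligned within the read (no end-trimming):
    identity = matches over all forced alignment columns, coverage = the
    fraction of determinant bases falling inside the read bounds. A hit is
    returned iff identity >= min_identity and coverage >= min_coverage.
    Longer-than-read determinants simply return no hit.
    """
    if not (0 < min_identity <= 1) or not (0 < min_coverage <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    if len(determinant.seq) > len(read.bases):
        return None
    det_codes = encode(determinant.seq)
    best = None
    for strand, target in (("+", read.bases), ("-", revcomp(read.bases))):
        res = _infix_scan(det_codes, encode(target), params)
        if best is None or res["score"] > best[1]["score"]:
            best = (strand, res)
    strand, res = best
    if res["columns"] == 0:
        return None
    identity = res["matches"] / res["columns"]
    coverage = (len(determinant.seq) - res["overhang"]) / len(determinant.seq)
    if identity < min_identity or coverage < min_coverage:
        return None
    s, e = res["target_start"], res["target_end"]
    if strand == "-":
        n = len(read.bases)
        s, e = n - e, n - s
    return DeterminantHit(
        read_id=read.read_id,
        determinant=determinant.label,
        identity=identity,
        coverage=coverage,
        read_interval=(s, e),
        strand=strand,
    )


def partition_reads(
    reads: Sequence[Read],
    dset: DeterminantSet,
    min_identity: float = 0.80,
    min_coverage: float = 0.90,
    params: AlignParams = AlignParams(),
) -> PartitionedReads:
    """Partition reads by determinant content.

    With ``dset.require_all`` (the default) a read passes only when every
    determinant hits — e.g. both loxP-containing determinants of a floxed
    design; otherwise any single hit suffices (second-pass mode for
    spotting useful intermediate alleles).
    """
    if len(dset) == 0:
        raise ValueError("determinant set is empty")
    passed, failed = [], []
    hits: Dict[str, List[DeterminantHit]] = {}
    for read in reads:
        read_hits = []
        for det in dset:
            h = scan_determinants(read, det, min_identity, min_coverage, params)
            if h is not None:
                read_hits.append(h)
        hits[read.read_id] = read_hits
        ok = (
            len(read_hits) == len(dset)
            if dset.require_all
            else len(read_hits) >= 1
        )
        (passed if ok else failed).append(read.read_id)
    return PartitionedReads(passed=passed, failed=failed, hits=hits)


@dataclass(frozen=True)
class VariantCall:
    pos: int  # 1-based on the mutant reference
    ref_base: str
    alt_base: str
    alt_fraction: float
    depth: int
    kind: str = "snv"
    low_confidence: bool = False  # inside a homopolymer run


def call_snvs(
    pileup: Pileup,
    min_alt_fraction: float = 0.3,
    min_depth: int = 20,
    mask: Optional[HomopolymerMask] = None,
) -> List[VariantCall]:
    """Emit an SNV wherever the top non-reference base is frequent enough.

    Ties between alternate bases break lexicographically; positions
    inside the homopolymer mask are annotated low-confidence rather than
    suppressed.
    """
    calls: List[VariantCall] = []
    masked = (
        mask.positions(len(pileup)) if mask is not None else np.zeros(len(pileup), dtype=bool)
    )
    depth = pileup.depth
    ref_codes = encode(pileup.reference)
    for pos in range(len(pileup)):
        d = int(depth[pos])
        if d < min_depth:
            continue
        rc = int(ref_codes[pos])
        best_base, best_count = None, -1
        for b in range(4):
            if b == rc:
                continue
            c = int(pileup.base_counts[b, pos])
            if c > best_count:  # lexicographic tie-break via ascending b
                best_base, best_count = b, c
        if best_base is None or best_count <= 0:
            continue
        frac = best_count / d
        if frac >= min_alt_fraction:
            calls.append(
                VariantCall(
                    pos=pos + 1,
                    ref_base=pileup.reference[pos],
                    alt_base="ACGT"[best_base],
                    alt_fraction=round(frac, 6),
                    depth=d,
                    low_confidence=bool(masked[pos]),
                )
            )
    return calls


@dataclass(frozen=True)
class SVCall:
    kind: str  # DEL, INS, DUP
    pos: int  # 1-based
    length: int
    supporting_reads: int
    support_fraction: float


def _classify_insertion(rec: AlignmentRecord, qpos: int, rpos: int, length: int, reference: str) -> str:
    """Call an insertion DUP when the inserted bases echo the adjacent reference."""
    ins_seq = rec.seq[qpos : qpos + length]
    left = reference[max(0, rpos - length) : rpos]
    if not left or len(ins_seq) < 10:
        return "INS"
    res = edlib.align(ins_seq, left, mode="NW", task="distance")
    if res["editDistance"] >= 0 and res["editDistance"] <= 0.2 * length:
        return "DUP"
    return "INS"


def detect_svs(
    records: Sequence[AlignmentRecord],
    reference: str,
    min_len: int = 30,
    min_support: int = 5,
    pos_tol: int = 20,
    len_tol: float = 0.2,
) -> List[SVCall]:
    """Cluster long I/D CIGAR operations into structural-variant calls.

    Per-read indels >= min_len are grouped when positions agree within
    ``pos_tol`` bp and lengths within ``len_tol`` (fractional); clusters
    supported by >= min_support reads become calls.
    """
    events = []  # (kind, ref_pos, length)
    n_reads = len(records)
    for rec in records:
        rpos, qpos = rec.ref_start, 0
        for op, length in rec.cigar:
            if op in ("M", "=", "X"):
                rpos += length
                qpos += length
            elif op == "D":
                if length >= min_len:
                    events.append(("DEL", rpos, length))
                rpos += length
            elif op == "I":
                if length >= min_len:
                    kind = _classify_insertion(rec, qpos, rpos, length, reference)
                    events.append((kind, rpos, length))
                qpos += length
            elif op == "S":
                qpos += length
    clusters: List[dict] = []
    for kind, pos, length in sorted(events):
        placed = False
        for cl in clusters:
            if (
                cl["kind"] == kind
                and abs(pos - cl["pos_mean"]) <= pos_tol
                and abs(length - cl["len_mean"]) <= len_tol * cl["len_mean"]
            ):
                cl["items"].append((pos, length))
                cl["pos_mean"] = np.mean([p for p, _ in cl["items"]])
                cl["len_mean"] = np.mean([l for _, l in cl["items"]])
                placed = True
                break
        if not placed:
            clusters.append(
                {"kind": kind, "pos_mean": float(pos), "len_mean": float(length), "items": [(pos, length)]}
            )
    calls = []
    for cl in clusters:
        support = len(cl["items"])
        if support >= min_support:
            calls.append(
                SVCall(
                    kind=cl["kind"],
                    pos=int(round(cl["pos_mean"])) + 1,
                    length=int(round(cl["len_mean"])),
                    supporting_reads=support,
                    support_fraction=round(support / n_reads, 6) if n_reads else 0.0,
                )
            )
    return sorted(calls, key=lambda c: (c.pos, c.kind))


@dataclass
class SampleReport:
    sample_id: str
    stage_counts: Dict[str, int]
    classification: str
    recall: Optional[RecallResult] = None
    snvs: List[VariantCall] = field(default_factory=list)
    svs: List[SVCall] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)
    schema_version: str = "1.0"

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "sample_id": self.sample_id,
            "stage_counts": self.stage_counts,
            "classification": self.classification,
            "recall": None
            if self.recall is None
            else {
                "consensus_threshold": self.recall.consensus_threshold,
                "n_positions": self.recall.n_positions,
                "n_masked": self.recall.n_masked,
                "n_zero_depth": self.recall.n_zero_depth,
                "n_recalled": self.recall.n_recalled,
                "recall_pct": round(self.recall.recall_pct, 4),
            },
            "snvs": [vars(v) for v in self.snvs],
            "svs": [vars(s) for s in self.svs],
            "notes": self.notes,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def classify_sample(
    sample_id: str,
    partition: PartitionedReads,
    recall_on_passed: Optional[RecallResult],
    snvs: Sequence[VariantCall],
    svs: Sequence[SVCall],
    stage_counts: Optional[Dict[str, int]] = None,
    min_passed_reads: int = 20,
) -> SampleReport:
    """Pure decision rule over the upstream artifacts."""
    notes: List[str] = []
    n_passed = partition.n_passed
    if n_passed == 0:
        cls = "NO_CONFORMING_ALLELE"
    elif n_passed < min_passed_reads:
        cls = "INSUFFICIENT_DATA"
        notes.append(f"only {n_passed} determinant-passing reads (< {min_passed_reads})")
    elif snvs or svs:
        cls = "CORRECT_WITH_CIS_VARIANT"
    elif recall_on_passed is not None and recall_on_passed.recall_pct == 100.0:
        cls = "CORRECT_ALLELE_PRESENT"
    else:
        cls = "CORRECT_WITH_CIS_VARIANT"
        pct = "NA" if recall_on_passed is None else f"{recall_on_passed.recall_pct:.2f}"
        notes.append(f"passed reads do not fully recall the mutant reference ({pct}%)")
    return SampleReport(
        sample_id=sample_id,
        stage_counts=stage_counts or {},
        classification=cls,
        recall=recall_on_passed,
        snvs=list(snvs),
        svs=list(svs),
        notes=notes,
    )


def write_vcf(
    calls: Sequence[VariantCall], reference: str, path: str | Path, ref_name: str = "ref"
) -> None:
    """Minimal VCF v4.2 with AF/DP INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref_name},length={len(reference)}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FILTER=<ID=homopolymer,Description="Inside a masked homopolymer run">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in calls:
            filt = "homopolymer" if v.low_confidence else "PASS"
            fh.write(
                f"{ref_name}\t{v.pos}\t.\t{v.ref_base}\t{v.alt_base}\t.\t{filt}\t"
                f"AF={v.alt_fraction};DP={v.depth}\n"
            )


def write_svs_tsv(calls: Sequence[SVCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tpos_1based\tlength\tsupporting_reads\tsupport_fraction\n")
        for c in calls:
            fh.write(
                f"{c.kind}\t{c.pos}\t{c.length}\t{c.supporting_reads}\t{c.support_fraction}\n"
            )


# ---------------------------------------------------------------------------
# End-to-end pipeline


def run_sample(
    reads: Sequence[Read],
    locus: EditedLocus,
    dset: DeterminantSet,
    sample_id: str = "sample",
    barcode_spec: Optional[BarcodeSpec] = None,
    quality_threshold: float = 90.0,
    subsample_proportion: float = 1.0,
    seed: int = 100,
    align_params: AlignParams = AlignParams(band=200),
    min_identity: float = 0.80,
    min_coverage: float = 0.90,
    consensus_threshold: float = 60.0,
    homopolymer_k: Optional[int] = 5,
    min_alt_fraction: float = 0.3,
    min_var_depth: int = 20,
    sv_min_len: int = 30,
    sv_min_support: int = 5,
    min_passed_reads: int = 20,
    out_dir: Optional[str | Path] = None,
) -> SampleReport:
    """prep -> align-to-mutant -> partition -> pileup -> recall -> variants -> classify.

    When ``out_dir`` is given, writes all_reads.sam, passed_reads.sam,
    pileup TSVs, variants.vcf, svs.tsv, decisions.tsv and report.json.
    """
    stage_counts: Dict[str, int] = {"raw": len(reads)}
    decisions: List[FilterDecision] = []
    working = list(reads)
    if barcode_spec is not None:
        working, dec = demux_and_dechimera(working, barcode_spec)
        decisions.extend(dec)
    stage_counts["demuxed"] = len(working)
    working, dec = quality_rank_filter(working, quality_threshold)
    decisions.extend(d for d in dec if not d.kept)
    stage_counts["quality_passed"] = len(working)
    if subsample_proportion < 1.0:
        working = subsample(working, subsample_proportion, seed=seed)
    stage_counts["after_subsample"] = len(working)

    mut_ref = locus.mut_seq
    records = align_reads(working, mut_ref, align_params, ref_name=f"{locus.name}_mut")
    records = filter_alignments(records, align_params.min_confidence)
    stage_counts["aligned"] = len(records)
    aligned_ids = {r.read_id for r in records}
    aligned_reads = [r for r in working if r.read_id in aligned_ids]

    partition = partition_reads(aligned_reads, dset, min_identity, min_coverage, align_params)
    stage_counts["determinant_passed"] = partition.n_passed
    passed_set = set(partition.passed)
    passed_records = [r for r in records if r.read_id in passed_set]

    mask = homopolymer_mask(mut_ref, homopolymer_k) if homopolymer_k else None
    pile_all = build_pileup(records, mut_ref, ref_name=f"{locus.name}_mut")
    pile_passed = build_pileup(passed_records, mut_ref, ref_name=f"{locus.name}_mut")
    rec_res = recall(pile_passed, consensus_threshold, mask) if passed_records else None

    snvs = call_snvs(pile_passed, min_alt_fraction, min_var_depth, mask) if passed_records else []
    svs = (
        detect_svs(passed_records, mut_ref, sv_min_len, sv_min_support)
        if passed_records
        else []
    )

    report = classify_sample(
        sample_id, partition, rec_res, snvs, svs, stage_counts, min_passed_reads
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ref_name = f"{locus.name}_mut"
        write_sam(records, mut_ref, out / "all_reads.sam", ref_name)
        write_sam(passed_records, mut_ref, out / "passed_reads.sam", ref_name)
        pile_all.to_tsv(out / "pileup_all.tsv")
        pile_passed.to_tsv(out / "pileup_passed.tsv")
        write_vcf(snvs, mut_ref, out / "variants.vcf", ref_name)
        write_svs_tsv(svs, out / "svs.tsv")
        write_decisions(decisions, out / "decisions.tsv")
        with open(out / "passed_read_ids.txt", "w") as fh:
            fh.write("".join(f"{rid}\n" for rid in partition.passed))
        with open(out / "failed_read_ids.txt", "w") as fh:
            fh.write("".join(f"{rid}\n" for rid in partition.failed))
        report.to_json(out / "report.json")
    return report


def run_pipeline(config_path: str | Path) -> SampleReport:
    """Run the whole screen from a YAML config file."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    locus = load_locus(
        cfg["locus"]["wt_fasta"], cfg["locus"]["mut_fasta"], cfg["locus"]["annotations"]
    )
    fastq = cfg["reads_fastq"]
    if not Path(fastq).exists():
        raise FileNotFoundError(f"reads FASTQ not found: {fastq}")
    reads = read_fastq(fastq)

    det_cfg = cfg.get("determinants", {})
    dset = derive_determinants(
        locus,
        mode=det_cfg.get("mode", "insert"),
        window=int(det_cfg.get("window", 30)),
        flank=int(det_cfg.get("flank", 15)),
    )
    dset.require_all = bool(det_cfg.get("require_all", True))

    bc = cfg.get("barcodes")
    barcode_spec = (
        BarcodeSpec(
            barcode_id=bc.get("barcode_id", "bc1"),
            fwd_seq=bc["fwd"],
            rev_seq=bc["rev"],
            max_mismatches=int(bc.get("max_mismatches", 3)),
            end_window=int(bc.get("end_window", 150)),
        )
        if bc
        else None
    )
    al = cfg.get("align", {})
    params = AlignParams(
        match_score=int(al.get("match", 2)),
        mismatch_penalty=int(al.get("mismatch", 4)),
        gap_open=int(al.get("gap_open", 4)),
        gap_extend=int(al.get("gap_extend", 2)),
        min_confidence=float(al.get("min_confidence", 90)),
        band=int(al.get("band", 200)),
    )
    rc = cfg.get("recall", {})
    var = cfg.get("variants", {})
    cls = cfg.get("classify", {})
    return run_sample(
        reads,
        locus,
        dset,
        sample_id=cfg.get("sample_id", "sample"),
        barcode_spec=barcode_spec,
        quality_threshold=float(cfg.get("quality_threshold", 90)),
        subsample_proportion=float(cfg.get("subsample", {}).get("proportion", 1.0)),
        seed=int(cfg.get("seed", 100)),
        align_params=params,
        min_identity=float(det_cfg.get("min_identity", 0.80)),
        min_coverage=float(det_cfg.get("min_coverage", 0.90)),
        consensus_threshold=float(rc.get("consensus_threshold", 60)),
        homopolymer_k=rc.get("homopolymer_k", 5),
        min_alt_fraction=float(var.get("min_alt_fraction", 0.3)),
        min_var_depth=int(var.get("min_depth", 20)),
        sv_min_len=int(var.get("sv_min_len", 30)),
        sv_min_support=int(var.get("sv_min_support", 5)),
        min_passed_reads=int(cls.get("min_passed_reads", 20)),
        out_dir=cfg.get("out_dir"),
    )
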