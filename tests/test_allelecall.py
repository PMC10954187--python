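"""Determinant partitioning, variant calling, classification, pipeline."""

import json

import numpy as np
import pytest

from mosaicscreen import (
    AlignParams,
    Pileup,
    align_reads,
    build_allele_set,
    build_pileup,
    call_snvs,
    classify_sample,
    detect_svs,
    filter_alignments,
    homopolymer_mask,
    partition_reads,
    recall,
    run_pipeline,
    run_sample,
    scan_determinants,
)
from mosaicscreen._seq import revcomp
from mosaicscreen.allelecall import PartitionedReads
from mosaicscreen.mosaicsim import (
    DEFAULT_BARCODE_PAIR,
    NOISELESS,
    ErrorModel,
    MosaicSample,
    attach_barcodes,
    default_mosaic_spec,
    inject_chimeras,
    simulate_reads,
    write_truth_table,
)
from mosaicscreen.readprep import BarcodeSpec
from mosaicscreen.seqio import Read, write_fasta, write_fastq

BAND = AlignParams(band=150)


def _read(read_id, bases, qual=30):
    return Read(read_id, bases, np.full(len(bases), qual, dtype=np.int64))


def _simulate(flox_locus, spec, fractions, depth, em, seed):
    alleles = build_allele_set(flox_locus, spec)
    sample = MosaicSample("s", alleles, fractions)
    return simulate_reads(sample, depth, em, seed)


class TestScanDeterminants:
    def test_verbatim_containment_is_perfect_hit(self, flox_locus, flox_dset):
        det = flox_dset.determinants[0]
        read = _read("r", flox_locus.mut_seq)
        hit = scan_determinants(read, det)
        assert hit is not None
        assert hit.identity == 1.0 and hit.coverage == 1.0
        assert hit.read_interval == det.mut_interval

    def test_wt_read_has_no_hit(self, flox_locus, flox_dset):
        read = _read("wt", flox_locus.wt_seq)
        for det in flox_dset:
            assert scan_determinants(read, det) is None

    def test_reverse_strand_detected(self, flox_locus, flox_dset):
        read = _read("rc", revcomp(flox_locus.mut_seq))
        hit = scan_determinants(read, flox_dset.determinants[0])
        assert hit is not None and hit.strand == "-"

    def test_determinant_longer_than_read_is_no_hit(self, flox_dset):
        assert scan_determinants(_read("tiny", "ACGT"), flox_dset.determinants[0]) is None

    def test_detection_robust_to_read_error(self, flox_locus, flox_dset):
        """Monte-Carlo: determinants found in >= 95% of 10%-error reads."""
        em = ErrorModel(sub_rate=0.04, ins_rate=0.03, del_rate=0.03, read_quality_spread=0.0)
        reads = _simulate(flox_locus, [{"class": "correct"}], [1.0], 300, em, seed=8)
        det = flox_dset.determinants[0]
        found = sum(scan_determinants(r, det) is not None for r in reads)
        assert found >= 0.95 * len(reads)


class TestPartitionReads:
    def test_noiseless_four_allele_mosaic_truth(self, flox_locus, flox_dset):
        spec = default_mosaic_spec(flox_locus)
        reads = _simulate(flox_locus, spec, [0.25] * 4, 80, NOISELESS, seed=9)
        truth = {r.read_id: r.truth_allele for r in reads}
        part = partition_reads(reads, flox_dset)
        # partial integration lacks the 5' loxP; everything else has both
        for rid in part.passed:
            assert truth[rid] != "partial_3prime_only"
        for rid in part.failed:
            assert truth[rid] == "partial_3prime_only"
        assert set(part.passed) | set(part.failed) == set(truth)
        assert not (set(part.passed) & set(part.failed))

    def test_no_allele_with_5prime_determinant_gives_empty_passed(
        self, flox_locus, flox_dset
    ):
        spec = [
            {"id": "partial", "class": "partial_integration", "revert": "loxp5"},
            {"id": "wt", "class": "wildtype"},
        ]
        reads = _simulate(flox_locus, spec, [0.6, 0.4], 60, NOISELESS, seed=10)
        part = partition_reads(reads, flox_dset)
        assert part.passed == []

    def test_require_any_mode(self, flox_locus, flox_dset):
        spec = [{"id": "partial", "class": "partial_integration", "revert": "loxp5"}]
        reads = _simulate(flox_locus, spec, [1.0], 20, NOISELESS, seed=11)
        flox_dset.require_all = True
        assert partition_reads(reads, flox_dset).passed == []
        try:
            flox_dset.require_all = False
            part = partition_reads(reads, flox_dset)
            assert len(part.passed) == len(reads)  # 3' determinant hits alone
        finally:
            flox_dset.require_all = True


class TestCallSnvs:
    def test_planted_snv_recovered_exactly(self, flox_locus, flox_dset):
        mut = flox_locus.mut_seq
        pos = 616
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[pos]]
        spec = [
            {"id": "snv_allele", "class": "snv_in_cis", "pos": pos, "alt": alt},
            {"id": "wt", "class": "wildtype"},
        ]
        em = ErrorModel()
        reads = _simulate(flox_locus, spec, [0.6, 0.4], 120, em, seed=12)
        part = partition_reads(reads, flox_dset)
        passed = [r for r in reads if r.read_id in set(part.passed)]
        recs = align_reads(passed, mut, BAND)
        pile = build_pileup(recs, mut)
        calls = call_snvs(pile, min_alt_fraction=0.3, min_depth=20)
        strong = [c for c in calls if not c.low_confidence]
        assert len(strong) == 1
        assert strong[0].pos == pos + 1 and strong[0].alt_base == alt

    def test_noiseless_correct_reads_give_no_calls(self, flox_locus):
        mut = flox_locus.mut_seq
        reads = _simulate(flox_locus, [{"class": "correct"}], [1.0], 30, NOISELESS, seed=13)
        recs = align_reads(reads, mut, BAND)
        assert call_snvs(build_pileup(recs, mut), min_depth=20) == []

    def test_alt_fraction_threshold_boundary(self):
        ref = "A" * 30
        pile = Pileup(ref)
        pile.base_counts[0, :] = 50  # ref A everywhere
        pile.base_counts[2, 10] = 50  # pos 10: 50 A, 50 G -> fraction 0.5
        pile.base_counts[0, 10] = 50
        assert len(call_snvs(pile, min_alt_fraction=0.3, min_depth=20)) == 1
        assert len(call_snvs(pile, min_alt_fraction=0.6, min_depth=20)) == 0


class TestDetectSvs:
    def test_noiseless_correct_reads_give_no_calls(self, flox_locus):
        mut = flox_locus.mut_seq
        reads = _simulate(flox_locus, [{"class": "correct"}], [1.0], 20, NOISELESS, seed=14)
        recs = align_reads(reads, mut, BAND)
        assert detect_svs(recs, mut) == []

    def test_heterozygous_deletion_detected(self, flox_locus):
        spec = [
            {"id": "del200", "class": "deletion", "start": 360, "end": 560},
            {"id": "ok", "class": "correct"},
        ]
        em = ErrorModel()
        reads = _simulate(flox_locus, spec, [0.5, 0.5], 60, em, seed=15)
        recs = align_reads(reads, flox_locus.mut_seq, AlignParams(band=300))
        calls = [c for c in detect_svs(recs, flox_locus.mut_seq) if c.kind == "DEL"]
        assert len(calls) == 1
        call = calls[0]
        assert abs(call.length - 200) <= 20  # +-10%
        n_del_truth = sum(r.truth_allele == "del200" for r in reads)
        assert abs(call.supporting_reads - n_del_truth) <= 0.2 * n_del_truth

    def test_two_distinct_deletions_not_merged(self, flox_locus):
        spec = [
            {"id": "delA", "class": "deletion", "start": 200, "end": 300},
            {"id": "delB", "class": "deletion", "start": 1600, "end": 1750},
        ]
        reads = _simulate(flox_locus, spec, [0.5, 0.5], 40, NOISELESS, seed=16)
        recs = align_reads(reads, flox_locus.mut_seq, AlignParams(band=300))
        dels = [c for c in detect_svs(recs, flox_locus.mut_seq) if c.kind == "DEL"]
        assert len(dels) == 2
        positions = sorted(c.pos for c in dels)
        assert positions[0] < 400 and positions[1] > 1500


class TestClassifySample:
    def _partition(self, n_passed, n_failed=0):
        return PartitionedReads(
            passed=[f"p{i}" for i in range(n_passed)],
            failed=[f"f{i}" for i in range(n_failed)],
            hits={},
        )

    def _full_recall(self):
        pile = Pileup("ACGTACGT")
        pile.base_counts[:, :] = 0
        for i, b in enumerate("ACGTACGT"):
            pile.base_counts["ACGT".index(b), i] = 30
        return recall(pile, 60)

    def test_empty_passed_is_no_conforming_allele(self):
        rep = classify_sample("s", self._partition(0, 10), None, [], [])
        assert rep.classification == "NO_CONFORMING_ALLELE"

    def test_few_passed_reads_is_insufficient_data(self):
        rep = classify_sample("s", self._partition(5), self._full_recall(), [], [])
        assert rep.classification == "INSUFFICIENT_DATA"

    def test_clean_positive(self):
        rep = classify_sample("s", self._partition(100), self._full_recall(), [], [])
        assert rep.classification == "CORRECT_ALLELE_PRESENT"

    def test_snv_forces_cis_variant_label(self):
        from mosaicscreen.allelecall import VariantCall

        snv = VariantCall(pos=617, ref_base="G", alt_base="A", alt_fraction=0.9, depth=100)
        rep = classify_sample("s", self._partition(100), self._full_recall(), [snv], [])
        assert rep.classification == "CORRECT_WITH_CIS_VARIANT"

    def test_low_recall_noted_as_cis_variant(self):
        pile = Pileup("AAAA")
        pile.base_counts[0, :2] = 30  # half the positions uncovered
        low = recall(pile, 60)
        rep = classify_sample("s", self._partition(100), low, [], [])
        assert rep.classification == "CORRECT_WITH_CIS_VARIANT"
        assert rep.notes


def _write_pipeline_inputs(tmp_path, flox_locus, reads):
    write_fasta([("wt", flox_locus.wt_seq)], tmp_path / "wt.fasta")
    write_fasta([("mut", flox_locus.mut_seq)], tmp_path / "mut.fasta")
    ann = ["name: synthetic_flox", "edits:"]
    for e in flox_locus.edits:
        ann.append(
            f"  - {{label: {e.label}, start: {e.start}, end: {e.end}, class: {e.edit_class}}}"
        )
    (tmp_path / "locus.yaml").write_text("\n".join(ann) + "\n")
    write_fastq(reads, tmp_path / "reads.fastq")


def _write_pipeline_config(tmp_path, quality=50.0):
    fwd, rev = DEFAULT_BARCODE_PAIR
    cfg = f"""
sample_id: founder_demo
locus:
  wt_fasta: {tmp_path}/wt.fasta
  mut_fasta: {tmp_path}/mut.fasta
  annotations: {tmp_path}/locus.yaml
reads_fastq: {tmp_path}/reads.fastq
barcodes: {{fwd: {fwd}, rev: {rev}}}
quality_threshold: {quality}
seed: 100
determinants: {{mode: insert}}
align: {{band: 150}}
out_dir: {tmp_path}/out
"""
    (tmp_path / "run.yaml").write_text(cfg)
    return tmp_path / "run.yaml"


@pytest.fixture(scope="module")
def pipeline_run(tmp_path_factory, flox_locus):
    tmp_path = tmp_path_factory.mktemp("pipeline")
    spec = [
        {"id": "correct_flox", "class": "correct"},
        {"id": "partial", "class": "partial_integration", "revert": "loxp5"},
        {"id": "wt", "class": "wildtype"},
    ]
    alleles = build_allele_set(flox_locus, spec)
    sample = MosaicSample("founder_demo", alleles, [0.5, 0.3, 0.2])
    reads = simulate_reads(sample, 120, ErrorModel(), seed=17)
    reads = attach_barcodes(reads, DEFAULT_BARCODE_PAIR)
    reads = inject_chimeras(reads, 0.05, seed=18)
    _write_pipeline_inputs(tmp_path, flox_locus, reads)
    cfg = _write_pipeline_config(tmp_path)
    report = run_pipeline(cfg)
    return tmp_path, cfg, report


class TestRunPipeline:
    def test_classification_matches_design(self, pipeline_run):
        _, _, report = pipeline_run
        assert report.classification == "CORRECT_ALLELE_PRESENT"
        assert report.recall.recall_pct == 100.0

    def test_stage_counts_non_increasing(self, pipeline_run):
        _, _, report = pipeline_run
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)

    def test_artifacts_written(self, pipeline_run):
        tmp_path, _, _ = pipeline_run
        out = tmp_path / "out"
        for name in (
            "all_reads.sam",
            "passed_reads.sam",
            "pileup_all.tsv",
            "pileup_passed.tsv",
            "variants.vcf",
            "svs.tsv",
            "report.json",
        ):
            assert (out / name).exists(), name

    def test_rerun_is_byte_identical(self, pipeline_run):
        tmp_path, cfg, _ = pipeline_run
        first = (tmp_path / "out" / "report.json").read_bytes()
        run_pipeline(cfg)
        assert (tmp_path / "out" / "report.json").read_bytes() == first

    def test_missing_fastq_is_clean_error(self, pipeline_run):
        tmp_path, cfg, _ = pipeline_run
        text = cfg.read_text().replace("reads.fastq", "absent.fastq")
        bad = tmp_path / "bad.yaml"
        bad.write_text(text)
        with pytest.raises(FileNotFoundError, match="absent.fastq"):
            run_pipeline(bad)
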