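"""Synthetic mosaic-founder sequencing data with truth labels.

Founders produced by zygote editing are mosaics: the targeted locus can
carry the correct edited allele alongside wild type, partial donor
integrations, deletions, duplications and edits with unintended point
mutations in cis. This module builds such allele mixtures from an
:class:`~mosaicscreen.refmodel.EditedLocus`, draws full-length amplicon
reads per allele fraction, corrupts them with an ONT-like i.i.d.
substitution/indel error process (optionally enriched inside homopolymer
runs), attaches flanking barcodes and injects artificial chimeric reads —
everything needed to exercise the downstream screen without real data.

Randomness: a single integer seed feeds one numpy Generator; the stream
order is fixed (allele assignment -> per read: strand, error scale,
deletions, substitutions, insertions -> chimeras), so identical inputs
give byte-identical FASTQ and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np

from ._seq import BASES, check_alphabet, random_seq, revcomp
from .refmodel import Edit, EditedLocus
from .seqio import MAX_PHRED, Read, write_fasta, write_fastq

ALLELE_CLASSES = (
    "correct",
    "wildtype",
    "partial_integration",
    "deletion",
    "duplication",
    "snv_in_cis",
)

#: The 34 bp loxP recognition sequence (used by the synthetic demo locus).
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"

#: Default dual-barcode pair (standard 24 bp nanopore barcodes 01/02).
#: Barcodes much shorter than ~20 bp produce chance internal matches at
#: edit distance 3 in kilobase-scale reads.
DEFAULT_BARCODE_PAIR = ("AAGAAAGTTGTCGGTGTCTTTGTG", "TCGATTCCGTTTGTAGTCGTCTGT")


@dataclass
class AlleleModel:
    allele_id: str
    seq: str
    allele_class: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.allele_class not in ALLELE_CLASSES:
            raise ValueError(f"unknown allele class {self.allele_class!r}")
        self.seq = check_alphabet(self.seq, f"allele {self.allele_id}")


@dataclass
class MosaicSample:
    sample_id: str
    alleles: List[AlleleModel]
    fractions: Sequence[float]

    def __post_init__(self) -> None:
        self.fractions = list(float(f) for f in self.fractions)
        if len(self.fractions) != len(self.alleles):
            raise ValueError("fractions and alleles must have the same length")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("allele fractions must be strictly positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"allele fractions sum to {sum(self.fractions)}, not 1")


@dataclass
class ErrorModel:
    """Per-base i.i.d. error process with optional homopolymer indel boost.

    ``read_quality_spread`` is the sigma of a lognormal per-read error
    scale with mean 1; it makes some reads genuinely better than others so
    that relative-quality filtering has something to rank.
    """

    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.02
    homopolymer_indel_multiplier: float = 2.0
    read_quality_spread: float = 0.3
    homopolymer_min_run: int = 4

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0,1)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1:
            raise ValueError("total error rate must be < 1")
        if self.homopolymer_indel_multiplier < 1:
            raise ValueError("homopolymer_indel_multiplier must be >= 1")


NOISELESS = ErrorModel(0.0, 0.0, 0.0, 1.0, 0.0)


@dataclass
class SimulatedRead(Read):
    truth_allele: str = ""
    allele_class: str = ""
    is_chimera: bool = False
    strand: str = "+"
    barcode_pair: tuple[str, str] = ("", "")


# ---------------------------------------------------------------------------
# Allele construction


def _hp_mask(seq: str, min_run: int) -> np.ndarray:
    """Boolean mask of positions inside single-base runs of length >= min_run."""
    from ._seq import homopolymer_runs

    mask = np.zeros(len(seq), dtype=bool)
    for start, end, _ in homopolymer_runs(seq):
        if end - start >= min_run:
            mask[start:end] = True
    return mask


def build_allele_set(locus: EditedLocus, spec: Iterable[dict]) -> List[AlleleModel]:
    """Construct alleles by applying declared transformations to the locus.

    Each spec entry is a dict with ``class`` plus class-specific keys:

    - ``correct`` / ``wildtype``: none
    - ``partial_integration``: ``revert`` (edit label restored to WT)
    - ``deletion`` / ``duplication``: ``start``, ``end`` (on the base seq),
      optional ``base`` ("mut" default, or "wt")
    - ``snv_in_cis``: ``pos``, ``alt``, optional ``ref`` (checked)
    """
    alleles: List[AlleleModel] = []
    for i, entry in enumerate(spec):
        cls = entry["class"]
        aid = entry.get("id", f"{cls}_{i}")
        desc = entry.get("description", "")
        if cls == "correct":
            seq = locus.mut_seq
        elif cls == "wildtype":
            seq = locus.wt_seq
        elif cls == "partial_integration":
            seq = locus.revert_edit(entry["revert"])
        elif cls in ("deletion", "duplication"):
            base = locus.wt_seq if entry.get("base") == "wt" else locus.mut_seq
            s, e = int(entry["start"]), int(entry["end"])
            if not (0 <= s < e <= len(base)):
                raise ValueError(f"allele {aid}: interval [{s},{e}) out of bounds")
            if cls == "deletion":
                seq = base[:s] + base[e:]
            else:
                seq = base[:s] + base[s:e] + base[s:e] + base[e:]
        elif cls == "snv_in_cis":
            base = locus.wt_seq if entry.get("base") == "wt" else locus.mut_seq
            pos, alt = int(entry["pos"]), str(entry["alt"]).upper()
            if not (0 <= pos < len(base)):
                raise ValueError(f"allele {aid}: SNV position {pos} out of bounds")
            ref = entry.get("ref")
            if ref is not None and base[pos] != str(ref).upper():
                raise ValueError(
                    f"allele {aid}: reference base at {pos} is {base[pos]}, "
                    f"not {ref}"
                )
            if alt == base[pos]:
                raise ValueError(f"allele {aid}: alt base equals reference base {alt}")
            seq = base[:pos] + alt + base[pos + 1 :]
        else:
            raise ValueError(f"unknown allele class {cls!r}")
        alleles.append(AlleleModel(aid, seq, cls, desc))
    return alleles


# ---------------------------------------------------------------------------
# Read simulation


def _corrupt(
    template: str, em: ErrorModel, scale: float, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Apply the error process to one template; returns (bases, quals).

    Draw order per read: deletions, substitutions, insertions, inserted
    base identities, substitution targets.
    """
    n = len(template)
    codes = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
    mult = np.ones(n)
    if em.homopolymer_indel_multiplier > 1:
        mult[_hp_mask(template, em.homopolymer_min_run)] = em.homopolymer_indel_multiplier
    p_del = np.minimum(em.del_rate * scale * mult, 0.9)
    p_ins = np.minimum(em.ins_rate * scale * mult, 0.9)
    p_sub = min(em.sub_rate * scale, 0.9)

    deleted = rng.random(n) < p_del
    substituted = rng.random(n) < p_sub
    inserted = rng.random(n) < p_ins

    # Per-base expected error used for quality emission.
    p_err = np.minimum(p_del + p_ins + p_sub, 0.999)
    with np.errstate(divide="ignore"):
        q = np.where(p_err > 0, -10.0 * np.log10(p_err), float(MAX_PHRED))
    q = np.clip(np.rint(q), 1, MAX_PHRED).astype(np.int64)

    out_bases: list[str] = []
    out_quals: list[int] = []
    n_sub = int((substituted & ~deleted).sum())
    n_ins = int(inserted.sum())
    sub_choices = rng.integers(0, 3, size=n_sub)  # offset among the 3 non-ref bases
    ins_choices = rng.integers(0, 4, size=n_ins)
    si = ii = 0
    for i in range(n):
        if not deleted[i]:
            base = chr(codes[i])
            if substituted[i]:
                alts = [b for b in BASES if b != base]
                base = alts[sub_choices[si]] if base in BASES else BASES[sub_choices[si]]
                si += 1
            out_bases.append(base)
            out_quals.append(int(q[i]))
        if inserted[i]:
            out_bases.append(BASES[ins_choices[ii]])
            out_quals.append(int(q[i]))
            ii += 1
    return "".join(out_bases), np.asarray(out_quals, dtype=np.int64)


def simulate_reads(
    sample: MosaicSample,
    depth: int,
    error_model: ErrorModel = ErrorModel(),
    seed: int = 100,
) -> List[SimulatedRead]:
    """Draw ``depth`` full-length amplicon reads from the allele mixture.

    Every read spans its whole source allele (PCR amplicon model), on a
    uniformly chosen strand, corrupted base-by-base by ``error_model``.
    Reads per allele are multinomial in the sample's fractions.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not sample.alleles:
        raise ValueError("sample has no alleles")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(depth), sample.fractions)
    reads: List[SimulatedRead] = []
    idx = 0
    for allele, n_reads in zip(sample.alleles, counts):
        for _ in range(n_reads):
            strand = "+" if rng.random() < 0.5 else "-"
            if error_model.read_quality_spread > 0:
                s = error_model.read_quality_spread
                scale = float(rng.lognormal(mean=-0.5 * s * s, sigma=s))
            else:
                scale = 1.0
            template = allele.seq if strand == "+" else revcomp(allele.seq)
            bases, quals = _corrupt(template, error_model, scale, rng)
            reads.append(
                SimulatedRead(
                    read_id=f"{sample.sample_id}_r{idx:06d}",
                    bases=bases,
                    quals=quals,
                    truth_allele=allele.allele_id,
                    allele_class=allele.allele_class,
                    strand=strand,
                )
            )
            idx += 1
    return reads


def attach_barcodes(
    reads: List[SimulatedRead], barcode_pair: tuple[str, str]
) -> List[SimulatedRead]:
    """Prepend the forward barcode and append revcomp of the reverse barcode.

    Barcode bases are emitted clean (errors, if desired, belong to the
    corruption step); their qualities are set to the read's median quality
    so per-read ranking is unchanged.
    """
    fwd, rev = barcode_pair
    if not fwd or not rev:
        raise ValueError("barcode sequences must be non-empty")
    out = []
    for r in reads:
        q = int(np.median(r.quals)) if len(r.quals) else 30
        bases = fwd + r.bases + revcomp(rev)
        quals = np.concatenate(
            [np.full(len(fwd), q, dtype=np.int64), r.quals, np.full(len(rev), q, dtype=np.int64)]
        )
        out.append(
            SimulatedRead(
                read_id=r.read_id,
                bases=bases,
                quals=quals,
                truth_allele=r.truth_allele,
                allele_class=r.allele_class,
                is_chimera=r.is_chimera,
                strand=r.strand,
                barcode_pair=(fwd, rev),
            )
        )
    return out


def inject_chimeras(
    reads: List[SimulatedRead], rate: float, seed: int = 100
) -> List[SimulatedRead]:
    """Replace round(rate * n) reads with concatenations of two barcoded reads.

    The junction places one read's 3' barcode and the partner's 5' barcode
    internally — the signature the chimera filter targets.
    """
    if not (0 <= rate < 1):
        raise ValueError("chimera rate must be in [0, 1)")
    n = len(reads)
    n_chim = int(round(rate * n))
    if n_chim == 0:
        return list(reads)
    rng = np.random.default_rng(seed)
    targets = rng.choice(n, size=n_chim, replace=False)
    out = list(reads)
    for t in sorted(int(x) for x in targets):
        j = int(rng.integers(0, n))
        if j == t:
            j = (j + 1) % n
        a, b = reads[t], reads[j]
        out[t] = SimulatedRead(
            read_id=a.read_id,
            bases=a.bases + b.bases,
            quals=np.concatenate([a.quals, b.quals]),
            truth_allele=a.truth_allele,
            allele_class=a.allele_class,
            is_chimera=True,
            strand=a.strand,
            barcode_pair=a.barcode_pair,
        )
    return out


# ---------------------------------------------------------------------------
# Synthetic demo locus and outputs


def make_flox_locus(
    seed: int = 7,
    length: int = 2000,
    loxp_positions: tuple[int, int] = (600, 1300),
    name: str = "synthetic_flox",
) -> EditedLocus:
    """A synthetic floxed locus: random WT with two loxP insertions.

    This is a stand-in locus generated from a seeded random sequence (no
    real genomic coordinates); it mimics the structure of a conditional
    allele where a core segment is flanked by two 34 bp loxP insertions.
    """
    rng = np.random.default_rng(seed)
    wt = random_seq(length, rng)
    p5, p3 = loxp_positions
    if not (0 < p5 < p3 <= length):
        raise ValueError("loxP positions must be ordered and inside the sequence")
    mut = wt[:p5] + LOXP + wt[p5:p3] + LOXP + wt[p3:]
    edits = [
        Edit("loxp5", p5, p5 + len(LOXP), "insertion"),
        Edit("loxp3", p3 + len(LOXP), p3 + 2 * len(LOXP), "insertion"),
    ]
    locus = EditedLocus(name, wt, mut, edits)
    locus.validate_consistency()
    return locus


def default_mosaic_spec(locus: EditedLocus) -> List[dict]:
    """A four-allele mosaic: correct flox, flox with an upstream deletion,
    3'-only partial integration, and a donor integration with a duplicated
    segment — the canonical hard case for founder genotyping."""
    e5 = locus.edits[0]
    del_start = max(0, e5.start - 220)
    del_end = max(del_start + 1, e5.start - 20)
    dup = locus.edits[-1]
    return [
        {"id": "correct_flox", "class": "correct"},
        {
            "id": "flox_upstream_del",
            "class": "deletion",
            "start": del_start,
            "end": del_end,
            "description": "floxed allele with an upstream deletion",
        },
        {
            "id": "partial_3prime_only",
            "class": "partial_integration",
            "revert": locus.edits[0].label,
            "description": "partial donor integration, 3' loxP only",
        },
        {
            "id": "dup_integration",
            "class": "duplication",
            "start": dup.start - 60,
            "end": dup.end + 60,
            "description": "donor integration with duplicated segment",
        },
    ]


def write_truth_table(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttruth_allele\tallele_class\tis_chimera\tstrand\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.truth_allele}\t{r.allele_class}\t"
                f"{str(r.is_chimera).lower()}\t{r.strand}\n"
            )


def write_alleles_fasta(alleles: Iterable[AlleleModel], path: str | Path) -> None:
    write_fasta([(a.allele_id, a.seq) for a in alleles], path)


def simulate_run(
    locus: EditedLocus,
    spec: Iterable[dict],
    fractions: Sequence[float],
    depth: int,
    error_model: ErrorModel = ErrorModel(),
    barcode_pair: Optional[tuple[str, str]] = None,
    chimera_rate: float = 0.0,
    seed: int = 100,
    sample_id: str = "sample",
) -> tuple[MosaicSample, List[SimulatedRead]]:
    """Allele construction + read simulation + barcoding + chimeras in one call."""
    alleles = build_allele_set(locus, spec)
    sample = MosaicSample(sample_id, alleles, fractions)
    reads = simulate_reads(sample, depth, error_model, seed)
    if barcode_pair is not None:
        reads = attach_barcodes(reads, barcode_pair)
        if chimera_rate > 0:
            reads = inject_chimeras(reads, chimera_rate, seed=seed + 1)
    return sample, reads
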