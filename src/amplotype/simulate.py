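"""Synthetic multiplexed-amplicon simulator with ground truth.

Generates FASTQ read sets that emulate pyrosequenced diploid amplicons
from a single polymorphic locus: a fixed synthetic 270 bp "exon" flanked
by boundary motifs, eight allelic variants at pairwise Hamming distances
4–18 substitutions (shaped like a class II HLA exon without shipping
database content), two pseudogene-like contaminant sequences carrying
blacklist motifs, MID barcodes, configurable allele imbalance
(minor_fraction), per-base substitution error with low-quality error
bases, optional homopolymer indels, contaminant reads, and barcode
corruption. Every run emits a truth table so each pipeline stage can be
scored exactly.

The fixture locus and its motifs are built deterministically from a
fixed internal seed and are part of the generator's definition, not a
per-run knob.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    AlleleRecord,
    MotifConfig,
    Read,
    reverse_complement,
    write_barcode_map,
    write_fastq,
)
from .util import derive_seed

_BASES = np.array(list("ACGT"))
_LOCUS_SEED = 714025  # fixed: defines the synthetic locus, never varied
EXON_LENGTH = 270
MOTIF_LENGTH = 12
BARCODE_LENGTH = 8
#: substitution counts defining each allele; disjoint position sets, so
#: allele i and j differ at sizes[i]+sizes[j] positions (range 4–18)
_ALLELE_SUB_COUNTS = (2, 2, 3, 4, 5, 6, 8, 10)


@functools.lru_cache(maxsize=1)
def _locus() -> dict:
    """Build the synthetic locus: alleles, pseudogenes, motifs, barcodes."""
    rng = np.random.default_rng(_LOCUS_SEED)
    while True:
        base = "".join(rng.choice(_BASES, EXON_LENGTH))
        start_motif = base[:MOTIF_LENGTH]
        end_motif = base[-MOTIF_LENGTH:]
        core = np.arange(MOTIF_LENGTH, EXON_LENGTH - MOTIF_LENGTH)
        n_var = sum(_ALLELE_SUB_COUNTS)
        var_pos = np.sort(rng.choice(core, size=n_var + 24, replace=False))
        alleles: list[AlleleRecord] = []
        cursor = 0
        for i, k in enumerate(_ALLELE_SUB_COUNTS, start=1):
            seq = list(base)
            for p in var_pos[cursor : cursor + k]:
                choices = [b for b in "ACGT" if b != seq[p]]
                seq[p] = choices[int(rng.integers(3))]
            cursor += k
            alleles.append(AlleleRecord(name=f"SYN*{i:02d}:01:01", sequence="".join(seq)))

        blacklist = []
        pseudogenes = []
        pseudo_pos = var_pos[cursor : cursor + 24]
        for j in range(2):
            seq = list(base)
            anchor = int(pseudo_pos[j * 12])
            motif = "".join(rng.choice(_BASES, MOTIF_LENGTH))
            seq[anchor : anchor + MOTIF_LENGTH] = list(motif)
            pseudo = "".join(seq)
            blacklist.append(pseudo[anchor : anchor + MOTIF_LENGTH])
            pseudogenes.append(pseudo)

        ok = (
            all(start_motif not in a.sequence[1:] for a in alleles)
            and all(a.sequence.find(end_motif) == EXON_LENGTH - MOTIF_LENGTH for a in alleles)
            and all(m not in a.sequence for a in alleles for m in blacklist)
            and all(p.startswith(start_motif) and p.endswith(end_motif) for p in pseudogenes)
            and blacklist[0] != blacklist[1]
        )
        if ok:
            return {
                "alleles": alleles,
                "pseudogenes": pseudogenes,
                "motifs": MotifConfig(
                    start_motif=start_motif,
                    end_motif=end_motif,
                    blacklist=tuple(blacklist),
                    min_exon_length=250,
                    max_exon_length=290,
                ),
            }


def default_allele_library() -> list[AlleleRecord]:
    """The eight synthetic alleles of the fixture locus."""
    return list(_locus()["alleles"])


def pseudogene_sequences() -> list[str]:
    """Contaminant templates carrying blacklist motifs (not in the library)."""
    return list(_locus()["pseudogenes"])


def default_motif_config() -> MotifConfig:
    return _locus()["motifs"]


def make_barcodes(n: int) -> list[str]:
    """n distinct 8-mer MID barcodes with pairwise Hamming distance >= 3."""
    rng = np.random.default_rng(_LOCUS_SEED + 1)
    barcodes: list[str] = []
    while len(barcodes) < n:
        cand = "".join(rng.choice(_BASES, BARCODE_LENGTH))
        if all(sum(a != b for a, b in zip(cand, bc)) >= 3 for bc in barcodes):
            barcodes.append(cand)
    return barcodes


@dataclass(frozen=True)
class QualityModel:
    """Phred-score generator: most correct bases are high quality, a small
    fraction are low; erroneous bases draw from the low component."""

    mean_q: float = 35.0
    sd_q: float = 4.0
    low_q_fraction: float = 0.08
    low_mean_q: float = 15.0
    low_sd_q: float = 4.0

    def correct_quals(self, n: int, rng: np.random.Generator) -> np.ndarray:
        low = rng.random(n) < self.low_q_fraction
        q = rng.normal(self.mean_q, self.sd_q, n)
        q[low] = rng.normal(self.low_mean_q, self.low_sd_q, low.sum())
        return np.clip(np.rint(q), 2, 40).astype(np.int16)

    def error_quals(self, n: int, rng: np.random.Generator) -> np.ndarray:
        q = rng.normal(self.low_mean_q, self.low_sd_q, n)
        return np.clip(np.rint(q), 2, 40).astype(np.int16)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``allele_pairs`` maps subject_id → (allele1, allele2) names from the
    fixture library; ``minor_fraction`` is the probability a read derives
    from allele2 (≤ 0.5: allele2 is the minor/under-amplified allele);
    ``reads_per_subject=None`` draws per-subject depth from the default
    truncated normal (mean 340, sd 132, floor 40).
    """

    allele_pairs: dict[str, tuple[str, str]]
    minor_fraction: float = 0.5
    reads_per_subject: int | None = None
    per_base_error: float = 0.01
    quality_model: QualityModel = field(default_factory=QualityModel)
    contaminant_fraction: float = 0.0
    barcode_corrupt_fraction: float = 0.0
    homopolymer_indels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.minor_fraction <= 0.5:
            raise ValueError("minor_fraction must lie in (0, 0.5]")
        for name in ("per_base_error", "contaminant_fraction", "barcode_corrupt_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.reads_per_subject is not None and self.reads_per_subject < 2:
            raise ValueError("reads_per_subject must be >= 2")


@dataclass
class TruthRecord:
    """Ground truth for one simulated subject."""

    subject_id: str
    allele1: str
    allele2: str
    minor_fraction: float  # realised fraction among allelic reads
    n_reads: int
    n_contaminants: int
    n_barcode_corrupted: int


def mutate_template(
    template: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """One noisy copy of a template under the configured error model.

    Returns (sequence, Phred qualities): substitution errors at
    ``per_base_error`` with low-quality error bases, plus optional
    homopolymer indels. Exposed so callers can build bare read clusters
    without the barcode/strand layers of a full subject simulation.
    """
    seq = np.array(list(template))
    n = len(seq)
    err = rng.random(n) < config.per_base_error
    if err.any():
        idx = np.nonzero(err)[0]
        for p in idx:
            choices = [b for b in "ACGT" if b != seq[p]]
            seq[p] = choices[int(rng.integers(3))]
    quals = config.quality_model.correct_quals(n, rng)
    if err.any():
        quals[err] = config.quality_model.error_quals(int(err.sum()), rng)
    out_seq = seq.tolist()
    out_quals = quals.tolist()

    if config.homopolymer_indels:
        # one indel per homopolymer run (>=3) at per_base_error rate,
        # emulating pyrosequencing flow miscalls
        s = "".join(out_seq)
        runs = []
        i = 0
        while i < len(s):
            j = i
            while j < len(s) and s[j] == s[i]:
                j += 1
            if j - i >= 3:
                runs.append((i, j))
            i = j
        offset = 0
        for start, end in runs:
            if rng.random() >= config.per_base_error:
                continue
            pos = start + offset
            if rng.random() < 0.5:  # over-call: insert a duplicate base
                out_seq.insert(pos, s[start])
                out_quals.insert(pos, int(config.quality_model.error_quals(1, rng)[0]))
                offset += 1
            else:  # under-call: drop a base
                del out_seq[pos]
                del out_quals[pos]
                offset -= 1
    return "".join(out_seq), np.asarray(out_quals, dtype=np.int16)


def simulate_subject(
    config: SimulationConfig, subject_id: str, barcode: str
) -> tuple[list[Read], TruthRecord]:
    """Simulate one subject's multiplexed reads plus its truth record."""
    locus = _locus()
    by_name = {a.name: a.sequence for a in locus["alleles"]}
    pair = config.allele_pairs[subject_id]
    for name in pair:
        if name not in by_name:
            raise ValueError(f"unknown allele name {name!r}")
    rng = np.random.default_rng(derive_seed(config.seed, "subject", subject_id))

    if config.reads_per_subject is not None:
        n = config.reads_per_subject
    else:
        n = max(40, int(round(rng.normal(340.0, 132.0))))

    reads: list[Read] = []
    n_minor = n_allelic = n_contam = n_corrupt = 0
    for i in range(n):
        if rng.random() < config.contaminant_fraction:
            template = locus["pseudogenes"][int(rng.integers(len(locus["pseudogenes"])))]
            n_contam += 1
        else:
            n_allelic += 1
            if rng.random() < config.minor_fraction:
                template = by_name[pair[1]]
                n_minor += 1
            else:
                template = by_name[pair[0]]
        amplicon, quals = mutate_template(template, config, rng)
        if rng.random() < 0.5:  # sequenced from the reverse strand
            amplicon = reverse_complement(amplicon)
            quals = quals[::-1]
        bc = barcode
        if rng.random() < config.barcode_corrupt_fraction:
            p = int(rng.integers(len(bc)))
            alt = [b for b in "ACGT" if b != bc[p]]
            bc = bc[:p] + alt[int(rng.integers(3))] + bc[p + 1 :]
            n_corrupt += 1
        bc_quals = config.quality_model.correct_quals(len(bc), rng)
        reads.append(
            Read(
                read_id=f"{subject_id}_r{i:05d}",
                sequence=bc + amplicon,
                quals=np.concatenate([bc_quals, quals]),
            )
        )
    truth = TruthRecord(
        subject_id=subject_id,
        allele1=pair[0],
        allele2=pair[1],
        minor_fraction=n_minor / n_allelic if n_allelic else 0.0,
        n_reads=n,
        n_contaminants=n_contam,
        n_barcode_corrupted=n_corrupt,
    )
    return reads, truth


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[Read], dict[str, str], list[TruthRecord]]:
    """Simulate every subject in the config; optionally write the files.

    Returns (multiplexed reads, barcode map, truth records). With
    ``out_dir`` set, writes reads.fastq, barcodes.tsv, truth.tsv and
    motifs.cfg (the fixture motif configuration) into it.
    """
    subjects = list(config.allele_pairs)
    barcodes = make_barcodes(len(subjects))
    barcode_map = dict(zip(barcodes, subjects))
    if len(set(barcode_map.values())) != len(subjects):
        raise ValueError("duplicate subject ids")

    all_reads: list[Read] = []
    truths: list[TruthRecord] = []
    for bc, sid in barcode_map.items():
        reads, truth = simulate_subject(config, sid, bc)
        all_reads.extend(reads)
        truths.append(truth)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fastq(all_reads, out_dir / "reads.fastq")
        write_barcode_map(barcode_map, out_dir / "barcodes.tsv")
        from .io import write_motif_config

        write_motif_config(default_motif_config(), out_dir / "motifs.cfg")
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write(
                "subject_id\tallele1\tallele2\tminor_fraction\tn_reads\t"
                "n_contaminants\tn_barcode_corrupted\n"
            )
            for t in truths:
                fh.write(
                    f"{t.subject_id}\t{t.allele1}\t{t.allele2}\t"
                    f"{t.minor_fraction:.4f}\t{t.n_reads}\t{t.n_contaminants}\t"
                    f"{t.n_barcode_corrupted}\n"
                )
    return all_reads, barcode_map, truths
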