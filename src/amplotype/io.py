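"""Reading and writing of the external formats the pipeline touches.

Formats: FASTQ (4-line, Phred+33) for amplicon reads, FASTA for the
known-allele library, TSV for the barcode map and the genotype report,
and a flat key=value file for motif configuration.

Quality encoding is fixed to Phred+33. Phred+64 input is not auto-detected:
silent mis-decoding is worse than a documented constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MAX_PHRED = 60
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A malformed input file (FASTQ/FASTA/TSV/config)."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """One amplicon read with per-base Phred qualities.

    ``quals`` is an int array aligned base-for-base with ``sequence``.
    ``subject_id`` is None until the read is demultiplexed.
    """

    read_id: str
    sequence: str
    quals: np.ndarray
    subject_id: str | None = None
    strand: str = "forward"

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.sequence) != len(self.quals):
            raise FormatError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quals)}"
            )
        if not self.sequence:
            raise FormatError(f"read {self.read_id!r}: empty sequence")
        if self.quals.size and (self.quals.min() < 0 or self.quals.max() > MAX_PHRED):
            raise FormatError(
                f"read {self.read_id!r}: Phred scores outside [0, {MAX_PHRED}]"
            )
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlleleRecord:
    """A known allele: name plus its exon sequence.

    Names follow the HLA convention ``LOCUS*ff:ff[:ff...]`` with colon-
    separated fields after the ``*``. The two-field prefix is the 4-digit
    (protein-level) group, the three-field prefix the 6-digit group. Names
    are otherwise opaque; G-group suffixes are kept verbatim.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if "*" not in self.name:
            raise FormatError(f"allele name {self.name!r} lacks a '*' separator")
        if not self.sequence:
            raise FormatError(f"allele {self.name!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def _group(self, n_fields: int) -> str:
        locus, _, rest = self.name.partition("*")
        fields = rest.split(":")
        return f"{locus}*{':'.join(fields[:n_fields])}"

    @property
    def group_4digit(self) -> str:
        return self._group(2)

    @property
    def group_6digit(self) -> str:
        return self._group(3)


@dataclass
class GenotypeReport:
    """Final genotype call for one subject with bagging summary metrics."""

    subject_id: str
    allele1: str
    allele2: str
    zygosity: str  # "heterozygous" | "homozygous"
    call_rate1: float
    call_rate2: float
    avg_cluster_size1: float
    avg_cluster_size2: float
    avg_identity1: float
    avg_identity2: float

    def __post_init__(self) -> None:
        for v in (self.call_rate1, self.call_rate2, self.avg_identity1, self.avg_identity2):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"percent metric out of [0,100]: {v}")
        if self.zygosity not in ("heterozygous", "homozygous"):
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        if self.zygosity == "homozygous" and self.allele1 != self.allele2:
            raise ValueError("homozygous report requires allele2 == allele1")


REPORT_COLUMNS = [
    "subject_id",
    "allele1_6digit",
    "allele2_6digit",
    "zygosity",
    "call_rate1",
    "call_rate2",
    "avg_cluster_size1",
    "avg_cluster_size2",
    "avg_identity1",
    "avg_identity2",
]


def read_fastq(path: str | Path) -> list[Read]:
    """Parse a Phred+33 FASTQ file into Reads, order preserved.

    Raises FormatError naming the offending record on any malformed
    4-line block (truncation, length mismatch, bad quality characters).
    """
    reads: list[Read] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # trailing blank lines are tolerated
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ (line count {len(lines)} not a multiple of 4)")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        rec = f"record {i // 4 + 1}"
        if not header.startswith("@"):
            raise FormatError(f"{path}: {rec}: header does not start with '@'")
        if not plus.startswith("+"):
            raise FormatError(f"{path}: {rec}: separator line does not start with '+'")
        read_id = header[1:].split()[0] if len(header) > 1 else ""
        if len(seq) != len(qual):
            raise FormatError(
                f"{path}: {rec} ({read_id!r}): sequence length {len(seq)} != quality length {len(qual)}"
            )
        quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
        try:
            reads.append(Read(read_id=read_id, sequence=seq.upper(), quals=quals))
        except FormatError as e:
            raise FormatError(f"{path}: {rec}: {e}") from e
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """Write 4-line Phred+33 FASTQ (byte-deterministic)."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_allele_library(path: str | Path) -> list[AlleleRecord]:
    """Parse a FASTA allele library; headers are allele names.

    Duplicate names and an empty library are hard errors (genotyping
    against an empty or ambiguous library is undefined).
    """
    from Bio import SeqIO

    records = [
        AlleleRecord(name=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: empty allele library")
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"{path}: duplicate allele names: {', '.join(dupes)}")
    return records


def write_allele_library(records: Iterable[AlleleRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.sequence}\n")


def read_barcode_map(path: str | Path) -> dict[str, str]:
    """Read the barcode→subject TSV (columns: barcode, subject_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["barcode", "subject_id"]:
        raise FormatError(f"{path}: expected columns barcode, subject_id")
    barcodes = df["barcode"].tolist()
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{path}: duplicate barcodes")
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise FormatError(f"{path}: barcodes of unequal length {sorted(lengths)}")
    bad = [b for b in barcodes if set(b) - set("ACGT")]
    if bad:
        raise FormatError(f"{path}: non-ACGT barcodes: {bad}")
    return dict(zip(df["barcode"], df["subject_id"]))


def write_barcode_map(entries: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tsubject_id\n")
        for bc, sid in entries.items():
            fh.write(f"{bc}\t{sid}\n")


def write_report(reports: Sequence[GenotypeReport], path: str | Path) -> None:
    """Write the genotype report TSV (floats to 1 decimal)."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in reports:
            row = [
                r.subject_id,
                r.allele1,
                r.allele2,
                r.zygosity,
                f"{r.call_rate1:.1f}",
                f"{r.call_rate2:.1f}",
                f"{r.avg_cluster_size1:.1f}",
                f"{r.avg_cluster_size2:.1f}",
                f"{r.avg_identity1:.1f}",
                f"{r.avg_identity2:.1f}",
            ]
            fh.write("\t".join(row) + "\n")


def read_report(path: str | Path) -> list[GenotypeReport]:
    """Parse a genotype report TSV back into GenotypeReport objects."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if list(df.columns) != REPORT_COLUMNS:
        raise FormatError(f"{path}: unexpected report columns {list(df.columns)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            GenotypeReport(
                subject_id=row["subject_id"],
                allele1=row["allele1_6digit"],
                allele2=row["allele2_6digit"],
                zygosity=row["zygosity"],
                call_rate1=float(row["call_rate1"]),
                call_rate2=float(row["call_rate2"]),
                avg_cluster_size1=float(row["avg_cluster_size1"]),
                avg_cluster_size2=float(row["avg_cluster_size2"]),
                avg_identity1=float(row["avg_identity1"]),
                avg_identity2=float(row["avg_identity2"]),
            )
        )
    return out


@dataclass(frozen=True)
class MotifConfig:
    """Exon-boundary and exclusion motifs used by the preprocessor.

    ``start_motif``/``end_motif`` flank the exon of interest; ``blacklist``
    motifs are diagnostic of pseudogene/paralog amplicons that must be
    excluded. Length bounds reject trimmed products outside the plausible
    exon size range.
    """

    start_motif: str
    end_motif: str
    blacklist: tuple[str, ...] = ()
    min_exon_length: int = 250
    max_exon_length: int = 290

    def __post_init__(self) -> None:
        if not self.start_motif or not self.end_motif:
            raise ValueError("boundary motifs must be non-empty")
        if self.min_exon_length >= self.max_exon_length:
            raise ValueError("min_exon_length must be < max_exon_length")
        object.__setattr__(self, "blacklist", tuple(self.blacklist))


def read_motif_config(path: str | Path) -> MotifConfig:
    """Read motif config from a flat key=value file.

    Keys: start_motif, end_motif, blacklist (comma-separated, may be empty),
    min_exon_length, max_exon_length.
    """
    kv: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            if "=" not in ln:
                raise FormatError(f"{path}: malformed line {ln!r}")
            k, _, v = ln.partition("=")
            kv[k.strip()] = v.strip()
    try:
        blacklist = tuple(m for m in kv.get("blacklist", "").split(",") if m)
        return MotifConfig(
            start_motif=kv["start_motif"],
            end_motif=kv["end_motif"],
            blacklist=blacklist,
            min_exon_length=int(kv.get("min_exon_length", 250)),
            max_exon_length=int(kv.get("max_exon_length", 290)),
        )
    except KeyError as e:
        raise FormatError(f"{path}: missing required key {e}") from e


def write_motif_config(config: MotifConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"start_motif={config.start_motif}\n")
        fh.write(f"end_motif={config.end_motif}\n")
        fh.write(f"blacklist={','.join(config.blacklist)}\n")
        fh.write(f"min_exon_length={config.min_exon_length}\n")
        fh.write(f"max_exon_length={config.max_exon_length}\n")
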