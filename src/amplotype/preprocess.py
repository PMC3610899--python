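"""Read cleaning: demultiplexing, exon trimming, paralog exclusion.

Multiplexed amplicon reads carry a subject-identifying MID barcode at the
5' end, followed by the amplicon in either orientation. Cleaning proceeds
in three stages:

1. demultiplex — exact match of the leading barcode against the map;
   unmatched reads are dropped (no fuzzy barcode correction).
2. orient_and_trim — locate the exon start/end boundary motifs in the read
   or its reverse complement, cut to the motif-delimited interval and
   standardise to forward orientation; reject reads whose motifs are
   missing, out of order, or whose trimmed length is implausible.
3. filter_blacklist — drop reads containing any motif diagnostic of
   pseudogene or paralogous-locus amplicons.

All coordinates are 0-based half-open; motif matching is exact substring
search with first occurrence winning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import MotifConfig, Read, reverse_complement

STAGES = ("input", "demultiplexed", "trimmed", "blacklist_filtered")


@dataclass
class AttritionLog:
    """Read counts surviving each cleaning stage, plus empty-subject flags."""

    counts: dict[str, int] = field(default_factory=dict)
    empty_subjects: list[str] = field(default_factory=list)

    def record(self, stage: str, count: int) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.counts[stage] = count

    def fraction_of_input(self, stage: str) -> float:
        total = self.counts.get("input", 0)
        return self.counts[stage] / total if total else 0.0

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\tfraction_of_input\n")
            for stage in STAGES:
                if stage in self.counts:
                    fh.write(
                        f"{stage}\t{self.counts[stage]}\t{self.fraction_of_input(stage):.4f}\n"
                    )
            for sid in self.empty_subjects:
                fh.write(f"# subject {sid}: 0 surviving reads, excluded\n")


def demultiplex(
    reads: list[Read], barcode_map: dict[str, str]
) -> tuple[list[Read], int]:
    """Assign subjects by exact leading-barcode match and clip the barcode.

    Reads whose prefix matches no barcode are dropped and counted; dropping
    is the contract, not an error.
    """
    if not barcode_map:
        raise ValueError("empty barcode map")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ValueError(f"barcodes of unequal length {sorted(lengths)}")
    L = lengths.pop()
    assigned: list[Read] = []
    unassigned = 0
    for r in reads:
        subject = barcode_map.get(r.sequence[:L])
        if subject is None or len(r) <= L:
            unassigned += 1
            continue
        assigned.append(
            Read(
                read_id=r.read_id,
                sequence=r.sequence[L:],
                quals=r.quals[L:],
                subject_id=subject,
                strand=r.strand,
            )
        )
    return assigned, unassigned


def _find_exon(sequence: str, config: MotifConfig) -> tuple[int, int] | None:
    """Locate [start-motif begin, end-motif end) in one orientation."""
    s = sequence.find(config.start_motif)
    if s < 0:
        return None
    e = sequence.find(config.end_motif, s + len(config.start_motif))
    if e < 0:
        return None
    return s, e + len(config.end_motif)


def orient_and_trim(read: Read, config: MotifConfig) -> Read | None:
    """Trim a read to the motif-delimited exon, forward orientation.

    Tries the read as-is, then its reverse complement. Returns None
    (rejection, not error) when motifs are absent/out of order or the
    trimmed length falls outside [min_exon_length, max_exon_length].
    """
    for strand, seq, quals in (
        ("forward", read.sequence, read.quals),
        ("reverse", reverse_complement(read.sequence), read.quals[::-1]),
    ):
        span = _find_exon(seq, config)
        if span is None:
            continue
        s, e = span
        if not config.min_exon_length <= e - s <= config.max_exon_length:
            return None
        return Read(
            read_id=read.read_id,
            sequence=seq[s:e],
            quals=quals[s:e],
            subject_id=read.subject_id,
            strand=strand if read.strand == "forward" else "reverse",
        )
    return None


def filter_blacklist(
    reads: list[Read], config: MotifConfig
) -> tuple[list[Read], int]:
    """Remove reads containing any blacklist motif (exact substring)."""
    if not config.blacklist:
        return list(reads), 0
    kept = [r for r in reads if not any(m in r.sequence for m in config.blacklist)]
    return kept, len(reads) - len(kept)


def clean_batch(
    reads: list[Read],
    barcode_map: dict[str, str],
    config: MotifConfig,
) -> tuple[dict[str, list[Read]], AttritionLog]:
    """demultiplex → orient_and_trim → filter_blacklist, with bookkeeping.

    Returns per-subject read sets (every mapped subject appears as a key)
    and the attrition log. Subjects left with zero reads are flagged in the
    log and carry an empty list; downstream genotyping skips them.
    """
    log = AttritionLog()
    log.record("input", len(reads))

    assigned, _ = demultiplex(reads, barcode_map)
    log.record("demultiplexed", len(assigned))

    trimmed = [t for r in assigned if (t := orient_and_trim(r, config)) is not None]
    log.record("trimmed", len(trimmed))

    kept, _ = filter_blacklist(trimmed, config)
    log.record("blacklist_filtered", len(kept))

    by_subject: dict[str, list[Read]] = {sid: [] for sid in barcode_map.values()}
    for r in kept:
        by_subject[r.subject_id].append(r)
    log.empty_subjects = sorted(sid for sid, rs in by_subject.items() if not rs)
    return by_subject, log
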