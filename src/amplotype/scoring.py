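"""Error taxonomy for simulated-vs-true genotype comparisons.

Calls are scored per allele (a diploid genotype contributes two). A
disagreement is a *sensitivity error* (allele dropout) when a true
heterozygote is reported homozygous for one of its real alleles — the
second allele was missed, typically because unbalanced amplification
under-represented it. Any other wrong allele is a *specificity error*:
an alternate genotype was called.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable

from .io import GenotypeReport


@dataclass
class ErrorTally:
    """Per-allele concordance counts over a scored cohort."""

    n_alleles: int = 0
    concordant: int = 0
    sensitivity_errors: int = 0
    specificity_errors: int = 0

    @property
    def concordance_rate(self) -> float:
        return self.concordant / self.n_alleles if self.n_alleles else 0.0


def score_genotypes(
    reports: list[GenotypeReport],
    truth: dict[str, tuple[str, str]],
    resolution: Callable[[str], str] = lambda name: name,
) -> ErrorTally:
    """Tally concordant / sensitivity-error / specificity-error alleles.

    ``truth`` maps subject_id to its true allele pair. ``resolution``
    optionally projects allele names before comparison (e.g. to their
    4-digit group). Subjects absent from ``truth`` are an error; subjects
    absent from ``reports`` are simply not scored.
    """
    tally = ErrorTally()
    for rep in reports:
        if rep.subject_id not in truth:
            raise KeyError(f"subject {rep.subject_id!r} missing from truth table")
        t1, t2 = truth[rep.subject_id]
        true_set = Counter([resolution(t1), resolution(t2)])
        called_set = Counter([resolution(rep.allele1), resolution(rep.allele2)])
        common = sum((true_set & called_set).values())
        errors = 2 - common
        tally.n_alleles += 2
        tally.concordant += common
        if errors == 0:
            continue
        truth_het = resolution(t1) != resolution(t2)
        called_hom = len(set(called_set)) == 1
        called_in_truth = next(iter(called_set)) in true_set if called_hom else False
        if truth_het and called_hom and called_in_truth:
            tally.sensitivity_errors += errors  # allele dropout
        else:
            tally.specificity_errors += errors
    return tally
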