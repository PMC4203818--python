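"""Integer copy-number calling and copy-number-aware diplotype assembly.

Copy number comes from a relative-quantification (RQ) assay against a
two-copy calibrator: the point estimate is ``round(2·RQ)`` (ties to
even), with a z-score and a confidence computed under a normal error
model on the replicate standard deviation.  A call is accepted only if
confidence exceeds 95% and the z-score is below 1.75 — the acceptance
thresholds used with TaqMan copy-number chemistry.

Diplotype assembly attaches the deletion allele (*5) and duplication
multipliers (×N) to the two phased haplotype labels.  When an individual
with three or more copies carries two *different* base alleles, the assay
cannot tell which allele is duplicated: the call is flagged ambiguous,
both slots keep their base labels, and the surplus copies are carried
separately (this is why duplicated alleles are systematically
undercounted at the allele level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

from scipy.stats import norm

from .alleles import (
    AlleleDefinitions,
    DELETION_ALLELE,
    format_star_label,
    parse_star_label,
)

#: CopyCaller-style acceptance thresholds
CONFIDENCE_THRESHOLD = 0.95
Z_THRESHOLD = 1.75

#: largest copy number the assembler accepts (guard against RQ outliers)
MAX_COPY_NUMBER = 6


@dataclass(frozen=True)
class CopyNumberCall:
    cn_integer: int
    confidence: float
    z_score: float
    pass_flag: bool


@dataclass
class DiplotypeCall:
    """Two star-allele slots plus total copy number for one individual.

    Invariant: the slot multipliers (with *5 counting 0) plus
    ``unassigned_copies`` sum to ``total_copy_number``.
    """

    individual_id: str
    allele_a: str
    allele_b: str
    total_copy_number: int
    duplication_ambiguous: bool = False
    unassigned_copies: int = 0
    blocked: bool = False
    block_reason: Optional[str] = None

    @classmethod
    def make_blocked(cls, individual_id: str, reason: str) -> "DiplotypeCall":
        """A phenotype-blocking placeholder for a failed copy-number call."""
        call = cls(
            individual_id=individual_id,
            allele_a="",
            allele_b="",
            total_copy_number=-1,
            blocked=True,
            block_reason=reason,
        )
        return call

    @property
    def slots(self) -> Tuple[str, str]:
        return (self.allele_a, self.allele_b)

    def __str__(self) -> str:
        if self.blocked:
            return f"{self.individual_id}: blocked ({self.block_reason})"
        s = f"{self.allele_a}/{self.allele_b}"
        if self.duplication_ambiguous:
            s += f" (+{self.unassigned_copies} unassigned cop"
            s += "y)" if self.unassigned_copies == 1 else "ies)"
        return s


def slot_multiplier(label: str) -> int:
    """Chromosome copies contributed by one slot (*5 contributes 0)."""
    if label == DELETION_ALLELE:
        return 0
    _base, mult = parse_star_label(label) if label.startswith("*") else (label, 1)
    return mult


def call_copy_number(rq_value: float, replicate_sd: float) -> CopyNumberCall:
    """Integer copy number from a relative quantification vs a 2-copy calibrator.

    ``cn = round(2·rq)`` with ties to even; ``z = |2·rq − cn| / sd``;
    confidence is the probability, under Normal(2·rq, sd), of landing in
    the rounding interval of ``cn``.
    """
    if rq_value <= 0:
        raise ValueError(f"relative quantification must be positive, got {rq_value}")
    if replicate_sd <= 0:
        raise ValueError("replicate_sd must be positive")
    doubled = 2.0 * rq_value
    cn = int(round(doubled))  # Python round: nearest integer, ties to even
    z = abs(doubled - cn) / replicate_sd
    confidence = float(
        norm.cdf((cn + 0.5 - doubled) / replicate_sd)
        - norm.cdf((cn - 0.5 - doubled) / replicate_sd)
    )
    pass_flag = confidence > CONFIDENCE_THRESHOLD and z < Z_THRESHOLD
    return CopyNumberCall(cn, confidence, z, pass_flag)


def decompose_duplication(label: str) -> Tuple[str, int]:
    """Inverse of duplication labelling: "*1x3" -> ("*1", 3)."""
    return parse_star_label(label)


def assemble_diplotype(
    labels: Tuple[str, Optional[str]],
    cn: Optional[int],
    defs: AlleleDefinitions,
    *,
    individual_id: str = "",
) -> DiplotypeCall:
    """Combine phased star labels with copy number into a diplotype call.

    Rules: CN 2 leaves labels unchanged; CN 1 pairs the single observed
    haplotype with *5; CN 0 is *5/*5; CN k ≥ 3 with two copies of the
    same base allele promotes one slot to base×(k−1); with two different
    base alleles the duplication is ambiguous and k−2 copies stay
    unassigned.
    """
    if cn is None:
        return DiplotypeCall.make_blocked(
            individual_id, "missing or failed copy-number call"
        )
    if cn < 0 or cn > MAX_COPY_NUMBER:
        raise ValueError(
            f"copy number {cn} outside supported range [0, {MAX_COPY_NUMBER}]"
        )
    a, b = labels

    if cn == 0:
        return DiplotypeCall(individual_id, DELETION_ALLELE, DELETION_ALLELE, 0)
    if cn == 1:
        present = [x for x in (a, b) if x is not None and x != DELETION_ALLELE]
        if len(set(present)) > 1:
            raise ValueError(
                f"{individual_id}: two distinct alleles {present} contradict CN=1"
            )
        if not present:
            raise ValueError(f"{individual_id}: CN=1 but no observed haplotype label")
        return DiplotypeCall(individual_id, present[0], DELETION_ALLELE, 1)

    if a is None or b is None:
        raise ValueError(f"{individual_id}: CN={cn} requires two phased labels")
    for lab in (a, b):
        if lab == DELETION_ALLELE:
            raise ValueError(
                f"{individual_id}: *5 with CN={cn} is contradictory"
            )
    if cn == 2:
        return DiplotypeCall(individual_id, a, b, 2)

    # cn >= 3: attach the surplus copies
    if not (a.startswith("*") and b.startswith("*")):
        # an unassignable ("Others") haplotype cannot anchor a duplication
        return DiplotypeCall(
            individual_id, a, b, cn,
            duplication_ambiguous=True, unassigned_copies=cn - 2,
        )
    base_a, mult_a = parse_star_label(a)
    base_b, mult_b = parse_star_label(b)
    if mult_a != 1 or mult_b != 1:
        raise ValueError(
            f"{individual_id}: phased labels must be base alleles, got {a}/{b}"
        )
    if base_a == base_b:
        return DiplotypeCall(
            individual_id, format_star_label(base_a, cn - 1), base_b, cn
        )
    return DiplotypeCall(
        individual_id,
        a,
        b,
        cn,
        duplication_ambiguous=True,
        unassigned_copies=cn - 2,
    )
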