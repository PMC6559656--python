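"""Carrier association statistics and detection-probability calculators.

2x2 carrier tables (carriers / non-carriers x cases / controls) are tested
with Fisher's exact test; odds ratios use the Haldane-Anscombe 0.5 correction
when a zero cell is present and Woolf (log-normal) confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

from scipy.stats import hypergeom

from .core import GenotypeMatrix, HaplotypeSet, Phenotype

__all__ = [
    "CountLevel",
    "ContingencyTable",
    "AssocResult",
    "carrier_table",
    "fisher_exact_2x2",
    "odds_ratio_haldane",
    "associate",
    "detection_probability",
    "min_detectable_frequency",
]


class CountLevel(str, Enum):
    SUBJECT = "subject"
    CHROMOSOME = "chromosome"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a..d laid out as [[a, b], [c, d]] =
    [[case carriers, case non-carriers], [control carriers, control non-c.]].
    """

    a: int
    b: int
    c: int
    d: int
    level: CountLevel = CountLevel.SUBJECT

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both group margins must be positive")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AssocResult:
    table: ContingencyTable
    p_two_sided: float
    odds_ratio: float
    ci95: tuple[float, float]
    correction_applied: bool


def _hap_matches(
    hap: Sequence[str], marker_ids: Sequence[str], pattern: Mapping[str, str]
) -> bool:
    idx = {mid: j for j, mid in enumerate(marker_ids)}
    for mid, allele in pattern.items():
        if mid not in idx:
            raise KeyError(f"pattern marker {mid!r} not in data")
        if hap[idx[mid]] != str(allele):
            return False
    return True


def carrier_table(
    haps: HaplotypeSet,
    pattern: Mapping[str, str],
    phenotype: Mapping[str, Phenotype],
    level: CountLevel = CountLevel.SUBJECT,
) -> ContingencyTable:
    """Count carriers of a haplotype pattern among cases and controls.

    ``pattern`` maps marker id -> allele; a chromosome matches if it carries
    every listed allele.  At subject level a carrier is a subject with at
    least one matching chromosome.
    """
    match = [
        _hap_matches(h, haps.marker_ids, pattern) for h in haps.haplotypes
    ]
    a = b = c = d = 0
    if level == CountLevel.CHROMOSOME:
        for m, s in zip(match, haps.subject_of):
            ph = phenotype.get(s)
            if ph is None:
                continue
            if ph == Phenotype.CASE:
                a, b = (a + 1, b) if m else (a, b + 1)
            else:
                c, d = (c + 1, d) if m else (c, d + 1)
    else:
        by_subject: dict[str, bool] = {}
        for m, s in zip(match, haps.subject_of):
            by_subject[s] = by_subject.get(s, False) or m
        for s, m in by_subject.items():
            ph = phenotype.get(s)
            if ph is None:
                continue
            if ph == Phenotype.CASE:
                a, b = (a + 1, b) if m else (a, b + 1)
            else:
                c, d = (c + 1, d) if m else (c, d + 1)
    return ContingencyTable(a, b, c, d, level=level)


def fisher_exact_2x2(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables (with the observed margins) no more probable than the observed."""
    row1 = t.a + t.b
    col1 = t.a + t.c
    total = row1 + t.c + t.d
    dist = hypergeom(total, col1, row1)
    p_obs = dist.pmf(t.a)
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    p = 0.0
    for x in range(lo, hi + 1):
        px = dist.pmf(x)
        if px <= p_obs * (1.0 + 1e-7):
            p += px
    return min(p, 1.0)


def odds_ratio_haldane(
    t: ContingencyTable, z: float = 1.96
) -> tuple[float, tuple[float, float], bool]:
    """Odds ratio with Haldane-Anscombe correction and Woolf CI.

    If any cell is zero, 0.5 is added to all four cells before computing
    OR = ad/bc and the CI exp(ln OR +- z * sqrt(sum 1/cell)).
    Returns (OR, (low, high), correction_applied).
    """
    corrected = t.has_zero_cell
    add = 0.5 if corrected else 0.0
    a, b, c, d = (t.a + add, t.b + add, t.c + add, t.d + add)
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        math.exp(log_or),
        (math.exp(log_or - z * se), math.exp(log_or + z * se)),
        corrected,
    )


def associate(t: ContingencyTable, z: float = 1.96) -> AssocResult:
    """Fisher p plus Haldane/Woolf odds-ratio summary for one table."""
    odds, ci, corrected = odds_ratio_haldane(t, z=z)
    return AssocResult(
        table=t,
        p_two_sided=fisher_exact_2x2(t),
        odds_ratio=odds,
        ci95=ci,
        correction_applied=corrected,
    )


def detection_probability(n_chromosomes: int, f: float) -> float:
    """P(an allele at frequency f appears at least once in the sample)
    = 1 - (1 - f)^n_chromosomes."""
    if not 0 < f <= 1:
        raise ValueError("f must be in (0, 1]")
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    return 1.0 - (1.0 - f) ** n_chromosomes


def min_detectable_frequency(n_chromosomes: int, confidence: float) -> float:
    """Smallest allele frequency detected with the given confidence:
    f = 1 - (1 - confidence)^(1 / n_chromosomes)."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    return 1.0 - (1.0 - confidence) ** (1.0 / n_chromosomes)
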