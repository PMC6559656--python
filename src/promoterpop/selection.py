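"""Diversity and neutrality statistics: Watterson theta, pairwise diversity,
heterozygosity and Tajima's D, overall and stratified by variant class.

Two pairwise-diversity normalizations are supported: ``paper`` divides the
sum of 2*p*(1-p) by 1 - 1/(n-1) (0.983051 at n = 60); ``standard`` applies
the usual n/(n-1) small-sample correction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import HaplotypeSet, Marker, VarClass

__all__ = [
    "TajimaConstants",
    "SelectionStats",
    "ClassStats",
    "harmonic_a1",
    "watterson_theta",
    "pi_from_freqs",
    "heterozygosity",
    "tajima_constants",
    "tajima_d",
    "site_frequencies",
    "selection_stats",
]


def harmonic_a1(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(S: int, n: int, L: float) -> tuple[float, float]:
    """Watterson estimator: returns (a1, theta per site)."""
    if L <= 0:
        raise ValueError("L must be positive")
    if S < 0:
        raise ValueError("S must be >= 0")
    a1 = harmonic_a1(n)
    return a1, S / a1 / L


def pi_from_freqs(
    freqs: Sequence[float], n: int, L: float, mode: str = "paper"
) -> float:
    """Pairwise diversity per site from per-site minor/derived frequencies.

    k = sum_j 2 p_j (1 - p_j); ``paper`` mode divides k by 1 - 1/(n-1),
    ``standard`` mode multiplies k by n/(n-1).  Monomorphic sites (p of 0 or
    1) are skipped.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    k = sum(2.0 * p * (1.0 - p) for p in freqs if 0.0 < p < 1.0)
    if mode == "paper":
        return k / (1.0 - 1.0 / (n - 1)) / L
    if mode == "standard":
        return k * n / (n - 1) / L
    raise ValueError(f"unknown pi mode {mode!r}")


def heterozygosity(allele_freqs: Sequence[float]) -> float:
    """h = 1 - sum p_i^2 (expected heterozygosity)."""
    tot = sum(allele_freqs)
    if not math.isclose(tot, 1.0, abs_tol=1e-6):
        raise ValueError(f"allele frequencies must sum to 1, got {tot}")
    return 1.0 - sum(p * p for p in allele_freqs)


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Tajima (1989) variance constants for sample size n."""
    if n < 2:
        raise ValueError("need n >= 2")
    a1 = harmonic_a1(n)
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from the segregating-site count and the *total* (not
    per-site) pairwise diversity.  Undefined (ValueError) for S = 0."""
    if S < 1:
        raise ValueError("Tajima's D is undefined for S = 0")
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (pi_total - S / c.a1) / math.sqrt(var)


def site_frequencies(
    haps: HaplotypeSet, indices: Optional[Sequence[int]] = None
) -> list[float]:
    """Per-site frequency of the non-major allele group (multiallelic sites
    are collapsed to most-common-allele vs rest); monomorphic sites yield 0."""
    if indices is None:
        indices = range(len(haps.marker_ids))
    out = []
    for j in indices:
        counts = Counter(haps.column(j))
        total = sum(counts.values())
        top = counts.most_common(1)[0][1]
        out.append((total - top) / total)
    return out


@dataclass(frozen=True)
class ClassStats:
    var_class: VarClass
    S: int
    theta_per_site: float
    pi_per_site: float
    tajima_D: Optional[float]
    mean_h: float


@dataclass(frozen=True)
class SelectionStats:
    n: int
    S: int
    L: float
    a1: float
    theta_per_site: float
    pi_per_site: float
    tajima_D: Optional[float]
    pi_mode: str
    by_class: Mapping[VarClass, ClassStats] = field(default_factory=dict)


def _stats_for(
    haps: HaplotypeSet, indices: Sequence[int], n: int, L: float, mode: str
) -> tuple[int, float, float, Optional[float]]:
    freqs = site_frequencies(haps, indices)
    seg = [f for f in freqs if f > 0.0]
    S = len(seg)
    a1, theta = watterson_theta(S, n, L)
    pi = pi_from_freqs(seg, n, L, mode=mode)
    D = tajima_d(S, pi * L, n) if S >= 1 else None
    return S, theta, pi, D


def selection_stats(
    haps: HaplotypeSet,
    markers: Sequence[Marker],
    L: float,
    pi_mode: str = "paper",
    classes: Optional[Sequence[VarClass]] = None,
) -> SelectionStats:
    """Overall and per-class S, theta, pi, Tajima's D and heterozygosity.

    Each marker contributes one segregating site; multiallelic loci enter
    theta/pi/D through a most-common-allele-vs-rest encoding, and their full
    allelic heterozygosity is reported separately as ``mean_h``.
    """
    if len(markers) != len(haps.marker_ids):
        raise ValueError("marker list must match haplotype columns")
    n = haps.n_chromosomes
    S, theta, pi, D = _stats_for(haps, range(len(markers)), n, L, pi_mode)
    by_class: dict[VarClass, ClassStats] = {}
    wanted = list(classes) if classes is not None else list(VarClass)
    for vc in wanted:
        idx = [j for j, mk in enumerate(markers) if mk.var_class == vc]
        if not idx:
            continue
        cS, ctheta, cpi, cD = _stats_for(haps, idx, n, L, pi_mode)
        hs = []
        for j in idx:
            counts = Counter(haps.column(j))
            tot = sum(counts.values())
            hs.append(heterozygosity([c / tot for c in counts.values()]))
        by_class[vc] = ClassStats(
            var_class=vc,
            S=cS,
            theta_per_site=ctheta,
            pi_per_site=cpi,
            tajima_D=cD,
            mean_h=sum(hs) / len(hs),
        )
    return SelectionStats(
        n=n, S=S, L=L, a1=harmonic_a1(n),
        theta_per_site=theta, pi_per_site=pi, tajima_D=D,
        pi_mode=pi_mode, by_class=by_class,
    )
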