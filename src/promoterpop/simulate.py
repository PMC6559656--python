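"""Synthetic cohorts: coalescent haplotypes with layered multi-class
mutations, diploid pairing and case/control labelling.

Binary variants (SNP / DNP / INDEL) follow the infinite-sites process on the
ancestral recombination graph; repeat loci (VNTR / SSLP / POLY_A) evolve by a
symmetric single-step model on the marginal genealogy of their position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .coalescent import (
    ArgResult,
    RecombMap,
    TreeNode,
    marginal_tree,
    simulate_arg,
)
from .core import (
    GenotypeMatrix,
    HaplotypeSet,
    HaplotypeSource,
    Marker,
    Phenotype,
    VarClass,
)

__all__ = ["SimConfig", "SimOutput", "simulate_haplotypes", "diploidize"]

_BINARY = (VarClass.SNP, VarClass.DNP, VarClass.INDEL)
_REPEAT = (VarClass.VNTR, VarClass.SSLP, VarClass.POLY_A)

_DEFAULT_MIX: dict[VarClass, float] = {
    VarClass.SNP: 0.88,
    VarClass.DNP: 0.02,
    VarClass.INDEL: 0.04,
    VarClass.VNTR: 0.02,
    VarClass.SSLP: 0.02,
    VarClass.POLY_A: 0.02,
}

_REPEAT_UNITS = {VarClass.VNTR: 30, VarClass.SSLP: 4, VarClass.POLY_A: 1}
_REPEAT_ROOT = {VarClass.VNTR: 6, VarClass.SSLP: 8, VarClass.POLY_A: 10}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    ``theta_per_kb`` is 4Nu scaled per kb; ``class_mix`` gives the expected
    proportion of markers in each variant class and must sum to 1.  ``seed``
    fully determines the output.
    """

    n_chromosomes: int = 60
    theta_per_kb: float = 1.5
    recomb_map: RecombMap = field(
        default_factory=lambda: RecombMap(18_000, 0.5, ())
    )
    class_mix: Mapping[VarClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    vntr_step_rate: float = 2.0
    tss_at_bp: Optional[int] = None  # physical coordinate of TSS-relative +1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2 or self.n_chromosomes % 2:
            raise ValueError("n_chromosomes must be an even integer >= 2")
        if self.theta_per_kb <= 0:
            raise ValueError("theta_per_kb must be positive")
        mix = {VarClass(k): float(v) for k, v in self.class_mix.items()}
        if any(v < 0 for v in mix.values()):
            raise ValueError("class proportions must be >= 0")
        tot = sum(mix.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-6):
            raise ValueError(f"class proportions must sum to 1, got {tot}")
        object.__setattr__(self, "class_mix", mix)

    @property
    def region_length_bp(self) -> int:
        return int(self.recomb_map.region_length_bp)

    @property
    def tss_physical(self) -> int:
        if self.tss_at_bp is not None:
            return self.tss_at_bp
        # default: last ninth of the region is downstream of the TSS
        return int(self.region_length_bp * 8 / 9)


@dataclass
class SimOutput:
    markers: list[Marker]
    haplotypes: HaplotypeSet
    true_trees: list[tuple[float, float, TreeNode]]
    true_breakpoints: list[float]
    arg: ArgResult


def _phys_to_tss(x: int, tss_at: int) -> int:
    return x - tss_at + 1 if x >= tss_at else x - tss_at


_BASES = "ACGT"


def _snp_alleles(rng: np.random.Generator) -> tuple[str, str]:
    anc, der = rng.choice(4, size=2, replace=False)
    return _BASES[anc], _BASES[der]


def _dnp_alleles(rng: np.random.Generator) -> tuple[str, str]:
    a = rng.integers(0, 4, size=2)
    b = (a + rng.integers(1, 4, size=2)) % 4
    return (
        _BASES[a[0]] + _BASES[a[1]],
        _BASES[b[0]] + _BASES[b[1]],
    )


def _indel_alleles(rng: np.random.Generator) -> tuple[str, str]:
    anchor = _BASES[rng.integers(0, 4)]
    ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=rng.integers(1, 7)))
    if rng.random() < 0.5:
        return anchor, anchor + ins  # insertion
    return anchor + ins, anchor  # deletion


def _evolve_repeat(
    root: TreeNode, root_count: int, step_rate: float, rng: np.random.Generator
) -> dict[int, int]:
    """Symmetric stepwise mutation down a genealogy; reflecting floor at 1."""
    counts: dict[int, int] = {}
    stack = [(root, root_count)]
    while stack:
        node, value = stack.pop()
        if node.leaf is not None:
            counts[node.leaf] = value
            continue
        for child in node.children:
            bl = node.time - child.time
            v = value
            for _ in range(rng.poisson(step_rate * bl)):
                v += 1 if rng.random() < 0.5 else -1
                if v < 1:
                    v = 1
            stack.append((child, v))
    return counts


def simulate_haplotypes(config: SimConfig) -> SimOutput:
    """Simulate phased chromosomes plus ground truth for one cohort.

    Returns markers (TSS-relative, position-sorted), the phased
    :class:`HaplotypeSet`, the marginal genealogies between successive true
    breakpoints, and the breakpoint positions themselves.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_chromosomes
    L = config.region_length_bp
    theta_per_bp = config.theta_per_kb / 1000.0

    arg = simulate_arg(n, config.recomb_map, theta_per_bp=theta_per_bp, rng=rng)

    mix = config.class_mix
    p_binary = sum(mix.get(c, 0.0) for c in _BINARY)
    p_repeat = sum(mix.get(c, 0.0) for c in _REPEAT)

    # binary (infinite-sites) mutations, classed proportionally within mix
    sites: list[tuple[int, VarClass, tuple[str, str], frozenset]] = []
    used_positions: set[int] = set()
    if p_binary > 0:
        bin_classes = [c for c in _BINARY if mix.get(c, 0.0) > 0]
        bin_weights = np.array([mix[c] for c in bin_classes]) / p_binary
        for pos_f, carriers in arg.mutations:
            pos = int(pos_f)
            while pos in used_positions:  # snap collisions: resample nearby
                pos = int(rng.integers(0, L))
            used_positions.add(pos)
            vc = bin_classes[int(rng.choice(len(bin_classes), p=bin_weights))]
            if vc == VarClass.SNP:
                alleles = _snp_alleles(rng)
            elif vc == VarClass.DNP:
                alleles = _dnp_alleles(rng)
            else:
                alleles = _indel_alleles(rng)
            sites.append((pos, vc, alleles, carriers))

    # repeat loci: count scaled to keep class proportions near the mix
    n_binary = len(sites)
    repeat_sites: list[tuple[int, VarClass, dict[int, int]]] = []
    if p_repeat > 0:
        if p_binary > 0:
            n_repeat = max(1, round(n_binary * p_repeat / p_binary))
        else:
            n_repeat = max(1, round(theta_per_bp * L))
        rep_classes = [c for c in _REPEAT if mix.get(c, 0.0) > 0]
        rep_weights = np.array([mix[c] for c in rep_classes]) / p_repeat
        for _ in range(n_repeat):
            vc = rep_classes[int(rng.choice(len(rep_classes), p=rep_weights))]
            for _attempt in range(50):
                pos = int(rng.integers(0, L))
                if pos in used_positions:
                    continue
                tree = marginal_tree(arg, pos + 0.5)
                counts = _evolve_repeat(
                    tree, _REPEAT_ROOT[vc], config.vntr_step_rate, rng
                )
                if len(set(counts.values())) >= 2:  # polymorphic only
                    used_positions.add(pos)
                    repeat_sites.append((pos, vc, counts))
                    break

    # assemble markers and haplotype vectors, position-sorted
    records: list[tuple[int, Marker, list[str]]] = []
    tss_at = config.tss_physical
    for pos, vc, (anc, der), carriers in sites:
        tpos = _phys_to_tss(pos, tss_at)
        marker = Marker(
            id=f"{'m' if tpos > 0 else 'u'}{abs(tpos)}_{vc.value}",
            position=tpos,
            var_class=vc,
            alleles=(anc, der),
        )
        col = [der if i in carriers else anc for i in range(n)]
        records.append((pos, marker, col))
    for pos, vc, counts in repeat_sites:
        tpos = _phys_to_tss(pos, tss_at)
        alleles = tuple(str(v) for v in sorted(set(counts.values())))
        marker = Marker(
            id=f"{'m' if tpos > 0 else 'u'}{abs(tpos)}_{vc.value}",
            position=tpos,
            var_class=vc,
            alleles=alleles,
        )
        col = [str(counts[i]) for i in range(n)]
        records.append((pos, marker, col))
    records.sort(key=lambda r: r[0])

    markers = [m for _, m, _ in records]
    vectors = [
        tuple(col[i] for _, _, col in records) for i in range(n)
    ]
    subject_of = [f"S{i // 2 + 1}" for i in range(n)]
    haps = HaplotypeSet(
        haplotypes=vectors,
        subject_of=subject_of,
        marker_ids=[m.id for m in markers],
        source=HaplotypeSource.SIMULATED,
    )

    cuts = [0.0] + arg.breakpoints + [float(L)]
    trees = [
        (lo, hi, marginal_tree(arg, (lo + hi) / 2))
        for lo, hi in zip(cuts, cuts[1:])
        if hi > lo
    ]
    return SimOutput(
        markers=markers,
        haplotypes=haps,
        true_trees=trees,
        true_breakpoints=list(arg.breakpoints),
        arg=arg,
    )


def _matches(
    hap: Sequence[str], marker_ids: Sequence[str], pattern: Mapping[str, str]
) -> bool:
    idx = {mid: j for j, mid in enumerate(marker_ids)}
    return all(hap[idx[mid]] == str(a) for mid, a in pattern.items())


def diploidize(
    haps: HaplotypeSet,
    case_fraction: float = 0.5,
    risk_haplotype: Optional[Mapping[str, str]] = None,
    odds: float = 1.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Randomly pair chromosomes into diploids and label case/control.

    Phenotypes follow a carrier model: a subject carrying >= 1 haplotype
    matching ``risk_haplotype`` has its odds of being a case multiplied by
    ``odds``.  ``odds = 1`` (or no pattern) makes labels independent of
    genotype; ``odds = inf`` makes every carrier a case (then remaining case
    slots are filled from non-carriers at random).
    """
    if not haps.haplotypes:
        raise ValueError("empty haplotype set")
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = haps.n_chromosomes
    perm = rng.permutation(n)
    subjects = [f"S{i + 1}" for i in range(n // 2)]
    pairs = [(int(perm[2 * i]), int(perm[2 * i + 1])) for i in range(n // 2)]

    carrier = [False] * len(subjects)
    if risk_haplotype is not None:
        for s, (i, j) in enumerate(pairs):
            carrier[s] = _matches(
                haps.haplotypes[i], haps.marker_ids, risk_haplotype
            ) or _matches(haps.haplotypes[j], haps.marker_ids, risk_haplotype)

    n_subj = len(subjects)
    phenotype: dict[str, Phenotype] = {}
    if risk_haplotype is None or odds == 1.0 or not any(carrier):
        case_idx = set(
            int(i)
            for i in rng.choice(n_subj, size=round(case_fraction * n_subj),
                                replace=False)
        )
    elif math.isinf(odds):
        n_cases = round(case_fraction * n_subj)
        carriers = [i for i in range(n_subj) if carrier[i]]
        noncarriers = [i for i in range(n_subj) if not carrier[i]]
        case_idx = set(carriers[:n_cases])
        remaining = n_cases - len(case_idx)
        if remaining > 0:
            case_idx |= set(
                int(noncarriers[i])
                for i in rng.choice(len(noncarriers), size=remaining,
                                    replace=False)
            )
    else:
        # logistic carrier model: choose the non-carrier case probability p0
        # so the expected case fraction matches case_fraction
        frac_c = sum(carrier) / n_subj

        def p1(p0: float) -> float:
            return odds * p0 / (1 - p0 + odds * p0)

        def excess(p0: float) -> float:
            return (1 - frac_c) * p0 + frac_c * p1(p0) - case_fraction

        p0 = brentq(excess, 1e-12, 1 - 1e-12)
        draws = rng.random(n_subj)
        case_idx = {
            i for i in range(n_subj)
            if draws[i] < (p1(p0) if carrier[i] else p0)
        }
    for i, s in enumerate(subjects):
        phenotype[s] = Phenotype.CASE if i in case_idx else Phenotype.CONTROL

    haplotypes = []
    subject_of = []
    for s, (i, j) in zip(subjects, pairs):
        haplotypes.append(haps.haplotypes[i])
        haplotypes.append(haps.haplotypes[j])
        subject_of.extend([s, s])
    paired = HaplotypeSet(
        haplotypes=haplotypes,
        subject_of=subject_of,
        marker_ids=list(haps.marker_ids),
        source=haps.source,
    )
    return paired.to_genotypes(phenotype=phenotype)
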