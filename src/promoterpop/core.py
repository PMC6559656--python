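"""Core data model: markers, genotype/haplotype containers, coordinates.

Coordinates are TSS-relative signed integers with no zero: +1 is the first
base of the first exon, -1 is the base immediately upstream.  All modules in
this package share these types.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "VarClass",
    "Phenotype",
    "HaplotypeSource",
    "Marker",
    "GenotypeMatrix",
    "HaplotypeSet",
    "RegionSummary",
    "InvalidMarkerError",
    "NoDataError",
    "classify_variant",
    "minor_allele_frequency",
    "region_summary",
    "tss_to_contig",
    "contig_to_tss",
]


class VarClass(str, Enum):
    """Variant classes used throughout the pipeline."""

    SNP = "SNP"
    DNP = "DNP"
    INDEL = "INDEL"
    VNTR = "VNTR"
    SSLP = "SSLP"
    POLY_A = "POLY_A"


class Phenotype(str, Enum):
    CASE = "case"
    CONTROL = "control"


class HaplotypeSource(str, Enum):
    SIMULATED = "simulated"
    PHASED = "phased"
    INPUT = "input"


class InvalidMarkerError(ValueError):
    """Raised when a marker definition violates its invariants."""


class NoDataError(ValueError):
    """Raised when a computation receives no usable calls."""


_REPEAT_CLASSES = frozenset({VarClass.VNTR, VarClass.SSLP, VarClass.POLY_A})


def _is_int_label(s: str) -> bool:
    try:
        int(s)
    except (TypeError, ValueError):
        return False
    return True


def classify_variant(
    alleles: Sequence[str], repeat_unit_bp: Optional[int] = None
) -> VarClass:
    """Classify a variant from its allele labels.

    Decision table:

    * repeat loci (``repeat_unit_bp`` given, labels are repeat counts):
      unit 1 bp -> POLY_A; unit 2-10 bp -> SSLP; unit > 10 bp -> VNTR
    * two single-base alleles -> SNP
    * two two-base same-length alleles -> DNP
    * length-changing allele set -> INDEL

    Raises
    ------
    InvalidMarkerError
        If fewer than two alleles are supplied or the combination does not
        match any class.
    """
    if len(alleles) < 2:
        raise InvalidMarkerError("a variant needs at least 2 alleles")
    if repeat_unit_bp is not None:
        if repeat_unit_bp < 1:
            raise InvalidMarkerError("repeat unit must be >= 1 bp")
        if not all(_is_int_label(a) for a in alleles):
            raise InvalidMarkerError("repeat alleles must be integer counts")
        if repeat_unit_bp == 1:
            return VarClass.POLY_A
        if repeat_unit_bp <= 10:
            return VarClass.SSLP
        return VarClass.VNTR
    lengths = {len(a) for a in alleles}
    if lengths == {1} and len(alleles) == 2:
        return VarClass.SNP
    if lengths == {2} and len(alleles) == 2:
        return VarClass.DNP
    if len(lengths) > 1:
        return VarClass.INDEL
    raise InvalidMarkerError(
        f"cannot classify alleles {list(alleles)!r} without a repeat unit"
    )


@dataclass(frozen=True)
class Marker:
    """A polymorphic site in TSS-relative coordinates.

    ``position`` is a signed integer with no zero; ``alleles`` is an ordered
    list of labels (for repeat classes the labels are repeat counts).
    """

    id: str
    position: int
    var_class: VarClass
    alleles: tuple[str, ...]
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(str(a) for a in self.alleles))
        if len(self.alleles) < 2:
            raise InvalidMarkerError(f"{self.id}: needs >= 2 alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise InvalidMarkerError(f"{self.id}: duplicate allele labels")
        if self.position == 0:
            raise InvalidMarkerError(f"{self.id}: position 0 does not exist")
        self._check_class()

    def _check_class(self) -> None:
        vc, alleles = self.var_class, self.alleles
        if vc == VarClass.SNP:
            if len(alleles) != 2 or any(len(a) != 1 for a in alleles):
                raise InvalidMarkerError(f"{self.id}: SNP needs two 1-bp alleles")
        elif vc == VarClass.DNP:
            if len(alleles) != 2 or any(len(a) != 2 for a in alleles):
                raise InvalidMarkerError(f"{self.id}: DNP needs two 2-bp alleles")
        elif vc in _REPEAT_CLASSES:
            if not all(_is_int_label(a) for a in alleles):
                raise InvalidMarkerError(
                    f"{self.id}: {vc.value} alleles must be repeat counts"
                )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alleles) == 2


@dataclass
class GenotypeMatrix:
    """Diploid calls for subjects x markers; missing calls are ``None``.

    ``calls[s][m]`` is an unordered allele pair (stored sorted) for subject
    index ``s`` at marker index ``m``.
    """

    subjects: list[str]
    marker_ids: list[str]
    calls: list[list[Optional[tuple[str, str]]]]
    phenotype: Optional[dict[str, Phenotype]] = None

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.subjects):
            raise ValueError("calls rows must match subject count")
        for row in self.calls:
            if len(row) != len(self.marker_ids):
                raise ValueError("calls columns must match marker count")
        self.calls = [
            [None if c is None else tuple(sorted(c)) for c in row]
            for row in self.calls
        ]
        if self.phenotype is not None:
            unknown = set(self.phenotype) - set(self.subjects)
            if unknown:
                raise ValueError(f"phenotype for unknown subjects: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def column(self, m: int) -> list[Optional[tuple[str, str]]]:
        return [row[m] for row in self.calls]

    def marker_index(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def validate_against(self, markers: Sequence[Marker]) -> None:
        """Check that every called allele is in its marker's allele list."""
        by_id = {mk.id: mk for mk in markers}
        for j, mid in enumerate(self.marker_ids):
            mk = by_id.get(mid)
            if mk is None:
                raise ValueError(f"no marker definition for column {mid!r}")
            allowed = set(mk.alleles)
            for i, row in enumerate(self.calls):
                call = row[j]
                if call is not None and not set(call) <= allowed:
                    raise ValueError(
                        f"subject {self.subjects[i]} marker {mid}: "
                        f"call {call} not in alleles {mk.alleles}"
                    )


@dataclass
class HaplotypeSet:
    """Phased chromosomes: 2 per subject, each an allele vector."""

    haplotypes: list[tuple[str, ...]]
    subject_of: list[str]
    marker_ids: list[str]
    source: HaplotypeSource = HaplotypeSource.INPUT

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.subject_of):
            raise ValueError("one subject label per chromosome required")
        counts = Counter(self.subject_of)
        bad = {s: c for s, c in counts.items() if c != 2}
        if bad:
            raise ValueError(f"subjects without exactly 2 chromosomes: {bad}")
        m = len(self.marker_ids)
        self.haplotypes = [tuple(str(a) for a in h) for h in self.haplotypes]
        for h in self.haplotypes:
            if len(h) != m:
                raise ValueError("haplotype length must equal marker count")

    @property
    def n_chromosomes(self) -> int:
        return len(self.haplotypes)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_of:
            seen.setdefault(s)
        return list(seen)

    def column(self, m: int) -> list[str]:
        return [h[m] for h in self.haplotypes]

    def subset_markers(self, indices: Sequence[int]) -> "HaplotypeSet":
        return HaplotypeSet(
            haplotypes=[tuple(h[i] for i in indices) for h in self.haplotypes],
            subject_of=list(self.subject_of),
            marker_ids=[self.marker_ids[i] for i in indices],
            source=self.source,
        )

    def to_genotypes(
        self, phenotype: Optional[Mapping[str, Phenotype]] = None
    ) -> GenotypeMatrix:
        """Collapse phased chromosomes into unordered diploid calls."""
        pairs: dict[str, list[tuple[str, ...]]] = {}
        order: list[str] = []
        for h, s in zip(self.haplotypes, self.subject_of):
            if s not in pairs:
                order.append(s)
            pairs.setdefault(s, []).append(h)
        calls = [
            [tuple(sorted((h1[j], h2[j]))) for j in range(len(self.marker_ids))]
            for h1, h2 in (pairs[s] for s in order)
        ]
        return GenotypeMatrix(
            subjects=order,
            marker_ids=list(self.marker_ids),
            calls=calls,
            phenotype=dict(phenotype) if phenotype is not None else None,
        )


@dataclass(frozen=True)
class RegionSummary:
    n_markers: int
    length_bp: int
    density_per_kb: float
    maf: Mapping[str, float]


def minor_allele_frequency(marker: Marker, calls: GenotypeMatrix) -> float:
    """Frequency of the rarest observed allele among non-missing calls.

    Returns 0.0 for a monomorphic column; raises :class:`NoDataError` if
    every call is missing.
    """
    j = calls.marker_index(marker.id)
    counts: Counter[str] = Counter()
    for call in calls.column(j):
        if call is not None:
            counts.update(call)
    total = sum(counts.values())
    if total == 0:
        raise NoDataError(f"all calls missing at {marker.id}")
    if len(counts) < 2:
        return 0.0
    return min(counts.values()) / total


def haplotype_maf(marker_index: int, haps: HaplotypeSet) -> float:
    """Minor allele frequency of a marker from phased chromosomes."""
    counts = Counter(haps.column(marker_index))
    total = sum(counts.values())
    if total == 0:
        raise NoDataError("empty haplotype set")
    if len(counts) < 2:
        return 0.0
    return min(counts.values()) / total


def region_summary(
    markers: Sequence[Marker], calls: Optional[GenotypeMatrix], length_bp: int
) -> RegionSummary:
    """Marker density per kb and the per-marker MAF map for a region."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    maf: dict[str, float] = {}
    if calls is not None:
        for mk in markers:
            maf[mk.id] = minor_allele_frequency(mk, calls)
    return RegionSummary(
        n_markers=len(markers),
        length_bp=length_bp,
        density_per_kb=len(markers) / (length_bp / 1000.0),
        maf=maf,
    )


def tss_to_contig(position: int, offset: int) -> int:
    """Map a TSS-relative signed position to a 1-based contig coordinate.

    ``offset`` is the contig coordinate of TSS-relative +1; position -1 maps
    to ``offset - 1`` (there is no position 0).
    """
    if position == 0:
        raise ValueError("TSS-relative position 0 does not exist")
    return offset + position - 1 if position > 0 else offset + position


def contig_to_tss(pos: int, offset: int) -> int:
    """Inverse of :func:`tss_to_contig`."""
    rel = pos - offset
    return rel + 1 if rel >= 0 else rel


def sort_markers(markers: Iterable[Marker]) -> list[Marker]:
    """Order markers by TSS-relative position (upstream first)."""
    return sorted(markers, key=lambda m: m.position)
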