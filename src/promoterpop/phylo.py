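"""Haplotype relatedness: Kimura 2-parameter distances (optionally
gamma-corrected), recoding of allele vectors into aligned pseudo-sequences,
and Saitou-Nei neighbor joining with Newick output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import HaplotypeSet, Marker, VarClass

__all__ = [
    "SaturationError",
    "DistanceMatrix",
    "Tree",
    "k2p_distance",
    "p_distance",
    "haplotypes_to_sequences",
    "distance_matrix",
    "nj_tree",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_REPEAT_CLASSES = frozenset({VarClass.VNTR, VarClass.SSLP, VarClass.POLY_A})


class SaturationError(ValueError):
    """The K2P logarithms are undefined for these divergence fractions."""


def _site_counts(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(compared sites, transitions, transversions), gaps excluded pairwise."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    compared = ts = tv = 0
    for x, y in zip(seq_a, seq_b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        compared += 1
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return compared, ts, tv


def k2p_distance(
    seq_a: str, seq_b: str, gamma_alpha: Optional[float] = None
) -> float:
    """Kimura 2-parameter distance between aligned sequences.

    With transition fraction P and transversion fraction Q:
    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q); in gamma mode with shape a,
    d = (a/2) [(1-2P-Q)^(-1/a) - 1] + (a/4) [(1-2Q)^(-1/a) - 1].
    """
    compared, ts, tv = _site_counts(seq_a, seq_b)
    if compared == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / compared, tv / compared
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated pair: P={P:.4f}, Q={Q:.4f}")
    if gamma_alpha is None:
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    a = gamma_alpha
    if a <= 0:
        raise ValueError("gamma shape must be positive")
    return (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + \
           (a / 4.0) * (w2 ** (-1.0 / a) - 1.0)


def p_distance(seq_a: str, seq_b: str) -> float:
    compared, ts, tv = _site_counts(seq_a, seq_b)
    if compared == 0:
        raise ValueError("no comparable sites")
    return (ts + tv) / compared


def haplotypes_to_sequences(
    haps: HaplotypeSet, markers: Sequence[Marker]
) -> tuple[list[str], dict]:
    """Recode haplotype allele vectors as aligned pseudo-sequences.

    Sequence-class markers contribute one site each with alleles mapped to
    distinct bases (sorted labels -> A, C, G, T).  Repeat-class markers are
    encoded ordinally as a thermometer: a locus spanning counts [lo, hi)
    contributes hi - lo sites, site k reading G if count > lo + k else A, so
    Hamming distance between two chromosomes equals their count difference.

    Returns (sequences, mapping) where ``mapping`` records the per-marker
    encoding for reproducibility.
    """
    if len(markers) != len(haps.marker_ids):
        raise ValueError("marker list must match haplotype columns")
    site_maps: list[tuple[int, dict]] = []
    mapping: dict = {}
    for j, mk in enumerate(markers):
        if mk.var_class in _REPEAT_CLASSES:
            counts = sorted(int(a) for a in mk.alleles)
            lo, hi = counts[0], counts[-1]
            mapping[mk.id] = {"encoding": "thermometer", "lo": lo, "hi": hi}
            site_maps.append((j, {"lo": lo, "hi": hi}))
        else:
            labels = sorted(mk.alleles)
            if len(labels) > 4:
                raise ValueError(
                    f"{mk.id}: >4 alleles cannot map to nucleotide codes"
                )
            # first two alleles map to a transition pair (A/G) so that the
            # common biallelic case does not saturate the K2P transversion term
            code = {lab: "AGCT"[i] for i, lab in enumerate(labels)}
            mapping[mk.id] = {"encoding": "categorical", "code": code}
            site_maps.append((j, {"code": code}))
    sequences = []
    for h in haps.haplotypes:
        chunks = []
        for j, sm in site_maps:
            if "code" in sm:
                chunks.append(sm["code"][h[j]])
            else:
                v = int(h[j])
                chunks.append(
                    "".join(
                        "G" if v > sm["lo"] + k else "A"
                        for k in range(sm["hi"] - sm["lo"])
                    )
                )
        sequences.append("".join(chunks))
    return sequences, mapping


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")


def distance_matrix(
    sequences: Sequence[str],
    labels: Optional[Sequence[str]] = None,
    gamma_alpha: Optional[float] = None,
    on_saturation: str = "pdist",
) -> DistanceMatrix:
    """All-pairs K2P distances over aligned pseudo-sequences.

    Saturated pairs (K2P logarithm undefined) either raise
    (``on_saturation="raise"``) or fall back to the raw p-distance for that
    pair (default; the affected pairs are logged).
    """
    n = len(sequences)
    labels = list(labels) if labels is not None else [f"h{i}" for i in range(n)]
    d = np.zeros((n, n))
    n_saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = k2p_distance(
                    sequences[i], sequences[j], gamma_alpha=gamma_alpha
                )
            except SaturationError:
                if on_saturation == "raise":
                    raise
                dij = p_distance(sequences[i], sequences[j])
                n_saturated += 1
            d[i, j] = d[j, i] = dij
    if n_saturated:
        logging.getLogger(__name__).info(
            "distance_matrix: %d saturated pair(s) fell back to p-distance",
            n_saturated,
        )
    return DistanceMatrix(labels=labels, d=d)


@dataclass
class _Node:
    label: Optional[str] = None
    children: list[tuple["_Node", float]] = field(default_factory=list)


@dataclass
class Tree:
    """Unrooted tree from neighbor joining (stored with a trifurcating root).

    Negative NJ branch-length estimates are clamped to zero; the unclamped
    values are kept in ``clamped_edges``.
    """

    root: _Node
    labels: list[str]
    clamped_edges: list[tuple[str, float]] = field(default_factory=list)

    def newick(self) -> str:
        def fmt(node: _Node, bl: Optional[float]) -> str:
            if node.children:
                inner = ",".join(fmt(c, b) for c, b in node.children)
                body = f"({inner})"
            else:
                body = node.label or ""
            return body if bl is None else f"{body}:{bl:.10g}"

        return fmt(self.root, None) + ";"

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (additivity check)."""
        idx = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        d = np.zeros((n, n))

        def leaves_below(node: _Node, dist: float) -> list[tuple[str, float]]:
            if not node.children:
                return [(node.label, dist)]
            out = []
            for c, bl in node.children:
                out.extend(leaves_below(c, dist + bl))
            return out

        def recurse(node: _Node) -> list[tuple[str, float]]:
            if not node.children:
                return [(node.label, 0.0)]
            groups = [leaves_below(c, bl) for c, bl in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi]:
                        for lb, db in groups[gj]:
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
            for c, _ in node.children:
                recurse(c)
            return [x for g in groups for x in g]

        recurse(self.root)
        return DistanceMatrix(labels=list(self.labels), d=d)

    @property
    def n_edges(self) -> int:
        def count(node: _Node) -> int:
            return sum(1 + count(c) for c, _ in node.children)

        return count(self.root)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Ties in Q are broken toward the lowest index pair, making the output
    deterministic.  For n leaves the tree has 2n - 3 edges.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.copy()
    nodes: list[_Node] = [_Node(label=lab) for lab in dm.labels]
    active = list(range(n))
    clamped: list[tuple[str, float]] = []

    def clamp(node: _Node, bl: float) -> float:
        if bl < 0:
            name = node.label or "internal"
            clamped.append((name, bl))
            return 0.0
        return bl

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index deterministic tie-break via lexicographic argmin
        fi, fj = divmod(int(np.argmin(q)), m)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        bl_i = 0.5 * dij + (r[fi] - r[fj]) / (2.0 * (m - 2))
        bl_j = dij - bl_i
        parent = _Node(children=[
            (nodes[i], clamp(nodes[i], bl_i)),
            (nodes[j], clamp(nodes[j], bl_j)),
        ])
        new = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    bl_i = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    bl_j = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    bl_k = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = _Node(children=[
        (nodes[i], clamp(nodes[i], bl_i)),
        (nodes[j], clamp(nodes[j], bl_j)),
        (nodes[k], clamp(nodes[k], bl_k)),
    ])
    return Tree(root=root, labels=list(dm.labels), clamped_edges=clamped)
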