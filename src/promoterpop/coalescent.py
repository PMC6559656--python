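"""Hudson-style coalescent with recombination (ancestral recombination graph).

Time is measured in units of 2N generations: a pair of lineages coalesces at
rate 1, a lineage spanning genetic length ``g`` (in rho = 4Nr units)
recombines at rate ``g / 2`` and mutations fall at ``theta / 2`` per site per
lineage.  Segments that reach their marginal MRCA are dropped so the process
terminates even under high recombination.

The event log is sufficient to rebuild the marginal genealogy at any
position, which is how mutations on specific loci (repeat loci, two-locus
lookup draws) are placed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RecombMap",
    "TreeNode",
    "ArgResult",
    "simulate_arg",
    "marginal_tree",
    "sample_mutation_on_tree",
]


@dataclass(frozen=True)
class RecombMap:
    """Piecewise-constant recombination map over ``[0, region_length_bp)``.

    ``hotspots`` are ``(center_bp, width_bp, intensity_factor)`` triples; the
    per-bp rate inside a hotspot is ``factor`` times the background rate.
    """

    region_length_bp: float
    background_rho_per_kb: float
    hotspots: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.region_length_bp <= 0:
            raise ValueError("region length must be positive")
        if self.background_rho_per_kb < 0:
            raise ValueError("background rho must be >= 0")
        object.__setattr__(self, "hotspots", tuple(
            (float(c), float(w), float(f)) for c, w, f in self.hotspots
        ))
        last_end = 0.0
        for c, w, f in sorted(self.hotspots):
            if f < 1:
                raise ValueError("hotspot intensity factor must be >= 1")
            lo, hi = c - w / 2, c + w / 2
            if lo < 0 or hi > self.region_length_bp:
                raise ValueError("hotspot outside region")
            if lo < last_end:
                raise ValueError("hotspots must not overlap")
            last_end = hi
        # breakpoints of the piecewise rate and cumulative genetic positions
        bounds = [0.0]
        rates = []
        bg = self.background_rho_per_kb / 1000.0
        for c, w, f in sorted(self.hotspots):
            lo, hi = c - w / 2, c + w / 2
            if lo > bounds[-1]:
                rates.append(bg)
                bounds.append(lo)
            rates.append(bg * f)
            bounds.append(hi)
        if bounds[-1] < self.region_length_bp:
            rates.append(bg)
            bounds.append(self.region_length_bp)
        cum = [0.0]
        for i, r in enumerate(rates):
            cum.append(cum[-1] + r * (bounds[i + 1] - bounds[i]))
        object.__setattr__(self, "_bounds", bounds)
        object.__setattr__(self, "_rates", rates)
        object.__setattr__(self, "_cum", cum)

    @property
    def total_rho(self) -> float:
        return self._cum[-1]

    def cumulative(self, x: float) -> float:
        """Genetic position (rho units) at physical position ``x``."""
        x = min(max(x, 0.0), self.region_length_bp)
        i = bisect.bisect_right(self._bounds, x) - 1
        i = min(i, len(self._rates) - 1)
        return self._cum[i] + self._rates[i] * (x - self._bounds[i])

    def invert(self, g: float) -> float:
        """Physical position whose cumulative genetic position is ``g``."""
        g = min(max(g, 0.0), self.total_rho)
        i = bisect.bisect_right(self._cum, g) - 1
        i = min(i, len(self._rates) - 1)
        if self._rates[i] == 0.0:
            return self._bounds[i]
        return self._bounds[i] + (g - self._cum[i]) / self._rates[i]


# --- ARG simulation -------------------------------------------------------

# a segment is (left, right, samples) with samples a frozenset of leaf ids


class _Lineage:
    __slots__ = ("id", "segments", "rec_rate", "mut_rate")

    def __init__(self, lid: int, segments: list):
        self.id = lid
        self.segments = segments
        self.rec_rate = 0.0
        self.mut_rate = 0.0


@dataclass
class ArgResult:
    """Raw output of :func:`simulate_arg`."""

    n: int
    recomb_map: RecombMap
    events: list  # ("coal", t, parent, c1, c2) | ("rec", t, child, lid, rid, bp)
    breakpoints: list[float]
    mutations: list[tuple[float, frozenset]]  # (position, carrier leaf set)


def _merge_segments(segs_a: list, segs_b: list, n: int):
    """Union two segment lists; returns (merged, any_mrca_dropped).

    Overlapping stretches union their sample sets; stretches whose union is
    the full sample set have reached their marginal MRCA and are dropped.
    """
    bounds = sorted({b for s in segs_a + segs_b for b in (s[0], s[1])})
    merged: list = []
    for lo, hi in zip(bounds, bounds[1:]):
        mid = (lo + hi) / 2
        samples: Optional[frozenset] = None
        for segs in (segs_a, segs_b):
            for l, r, ss in segs:
                if l <= mid < r:
                    samples = ss if samples is None else samples | ss
                    break
        if samples is None or len(samples) == n:
            continue
        if merged and merged[-1][1] == lo and merged[-1][2] == samples:
            merged[-1] = (merged[-1][0], hi, samples)
        else:
            merged.append((lo, hi, samples))
    return merged


def simulate_arg(
    n: int,
    recomb_map: RecombMap,
    theta_per_bp: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> ArgResult:
    """Simulate the ancestral recombination graph for ``n`` chromosomes.

    Mutations (rate ``theta_per_bp`` = 4Nu per bp) are dropped on the fly on
    ancestral material under the infinite-sites model; each is recorded as a
    continuous position plus its carrier leaf set.
    """
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    rng = rng if rng is not None else np.random.default_rng()
    L = recomb_map.region_length_bp
    G = recomb_map.cumulative

    lineages: list[_Lineage] = []
    next_id = 0
    full = frozenset(range(n))

    def refresh(lin: _Lineage) -> None:
        segs = lin.segments
        span_g = G(segs[-1][1]) - G(segs[0][0])
        lin.rec_rate = span_g / 2.0
        lin.mut_rate = theta_per_bp / 2.0 * sum(r - l for l, r, _ in segs)

    for i in range(n):
        lin = _Lineage(next_id, [(0.0, L, frozenset([i]))])
        next_id += 1
        refresh(lin)
        lineages.append(lin)

    events: list = []
    breakpoints: list[float] = []
    mutations: list[tuple[float, frozenset]] = []
    t = 0.0

    while lineages:
        k = len(lineages)
        coal_rate = k * (k - 1) / 2.0
        rec_total = sum(lin.rec_rate for lin in lineages)
        mut_total = sum(lin.mut_rate for lin in lineages)
        total = coal_rate + rec_total + mut_total
        if total <= 0:  # lone lineage that can neither coalesce nor recombine
            break
        t += rng.exponential(1.0 / total)
        u = rng.uniform(0.0, total)
        if u < mut_total:
            # mutation: pick lineage by rate, position uniform on its material
            for lin in lineages:
                if u < lin.mut_rate:
                    break
                u -= lin.mut_rate
            lengths = [r - l for l, r, _ in lin.segments]
            v = rng.uniform(0.0, sum(lengths))
            for (l, r, ss), w in zip(lin.segments, lengths):
                if v < w:
                    mutations.append((l + v, ss))
                    break
                v -= w
        elif u < mut_total + rec_total:
            u -= mut_total
            for idx, lin in enumerate(lineages):
                if u < lin.rec_rate:
                    break
                u -= lin.rec_rate
            lo_g = G(lin.segments[0][0])
            hi_g = G(lin.segments[-1][1])
            bp = recomb_map.invert(rng.uniform(lo_g, hi_g))
            left_segs, right_segs = [], []
            for l, r, ss in lin.segments:
                if r <= bp:
                    left_segs.append((l, r, ss))
                elif l >= bp:
                    right_segs.append((l, r, ss))
                else:
                    left_segs.append((l, bp, ss))
                    right_segs.append((bp, r, ss))
            if not left_segs or not right_segs:
                continue  # breakpoint at a material edge: no-op
            left = _Lineage(next_id, left_segs)
            next_id += 1
            right = _Lineage(next_id, right_segs)
            next_id += 1
            refresh(left)
            refresh(right)
            events.append(("rec", t, lin.id, left.id, right.id, bp))
            breakpoints.append(bp)
            lineages[idx] = left
            lineages.append(right)
        else:
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            merged = _merge_segments(a.segments, b.segments, n)
            parent = _Lineage(next_id, merged)
            next_id += 1
            events.append(("coal", t, parent.id, a.id, b.id))
            lineages = [lin for lin in lineages if lin.id not in (a.id, b.id)]
            if merged:
                refresh(parent)
                lineages.append(parent)

    return ArgResult(
        n=n,
        recomb_map=recomb_map,
        events=events,
        breakpoints=sorted(breakpoints),
        mutations=mutations,
    )


# --- marginal trees -------------------------------------------------------


class TreeNode:
    """Node of a marginal genealogy (leaf ids 0..n-1 at time 0)."""

    __slots__ = ("time", "children", "leaf", "n_leaves")

    def __init__(self, time: float, children: Optional[list] = None,
                 leaf: Optional[int] = None):
        self.time = time
        self.children = children or []
        self.leaf = leaf
        self.n_leaves = 1 if leaf is not None else sum(
            c.n_leaves for c in self.children
        )

    def leaves(self) -> frozenset:
        if self.leaf is not None:
            return frozenset([self.leaf])
        out: set = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if node.leaf is not None:
                out.add(node.leaf)
            else:
                stack.extend(node.children)
        return frozenset(out)

    def total_branch_length(self) -> float:
        tot = 0.0
        stack = [self]
        while stack:
            node = stack.pop()
            for c in node.children:
                tot += node.time - c.time
                stack.append(c)
        return tot

    def edges(self) -> list[tuple["TreeNode", float]]:
        """All (child, branch_length) pairs below this node."""
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            for c in node.children:
                out.append((c, node.time - c.time))
                stack.append(c)
        return out

    def newick(self, labels: Optional[Sequence[str]] = None) -> str:
        def fmt(node: TreeNode, parent_time: float) -> str:
            bl = parent_time - node.time
            if node.leaf is not None:
                name = labels[node.leaf] if labels else f"h{node.leaf}"
                return f"{name}:{bl:.6g}"
            inner = ",".join(fmt(c, node.time) for c in node.children)
            return f"({inner}):{bl:.6g}"

        inner = ",".join(fmt(c, self.time) for c in self.children)
        return f"({inner});"


def marginal_tree(arg: ArgResult, x: float) -> TreeNode:
    """Rebuild the genealogy of position ``x`` from the ARG event log."""
    nodes: dict[int, TreeNode] = {
        i: TreeNode(0.0, leaf=i) for i in range(arg.n)
    }
    for ev in arg.events:
        if ev[0] == "rec":
            _, t, child, lid, rid, bp = ev
            node = nodes.pop(child, None)
            if node is not None:
                nodes[lid if x < bp else rid] = node
        else:
            _, t, parent, c1, c2 = ev
            a = nodes.pop(c1, None)
            b = nodes.pop(c2, None)
            if a is not None and b is not None:
                merged = TreeNode(t, children=[a, b])
                if merged.n_leaves == arg.n:
                    return merged
                nodes[parent] = merged
            elif a is not None:
                nodes[parent] = a
            elif b is not None:
                nodes[parent] = b
    if len(nodes) == 1:
        return next(iter(nodes.values()))
    raise RuntimeError("ARG event log did not fully coalesce at position "
                       f"{x}: {len(nodes)} roots")


def sample_mutation_on_tree(
    root: TreeNode, rng: np.random.Generator
) -> frozenset:
    """Drop one mutation uniformly on total branch length; returns carriers."""
    edges = root.edges()
    lengths = np.array([bl for _, bl in edges])
    total = lengths.sum()
    if total <= 0:
        raise ValueError("tree has zero branch length")
    idx = int(rng.choice(len(edges), p=lengths / total))
    return edges[idx][0].leaves()
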