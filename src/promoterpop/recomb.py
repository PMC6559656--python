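"""Recombination-rate profiling and hotspot calling.

Deterministic lower bound: Hudson-Kaplan interval removal over
four-gamete-violating marker pairs.  Rate estimation: pairwise composite
likelihood against a Monte-Carlo two-locus lookup table (folded two-locus
haplotype configurations simulated at a grid of rho values), maximized per
sliding window, with hotspots called as window runs exceeding a factor of
the regional background.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coalescent import RecombMap, marginal_tree, sample_mutation_on_tree, simulate_arg
from .core import HaplotypeSet, Marker

__all__ = [
    "TwoLocusLookup",
    "RhoProfile",
    "Hotspot",
    "rmin_hudson_kaplan",
    "fold_config",
    "build_lookup",
    "composite_rho",
    "call_hotspots",
]

logger = logging.getLogger(__name__)

DEFAULT_RHO_GRID = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)


# --- four-gamete / Rmin ---------------------------------------------------


def _four_gametes(col_a: Sequence[str], col_b: Sequence[str]) -> bool:
    pairs = {
        (x, y) for x, y in zip(col_a, col_b)
        if x not in (None, ".") and y not in (None, ".")
    }
    return len(pairs) == 4


def rmin_hudson_kaplan(
    haps: HaplotypeSet, markers: Optional[Sequence[Marker]] = None
) -> tuple[int, list[tuple[str, str]]]:
    """Hudson-Kaplan minimum number of recombination events.

    Considers every biallelic marker pair failing the four-gamete test and
    greedily places breakpoints in the minimal set of disjoint intervals.
    Returns (rmin, list of flanking marker-id pairs, one per breakpoint).
    """
    m = len(haps.marker_ids)
    cols = [haps.column(j) for j in range(m)]
    biallelic = [len(set(c)) == 2 for c in cols]
    intervals = []  # (i, j) marker indices, breakpoint within (i, j)
    for i, j in itertools.combinations(range(m), 2):
        if biallelic[i] and biallelic[j] and _four_gametes(cols[i], cols[j]):
            intervals.append((i, j))
    # greedy disjoint-interval cover on the gaps between adjacent markers
    intervals.sort(key=lambda iv: iv[1])
    rmin = 0
    chosen: list[tuple[str, str]] = []
    last_gap = -1
    for i, j in intervals:
        if i > last_gap:
            last_gap = j - 1  # breakpoint in the gap just left of marker j
            rmin += 1
            chosen.append((haps.marker_ids[j - 1], haps.marker_ids[j]))
    return rmin, chosen


# --- two-locus lookup -----------------------------------------------------


def fold_config(n00: int, n01: int, n10: int, n11: int) -> tuple[int, ...]:
    """Canonical (allele-label- and locus-order-free) two-locus config."""
    mats = []
    base = ((n00, n01), (n10, n11))
    for rows in (base, base[::-1]):
        for m0 in (rows, tuple(r[::-1] for r in rows)):
            for m1 in (m0, tuple(zip(*m0))):
                mats.append(tuple(x for r in m1 for x in r))
    return min(mats)


@dataclass
class TwoLocusLookup:
    """Monte-Carlo table of folded two-locus configuration log-probabilities
    at each grid rho, for a fixed sample size."""

    n: int
    rho_grid: tuple[float, ...]
    counts: dict[tuple[int, ...], list[int]]
    reps_per_point: int
    seed: int

    def __post_init__(self) -> None:
        self.rho_grid = tuple(float(r) for r in self.rho_grid)
        self._n_configs = len(self.counts)
        self._logprobs = {
            cfg: [
                math.log((c + 1.0) / (self.reps_per_point + self._n_configs))
                for c in row
            ]
            for cfg, row in self.counts.items()
        }
        self._default = [
            math.log(1.0 / (self.reps_per_point + self._n_configs))
        ] * len(self.rho_grid)

    def log_prob(self, config: tuple[int, ...], rho: float) -> float:
        """Add-one-smoothed log P(folded config | rho), linearly interpolated
        in rho between grid points (clamped at the ends)."""
        row = self._logprobs.get(fold_config(*config), self._default)
        grid = self.rho_grid
        if rho <= grid[0]:
            return row[0]
        if rho >= grid[-1]:
            return row[-1]
        k = int(np.searchsorted(grid, rho)) - 1
        w = (rho - grid[k]) / (grid[k + 1] - grid[k])
        return row[k] * (1 - w) + row[k + 1] * w

    def to_json(self, path) -> None:
        doc = {
            "n": self.n,
            "rho_grid": list(self.rho_grid),
            "reps_per_point": self.reps_per_point,
            "seed": self.seed,
            "counts": {
                ",".join(map(str, cfg)): row for cfg, row in self.counts.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "TwoLocusLookup":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            n=doc["n"],
            rho_grid=tuple(doc["rho_grid"]),
            counts={
                tuple(int(x) for x in key.split(",")): row
                for key, row in doc["counts"].items()
            },
            reps_per_point=doc["reps_per_point"],
            seed=doc["seed"],
        )


def _two_locus_trees(n: int, rho: float, rng: np.random.Generator):
    """Coalescent for exactly two loci separated by ``rho``.

    Each lineage tracks its descendant sample set and genealogy node at each
    locus; only lineages ancestral at both loci recombine (rate rho/2).
    Returns the two marginal genealogy roots.
    """
    from .coalescent import TreeNode as _TN

    full = frozenset(range(n))
    # lineage: [setA, setB, nodeA, nodeB]
    lineages = [
        [frozenset([i]), frozenset([i]), _TN(0.0, leaf=i), _TN(0.0, leaf=i)]
        for i in range(n)
    ]
    roots: list = [None, None]
    t = 0.0
    while lineages:
        k = len(lineages)
        both = [lin for lin in lineages if lin[0] and lin[1]]
        coal_rate = k * (k - 1) / 2.0
        rec_rate = len(both) * rho / 2.0
        total = coal_rate + rec_rate
        t += rng.exponential(1.0 / total)
        if rng.uniform(0.0, total) < rec_rate:
            lin = both[int(rng.integers(len(both)))]
            lineages.remove(lin)
            lineages.append([lin[0], frozenset(), lin[2], None])
            lineages.append([frozenset(), lin[1], None, lin[3]])
            continue
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        lineages = [lin for lin in lineages if lin is not a and lin is not b]
        parent = [frozenset(), frozenset(), None, None]
        for loc in (0, 1):
            sa, sb = a[loc], b[loc]
            na, nb = a[loc + 2], b[loc + 2]
            if sa and sb:
                node = _TN(t, children=[na, nb])
                union = sa | sb
                if union == full:
                    roots[loc] = node
                else:
                    parent[loc] = union
                    parent[loc + 2] = node
            elif sa:
                parent[loc], parent[loc + 2] = sa, na
            elif sb:
                parent[loc], parent[loc + 2] = sb, nb
        if parent[0] or parent[1]:
            lineages.append(parent)
    return roots[0], roots[1]


def build_lookup(
    n: int,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    reps: int = 20_000,
    seed: int = 0,
) -> TwoLocusLookup:
    """Simulate the two-locus lookup table.

    For each grid rho, two-locus ancestral histories are drawn and one
    segregating mutation is placed on each locus's marginal genealogy
    (branch-length-proportional, the small-theta limit of conditioning on
    biallelic loci); folded configurations are tabulated.
    """
    if n > 120:
        raise ValueError("lookup limited to n <= 120")
    if 0.0 not in [float(r) for r in rho_grid]:
        raise ValueError("rho grid must include 0")
    rho_grid = tuple(sorted(float(r) for r in rho_grid))
    rng = np.random.default_rng(seed)
    counts: dict[tuple[int, ...], list[int]] = {}
    for gi, rho in enumerate(rho_grid):
        for _ in range(reps):
            tree_a, tree_b = _two_locus_trees(n, rho, rng)
            A = sample_mutation_on_tree(tree_a, rng)
            B = sample_mutation_on_tree(tree_b, rng)
            n11 = len(A & B)
            n10 = len(A - B)
            n01 = len(B - A)
            n00 = n - n11 - n10 - n01
            cfg = fold_config(n00, n01, n10, n11)
            if cfg not in counts:
                counts[cfg] = [0] * len(rho_grid)
            counts[cfg][gi] += 1
    return TwoLocusLookup(
        n=n, rho_grid=rho_grid, counts=counts, reps_per_point=reps, seed=seed
    )


# --- composite-likelihood profile ----------------------------------------


@dataclass(frozen=True)
class Hotspot:
    start_bp: float
    end_bp: float
    peak_rho_per_kb: float
    factor: float


@dataclass
class RhoProfile:
    windows: list[tuple[float, float, float, int]]  # start, end, rho/kb, pairs
    background: float
    hotspots: list[Hotspot] = field(default_factory=list)


def _linear_position(position: int) -> float:
    # collapse the no-zero TSS convention onto a continuous axis
    return float(position - 1 if position > 0 else position)


def composite_rho(
    haps: HaplotypeSet,
    markers: Sequence[Marker],
    lookup: TwoLocusLookup,
    window_bp: float = 2000.0,
    step_bp: float = 500.0,
    max_pair_span_bp: float = 5000.0,
    candidate_rho_per_kb: Optional[Sequence[float]] = None,
    min_minor_copies: Optional[int] = None,
    min_pairs: int = 3,
) -> RhoProfile:
    """Sliding-window composite-likelihood rho profile (per kb).

    Every fully-called biallelic marker pair (span capped at
    ``max_pair_span_bp``, both minor alleles carried by at least
    ``min_minor_copies`` chromosomes) is assigned to the window containing
    its midpoint; its folded two-locus configuration is scored against the
    lookup at ``rho_candidate * distance_kb`` and the candidate maximizing
    the summed log-likelihood is reported per window.  Windows with fewer
    than ``min_pairs`` usable pairs are left undefined (NaN).

    ``min_minor_copies`` defaults to ~8% of the chromosomes (at least 2):
    rare-variant configurations carry little recombination signal but large
    Monte-Carlo noise from the lookup.
    """
    if lookup.n != haps.n_chromosomes:
        raise ValueError(
            f"lookup built for n={lookup.n}, data has {haps.n_chromosomes}"
        )
    if len(markers) != len(haps.marker_ids):
        raise ValueError("marker list must match haplotype columns")
    if min_minor_copies is None:
        min_minor_copies = max(2, round(0.08 * haps.n_chromosomes))
    if candidate_rho_per_kb is None:
        top = max(lookup.rho_grid) / 2.0
        candidate_rho_per_kb = np.concatenate(
            [[0.0], np.geomspace(0.05, top, 50)]
        )
    cand = np.asarray(candidate_rho_per_kb, dtype=float)

    pos = [_linear_position(mk.position) for mk in markers]
    cols = [haps.column(j) for j in range(len(markers))]
    usable = []
    for j, c in enumerate(cols):
        called = [x for x in c if x not in (None, ".")]
        counts = Counter(called)
        if (
            len(counts) == 2
            and len(called) == haps.n_chromosomes
            and min(counts.values()) >= min_minor_copies
        ):
            usable.append(j)

    # (midpoint, distance_kb, folded config) for every scored pair
    pair_data: list[tuple[float, float, tuple[int, ...]]] = []
    for i, j in itertools.combinations(usable, 2):
        d = abs(pos[j] - pos[i])
        if d == 0 or d > max_pair_span_bp:
            continue
        counts = Counter(zip(cols[i], cols[j]))
        a_alleles = sorted({x for x, _ in counts})
        b_alleles = sorted({y for _, y in counts})
        cfg = fold_config(
            counts.get((a_alleles[0], b_alleles[0]), 0),
            counts.get((a_alleles[0], b_alleles[1]), 0),
            counts.get((a_alleles[1], b_alleles[0]), 0),
            counts.get((a_alleles[1], b_alleles[1]), 0),
        )
        pair_data.append(((pos[i] + pos[j]) / 2.0, d / 1000.0, cfg))

    lo = min(pos)
    hi = max(pos)
    windows: list[tuple[float, float, float, int]] = []
    start = lo
    while start < hi:
        end = start + window_bp
        pairs = [p for p in pair_data if start <= p[0] < end]
        if len(pairs) < min_pairs:
            windows.append((start, end, float("nan"), len(pairs)))
            start += step_bp
            continue
        scores = np.zeros(len(cand))
        for _, d_kb, cfg in pairs:
            for k, rc in enumerate(cand):
                scores[k] += lookup.log_prob(cfg, rc * d_kb)
        best = int(np.argmax(scores))
        windows.append((start, end, float(cand[best]), len(pairs)))
        start += step_bp

    defined = [w[2] for w in windows if not math.isnan(w[2])]
    if not defined:
        raise ValueError("no window had enough marker pairs for estimation")
    background = float(np.median(defined))
    profile = RhoProfile(windows=windows, background=background)
    # robust defaults for the auto-called hotspots: a real hotspot wider
    # than the step spans >= 2 windows
    profile.hotspots = call_hotspots(profile, min_run=2)
    return profile


def call_hotspots(
    profile: RhoProfile,
    factor_threshold: float = 5.0,
    absolute_min_per_kb: float = 4.0,
    min_pairs: int = 10,
    min_run: int = 1,
) -> list[Hotspot]:
    """Maximal runs of windows with rho >= factor * background (runs merged
    across a single-window gap).

    The threshold is ``max(factor * background, absolute_min_per_kb)`` so a
    zero or deflated background estimate does not promote noise windows
    (logged when the absolute floor governs).  Windows supported by fewer
    than ``min_pairs`` marker pairs are never eligible, and runs shorter
    than ``min_run`` windows are discarded (a real hotspot wider than the
    window step spans several windows)."""
    background = profile.background
    threshold = max(factor_threshold * background, absolute_min_per_kb)
    if threshold == absolute_min_per_kb:
        logger.info(
            "call_hotspots: absolute floor %.3g per kb governs "
            "(background %.3g)", absolute_min_per_kb, background,
        )
    hot_idx = [
        k for k, (_, _, rho, n_pairs) in enumerate(profile.windows)
        if not math.isnan(rho) and rho >= threshold and n_pairs >= min_pairs
    ]
    if not hot_idx:
        return []
    runs: list[list[int]] = [[hot_idx[0]]]
    for k in hot_idx[1:]:
        if k - runs[-1][-1] <= 2:  # gap of at most one window
            runs[-1].append(k)
        else:
            runs.append([k])
    hotspots = []
    for run in runs:
        if len(run) < min_run:
            continue
        rhos = [profile.windows[k][2] for k in run]
        peak = max(rhos)
        hotspots.append(Hotspot(
            start_bp=profile.windows[run[0]][0],
            end_bp=profile.windows[run[-1]][1],
            peak_rho_per_kb=peak,
            factor=peak / background if background > 0 else float("inf"),
        ))
    return hotspots
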