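"""EM haplotype-frequency estimation and most-probable phase assignment.

The E-step weights each ordered haplotype pair compatible with a subject's
multilocus genotype by the product of current frequencies; the M-step
re-estimates frequencies from the expected pair counts.  Long regions are
handled by partition-ligation: blocks of at most ``block_size`` markers are
phased independently and then ligated pairwise by EM over block-haplotype
combinations, pruning to the best candidates per subject.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import GenotypeMatrix, HaplotypeSet, HaplotypeSource

__all__ = ["PhaseResult", "em_phase", "count_distinct_haplotypes"]

logger = logging.getLogger(__name__)

MAX_UNPARTITIONED_MARKERS = 30
DEFAULT_BLOCK_SIZE = 12
PRUNE_K = 24  # candidate pairs kept per subject during ligation


@dataclass
class PhaseResult:
    haplotype_freqs: dict[tuple[str, ...], float]
    phased: HaplotypeSet
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    dropped_subjects: list[str] = field(default_factory=list)
    ties: list[str] = field(default_factory=list)


def _compatible_pairs(genotype: Sequence[tuple[str, str]]):
    """All unordered haplotype pairs compatible with an unphased genotype."""
    het = [j for j, (a, b) in enumerate(genotype) if a != b]
    base = [a for a, _ in genotype]
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    # fix the first het site to enumerate unordered pairs exactly once
    for bits in itertools.product((0, 1), repeat=len(het) - 1):
        h1, h2 = list(base), list(base)
        for j, bit in zip(het, (0,) + bits):
            a, b = sorted(genotype[j])
            h1[j], h2[j] = (a, b) if bit == 0 else (b, a)
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def _em_run(
    subject_pairs: list[list[tuple[int, int]]],
    n_haps: int,
    init: np.ndarray,
    tol: float,
    max_iter: int,
):
    """Core EM over integer-indexed unordered pair lists.

    Returns (freqs, loglik_trace, n_iter, converged, posteriors) where
    posteriors[s] is the per-pair posterior for subject s.
    """
    freqs = init.copy()
    n_subj = len(subject_pairs)
    trace: list[float] = []
    converged = False
    it = 0
    posteriors: list[np.ndarray] = []
    for it in range(1, max_iter + 1):
        counts = np.zeros(n_haps)
        loglik = 0.0
        posteriors = []
        for pairs in subject_pairs:
            w = np.array([
                (1.0 if i == j else 2.0) * freqs[i] * freqs[j]
                for i, j in pairs
            ])
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(pairs), 1.0 / len(pairs))
                tot = 1e-300
            else:
                w = w / tot
            loglik += np.log(tot)
            posteriors.append(w)
            for (i, j), wij in zip(pairs, w):
                counts[i] += wij
                counts[j] += wij
        new_freqs = counts / (2.0 * n_subj)
        trace.append(float(loglik))
        delta = np.abs(new_freqs - freqs).max()
        freqs = new_freqs
        if delta < tol:
            converged = True
            break
    return freqs, trace, it, converged, posteriors


def _phase_block(
    genotypes: list[tuple],
    tol: float,
    max_iter: int,
    n_restarts: int,
    rng: np.random.Generator,
):
    """EM-phase one block; returns (hap list, freqs, per-subject candidate
    pair lists with posteriors, loglik trace, n_iter, converged)."""
    hap_index: dict[tuple, int] = {}

    def idx(h: tuple) -> int:
        if h not in hap_index:
            hap_index[h] = len(hap_index)
        return hap_index[h]

    subject_pairs = [
        [(idx(h1), idx(h2)) for h1, h2 in _compatible_pairs(g)]
        for g in genotypes
    ]
    n_haps = len(hap_index)
    starts = [np.full(n_haps, 1.0 / n_haps)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.dirichlet(np.ones(n_haps)))
    best = None
    for init in starts:
        res = _em_run(subject_pairs, n_haps, init, tol, max_iter)
        if best is None or res[1][-1] > best[1][-1]:
            best = res
    freqs, trace, n_iter, converged, posteriors = best
    haps = [None] * n_haps
    for h, i in hap_index.items():
        haps[i] = h
    return haps, freqs, subject_pairs, posteriors, trace, n_iter, converged


def _ligate(
    left: tuple[list, list[list], list[np.ndarray]],
    right: tuple[list, list[list], list[np.ndarray]],
    tol: float,
    max_iter: int,
):
    """Combine adjacent phased blocks by EM over joined candidate pairs."""
    lhaps, lpairs, lpost = left
    rhaps, rpairs, rpost = right
    hap_index: dict[tuple, int] = {}

    def idx(h: tuple) -> int:
        if h not in hap_index:
            hap_index[h] = len(hap_index)
        return hap_index[h]

    subject_pairs: list[list[tuple[int, int]]] = []
    for lp, lw, rp, rw in zip(lpairs, lpost, rpairs, rpost):
        cands: dict[tuple[int, int], float] = {}
        for (li, lj), wl in zip(lp, lw):
            if wl < 1e-9:
                continue
            for (ri, rj), wr in zip(rp, rw):
                if wr < 1e-9:
                    continue
                for la, lb, ra, rb in ((li, lj, ri, rj), (li, lj, rj, ri)):
                    h1 = lhaps[la] + rhaps[ra]
                    h2 = lhaps[lb] + rhaps[rb]
                    key = tuple(sorted((idx(h1), idx(h2))))
                    cands[key] = max(cands.get(key, 0.0), wl * wr)
        top = sorted(cands, key=lambda k: -cands[k])[:PRUNE_K]
        subject_pairs.append(list(top))
    n_haps = len(hap_index)
    init = np.full(n_haps, 1.0 / n_haps)
    freqs, trace, n_iter, converged, posteriors = _em_run(
        subject_pairs, n_haps, init, tol, max_iter
    )
    haps = [None] * n_haps
    for h, i in hap_index.items():
        haps[i] = h
    return haps, freqs, subject_pairs, posteriors, trace, n_iter, converged


def em_phase(
    calls: GenotypeMatrix,
    marker_ids: Optional[Sequence[str]] = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 3,
    seed: int = 0,
    ligate: bool = False,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> PhaseResult:
    """Estimate haplotype frequencies and the most probable phase per subject.

    Subjects with missing calls at the selected markers are dropped (and
    listed in the result).  More than 30 markers are refused unless
    ``ligate=True``, which switches to partition-ligation.
    """
    ids = list(marker_ids) if marker_ids is not None else list(calls.marker_ids)
    cols = [calls.marker_ids.index(mid) for mid in ids]
    if len(ids) > MAX_UNPARTITIONED_MARKERS and not ligate:
        raise ValueError(
            f"{len(ids)} markers exceed the state-space guard "
            f"({MAX_UNPARTITIONED_MARKERS}); pass ligate=True"
        )
    kept_subjects: list[str] = []
    dropped: list[str] = []
    genotypes: list[tuple] = []
    for i, s in enumerate(calls.subjects):
        g = [calls.calls[i][j] for j in cols]
        if any(c is None for c in g):
            dropped.append(s)
        else:
            kept_subjects.append(s)
            genotypes.append(tuple(g))
    if dropped:
        logger.info("em_phase: dropped %d subjects with missing calls: %s",
                    len(dropped), dropped)
    if not genotypes:
        raise ValueError("no subjects without missing calls")
    rng = np.random.default_rng(seed)

    if ligate and len(ids) > block_size:
        n_blocks = -(-len(ids) // block_size)
        edges = np.linspace(0, len(ids), n_blocks + 1).astype(int)
        blocks = []
        trace: list[float] = []
        total_iter = 0
        converged = True
        for lo, hi in zip(edges, edges[1:]):
            sub = [g[lo:hi] for g in genotypes]
            haps, freqs, pairs, post, tr, it, conv = _phase_block(
                sub, tol, max_iter, n_restarts, rng
            )
            blocks.append((haps, pairs, post))
            total_iter += it
            converged &= conv
        current = blocks[0]
        for nxt in blocks[1:]:
            haps, freqs, pairs, post, tr, it, conv = _ligate(
                current, nxt, tol, max_iter
            )
            current = (haps, pairs, post)
            trace = tr
            total_iter += it
            converged &= conv
        haps, pairs_lists, posteriors = current
        n_iter = total_iter
    else:
        haps, freqs, pairs_lists, posteriors, trace, n_iter, converged = (
            _phase_block(genotypes, tol, max_iter, n_restarts, rng)
        )

    freq_map = {
        h: float(f) for h, f in zip(haps, freqs) if f > 1e-12
    }
    # most-probable phase, deterministic lexicographic tie-break
    phased_vectors: list[tuple] = []
    subject_of: list[str] = []
    ties: list[str] = []
    for s, pairs, w in zip(kept_subjects, pairs_lists, posteriors):
        best_w = w.max()
        best = [p for p, wij in zip(pairs, w) if wij >= best_w - 1e-12]
        if len(best) > 1:
            ties.append(s)
            logger.info("em_phase: posterior tie for subject %s", s)
            best.sort(key=lambda p: tuple(sorted((haps[p[0]], haps[p[1]]))))
        i, j = best[0]
        h1, h2 = sorted((haps[i], haps[j]))
        phased_vectors.extend([h1, h2])
        subject_of.extend([s, s])
    phased = HaplotypeSet(
        haplotypes=phased_vectors,
        subject_of=subject_of,
        marker_ids=ids,
        source=HaplotypeSource.PHASED,
    )
    return PhaseResult(
        haplotype_freqs=freq_map,
        phased=phased,
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        dropped_subjects=dropped,
        ties=ties,
    )


def count_distinct_haplotypes(
    haps: HaplotypeSet, level: str = "chromosome"
) -> tuple[int, dict[tuple[str, ...], int]]:
    """Number of distinct haplotypes and their multiplicities.

    ``level="chromosome"`` counts occurrences over all 2N chromosomes;
    ``level="subject"`` counts, for each distinct haplotype, the number of
    subjects carrying it at least once.
    """
    if not haps.haplotypes:
        raise ValueError("empty haplotype set")
    if level == "chromosome":
        mult = Counter(haps.haplotypes)
    elif level == "subject":
        mult = Counter(
            h for s in haps.subjects
            for h in {
                hap for hap, subj in zip(haps.haplotypes, haps.subject_of)
                if subj == s
            }
        )
    else:
        raise ValueError("level must be 'chromosome' or 'subject'")
    return len(mult), dict(mult)
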