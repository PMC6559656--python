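import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promoterpop.coalescent import RecombMap
from promoterpop.core import VarClass
from promoterpop.ld import (
    UndefinedLDError,
    biallelic_ld,
    dprime_confidence_bounds,
    find_blocks,
    ld_matrix,
    multiallelic_dprime,
    region_mean_ld,
)
from promoterpop.simulate import SimConfig, simulate_haplotypes

from conftest import make_haps


def _cols(counts):
    """Build two haplotype columns from gamete counts {(a,b): n}."""
    a, b = [], []
    for (x, y), n in counts.items():
        a.extend([x] * n)
        b.extend([y] * n)
    return a, b


class TestBiallelicLD:
    def test_perfect_ld(self):
        a, b = _cols({("A", "T"): 30, ("G", "C"): 30})
        r = biallelic_ld(a, b)
        assert r.D_prime == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1.0)

    def test_one_missing_gamete(self):
        # AB=30, Ab=20, aB=0, ab=50: D' = 1 by construction; r2 from the
        # definition r2 = D^2 / (pA qA pB qB) = 0.15^2/(0.25*0.3*0.7)
        a, b = _cols({("A", "B"): 30, ("A", "b"): 20, ("a", "b"): 50})
        r = biallelic_ld(a, b)
        assert r.D_prime == pytest.approx(1.0)
        assert r.r2 == pytest.approx(0.15**2 / (0.25 * 0.3 * 0.7))

    def test_independence(self):
        a, b = _cols({("A", "B"): 15, ("A", "b"): 15,
                      ("a", "B"): 15, ("a", "b"): 15})
        r = biallelic_ld(a, b)
        assert r.D_prime == pytest.approx(0.0)
        assert r.r2 == pytest.approx(0.0)

    def test_monomorphic_undefined(self):
        with pytest.raises(UndefinedLDError):
            biallelic_ld(["A"] * 10, ["B"] * 5 + ["b"] * 5)

    def test_missing_skipped_pairwise(self):
        a, b = _cols({("A", "B"): 30, ("a", "b"): 30})
        a[0] = None
        r = biallelic_ld(a, b)
        assert r.n_chromosomes == 59

    def test_too_much_missing_undefined(self):
        a, b = _cols({("A", "B"): 5, ("a", "b"): 5})
        a = [None] * 3 + a[3:]
        with pytest.raises(UndefinedLDError):
            biallelic_ld(a, b)

    @given(
        nAB=st.integers(1, 30), nAb=st.integers(1, 30),
        naB=st.integers(1, 30), nab=st.integers(1, 30),
    )
    @settings(max_examples=100)
    def test_bounds_and_relabel_invariance(self, nAB, nAb, naB, nab):
        a, b = _cols({("A", "B"): nAB, ("A", "b"): nAb,
                      ("a", "B"): naB, ("a", "b"): nab})
        r = biallelic_ld(a, b)
        assert 0.0 <= r.D_prime <= 1.0
        assert 0.0 <= r.r2 <= 1.0
        # relabel alleles at both loci and swap loci
        a2 = ["A" if x == "a" else "a" for x in a]
        r2 = biallelic_ld(a2, b)
        assert r2.D_prime == pytest.approx(r.D_prime, abs=1e-12)
        assert r2.r2 == pytest.approx(r.r2, abs=1e-12)
        r3 = biallelic_ld(b, a)
        assert r3.D_prime == pytest.approx(r.D_prime, abs=1e-12)
        assert r3.r2 == pytest.approx(r.r2, abs=1e-12)

    def test_dprime_one_iff_missing_gamete(self):
        a, b = _cols({("A", "B"): 10, ("A", "b"): 10,
                      ("a", "B"): 10, ("a", "b"): 10})
        assert biallelic_ld(a, b).D_prime < 1.0
        a, b = _cols({("A", "B"): 10, ("A", "b"): 10, ("a", "b"): 10})
        assert biallelic_ld(a, b).D_prime == pytest.approx(1.0)


def _multiallelic_brute(a, b):
    """Exhaustive allele-pair enumeration of Hedrick's weighted |D'|."""
    n = len(a)
    alle_a, alle_b = sorted(set(a)), sorted(set(b))
    total = 0.0
    for x in alle_a:
        for y in alle_b:
            p = a.count(x) / n
            q = b.count(y) / n
            pxy = sum(1 for u, v in zip(a, b) if u == x and v == y) / n
            D = pxy - p * q
            if D >= 0:
                dmax = min(p * (1 - q), (1 - p) * q)
            else:
                dmax = min(p * q, (1 - p) * (1 - q))
            if dmax > 0:
                total += p * q * abs(D) / dmax
    return total


class TestMultiallelicDPrime:
    def test_reduces_to_biallelic(self):
        a, b = _cols({("A", "B"): 30, ("A", "b"): 20, ("a", "b"): 50})
        assert multiallelic_dprime(a, b) == pytest.approx(
            biallelic_ld(a, b).D_prime
        )

    def test_perfect_coupling_three_alleles(self):
        a = ["1"] * 20 + ["2"] * 20 + ["3"] * 20
        b = ["x"] * 20 + ["y"] * 20 + ["z"] * 20
        assert multiallelic_dprime(a, b) == pytest.approx(1.0)

    def test_worked_table_vs_brute_force(self):
        # 3-allele vs 2-allele table written out explicitly
        counts = {("1", "A"): 12, ("1", "G"): 3, ("2", "A"): 5,
                  ("2", "G"): 15, ("3", "A"): 8, ("3", "G"): 7}
        a, b = _cols(counts)
        assert multiallelic_dprime(a, b) == pytest.approx(
            _multiallelic_brute(a, b), rel=1e-12
        )

    def test_monomorphic_undefined(self):
        with pytest.raises(UndefinedLDError):
            multiallelic_dprime(["1"] * 10, ["x"] * 5 + ["y"] * 5)


class TestRegionMeans:
    def test_all_perfect(self):
        vectors = [("A", "T", "C")] * 5 + [("G", "A", "G")] * 5
        haps = make_haps(vectors)
        matrix = ld_matrix(haps)
        dp, r2, n_pairs = region_mean_ld(matrix)
        assert dp == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert n_pairs == 3

    def test_manual_average_four_markers(self):
        rng = np.random.default_rng(2)
        vectors = [
            tuple(rng.choice(["A", "G"], size=4)) for _ in range(30)
        ]
        # ensure polymorphism at all 4 columns
        vectors += [("A", "A", "A", "A"), ("G", "G", "G", "G")]
        haps = make_haps(vectors)
        matrix = ld_matrix(haps)
        dps = []
        for i, j in itertools.combinations(range(4), 2):
            r = biallelic_ld(haps.column(i), haps.column(j))
            dps.append(r.D_prime)
        dp, _, n_pairs = region_mean_ld(matrix)
        assert n_pairs == 6
        assert dp == pytest.approx(np.mean(dps))

    def test_two_pair_average(self):
        class FakeRes:
            def __init__(self, dp, r2):
                self.D_prime, self.r2 = dp, r2

        from promoterpop.ld import LDMatrix

        m = LDMatrix(markers=["a", "b", "c"], pairwise={
            ("a", "b"): FakeRes(0.8, 0.3),
            ("b", "c"): FakeRes(0.6, 0.1),
        })
        dp, r2, n = region_mean_ld(m)
        assert dp == pytest.approx(0.7)
        assert r2 == pytest.approx(0.2)


class TestConfidenceBounds:
    def test_perfect_ld_tight_upper(self):
        a, b = _cols({("A", "B"): 30, ("a", "b"): 30})
        lo, hi = dprime_confidence_bounds(a, b)
        assert hi >= 0.98  # grid discretization can stop one step below 1.0
        assert lo > 0.8

    def test_no_ld_low_bounds(self):
        a, b = _cols({("A", "B"): 15, ("A", "b"): 15,
                      ("a", "B"): 15, ("a", "b"): 15})
        lo, hi = dprime_confidence_bounds(a, b)
        assert lo < 0.3
        assert hi < 0.9


class TestBlocks:
    def test_single_block_under_perfect_ld(self):
        vectors = [("A", "T", "C", "G")] * 40 + [("G", "A", "G", "T")] * 20
        haps = make_haps(vectors)
        blocks = find_blocks(haps)
        assert len(blocks) == 1
        assert blocks[0].marker_ids == tuple(haps.marker_ids)

    def test_no_blocks_without_ld(self):
        rng = np.random.default_rng(0)
        vectors = [tuple(rng.choice(["A", "G"], size=5)) for _ in range(60)]
        haps = make_haps(vectors)
        blocks = find_blocks(haps)
        assert blocks == []

    def test_zero_recombination_simulation_one_block(self):
        # property over replicates: rho=0 gives a single dominant block
        hits = 0
        reps = 10
        for seed in range(reps):
            cfg = SimConfig(
                n_chromosomes=60, theta_per_kb=0.6,
                recomb_map=RecombMap(6_000, 0.0),
                class_mix={VarClass.SNP: 1.0}, seed=seed + 100,
            )
            out = simulate_haplotypes(cfg)
            # common markers only (MAF >= 0.1): rare markers uninformative
            common = [
                j for j in range(len(out.markers))
                if min(
                    out.haplotypes.column(j).count(a)
                    for a in set(out.haplotypes.column(j))
                ) >= 6
            ]
            if len(common) < 4:
                continue
            sub = out.haplotypes.subset_markers(common)
            blocks = find_blocks(sub)
            if blocks and len(blocks[0].marker_ids) >= 0.9 * len(common):
                hits += 1
        assert hits >= 0.9 * reps

    def test_r2_decreases_with_rho(self):
        # mean r2 of marker pairs >= 1 kb apart decreases as map rho grows
        means = []
        for rho in (0.0, 5.0, 20.0):
            vals = []
            for seed in range(25):
                cfg = SimConfig(
                    n_chromosomes=40, theta_per_kb=0.8,
                    recomb_map=RecombMap(5_000, rho),
                    class_mix={VarClass.SNP: 1.0}, seed=seed + 500,
                )
                out = simulate_haplotypes(cfg)
                cols = [out.haplotypes.column(j)
                        for j in range(len(out.markers))]
                pos = [m.position for m in out.markers]
                for i, j in itertools.combinations(range(len(cols)), 2):
                    if abs(pos[j] - pos[i]) < 1_000:
                        continue
                    try:
                        vals.append(biallelic_ld(cols[i], cols[j]).r2)
                    except UndefinedLDError:
                        continue
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
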