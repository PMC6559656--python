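import itertools
import math
from importlib import resources

import numpy as np
import pytest

from promoterpop.coalescent import RecombMap
from promoterpop.core import VarClass
from promoterpop.recomb import (
    DEFAULT_RHO_GRID,
    RhoProfile,
    TwoLocusLookup,
    build_lookup,
    call_hotspots,
    composite_rho,
    fold_config,
    rmin_hudson_kaplan,
)
from promoterpop.simulate import SimConfig, simulate_haplotypes

from conftest import make_haps


@pytest.fixture(scope="session")
def lookup_n60():
    path = resources.files("promoterpop") / "data" / "two_locus_n60.json"
    return TwoLocusLookup.from_json(str(path))


def _rmin_brute_force(haps):
    """Minimal number of gaps hitting all four-gamete-violating intervals."""
    m = len(haps.marker_ids)
    cols = [haps.column(j) for j in range(m)]
    intervals = []
    for i, j in itertools.combinations(range(m), 2):
        if len(set(cols[i])) == 2 and len(set(cols[j])) == 2:
            if len(set(zip(cols[i], cols[j]))) == 4:
                intervals.append((i, j))
    if not intervals:
        return 0
    gaps = list(range(m - 1))  # gap g sits between markers g and g+1
    for k in range(1, m):
        for chosen in itertools.combinations(gaps, k):
            if all(any(i <= g < j for g in chosen) for i, j in intervals):
                return k
    return m - 1


class TestRmin:
    def test_no_recombination_zero(self, neutral_cohort):
        rmin, intervals = rmin_hudson_kaplan(neutral_cohort.haplotypes)
        assert rmin == 0
        assert intervals == []

    def test_single_violating_pair(self):
        haps = make_haps([
            ("A", "B"), ("A", "b"), ("a", "B"), ("a", "b"),
        ])
        rmin, intervals = rmin_hudson_kaplan(haps)
        assert rmin == 1
        assert len(intervals) == 1

    def test_eight_marker_hand_built_vs_brute_force(self):
        rng = np.random.default_rng(77)
        for rep in range(25):
            vectors = [
                tuple(rng.choice(["A", "G"], size=8)) for _ in range(12)
            ]
            haps = make_haps(vectors)
            rmin, _ = rmin_hudson_kaplan(haps)
            assert rmin == _rmin_brute_force(haps)

    def test_lower_bound_on_true_breakpoints(self):
        for seed in range(20):
            cfg = SimConfig(
                n_chromosomes=30, theta_per_kb=1.0,
                recomb_map=RecombMap(5_000, 1.0),
                class_mix={VarClass.SNP: 1.0}, seed=seed,
            )
            out = simulate_haplotypes(cfg)
            rmin, _ = rmin_hudson_kaplan(out.haplotypes)
            assert rmin <= len(out.true_breakpoints)


class TestFoldConfig:
    def test_invariances(self):
        base = fold_config(20, 5, 3, 32)
        assert fold_config(5, 20, 32, 3) == base   # allele swap at B
        assert fold_config(3, 32, 20, 5) == base   # allele swap at A
        assert fold_config(20, 3, 5, 32) == base   # locus swap
        assert fold_config(32, 3, 5, 20) == base   # both swaps

    def test_canonical_is_member_of_orbit(self):
        cfg = fold_config(1, 2, 3, 4)
        assert sorted(cfg) == [1, 2, 3, 4]


@pytest.fixture(scope="module")
def small_lookup():
    return build_lookup(10, rho_grid=(0.0, 5.0, 50.0), reps=600, seed=3)


class TestLookup:
    def test_probabilities_normalize(self, small_lookup):
        for gi in range(len(small_lookup.rho_grid)):
            tot = sum(row[gi] for row in small_lookup.counts.values())
            assert tot == small_lookup.reps_per_point

    def test_four_gamete_mass_increases_with_rho(self, small_lookup):
        def fg_mass(gi):
            hits = 0
            for cfg, row in small_lookup.counts.items():
                if all(c > 0 for c in cfg):  # all four gametes present
                    hits += row[gi]
            return hits / small_lookup.reps_per_point

        assert fg_mass(0) < fg_mass(2)  # rho = 0 vs rho = 50

    def test_serialization_identity(self, small_lookup, tmp_path):
        p = tmp_path / "lk.json"
        small_lookup.to_json(p)
        reloaded = TwoLocusLookup.from_json(p)
        for cfg in small_lookup.counts:
            for rho in small_lookup.rho_grid:
                assert reloaded.log_prob(cfg, rho) == \
                    small_lookup.log_prob(cfg, rho)

    def test_doubling_reps_within_monte_carlo_error(self):
        lk1 = build_lookup(10, rho_grid=(0.0, 5.0), reps=500, seed=1)
        lk2 = build_lookup(10, rho_grid=(0.0, 5.0), reps=1000, seed=2)
        checked = 0
        for cfg, row in lk1.counts.items():
            p1 = (row[0] + 1) / (lk1.reps_per_point + len(lk1.counts))
            if p1 < 0.02:  # only well-estimated configs
                continue
            se = math.sqrt((1 - p1) / (p1 * lk1.reps_per_point))
            lp1 = lk1.log_prob(cfg, 0.0)
            lp2 = lk2.log_prob(cfg, 0.0)
            assert abs(lp1 - lp2) < 3 * se + 0.2  # smoothing-floor slack
            checked += 1
        assert checked >= 3

    def test_grid_must_include_zero(self):
        with pytest.raises(ValueError):
            build_lookup(10, rho_grid=(1.0, 5.0), reps=10)

    def test_interpolation_between_grid_points(self, small_lookup):
        cfg = next(iter(small_lookup.counts))
        lp0 = small_lookup.log_prob(cfg, 0.0)
        lp5 = small_lookup.log_prob(cfg, 5.0)
        mid = small_lookup.log_prob(cfg, 2.5)
        assert min(lp0, lp5) - 1e-12 <= mid <= max(lp0, lp5) + 1e-12


class TestCompositeRho:
    def _simulate(self, seed, rho, hotspots=()):
        cfg = SimConfig(
            n_chromosomes=60, theta_per_kb=1.2,
            recomb_map=RecombMap(18_000, rho, hotspots),
            class_mix={VarClass.SNP: 1.0}, seed=seed,
        )
        return simulate_haplotypes(cfg)

    def test_rho_zero_estimates_near_zero(self, lookup_n60):
        # the regional (median) estimate on rho=0 data stays at or below the
        # smallest positive lookup grid value (rho = 1 over a typical 2 kb
        # pair, i.e. 0.5 per kb) in >= 90% of replicates
        low = 0
        reps = 10
        for seed in range(reps):
            out = self._simulate(seed, 0.0)
            profile = composite_rho(out.haplotypes, out.markers, lookup_n60)
            low += profile.background <= 0.5
        assert low >= 0.9 * reps

    def test_flat_map_no_hotspots_called(self, lookup_n60):
        clean = 0
        reps = 15
        for seed in range(reps):
            out = self._simulate(seed + 50, 0.5)
            profile = composite_rho(out.haplotypes, out.markers, lookup_n60)
            hotspots = call_hotspots(profile, factor_threshold=5.0,
                                     min_run=2)
            clean += not hotspots
        assert clean >= 0.8 * reps

    def test_profile_nonnegative_and_windows_tile(self, lookup_n60):
        out = self._simulate(3, 0.5, ((9_000, 2_000, 10.0),))
        profile = composite_rho(out.haplotypes, out.markers, lookup_n60)
        starts = [w[0] for w in profile.windows]
        assert np.allclose(np.diff(starts), 500.0)
        for _, _, rho_hat, _ in profile.windows:
            assert math.isnan(rho_hat) or rho_hat >= 0.0

    def test_peak_robust_to_lookup_build(self, lookup_n60):
        # same data scored with an independently simulated (smaller) lookup
        # localizes its peak window in nearly the same place
        lk2 = build_lookup(60, rho_grid=DEFAULT_RHO_GRID, reps=6000, seed=99)
        out = self._simulate(11, 0.5, ((9_000, 2_000, 10.0),))
        p1 = composite_rho(out.haplotypes, out.markers, lookup_n60)
        p2 = composite_rho(out.haplotypes, out.markers, lk2)

        def peak_center(profile):
            best = max(
                (w for w in profile.windows
                 if not math.isnan(w[2]) and w[3] >= 10),
                key=lambda w: w[2],
            )
            return (best[0] + best[1]) / 2

        assert abs(peak_center(p1) - peak_center(p2)) <= 1_500.0

    def test_mismatched_n_rejected(self, lookup_n60):
        cfg = SimConfig(
            n_chromosomes=20, theta_per_kb=1.0,
            recomb_map=RecombMap(5_000, 0.0),
            class_mix={VarClass.SNP: 1.0}, seed=0,
        )
        out = simulate_haplotypes(cfg)
        with pytest.raises(ValueError, match="lookup built for"):
            composite_rho(out.haplotypes, out.markers, lookup_n60)


class TestCallHotspots:
    def _profile(self, rhos):
        windows = [
            (i * 500.0, i * 500.0 + 2000.0, r, 10) for i, r in enumerate(rhos)
        ]
        defined = [r for r in rhos if not math.isnan(r)]
        return RhoProfile(windows=windows,
                          background=float(np.median(defined)))

    def test_flat_profile_empty(self):
        profile = self._profile([1.0] * 12)
        assert call_hotspots(profile) == []

    def test_single_spike(self):
        profile = self._profile([1.0] * 5 + [8.0] + [1.0] * 5)
        hs = call_hotspots(profile)
        assert len(hs) == 1
        assert hs[0].start_bp == 2500.0
        assert hs[0].peak_rho_per_kb == 8.0
        assert hs[0].factor == pytest.approx(8.0)

    def test_two_separated_spikes(self):
        profile = self._profile(
            [1.0] * 3 + [9.0] + [1.0] * 4 + [7.0] + [1.0] * 3
        )
        hs = call_hotspots(profile)
        assert len(hs) == 2

    def test_adjacent_spikes_merged_across_gap(self):
        profile = self._profile([1.0] * 3 + [9.0, 1.0, 9.0] + [1.0] * 3)
        hs = call_hotspots(profile)
        assert len(hs) == 1

    def test_zero_background_absolute_floor(self):
        profile = self._profile([0.0] * 6 + [3.0] + [0.0] * 5)
        hs = call_hotspots(profile, absolute_min_per_kb=1.0)
        assert len(hs) == 1
        assert math.isinf(hs[0].factor)
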