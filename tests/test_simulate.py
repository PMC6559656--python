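import itertools
import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from promoterpop.coalescent import RecombMap, marginal_tree, simulate_arg
from promoterpop.core import Phenotype, VarClass
from promoterpop.selection import harmonic_a1
from promoterpop.simulate import SimConfig, diploidize, simulate_haplotypes


class TestRecombMap:
    def test_total_rho(self):
        rmap = RecombMap(10_000, 0.5, ((5_000, 2_000, 10.0),))
        # background 0.5/kb * 10 kb + (10-1) * 0.5/kb * 2 kb
        assert rmap.total_rho == pytest.approx(5.0 + 9.0)

    def test_cumulative_invert_round_trip(self):
        rmap = RecombMap(10_000, 0.5, ((5_000, 2_000, 10.0),))
        for x in (0, 1234, 4500, 5000, 6100, 9999):
            g = rmap.cumulative(x)
            assert rmap.invert(g) == pytest.approx(x, abs=1e-6)

    def test_hotspot_outside_region_rejected(self):
        with pytest.raises(ValueError):
            RecombMap(10_000, 0.5, ((9_900, 1_000, 5.0),))

    def test_overlapping_hotspots_rejected(self):
        with pytest.raises(ValueError):
            RecombMap(10_000, 0.5, ((5_000, 2_000, 5.0),
                                    (6_000, 2_000, 5.0)))


class TestSimConfig:
    def test_odd_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=59)

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(class_mix={VarClass.SNP: 0.5})


class TestSimulateHaplotypes:
    def test_same_seed_identical(self):
        cfg = SimConfig(n_chromosomes=20, theta_per_kb=1.0,
                        recomb_map=RecombMap(5_000, 0.5), seed=9)
        a = simulate_haplotypes(cfg)
        b = simulate_haplotypes(cfg)
        assert a.haplotypes.haplotypes == b.haplotypes.haplotypes
        assert a.true_breakpoints == b.true_breakpoints
        assert [m.id for m in a.markers] == [m.id for m in b.markers]

    def test_no_recombination_no_breakpoints_four_gamete_clean(self):
        cfg = SimConfig(n_chromosomes=30, theta_per_kb=1.5,
                        recomb_map=RecombMap(5_000, 0.0),
                        class_mix={VarClass.SNP: 1.0}, seed=3)
        out = simulate_haplotypes(cfg)
        assert out.true_breakpoints == []
        cols = [out.haplotypes.column(j) for j in range(len(out.markers))]
        for ca, cb in itertools.combinations(cols, 2):
            gametes = set(zip(ca, cb))
            assert len(gametes) <= 3  # four-gamete test passes everywhere

    def test_watterson_segregating_sites(self):
        # mean S over replicates ~ theta_region * a1(60)
        theta_region = 3.79
        L = 2_000
        a1 = harmonic_a1(60)
        S = []
        for seed in range(200):
            cfg = SimConfig(
                n_chromosomes=60, theta_per_kb=theta_region / (L / 1000),
                recomb_map=RecombMap(L, 0.0),
                class_mix={VarClass.SNP: 1.0}, seed=seed,
            )
            S.append(len(simulate_haplotypes(cfg).markers))
        expected = theta_region * a1
        se = np.std(S) / math.sqrt(len(S))
        assert abs(np.mean(S) - expected) < 4 * se

    def test_pairwise_diversity_matches_theta(self):
        # mean pi per site ~ theta per site
        theta_kb = 1.0
        L = 2_000
        pis = []
        for seed in range(300):
            cfg = SimConfig(
                n_chromosomes=20, theta_per_kb=theta_kb,
                recomb_map=RecombMap(L, 0.0),
                class_mix={VarClass.SNP: 1.0}, seed=seed,
            )
            out = simulate_haplotypes(cfg)
            n = 20
            k = 0.0
            for j in range(len(out.markers)):
                col = out.haplotypes.column(j)
                p = col.count(col[0]) / n
                k += 2 * p * (1 - p) * n / (n - 1)
            pis.append(k / L)
        target = theta_kb / 1000
        assert np.mean(pis) == pytest.approx(target, rel=0.1)

    def test_breakpoints_grow_with_map_rho(self):
        counts = {}
        for rho in (0.5, 1.0, 2.0):
            bps = []
            for seed in range(60):
                cfg = SimConfig(
                    n_chromosomes=20, theta_per_kb=0.2,
                    recomb_map=RecombMap(5_000, rho),
                    class_mix={VarClass.SNP: 1.0}, seed=seed,
                )
                bps.append(len(simulate_haplotypes(cfg).true_breakpoints))
            counts[rho] = np.mean(bps)
        assert counts[0.5] < counts[1.0] < counts[2.0]
        # roughly linear: doubling rho roughly doubles breakpoints
        assert 1.5 < counts[1.0] / counts[0.5] < 3.0
        assert 1.5 < counts[2.0] / counts[1.0] < 3.0

    def test_class_mix_produces_all_classes(self, mixed_cohort):
        classes = {m.var_class for m in mixed_cohort.markers}
        assert VarClass.SNP in classes
        assert classes & {VarClass.VNTR, VarClass.SSLP, VarClass.POLY_A}

    def test_repeat_markers_polymorphic_integer_alleles(self, mixed_cohort):
        for m in mixed_cohort.markers:
            if m.var_class in (VarClass.VNTR, VarClass.SSLP, VarClass.POLY_A):
                assert len(m.alleles) >= 2
                assert all(int(a) >= 1 for a in m.alleles)

    def test_positions_tss_relative_no_zero(self, mixed_cohort):
        assert all(m.position != 0 for m in mixed_cohort.markers)
        positions = [m.position for m in mixed_cohort.markers]
        assert positions == sorted(positions)
        assert any(p < 0 for p in positions)  # upstream exists

    def test_true_trees_cover_region(self, mixed_cohort):
        lo = mixed_cohort.true_trees[0][0]
        hi = mixed_cohort.true_trees[-1][1]
        assert lo == 0.0 and hi == 18_000.0
        for (a, b, tree) in mixed_cohort.true_trees:
            assert b > a
            assert tree.n_leaves == 60


class TestMsprimeCrossValidation:
    """Our engine vs an independent coalescent simulator (KS, alpha = 0.01
    Bonferroni-corrected over the comparisons made)."""

    N_REPS = 400

    def _ours(self, rho_per_kb):
        rng_seeds = range(self.N_REPS)
        S, sfs = [], []
        for seed in rng_seeds:
            cfg = SimConfig(
                n_chromosomes=20, theta_per_kb=1.0,
                recomb_map=RecombMap(5_000, rho_per_kb),
                class_mix={VarClass.SNP: 1.0}, seed=seed,
            )
            out = simulate_haplotypes(cfg)
            S.append(len(out.markers))
            for j in range(len(out.markers)):
                col = out.haplotypes.column(j)
                anc = out.markers[j].alleles[0]
                sfs.append(sum(1 for x in col if x != anc))
        return np.array(S), np.array(sfs)

    def _msprime(self, rho_per_kb):
        msprime = pytest.importorskip("msprime")
        S, sfs = [], []
        reps = msprime.sim_ancestry(
            samples=10, ploidy=2, sequence_length=5_000,
            recombination_rate=rho_per_kb / 1000 / 4,
            population_size=1, num_replicates=self.N_REPS, random_seed=1234,
        )
        for ts in reps:
            mts = msprime.sim_mutations(
                ts, rate=1.0 / 1000 / 4, model=msprime.InfiniteSites(),
                random_seed=None,
            )
            S.append(mts.num_sites)
            for var in mts.variants():
                sfs.append(int(np.sum(var.genotypes == 1)))
        return np.array(S), np.array(sfs)

    @pytest.mark.parametrize("rho_per_kb", [0.0, 1.0])
    def test_s_and_sfs_distributions_match(self, rho_per_kb):
        ours_S, ours_sfs = self._ours(rho_per_kb)
        ms_S, ms_sfs = self._msprime(rho_per_kb)
        alpha = 0.01 / 4  # 2 statistics x 2 rho settings
        assert ks_2samp(ours_S, ms_S).pvalue > alpha
        assert ks_2samp(ours_sfs, ms_sfs).pvalue > alpha


class TestDiploidize:
    def test_null_odds_carrier_fraction_balanced(self, neutral_cohort):
        haps = neutral_cohort.haplotypes
        # pick a common allele as the "risk" pattern
        j = max(range(len(haps.marker_ids)),
                key=lambda j: min(
                    haps.column(j).count(a) for a in set(haps.column(j))
                ))
        allele = haps.column(j)[0]
        pattern = {haps.marker_ids[j]: allele}
        diffs = []
        for seed in range(200):
            gm = diploidize(haps, risk_haplotype=pattern, odds=1.0, seed=seed)
            # recount carriers by phenotype from genotypes
            jj = gm.marker_ids.index(haps.marker_ids[j])
            case_car = ctrl_car = 0
            for i, s in enumerate(gm.subjects):
                call = gm.calls[i][jj]
                is_car = allele in call
                if gm.phenotype[s] == Phenotype.CASE:
                    case_car += is_car
                else:
                    ctrl_car += is_car
            diffs.append(case_car - ctrl_car)
        assert abs(np.mean(diffs)) < 1.0  # binomial error around 0

    def test_infinite_odds_all_carriers_cases(self, neutral_cohort):
        haps = neutral_cohort.haplotypes
        j = 0
        allele = haps.column(j)[0]
        pattern = {haps.marker_ids[j]: allele}
        gm = diploidize(haps, risk_haplotype=pattern, odds=float("inf"),
                        case_fraction=0.5, seed=1)
        jj = gm.marker_ids.index(haps.marker_ids[j])
        carriers = [
            s for i, s in enumerate(gm.subjects)
            if allele in gm.calls[i][jj]
        ]
        n_cases = sum(
            1 for s in gm.subjects if gm.phenotype[s] == Phenotype.CASE
        )
        if len(carriers) <= n_cases:
            assert all(
                gm.phenotype[s] == Phenotype.CASE for s in carriers
            )

    def test_empty_set_rejected(self):
        from promoterpop.core import HaplotypeSet

        with pytest.raises(ValueError):
            diploidize(HaplotypeSet(haplotypes=[], subject_of=[],
                                    marker_ids=[]))

    def test_deterministic(self, neutral_cohort):
        g1 = diploidize(neutral_cohort.haplotypes, seed=3)
        g2 = diploidize(neutral_cohort.haplotypes, seed=3)
        assert g1.calls == g2.calls
        assert g1.phenotype == g2.phenotype
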