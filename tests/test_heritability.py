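import math

import numpy as np
import pytest

import evoherit as ev
from evoherit.heritability import (
    MonomorphicLocusError,
    increments_by_founder,
    narrow_sense_with_ci,
    reml_loglik,
    standardized_genotypes,
)

from conftest import small_config
from oracles import (
    brute_variance_partition_fitness,
    brute_variance_partition_increment,
)


class TestBroadSenseFitness:
    def test_two_founders_no_error(self):
        vc = ev.broad_sense_fitness([1, 3], [0, 0])
        assert vc.sigma_t2 == pytest.approx(1.0)
        assert vc.sigma_noise2 == 0.0
        assert vc.H2 == pytest.approx(1.0)

    def test_pure_error_flags_undefined_h2(self):
        vc = ev.broad_sense_fitness([1, 1], [1, 1])
        assert vc.sigma_t2 == 0.0
        assert vc.sigma_f2 == pytest.approx(-1.0)
        assert math.isnan(vc.H2)
        assert vc.H2_clipped == 0.0

    def test_three_founder_hand_computation(self):
        vc = ev.broad_sense_fitness([0, 2, 4], [0.5, 0.5, 0.5])
        assert vc.sigma_t2 == pytest.approx(8 / 3)
        assert vc.sigma_noise2 == pytest.approx(0.5)
        assert vc.H2 == pytest.approx((8 / 3 - 0.5) / (8 / 3))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(2, 12)
            means = rng.normal(size=n)
            evars = rng.uniform(0, 0.5, size=n)
            vc = ev.broad_sense_fitness(means, evars)
            t, e, f = brute_variance_partition_fitness(list(means), list(evars))
            assert vc.sigma_t2 == pytest.approx(t, abs=1e-12)
            assert vc.sigma_noise2 == pytest.approx(e, abs=1e-12)
            assert vc.sigma_f2 == pytest.approx(f, abs=1e-12)


class TestBroadSenseIncrement:
    def test_perfectly_heritable_increments(self):
        vc = ev.broad_sense_increment({"A": [1, 1], "B": [3, 3]})
        assert vc.sigma_noise2 == 0.0
        assert vc.sigma_t2 == pytest.approx(1.0)
        assert vc.H2 == pytest.approx(1.0)

    def test_single_founder_noise_only(self):
        vc = ev.broad_sense_increment({"A": [1, 3]})
        assert vc.sigma_noise2 == pytest.approx(2.0)
        assert vc.sigma_t2 == pytest.approx(1.0)
        assert vc.sigma_f2 == pytest.approx(-1.0)
        assert vc.H2_clipped == 0.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n_founders = rng.integers(1, 8)
            groups = {
                i: rng.normal(size=rng.integers(2, 6)) for i in range(n_founders)
            }
            vc = ev.broad_sense_increment(groups)
            t, p, f = brute_variance_partition_increment(
                [list(v) for v in groups.values()]
            )
            assert vc.sigma_t2 == pytest.approx(t, abs=1e-12)
            assert vc.sigma_noise2 == pytest.approx(p, abs=1e-12)
            assert vc.H2 == pytest.approx(f / t, abs=1e-12)

    def test_singleton_founders_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="single population"):
            vc = ev.broad_sense_increment({"A": [1, 2], "B": [5]})
        assert vc.n == 2
        with pytest.raises(ValueError):
            ev.broad_sense_increment({"A": [1], "B": [5]})

    def test_added_measurement_noise_does_not_inflate_h2(self):
        """Adding i.i.d. noise to population increments leaves expected H²
        no higher (monotonicity over a simulation ensemble)."""
        rng = np.random.default_rng(3)
        h_clean, h_noisy = [], []
        for _ in range(60):
            founder_eff = rng.normal(0, 1, size=40)
            clean = {i: founder_eff[i] + rng.normal(0, 0.5, size=4)
                     for i in range(40)}
            noisy = {i: v + rng.normal(0, 1.0, size=4) for i, v in clean.items()}
            h_clean.append(ev.broad_sense_increment(clean).H2)
            h_noisy.append(ev.broad_sense_increment(noisy).H2)
        assert np.mean(h_noisy) < np.mean(h_clean)


class TestJackknife:
    def test_constant_statistic_zero_width(self):
        lo, hi = ev.delete_half_jackknife(lambda s: 1.23, list(range(10)),
                                          n_resamples=50, seed=0)
        assert lo == hi == 1.23

    def test_fixed_seed_reproducible(self):
        founders = list(range(20))
        data = dict(zip(founders, np.random.default_rng(1).normal(size=20)))
        stat = lambda s: float(np.mean([data[f] for f in s]))
        a = ev.delete_half_jackknife(stat, founders, n_resamples=2, seed=5)
        b = ev.delete_half_jackknife(stat, founders, n_resamples=2, seed=5)
        assert a == b

    def test_too_many_failures_raises(self):
        def stat(s):
            raise RuntimeError("boom")
        with pytest.raises(RuntimeError, match="failed"):
            ev.delete_half_jackknife(stat, list(range(10)), n_resamples=20, seed=0)

    def test_h2_interval_covers_generative_value(self):
        """CI from the jackknife covers the generative H² in most replicate
        simulations (coverage check at reduced scale)."""
        hits = 0
        n_sims = 20
        for s in range(n_sims):
            rng = np.random.default_rng(100 + s)
            n, reps = 120, 4
            sigma_f, sigma_p = math.sqrt(0.6), math.sqrt(0.4)  # true H² = 0.6
            eff = rng.normal(0, sigma_f, size=n)
            data = {i: eff[i] + rng.normal(0, sigma_p, size=reps)
                    for i in range(n)}
            def stat(subset):
                return ev.broad_sense_increment({f: data[f] for f in subset}).H2
            lo, hi = ev.delete_half_jackknife(stat, list(range(n)),
                                              n_resamples=120, seed=s)
            if lo - 0.05 <= 0.6 <= hi + 0.05:
                hits += 1
        assert hits >= 17


class TestKinship:
    def test_identical_founders_share_relatedness(self):
        rng = np.random.default_rng(0)
        alleles = rng.integers(0, 2, size=(5, 50)).astype(np.int8)
        alleles[1] = alleles[0]
        g = ev.GenotypeMatrix(
            founders=[f"f{i}" for i in range(5)],
            chrom=np.array(["c"] * 50), pos=np.arange(1, 51), alleles=alleles,
        )
        # drop monomorphic columns that the duplication may have created
        g = g.subset_loci(np.flatnonzero(~g.monomorphic_mask()))
        r = ev.kinship_matrix(g).values
        assert r[0, 1] == pytest.approx(r[0, 0], abs=1e-12)
        assert r[0, 1] == pytest.approx(r[1, 1], abs=1e-12)

    def test_opposite_founders_at_half_frequency(self):
        m = 30
        a = np.zeros((2, m), dtype=np.int8)
        a[1] = 1
        g = ev.GenotypeMatrix(
            founders=["a", "b"], chrom=np.array(["c"] * m),
            pos=np.arange(1, m + 1), alleles=a,
        )
        r = ev.kinship_matrix(g).values
        assert r[0, 1] == pytest.approx(-1.0, abs=1e-12)
        assert r[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_random_panel_off_diagonal_concentration(self):
        rng = np.random.default_rng(1)
        alleles = rng.integers(0, 2, size=(230, 1000)).astype(np.int8)
        g = ev.GenotypeMatrix(
            founders=[f"f{i}" for i in range(230)],
            chrom=np.array(["c"] * 1000), pos=np.arange(1, 1001), alleles=alleles,
        )
        r = ev.kinship_matrix(g).values
        off = r[~np.eye(230, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.1
        assert np.allclose(r, r.T)

    def test_monomorphic_locus_named_in_error(self):
        a = np.ones((4, 3), dtype=np.int8)
        a[:, :2] = np.random.default_rng(0).integers(0, 2, size=(4, 2))
        a[:, 2] = 1
        g = ev.GenotypeMatrix(
            founders=list("abcd"), chrom=np.array(["cX"] * 3),
            pos=np.array([1, 2, 3]), alleles=a,
        )
        with pytest.raises(MonomorphicLocusError, match="cX:3"):
            ev.kinship_matrix(g)


@pytest.fixture(scope="module")
def panel():
    cfg = small_config(n_founders=150, seed=17)
    return ev.simulate_genotypes(cfg)


class TestREML:
    def test_noiseless_additive_trait_gives_h2_near_one(self, panel):
        g = standardized_genotypes(panel)
        rng = np.random.default_rng(2)
        y = g @ rng.normal(size=g.shape[1])
        res = ev.narrow_sense_reml(y, ev.kinship_matrix(panel))
        assert res.h2 >= 0.99

    def test_pure_noise_trait_gives_low_h2(self, panel):
        low = 0
        kin = ev.kinship_matrix(panel)
        for s in range(25):
            y = np.random.default_rng(s).normal(size=panel.n_founders)
            if ev.narrow_sense_reml(y, kin).h2 < 0.2:
                low += 1
        assert low >= 22

    def test_optimum_beats_random_admissible_points(self, panel):
        rng = np.random.default_rng(5)
        g = standardized_genotypes(panel)
        y = 0.7 * (g @ rng.normal(size=g.shape[1])) + rng.normal(
            0, 0.5, size=panel.n_founders
        )
        kin = ev.kinship_matrix(panel)
        res = ev.narrow_sense_reml(y, kin)
        vary = y.var(ddof=1)
        for _ in range(50):
            sa = rng.uniform(0, 2 * vary)
            se = rng.uniform(1e-6, 2 * vary)
            assert res.loglik >= reml_loglik(y, kin, sa, se) - 1e-6

    def test_trait_kinship_mismatch_rejected(self, panel):
        kin = ev.kinship_matrix(panel)
        with pytest.raises(ValueError):
            ev.narrow_sense_reml(np.zeros(panel.n_founders - 1), kin)

    def test_jackknife_ci_brackets_estimate(self, panel):
        rng = np.random.default_rng(9)
        g = standardized_genotypes(panel)
        y = g @ rng.normal(size=g.shape[1]) * 0.7
        y = y + rng.normal(0, y.std(), size=y.size)
        import pandas as pd
        trait = pd.Series(y, index=panel.founders)
        res = narrow_sense_with_ci(trait, panel, n_resamples=30, seed=1)
        lo, hi = res.ci
        assert lo <= hi
        assert lo - 0.25 <= res.h2 <= hi + 0.25
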