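"""Allele-class pooling, the required-selection solver (against a
bisection-on-recursion oracle), profile construction, and asymmetry tests."""

import numpy as np
import pytest
from scipy.optimize import brentq

from sympop.selection import (
    MigrationSelectionModel,
    PooledLocus,
    PooledPair,
    pool_alleles,
    required_s,
    selection_delta_p,
)
from sympop.simulate import TwoIslandConfig, iterate_two_island_deterministic


def oracle_s_sequential(p_fav: float, p_imm: float, m: float, h: float = 0.5) -> float:
    """Bisection on s over the full migration-then-selection recursion until
    the one-generation update returns the observed frequency."""

    def gap(s):
        p_star = (1 - m) * p_fav + m * p_imm
        return p_star + selection_delta_p(p_star, s, h) - p_fav

    return brentq(gap, 0.0, 1.0, xtol=1e-12)


def oracle_s_compensatory(p_fav: float, p_imm: float, m: float, h: float = 0.5) -> float:
    delta = m * (p_fav - p_imm)
    return brentq(lambda s: selection_delta_p(p_fav, s, h) - delta, 0.0, 1.0, xtol=1e-12)


class TestPoolAlleles:
    def test_identical_maps_tie_to_ancestral_class(self):
        f = {1: 0.4, 2: 0.6}
        a1, a2, cls = pool_alleles(f, dict(f))
        assert a1 == a2 == pytest.approx(1.0)
        assert set(cls) == {1, 2}

    def test_two_allele_case(self):
        a1, a2, cls = pool_alleles({1: 0.7, 2: 0.3}, {1: 0.2, 2: 0.8})
        assert cls == (1,)
        assert (a1, a2) == (0.7, 0.2)

    def test_three_allele_complements(self):
        fa = {1: 0.5, 2: 0.3, 3: 0.2}
        fd = {1: 0.1, 2: 0.5, 3: 0.4}
        a1, a2, cls = pool_alleles(fa, fd)
        assert cls == (1,)
        assert (a1, a2) == (0.5, 0.1)
        # derived-class frequencies are the complements and sum to 1 per pop
        assert 1 - a1 == pytest.approx(0.5) and 1 - a2 == pytest.approx(0.9)

    def test_class_split_invariance(self):
        # splitting an ancestral-class allele into two with the same total
        a1, a2, _ = pool_alleles({1: 0.6, 2: 0.4}, {1: 0.2, 2: 0.8})
        b1, b2, _ = pool_alleles({1: 0.3, 9: 0.3, 2: 0.4}, {1: 0.1, 9: 0.1, 2: 0.8})
        assert (a1, a2) == (pytest.approx(b1), pytest.approx(b2))


class TestRequiredS:
    def test_no_difference_or_no_migration_is_zero(self):
        assert required_s(0.6, 0.6, 0.05).s == 0.0
        assert required_s(0.9, 0.1, 0.0).s == 0.0

    def test_sequential_hand_example(self):
        res = required_s(0.9, 0.1, 0.05, convention="sequential")
        assert res.s == pytest.approx(0.608, abs=5e-4)
        assert res.s == pytest.approx(oracle_s_sequential(0.9, 0.1, 0.05), abs=1e-10)

    def test_capping(self):
        res = required_s(0.995, 0.005, 0.1)
        assert res.s == 1.0 and res.capped
        # oracle confirms even s=1 cannot compensate
        delta = 0.1 * 0.99
        assert selection_delta_p(0.995, 1.0) < delta

    def test_degenerate_fixed_resident(self):
        res = required_s(1.0, 0.2, 0.05)
        assert res.capped and res.degenerate

    @pytest.mark.parametrize("convention,oracle",
                             [("compensatory", oracle_s_compensatory),
                              ("sequential", oracle_s_sequential)])
    def test_closed_form_matches_bisection_grid(self, convention, oracle):
        for m in (0.01, 0.03, 0.05, 0.1):
            for p_fav in np.arange(0.55, 0.96, 0.05):
                for p_imm in np.arange(0.05, 0.51, 0.05):
                    res = required_s(p_fav, p_imm, m, convention=convention)
                    if res.capped:
                        continue
                    assert res.s == pytest.approx(
                        oracle(p_fav, p_imm, m), abs=1e-8
                    ), (m, p_fav, p_imm)

    def test_general_dominance_bisection_path(self):
        for h in (0.0, 0.25, 1.0):
            res = required_s(0.8, 0.2, 0.05, h=h)
            delta = 0.05 * 0.6
            assert selection_delta_p(0.8, res.s, h) == pytest.approx(delta, abs=1e-10)

    def test_monotone_in_m_and_difference(self):
        s_vals = [required_s(0.8, 0.2, m).s for m in (0.01, 0.03, 0.05, 0.1)]
        assert all(b > a for a, b in zip(s_vals, s_vals[1:]))
        s_diff = [required_s(0.6 + d, 0.4 - d, 0.05).s for d in (0.0, 0.1, 0.2, 0.3)]
        assert all(b > a for a, b in zip(s_diff, s_diff[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_s(0.3, 0.6, 0.05)
        with pytest.raises(ValueError):
            required_s(0.6, 0.3, 0.7)


class TestEquilibriumRoundTrip:
    def test_deterministic_equilibria_inverted_exactly(self):
        rng = np.random.default_rng(3)
        s_true = rng.uniform(0.05, 0.5, size=19)
        for m in (0.01, 0.03, 0.05):
            cfg = TwoIslandConfig(m=m, s=s_true)
            p1, p2, _ = iterate_two_island_deterministic(
                np.full(19, 0.55), np.full(19, 0.45), cfg, tol=1e-13
            )
            loci = [
                PooledLocus(locus=f"L{i}", a1=float(p1[i]), a2=float(p2[i]))
                for i in range(19)
            ]
            pair = PooledPair("rt", "anc", "der", loci, m=m)
            res = MigrationSelectionModel(pair).fit(convention="sequential")
            assert np.allclose(res.profile["s_ancestral"], s_true, atol=1e-6)
            assert np.allclose(res.profile["s_derived"], s_true, atol=1e-6)


class TestSelectionProfile:
    def _pair(self, recs, m=0.05):
        loci = [PooledLocus(locus=f"L{i}", a1=a, a2=b) for i, (a, b) in enumerate(recs)]
        return PooledPair("t", "anc", "der", loci, m=m)

    def test_equal_frequencies_give_zero(self):
        res = MigrationSelectionModel(self._pair([(0.5, 0.5)] * 4)).fit()
        assert (res.profile[["s_derived", "s_ancestral"]] == 0).all().all()
        assert res.summary_stats()["mean"].tolist() == [0.0, 0.0]

    def test_symmetric_frequencies_give_symmetric_directions(self):
        recs = [(0.9, 0.1), (0.7, 0.3), (0.8, 0.2)]
        res = MigrationSelectionModel(self._pair(recs)).fit()
        assert np.allclose(res.profile["s_derived"], res.profile["s_ancestral"])
        assert res.asymmetry_tests()["paired_t"] == 0.0

    def test_capped_loci_counted_and_summarized_on_capped_values(self):
        res = MigrationSelectionModel(self._pair([(0.999, 0.001), (0.7, 0.3)], m=0.1)).fit()
        stats = res.summary_stats()
        assert stats["n_capped"].iloc[0] == 1
        assert res.profile["s_derived"].max() == 1.0

    def test_reporting_floor(self):
        res = MigrationSelectionModel(self._pair([(0.5, 0.5), (0.9, 0.1)])).fit()
        rep = res.reporting_profile()
        assert rep["s_derived"].min() == 0.001
        assert res.profile["s_derived"].min() == 0.0  # raw retained

    def test_pooling_invariance_of_profile(self, radiation_freqs):
        res = MigrationSelectionModel.from_frequencies(
            radiation_freqs, "p03", "p21", m=0.03
        ).fit()
        assert ((res.profile["a1"] + 1e-12) >= res.profile["a2"]).all()
        assert res.profile["s_derived"].between(0, 1).all()


class TestAsymmetryTests:
    def _results(self, sd, sa, m=0.03):
        loci = [PooledLocus(locus=f"L{i}", a1=0.5, a2=0.5) for i in range(len(sd))]
        pair = PooledPair("t", "anc", "der", loci, m=m)
        res = MigrationSelectionModel(pair).fit()
        res.profile["s_derived"] = sd
        res.profile["s_ancestral"] = sa
        return res

    def test_identical_directions(self):
        x = np.linspace(0.05, 0.3, 19)
        t = self._results(x, x.copy()).asymmetry_tests()
        assert t["paired_t"] == 0.0 and t["F"] == pytest.approx(1.0)
        assert t["paired_t_df"] == 18 and t["F_df"] == (18, 18)

    def test_variance_ratio_direction_reported(self):
        rng = np.random.default_rng(8)
        sa = 0.15 + 0.02 * rng.standard_normal(19)
        sd = 0.15 + 0.08 * rng.standard_normal(19)
        t = self._results(sd, sa).asymmetry_tests()
        assert t["larger_variance"] == "derived"
        assert t["F"] > 1

    def test_f_power_at_8x_variance(self):
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 200
        for _ in range(reps):
            sa = 0.15 + 0.03 * rng.standard_normal(19)
            sd = 0.15 + 0.03 * np.sqrt(8) * rng.standard_normal(19)
            t = self._results(sd, sa).asymmetry_tests()
            rejections += t["F_p"] < 0.01
        assert rejections / reps >= 0.8

    def test_paired_t_type_i_error(self):
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            sa = 0.15 + 0.05 * rng.standard_normal(19)
            sd = 0.15 + 0.05 * rng.standard_normal(19)
            t = self._results(sd, sa).asymmetry_tests()
            rejections += t["paired_t_p"] < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_needs_three_loci(self):
        with pytest.raises(ValueError):
            self._results(np.array([0.1, 0.2]), np.array([0.1, 0.2])).asymmetry_tests()


def test_model_summary_smoke(radiation_freqs):
    res = MigrationSelectionModel.from_frequencies(
        radiation_freqs, "p14", "p29", m=0.01, pair_id="zephyria_vs_black_hawthorn"
    ).fit()
    text = res.summary()
    assert "zephyria_vs_black_hawthorn" in text and "paired t" in text
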