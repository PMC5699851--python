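import math

import numpy as np
import pytest

from avidity.irreversible import ec50_irreversible, f21_from_bridging
from avidity.oracles import (
    fixed_point_reversible_ec50,
    mass_action_dimerization,
)
from avidity.reversible import (
    blended_f21,
    ec50_reversible,
    f21_monomeric_limit,
    fig4_grid,
    monomer_fraction_at,
    solution_dimer_fraction,
    state_fractions_reversible,
    threshold_tether_for_fold,
)
from avidity.reversible import _one_minus_2f21, _route_fractions
from avidity.tether import TetherGeometry


class TestSolutionDimerFraction:
    def test_weak_dimerization_stays_monomeric(self):
        assert solution_dimer_fraction(1e-6, 1e6) == pytest.approx(0.0, abs=1e-10)

    def test_half_dimerized_at_kdim(self):
        assert solution_dimer_fraction(1e-2, 1e-2) == pytest.approx(0.5, abs=1e-14)

    def test_matches_mass_action_oracle(self, rng):
        for _ in range(500):
            L0, kdim = 10.0 ** rng.uniform(-7, 0, size=2)
            assert solution_dimer_fraction(L0, kdim) == pytest.approx(
                mass_action_dimerization(L0, kdim), rel=1e-10, abs=1e-14
            )

    def test_printed_example(self):
        assert solution_dimer_fraction(2e-4, 1e-2) == pytest.approx(0.03709, rel=1e-3)

    def test_mass_action_residual_with_sequestered_fraction(self, rng):
        # K_Dim F_DL = 2 L0 F_ML^2 must hold with F_ML = 1 - d21 - F_DL
        for _ in range(200):
            L0, kdim = 10.0 ** rng.uniform(-6, 0, size=2)
            d21 = rng.uniform(0.0, 0.9)
            f_dl = solution_dimer_fraction(L0, kdim, d21)
            f_ml = 1.0 - d21 - f_dl
            assert kdim * f_dl == pytest.approx(2.0 * L0 * f_ml * f_ml, rel=1e-10, abs=1e-300)
            assert 0.0 <= f_dl <= 1.0 - d21


class TestMonomericLimitF21:
    def test_no_on_target_dimerization(self, rng):
        for r in rng.uniform(0, 1, size=20):
            assert f21_monomeric_limit(r, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_complete_on_target_dimerization(self, rng):
        for r in rng.uniform(0, 1, size=20):
            assert f21_monomeric_limit(r, 1.0) == pytest.approx(r, rel=1e-14)

    def test_half_half_closed_form(self):
        # frozen hand evaluation of the closed form at R = 1/2, F_L,Dim = 1/2
        assert f21_monomeric_limit(0.5, 0.5) == pytest.approx(0.1392498829, rel=1e-9)

    def test_bounded_by_occupancy(self, rng):
        for _ in range(200):
            r, f = rng.uniform(0, 1, size=2)
            val = f21_monomeric_limit(r, f)
            assert 0.0 <= val <= r + 1e-12


class TestBlendedF21:
    def test_pure_monomer_pool(self):
        assert blended_f21(0.5, 1.0, 0.0, 0.4, 0.9) == pytest.approx(
            f21_monomeric_limit(0.5, 0.4), rel=1e-14
        )

    def test_pure_dimer_pool(self):
        assert blended_f21(0.5, 0.0, 1.0, 0.4, 0.9) == pytest.approx(
            f21_from_bridging(0.5, 0.9), rel=1e-14
        )

    def test_half_occupancy_weight_identity(self):
        # at R = 1/2 with F_ML = 1 - F_DL the monomer weight reduces to
        # (1 - F_DL)^2 / (1 + F_DL^2)
        f_dl = 0.3
        f_ml = 1.0 - f_dl
        w_mono = f_ml**2 / (1.0 + f_dl**2)
        got = blended_f21(0.5, f_ml, f_dl, 0.4, 0.9)
        expected = w_mono * f21_monomeric_limit(0.5, 0.4) + (
            1.0 - w_mono
        ) * f21_from_bridging(0.5, 0.9)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_degenerate_pool_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert blended_f21(0.5, 0.0, 0.0, 0.4, 0.9) == 0.0


class TestReversibleEC50:
    def test_no_dimerization_anywhere_gives_monomer_ec50(self):
        res = ec50_reversible(1e-6, 1e9, TetherGeometry(30.0))
        assert res.ec50 == pytest.approx(1e-6, rel=1e-6)
        assert res.fold == pytest.approx(1.0, rel=1e-6)

    def test_short_tether_gives_fold_one(self):
        res = ec50_reversible(1e-6, 1e-3, TetherGeometry(5.0, 10.0))
        assert res.fold == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("kd", [1e-3, 1e-6, 1e-9])
    def test_dimeric_limit_is_twice_irreversible_ec50(self, kd):
        for rho_p in [5.0, 20.0, 60.0, 100.0]:
            geom = TetherGeometry(rho_p)
            rev = ec50_reversible(kd, 1e-12 * kd, geom).ec50
            irrev = ec50_irreversible(kd, geom, 0.0).ec50_model
            assert abs(rev - 2.0 * irrev) / rev < 1e-3

    def test_weak_ligand_sixteen_angstrom_example(self):
        # independent route: damped fixed-point iteration oracle
        res = ec50_reversible(1e-3, 1e-2, TetherGeometry(16.0))
        oracle = fixed_point_reversible_ec50(1e-3, 1e-2, TetherGeometry(16.0))
        assert res.ec50 == pytest.approx(oracle, rel=1e-8)
        assert res.ec50 == pytest.approx(2.22e-4, rel=1e-2)
        assert res.fold == pytest.approx(4.51, rel=1e-2)

    def test_agrees_with_fixed_point_oracle_randomized(self, rng):
        for _ in range(100):
            kd = 10.0 ** rng.uniform(-9, -3)
            kdim = 10.0 ** rng.uniform(-9, 0)
            rho_p = rng.uniform(5.0, 100.0)
            geom = TetherGeometry(rho_p)
            assert ec50_reversible(kd, kdim, geom).ec50 == pytest.approx(
                fixed_point_reversible_ec50(kd, kdim, geom), rel=1e-8
            )

    def test_root_unique_on_bracket(self, rng):
        # g(L0) = K_D (1 - 2 F21(L0)) - L0 crosses zero exactly once on the
        # bracket.  (g is not strictly monotone: the monomer/dimer route
        # weights shift with L0, allowing relative wiggles of ~1e-5, but the
        # sign change stays unique.)
        for _ in range(100):
            kd = 10.0 ** rng.uniform(-9, -3)
            kdim = 10.0 ** rng.uniform(-9, 0)
            geom = TetherGeometry(rng.uniform(5.0, 100.0))
            f_t_dim, f_l_dim = _route_fractions(geom, kd, kdim)
            L_grid = np.logspace(math.log10(kd) - 12, math.log10(kd), 400)
            g = np.array(
                [
                    kd * _one_minus_2f21(L, kd, kdim, f_t_dim, f_l_dim)[0] - L
                    for L in L_grid
                ]
            )
            sign_changes = np.count_nonzero(np.diff(np.sign(g)) != 0)
            assert sign_changes <= 1
            assert g[0] > 0.0 and g[-1] <= 0.0

    def test_never_beats_the_irreversible_dimer(self):
        for kd in [1e-3, 1e-6, 1e-9]:
            for kdim in [1e-7, 1e-4, 1e-1]:
                for rho_p in [8.0, 25.0, 80.0]:
                    geom = TetherGeometry(rho_p)
                    fold_rev = ec50_reversible(kd, kdim, geom).fold
                    fold_irrev = ec50_irreversible(kd, geom, 0.0).fold
                    assert fold_rev <= fold_irrev * (1.0 + 1e-9)

    def test_fold_equals_kd_over_ec50(self):
        res = ec50_reversible(1e-6, 1e-4, TetherGeometry(20.0))
        assert res.fold == pytest.approx(1e-6 / res.ec50, rel=1e-12)


class TestMonomerFraction:
    def test_half_at_kdim(self):
        assert monomer_fraction_at(1e-3, 1e-3) == pytest.approx(0.5, abs=1e-12)

    def test_limits(self):
        assert monomer_fraction_at(1e-6, 1e9) == pytest.approx(1.0, abs=1e-10)
        assert monomer_fraction_at(1e-3, 1e-15) == pytest.approx(0.0, abs=1e-5)


class TestThresholdTether:
    def test_weak_dimerizer_threshold(self):
        rho = threshold_tether_for_fold(1e-3, 1e-2, 4.0)
        assert 12.0 <= rho <= 20.0  # ~16 A regime
        # the threshold is exact: fold crosses 4 there
        assert ec50_reversible(1e-3, 1e-2, TetherGeometry(rho)).fold == pytest.approx(
            4.0, rel=1e-6
        )
        assert ec50_reversible(1e-3, 1e-2, TetherGeometry(rho + 1.0)).fold < 4.0

    def test_better_dimerizer_reaches_longer(self):
        rho = threshold_tether_for_fold(1e-3, 1e-3, 4.0)
        assert 30.0 <= rho <= 50.0  # ~40 A regime

    def test_trivial_target_hits_upper_bracket(self):
        assert threshold_tether_for_fold(1e-3, 1e-2, 1.0, rho_max=500.0) == 500.0

    def test_unreachable_fold_returns_none(self):
        assert threshold_tether_for_fold(1e-6, 1e9, 50.0) is None


class TestStateFractions:
    def test_conservation_identities_at_solved_root(self, rng):
        for _ in range(50):
            kd = 10.0 ** rng.uniform(-9, -3)
            kdim = 10.0 ** rng.uniform(-7, -1)
            geom = TetherGeometry(rng.uniform(6.0, 80.0))
            res = ec50_reversible(kd, kdim, geom)
            s = state_fractions_reversible(res.ec50, kd, kdim, geom, r=0.5)
            assert s.f_u + s.f_1 + s.f_22 + s.f_21 == pytest.approx(1.0, abs=1e-9)
            assert s.f_ml + s.f_dl + s.d_21 == pytest.approx(1.0, abs=1e-9)
            assert s.l_u + s.l_1 == pytest.approx(s.f_ml, abs=1e-12)
            assert s.d_u + s.d_1 + s.d_22 == pytest.approx(s.f_dl, abs=1e-12)
            # binomial splits in the common bound-ligand fraction
            assert s.d_1 == pytest.approx(2 * s.f_l * (1 - s.f_l) * s.f_dl, abs=1e-12)
            assert 0.0 <= s.f_21 <= 0.5


class TestFig4Grid:
    def test_single_cell_matches_pointwise_call(self):
        df = fig4_grid([1e-3], [1e-2], [16.0])
        res = ec50_reversible(1e-3, 1e-2, TetherGeometry(16.0))
        assert df.loc[0, "EC50"] == res.ec50
        assert df.loc[0, "fold"] == res.fold
        assert df.loc[0, "F_ML_at_ec50"] == res.f_ml_at_ec50

    def test_fold_monotone_along_tether(self):
        rhos = np.linspace(6.0, 100.0, 20)
        df = fig4_grid([1e-3, 1e-6], [1e-3, 1e-1], rhos)
        for (_, _), grp in df.groupby(["K_D", "K_Dim"]):
            assert np.all(np.diff(grp["fold"].to_numpy()) <= 1e-12)

    def test_deterministic(self):
        args = ([1e-6], [1e-4, 1e-2], np.linspace(10, 50, 5))
        assert fig4_grid(*args).equals(fig4_grid(*args))
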