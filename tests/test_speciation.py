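"""Equilibrium solver versus brute-force oracles and conservation laws."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lanthafit as lf
from lanthafit.errors import InputError, ProtocolError
from lanthafit.speciation import TitrationProtocol

UM = 1e-6


def bisect_free_metal(l_tot, m_tot, kd11, kd12, tol=1e-16):
    """Independent oracle: bisection on the scalar metal balance."""
    def g(m):
        b = m / kd11 + (m * m / (kd11 * kd12) if math.isfinite(kd12) else 0.0)
        bm = m / kd11 + (2 * m * m / (kd11 * kd12) if math.isfinite(kd12) else 0.0)
        return m + l_tot / (1 + b) * bm - m_tot
    lo, hi = 0.0, m_tot
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * max(m_tot, 1.0):
            break
    return 0.5 * (lo + hi)


def species_from_free(m, l_tot, kd11, kd12):
    b = m / kd11 + (m * m / (kd11 * kd12) if math.isfinite(kd12) else 0.0)
    free_l = l_tot / (1 + b)
    c_lm = free_l * m / kd11
    c_lm2 = c_lm * m / kd12 if math.isfinite(kd12) else 0.0
    return free_l, m, c_lm, c_lm2


class TestSolveSpeciation:
    def test_no_metal_means_no_complex(self):
        st_ = lf.solve_speciation(lf.MixtureComposition(l_tot=10 * UM, m_tot=0.0),
                                  lf.BindingModel(0.5 * UM, 1.1 * UM))
        assert st_.free_l == pytest.approx(10 * UM)
        assert st_.c_lm == 0.0 and st_.c_lm2 == 0.0

    def test_vanishing_affinity_limit(self):
        st_ = lf.solve_speciation(lf.MixtureComposition(l_tot=10 * UM, m_tot=10 * UM),
                                  lf.BindingModel(1.0, 1.0))
        assert st_.free_l == pytest.approx(10 * UM, rel=1e-4)
        assert st_.free_m == pytest.approx(10 * UM, rel=1e-4)
        assert st_.c_lm + st_.c_lm2 < 1e-4 * 10 * UM

    def test_matches_bisection_oracle_reference_case(self):
        l_tot, m_tot, kd11, kd12 = 10 * UM, 10 * UM, 0.5 * UM, 1.1 * UM
        st_ = lf.solve_speciation(lf.MixtureComposition(l_tot=l_tot, m_tot=m_tot),
                                  lf.BindingModel(kd11, kd12))
        m_ref = bisect_free_metal(l_tot, m_tot, kd11, kd12)
        ref = species_from_free(m_ref, l_tot, kd11, kd12)
        for got, want in zip((st_.free_l, st_.free_m, st_.c_lm, st_.c_lm2), ref):
            assert got == pytest.approx(want, rel=1e-8)

    def test_oracle_equivalence_random_instances(self, rng):
        """Solver vs bisection on 100 random compositions, every species."""
        for _ in range(100):
            l_tot = 10 ** rng.uniform(-7, -4)
            m_tot = 10 ** rng.uniform(-7, -4)
            kd11 = 10 ** rng.uniform(-8, -4)
            kd12 = 10 ** rng.uniform(-8, -3)
            st_ = lf.solve_speciation(lf.MixtureComposition(l_tot=l_tot, m_tot=m_tot),
                                      lf.BindingModel(kd11, kd12))
            m_ref = bisect_free_metal(l_tot, m_tot, kd11, kd12)
            ref = species_from_free(m_ref, l_tot, kd11, kd12)
            scale = max(m_tot, l_tot)
            for got, want in zip((st_.free_l, st_.free_m, st_.c_lm, st_.c_lm2), ref):
                assert abs(got - want) <= 1e-6 * scale

    def test_mass_conservation_random_draws(self, rng):
        """Both balances hold to 1e-8 relative over 1000 random draws."""
        for _ in range(1000):
            l_tot = 10 ** rng.uniform(-8, -3)
            m_tot = 10 ** rng.uniform(-8, -3)
            model = lf.BindingModel(10 ** rng.uniform(-9, -3),
                                    10 ** rng.uniform(-9, -2))
            st_ = lf.solve_speciation(
                lf.MixtureComposition(l_tot=l_tot, m_tot=m_tot), model)
            assert abs(st_.free_m + st_.c_lm + 2 * st_.c_lm2 - m_tot) <= 1e-8 * m_tot
            assert abs(st_.free_l + st_.c_lm + st_.c_lm2 - l_tot) <= 1e-8 * l_tot

    @given(kd_hi=st.floats(1e-7, 1e-4), factor=st.floats(0.01, 0.99))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_tighter_binding_never_unbinds(self, kd_hi, factor):
        comp = lf.MixtureComposition(l_tot=10 * UM, m_tot=10 * UM)
        loose = lf.solve_speciation(comp, lf.BindingModel(kd_hi, 10 * kd_hi))
        tight = lf.solve_speciation(comp, lf.BindingModel(kd_hi * factor,
                                                          10 * kd_hi * factor))
        assert tight.c_lm + tight.c_lm2 >= loose.c_lm + loose.c_lm2 - 1e-15

    @given(m1=st.floats(1e-7, 5e-5), scale=st.floats(1.01, 10.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_more_metal_never_less_bound(self, m1, scale):
        model = lf.BindingModel(0.5 * UM, 1.1 * UM)
        a = lf.solve_speciation(lf.MixtureComposition(l_tot=10 * UM, m_tot=m1), model)
        b = lf.solve_speciation(lf.MixtureComposition(l_tot=10 * UM, m_tot=m1 * scale),
                                model)
        assert b.bound_m >= a.bound_m - 1e-15

    def test_infinite_kd12_reduces_to_single_site_quadratic(self, rng):
        """kd_12 -> inf equals the closed-form 1:1 quadratic solution."""
        for _ in range(50):
            l_tot = 10 ** rng.uniform(-7, -4)
            m_tot = 10 ** rng.uniform(-7, -4)
            kd = 10 ** rng.uniform(-8, -4)
            st_ = lf.solve_speciation(
                lf.MixtureComposition(l_tot=l_tot, m_tot=m_tot),
                lf.BindingModel(kd))
            # [LM] from the standard quadratic for L + M <-> LM
            b = l_tot + m_tot + kd
            c_lm = (b - math.sqrt(b * b - 4 * l_tot * m_tot)) / 2
            assert st_.c_lm == pytest.approx(c_lm, rel=1e-8, abs=1e-20)
            assert st_.c_lm2 == 0.0

    def test_input_validation(self):
        with pytest.raises(InputError):
            lf.BindingModel(-1.0)
        with pytest.raises(InputError):
            lf.BindingModel(math.nan)
        with pytest.raises(InputError):
            lf.MixtureComposition(l_tot=-1e-6, m_tot=0.0)
        with pytest.raises(InputError):
            lf.MixtureComposition(l_tot=1e-6, m_tot=1e-6, n_tot=1e-6)  # no model
        comp = lf.MixtureComposition(
            l_tot=1e-6, m_tot=1e-6, n_tot=1e-6,
            competitor_model=lf.BindingModel(1e-6))
        with pytest.raises(InputError):
            lf.solve_speciation(comp, lf.BindingModel(1e-6))


def grid_refine_competition(l_tot, m_tot, n_tot, model, nmodel,
                            rounds=14, n_grid=41):
    """Independent 2-D oracle: iterative grid refinement on (free_m, free_n)."""
    def balances(m, n):
        bm = m / model.kd_11 + m * m / (model.kd_11 * model.kd_12)
        bn = n / nmodel.kd_11 + n * n / (nmodel.kd_11 * nmodel.kd_12)
        L = l_tot / (1 + bm + bn)
        gm = m + L * (m / model.kd_11 + 2 * m * m / (model.kd_11 * model.kd_12)) - m_tot
        gn = n + L * (n / nmodel.kd_11 + 2 * n * n / (nmodel.kd_11 * nmodel.kd_12)) - n_tot
        return gm, gn
    m_lo, m_hi, n_lo, n_hi = 0.0, m_tot, 0.0, n_tot
    best = (0.0, 0.0)
    for _ in range(rounds):
        ms = np.linspace(m_lo, m_hi, n_grid)
        ns = np.linspace(n_lo, n_hi, n_grid)
        err = np.empty((n_grid, n_grid))
        for i, m in enumerate(ms):
            for j, n in enumerate(ns):
                gm, gn = balances(m, n)
                err[i, j] = gm * gm + gn * gn
        i, j = np.unravel_index(np.argmin(err), err.shape)
        best = (ms[i], ns[j])
        # keep a generous window: the SSE valley can be shallow and curved
        dm, dn = (m_hi - m_lo) / (n_grid - 1), (n_hi - n_lo) / (n_grid - 1)
        m_lo, m_hi = max(0.0, ms[i] - 3 * dm), min(m_tot, ms[i] + 3 * dm)
        n_lo, n_hi = max(0.0, ns[j] - 3 * dn), min(n_tot, ns[j] + 3 * dn)
    return best


class TestCompetitionSpeciation:
    def test_degenerates_to_single_metal(self):
        comp = lf.MixtureComposition(l_tot=10 * UM, m_tot=10 * UM)
        model = lf.BindingModel(0.5 * UM, 1.1 * UM)
        a = lf.solve_competition_speciation(comp, model)
        b = lf.solve_speciation(comp, model)
        assert a == b

    def test_exchange_symmetry_identical_metals(self):
        model = lf.BindingModel(0.5 * UM, 1.1 * UM)
        comp = lf.MixtureComposition(
            l_tot=10 * UM, m_tot=10 * UM, n_tot=10 * UM,
            competitor_model=lf.BindingModel(0.5 * UM, 1.1 * UM))
        st_ = lf.solve_competition_speciation(comp, model)
        assert st_.c_lm == pytest.approx(st_.c_ln, rel=1e-8)
        assert st_.c_lm2 == pytest.approx(st_.c_ln2, rel=1e-8)
        assert st_.free_m == pytest.approx(st_.free_n, rel=1e-8)

    def test_stronger_competitor_frees_primary_metal(self):
        """2-D grid-refinement oracle on the reference competition mixture."""
        model = lf.BindingModel(0.5 * UM, 5 * UM)
        nmodel = lf.BindingModel(0.05 * UM, 0.5 * UM)
        single = lf.solve_speciation(
            lf.MixtureComposition(l_tot=10 * UM, m_tot=10 * UM), model)
        comp = lf.MixtureComposition(l_tot=10 * UM, m_tot=10 * UM, n_tot=10 * UM,
                                     competitor_model=nmodel)
        st_ = lf.solve_competition_speciation(comp, model)
        assert st_.free_m > single.free_m  # competitor displaces Eu to aquo
        m_ref, n_ref = grid_refine_competition(10 * UM, 10 * UM, 10 * UM,
                                               model, nmodel)
        assert st_.free_m == pytest.approx(m_ref, rel=1e-5)
        assert st_.free_n == pytest.approx(n_ref, rel=1e-5)

    def test_all_balances_random_instances(self, rng):
        for _ in range(25):
            model = lf.BindingModel(10 ** rng.uniform(-8, -5),
                                    10 ** rng.uniform(-7, -4))
            nmodel = lf.BindingModel(10 ** rng.uniform(-8, -5),
                                     10 ** rng.uniform(-7, -4))
            l_tot, m_tot, n_tot = (10 ** rng.uniform(-6, -4) for _ in range(3))
            comp = lf.MixtureComposition(l_tot=l_tot, m_tot=m_tot, n_tot=n_tot,
                                         competitor_model=nmodel)
            st_ = lf.solve_competition_speciation(comp, model)
            assert abs(st_.free_m + st_.c_lm + 2 * st_.c_lm2 - m_tot) <= 1e-8 * m_tot
            assert abs(st_.free_n + st_.c_ln + 2 * st_.c_ln2 - n_tot) <= 1e-8 * n_tot
            lig = st_.free_l + st_.c_lm + st_.c_lm2 + st_.c_ln + st_.c_ln2
            assert abs(lig - l_tot) <= 1e-8 * l_tot


class TestTitrationPath:
    def test_buffer_addition_dilutes_only(self):
        prot = TitrationProtocol(cell_volume_ul=100.0, cell={"l": 10 * UM},
                                 syringe={}, injection_volumes_ul=(25.0,),
                                 mode="additive")
        path = lf.titration_path(prot)
        assert path[1].l_tot == pytest.approx(10 * UM * 100.0 / 125.0)

    def test_zero_volume_injections_are_identity(self):
        prot = TitrationProtocol(cell_volume_ul=200.0, cell={"l": 30 * UM},
                                 syringe={"m": 900 * UM},
                                 injection_volumes_ul=(0.0, 0.0))
        path = lf.titration_path(prot)
        assert all(c.l_tot == 30 * UM and c.m_tot == 0.0 for c in path)

    def test_overflow_bookkeeping_matches_step_oracle(self):
        """25 x 2 µL of 900 µM metal into a 200 µL cell at 30 µM peptide."""
        prot = TitrationProtocol(cell_volume_ul=200.0, cell={"l": 30 * UM},
                                 syringe={"m": 900 * UM},
                                 injection_volumes_ul=(2.0,) * 25)
        path = lf.titration_path(prot)
        # independent spreadsheet-style recursion of the displacement model
        l, m, V = 30 * UM, 0.0, 200.0
        for i, v in enumerate((2.0,) * 25, start=1):
            l = l * (V - v / 2) / (V + v / 2)
            m = (m * (V - v / 2) + 900 * UM * v) / (V + v / 2)
            assert path[i].l_tot == pytest.approx(l, rel=1e-12)
            assert path[i].m_tot == pytest.approx(m, rel=1e-12)
        assert path[25].m_tot < 900 * UM * 50.0 / 200.0  # displacement loss

    def test_overfill_raises_protocol_error(self):
        with pytest.raises(ProtocolError):
            TitrationProtocol(cell_volume_ul=100.0, cell={}, syringe={},
                              injection_volumes_ul=(30.0, 30.0))
        with pytest.raises(ProtocolError):
            TitrationProtocol(cell_volume_ul=100.0, cell={}, syringe={},
                              injection_volumes_ul=())
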