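import math

import numpy as np
import pytest

from igpbpk.engine import (DoseRegimen, DrugProperties, build_model, simulate,
                           terminal_half_life)
from igpbpk.fcrn import FcRnParameters
from igpbpk.physiology import PERFUSED_TISSUES

FCRN = FcRnParameters(k_rec=0.12, k_deg=10.0)


def mab(**kw):
    base = dict(name="test-mab", modality="mAb", mw=150_000.0,
                kd_human_fcrn=0.7)
    base.update(kw)
    return DrugProperties(**base)


IV = DoseRegimen(route="iv_infusion", dose_mg_per_kg=5.0, infusion_duration=1.0)


class TestBuildModel:
    def test_monkey_kd_species_scaling(self, monkey_phys):
        model = build_model(monkey_phys, mab(kd_human_fcrn=1.0), FCRN)
        assert math.isclose(model.kd_eff, 0.45, rel_tol=1e-12)

    def test_human_kd_unscaled(self, human_phys):
        model = build_model(human_phys, mab(kd_human_fcrn=1.0), FCRN)
        assert model.kd_eff == 1.0

    def test_flow_matrix_balances_by_brute_force(self, human_phys):
        model = build_model(human_phys, mab(), FCRN)
        lu = model.lung_idx
        # arterial inflow (lung outflow) equals summed parallel tissue inflow
        q_par = sum(model.q[i] for i in range(len(PERFUSED_TISSUES)) if i != lu)
        assert math.isclose(model.q[lu] - model.lymph[lu], q_par, rel_tol=1e-9)
        # venous inflow equals venous outflow at steady fluid flow
        ven_in = q_par - sum(model.lymph[i] for i in
                             range(len(PERFUSED_TISSUES)) if i != lu) \
            + model.lymph.sum()
        assert math.isclose(ven_in, model.q[lu], rel_tol=1e-9)

    def test_modality_constraints(self):
        with pytest.raises(ValueError, match="renal"):
            mab(cl_renal=0.1).validate()
        with pytest.raises(ValueError, match="deconjugation"):
            mab(k_deconj=0.01).validate()
        DrugProperties(name="b", modality="BiTCE", mw=55_000.0,
                       kd_human_fcrn=0.5, cl_renal=0.1).validate()

    def test_only_catabolism_without_optional_pathways(self, human_phys):
        model = build_model(human_phys, mab(cl_add=0.0), FCRN)
        res = simulate(model, IV, t_end=48.0)
        elim = res.cumulative_eliminated()
        assert elim["catabolism"][-1] > 0
        for p in ("additional", "renal", "deconjugation"):
            assert elim[p][-1] == 0.0


class TestSimulate:
    def test_zero_dose_gives_zero_profile(self, human_phys):
        model = build_model(human_phys, mab(), FCRN)
        reg = DoseRegimen(route="iv_infusion", dose_mg=0.0,
                          infusion_duration=1.0)
        res = simulate(model, reg, t_end=24.0)
        assert np.all(res.plasma_conc_uM == 0.0)
        assert np.all(res.y == 0.0)

    def test_closed_form_monoexponential(self, human_phys):
        # all distribution and FcRn disabled; IV bolus + only cl_add
        cl = 0.05
        model = build_model(human_phys, mab(cl_add=cl), FCRN, plasma_only=True)
        reg = DoseRegimen(route="iv_infusion", dose_mg=350.0,
                          infusion_duration=1e-6)
        res = simulate(model, reg, t_end=300.0, rtol=1e-10, atol=1e-14)
        vp = human_phys.v_venous + human_phys.v_arterial
        d_umol = 350.0 / 150_000.0 * 1000.0
        sel = res.t >= 1e-6
        expected = d_umol / vp * np.exp(-cl * (res.t[sel]) / vp)
        assert np.allclose(res.plasma_conc_uM[sel], expected, rtol=1e-3)

    def test_mass_balance_conservation(self, human_phys):
        model = build_model(human_phys, mab(cl_add=0.01), FCRN)
        res = simulate(model, IV, t_end=500.0, rtol=1e-10, atol=1e-13)
        assert res.mass_balance_error() < 1e-6

    def test_dose_linearity_in_nonsaturating_regime(self, human_phys):
        model = build_model(human_phys, mab(cl_add=0.005), FCRN)
        grids = np.linspace(0, 300, 61)
        lo = simulate(model, DoseRegimen(route="iv_infusion",
                                         dose_mg_per_kg=0.1,
                                         infusion_duration=1.0),
                      t_end=300.0, t_eval=grids)
        hi = simulate(model, DoseRegimen(route="iv_infusion",
                                         dose_mg_per_kg=0.2,
                                         infusion_duration=1.0),
                      t_end=300.0, t_eval=grids)
        sel = lo.plasma_conc_uM > 0
        ratio = hi.plasma_conc_uM[sel] / lo.plasma_conc_uM[sel]
        assert np.all(np.abs(ratio - 2.0) < 2e-3 * 2.0)

    def test_cl_add_reduces_auc_and_weak_binding_reduces_auc(self, human_phys):
        t_eval = np.linspace(0, 500, 101)

        def auc(drug):
            model = build_model(human_phys, drug, FCRN)
            res = simulate(model, IV, t_end=500.0, t_eval=t_eval)
            return np.trapezoid(res.plasma_conc_uM, res.t)

        base = auc(mab(cl_add=0.0))
        assert auc(mab(cl_add=0.02)) < base
        assert auc(mab(kd_human_fcrn=7.0)) < auc(mab(kd_human_fcrn=0.7))

    def test_sc_complete_absorption_approaches_iv(self, human_phys):
        model = build_model(human_phys, mab(cl_add=0.01), FCRN)
        # fine early grid so the trapezoidal AUC resolves the IV bolus spike
        t_eval = np.union1d(np.geomspace(1e-3, 400, 160),
                            np.linspace(0, 400, 81))
        sc = DoseRegimen(route="sc", dose_mg=100.0, ka=50.0, f_sc=1.0)
        res_sc = simulate(model, sc, t_end=400.0, t_eval=t_eval, rtol=1e-9)
        # everything leaves the depot and nothing is lost presystemically
        assert res_sc.cumulative_eliminated()["presystemic_loss"][-1] == 0.0
        depot_left = res_sc.y[-1, res_sc.labels.index("sc_depot")]
        dose_umol = 100.0 / 150_000.0 * 1000.0
        assert depot_left < 1e-6 * dose_umol
        iv = DoseRegimen(route="iv_infusion", dose_mg=100.0,
                         infusion_duration=1e-4)
        res_iv = simulate(model, iv, t_end=400.0, t_eval=t_eval, rtol=1e-9)
        auc_sc = np.trapezoid(res_sc.plasma_conc_uM, res_sc.t)
        auc_iv = np.trapezoid(res_iv.plasma_conc_uM, res_iv.t)
        assert math.isclose(auc_sc, auc_iv, rel_tol=0.01)

    def test_sc_bioavailability_partitions_dose(self, human_phys):
        model = build_model(human_phys, mab(cl_add=0.005), FCRN)
        sc = DoseRegimen(route="sc", dose_mg=100.0, ka=0.02, f_sc=0.6)
        res = simulate(model, sc, t_end=2000.0)
        dose_umol = 100.0 / 150_000.0 * 1000.0
        lost = res.cumulative_eliminated()["presystemic_loss"][-1]
        assert math.isclose(lost, 0.4 * dose_umol, rel_tol=1e-3)

    def test_t_end_before_last_dose_rejected(self, human_phys):
        model = build_model(human_phys, mab(), FCRN)
        reg = DoseRegimen(route="iv_infusion", dose_mg=10.0,
                          infusion_duration=1.0, dose_times=(0.0, 168.0))
        with pytest.raises(ValueError, match="beyond the last dose"):
            simulate(model, reg, t_end=100.0)

    def test_multiple_dose_administration_bookkeeping(self, human_phys):
        model = build_model(human_phys, mab(cl_add=0.01), FCRN)
        reg = DoseRegimen(route="iv_infusion", dose_mg=70.0,
                          infusion_duration=2.0, dose_times=(0.0, 72.0, 144.0))
        res = simulate(model, reg, t_end=400.0)
        dose_umol = 3 * 70.0 / 150_000.0 * 1000.0
        assert math.isclose(res.administered[-1], dose_umol, rel_tol=1e-12)
        assert res.mass_balance_error() < 1e-6


class TestTerminalHalfLife:
    def test_monoexponential_exact(self):
        k = 0.01
        t = np.linspace(0, 600, 50)
        assert math.isclose(terminal_half_life(t, 5 * np.exp(-k * t)),
                            math.log(2) / k, rel_tol=1e-9)

    def test_doubling_clearance_halves_half_life(self, human_phys):
        th = {}
        for cl in (0.02, 0.04):
            model = build_model(human_phys, mab(cl_add=cl), FCRN,
                                plasma_only=True)
            reg = DoseRegimen(route="iv_infusion", dose_mg=100.0,
                              infusion_duration=0.5)
            res = simulate(model, reg, t_end=600.0)
            th[cl] = terminal_half_life(res)
        assert math.isclose(th[0.02], 2 * th[0.04], rel_tol=1e-6)

    def test_biexponential_terminal_slope_recovered(self):
        t = np.linspace(0, 1000, 200)
        c = 8 * np.exp(-0.05 * t) + 2 * np.exp(-0.004 * t)
        assert math.isclose(terminal_half_life(t, c), math.log(2) / 0.004,
                            rel_tol=0.01)

    def test_rising_profile_rejected(self):
        t = np.linspace(0, 10, 20)
        with pytest.raises(ValueError, match="not decreasing"):
            terminal_half_life(t, np.exp(0.1 * t))
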