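import math

import numpy as np
import pytest

from pkautoinit.dataio import PooledProfile, annotate_doses, parse_dataset, \
    pool_observations
from pkautoinit.fixtures import generate_dataset
from pkautoinit.nca import auc_linuplogdown, modal_tau, nca_onecpt, \
    wagner_nelson_ka
from pkautoinit.terminal_phase import fit_lambda_z

from conftest import make_design, mono_exp_profile


class TestAUC:
    def test_linear_up_then_log_down(self):
        # rising 0->10 linear (5), falling 10->5 logarithmic (5/ln2)
        assert auc_linuplogdown([0, 1, 2], [0, 10, 5]) == pytest.approx(
            5 + 5 / math.log(2), abs=1e-4
        )

    def test_constant_profile_is_rectangle(self):
        assert auc_linuplogdown([0, 3], [4, 4]) == pytest.approx(12.0)

    def test_single_point_undefined(self):
        with pytest.raises(ValueError):
            auc_linuplogdown([1.0], [5.0])

    def test_fall_to_zero_uses_linear_rule(self):
        assert auc_linuplogdown([0, 2], [4, 0]) == pytest.approx(4.0)

    def test_bracketed_by_pure_rules_on_falling_segment(self):
        # log trapezoid < lin-up/log-down(=log here) < linear trapezoid
        t, c = [0.0, 1.0], [10.0, 5.0]
        log_t = (10 - 5) / math.log(2)
        lin_t = 7.5
        v = auc_linuplogdown(t, c)
        assert log_t <= v <= lin_t

    def test_exponential_auc_close_to_analytic(self):
        t = np.linspace(0, 50, 200)
        c = 5 * np.exp(-0.1 * t)
        assert auc_linuplogdown(t, c) == pytest.approx(
            5 / 0.1 * (1 - math.exp(-5.0)), rel=1e-4
        )


def _pooled(df, group="first_dose", n_bins=50):
    doses, obs = annotate_doses(parse_dataset(df))
    return pool_observations(obs, group, n_bins), doses, obs


class TestNCAOneCpt:
    def test_bolus_closed_form_cl_and_vz(self):
        spec = make_design("bolus", cl=2.0, vc=20.0, sampling="custom",
                           n_subjects=3)
        spec.custom_times = tuple(np.geomspace(0.1, 60, 50))
        prof, doses, obs = _pooled(generate_dataset(spec))
        fit = fit_lambda_z(prof)
        est = nca_onecpt(prof, fit, "bolus", multiple=False)
        assert est.cl == pytest.approx(2.0, rel=0.02)  # AUC = Dose/CL
        assert est.v == pytest.approx(20.0, rel=0.02)

    def test_doubling_concentrations_halves_cl(self):
        prof = mono_exp_profile(c0=0.05, ke=0.1, times=np.linspace(0.5, 40, 30))
        fit = fit_lambda_z(prof)
        est1 = nca_onecpt(prof, fit, "bolus")
        prof2 = PooledProfile(group=prof.group, tad=prof.tad,
                              conc=2 * prof.conc, n_points=prof.n_points)
        est2 = nca_onecpt(prof2, fit_lambda_z(prof2), "bolus")
        assert est2.cl == pytest.approx(est1.cl / 2, rel=1e-9)

    def test_modal_tau_prefers_most_frequent_interval(self):
        rows = ["ID,TIME,AMT,EVID,DV"]
        for sid in range(1, 10):  # 9 subjects q12h
            rows += [f"{sid},0,100,1,.", f"{sid},12,100,1,.",
                     f"{sid},24,100,1,.", f"{sid},26,0,0,1"]
        for sid in (10, 11):  # 2 subjects q24h
            rows += [f"{sid},0,100,1,.", f"{sid},24,100,1,.",
                     f"{sid},26,0,0,1"]
        doses, _ = annotate_doses(parse_dataset("\n".join(rows) + "\n"))
        assert modal_tau(doses) == 12.0

    def test_multiple_dose_auc_tau_recovers_cl(self):
        # steady state q12h bolus: AUC_0-tau equals Dose/CL exactly
        spec = make_design("bolus", cl=2.0, vc=20.0, dosing=(100.0, 12.0, 30),
                           sampling="custom", n_subjects=3)
        spec.custom_times = tuple(np.linspace(0.0, 12.0, 25))
        df = generate_dataset(spec)
        doses, obs = annotate_doses(parse_dataset(df))
        prof = pool_observations(obs, "multi_dose", 25)
        fit = fit_lambda_z(prof)
        est = nca_onecpt(prof, fit, "bolus", multiple=True, tau=12.0)
        assert est.cl == pytest.approx(2.0, rel=0.02)


class TestWagnerNelson:
    def test_dense_noise_free_oral_recovers_ka(self):
        ka, ke = 1.5, 0.1
        t = np.concatenate([np.arange(0.05, 4.0, 0.05), np.linspace(4, 60, 100)])
        c = ka / (20 * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
        prof = PooledProfile(group="first_dose", tad=t, conc=c,
                             n_points=np.ones(len(t), dtype=int))
        est = wagner_nelson_ka(prof, ke)
        assert est == pytest.approx(ka, rel=0.02)

    def test_single_prepeak_point_unavailable(self):
        prof = PooledProfile(
            group="first_dose", tad=np.array([1.0, 2.0, 6.0]),
            conc=np.array([1.0, 2.0, 1.2]), n_points=np.ones(3, dtype=int),
        )
        assert wagner_nelson_ka(prof, 0.1) is None

    def test_dose_scale_invariance(self):
        ka, ke = 0.9, 0.08
        t = np.linspace(0.1, 48, 120)
        c = ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
        p1 = PooledProfile("first_dose", t, c, np.ones(len(t), dtype=int))
        p2 = PooledProfile("first_dose", t, 7 * c, np.ones(len(t), dtype=int))
        assert wagner_nelson_ka(p1, ke) == pytest.approx(
            wagner_nelson_ka(p2, ke), rel=1e-9
        )

    def test_fraction_absorbed_monotone_on_clean_data(self):
        ka, ke = 1.2, 0.1
        t = np.linspace(0.05, 40, 200)
        c = ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t))])
        auc_inf = cum[-1] + c[-1] / ke
        frac = (c + ke * cum) / (ke * auc_inf)
        assert np.all(np.diff(frac) > -1e-9)
        assert frac[-1] == pytest.approx(1.0, abs=0.01)
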