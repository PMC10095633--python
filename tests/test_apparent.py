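"""Naive analysis models and least-squares fitting."""

import numpy as np
import pytest
from scipy.optimize import brentq

from lipidbind import (
    SystemComposition,
    TitrationDataset,
    eval_eq6,
    eval_eq7,
    fit,
    generate_titration,
    solve_dilute,
)
from lipidbind.equilibrium import distribution_curve
from lipidbind.scenarios import SyntheticSpec


def noiseless_dataset(keq=1e6, kp=1e3, pt=1e-5, alpha_lb=0.01, n=20):
    lt = np.logspace(np.log10(0.01 / keq), np.log10(100 / keq), n)
    res = distribution_curve(keq, kp, lt, pt, alpha_lb, 0.0, general=True)
    return TitrationDataset(
        lt_values=lt,
        observed=res["saturation"],
        pt_molar=pt,
        alpha_lb=alpha_lb,
        kp_lb_lw=kp,
    )


class TestEvalEq6:
    def test_no_protein_no_binding(self):
        assert eval_eq6(1e6, 0.0, 1e-6) == 0.0

    def test_matches_dilute_solver_without_lipid(self):
        comp = SystemComposition(ligand_total=3e-6, protein_total=1e-6)
        expected = solve_dilute(1e6, 0.0, comp).l_p
        assert eval_eq6(1e6, 1e-6, 3e-6) == pytest.approx(expected, rel=1e-12)

    def test_depletion_case_against_bisection(self):
        keq, pt, lt = 1e6, 1e-5, 1e-5

        def residual(lw):
            return keq * lw**2 + (1 - keq * (lt - pt)) * lw - lt

        lw = brentq(residual, 0.0, lt, xtol=1e-25, rtol=8.9e-16)
        assert eval_eq6(keq, pt, lt) == pytest.approx(lt - lw, rel=1e-10)

    def test_bound_within_physical_limits(self):
        lt = np.logspace(-8, -3, 30)
        lp = np.asarray(eval_eq6(1e7, 1e-6, lt))
        assert np.all(lp >= 0)
        assert np.all(lp <= np.minimum(lt, 1e-6) + 1e-20)


class TestEvalEq7:
    def test_half_saturation(self):
        assert eval_eq7(1e6, 1e-5, 1e-6) == pytest.approx(5e-6, rel=1e-12)

    def test_saturation_limit(self):
        assert eval_eq7(1e6, 1e-5, 10.0) == pytest.approx(1e-5, rel=1e-6)


class TestFit:
    def test_eq6_self_consistency_noiseless(self):
        lt = np.logspace(-8, -4, 20)
        sat = np.asarray(eval_eq6(1e6, 1e-5, lt)) / 1e-5
        ds = TitrationDataset(lt_values=lt, observed=sat, pt_molar=1e-5)
        r = fit(ds, "eq6")
        assert r.converged
        assert r.estimates["keq_app_lw"] == pytest.approx(1e6, rel=1e-6)

    def test_eq7_self_consistency_noiseless(self):
        lt = np.logspace(-8, -4, 20)
        sat = np.asarray(eval_eq7(2e5, 1e-6, lt)) / 1e-6
        ds = TitrationDataset(lt_values=lt, observed=sat, pt_molar=1e-6)
        r = fit(ds, "eq7")
        assert r.estimates["keq_app_lt"] == pytest.approx(2e5, rel=1e-6)

    def test_eq6_on_lipid_data_matches_bias_prediction(self):
        # apparent constant from the lipid-neglecting fit lands on
        # Keq/(1 + KP*alpha_Lb) within 1% in the dilute regime
        keq, kp, alb = 1e6, 1e3, 0.005
        r = fit(noiseless_dataset(keq=keq, kp=kp, alpha_lb=alb), "eq6")
        assert r.estimates["keq_app_lw"] == pytest.approx(keq / (1 + kp * alb), rel=0.01)

    def test_eq7_worse_than_eq6_on_lipid_data(self):
        ds = noiseless_dataset()
        r6, r7 = fit(ds, "eq6"), fit(ds, "eq7")
        assert r7.rss > r6.rss
        # systematic residual structure: long runs of one sign
        signs = np.sign(r7.residuals[np.abs(r7.residuals) > 1e-12])
        assert np.max(np.abs(np.cumsum(signs))) >= len(ds) / 4

    def test_eq7_apparent_affinity_falls_with_protein_concentration(self):
        estimates = []
        for pt in (1e-6, 1e-5, 1e-4):
            r = fit(noiseless_dataset(pt=pt), "eq7")
            estimates.append(r.estimates["keq_app_lt"])
        assert estimates[0] > estimates[1] > estimates[2]

    def test_full_model_recovers_intrinsic_constant(self):
        r = fit(noiseless_dataset(), "full")
        assert r.estimates["keq_lw"] == pytest.approx(1e6, rel=1e-6)

    def test_full_model_requires_composition_metadata(self):
        ds = noiseless_dataset()
        ds.kp_lb_lw = None
        with pytest.raises(ValueError, match="kp_lb_lw"):
            fit(ds, "full")

    def test_degenerate_constant_response_rejected(self):
        ds = TitrationDataset(
            lt_values=np.array([1e-6, 2e-6, 3e-6]),
            observed=np.array([0.5, 0.5, 0.5]),
            pt_molar=1e-6,
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit(ds, "eq6")

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model_id"):
            fit(noiseless_dataset(), "eq9")

    def test_noisy_recovery_within_three_stderr(self):
        spec = SyntheticSpec(
            keq_lw=1e6, kp_lb_lw=1e3, pt_molar=1e-5, alpha_lb=0.01, seed=42
        )
        r = fit(generate_titration(spec), "full")
        assert r.converged
        err = abs(r.estimates["keq_lw"] - 1e6)
        assert err <= 3 * r.stderr["keq_lw"]


class TestTitrationDataset:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(lt_values=[1e-6, 2e-6], observed=[0.1, 0.2], pt_molar=1e-6), "3"),
            (
                dict(lt_values=[1e-6, 2e-6, -1e-6], observed=[0.1, 0.2, 0.3], pt_molar=1e-6),
                "positive",
            ),
            (
                dict(lt_values=[1e-6, 2e-6, 3e-6], observed=[0.1, 0.2], pt_molar=1e-6),
                "length",
            ),
            (
                dict(
                    lt_values=[1e-6, 2e-6, 3e-6],
                    observed=[0.1, 0.2, 0.3],
                    pt_molar=1e-6,
                    response_kind="banana",
                ),
                "response_kind",
            ),
        ],
    )
    def test_invariants_enforced(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            TitrationDataset(**{k: np.asarray(v) if isinstance(v, list) else v for k, v in kwargs.items()})
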