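"""Three-compartment equilibrium solvers against an independent oracle."""

import numpy as np
import pytest

from lipidbind import (
    DiluteRegimeWarning,
    ProteinSpec,
    SystemComposition,
    saturation_curve,
    solve_dilute,
    solve_general,
)


def comp(lt, pt=0.0, alpha_lb=0.0, protein=None):
    return SystemComposition(
        ligand_total=lt, protein_total=pt, lipid_volume_fraction=alpha_lb, protein=protein
    )


class TestDiluteSolver:
    def test_no_binding_agents_leaves_ligand_free(self):
        r = solve_dilute(1e6, 0.0, comp(1e-5))
        assert r.l_w == pytest.approx(1e-5, rel=1e-12)
        assert r.l_lb == 0.0 and r.l_p == 0.0

    def test_reference_case_against_bisection(self, oracle):
        # Keq=1e6, KP=1e3, PT=LT=10 uM, 1% lipid: frozen oracle values
        r = solve_dilute(1e6, 1e3, comp(1e-5, 1e-5, 0.01))
        assert r.l_w == pytest.approx(5.727622878795812e-07, rel=1e-9)
        assert r.l_lb == pytest.approx(5.785477655349304e-06, rel=1e-9)
        assert r.l_p == pytest.approx(3.6417600567711146e-06, rel=1e-9)
        lw, llb, lp = oracle(1e6, 1e3, 1e-5, 1e-5, 0.01)
        assert r.l_w == pytest.approx(lw, rel=1e-10)

    def test_vanishing_ligand_limit(self):
        r = solve_dilute(1e6, 1e3, comp(0.0, 1e-5, 0.01))
        assert r.l_w == r.l_lb == r.l_p == 0.0
        assert r.saturation == 0.0

    def test_warns_outside_dilute_regime(self):
        with pytest.warns(DiluteRegimeWarning):
            solve_dilute(1e6, 10.0, comp(1e-6, 1e-6, 0.05))

    def test_lipid_ratio_consistency(self):
        # L_Lb / L_W = KP * V_Lb / V_W exactly on output
        alpha_lb = 0.01
        r = solve_dilute(1e6, 1e3, comp(1e-5, 1e-5, alpha_lb))
        assert r.l_lb / r.l_w == pytest.approx(1e3 * alpha_lb / (1 - alpha_lb), rel=1e-12)


class TestGeneralSolver:
    def test_reduces_to_pure_binding_without_lipid(self, oracle):
        r = solve_general(1e6, 0.0, comp(1e-5, 1e-5))
        lw, _, lp = oracle(1e6, 0.0, 1e-5, 1e-5, 0.0, general=True)
        assert r.l_w == pytest.approx(lw, rel=1e-10)
        assert r.l_p == pytest.approx(lp, rel=1e-8)

    def test_agrees_with_dilute_in_validity_region(self):
        c = comp(1e-5, 1e-6, 1e-3, protein=ProteinSpec(50_000))
        rg = solve_general(1e6, 1e3, c)
        rd = solve_dilute(1e6, 1e3, c)
        for fld in ("l_w", "l_lb", "l_p"):
            assert getattr(rg, fld) == pytest.approx(getattr(rd, fld), rel=1e-3)

    def test_polar_ligand_exclusion_raises_saturation(self):
        # a ligand excluded from the lipid (KP < 1) concentrates in water
        protein = ProteinSpec(50_000)
        base = solve_general(1e6, 0.1, comp(1e-6, 1e-6, 0.0, protein))
        lipid = solve_general(1e6, 0.1, comp(1e-6, 1e-6, 0.10, protein))
        assert lipid.saturation > base.saturation

    def test_conservation_and_oracle_equivalence_over_draws(self, oracle, random_systems):
        keqs, kps = random_systems["keq"], random_systems["kp"]
        albs, pts, lts = random_systems["alpha_lb"], random_systems["pt"], random_systems["lt"]
        for keq, kp, alb, pt, lt in zip(keqs, kps, albs, pts, lts):
            r = solve_general(keq, kp, comp(lt, pt, alb))
            # mass and protein conservation
            assert r.l_w + r.l_lb + r.l_p == pytest.approx(lt, rel=1e-10)
            assert r.l_p + r.p_free == pytest.approx(pt, rel=1e-10, abs=1e-25)
            assert r.l_w >= 0 and r.l_lb >= 0 and r.l_p >= 0
            assert 0.0 <= r.saturation <= 1.0 + 1e-12
            # closed-form root matches bisection
            lw_oracle, _, _ = oracle(keq, kp, pt, lt, alb, general=True)
            assert r.l_w == pytest.approx(lw_oracle, rel=1e-8)


class TestMonotonicity:
    def test_saturation_nondecreasing_in_lt_and_keq(self):
        protein = ProteinSpec(50_000)
        lts = np.logspace(-8, -4, 25)
        sats = [solve_general(1e6, 1e3, comp(lt, 1e-6, 0.01, protein)).saturation for lt in lts]
        assert np.all(np.diff(sats) >= -1e-14)
        keqs = np.logspace(3, 9, 25)
        sats = [solve_general(k, 1e3, comp(1e-6, 1e-6, 0.01, protein)).saturation for k in keqs]
        assert np.all(np.diff(sats) >= -1e-14)

    @pytest.mark.parametrize("kp, sign", [(1e3, -1), (0.1, +1)])
    def test_saturation_vs_lipid_volume_depends_on_lipophilicity(self, kp, sign):
        # sequestration (KP > 1) lowers saturation; exclusion (KP < 1) raises it
        protein = ProteinSpec(50_000)
        albs = np.linspace(0.0, 0.15, 16)
        sats = [solve_general(1e6, kp, comp(1e-6, 1e-6, a, protein)).saturation for a in albs]
        diffs = np.diff(sats)
        assert np.all(sign * diffs >= -1e-14)


class TestSaturationCurve:
    def test_single_point_matches_solver(self):
        template = comp(1e-9, 1e-6, 0.01)
        [(lt, sat)] = saturation_curve(1e6, 1e3, template, [1e-6])
        assert sat == pytest.approx(
            solve_general(1e6, 1e3, comp(1e-6, 1e-6, 0.01)).saturation, rel=1e-12
        )

    def test_curves_ordered_by_lipid_volume(self):
        # more lipid -> lower saturation at every total-ligand value
        lts = np.logspace(-7, -3, 15)
        prev = None
        for alb in (0.0, 1e-3, 1e-2, 5e-2):
            template = comp(1e-9, 1e-5, alb, ProteinSpec(50_000))
            sats = np.array([s for _, s in saturation_curve(1e6, 1e3, template, lts)])
            if prev is not None:
                assert np.all(sats <= prev + 1e-12)
            prev = sats

    def test_half_saturation_at_reciprocal_keq_without_lipid(self):
        # PT -> 0: saturation = Keq*LT/(1+Keq*LT), half at LT = 1/Keq
        template = comp(1e-9, 1e-12, 0.0)
        [(_, sat)] = saturation_curve(1e6, 0.0, template, [1e-6])
        assert sat == pytest.approx(0.5, rel=1e-4)

    def test_empty_or_invalid_grid_rejected(self):
        template = comp(1e-9, 1e-6, 0.0)
        with pytest.raises(ValueError):
            saturation_curve(1e6, 0.0, template, [])
        with pytest.raises(ValueError):
            saturation_curve(1e6, 0.0, template, [1e-6, -1e-6])
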