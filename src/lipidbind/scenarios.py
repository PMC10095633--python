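"""Canonical simulation scenarios and the seeded synthetic-titration generator.

Each scenario reproduces, as a plain numeric table, one of the standard
illustrations of how a lipid phase distorts apparent ligand-protein
affinities:

``fig2``   saturation curves for a 50 kDa water-soluble protein
           (Keq = 1e6 1/M, KP = 1e3, P_T = 10 uM) at increasing lipid
           volume fractions, with the two naive fits and their residuals.
``fig3``   apparent affinity vs lipid volume fraction for the
           lipid-neglecting and excess-ligand fits at P_T = 1, 10 and
           100 uM, against the closed-form dilute prediction.
``fig5``   membrane-protein sweep (P_T = 1 uM, Keq = 1e6 1/M): bias
           ratio, aqueous/lipid ligand fractions and saturation vs
           alpha_Lb in 0..0.15 for log10 KP in {-1, 0, 2, 3, 4, 5} at
           L_T = 1 and 10 uM.
``fig6a-c`` how apparent affinity tracks ligand lipophilicity when the
           intrinsic constant is fixed (a), scales linearly with KP (b),
           or supralinearly as KP^2 (c); alpha_Lb = 0.1%, P_T = 1 uM.
``fig7``   apparent affinity vs KP slabs for intrinsic constants
           1e4..1e10 1/M at alpha_Lb in {0.001, 0.01, 0.1}.

Grid densities are configurable; the parameter values above are the
scenario definitions themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import bias as _bias
from .apparent import TitrationDataset, eval_eq6, eval_eq7, fit
from .core_thermo import molar_volume
from .equilibrium import distribution_curve

__all__ = [
    "SCENARIO_IDS",
    "ScenarioSpec",
    "SyntheticSpec",
    "run_scenario",
    "generate_titration",
]

SCENARIO_IDS = ("fig2", "fig3", "fig5", "fig6a", "fig6b", "fig6c", "fig7")


@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario id plus grid-density overrides."""

    scenario_id: str
    n_points: int = 50  # density of the swept axis (alpha_Lb, KP or L_T)
    n_lt: int = 20  # titration length where fits are involved

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise ValueError(
                f"unknown scenario {self.scenario_id!r}; expected one of {SCENARIO_IDS}"
            )
        if self.n_points < 2 or self.n_lt < 3:
            raise ValueError("n_points must be >= 2 and n_lt >= 3")


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and noise model for one synthetic titration.

    The total-ligand grid is log-spaced over ``0.01/keq_lw`` to
    ``100/keq_lw`` unless given explicitly; noise is additive Gaussian
    on the saturation fraction, clipped to [0, 1].  A seed is mandatory
    so every dataset is exactly reproducible.
    """

    keq_lw: float  # 1/M
    kp_lb_lw: float  # dimensionless
    pt_molar: float  # M
    alpha_lb: float  # dimensionless
    seed: int
    mw_gmol: float = 50_000.0
    n_points: int = 20
    sigma: float = 0.02  # s.d. of additive noise on saturation
    lt_grid: Optional[tuple] = None  # M, overrides the default grid

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.keq_lw <= 0:
            raise ValueError("keq_lw must be > 0")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")


# -- scenario parameter sets -------------------------------------------------

_FIG2 = dict(keq=1e6, kp=1e3, pt=1e-5, mw=50_000.0, alphas=(0.0, 1e-3, 1e-2, 5e-2))
_FIG3 = dict(keq=1e6, kp=1e3, mw=50_000.0, pts=(1e-6, 1e-5, 1e-4))
_FIG5 = dict(keq=1e6, pt=1e-6, mw=50_000.0, log_kps=(-1.0, 0.0, 2.0, 3.0, 4.0, 5.0),
             lts=(1e-6, 1e-5), alpha_max=0.15)
_FIG6 = dict(pt=1e-6, mw=50_000.0, alpha_lb=1e-3, keq_a=1e6, kp_p_lb_b=1.0,
             kp_min=1e-1, kp_max=1e5)
_FIG7 = dict(alphas=(1e-3, 1e-2, 1e-1), log_keqs=(4, 5, 6, 7, 8, 9, 10),
             kp_min=1e-1, kp_max=1e7)


def _lt_grid(keq: float, n: int) -> np.ndarray:
    return np.logspace(np.log10(0.01 / keq), np.log10(100.0 / keq), n)


def _fit_both(lt: np.ndarray, sat: np.ndarray, pt: float) -> tuple[float, float, float, float]:
    """eq6 and eq7 apparent constants and rss on a noiseless curve."""
    ds = TitrationDataset(lt_values=lt, observed=sat, pt_molar=pt)
    r6 = fit(ds, "eq6")
    r7 = fit(ds, "eq7")
    return (
        r6.estimates["keq_app_lw"], r7.estimates["keq_app_lt"], r6.rss, r7.rss,
    )


def _scenario_fig2(spec: ScenarioSpec) -> pd.DataFrame:
    p = _FIG2
    alpha_p = p["pt"] * molar_volume(p["mw"])
    lt = _lt_grid(p["keq"], max(spec.n_points, spec.n_lt))
    rows = []
    for alb in p["alphas"]:
        res = distribution_curve(p["keq"], p["kp"], lt, p["pt"], alb, alpha_p)
        sat = res["saturation"]
        k6, k7, _, _ = _fit_both(lt, sat, p["pt"])
        fit6 = np.asarray(eval_eq6(k6, p["pt"], lt)) / p["pt"]
        fit7 = np.asarray(eval_eq7(k7, p["pt"], lt)) / p["pt"]
        for i in range(lt.size):
            rows.append(
                dict(
                    alpha_lb=alb,
                    lt_molar=lt[i],
                    saturation=sat[i],
                    fit_eq6=fit6[i],
                    resid_eq6=sat[i] - fit6[i],
                    fit_eq7=fit7[i],
                    resid_eq7=sat[i] - fit7[i],
                    keq_app_eq6=k6,
                    keq_app_eq7=k7,
                )
            )
    return pd.DataFrame(rows)


def _scenario_fig3(spec: ScenarioSpec) -> pd.DataFrame:
    p = _FIG3
    vbar = molar_volume(p["mw"])
    alphas = np.concatenate([[0.0], np.logspace(-4, -1, spec.n_points - 1)])
    rows = []
    for pt in p["pts"]:
        lt = _lt_grid(p["keq"], spec.n_lt)
        alpha_p = pt * vbar
        for alb in alphas:
            res = distribution_curve(p["keq"], p["kp"], lt, pt, alb, alpha_p)
            k6, k7, _, _ = _fit_both(lt, res["saturation"], pt)
            rows.append(
                dict(
                    pt_molar=pt,
                    alpha_lb=alb,
                    keq_app_eq6=k6,
                    keq_app_eq7=k7,
                    bias_prediction=p["keq"] * _bias.bias_dilute(p["kp"], alb).ratio,
                )
            )
    return pd.DataFrame(rows)


def _scenario_fig5(spec: ScenarioSpec) -> pd.DataFrame:
    p = _FIG5
    alpha_p = p["pt"] * molar_volume(p["mw"])
    alphas = np.linspace(0.0, p["alpha_max"], spec.n_points)
    rows = []
    for log_kp in p["log_kps"]:
        kp = 10.0**log_kp
        for alb in alphas:
            lt = _lt_grid(p["keq"], spec.n_lt)
            res_fit = distribution_curve(p["keq"], kp, lt, p["pt"], alb, alpha_p)
            k6, _, _, _ = _fit_both(lt, res_fit["saturation"], p["pt"])
            for lt_point in p["lts"]:
                res = distribution_curve(
                    p["keq"], kp, np.asarray([lt_point]), p["pt"], alb, alpha_p
                )
                rows.append(
                    dict(
                        log_kp=log_kp,
                        alpha_lb=alb,
                        lt_molar=lt_point,
                        keq_app_ratio=k6 / p["keq"],
                        f_w=float(res["l_w"][0]) / lt_point,
                        f_lb=float(res["l_lb"][0]) / lt_point,
                        saturation=float(res["saturation"][0]),
                    )
                )
    return pd.DataFrame(rows)


def _scenario_fig6(spec: ScenarioSpec, case: str) -> pd.DataFrame:
    p = _FIG6
    vbar = molar_volume(p["mw"])
    alpha_p = p["pt"] * vbar
    kps = np.logspace(np.log10(p["kp_min"]), np.log10(p["kp_max"]), spec.n_points)
    rows = []
    for kp in kps:
        if case == "a":  # intrinsic affinity independent of lipophilicity
            keq = p["keq_a"]
            kp_p_lw = keq / vbar
            kp_p_lb = kp_p_lw / kp
        elif case == "b":  # affinity scales with lipophilicity (KP_P_Lb fixed)
            kp_p_lb = p["kp_p_lb_b"]
            kp_p_lw = kp * kp_p_lb
            keq = kp_p_lw * vbar
        else:  # c: supralinear, KP_P_LW = KP^2
            kp_p_lw = kp * kp
            kp_p_lb = kp
            keq = kp_p_lw * vbar
        ratio = _bias.bias_general(kp, p["alpha_lb"], alpha_p).ratio
        rows.append(
            dict(
                kp_lb_lw=kp,
                kp_p_lb=kp_p_lb,
                kp_p_lw=kp_p_lw,
                keq_lw=keq,
                keq_app=keq * ratio,
                keq_app_ratio=ratio,
            )
        )
    return pd.DataFrame(rows)


def _scenario_fig7(spec: ScenarioSpec) -> pd.DataFrame:
    p = _FIG7
    kps = np.logspace(np.log10(p["kp_min"]), np.log10(p["kp_max"]), spec.n_points)
    rows = []
    for alb in p["alphas"]:
        for log_keq in p["log_keqs"]:
            keq = 10.0**log_keq
            for kp in kps:
                ratio = _bias.bias_dilute(kp, alb).ratio
                rows.append(
                    dict(
                        alpha_lb=alb,
                        keq_lw=keq,
                        kp_lb_lw=kp,
                        keq_app=keq * ratio,
                        keq_app_ratio=ratio,
                    )
                )
    return pd.DataFrame(rows)


def run_scenario(spec: ScenarioSpec | str) -> pd.DataFrame:
    """Emit the numeric table behind one scenario.

    Accepts a :class:`ScenarioSpec` or a bare scenario id.  Tables carry
    molar quantities in columns suffixed ``_molar`` and dimensionless
    ratios otherwise; see the module docstring for each schema.
    """
    if isinstance(spec, str):
        spec = ScenarioSpec(scenario_id=spec)
    sid = spec.scenario_id
    if sid == "fig2":
        return _scenario_fig2(spec)
    if sid == "fig3":
        return _scenario_fig3(spec)
    if sid == "fig5":
        return _scenario_fig5(spec)
    if sid.startswith("fig6"):
        return _scenario_fig6(spec, sid[-1])
    return _scenario_fig7(spec)


def generate_titration(spec: SyntheticSpec) -> TitrationDataset:
    """Simulate a noisy saturation titration with known ground truth.

    The noiseless response comes from the exact three-compartment
    solver; seeded Gaussian noise (s.d. ``spec.sigma``) is added on the
    saturation fraction and clipped to [0, 1].  The returned dataset
    carries the generator parameters under ``ground_truth`` so recovery
    tests can compare estimates against them.
    """
    lt = (
        np.asarray(spec.lt_grid, dtype=float)
        if spec.lt_grid is not None
        else _lt_grid(spec.keq_lw, spec.n_points)
    )
    alpha_p = spec.pt_molar * molar_volume(spec.mw_gmol)
    res = distribution_curve(
        spec.keq_lw, spec.kp_lb_lw, lt, spec.pt_molar, spec.alpha_lb, alpha_p
    )
    sat = res["saturation"]
    if spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        sat = np.clip(sat + rng.normal(0.0, spec.sigma, size=sat.shape), 0.0, 1.0)
    return TitrationDataset(
        lt_values=lt,
        observed=sat,
        pt_molar=spec.pt_molar,
        response_kind="saturation",
        alpha_lb=spec.alpha_lb,
        mw_gmol=spec.mw_gmol,
        kp_lb_lw=spec.kp_lb_lw,
        ground_truth=dict(
            keq_lw=spec.keq_lw,
            kp_lb_lw=spec.kp_lb_lw,
            pt_molar=spec.pt_molar,
            alpha_lb=spec.alpha_lb,
            sigma=spec.sigma,
            seed=spec.seed,
        ),
    )
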