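"""Naive titration-analysis models and least-squares fitting.

Saturation binding data taken in the presence of a lipid phase are, in
practice, almost always analysed with one of two simplified models:

* a ligand-depletion quadratic that accounts for the ligand bound to the
  protein but ignores the lipid phase ("lipid-neglecting" model), and
* an excess-ligand hyperbola that treats the total ligand concentration
  as free ("excess-ligand" model).

Both return *apparent* association constants that depend on the assay
composition.  The full model fits the intrinsic constant by solving the
three-compartment equilibrium with the lipid partition coefficient and
lipid volume fraction supplied as known quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import least_squares

from .core_thermo import molar_volume
from .equilibrium import distribution_curve

__all__ = [
    "TitrationDataset",
    "FitResult",
    "eval_eq6",
    "eval_eq7",
    "fit",
    "MODEL_IDS",
]

MODEL_IDS = ("full", "eq6", "eq7")

_LN10 = np.log(10.0)


@dataclass
class TitrationDataset:
    """A titration: total ligand grid vs observed protein-bound response.

    ``response_kind`` is ``"saturation"`` (bound fraction, L_P/P_T) or
    ``"bound_concentration"`` (L_P in M).  Composition metadata travels
    with the data; ``kp_lb_lw`` must be present for full-model fits.
    ``ground_truth`` records generator parameters on synthetic data.
    """

    lt_values: np.ndarray  # M, total ligand per total volume
    observed: np.ndarray  # dimensionless saturation or M
    pt_molar: float  # M, total protein
    response_kind: str = "saturation"
    alpha_lb: float = 0.0
    mw_gmol: Optional[float] = None
    kp_lb_lw: Optional[float] = None
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.lt_values = np.asarray(self.lt_values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.lt_values.shape != self.observed.shape:
            raise ValueError(
                f"lt_values and observed differ in length: "
                f"{self.lt_values.size} vs {self.observed.size}"
            )
        if self.lt_values.size < 3:
            raise ValueError(f"need at least 3 titration points, got {self.lt_values.size}")
        if np.any(self.lt_values <= 0):
            raise ValueError("lt_values must be strictly positive")
        if self.response_kind not in ("saturation", "bound_concentration"):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")
        if self.pt_molar < 0:
            raise ValueError("pt_molar must be >= 0")

    def __len__(self) -> int:
        return int(self.lt_values.size)


@dataclass
class FitResult:
    """Outcome of a single-constant least-squares fit."""

    model_id: str
    estimates: dict  # name -> value, 1/M
    stderr: dict  # name -> standard error, 1/M
    residuals: np.ndarray  # observed - predicted, response scale
    rss: float
    converged: bool
    n_iter: int
    log10_estimates: dict = field(default_factory=dict)
    log10_stderr: dict = field(default_factory=dict)


def eval_eq6(keq_app_lw: float, pt: float, lt) -> np.ndarray | float:
    """Protein-bound ligand under the lipid-neglecting depletion model.

    Free ligand is the positive root of
    ``K*LW^2 + (1 - K*(LT - PT))*LW - LT = 0`` and the bound amount is
    ``LP = LT - LW``; identical to the dilute three-compartment solution
    with no lipid present.  All concentrations molar per total volume.
    """
    if keq_app_lw < 0 or pt < 0:
        raise ValueError("keq_app_lw and pt must be >= 0")
    res = distribution_curve(keq_app_lw, 0.0, lt, pt, 0.0, 0.0, general=False)
    lp = res["l_p"]
    return lp if np.ndim(lt) else float(lp)


def eval_eq7(keq_app_lt: float, pt: float, lt) -> np.ndarray | float:
    """Protein-bound ligand under the excess-ligand hyperbola.

    ``LP = PT * K * LT / (1 + K * LT)``: the free concentration is
    approximated by the total, valid only when LT >> PT and no other
    sink depletes the ligand.
    """
    if keq_app_lt < 0 or pt < 0:
        raise ValueError("keq_app_lt and pt must be >= 0")
    lt_arr = np.asarray(lt, dtype=float)
    lp = pt * keq_app_lt * lt_arr / (1.0 + keq_app_lt * lt_arr)
    return lp if lt_arr.ndim else float(lp)


def _predictor(
    dataset: TitrationDataset,
    model_id: str,
    kp_lb_lw: Optional[float],
    alpha_lb: Optional[float],
) -> Callable[[float], np.ndarray]:
    """Response (on the dataset's observation scale) as a function of Keq."""
    lt = dataset.lt_values
    pt = dataset.pt_molar
    # account for the protein's own volume when the dataset says how big it is
    alpha_p = 0.0
    if dataset.mw_gmol is not None:
        alpha_p = pt * molar_volume(dataset.mw_gmol)

    def to_response(lp: np.ndarray) -> np.ndarray:
        if dataset.response_kind == "saturation":
            return lp / pt if pt > 0 else np.zeros_like(lp)
        return lp

    if model_id == "eq6":
        return lambda keq: to_response(np.asarray(eval_eq6(keq, pt, lt)))
    if model_id == "eq7":
        return lambda keq: to_response(np.asarray(eval_eq7(keq, pt, lt)))
    if model_id == "full":
        if kp_lb_lw is None or alpha_lb is None:
            raise ValueError("full-model fit requires kp_lb_lw and alpha_lb")

        def predict(keq: float) -> np.ndarray:
            res = distribution_curve(keq, kp_lb_lw, lt, pt, alpha_lb, alpha_p, general=True)
            return to_response(res["l_p"])

        return predict
    raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def _initial_keq(dataset: TitrationDataset) -> float:
    """Half-saturation heuristic: Keq0 = 1/LT at the response closest to 0.5.

    Uses the response normalised to its maximum so bound-concentration
    data get the same treatment.
    """
    obs = dataset.observed
    top = np.max(np.abs(obs))
    norm = obs / top if top > 0 else obs
    idx = int(np.argmin(np.abs(norm - 0.5)))
    return 1.0 / dataset.lt_values[idx]


def fit(
    dataset: TitrationDataset,
    model_id: str,
    fixed: Optional[dict] = None,
) -> FitResult:
    """Least-squares estimate of the association constant.

    ``model_id`` selects the lipid-neglecting quadratic (``"eq6"``), the
    excess-ligand hyperbola (``"eq7"``) or the three-compartment model
    (``"full"``, estimating the intrinsic Keq_LW with ``kp_lb_lw`` and
    ``alpha_lb`` held fixed at their known values).  ``fixed`` may
    override the dataset metadata (keys ``kp_lb_lw``, ``alpha_lb``).

    The optimisation runs in log10(Keq) to enforce positivity, starting
    from the half-saturation point with a 5-point log-spaced multistart
    fallback.  Residuals are unweighted on the observed response scale.
    Non-convergence is flagged on the result, never silently ignored.
    """
    fixed = fixed or {}
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    if np.ptp(dataset.observed) == 0.0:
        raise ValueError("degenerate dataset: observed response is constant")

    kp = fixed.get("kp_lb_lw", dataset.kp_lb_lw)
    alb = fixed.get("alpha_lb", dataset.alpha_lb)
    predict = _predictor(dataset, model_id, kp, alb)
    obs = dataset.observed

    def resid(theta: np.ndarray) -> np.ndarray:
        # clamp wild optimizer excursions before exponentiation
        return predict(10.0 ** float(np.clip(theta[0], -120.0, 120.0))) - obs

    lt = dataset.lt_values
    starts = [np.log10(_initial_keq(dataset))]
    starts += list(np.linspace(np.log10(0.1 / lt.max()), np.log10(10.0 / lt.min()), 5))

    best = None
    for i, theta0 in enumerate(starts):
        sol = least_squares(
            resid, x0=[theta0], method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or (sol.success and rss < best[1] * (1 - 1e-12)):
            best = (sol, rss)
        # accept the half-saturation start when it converged cleanly and
        # leaves no systematic residual worth a multistart
        if i == 0 and sol.success and rss <= 1e-20 * max(1.0, float(np.sum(obs**2))):
            break

    sol, rss = best
    theta_hat = float(sol.x[0])
    keq_hat = 10.0**theta_hat

    n, p = obs.size, 1
    jtj = float(np.sum(sol.jac**2))
    if n > p and jtj > 0:
        s2 = rss / (n - p)
        se_theta = float(np.sqrt(s2 / jtj))
    else:
        se_theta = float("nan")
    se_keq = keq_hat * _LN10 * se_theta  # delta method, log10 -> linear

    name = {"full": "keq_lw", "eq6": "keq_app_lw", "eq7": "keq_app_lt"}[model_id]
    return FitResult(
        model_id=model_id,
        estimates={name: keq_hat},
        stderr={name: se_keq},
        residuals=obs - predict(keq_hat),
        rss=rss,
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
        log10_estimates={name: theta_hat},
        log10_stderr={name: se_theta},
    )
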