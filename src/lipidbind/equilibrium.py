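"""Exact equilibrium distribution of a ligand among water, lipid and protein.

Mass balance for a single-site protein plus a non-saturable lipid phase
closes to a quadratic in the free aqueous ligand concentration, of which
the physically meaningful root is always the larger one (x+).  Two
solvers are provided: :func:`solve_dilute` references the binding step to
the per-total-volume free concentration (valid when water occupies
essentially the whole system, alpha_W >= 0.99), and :func:`solve_general`
keeps exact volume bookkeeping by referencing both the lipid partition
and the binding step to the *local* aqueous concentration, so it remains
correct at any lipid or protein loading.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_thermo import SystemComposition

__all__ = [
    "DILUTE_ALPHA_W",
    "DiluteRegimeWarning",
    "DistributionResult",
    "solve_dilute",
    "solve_general",
    "saturation_curve",
]

#: Water volume fraction below which the dilute-regime solver warns.
DILUTE_ALPHA_W = 0.99


class DiluteRegimeWarning(UserWarning):
    """The composition is outside the stated dilute validity region."""


@dataclass(frozen=True)
class DistributionResult:
    """Equilibrium amounts of ligand in each medium, per total volume (M)."""

    l_w: float  # free ligand in water
    l_lb: float  # associated with the lipid bilayer
    l_p: float  # bound to the protein
    p_free: float  # unoccupied protein
    ligand_total: float
    protein_total: float

    @property
    def f_w(self) -> float:
        return self.l_w / self.ligand_total if self.ligand_total > 0 else 0.0

    @property
    def f_lb(self) -> float:
        return self.l_lb / self.ligand_total if self.ligand_total > 0 else 0.0

    @property
    def f_p(self) -> float:
        return self.l_p / self.ligand_total if self.ligand_total > 0 else 0.0

    @property
    def saturation(self) -> float:
        """Fraction of binding sites occupied, l_p / protein_total."""
        return self.l_p / self.protein_total if self.protein_total > 0 else 0.0


def _free_ligand(keq: float, gamma: float, lt, pt: float):
    """Positive root of the mass-balance quadratic.

    gamma * keq * LW**2 + (gamma - keq*(LT - PT)) * LW - LT = 0

    where ``gamma = 1 + KP*V_Lb/V_W`` collects the lipid term and ``keq``
    is the binding constant referenced to whatever concentration scale
    the caller uses.  Accepts scalar or ndarray ``lt``.  The x+ root is
    evaluated in the cancellation-free form: -2c/(b + sqrt(b^2 - 4ac))
    when b > 0.
    """
    lt = np.asarray(lt, dtype=float)
    if keq == 0.0 or pt == 0.0:
        # no saturable sink: linear partitioning only
        out = lt / gamma
        return out if out.ndim else float(out)
    a = gamma * keq
    b = gamma - keq * (lt - pt)
    c = -lt
    disc = b * b - 4.0 * a * c  # c <= 0 so disc >= b^2 >= 0
    sq = np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        lw = np.where(b > 0.0, -2.0 * c / (b + sq), (sq - b) / (2.0 * a))
    return lw if lw.ndim else float(lw)


def _bound_split(lw, kp_ratio, lt):
    """Lipid-associated and protein-bound ligand given free LW."""
    l_lb = lw * kp_ratio
    l_p = lt - lw - l_lb
    return l_lb, l_p


def distribution_curve(
    keq_lw: float,
    kp_lb_lw: float,
    lt: np.ndarray,
    pt: float,
    alpha_lb: float,
    alpha_p: float = 0.0,
    general: bool = True,
) -> dict[str, np.ndarray]:
    """Vectorised equilibrium over an array of total ligand concentrations.

    Returns per-total-volume molar arrays ``l_w``, ``l_lb``, ``l_p`` and
    the protein ``saturation``.  Workhorse behind the scalar solvers, the
    model fits and the scenario tables.
    """
    if keq_lw < 0 or kp_lb_lw < 0:
        raise ValueError("keq_lw and kp_lb_lw must be >= 0")
    alpha_w = 1.0 - alpha_lb - alpha_p
    if alpha_w <= 0:
        raise ValueError(f"water volume fraction must be > 0, got {alpha_w}")
    kp_ratio = kp_lb_lw * alpha_lb / alpha_w  # = KP * V_Lb / V_W
    gamma = 1.0 + kp_ratio
    keq = keq_lw / alpha_w if general else keq_lw
    lt = np.asarray(lt, dtype=float)
    lw = _free_ligand(keq, gamma, lt, pt)
    l_lb, l_p = _bound_split(lw, kp_ratio, lt)
    # guard against roundoff pushing tiny amounts negative
    l_p = np.maximum(l_p, 0.0)
    sat = l_p / pt if pt > 0 else np.zeros_like(l_p)
    return {"l_w": lw, "l_lb": l_lb, "l_p": l_p, "saturation": sat}


def _solve(keq_lw: float, kp_lb_lw: float, composition: SystemComposition, general: bool) -> DistributionResult:
    lt = composition.ligand_total
    pt = composition.protein_total
    res = distribution_curve(
        keq_lw,
        kp_lb_lw,
        np.asarray([lt]),
        pt,
        composition.lipid_volume_fraction,
        composition.protein_volume_fraction,
        general=general,
    )
    l_w = float(res["l_w"][0])
    l_lb = float(res["l_lb"][0])
    l_p = float(res["l_p"][0])
    return DistributionResult(
        l_w=l_w,
        l_lb=l_lb,
        l_p=l_p,
        p_free=pt - l_p,
        ligand_total=lt,
        protein_total=pt,
    )


def solve_dilute(keq_lw: float, kp_lb_lw: float, composition: SystemComposition) -> DistributionResult:
    """Equilibrium distribution in the dilute regime.

    ``keq_lw`` (1/M) multiplies the free ligand concentration per total
    volume, which coincides with the local aqueous concentration only
    when water dominates the system; a :class:`DiluteRegimeWarning` is
    emitted when alpha_W < 0.99.
    """
    if composition.water_volume_fraction < DILUTE_ALPHA_W:
        warnings.warn(
            f"composition outside the dilute regime (alpha_W = "
            f"{composition.water_volume_fraction:.4g} < {DILUTE_ALPHA_W}); "
            "consider solve_general",
            DiluteRegimeWarning,
            stacklevel=2,
        )
    return _solve(keq_lw, kp_lb_lw, composition, general=False)


def solve_general(keq_lw: float, kp_lb_lw: float, composition: SystemComposition) -> DistributionResult:
    """Equilibrium distribution with exact volume bookkeeping.

    The local aqueous concentration c_W = n_W/V_W drives both the lipid
    partition (n_Lb = KP * c_W * V_Lb) and the binding step
    (L_P / (P * c_W) = Keq_LW), so the result is valid at any lipid or
    protein volume fraction with alpha_W > 0.  Agrees with
    :func:`solve_dilute` to better than 0.1% when alpha_Lb + alpha_P <= 0.01.
    """
    return _solve(keq_lw, kp_lb_lw, composition, general=True)


def saturation_curve(
    keq_lw: float,
    kp_lb_lw: float,
    composition_template: SystemComposition,
    lt_grid,
    general: bool = True,
) -> list[tuple[float, float]]:
    """Protein saturation along a grid of total ligand concentrations.

    ``composition_template`` supplies everything except ``ligand_total``,
    which is swept over ``lt_grid`` (strictly positive, sorted
    ascending).  Returns ``[(LT, saturation), ...]``.
    """
    lt_grid = list(lt_grid)
    if not lt_grid:
        raise ValueError("lt_grid must not be empty")
    arr = np.asarray(lt_grid, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("lt_grid values must be strictly positive")
    if np.any(np.diff(arr) < 0):
        raise ValueError("lt_grid must be sorted ascending")
    res = distribution_curve(
        keq_lw,
        kp_lb_lw,
        arr,
        composition_template.protein_total,
        composition_template.lipid_volume_fraction,
        composition_template.protein_volume_fraction,
        general=general,
    )
    return list(zip(arr.tolist(), res["saturation"].tolist()))
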