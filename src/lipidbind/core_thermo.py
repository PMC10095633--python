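"""Unit conventions and thermodynamic-cycle relations.

A ligand in a membrane-containing assay distributes among three media:
the aqueous phase (W), the lipid bilayer (Lb) and the protein binding
site (P).  The three pairwise equilibria form a thermodynamic cycle, so
only two of the three constants are independent (micro-reversibility).
Partition coefficients are ratios of *local* concentrations and are
dimensionless; the molar binding constant from medium X follows as

    Keq_LX = KP_P_LX * Vbar_P          [1/M]

where ``Vbar_P`` is the protein molar volume in L/mol.  Total
concentrations (moles per total system volume) are used everywhere a
quantity is labelled molar; every function states which convention each
argument follows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "DEFAULT_SPECIFIC_VOLUME",
    "CYCLE_RTOL",
    "ProteinSpec",
    "AffinitySet",
    "SystemComposition",
    "molar_volume",
    "keq_from_partition",
    "partition_from_keq",
    "close_cycle",
    "membrane_partition",
    "invert_membrane_partition",
]

#: Protein partial specific volume in mL/g.  With this value 10 uM of a
#: 50 kDa protein occupies a volume fraction of 4.2e-4, the convention
#: adopted throughout; typical globular proteins fall in 0.70-0.86 mL/g,
#: so it is user-overridable.
DEFAULT_SPECIFIC_VOLUME = 0.84

#: Relative tolerance at which the thermodynamic cycle is enforced.
CYCLE_RTOL = 1e-12


def molar_volume(molecular_weight: float, specific_volume: float = DEFAULT_SPECIFIC_VOLUME) -> float:
    """Protein molar volume in L/mol.

    Parameters
    ----------
    molecular_weight : float
        Molar mass in g/mol.
    specific_volume : float
        Partial specific volume in mL/g.

    Returns
    -------
    float
        ``molecular_weight * specific_volume / 1000`` in L/mol.
    """
    if molecular_weight <= 0:
        raise ValueError(f"molecular_weight must be > 0, got {molecular_weight}")
    if specific_volume <= 0:
        raise ValueError(f"specific_volume must be > 0, got {specific_volume}")
    return molecular_weight * specific_volume / 1000.0


@dataclass(frozen=True)
class ProteinSpec:
    """A single-site protein characterised by its size.

    ``molar_volume`` (L/mol) converts the protein<->water partition
    coefficient into the molar binding constant and sets the volume
    fraction the protein occupies at a given molar concentration.
    """

    molecular_weight: float  # g/mol
    specific_volume: float = DEFAULT_SPECIFIC_VOLUME  # mL/g

    #: number of binding sites; the whole framework assumes one.
    n_sites: int = field(default=1, init=False)

    def __post_init__(self) -> None:
        # delegate validation
        molar_volume(self.molecular_weight, self.specific_volume)

    @property
    def molar_volume(self) -> float:
        """L/mol."""
        return molar_volume(self.molecular_weight, self.specific_volume)


def keq_from_partition(kp_p_lx: float, molar_volume: float) -> float:
    """Molar binding constant (1/M) from a protein partition coefficient.

    ``kp_p_lx`` is the dimensionless ratio of local ligand concentration
    in the protein to that in medium X; ``molar_volume`` is the protein
    molar volume in L/mol.
    """
    if kp_p_lx < 0:
        raise ValueError(f"partition coefficient must be >= 0, got {kp_p_lx}")
    if molar_volume <= 0:
        raise ValueError(f"molar_volume must be > 0, got {molar_volume}")
    return kp_p_lx * molar_volume


def partition_from_keq(keq_lx: float, molar_volume: float) -> float:
    """Inverse of :func:`keq_from_partition`: Keq (1/M) -> dimensionless KP."""
    if keq_lx < 0:
        raise ValueError(f"binding constant must be >= 0, got {keq_lx}")
    if molar_volume <= 0:
        raise ValueError(f"molar_volume must be > 0, got {molar_volume}")
    return keq_lx / molar_volume


@dataclass(frozen=True)
class AffinitySet:
    """The partition coefficients of one ligand joined by cycle closure.

    Fields
    ------
    kp_lb_lw : dimensionless
        Lipid-bilayer/water partition coefficient ("ligand lipophilicity").
    kp_p_lw : dimensionless
        Protein/water partition coefficient.
    kp_p_lb : dimensionless
        Protein/lipid-bilayer partition coefficient.
    keq_lw : 1/M, optional
        Molar binding constant from water; equals ``kp_p_lw * Vbar_P``
        for the associated protein.
    kp_m_lw : dimensionless, optional
        Whole-membrane (lipid + protein) partition coefficient.

    Whenever all three pairwise coefficients are set, the cycle
    ``kp_p_lw = kp_lb_lw * kp_p_lb`` must close to ``CYCLE_RTOL``.
    """

    kp_lb_lw: Optional[float] = None
    kp_p_lw: Optional[float] = None
    kp_p_lb: Optional[float] = None
    keq_lw: Optional[float] = None
    kp_m_lw: Optional[float] = None
    protein: Optional[ProteinSpec] = None

    def __post_init__(self) -> None:
        for name in ("kp_lb_lw", "kp_p_lw", "kp_p_lb", "keq_lw", "kp_m_lw"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if None not in (self.kp_lb_lw, self.kp_p_lw, self.kp_p_lb):
            prod = self.kp_lb_lw * self.kp_p_lb
            if not math.isclose(self.kp_p_lw, prod, rel_tol=CYCLE_RTOL, abs_tol=0.0):
                raise ValueError(
                    "thermodynamic cycle violated: "
                    f"kp_p_lw={self.kp_p_lw!r} != kp_lb_lw*kp_p_lb={prod!r}"
                )
        if self.keq_lw is not None and self.kp_p_lw is not None and self.protein is not None:
            expect = keq_from_partition(self.kp_p_lw, self.protein.molar_volume)
            if not math.isclose(self.keq_lw, expect, rel_tol=CYCLE_RTOL, abs_tol=0.0):
                raise ValueError(
                    f"keq_lw={self.keq_lw!r} inconsistent with kp_p_lw * Vbar_P = {expect!r}"
                )


def close_cycle(
    kp_lb_lw: Optional[float] = None,
    kp_p_lw: Optional[float] = None,
    kp_p_lb: Optional[float] = None,
    protein: Optional[ProteinSpec] = None,
) -> AffinitySet:
    """Fill in the third partition coefficient from the other two.

    Exactly two of ``kp_lb_lw``, ``kp_p_lw``, ``kp_p_lb`` must be given;
    the third follows from ``kp_p_lw = kp_lb_lw * kp_p_lb``.  When a
    ``protein`` is supplied, ``keq_lw`` is filled in as well.
    """
    known = {
        "kp_lb_lw": kp_lb_lw,
        "kp_p_lw": kp_p_lw,
        "kp_p_lb": kp_p_lb,
    }
    given = [k for k, v in known.items() if v is not None]
    if len(given) != 2:
        raise ValueError(
            f"exactly two of (kp_lb_lw, kp_p_lw, kp_p_lb) must be given, got {given}"
        )
    for k in given:
        if known[k] < 0:
            raise ValueError(f"{k} must be >= 0, got {known[k]}")

    if kp_p_lw is None:
        kp_p_lw = kp_lb_lw * kp_p_lb
    elif kp_p_lb is None:
        if kp_lb_lw == 0:
            raise ValueError("cannot close cycle: kp_lb_lw is 0 (division by zero)")
        kp_p_lb = kp_p_lw / kp_lb_lw
    else:  # kp_lb_lw is None
        if kp_p_lb == 0:
            raise ValueError("cannot close cycle: kp_p_lb is 0 (division by zero)")
        kp_lb_lw = kp_p_lw / kp_p_lb

    keq_lw = keq_from_partition(kp_p_lw, protein.molar_volume) if protein is not None else None
    return AffinitySet(
        kp_lb_lw=kp_lb_lw,
        kp_p_lw=kp_p_lw,
        kp_p_lb=kp_p_lb,
        keq_lw=keq_lw,
        protein=protein,
    )


def membrane_partition(kp_lb_lw: float, kp_p_lw: float, v_lb: float, v_p: float) -> float:
    """Whole-membrane/water partition coefficient.

    The membrane volume is ``v_lb + v_p`` (lipid bilayer plus embedded
    protein, any common volume unit) and the overall coefficient is the
    volume-weighted mean of the two component coefficients:

        KP_M_LW = KP_Lb_LW * v_lb/(v_lb+v_p) + KP_P_LW * v_p/(v_lb+v_p)

    The protein term cannot be dropped even for dilute protein, because
    a large ``kp_p_lw`` offsets a small volume fraction.
    """
    if kp_lb_lw < 0 or kp_p_lw < 0:
        raise ValueError("partition coefficients must be >= 0")
    if v_lb < 0 or v_p < 0:
        raise ValueError("volumes must be >= 0")
    v_m = v_lb + v_p
    if v_m <= 0:
        raise ValueError("membrane volume v_lb + v_p must be > 0")
    return kp_lb_lw * v_lb / v_m + kp_p_lw * v_p / v_m


def invert_membrane_partition(kp_m_lw: float, kp_lb_lw: float, v_lb: float, v_p: float) -> float:
    """Solve the whole-membrane relation for the protein coefficient.

    Given the experimentally accessible ``kp_m_lw`` (membrane with
    protein) and ``kp_lb_lw`` (protein-free bilayer), return
    ``kp_p_lw``.  Exact inverse of :func:`membrane_partition`.
    """
    if v_p <= 0:
        raise ValueError("v_p must be > 0 to recover the protein partition coefficient")
    if v_lb < 0:
        raise ValueError("v_lb must be >= 0")
    v_m = v_lb + v_p
    kp_p_lw = (kp_m_lw - kp_lb_lw * v_lb / v_m) * v_m / v_p
    if kp_p_lw < 0:
        raise ValueError(
            "inconsistent inputs: kp_m_lw < kp_lb_lw * v_lb/(v_lb+v_p) implies a "
            f"negative protein partition coefficient ({kp_p_lw!r}); the measured "
            "membrane affinity cannot be below the lipid contribution alone"
        )
    return kp_p_lw


@dataclass(frozen=True)
class SystemComposition:
    """Volumes and total concentrations defining one assay condition.

    ``ligand_total`` and ``protein_total`` are molar with respect to the
    *total* system volume.  ``lipid_volume_fraction`` is
    alpha_Lb = V_Lb / V_T.  When a :class:`ProteinSpec` is attached, the
    protein volume fraction alpha_P = protein_total * Vbar_P is accounted
    for; otherwise the protein volume is treated as negligible.
    """

    ligand_total: float  # M (per total volume)
    protein_total: float = 0.0  # M (per total volume)
    lipid_volume_fraction: float = 0.0  # dimensionless
    protein: Optional[ProteinSpec] = None
    total_volume: float = 1.0  # L; only sets the absolute scale

    def __post_init__(self) -> None:
        if self.ligand_total < 0:
            raise ValueError(f"ligand_total must be >= 0, got {self.ligand_total}")
        if self.protein_total < 0:
            raise ValueError(f"protein_total must be >= 0, got {self.protein_total}")
        if not 0.0 <= self.lipid_volume_fraction < 1.0:
            raise ValueError(
                f"lipid_volume_fraction must be in [0, 1), got {self.lipid_volume_fraction}"
            )
        if self.total_volume <= 0:
            raise ValueError(f"total_volume must be > 0, got {self.total_volume}")
        if not 0.0 <= self.protein_volume_fraction < 1.0:
            raise ValueError(
                f"protein volume fraction {self.protein_volume_fraction} out of [0, 1)"
            )
        if self.water_volume_fraction <= 0:
            raise ValueError(
                "water volume fraction must be > 0; lipid + protein fill the system "
                f"(alpha_Lb={self.lipid_volume_fraction}, alpha_P={self.protein_volume_fraction})"
            )

    @property
    def protein_volume_fraction(self) -> float:
        """alpha_P = protein_total * Vbar_P (0 when no ProteinSpec attached)."""
        if self.protein is None:
            return 0.0
        return self.protein_total * self.protein.molar_volume

    @property
    def water_volume_fraction(self) -> float:
        """alpha_W = 1 - alpha_Lb - alpha_P."""
        return 1.0 - self.lipid_volume_fraction - self.protein_volume_fraction
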