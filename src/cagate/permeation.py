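"""Bi-ionic permeability calculations for a weakly Ca2+-selective cation channel.

Relative permeabilities are expressed against Cs+ (the internal reference
cation in the recording solutions).  Monovalent test ions use the
paired-bath form based on the shift in reversal potential between the test
bath and the Cs+ bath; divalent ions use the absolute bi-ionic expression.
Concentrations are converted to effective activities with either a fixed
activity-coefficient table or the extended Debye-Hueckel equation.

Units: potentials mV, concentrations mM at the :class:`IonSpecies` surface,
activities M internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

from scipy.optimize import brentq

from .constants import TEXTBOOK, PhysicalConstants

__all__ = [
    "IonSpecies",
    "ActivityModel",
    "PermeabilityResult",
    "PAPER_GAMMA_TABLE",
    "activity_coefficient",
    "effective_activity",
    "nernst_potential",
    "monovalent_permeability_ratio",
    "divalent_permeability_ratio",
    "erev_from_permeability",
    "fraction_ca_current",
    "junction_correct",
]

#: Tabulated activity coefficients for the recording ionic strengths.
PAPER_GAMMA_TABLE: Mapping[str, float] = {"Na": 0.74, "K": 0.72, "Cs": 0.69, "Ca": 0.29}

_ALLOWED_VALENCES = {1, 2, 3, -1}


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species on one side of the membrane.

    concentration is in mM; side is 'internal' or 'external'.
    """

    name: str
    valence: int
    concentration: float
    side: Literal["internal", "external"] = "external"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0 mM")
        if self.valence not in _ALLOWED_VALENCES:
            raise ValueError(f"valence must be one of {sorted(_ALLOWED_VALENCES)}")
        if self.side not in ("internal", "external"):
            raise ValueError("side must be 'internal' or 'external'")


@dataclass(frozen=True)
class ActivityModel:
    """How concentrations are converted to activities.

    mode='fixed-table' looks the ion up in ``table`` (default: the tabulated
    values for the standard recording solutions).  mode='debye-huckel'
    evaluates the extended Debye-Hueckel law

        log10(gamma) = -A z^2 sqrt(I) / (1 + B a sqrt(I))

    with the Debye constants ``dh_A`` (M^-1/2) and ``dh_B`` (M^-1/2 A^-1),
    ion-size parameters ``ion_size`` in Angstrom and ionic strength in M.
    """

    mode: Literal["fixed-table", "debye-huckel"] = "fixed-table"
    table: Mapping[str, float] = field(default_factory=lambda: dict(PAPER_GAMMA_TABLE))
    dh_A: float = 0.509
    dh_B: float = 0.328
    ion_size: Mapping[str, float] = field(
        default_factory=lambda: {"Na": 4.0, "K": 3.0, "Cs": 2.5, "Ca": 6.0}
    )
    ionic_strength: float = 0.15

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0 M")
        for ion, g in self.table.items():
            if not 0 < g <= 1:
                raise ValueError(f"gamma for {ion} must be in (0, 1]")


@dataclass(frozen=True)
class PermeabilityResult:
    """Outcome of a relative-permeability calculation (P_X / P_Cs)."""

    test_ion: str
    reference_ion: str
    ratio: float
    erev_used: float  # mV (delta-E_rev for the monovalent method)
    method: Literal["monovalent-delta", "divalent-absolute"]
    activities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("permeability ratio must be >= 0")


def activity_coefficient(ion: IonSpecies, model: ActivityModel) -> float:
    """Activity coefficient gamma for ``ion`` under ``model``.

    Raises KeyError for an ion missing from the fixed table.
    """
    if model.mode == "fixed-table":
        try:
            return model.table[ion.name]
        except KeyError:
            raise KeyError(
                f"no tabulated activity coefficient for ion {ion.name!r}"
            ) from None
    sqrt_i = math.sqrt(model.ionic_strength)
    if sqrt_i == 0.0:
        return 1.0
    a = model.ion_size.get(ion.name, 4.0)
    log10_gamma = -model.dh_A * ion.valence**2 * sqrt_i / (1.0 + model.dh_B * a * sqrt_i)
    return 10.0**log10_gamma


def effective_activity(ion: IonSpecies, gamma: float) -> float:
    """Effective activity alpha = gamma * [X], returned in M."""
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    if ion.concentration < 0:
        raise ValueError("concentration must be >= 0 mM")
    return gamma * ion.concentration * 1e-3


def nernst_potential(
    activity_out: float,
    activity_in: float,
    valence: int,
    constants: PhysicalConstants = TEXTBOOK,
) -> float:
    """Nernst equilibrium potential (RT/zF) ln(a_out/a_in), in mV."""
    if activity_out <= 0 or activity_in <= 0:
        raise ValueError("activities must be strictly positive")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    return constants.rt_over_f_mv / valence * math.log(activity_out / activity_in)


def monovalent_permeability_ratio(
    delta_erev: float,
    activity_cs_ext: float,
    activity_x_ext: float,
    constants: PhysicalConstants = TEXTBOOK,
) -> float:
    """P_X/P_Cs from the paired-bath reversal-potential shift (monovalent X).

    ``delta_erev`` is E_rev(X bath) - E_rev(Cs bath) in mV, junction-corrected.

        P_X/P_Cs = (alpha_Cs,e / alpha_X,e) * exp(dErev * F / RT)
    """
    if activity_cs_ext <= 0 or activity_x_ext <= 0:
        raise ValueError("activities must be strictly positive")
    return (activity_cs_ext / activity_x_ext) * math.exp(delta_erev / constants.rt_over_f_mv)


def divalent_permeability_ratio(
    erev: float,
    activity_cs_int: float,
    activity_x_ext: float,
    constants: PhysicalConstants = TEXTBOOK,
) -> float:
    """P_X/P_Cs for a divalent test ion X from the absolute bi-ionic E_rev.

        P_X/P_Cs = alpha_Cs,i * u * (u + 1) / (4 * alpha_X,e),
        u = exp(E_rev * F / RT)
    """
    if activity_cs_int <= 0 or activity_x_ext <= 0:
        raise ValueError("activities must be strictly positive")
    u = math.exp(erev / constants.rt_over_f_mv)
    return activity_cs_int * u * (u + 1.0) / (4.0 * activity_x_ext)


def erev_from_permeability(
    ratio: float,
    *,
    method: Literal["monovalent-delta", "divalent-absolute"],
    activity_cs: float,
    activity_x_ext: float,
    constants: PhysicalConstants = TEXTBOOK,
    bracket_mv: float = 500.0,
) -> float:
    """Invert the forward permeability equations for E_rev (mV).

    For the monovalent method ``activity_cs`` is the external Cs+ activity
    and the returned value is the delta-E_rev; for the divalent method it is
    the internal Cs+ activity and the returned value is the absolute E_rev.
    The forward-then-inverse round trip is exact to better than 1e-8 mV.
    """
    if ratio <= 0:
        raise ValueError("permeability ratio must be > 0")
    if method == "monovalent-delta":
        # closed form: dE = RT/F * ln(ratio * aX / aCs)
        return constants.rt_over_f_mv * math.log(ratio * activity_x_ext / activity_cs)
    if method != "divalent-absolute":
        raise ValueError(f"unknown method {method!r}")

    def resid(e_mv: float) -> float:
        return (
            divalent_permeability_ratio(e_mv, activity_cs, activity_x_ext, constants)
            - ratio
        )

    lo, hi = -bracket_mv, bracket_mv
    if resid(lo) * resid(hi) > 0:
        raise ValueError("target ratio not bracketed within +/- %.0f mV" % bracket_mv)
    return brentq(resid, lo, hi, xtol=1e-12, rtol=1e-15)


def fraction_ca_current(ca_ext: float, na_ext: float, p_ca_over_p_na: float) -> float:
    """Fraction r of the current carried by Ca2+, r = ([Ca]e/[Na]e) * (P_Ca/P_Na).

    Concentrations in mM.  With the standard bath (2 mM Ca2+, 150 mM Na+)
    and P_Ca/P_Na = 14.9 this gives r = 0.199.
    """
    if na_ext <= 0:
        raise ValueError("external Na+ concentration must be > 0 mM")
    if ca_ext < 0:
        raise ValueError("external Ca2+ concentration must be >= 0 mM")
    return (ca_ext / na_ext) * p_ca_over_p_na


def junction_correct(erev_measured: float, junction_potential: float) -> float:
    """Liquid-junction correction: corrected = measured - JP (both mV).

    The correction is a plain subtraction under the convention that the
    amplifier-reported potential overstates the true membrane potential by
    the junction potential; applying it twice shifts twice.
    """
    return erev_measured - junction_potential
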