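"""Physical constants used throughout the package.

Two parameterisations are provided: :data:`TEXTBOOK` keeps the rounded
values commonly used in patch-clamp bookkeeping (e = 1.6e-19 C,
N_A = 6.02e23 /mol), which reproduce published worked numbers exactly,
and :data:`CODATA` carries the modern recommended values.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants for electro-diffusion arithmetic.

    Attributes
    ----------
    F : float
        Faraday constant, C/mol.
    R : float
        Molar gas constant, J/(mol*K).
    T : float
        Absolute temperature, K.
    N_A : float
        Avogadro constant, /mol.
    e : float
        Elementary charge, C.
    """

    F: float = 96485.0
    R: float = 8.314
    T: float = 298.15
    N_A: float = 6.02e23
    e: float = 1.6e-19

    def __post_init__(self) -> None:
        for name in ("F", "R", "T", "N_A", "e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be strictly positive")

    @property
    def rt_over_f_mv(self) -> float:
        """RT/F in millivolts (~25.69 mV at 25 degC)."""
        return 1000.0 * self.R * self.T / self.F


#: Rounded constants used in the published accumulation formula.
TEXTBOOK = PhysicalConstants()

#: CODATA 2018 values (temperature still 25 degC).
CODATA = PhysicalConstants(F=96485.33212, R=8.31446, N_A=6.02214076e23, e=1.602176634e-19)
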