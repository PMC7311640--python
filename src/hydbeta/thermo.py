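"""Nernst-equation machinery for NADH-driven hydrogen production.

A non-bifurcating NADH-dependent hydrogenase catalyses

    NADH + H+  <->  NAD+ + H2

Hydrogen production from NADH alone is endergonic except at very low
hydrogen partial pressure, which is why such enzymes only function in
syntrophy with a hydrogen consumer. At equilibrium the NAD+/NADH couple and
the 2H+/H2 couple sit at the same potential; because both are two-electron
couples, the equilibrium hydrogen partial pressure is directly proportional
to the NADH/NAD+ ratio.

Potentials are handled in millivolts, pressures in pascals. The half-cell
potential at temperature ``T`` and the given pH is

    E = E0' - s * (m/n) * (pH - 7) + (s/n) * log10(ox/red)

with ``s = ln(10) R T / F`` (59.16 mV at 25 C), ``n`` electrons and ``m``
protons per reaction; for the hydrogen couple ``ox/red = p0 / p(H2)``.
Default midpoint potentials (pH 7, 25 C): E0'(NAD+/NADH) = -320 mV,
E0'(2H+/H2) = -414 mV. All constants are overridable and echoed in results.

Note: predicted equilibrium pressure increases as pH decreases at fixed
ratio (the hydrogen couple gains a full -s per pH unit against the NAD
couple's -s/2), and scales exactly linearly with the NADH/NAD+ ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Gas constant, J mol-1 K-1.
R = 8.314462618
#: Faraday constant, C mol-1.
F = 96485.33212
#: Standard pressure, Pa (1 atm).
P_STANDARD = 101325.0


@dataclass(frozen=True)
class RedoxCouple:
    """A half-cell: midpoint potential at pH 7, 25 C, plus stoichiometry."""

    name: str
    E0_prime_mV: float
    n_electrons: int
    protons_per_reaction: int

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")


@dataclass(frozen=True)
class Conditions:
    """Assay conditions: temperature, pH and the reference pressure."""

    temperature_K: float = 298.15
    pH: float = 7.5
    reference_pressure_Pa: float = P_STANDARD

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if not 0 < self.pH < 14:
            raise ValueError("pH must lie in (0, 14)")

    @property
    def nernst_slope_mV(self) -> float:
        """ln(10) R T / F in millivolts (59.16 mV at 298.15 K)."""
        return 1000.0 * math.log(10.0) * R * self.temperature_K / F


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium hydrogen pressure implied by a NADH/NAD+ ratio."""

    ratio_nadh_nad: float
    p_h2_Pa: float
    E_couple_mV: float
    conditions: Conditions = Conditions()

    def __post_init__(self) -> None:
        if self.p_h2_Pa <= 0:
            raise ValueError("equilibrium pressure must be positive")


#: NAD+/NADH couple: 2 electrons, 1 proton (NADH + H+ <-> NAD+ + 2e- + 2H+ net one).
NAD_COUPLE = RedoxCouple("NAD+/NADH", E0_prime_mV=-320.0, n_electrons=2, protons_per_reaction=1)
#: 2H+/H2 couple: 2 electrons, 2 protons.
H2_COUPLE = RedoxCouple("2H+/H2", E0_prime_mV=-414.0, n_electrons=2, protons_per_reaction=2)


def nernst_potential(couple: RedoxCouple, conditions: Conditions,
                     ratio_ox_over_red: float | None = None,
                     p_gas_Pa: float | None = None) -> float:
    """Half-cell potential in mV under the stated conditions.

    Provide either ``ratio_ox_over_red`` (for solution couples) or
    ``p_gas_Pa`` (for the hydrogen couple, where the reduced species is the
    gas: ox/red = p0 / p).
    """
    if (ratio_ox_over_red is None) == (p_gas_Pa is None):
        raise ValueError("provide exactly one of ratio_ox_over_red or p_gas_Pa")
    if p_gas_Pa is not None:
        if p_gas_Pa <= 0:
            raise ValueError("gas pressure must be positive")
        ratio_ox_over_red = conditions.reference_pressure_Pa / p_gas_Pa
    if ratio_ox_over_red <= 0:
        raise ValueError("ox/red ratio must be positive")
    s = conditions.nernst_slope_mV
    n = couple.n_electrons
    m = couple.protons_per_reaction
    return (
        couple.E0_prime_mV
        - s * (m / n) * (conditions.pH - 7.0)
        + (s / n) * math.log10(ratio_ox_over_red)
    )


def equilibrium_h2_pressure(ratio_nadh_nad: float,
                            conditions: Conditions = Conditions(),
                            nad_couple: RedoxCouple = NAD_COUPLE,
                            h2_couple: RedoxCouple = H2_COUPLE) -> EquilibriumResult:
    """Solve E_NAD(ratio, pH) = E_H2(p, pH) for the hydrogen pressure (closed form).

    The two-electron stoichiometry cancels, leaving p exactly proportional
    to the NADH/NAD+ ratio.
    """
    if ratio_nadh_nad <= 0:
        raise ValueError("NADH/NAD+ ratio must be positive")
    s = conditions.nernst_slope_mV
    e_nad = nernst_potential(nad_couple, conditions, ratio_ox_over_red=1.0 / ratio_nadh_nad)
    # E_H2 = E0H - s*(pH-7) - (s/2)*log10(p/p0)  =  e_nad
    e_h2_standard = h2_couple.E0_prime_mV - s * (
        h2_couple.protons_per_reaction / h2_couple.n_electrons
    ) * (conditions.pH - 7.0)
    log_p = (e_h2_standard - e_nad) * h2_couple.n_electrons / s
    p = conditions.reference_pressure_Pa * 10.0 ** log_p
    return EquilibriumResult(
        ratio_nadh_nad=ratio_nadh_nad, p_h2_Pa=p, E_couple_mV=e_nad,
        conditions=conditions,
    )


def ratio_for_pressure(p_h2_Pa: float,
                       conditions: Conditions = Conditions(),
                       nad_couple: RedoxCouple = NAD_COUPLE,
                       h2_couple: RedoxCouple = H2_COUPLE) -> float:
    """NADH/NAD+ ratio whose equilibrium hydrogen pressure equals ``p_h2_Pa``.

    Exact inverse of :func:`equilibrium_h2_pressure` (linear in p).
    """
    if p_h2_Pa <= 0:
        raise ValueError("pressure must be positive")
    unit = equilibrium_h2_pressure(1.0, conditions, nad_couple, h2_couple).p_h2_Pa
    return p_h2_Pa / unit


def headspace_amount(p_Pa: float, headspace_volume_L: float,
                     temperature_K: float) -> float:
    """Ideal-gas amount of hydrogen in a headspace, in nanomoles."""
    if p_Pa < 0 or headspace_volume_L <= 0 or temperature_K <= 0:
        raise ValueError("pressure must be >= 0; volume and temperature positive")
    mol = p_Pa * headspace_volume_L * 1e-3 / (R * temperature_K)
    return mol * 1e9
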