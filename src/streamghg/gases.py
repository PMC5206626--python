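"""Physical chemistry of dissolved gases in fresh water.

Everything downstream of this module works in a fixed unit system:
concentrations in uM (numerically identical to mmol m-3), gas transfer
velocities in m d-1, diffusive fluxes in mmol m-2 d-1, temperatures in
deg C.  Conversions to other units happen only at I/O boundaries.

The module provides Schmidt numbers Sc(T), the Sc-based normalisation of
gas transfer velocities to k600 (Sc = 600 is CO2 in fresh water at
20 deg C), Henry's-law equilibrium concentrations, the diffusive flux
F = k (C_aq - C_eq), and CH4 -> CO2-equivalent conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

__all__ = [
    "GasSpec",
    "CH4",
    "CO2",
    "PROPANE",
    "GASES",
    "schmidt_number",
    "k600_from_k",
    "k_gas_from_k600",
    "equilibrium_concentration",
    "diffusive_flux",
    "co2_equivalents",
    "water_kinematic_viscosity",
]

#: Validity range (deg C) of the freshwater Schmidt-number fits.
TEMP_MIN = 0.0
TEMP_MAX = 35.0


def _vogel_viscosity(temp_c: float) -> float:
    """Dynamic viscosity of pure water (mPa s), Vogel-type correlation."""
    t_k = temp_c + 273.15
    return math.exp(-3.7188 + 578.919 / (t_k - 137.546))


def _water_density(temp_c: float) -> float:
    """Density of pure water (kg m-3), Kell-type polynomial."""
    t = temp_c
    return 999.974950 * (
        1.0 - (t - 3.983035) ** 2 * (t + 301.797) / (522528.9 * (t + 69.34881))
    )


def water_kinematic_viscosity(temp_c: float) -> float:
    """Kinematic viscosity of pure water in cm2 s-1."""
    # mPa s -> Pa s is 1e-3; m2 s-1 -> cm2 s-1 is 1e4
    return _vogel_viscosity(temp_c) * 1e-3 / _water_density(temp_c) * 1e4


@dataclass(frozen=True)
class GasSpec:
    """Per-gas physical constants.

    Parameters
    ----------
    name : str
        Identifier ("CH4", "CO2", "C3H8").
    molar_mass : float
        g mol-1.
    schmidt_coeffs : tuple of float, optional
        Ascending-order polynomial coefficients of Sc(T), T in deg C
        (freshwater fits).  If ``None``, Sc is computed as nu(T)/D(T)
        from ``diffusivity_arrhenius``.
    diffusivity_arrhenius : (float, float), optional
        ``(A_cm2_s, Ea_over_R_K)`` of an Arrhenius diffusivity
        D(T) = A exp(-Ea/R / T_K) in cm2 s-1.
    henry : callable, optional
        KH(T degC) -> mol L-1 atm-1, freshwater solubility function.
    """

    name: str
    molar_mass: float
    schmidt_coeffs: tuple[float, ...] | None = None
    diffusivity_arrhenius: tuple[float, float] | None = None
    henry: Callable[[float], float] | None = None

    def solubility(self, temp_c: float) -> float:
        """KH(T) in mol L-1 atm-1."""
        if self.henry is None:
            raise ValueError(f"no solubility function defined for {self.name}")
        return self.henry(temp_c)


def _kh_co2_weiss(temp_c: float) -> float:
    # Weiss-type freshwater CO2 solubility, mol L-1 atm-1.
    t_k = temp_c + 273.15
    return math.exp(
        -58.0931 + 90.5069 * (100.0 / t_k) + 22.2940 * math.log(t_k / 100.0)
    )


def _kh_ch4_freshwater(temp_c: float) -> float:
    # Yamamoto-type freshwater CH4 Bunsen solubility divided by the molar
    # volume of an ideal gas at STP (22.414 L mol-1) -> mol L-1 atm-1.
    t_k = temp_c + 273.15
    bunsen = math.exp(
        -67.1962 + 99.1624 * (100.0 / t_k) + 27.9015 * math.log(t_k / 100.0)
    )
    return bunsen / 22.414


def _kh_propane(temp_c: float) -> float:
    # van 't Hoff extrapolation from KH(25 degC) = 1.4e-3 mol L-1 atm-1.
    t_k = temp_c + 273.15
    return 1.4e-3 * math.exp(2400.0 * (1.0 / t_k - 1.0 / 298.15))


# Freshwater Schmidt-number polynomials (fourth order in T/degC); the
# CO2 fit evaluates to 600 (nearest integer) at 20 degC, which anchors
# the k600 convention.
CO2 = GasSpec(
    name="CO2",
    molar_mass=44.01,
    schmidt_coeffs=(1923.6, -125.06, 4.3773, -0.085681, 0.00070284),
    henry=_kh_co2_weiss,
)

CH4 = GasSpec(
    name="CH4",
    molar_mass=16.04,
    schmidt_coeffs=(1909.4, -120.78, 4.1555, -0.080578, 0.00065777),
    henry=_kh_ch4_freshwater,
)

# Propane has no published freshwater Sc polynomial; Sc = nu/D with an
# Arrhenius fit through the Wise & Houghton diffusivity data
# (D ~ 1.10e-5 cm2 s-1 at 20 degC, activation temperature 2137 K).
PROPANE = GasSpec(
    name="C3H8",
    molar_mass=44.10,
    diffusivity_arrhenius=(1.61e-2, 2137.0),
    henry=_kh_propane,
)

GASES: dict[str, GasSpec] = {g.name: g for g in (CH4, CO2, PROPANE)}


def schmidt_number(gas: GasSpec, temp_c: float) -> float:
    """Schmidt number of `gas` in fresh water at `temp_c` (deg C).

    Raises
    ------
    ValueError
        If `temp_c` lies outside the fit validity range [0, 35] deg C.
    """
    if not (TEMP_MIN <= temp_c <= TEMP_MAX):
        raise ValueError(
            f"temperature {temp_c} degC outside the Schmidt-number validity "
            f"range [{TEMP_MIN}, {TEMP_MAX}] degC for {gas.name}"
        )
    if gas.schmidt_coeffs is not None:
        return float(sum(a * temp_c**i for i, a in enumerate(gas.schmidt_coeffs)))
    if gas.diffusivity_arrhenius is not None:
        a, ea_over_r = gas.diffusivity_arrhenius
        diff = a * math.exp(-ea_over_r / (temp_c + 273.15))  # cm2 s-1
        return water_kinematic_viscosity(temp_c) / diff
    raise ValueError(f"no Schmidt-number parameterisation for {gas.name}")


def k600_from_k(k: float, sc: float) -> float:
    """Normalise a gas transfer velocity to Sc = 600.

    k600 = k * (600/Sc)**(-1/2); `k` in m d-1.
    """
    if sc <= 0:
        raise ValueError(f"Schmidt number must be positive, got {sc}")
    return k * (600.0 / sc) ** -0.5


def k_gas_from_k600(k600: float, sc_gas: float) -> float:
    """Denormalise k600 to a specific gas: k_g = k600 * (Sc_g/600)**(-1/2)."""
    if sc_gas <= 0:
        raise ValueError(f"Schmidt number must be positive, got {sc_gas}")
    return k600 * (sc_gas / 600.0) ** -0.5


def equilibrium_concentration(
    atm_mixing_ratio_ppm: float,
    temp_c: float,
    gas: GasSpec,
    pressure_atm: float = 1.0,
) -> float:
    """Henry's-law water concentration in equilibrium with the atmosphere.

    C_eq = KH(T) * x * P with x the mixing ratio; returned in uM.
    """
    if atm_mixing_ratio_ppm < 0:
        raise ValueError("atmospheric mixing ratio must be non-negative")
    kh = gas.solubility(temp_c)  # mol L-1 atm-1
    partial_pressure = atm_mixing_ratio_ppm * 1e-6 * pressure_atm
    return kh * partial_pressure * 1e6  # mol L-1 -> umol L-1


def diffusive_flux(k_gas: float, c_aq: float, c_eq: float) -> float:
    """Diffusive gas flux to the atmosphere, F = k (C_aq - C_eq).

    With `k_gas` in m d-1 and concentrations in uM (= mmol m-3) the
    result is in mmol m-2 d-1; negative for undersaturated water.
    """
    if k_gas < 0:
        raise ValueError("gas transfer velocity must be non-negative")
    return k_gas * (c_aq - c_eq)


def co2_equivalents(
    ch4_mass_kg: float, co2_mass_mg: float, gwp: float = 28.0
) -> tuple[float, float]:
    """Combine annual CH4 (kg) and CO2 (Mg) into CO2-equivalents.

    Returns ``(total_Mg_co2eq, ch4_share_pct)`` using a mass-based
    100-yr global warming potential (default 28) for CH4.  The share is
    reported as 0 when the total is zero.
    """
    if ch4_mass_kg < 0 or co2_mass_mg < 0:
        raise ValueError("masses must be non-negative")
    ch4_co2eq_mg = ch4_mass_kg * gwp / 1000.0
    total = co2_mass_mg + ch4_co2eq_mg
    share = 100.0 * ch4_co2eq_mg / total if total > 0 else 0.0
    return total, share
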