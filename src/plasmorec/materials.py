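"""Dispersive material models for the SPR fiber sensor.

Conventions
-----------
Time dependence is ``exp(-i*omega*t)`` throughout the package, so a passive
(lossy) medium has ``Im(eps) >= 0``.  All lengths are metres, angular
frequencies rad/s, number densities m^-3.

The gold film follows a single-Lorentz-pole Drude-Lorentz dispersion

    eps(w) = eps_inf - w_D^2 / (w^2 + i*g_D*w)
                     - d_eps * w_L^2 / (w^2 - w_L^2 + i*g_L*w)

with the Drude plasma frequency ``w_D`` proportional to the square root of
the free-electron density.  Excess charge ``dN`` driven onto the film by an
electrode potential therefore rescales it to

    w_D' = w_D * sqrt(1 + dN/N)

which is the sensing mechanism: the neuron's transmembrane potential charges
the gold double layer, shifts the plasma frequency, and moves the plasmon
absorption peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.constants import c as C_LIGHT
from scipy.constants import e as E_CHARGE

__all__ = [
    "WAVELENGTH_MIN",
    "WAVELENGTH_MAX",
    "DrudeLorentzParams",
    "ChargeState",
    "Medium",
    "VIAL_GOLD",
    "GOLD_ELECTRON_DENSITY",
    "modified_plasma_frequency",
    "voltage_to_delta_N",
    "drude_lorentz_permittivity",
    "silica_permittivity",
    "silica_index",
    "cladding_index",
    "buffer_permittivity",
    "make_silica",
    "make_cladding",
    "make_buffer",
    "make_gold",
]

#: Validity window of every dispersion model in this module (metres).
WAVELENGTH_MIN = 300e-9
WAVELENGTH_MAX = 2000e-9

#: Free-electron density of bulk gold (one 6s electron per atom), m^-3.
GOLD_ELECTRON_DENSITY = 5.90e28


class WavelengthRangeError(ValueError):
    """Vacuum wavelength outside the dispersion models' validity window."""


def _check_wavelength(lambda0) -> np.ndarray:
    lam = np.asarray(lambda0, dtype=float)
    if np.any(lam < WAVELENGTH_MIN) or np.any(lam > WAVELENGTH_MAX):
        raise WavelengthRangeError(
            f"wavelength {lambda0!r} outside validity window "
            f"[{WAVELENGTH_MIN*1e9:.0f} nm, {WAVELENGTH_MAX*1e9:.0f} nm]"
        )
    return lam


@dataclass(frozen=True)
class DrudeLorentzParams:
    """Parameters of the single-pole Drude-Lorentz metal dispersion.

    Attributes
    ----------
    eps_inf : float
        High-frequency permittivity limit (dimensionless, >= 1).
    omega_D, gamma_D : float
        Drude plasma frequency and collision rate, rad/s.
    omega_L, gamma_L : float
        Lorentz oscillator resonance frequency and width, rad/s.
    delta_eps : float
        Dimensionless Lorentz oscillator strength (>= 0).
    """

    eps_inf: float
    omega_D: float
    gamma_D: float
    omega_L: float
    gamma_L: float
    delta_eps: float

    def __post_init__(self) -> None:
        if self.eps_inf < 1.0:
            raise ValueError("eps_inf must be >= 1")
        if self.delta_eps < 0.0:
            raise ValueError("delta_eps must be >= 0")
        for name in ("omega_D", "omega_L"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("gamma_D", "gamma_L"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")


#: Default gold parameter set: the widely used single-Lorentz-pole fit of the
#: Drude-Lorentz model to tabulated experimental gold optical constants over
#: the visible/near-IR (Vial et al., Phys. Rev. B 71, 085416, 2005).
VIAL_GOLD = DrudeLorentzParams(
    eps_inf=5.9673,
    omega_D=2 * np.pi * 2113.6e12,  # 1.3280e16 rad/s
    gamma_D=2 * np.pi * 15.92e12,   # 1.0003e14 rad/s
    omega_L=2 * np.pi * 650.07e12,  # 4.0845e15 rad/s
    gamma_L=2 * np.pi * 104.86e12,  # 6.5885e14 rad/s
    delta_eps=1.09,
)


@dataclass(frozen=True)
class ChargeState:
    """Electrical state of the gold film under an applied potential.

    ``delta_N`` is the signed excess free-electron density residing in the
    charged region of the film; ``N`` is the unperturbed density.  The
    constructor enforces ``1 + delta_N/N > 0`` so the modified plasma
    frequency stays real, and that zero potential carries zero excess charge.
    """

    potential: float = 0.0                 # volts on the gold electrode
    N: float = GOLD_ELECTRON_DENSITY       # m^-3
    delta_N: float = 0.0                   # m^-3, signed
    capacitance_per_area: float = 0.2      # F/m^2
    charge_layer_thickness: float = 0.8e-9  # m

    def __post_init__(self) -> None:
        if self.N <= 0.0:
            raise ValueError("free-electron density N must be positive")
        if 1.0 + self.delta_N / self.N <= 0.0:
            raise ValueError(
                "1 + delta_N/N must be positive (modified plasma frequency real)"
            )
        if self.potential == 0.0 and self.delta_N != 0.0:
            raise ValueError("delta_N must vanish at zero potential")

    @classmethod
    def from_potential(
        cls,
        potential: float,
        *,
        capacitance_per_area: float = 0.2,
        charge_layer_thickness: float = 0.8e-9,
        N: float = GOLD_ELECTRON_DENSITY,
        sign_convention: int = -1,
    ) -> "ChargeState":
        """Build the charge state for an electrode potential.

        ``sign_convention=-1`` (default): a positive potential on the gold
        depletes electrons (``delta_N < 0``); ``+1`` flips this.
        """
        dN = voltage_to_delta_N(potential, capacitance_per_area, charge_layer_thickness)
        return cls(
            potential=potential,
            N=N,
            delta_N=sign_convention * dN,
            capacitance_per_area=capacitance_per_area,
            charge_layer_thickness=charge_layer_thickness,
        )


@dataclass(frozen=True)
class Medium:
    """A named medium with a wavelength-dependent relative permittivity."""

    name: str
    permittivity_fn: Callable[[float], complex] = field(repr=False)

    def permittivity(self, lambda0: float) -> complex:
        return self.permittivity_fn(lambda0)

    def index(self, lambda0: float) -> complex:
        return np.sqrt(complex(self.permittivity_fn(lambda0)))


def modified_plasma_frequency(omega_D: float, delta_N: float, N: float) -> float:
    """Plasma frequency of a metal whose electron density changed by ``delta_N``.

    ``omega_p^2`` is proportional to the free-electron density, so

        omega_D' = omega_D * sqrt(1 + delta_N / N).
    """
    if N <= 0.0:
        raise ValueError("N must be positive")
    ratio = 1.0 + delta_N / N
    if ratio <= 0.0:
        raise ValueError(f"1 + delta_N/N = {ratio} must be positive")
    return omega_D * np.sqrt(ratio)


def voltage_to_delta_N(
    potential: float,
    capacitance_per_area: float,
    charge_layer_thickness: float,
) -> float:
    """Unsigned-convention excess electron density for an electrode potential.

    A double layer of areal capacitance ``C`` charged to ``V`` stores surface
    charge ``sigma = C*V``; spread over a layer of thickness ``d`` this is an
    electron-density change of magnitude ``C*V / (e*d)``.  The returned value
    carries the sign of ``V``; the caller applies the electrode sign
    convention (see :meth:`ChargeState.from_potential`).
    """
    if capacitance_per_area <= 0.0:
        raise ValueError("capacitance_per_area must be positive")
    if charge_layer_thickness <= 0.0:
        raise ValueError("charge_layer_thickness must be positive")
    return capacitance_per_area * potential / (E_CHARGE * charge_layer_thickness)


def drude_lorentz_permittivity(
    lambda0,
    params: DrudeLorentzParams = VIAL_GOLD,
    charge: Optional[ChargeState] = None,
):
    """Complex relative permittivity of the (possibly charged) metal.

    Parameters
    ----------
    lambda0 : float or array
        Vacuum wavelength in metres, within [300 nm, 2000 nm].
    params : DrudeLorentzParams
        Dispersion parameters; defaults to the gold fit :data:`VIAL_GOLD`.
    charge : ChargeState, optional
        If given, the Drude plasma frequency is replaced by the
        charge-modified value.

    Returns
    -------
    complex or complex ndarray with ``Im(eps) >= 0``.
    """
    lam = _check_wavelength(lambda0)
    omega = 2.0 * np.pi * C_LIGHT / lam
    omega_D = params.omega_D
    if charge is not None:
        omega_D = modified_plasma_frequency(omega_D, charge.delta_N, charge.N)
    drude = omega_D**2 / (omega**2 + 1j * params.gamma_D * omega)
    lorentz = (
        params.delta_eps
        * params.omega_L**2
        / (omega**2 - params.omega_L**2 + 1j * params.gamma_L * omega)
    )
    eps = params.eps_inf - drude - lorentz
    if np.isscalar(lambda0):
        return complex(eps)
    return eps


# Malitson (1965) three-term Sellmeier fit for fused silica; lambda in um.
_SELLMEIER_B = (0.6961663, 0.4079426, 0.8974794)
_SELLMEIER_C = (0.0684043**2, 0.1162414**2, 9.896161**2)  # um^2


def silica_index(lambda0):
    """Refractive index of fused silica (Sellmeier fit), real."""
    lam_um2 = (_check_wavelength(lambda0) * 1e6) ** 2
    n2 = 1.0 + sum(B * lam_um2 / (lam_um2 - C) for B, C in zip(_SELLMEIER_B, _SELLMEIER_C))
    n = np.sqrt(n2)
    return float(n) if np.isscalar(lambda0) else n


def silica_permittivity(lambda0):
    """Relative permittivity of fused silica (real, lossless)."""
    n = silica_index(lambda0)
    return n * n


def cladding_index(lambda0, na: float = 0.22, na_reference_wavelength: float = 633e-9):
    """Index of the fiber cladding.

    The cladding is modelled as depressed-index silica: the fractional index
    step ``Delta`` is fixed so the numerical aperture equals ``na`` at the
    reference wavelength, then applied at every wavelength (the glass
    dispersion is carried by the silica Sellmeier fit).
    """
    n_ref = silica_index(na_reference_wavelength)
    if not 0.0 < na < n_ref:
        raise ValueError("numerical aperture must lie in (0, n_core)")
    delta = 1.0 - np.sqrt(n_ref**2 - na**2) / n_ref
    return silica_index(lambda0) * (1.0 - delta)


def buffer_permittivity(lambda0, n: float = 1.334):
    """Relative permittivity of the aqueous buffer (constant index).

    1X phosphate-buffered saline is modelled as a non-dispersive dielectric
    of refractive index ``n`` (default 1.334).
    """
    _check_wavelength(lambda0)
    if np.isscalar(lambda0):
        return n * n
    return np.full(np.shape(lambda0), n * n, dtype=float)


# ---------------------------------------------------------------------------
# Medium factories


def make_silica() -> Medium:
    return Medium("silica_core", lambda lam: complex(silica_permittivity(lam)))


def make_cladding(na: float = 0.22) -> Medium:
    return Medium("cladding", lambda lam: complex(cladding_index(lam, na=na) ** 2))


def make_buffer(n: float = 1.334) -> Medium:
    return Medium("buffer", lambda lam: complex(buffer_permittivity(lam, n=n)))


def make_gold(
    params: DrudeLorentzParams = VIAL_GOLD,
    charge: Optional[ChargeState] = None,
    name: str = "gold",
) -> Medium:
    return Medium(name, lambda lam: complex(drude_lorentz_permittivity(lam, params, charge)))
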