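"""Planar multilayer optics and the multimode-fiber ray transmission model.

Two roles:

* the fast spectrum engine of the sensor pipeline — the polished fiber is
  idealised as a plane silica | gold | buffer stack interrogated by rays
  bouncing under total internal reflection; and
* the independent one-dimensional oracle for the 2-D mode solver — complex
  slab-mode indices from a transfer-matrix dispersion determinant.

Transfer matrices are the Abelès characteristic matrices; the time
convention is ``exp(-i*omega*t)`` and transverse wavenumbers take the branch
``Im(kz) >= 0`` so evanescent tails decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .materials import Medium

__all__ = [
    "LayerStack",
    "RayModelParams",
    "reflectance",
    "fiber_transmission",
    "spp_effective_index",
    "spp_phase_matching_angle",
    "kretschmann_dip_angle",
    "slab_mode_dispersion",
    "slab_mode_neff",
]

#: Sentinel thickness of the two semi-infinite outer layers.
SEMI_INF = math.inf


class EvanescentBookkeepingError(RuntimeError):
    """Raised when reflectance bookkeeping would yield unphysical R > 1."""


@dataclass(frozen=True)
class LayerStack:
    """Ordered planar stack: (medium, thickness) with semi-infinite ends.

    The first entry is the incidence half-space (the fiber core), the last
    the ambient half-space; both carry the :data:`SEMI_INF` sentinel.
    """

    layers: Tuple[Tuple[Medium, float], ...]

    def __init__(self, layers: Sequence[Tuple[Medium, float]]):
        layers = tuple((m, float(d)) for m, d in layers)
        if len(layers) < 2:
            raise ValueError("a stack needs at least two layers")
        if not (math.isinf(layers[0][1]) and math.isinf(layers[-1][1])):
            raise ValueError("first and last layer must be semi-infinite")
        for _, d in layers[1:-1]:
            if not (0.0 < d < math.inf):
                raise ValueError("interior layer thicknesses must be finite and positive")
        object.__setattr__(self, "layers", layers)

    @property
    def media(self) -> Tuple[Medium, ...]:
        return tuple(m for m, _ in self.layers)

    def permittivities(self, lambda0: float) -> np.ndarray:
        return np.array([m.permittivity(lambda0) for m, _ in self.layers], dtype=complex)

    def thicknesses(self) -> np.ndarray:
        return np.array([d for _, d in self.layers], dtype=float)


@dataclass(frozen=True)
class RayModelParams:
    """Geometric-optics parameters of the sensing region.

    ``gold_bounce_fraction`` is the fraction of wall reflections that strike
    the gold-coated surface (1 for a film covering the whole perimeter, 1/2
    when gold covers one side of the polished fiber); the remaining bounces
    are lossless total internal reflections at the intact cladding.
    """

    sensing_length: float = 5e-3
    core_diameter: float = 10e-6
    numerical_aperture: float = 0.22
    angular_distribution: str = "uniform_angle"  # or "mode_power"
    n_angles: int = 64
    gold_bounce_fraction: float = 1.0
    polarization: str = "unpolarized"            # or "p"
    theta_max: float = math.radians(89.5)

    def __post_init__(self) -> None:
        if self.sensing_length <= 0.0:
            raise ValueError("sensing_length must be positive")
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("numerical aperture must lie in (0, 1)")
        if self.n_angles < 16:
            raise ValueError("n_angles must be at least 16")
        if not 0.0 < self.gold_bounce_fraction <= 1.0:
            raise ValueError("gold_bounce_fraction must lie in (0, 1]")


def _kz(eps, k0, kx):
    """Transverse wavenumber with the decaying branch ``Im(kz) >= 0``."""
    kz = np.sqrt(eps * k0**2 - np.asarray(kx) ** 2 + 0j)
    # principal sqrt already gives Im >= 0 for Im(arg) >= 0; guard the
    # numerically-negative-imaginary corner explicitly
    flip = kz.imag < 0
    return np.where(flip, -kz, kz)


def _amplitudes(eps, d, k0, kx, polarization):
    """Complex r, t and admittances for a stack; broadcasts over k0/kx.

    ``eps`` has the layer axis first.  Returns (r, t, q_in, q_out).
    """
    n_layers = eps.shape[0]
    kz = _kz(eps, k0, kx)
    if polarization == "p":
        q = kz / (k0 * eps)
    elif polarization == "s":
        q = kz / k0
    else:
        raise ValueError("polarization must be 'p' or 's'")

    # characteristic matrix product over interior layers
    m00 = np.ones_like(q[0])
    m01 = np.zeros_like(q[0])
    m10 = np.zeros_like(q[0])
    m11 = np.ones_like(q[0])
    for j in range(1, n_layers - 1):
        delta = kz[j] * d[j]
        c = np.cos(delta)
        s = np.sin(delta)
        a00, a01 = c, -1j * s / q[j]
        a10, a11 = -1j * q[j] * s, c
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )

    q_in, q_out = q[0], q[-1]
    denom = q_in * (m00 + m01 * q_out) + (m10 + m11 * q_out)
    r = (q_in * (m00 + m01 * q_out) - (m10 + m11 * q_out)) / denom
    t = 2.0 * q_in / denom
    return r, t, q_in, q_out


def reflectance(stack: LayerStack, lambda0, theta, polarization: str = "p") -> dict:
    """Power reflectance of a plane wave incident from the first medium.

    Parameters
    ----------
    stack : LayerStack
    lambda0 : float
        Vacuum wavelength (m).
    theta : float or array
        Angle of incidence from the stack normal, in (0, pi/2), radians.
    polarization : {'p', 's'}

    Returns
    -------
    dict with ``R`` (power reflectance), ``r`` (amplitude), ``T`` (power
    transmittance into the final half-space; 0 under total internal
    reflection).
    """
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr <= 0.0) or np.any(theta_arr >= np.pi / 2):
        raise ValueError("theta must lie strictly inside (0, pi/2)")
    eps = stack.permittivities(lambda0)
    if eps[0].imag != 0.0:
        raise ValueError("incidence medium must be lossless")
    d = stack.thicknesses()
    k0 = 2.0 * np.pi / lambda0
    n_in = np.sqrt(eps[0].real)
    kx = k0 * n_in * np.sin(theta_arr)

    eps_b = eps.reshape((len(eps),) + (1,) * theta_arr.ndim)
    r, t, q_in, q_out = _amplitudes(eps_b, d, k0, kx, polarization)
    R = np.abs(r) ** 2
    if np.any(R > 1.0 + 1e-8):
        raise EvanescentBookkeepingError(
            f"reflectance exceeded unity (max {float(np.max(R)):.6g})"
        )
    R = np.minimum(R, 1.0)
    # transmitted power flux; zero for evanescent transmission
    T = np.real(q_out) / np.real(q_in) * np.abs(t) ** 2
    if theta_arr.ndim == 0:
        return {"R": float(R), "r": complex(r), "T": float(T)}
    return {"R": R, "r": r, "T": T}


def _quadrature(theta_c, theta_max, n):
    x, w = np.polynomial.legendre.leggauss(n)
    theta = 0.5 * (theta_max - theta_c) * x + 0.5 * (theta_max + theta_c)
    weight = 0.5 * (theta_max - theta_c) * w
    return theta, weight


def fiber_transmission(stack: LayerStack, params: RayModelParams, lambda0: float) -> float:
    """Power transmission of the sensing region at one wavelength.

    A ray at internal angle ``theta`` (from the wall normal) undergoes
    ``N(theta) = L / (D * tan(theta))`` wall reflections over the sensing
    length ``L`` of a core of transverse extent ``D``; a fraction
    ``gold_bounce_fraction`` of them strike the gold film with power
    reflectance ``R(theta, lambda)``, the rest are lossless.  The launch
    power is averaged over the guided angular range set by the numerical
    aperture:

        T(lambda) = Int P(theta) * R^(N_gold(theta)) dtheta / Int P(theta) dtheta
    """
    eps = stack.permittivities(lambda0)
    n_in = math.sqrt(eps[0].real)
    na = params.numerical_aperture
    if na >= n_in:
        raise ValueError("numerical aperture inconsistent with core index")
    sin_theta_c = math.sqrt(n_in**2 - na**2) / n_in
    theta_c = math.asin(sin_theta_c)
    if theta_c >= params.theta_max:
        raise ValueError("empty guided angular range")

    theta, w = _quadrature(theta_c, params.theta_max, params.n_angles)
    if params.angular_distribution == "uniform_angle":
        p_launch = np.ones_like(theta)
    elif params.angular_distribution == "mode_power":
        p_launch = np.sin(theta) * np.cos(theta)
    else:
        raise ValueError(f"unknown angular distribution {params.angular_distribution!r}")

    n_gold = params.gold_bounce_fraction * params.sensing_length / (
        params.core_diameter * np.tan(theta)
    )
    r_p = reflectance(stack, lambda0, theta, "p")["R"]
    if params.polarization == "p":
        per_ray = r_p**n_gold
    elif params.polarization == "unpolarized":
        r_s = reflectance(stack, lambda0, theta, "s")["R"]
        per_ray = 0.5 * (r_p**n_gold + r_s**n_gold)
    else:
        raise ValueError(f"unknown polarization {params.polarization!r}")

    T = float(np.sum(w * p_launch * per_ray) / np.sum(w * p_launch))
    return min(max(T, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Analytic SPP helpers (oracles)


def spp_effective_index(eps_metal: complex, eps_dielectric: complex) -> complex:
    """Effective index of the bound SPP at a single metal-dielectric interface."""
    return np.sqrt(eps_metal * eps_dielectric / (eps_metal + eps_dielectric) + 0j)


def spp_phase_matching_angle(eps_metal: complex, eps_dielectric: complex, n_prism: float) -> float:
    """Internal angle where the evanescent tail phase-matches the SPP.

    Solves ``n_prism * sin(theta) = Re(n_spp)`` (radians).
    """
    n_spp = spp_effective_index(eps_metal, eps_dielectric).real
    s = n_spp / n_prism
    if not 0.0 < s < 1.0:
        raise ValueError("no phase-matching angle: Re(n_spp) outside (0, n_prism)")
    return math.asin(s)


def kretschmann_dip_angle(stack: LayerStack, lambda0: float, n_scan: int = 2000) -> float:
    """Angle of minimum p reflectance beyond the critical angle (radians)."""
    eps = stack.permittivities(lambda0)
    n_in = math.sqrt(eps[0].real)
    n_out = math.sqrt(eps[-1].real)
    theta_c = math.asin(min(n_out / n_in, 1.0 - 1e-9))
    theta = np.linspace(theta_c + 1e-4, math.radians(89.9), n_scan)
    R = reflectance(stack, lambda0, theta, "p")["R"]
    i = int(np.argmin(R))
    if 0 < i < len(theta) - 1:
        # parabolic refinement
        y0, y1, y2 = R[i - 1], R[i], R[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            return float(theta[i] + 0.5 * (y0 - y2) / denom * (theta[1] - theta[0]))
    return float(theta[i])


# ---------------------------------------------------------------------------
# 1-D slab-mode dispersion (oracle for the 2-D solver)


def slab_mode_dispersion(
    thicknesses: Sequence[float],
    permittivities: Sequence[complex],
    lambda0: float,
    n_eff: complex,
) -> complex:
    """TM dispersion determinant of a PEC-terminated planar stack.

    The stack is a finite sequence of layers sandwiched between perfect
    electric conductors (matching the windowed 2-D solver).  With
    ``u = H_t`` and ``v = u' / eps`` (proportional to the tangential E
    field), a PEC wall imposes ``v = 0``; launching ``(u, v) = (1, 0)`` at
    one wall and propagating the transfer matrix across the stack, the
    returned value is ``v`` at the far wall — zero exactly on a modal
    effective index.
    """
    k0 = 2.0 * np.pi / lambda0
    beta2 = (n_eff * k0) ** 2
    u, v = 1.0 + 0.0j, 0.0j
    for d, eps in zip(thicknesses, permittivities):
        kappa = np.sqrt(beta2 - eps * k0**2 + 0j)
        if abs(kappa) < 1e-6:            # near-degenerate: series limit
            ch, sh_over = 1.0 + 0.5 * (kappa * d) ** 2, d * (1 + (kappa * d) ** 2 / 6.0)
            u, v = u * ch + v * eps * sh_over, u * kappa**2 * sh_over / eps + v * ch
        else:
            ch = np.cosh(kappa * d)
            sh = np.sinh(kappa * d)
            u, v = u * ch + v * (eps / kappa) * sh, u * (kappa / eps) * sh + v * ch
    return v


def slab_mode_neff(
    thicknesses: Sequence[float],
    permittivities: Sequence[complex],
    lambda0: float,
    guess: complex,
    tol: float = 1e-12,
    max_iter: int = 80,
) -> complex:
    """Complex effective index of a TM slab mode near ``guess``.

    Secant iteration on :func:`slab_mode_dispersion`; the determinant is an
    analytic function of ``n_eff`` so complex secant converges quadratically
    from a decent guess.
    """
    f = lambda n: slab_mode_dispersion(thicknesses, permittivities, lambda0, n)
    x0 = complex(guess)
    x1 = x0 * (1 + 1e-5) + 1e-8
    f0, f1 = f(x0), f(x1)
    for _ in range(max_iter):
        if f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        if abs(x2 - x1) < tol * max(1.0, abs(x2)):
            return x2
        x0, f0, x1 = x1, f1, x2
        f1 = f(x1)
    if abs(f1) > 1e-6 * (abs(f0) + 1.0):
        raise RuntimeError(f"slab-mode root search failed near {guess}")
    return x1
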