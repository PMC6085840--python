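"""Full-vector finite-difference frequency-domain waveguide mode solver.

Solves the source-free curl-curl equation for the transverse electric field
of z-invariant structures,

    curl curl E - k0^2 eps_r E = 0,       E ~ exp(i beta z - i omega t),

discretised on the staggered (Yee-like) tensor grid of a
:class:`~plasmorec.geometry.PermittivityMap`.  Eliminating Ez through the
divergence condition ``div(eps E) = 0`` gives the standard transverse-field
eigenproblem

    beta^2 Ex = eps_x Ex + dy^2 Ex - dx dy Ey
               + dx[(1/eps_z)(dx(eps_x Ex) + dy(eps_y Ey))]
    beta^2 Ey = eps_y Ey + dx^2 Ey - dy dx Ex
               + dy[(1/eps_z)(dx(eps_x Ex) + dy(eps_y Ey))]

with Ex on (cell-centre x, vertex y) points, Ey on (vertex x, cell-centre y)
points and eps_z on cell vertices.  The window boundary is a perfect
electric conductor: tangential E vanishes there, which is adequate for the
bound and plasmon-hybrid modes this package needs (leaky-mode absorbers are
out of scope).  Eigenpairs come from sparse shift-invert Arnoldi iteration
targeted near a real effective-index guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.constants import epsilon_0, mu_0

from .geometry import PermittivityMap

__all__ = [
    "WaveProblem",
    "Mode",
    "SolverConvergenceError",
    "solve_modes",
    "modal_attenuation",
    "aggregate_absorption",
    "guided_modes",
]

ETA0 = math.sqrt(mu_0 / epsilon_0)


class SolverConvergenceError(RuntimeError):
    """Eigensolver failed; carries iteration diagnostics in ``.details``."""

    def __init__(self, message: str, details: Optional[dict] = None):
        super().__init__(message)
        self.details = details or {}


@dataclass(frozen=True)
class WaveProblem:
    """One modal eigenproblem: a permittivity map at one vacuum wavelength."""

    map: PermittivityMap
    lambda0: float
    n_modes: int = 10
    n_eff_guess: Optional[complex] = None

    def __post_init__(self) -> None:
        if self.lambda0 <= 0.0:
            raise ValueError("lambda0 must be positive")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if abs(self.map.lambda0 - self.lambda0) > 1e-15 + 1e-9 * self.lambda0:
            raise ValueError("permittivity map was built for a different wavelength")

    @property
    def k0(self) -> float:
        return 2.0 * math.pi / self.lambda0


@dataclass
class Mode:
    """One computed eigenmode of the cross-section.

    ``Ex`` is sampled at (cell-centre x, interior-vertex y) and ``Ey`` at
    (interior-vertex x, cell-centre y); both are normalised so the modal
    quasi-power ``Re(n_eff)/(2 eta0) * Int(|Ex|^2+|Ey|^2) dA`` equals 1.
    """

    n_eff: complex
    Ex: np.ndarray
    Ey: np.ndarray
    lambda0: float
    residual: float
    power: float = 1.0

    def mirror_x_defect(self) -> float:
        """Deviation from even/odd symmetry under x -> -x (0 = symmetric).

        Under the mirror, the x field component flips sign; a symmetric
        structure's modes satisfy (Ex, Ey)(-x) = s * (-Ex, Ey)(x) with
        s = +-1.  Returns the smaller residual over both parities, relative
        to the field norm.
        """
        ex_m = self.Ex[::-1, :]
        ey_m = self.Ey[::-1, :]
        norm = math.sqrt(float(np.sum(np.abs(self.Ex) ** 2) + np.sum(np.abs(self.Ey) ** 2)))
        defects = []
        for s in (+1.0, -1.0):
            d = np.sum(np.abs(self.Ex + s * ex_m) ** 2) + np.sum(np.abs(self.Ey - s * ey_m) ** 2)
            defects.append(math.sqrt(float(d)) / norm)
        return min(defects)

    def export(self, path_prefix: str, provenance: Optional[dict] = None) -> None:
        """Dump Ex and Ey (real and imaginary parts) as plain-text arrays."""
        header = [f"n_eff={self.n_eff!r}", f"lambda0_m={self.lambda0!r}"]
        for k, v in (provenance or {}).items():
            header.append(f"{k}={v!r}")
        for name, arr in (("Ex", self.Ex), ("Ey", self.Ey)):
            for part, data in (("re", arr.real), ("im", arr.imag)):
                np.savetxt(
                    f"{path_prefix}_{name}_{part}.csv",
                    data,
                    delimiter=",",
                    header="\n".join(header),
                )


# ---------------------------------------------------------------------------
# Discrete operators


def _diff_pair(nodes: np.ndarray):
    """(Dc, Dv) 1-D difference matrices for one axis.

    ``Dc`` ((n_cells) x (n_cells+1)) differentiates vertex samples to cell
    centres; ``Dv`` ((n_cells-1) x n_cells) differentiates centre samples to
    interior vertices.
    """
    h = np.diff(nodes)                      # cell sizes
    n = len(h)
    Dc = sp.diags([-1.0 / h, 1.0 / h], offsets=[0, 1], shape=(n, n + 1), format="csr")
    g = 0.5 * (h[:-1] + h[1:])              # centre-to-centre spacings
    Dv = sp.diags([-1.0 / g, 1.0 / g], offsets=[0, 1], shape=(n - 1, n), format="csr")
    return Dc, Dv


def _staggered_eps(pmap: PermittivityMap):
    """(eps_x, eps_y, eps_z) on the staggered field/vertex points."""
    eps = pmap.eps
    hx = np.diff(pmap.xn)
    hy = np.diff(pmap.yn)
    # eps_x at (centre x, interior vertex y): y-thickness-weighted average
    wy0 = hy[:-1] / (hy[:-1] + hy[1:])
    eps_x = eps[:, :-1] * wy0 + eps[:, 1:] * (1.0 - wy0)
    # eps_y at (interior vertex x, centre y)
    wx0 = (hx[:-1] / (hx[:-1] + hx[1:]))[:, None]
    eps_y = eps[:-1, :] * wx0 + eps[1:, :] * (1.0 - wx0)
    # eps_z at interior vertices: area-weighted 4-cell average
    wxa = hx[:-1][:, None]
    wxb = hx[1:][:, None]
    wya = hy[:-1][None, :]
    wyb = hy[1:][None, :]
    area = (wxa + wxb) * (wya + wyb)
    eps_z = (
        eps[:-1, :-1] * wxa * wya
        + eps[1:, :-1] * wxb * wya
        + eps[:-1, 1:] * wxa * wyb
        + eps[1:, 1:] * wxb * wyb
    ) / area
    return eps_x, eps_y, eps_z


def _assemble(pmap: PermittivityMap, k0: float):
    """Sparse operator P (eigenvalues n_eff^2) plus the Ex/Ey array shapes."""
    Dcx, Dvx = _diff_pair(pmap.xn)
    Dcy, Dvy = _diff_pair(pmap.yn)
    nx = len(pmap.xn) - 1
    ny = len(pmap.yn) - 1
    # interior-vertex restrictions (PEC: fields/potentials vanish on the wall)
    Dcx_i = Dcx[:, 1:nx]
    Dcy_i = Dcy[:, 1:ny]

    Ix = sp.identity(nx, format="csr")
    Iy = sp.identity(ny, format="csr")
    Ixv = sp.identity(nx - 1, format="csr")
    Iyv = sp.identity(ny - 1, format="csr")

    eps_x, eps_y, eps_z = _staggered_eps(pmap)
    Ex_shape = (nx, ny - 1)
    Ey_shape = (nx - 1, ny)
    Dx_ex = sp.kron(Dvx, Iyv, format="csr")          # Ex -> vertices
    Dy_ey = sp.kron(Ixv, Dvy, format="csr")          # Ey -> vertices
    Dx_back = sp.kron(Dcx_i, Iyv, format="csr")      # vertices -> Ex points
    Dy_back = sp.kron(Ixv, Dcy_i, format="csr")      # vertices -> Ey points

    Mx = sp.diags(eps_x.ravel())
    My = sp.diags(eps_y.ravel())
    Wz = sp.diags(1.0 / eps_z.ravel())

    k2 = k0 * k0
    # second derivatives (PEC: tangential field zero on the wall)
    Lyy = sp.kron(Ix, Dvy @ Dcy_i, format="csr") / k2
    Lxx = sp.kron(Dvx @ Dcx_i, Iy, format="csr") / k2

    div_x = Dx_ex @ Mx                                # dx(eps_x Ex) at vertices
    div_y = Dy_ey @ My                                # dy(eps_y Ey) at vertices

    Pxx = Mx + Lyy + (Dx_back @ (Wz @ div_x)) / k2
    Pxy = (Dx_back @ (Wz @ div_y - Dy_ey)) / k2
    Pyy = My + Lxx + (Dy_back @ (Wz @ div_y)) / k2
    Pyx = (Dy_back @ (Wz @ div_x - Dx_ex)) / k2

    P = sp.bmat([[Pxx, Pxy], [Pyx, Pyy]], format="csc")
    return P, Ex_shape, Ey_shape


def _dielectric_guess(pmap: PermittivityMap) -> float:
    re = pmap.eps.real
    dielectric = re[re > 0.0]
    if dielectric.size == 0:
        raise ValueError("permittivity map has no dielectric cells")
    return float(np.sqrt(np.max(dielectric)))


def solve_modes(problem: WaveProblem, filter_spurious: bool = True) -> List[Mode]:
    """Compute the ``n_modes`` eigenmodes nearest the effective-index guess.

    Modes are sorted by descending ``Re(n_eff)``.  Eigenpairs whose phase
    index exceeds the largest material index (discretisation artefacts) are
    filtered out when ``filter_spurious`` is true.

    Raises
    ------
    SolverConvergenceError
        If the Arnoldi iteration does not converge; diagnostics are attached.
    """
    pmap = problem.map
    k0 = problem.k0
    P, ex_shape, ey_shape = _assemble(pmap, k0)
    n_ex = ex_shape[0] * ex_shape[1]

    guess = problem.n_eff_guess
    if guess is None:
        guess = _dielectric_guess(pmap)
    sigma = complex(guess) ** 2

    k = min(problem.n_modes + 4, P.shape[0] - 2)  # headroom for filtering
    try:
        vals, vecs = spla.eigs(P, k=k, sigma=sigma, which="LM")
    except spla.ArpackNoConvergence as exc:
        raise SolverConvergenceError(
            "mode eigensolver did not converge",
            details={
                "converged_eigenvalues": len(exc.eigenvalues),
                "requested": k,
                "sigma": sigma,
                "unknowns": P.shape[0],
            },
        ) from exc

    n_max = pmap.max_real_index()
    modes: List[Mode] = []
    order = np.argsort(-np.sqrt(vals).real)
    hx = np.diff(pmap.xn)
    hy = np.diff(pmap.yn)
    gx = 0.5 * (hx[:-1] + hx[1:])
    gy = 0.5 * (hy[:-1] + hy[1:])
    dA_ex = np.outer(hx, gy)
    dA_ey = np.outer(gx, hy)

    for idx in order:
        lam = vals[idx]
        n_eff = np.sqrt(lam + 0j)
        if n_eff.real < 0:
            n_eff = -n_eff
        if n_eff.imag < -1e-12:
            n_eff = np.conj(n_eff)
        if filter_spurious and n_eff.real > n_max + 1e-6:
            continue
        v = vecs[:, idx]
        res = float(np.linalg.norm(P @ v - lam * v) / (abs(lam) * np.linalg.norm(v)))
        Ex = v[:n_ex].reshape(ex_shape)
        Ey = v[n_ex:].reshape(ey_shape)
        quasi_power = (
            max(n_eff.real, 1e-12)
            / (2.0 * ETA0)
            * float(np.sum(np.abs(Ex) ** 2 * dA_ex) + np.sum(np.abs(Ey) ** 2 * dA_ey))
        )
        scale = 1.0 / math.sqrt(quasi_power)
        modes.append(
            Mode(
                n_eff=complex(n_eff),
                Ex=Ex * scale,
                Ey=Ey * scale,
                lambda0=problem.lambda0,
                residual=res,
            )
        )
        if len(modes) == problem.n_modes:
            break
    return modes


def guided_modes(modes: Sequence[Mode], n_low: float, n_high: float) -> List[Mode]:
    """Modes whose phase index lies in the guided band (n_low, n_high)."""
    return [m for m in modes if n_low < m.n_eff.real < n_high]


def modal_attenuation(mode: Mode, lambda0: float, length: float) -> float:
    """Fraction of modal power absorbed over ``length``.

    The power attenuation coefficient is ``alpha = 4 pi Im(n_eff) / lambda0``
    (twice the field decay rate ``2 pi Im(n_eff) / lambda0``); the absorbed
    fraction is ``1 - exp(-alpha * length)``.
    """
    im = mode.n_eff.imag
    if im < -1e-9:
        raise ValueError(f"negative modal loss Im(n_eff) = {im}")
    alpha = 4.0 * math.pi * max(im, 0.0) / lambda0
    return -math.expm1(-alpha * length)


def aggregate_absorption(
    modes: Sequence[Mode],
    weights: Optional[Sequence[float]],
    lambda0: float,
    length: float,
) -> float:
    """Launch-weighted mean absorbed power fraction over the sensing length."""
    if not modes:
        raise ValueError("no modes to aggregate")
    if weights is None:
        weights = np.full(len(modes), 1.0 / len(modes))
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(modes),):
        raise ValueError("weights length must match number of modes")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if not math.isclose(s, 1.0, rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError("weights must sum to 1")
    return float(sum(wi * modal_attenuation(m, lambda0, length) for wi, m in zip(w, modes)))
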