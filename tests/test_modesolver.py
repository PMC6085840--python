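"""Full-vector finite-difference mode solver against independent oracles."""

import math

import numpy as np
import pytest

from plasmorec.geometry import PermittivityMap, graded_axis, symmetric_axis
from plasmorec.materials import cladding_index, drude_lorentz_permittivity, silica_index
from plasmorec.modesolver import (
    Mode,
    WaveProblem,
    aggregate_absorption,
    guided_modes,
    modal_attenuation,
    solve_modes,
)
from plasmorec.planar import slab_mode_neff, spp_effective_index
from plasmorec.validation import bessel_he11_neff

LAM = 680e-9


def homogeneous_map(n: float, half_width: float, n_cells: int, lam: float) -> PermittivityMap:
    xn = np.linspace(-half_width, half_width, n_cells + 1)
    eps = np.full((n_cells, n_cells), n * n, dtype=complex)
    return PermittivityMap(xn, xn.copy(), eps, np.zeros_like(eps, dtype=np.int8), ("m",), lam)


def circular_fiber_map(a, n1, n2, lam, h):
    """Step-index fiber on a graded symmetric grid with sub-cell averaging."""
    xn = symmetric_axis(2 * a, [(a - 0.4e-6, a + 0.4e-6, h)], 2 * h)
    nss = 6
    offs = (np.arange(nss) + 0.5) / nss
    dx = np.diff(xn)
    acc = np.zeros((len(xn) - 1, len(xn) - 1), dtype=complex)
    for ox in offs:
        xs = xn[:-1] + ox * dx
        for oy in offs:
            ys = xn[:-1] + oy * dx
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            acc += np.where(np.hypot(X, Y) < a, n1 * n1, n2 * n2)
    eps = acc / (nss * nss)
    return PermittivityMap(xn, xn.copy(), eps, np.zeros_like(eps, dtype=np.int8), ("m",), lam)


class TestHomogeneousLimit:
    def test_box_fundamental_converges_second_order(self):
        """Uniform medium in the PEC window: the scalar-like fundamental equals
        sqrt(n^2 - 2 (pi/L/k0)^2); error shrinks ~4x per mesh halving."""
        n, W = 1.45, 2e-6
        k0 = 2 * math.pi / LAM
        kt = math.pi / (2 * W)
        exact = math.sqrt(n * n - 2 * (kt / k0) ** 2)
        errs = []
        for cells in (60, 120):
            pm = homogeneous_map(n, W, cells, LAM)
            modes = solve_modes(WaveProblem(map=pm, lambda0=LAM, n_modes=3, n_eff_guess=n))
            scalar_like = min(modes, key=lambda m: abs(m.n_eff.real - exact))
            errs.append(abs(scalar_like.n_eff.real - exact))
        assert errs[0] < 5e-5
        assert errs[0] / errs[1] > 2.5  # ~O(h^2)

    def test_te_like_pair_degenerate(self):
        """The two lowest vector box modes (single transverse half-wave) are a
        degenerate pair at sqrt(n^2 - (pi/L/k0)^2)."""
        n, W = 1.45, 2e-6
        k0 = 2 * math.pi / LAM
        kt = math.pi / (2 * W)
        exact = math.sqrt(n * n - (kt / k0) ** 2)
        pm = homogeneous_map(n, W, 80, LAM)
        modes = solve_modes(WaveProblem(map=pm, lambda0=LAM, n_modes=2, n_eff_guess=n))
        assert modes[0].n_eff.real == pytest.approx(exact, abs=2e-5)
        assert modes[0].n_eff.real == pytest.approx(modes[1].n_eff.real, abs=1e-9)


class TestStepIndexFiber:
    def test_fundamental_matches_bessel_dispersion(self):
        """HE11 of the 5 um, NA 0.22 fiber agrees with the exact Bessel root
        within 1e-4, and the error shrinks under grid refinement."""
        a, na = 5e-6, 0.22
        n1 = silica_index(LAM)
        n2 = cladding_index(LAM, na=na)
        target = bessel_he11_neff(a, n1, n2, LAM)
        errs = []
        for h in (200e-9, 120e-9):
            pm = circular_fiber_map(a, n1, n2, LAM, h)
            modes = solve_modes(WaveProblem(map=pm, lambda0=LAM, n_modes=2, n_eff_guess=n1))
            errs.append(abs(modes[0].n_eff.real - target))
        assert errs[-1] < 1e-4
        assert errs[1] < errs[0]

    def test_residual_and_loss_invariants(self):
        a, na = 5e-6, 0.22
        n1 = silica_index(LAM)
        n2 = cladding_index(LAM, na=na)
        pm = circular_fiber_map(a, n1, n2, LAM, 200e-9)
        modes = solve_modes(WaveProblem(map=pm, lambda0=LAM, n_modes=4, n_eff_guess=n1))
        for m in modes:
            assert m.residual < 1e-8
            assert m.n_eff.imag >= -1e-12  # passive map
            assert m.n_eff.real <= n1 + 1e-6  # spurious filtered


class TestExtrudedSlab:
    def test_plasmonic_mode_matches_1d_pole_search(self):
        """The x-invariant silica | gold 50 nm | water stack extruded to 2-D:
        the bound plasmonic mode's complex index matches the 1-D transfer-matrix
        dispersion root within 1% in both real and imaginary part."""
        lam = 633e-9
        eps = [
            complex(silica_index(lam) ** 2),
            drude_lorentz_permittivity(lam),
            complex(1.334**2),
        ]
        th = [1.5e-6, 50e-9, 2.0e-6]
        n1d = slab_mode_neff(th, eps, lam, spp_effective_index(eps[1], eps[2]))

        Lx = 40e-6
        xn = np.linspace(0.0, Lx, 11)
        yn = graded_axis(0.0, sum(th), [(th[0] - 0.3e-6, th[0] + th[1] + 0.3e-6, 5e-9)], 80e-9)
        yc = 0.5 * (yn[:-1] + yn[1:])
        eps_col = np.where(yc < th[0], eps[0], np.where(yc < th[0] + th[1], eps[1], eps[2]))
        eps2d = np.tile(eps_col, (len(xn) - 1, 1))
        pm = PermittivityMap(xn, yn, eps2d, np.zeros_like(eps2d, dtype=np.int8), ("m",), lam)

        # x-separability: the lowest transverse wavenumber is pi/Lx
        k0 = 2 * math.pi / lam
        target = np.sqrt(n1d**2 - (math.pi / Lx / k0) ** 2 + 0j)
        modes = solve_modes(
            WaveProblem(map=pm, lambda0=lam, n_modes=2, n_eff_guess=complex(target))
        )
        got = modes[0].n_eff
        assert abs(got.real - target.real) / abs(target.real) < 0.01
        assert abs(got.imag - target.imag) / abs(target.imag) < 0.01


class TestAttenuation:
    def test_closed_forms(self):
        m0 = Mode(n_eff=1.45 + 0j, Ex=np.zeros((2, 2)), Ey=np.zeros((2, 2)), lambda0=LAM, residual=0)
        assert modal_attenuation(m0, LAM, 1.0) == 0.0
        # alpha * L = ln 2  ->  half the power absorbed
        im = math.log(2) * LAM / (4 * math.pi)
        m = Mode(n_eff=1.45 + 1j * im, Ex=np.zeros((2, 2)), Ey=np.zeros((2, 2)), lambda0=LAM, residual=0)
        assert modal_attenuation(m, LAM, 1.0) == pytest.approx(0.5, rel=1e-12)
        # doubling the length composes exponentially: 1-(1-f)^2
        f1 = modal_attenuation(m, LAM, 0.3)
        f2 = modal_attenuation(m, LAM, 0.6)
        assert f2 == pytest.approx(1 - (1 - f1) ** 2, rel=1e-12)

    def test_negative_loss_rejected(self):
        m = Mode(n_eff=1.45 - 1e-3j, Ex=np.zeros((2, 2)), Ey=np.zeros((2, 2)), lambda0=LAM, residual=0)
        with pytest.raises(ValueError):
            modal_attenuation(m, LAM, 1.0)

    def test_aggregate_properties(self):
        def mk(im):
            return Mode(n_eff=1.44 + 1j * im, Ex=np.zeros((2, 2)), Ey=np.zeros((2, 2)),
                        lambda0=LAM, residual=0)

        modes = [mk(0.0), mk(1e-5), mk(5e-5)]
        L = 1e-3
        single = aggregate_absorption([modes[1]], [1.0], LAM, L)
        assert single == pytest.approx(modal_attenuation(modes[1], LAM, L))
        assert aggregate_absorption([mk(0.0), mk(0.0)], None, LAM, L) == 0.0
        w = [0.2, 0.3, 0.5]
        forward = aggregate_absorption(modes, w, LAM, L)
        perm = [2, 0, 1]
        backward = aggregate_absorption([modes[i] for i in perm], [w[i] for i in perm], LAM, L)
        assert forward == pytest.approx(backward, rel=1e-14)
        with pytest.raises(ValueError):
            aggregate_absorption(modes, [0.5, 0.5], LAM, L)
        with pytest.raises(ValueError):
            aggregate_absorption(modes, [0.2, 0.3, 0.4], LAM, L)

    def test_guided_mode_classification(self):
        def mk(re):
            return Mode(n_eff=re + 0j, Ex=np.zeros((2, 2)), Ey=np.zeros((2, 2)),
                        lambda0=LAM, residual=0)

        modes = [mk(1.46), mk(1.43), mk(1.40)]
        assert [m.n_eff.real for m in guided_modes(modes, 1.41, 1.455)] == [1.43]


class TestProblemValidation:
    def test_wavelength_mismatch_rejected(self):
        pm = homogeneous_map(1.45, 1e-6, 10, LAM)
        with pytest.raises(ValueError):
            WaveProblem(map=pm, lambda0=700e-9, n_modes=1)

    def test_k0_consistent(self):
        pm = homogeneous_map(1.45, 1e-6, 10, LAM)
        prob = WaveProblem(map=pm, lambda0=LAM, n_modes=1)
        assert prob.k0 == 2 * math.pi / LAM
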