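"""Transfer-matrix multilayer optics and the fiber ray-transmission model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plasmorec.config import SensorConfig
from plasmorec.materials import (
    Medium,
    drude_lorentz_permittivity,
    make_buffer,
    make_gold,
    make_silica,
    silica_index,
)
from plasmorec.pipeline import design_stack, ray_params_for_design
from plasmorec.planar import (
    SEMI_INF,
    LayerStack,
    RayModelParams,
    fiber_transmission,
    kretschmann_dip_angle,
    reflectance,
    slab_mode_dispersion,
    slab_mode_neff,
    spp_effective_index,
    spp_phase_matching_angle,
)
from plasmorec.validation import fresnel_three_layer_p


def const_medium(n: float) -> Medium:
    return Medium(f"n={n}", lambda lam, n=n: n * n)


def two_layer(n1, n2):
    return LayerStack([(const_medium(n1), SEMI_INF), (const_medium(n2), SEMI_INF)])


class TestReflectance:
    @given(
        st.floats(min_value=1.0, max_value=2.5),
        st.floats(min_value=1.0, max_value=2.5),
    )
    def test_normal_incidence_fresnel(self, n1, n2):
        """Two lossless media at near-normal incidence: R = ((n1-n2)/(n1+n2))^2."""
        R = reflectance(two_layer(n1, n2), 633e-9, 1e-8, "p")["R"]
        assert R == pytest.approx(((n1 - n2) / (n1 + n2)) ** 2, abs=1e-10)

    @given(
        st.floats(min_value=1.2, max_value=2.0),
        st.floats(min_value=1.0, max_value=2.4),
        st.floats(min_value=0.05, max_value=1.5),
        st.sampled_from(["p", "s"]),
    )
    def test_two_layer_matches_fresnel_at_any_angle(self, n1, n2, theta, pol):
        """Transfer matrix for a bare interface equals the closed-form Fresnel
        coefficient at machine precision (propagating or total-internal)."""
        lam = 700e-9
        out = reflectance(two_layer(n1, n2), lam, theta, pol)
        k0 = 2 * math.pi / lam
        kx = k0 * n1 * math.sin(theta)
        kz1 = np.sqrt(complex(n1**2 * k0**2 - kx**2))
        kz2 = np.sqrt(complex(n2**2 * k0**2 - kx**2))
        if kz2.imag < 0:
            kz2 = -kz2
        if pol == "s":
            r = (kz1 - kz2) / (kz1 + kz2)
        else:
            r = (n2**2 * kz1 - n1**2 * kz2) / (n2**2 * kz1 + n1**2 * kz2)
        assert out["R"] == pytest.approx(abs(r) ** 2, abs=1e-12)

    def test_energy_conservation_random_lossless_stacks(self):
        """R + T = 1 to 1e-10 for 200 random lossless stacks, any angle/pol."""
        rng = np.random.default_rng(42)
        lam = 650e-9
        worst = 0.0
        for _ in range(200):
            n_interior = int(rng.integers(0, 4))
            layers = [(const_medium(float(rng.uniform(1.2, 2.2))), SEMI_INF)]
            for _ in range(n_interior):
                layers.append(
                    (const_medium(float(rng.uniform(1.0, 2.4))), float(rng.uniform(2e-8, 5e-7)))
                )
            layers.append((const_medium(float(rng.uniform(1.0, 2.4))), SEMI_INF))
            stack = LayerStack(layers)
            theta = float(rng.uniform(0.02, 1.55))
            pol = "p" if rng.integers(2) else "s"
            out = reflectance(stack, lam, theta, pol)
            worst = max(worst, abs(out["R"] + out["T"] - 1.0))
        assert worst <= 1e-10

    def test_total_internal_reflection(self):
        """Beyond the critical angle into a lower-index half-space: R=1, T=0."""
        out = reflectance(two_layer(1.5, 1.0), 633e-9, math.radians(60), "s")
        assert out["R"] == pytest.approx(1.0, abs=1e-12)
        assert out["T"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("theta_deg", [20.0, 45.0, 70.0, 80.0])
    def test_three_layer_vs_independent_airy_formula(self, theta_deg):
        """Lossy 3-layer amplitude agrees with an independently coded Airy sum."""
        lam = 633e-9
        stack = LayerStack(
            [(make_silica(), SEMI_INF), (make_gold(), 50e-9), (make_buffer(), SEMI_INF)]
        )
        theta = math.radians(theta_deg)
        got = reflectance(stack, lam, theta, "p")["r"]
        want = fresnel_three_layer_p(
            complex(silica_index(lam) ** 2),
            drude_lorentz_permittivity(lam),
            complex(1.334**2),
            50e-9,
            lam,
            theta,
        )
        assert got == pytest.approx(want, rel=1e-9)

    def test_invalid_angle_rejected(self):
        with pytest.raises(ValueError):
            reflectance(two_layer(1.5, 1.0), 633e-9, 0.0, "p")
        with pytest.raises(ValueError):
            reflectance(two_layer(1.5, 1.0), 633e-9, math.pi / 2, "p")


class TestKretschmann:
    def test_dip_matches_phase_matching_within_one_degree(self):
        """p-reflectance dip through a standard coupling prism sits at the SPP
        phase-matching angle to < 1 degree at 633 nm."""
        lam = 633e-9
        n_prism = 1.723  # dense flint coupling prism
        stack = LayerStack(
            [(const_medium(n_prism), SEMI_INF), (make_gold(), 50e-9), (make_buffer(), SEMI_INF)]
        )
        dip = kretschmann_dip_angle(stack, lam)
        eps_m = drude_lorentz_permittivity(lam)
        target = spp_phase_matching_angle(eps_m, 1.334**2, n_prism)
        assert abs(math.degrees(dip - target)) < 1.0

    def test_s_polarization_shows_no_dip(self):
        """Silica | gold 50 nm | water: min R_s - min R_p > 0.3 (plasmons are TM)."""
        lam = 633e-9
        stack = LayerStack(
            [(make_silica(), SEMI_INF), (make_gold(), 50e-9), (make_buffer(), SEMI_INF)]
        )
        n1 = silica_index(lam)
        theta = np.linspace(math.asin(1.334 / n1) + 0.01, math.radians(89.5), 800)
        r_p = reflectance(stack, lam, theta, "p")["R"]
        r_s = reflectance(stack, lam, theta, "s")["R"]
        assert r_s.min() - r_p.min() > 0.3


class TestFiberTransmission:
    def test_lossless_stack_transmits_fully(self):
        """Without gold the guided rays are pure TIR: T = 1 to 1e-12."""
        cfg = SensorConfig()
        stack = LayerStack([(make_silica(), SEMI_INF), (make_buffer(), SEMI_INF)])
        params = ray_params_for_design(cfg)
        assert fiber_transmission(stack, params, 680e-9) == pytest.approx(1.0, abs=1e-12)

    def test_zero_sensing_length_is_identity(self):
        cfg = SensorConfig()
        stack = design_stack(cfg, 0.0)
        params = replace(ray_params_for_design(cfg), sensing_length=1e-30)
        assert fiber_transmission(stack, params, 660e-9) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_nonincreasing_in_length(self):
        cfg = SensorConfig()
        stack = design_stack(cfg, 0.0)
        base = ray_params_for_design(cfg)
        for lam in (600e-9, 660e-9, 720e-9):
            T = [
                fiber_transmission(stack, replace(base, sensing_length=L), lam)
                for L in (10e-6, 50e-6, 200e-6, 1e-3)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(T, T[1:]))

    def test_ambient_index_rise_red_shifts_dip(self):
        """Raising the ambient index 1.33 -> 1.36 moves argmin T to longer lambda."""
        cfg = SensorConfig()
        params = ray_params_for_design(cfg)
        lams = np.arange(560e-9, 860e-9, 2e-9)
        argmins = []
        for n_amb in (1.33, 1.36):
            stack = LayerStack(
                [(make_silica(), SEMI_INF), (make_gold(), 50e-9), (make_buffer(n_amb), SEMI_INF)]
            )
            T = np.array([fiber_transmission(stack, params, lam) for lam in lams])
            argmins.append(lams[int(np.argmin(T))])
        assert argmins[1] > argmins[0] + 20e-9

    def test_transmission_bounded(self):
        cfg = SensorConfig()
        stack = design_stack(cfg, 0.05)
        params = ray_params_for_design(cfg)
        for lam in (550e-9, 650e-9, 750e-9):
            T = fiber_transmission(stack, params, lam)
            assert 0.0 <= T <= 1.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            RayModelParams(numerical_aperture=1.2)
        with pytest.raises(ValueError):
            RayModelParams(n_angles=4)
        with pytest.raises(ValueError):
            RayModelParams(sensing_length=-1.0)
        cfg = SensorConfig()
        stack = design_stack(cfg, 0.0)
        params = replace(ray_params_for_design(cfg), numerical_aperture=0.9999)
        with pytest.raises(ValueError):
            # NA larger than the core index supports -> empty angular range
            fiber_transmission(two_layer(0.9, 0.8), params, 650e-9)


class TestLayerStack:
    def test_construction_invariants(self):
        with pytest.raises(ValueError):
            LayerStack([(const_medium(1.5), SEMI_INF)])
        with pytest.raises(ValueError):
            LayerStack([(const_medium(1.5), 1e-6), (const_medium(1.0), SEMI_INF)])
        with pytest.raises(ValueError):
            LayerStack(
                [
                    (const_medium(1.5), SEMI_INF),
                    (const_medium(1.2), -1e-9),
                    (const_medium(1.0), SEMI_INF),
                ]
            )


class TestSlabModeOracle:
    def test_root_annihilates_dispersion_determinant(self):
        lam = 633e-9
        th = [1.5e-6, 50e-9, 2.0e-6]
        ep = [complex(silica_index(lam) ** 2), drude_lorentz_permittivity(lam), complex(1.334**2)]
        guess = spp_effective_index(ep[1], ep[2])
        root = slab_mode_neff(th, ep, lam, guess)
        # determinant residual at the root is tiny relative to nearby values
        at_root = abs(slab_mode_dispersion(th, ep, lam, root))
        nearby = abs(slab_mode_dispersion(th, ep, lam, root + 1e-3))
        assert at_root < 1e-8 * nearby
        assert root.imag > 0.0  # lossy plasmonic mode
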