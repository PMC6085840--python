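"""End-to-end sensor experiments.

Absorption spectra versus electrode potential, absorption-peak localisation
and voltage-induced peak shifts, synthetic action potentials, and
time-resolved intensity traces at a fixed excitation wavelength.

Public wavelengths are in nanometres and potentials in volts; everything is
converted to SI internally.  Two engines compute the absorbance:

``planar``
    The polished fiber idealised as a plane silica | gold [| charged
    sub-layer] | buffer stack interrogated by a ray bundle
    (:mod:`plasmorec.planar`).  For the fully-removed-cladding design the
    annular shell is treated as a planar film seen by every bounce — a
    documented approximation.
``modal``
    Full-vector eigenmodes of the discretised cross-section
    (:mod:`plasmorec.modesolver`), aggregated with equal launch weights over
    the guided modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .config import SensorConfig
from .geometry import FiberGeometry, build_cross_section
from .materials import (
    ChargeState,
    Medium,
    drude_lorentz_permittivity,
    make_buffer,
    make_cladding,
    make_gold,
    make_silica,
    silica_index,
    cladding_index,
)
from .modesolver import WaveProblem, aggregate_absorption, guided_modes, solve_modes
from .planar import LayerStack, RayModelParams, SEMI_INF, fiber_transmission, spp_effective_index

__all__ = [
    "AbsorptionSpectrum",
    "APWaveform",
    "IntensityTrace",
    "design_stack",
    "ray_params_for_design",
    "absorption_spectrum",
    "absorbance_at",
    "find_peak",
    "peak_shift",
    "synthesize_action_potential",
    "intensity_trace",
]

DEFAULT_PLANAR_GRID_NM = (500.0, 900.0, 0.25)
DEFAULT_MODAL_GRID_NM = (550.0, 750.0, 2.0)


class NoInteriorPeakError(ValueError):
    """The spectrum's maximum sits on the grid boundary."""


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Wavelength-resolved absorbance of one design at one potential."""

    wavelengths: np.ndarray          # nm, strictly increasing
    absorbance: np.ndarray           # in [0, 1)
    design: str
    potential: float                 # volts
    engine: str
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if a.shape != w.shape:
            raise ValueError("absorbance and wavelengths must have the same shape")
        if np.any(a < 0.0) or np.any(a >= 1.0):
            raise ValueError("absorbance must lie in [0, 1)")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "absorbance", a)

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#design={self.design}\n#potential_V={self.potential!r}\n")
            fh.write(f"#engine={self.engine}\n")
            for k, v in self.provenance.items():
                fh.write(f"#{k}={v!r}\n")
            fh.write("wavelength_nm,transmission,absorbance\n")
            for w, a in zip(self.wavelengths, self.absorbance):
                fh.write(f"{w:.6f},{1.0 - a:.9f},{a:.9f}\n")


@dataclass(frozen=True)
class APWaveform:
    """A transmembrane-potential waveform sampled on a uniform time grid."""

    time: np.ndarray        # ms, strictly increasing
    potential: np.ndarray   # volts

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.potential, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if v.shape != t.shape:
            raise ValueError("potential and time must have the same shape")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "potential", v)


@dataclass(frozen=True)
class IntensityTrace:
    """Normalised transmitted intensity versus time at one excitation line."""

    time: np.ndarray                 # ms
    intensity: np.ndarray            # (0, 1]
    excitation_wavelength: float     # nm
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if i.shape != t.shape:
            raise ValueError("intensity and time must have the same shape")
        if np.any(i <= 0.0) or np.any(i > 1.0):
            raise ValueError("intensity must lie in (0, 1]")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", i)

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#excitation_wavelength_nm={self.excitation_wavelength!r}\n")
            for k, v in self.provenance.items():
                fh.write(f"#{k}={v!r}\n")
            fh.write("time_ms,intensity\n")
            for t, i in zip(self.time, self.intensity):
                fh.write(f"{t:.6f},{i:.9f}\n")


# ---------------------------------------------------------------------------
# Design plumbing


def _charge_state(config: SensorConfig, potential: float, layer_thickness: float) -> ChargeState:
    return ChargeState.from_potential(
        config.coupling_factor * potential,
        capacitance_per_area=config.charge.capacitance_per_area,
        charge_layer_thickness=layer_thickness,
        N=config.charge.N,
        sign_convention=config.charge.sign_convention,
    )


def design_stack(config: SensorConfig, potential: float) -> LayerStack:
    """Planar layer stack of the sensing interface at an electrode potential.

    The charge localisation mode (see
    :class:`~plasmorec.config.ChargeConfig`) decides whether the
    double-layer electron-density change modifies the whole film
    (``filmwide``, the uniform-field treatment), an explicit thin sub-layer
    at the gold/buffer interface (``surface_layer``), or the film with the
    charge spread through it (``uniform_film``).
    """
    t = config.fiber.gold_thickness
    silica = make_silica()
    buffer = make_buffer(config.buffer_n)
    layers = [(silica, SEMI_INF)]
    if t > 0.0:
        if potential == 0.0:
            layers.append((make_gold(config.gold), t))
        elif config.charge.localization == "filmwide":
            charge = _charge_state(config, potential, config.charge.layer_thickness)
            layers.append((make_gold(config.gold, charge, name="gold_charged"), t))
        elif config.charge.localization == "uniform_film":
            charge = _charge_state(config, potential, t)
            layers.append((make_gold(config.gold, charge, name="gold_charged"), t))
        elif config.charge.localization == "surface_layer":
            d = config.charge.layer_thickness
            if not 0.0 < d < t:
                raise ValueError("charge layer thickness must lie inside the film")
            charge = _charge_state(config, potential, d)
            layers.append((make_gold(config.gold), t - d))
            layers.append((make_gold(config.gold, charge, name="gold_charged"), d))
        else:
            raise ValueError(f"unknown charge localization {config.charge.localization!r}")
    layers.append((buffer, SEMI_INF))
    return LayerStack(layers)


def ray_params_for_design(config: SensorConfig) -> RayModelParams:
    """Ray-model parameters encoding each design's reflection bookkeeping.

    The gold covers the whole perimeter in the fully-removed-cladding
    design (every bounce is a gold bounce); in the two polished designs it
    covers one side, so alternate bounces hit intact (lossless) cladding.
    Removing half the core halves the transverse extent a ray traverses
    between walls.
    """
    design = config.fiber.design
    r = config.fiber.core_radius
    if design == "full_clad_removed":
        frac, width = 1.0, 2.0 * r
    elif design == "half_clad_removed":
        frac, width = 0.5, 2.0 * r
    elif design == "half_core_removed":
        frac, width = 0.5, r
    else:
        raise ValueError(f"unknown design {design!r}")
    return RayModelParams(
        sensing_length=config.ray.sensing_length,
        core_diameter=width,
        numerical_aperture=config.fiber.na,
        angular_distribution=config.ray.angular_distribution,
        n_angles=config.ray.n_angles,
        gold_bounce_fraction=frac,
        polarization=config.ray.polarization,
        theta_max=math.radians(config.ray.theta_max_deg),
    )


def _effective_gold_medium(config: SensorConfig, potential: float) -> Medium:
    """Gold medium for the 2-D map, charge folded in.

    ``surface_layer`` localisation cannot be meshed as a 0.5 nm region, so
    it enters the film as a thickness-weighted effective-medium correction.
    """
    t = config.fiber.gold_thickness
    if potential == 0.0 or t == 0.0:
        return make_gold(config.gold)
    if config.charge.localization == "filmwide":
        charge = _charge_state(config, potential, config.charge.layer_thickness)
        return make_gold(config.gold, charge, name="gold_charged")
    if config.charge.localization == "uniform_film":
        return make_gold(config.gold, _charge_state(config, potential, t), name="gold_charged")
    d = config.charge.layer_thickness
    charge = _charge_state(config, potential, d)
    params = config.gold

    def eps_fn(lam: float) -> complex:
        eps_bulk = drude_lorentz_permittivity(lam, params)
        eps_charged = drude_lorentz_permittivity(lam, params, charge)
        return ((t - d) * eps_bulk + d * eps_charged) / t

    return Medium("gold_effective", eps_fn)


def design_geometry(config: SensorConfig, potential: float = 0.0) -> FiberGeometry:
    """Fiber geometry of the configured design with charge-aware media."""
    media = {
        "core": make_silica(),
        "cladding": make_cladding(config.fiber.na),
        "buffer": make_buffer(config.buffer_n),
        "gold": _effective_gold_medium(config, potential),
    }
    return FiberGeometry(
        design=config.fiber.design,
        media=media,
        core_radius=config.fiber.core_radius,
        gold_thickness=config.fiber.gold_thickness,
        cladding_thickness=config.fiber.cladding_thickness,
    )


# ---------------------------------------------------------------------------
# Absorbance engines


def _planar_absorbance(config: SensorConfig, potential: float, lambda0: float) -> float:
    stack = design_stack(config, potential)
    params = ray_params_for_design(config)
    return 1.0 - fiber_transmission(stack, params, lambda0)


def _modal_absorbance(config: SensorConfig, potential: float, lambda0: float) -> float:
    geom = design_geometry(config, potential)
    pmap = build_cross_section(
        geom,
        lambda0,
        min_cells_in_film=config.mesh.min_cells_in_film,
        window_factor=config.mesh.window_factor,
        points_per_wavelength=config.mesh.points_per_wavelength,
        volume_averaging=config.mesh.volume_averaging,
    )
    n_core = silica_index(lambda0)
    n_clad = cladding_index(lambda0, na=config.fiber.na)
    n_low = max(n_clad, config.buffer_n)

    eps_m = drude_lorentz_permittivity(lambda0, config.gold)
    n_spp = spp_effective_index(eps_m, config.buffer_n**2).real
    guesses = [n_core]
    if abs(n_spp - n_core) > 1e-3:
        guesses.append(n_spp)

    merged = []
    for g in guesses:
        problem = WaveProblem(
            map=pmap,
            lambda0=lambda0,
            n_modes=config.solver.n_modes,
            n_eff_guess=g,
        )
        for m in solve_modes(problem):
            if all(abs(m.n_eff - q.n_eff) > 1e-9 for q in merged):
                merged.append(m)
    guided = guided_modes(merged, n_low, n_core)
    if not guided:
        raise RuntimeError(
            f"no guided modes found (design={config.fiber.design}, "
            f"lambda={lambda0*1e9:.1f} nm, V={potential})"
        )
    return aggregate_absorption(guided, None, lambda0, config.ray.sensing_length)


def absorbance_at(
    design: str,
    potential: float,
    wavelength_nm: float,
    engine: str = "planar",
    config: Optional[SensorConfig] = None,
) -> float:
    """Absorbance of one design at one potential and wavelength."""
    from dataclasses import replace

    config = config or SensorConfig()
    if design != config.fiber.design:
        config = replace(config, fiber=replace(config.fiber, design=design))
    lam = wavelength_nm * 1e-9
    try:
        if engine == "planar":
            return _planar_absorbance(config, potential, lam)
        if engine == "modal":
            return _modal_absorbance(config, potential, lam)
    except Exception as exc:
        raise RuntimeError(
            f"absorbance evaluation failed (design={design}, "
            f"lambda={wavelength_nm} nm, V={potential})"
        ) from exc
    raise ValueError(f"unknown engine {engine!r}")


def absorption_spectrum(
    design: str,
    potential: float,
    lambda_grid_nm: Optional[Sequence[float]] = None,
    engine: str = "planar",
    config: Optional[SensorConfig] = None,
) -> AbsorptionSpectrum:
    """Absorbance spectrum of one design at a fixed electrode potential.

    ``lambda_grid_nm`` defaults to 500-900 nm in 0.25 nm steps for the
    planar engine and 550-750 nm in 2 nm steps for the modal engine.
    """
    if lambda_grid_nm is None:
        lo, hi, step = DEFAULT_PLANAR_GRID_NM if engine == "planar" else DEFAULT_MODAL_GRID_NM
        lambda_grid_nm = np.arange(lo, hi + 0.5 * step, step)
    grid = np.asarray(lambda_grid_nm, dtype=float)
    absorbance = np.array(
        [absorbance_at(design, potential, w, engine=engine, config=config) for w in grid]
    )
    cfg = config or SensorConfig()
    return AbsorptionSpectrum(
        wavelengths=grid,
        absorbance=absorbance,
        design=design,
        potential=potential,
        engine=engine,
        provenance={
            "capacitance_per_area_F_m2": cfg.charge.capacitance_per_area,
            "charge_layer_nm": cfg.charge.layer_thickness * 1e9,
            "sensing_length_mm": cfg.ray.sensing_length * 1e3,
        },
    )


# ---------------------------------------------------------------------------
# Peaks and shifts


def _parabolic_vertex(x0, x1, x2, y0, y1, y2) -> float:
    """Vertex abscissa of the parabola through three (possibly uneven) points."""
    a = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
    b = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if b == 0.0:
        return float(x1)
    return float(x1 - 0.5 * a / b)


def find_peak(spectrum: AbsorptionSpectrum) -> float:
    """Peak wavelength (nm) of the absorbance, parabolic sub-grid refinement."""
    a = spectrum.absorbance
    w = spectrum.wavelengths
    i = int(np.argmax(a))
    if i == 0 or i == len(a) - 1:
        raise NoInteriorPeakError(
            f"absorbance maximum at grid boundary ({w[i]:.2f} nm); no interior peak"
        )
    return _parabolic_vertex(w[i - 1], w[i], w[i + 1], a[i - 1], a[i], a[i + 1])


def peak_shift(
    design: str,
    v1: float,
    v2: float,
    engine: str = "planar",
    config: Optional[SensorConfig] = None,
    lambda_grid_nm: Optional[Sequence[float]] = None,
) -> float:
    """Signed absorption-peak shift ``lambda_peak(v2) - lambda_peak(v1)`` in nm."""
    if v1 == v2:
        return 0.0
    s1 = absorption_spectrum(design, v1, lambda_grid_nm, engine=engine, config=config)
    s2 = absorption_spectrum(design, v2, lambda_grid_nm, engine=engine, config=config)
    return find_peak(s2) - find_peak(s1)


# ---------------------------------------------------------------------------
# Synthetic action potentials


def _hh_rates(v: float):
    """Standard squid-axon rate constants (v in mV)."""

    def vtrap(x, y):
        return y if abs(x / y) < 1e-7 else x / math.expm1(x / y)

    a_m = 0.1 * vtrap(-(v + 40.0), 10.0)
    b_m = 4.0 * math.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * math.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (math.exp(-(v + 35.0) / 10.0) + 1.0)
    a_n = 0.01 * vtrap(-(v + 55.0), 10.0)
    b_n = 0.125 * math.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def _hh_derivatives(state, i_ext):
    v, m, h, n = state
    a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v)
    g_na, g_k, g_l = 120.0, 36.0, 0.3      # mS/cm^2
    e_na, e_k, e_l = 50.0, -77.0, -54.387  # mV
    i_na = g_na * m**3 * h * (v - e_na)
    i_k = g_k * n**4 * (v - e_k)
    i_l = g_l * (v - e_l)
    dv = i_ext - i_na - i_k - i_l          # C_m = 1 uF/cm^2
    return np.array([
        dv,
        a_m * (1 - m) - b_m * m,
        a_h * (1 - h) - b_h * h,
        a_n * (1 - n) - b_n * n,
    ])


def hodgkin_huxley_trace(
    duration: float,
    dt: float,
    stimulus_amplitude: float = 10.0,
    stimulus_start: float = 2.0,
    stimulus_duration: float = 1.0,
    v_rest: float = -65.0,
) -> np.ndarray:
    """Membrane potential (mV) of a standard HH point neuron, fixed-step RK4.

    ``stimulus_amplitude`` is the injected current in uA/cm^2 applied from
    ``stimulus_start`` for ``stimulus_duration`` (ms).
    """
    n_steps = int(round(duration / dt))
    a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v_rest)
    state = np.array([
        v_rest,
        a_m / (a_m + b_m),
        a_h / (a_h + b_h),
        a_n / (a_n + b_n),
    ])
    out = np.empty(n_steps + 1)
    out[0] = state[0]
    for k in range(n_steps):
        t = k * dt
        i_ext = stimulus_amplitude if stimulus_start <= t < stimulus_start + stimulus_duration else 0.0
        k1 = _hh_derivatives(state, i_ext)
        k2 = _hh_derivatives(state + 0.5 * dt * k1, i_ext)
        k3 = _hh_derivatives(state + 0.5 * dt * k2, i_ext)
        k4 = _hh_derivatives(state + dt * k3, i_ext)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise RuntimeError(f"Hodgkin-Huxley integration diverged at t={t:.3f} ms")
        out[k + 1] = state[0]
    return out


def _template_spike(t: np.ndarray) -> np.ndarray:
    """Piecewise-analytic spike shape (unit-free), rest exactly 0."""
    t0 = 2.0
    rise = np.clip(t - t0, 0.0, None)
    depol = (np.exp(-rise / 1.0) - np.exp(-rise / 0.25)) * (t >= t0)
    t1 = t0 + 1.5
    after = np.clip(t - t1, 0.0, None)
    hyper = (np.exp(-after / 4.0) - np.exp(-after / 1.0)) * (t >= t1)
    return depol - 0.55 * hyper


def synthesize_action_potential(
    kind: str = "template",
    duration: float = 12.0,
    dt: float = 0.02,
    seed: Optional[int] = None,
    v_min: float = -0.1,
    v_max: float = 0.1,
    **hh_kwargs,
) -> APWaveform:
    """Generate a deterministic synthetic action potential.

    ``template`` is a piecewise-analytic spike; ``hodgkin_huxley`` integrates
    the standard squid-axon point neuron (RK4) under a current pulse.  Either
    waveform's full excursion is affinely mapped onto the configured
    electrode range ``[v_min, v_max]`` (volts; default the physiological
    +-100 mV envelope), so the maximum equals ``v_max`` and the minimum
    ``v_min`` exactly.  ``seed`` is accepted for interface uniformity; the
    generator is deterministic.
    """
    n = int(round(duration / dt))
    if n + 1 < 50:
        raise ValueError("duration/dt must yield at least 50 samples")
    t = np.arange(n + 1) * dt
    if kind == "template":
        v = _template_spike(t)
    elif kind == "hodgkin_huxley":
        v = hodgkin_huxley_trace(duration, dt, **hh_kwargs)
    else:
        raise ValueError(f"unknown waveform kind {kind!r}")
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise ValueError("degenerate waveform: no excursion to rescale")
    scaled = v_min + (v - lo) * (v_max - v_min) / (hi - lo)
    return APWaveform(time=t, potential=scaled)


# ---------------------------------------------------------------------------
# Intensity tracking


def intensity_trace(
    design: str,
    waveform: APWaveform,
    excitation_wavelength_nm: float,
    engine: str = "planar",
    config: Optional[SensorConfig] = None,
    method: str = "interpolant",
    n_knots: int = 9,
) -> IntensityTrace:
    """Transmitted intensity versus time while the potential follows the AP.

    Per sample, ``intensity = 1 - absorbance(design, V(t), lambda_exc)``.
    ``method='interpolant'`` evaluates the absorbance on ``n_knots`` (>= 5)
    potential knots spanning the waveform range and interpolates with a
    cubic spline; ``method='direct'`` solves every sample.
    """
    v = waveform.potential
    if method == "direct":
        a = np.array(
            [absorbance_at(design, float(vi), excitation_wavelength_nm, engine, config) for vi in v]
        )
    elif method == "interpolant":
        if n_knots < 5:
            raise ValueError("interpolant needs at least 5 potential knots")
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            knots = np.array([lo])
            a = np.full_like(v, absorbance_at(design, lo, excitation_wavelength_nm, engine, config))
        else:
            knots = np.linspace(lo, hi, n_knots)
            a_knots = np.array(
                [absorbance_at(design, float(k), excitation_wavelength_nm, engine, config) for k in knots]
            )
            a = CubicSpline(knots, a_knots)(v)
    else:
        raise ValueError(f"unknown method {method!r}")
    return IntensityTrace(
        time=waveform.time,
        intensity=np.clip(1.0 - a, 1e-12, 1.0),
        excitation_wavelength=excitation_wavelength_nm,
        provenance={"design": design, "engine": engine, "method": method},
    )
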