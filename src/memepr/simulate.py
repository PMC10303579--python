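"""Synthetic first-derivative nitroxide EPR spectra.

Three generators cover the motional regimes met in spin-labelled membranes:

fast isotropic
    Motional-narrowing regime of a chain-end label (16-PC-like): three
    Lorentzian hyperfine lines whose mI-dependent peak-to-peak widths encode
    prescribed rotational correlation times τ2B and τ2C.  The generator is
    the exact inverse of the amplitude-ratio τ extraction: with widths
    ΔH(mI) = A + B·mI + C·mI² and B = −τ2B/(2·6.51e−10),
    C = τ2C/(2·6.51e−10), a unit-area Lorentzian-derivative line has
    peak-to-peak amplitude ∝ ΔH⁻², so the extraction formulas return the
    prescribed times exactly in the noise-free limit.

ordered powder
    Axially ordered label (5-PC-like): orientation-dependent splitting
    T(θ) = sqrt(T′∥²cos²θ + T′⊥²sin²θ) averaged over a sinθ-weighted powder,
    one manifold per mI ∈ {−1, 0, +1}, convolved with a derivative
    broadening kernel.  T′∥/T′⊥ are constructed from a target order
    parameter S and isotropic constant a₀ by inverting
    S = 0.5407(T′∥ − T′⊥)/a₀ with a₀ = (T′∥ + 2T′⊥)/3.

rigid limit
    Frozen sample (134 K-like): full powder average of
    A(θ,φ) = sqrt(Azz²cos²θ + sin²θ(Axx²cos²φ + Ayy²sin²φ)); the outermost
    extrema are separated by ≈ 2Azz, the polarity observable.

Field axes are in gauss.  Noise is Gaussian, expressed as a fraction of the
maximum absolute amplitude, and fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .spectrum import Spectrum, SpectrumMeta

__all__ = [
    "TAU_PREFACTOR",
    "S_COEFFICIENT",
    "FastMotionParams",
    "OrderedPowderParams",
    "RigidLimitParams",
    "SimulationError",
    "splittings_from_order",
    "simulate_fast_isotropic",
    "simulate_ordered_powder",
    "simulate_rigid_powder",
]

#: Motional-narrowing prefactor (s/G) of the τ2B/τ2C amplitude-ratio formulas.
TAU_PREFACTOR = 6.51e-10

#: Coefficient of the splitting-based order parameter S = 0.5407 (T′∥−T′⊥)/a₀.
S_COEFFICIENT = 0.5407


class SimulationError(ValueError):
    """Unphysical or infeasible simulation parameters."""


@dataclass
class FastMotionParams:
    """Fast-isotropic (motional narrowing) generator parameters.

    Noise defaults emulate a signal-averaged, deoxygenated cw-EPR acquisition
    (high SNR); τ targets in seconds, fields/widths in gauss.
    """

    tau_2B_target: float = 1e-10
    tau_2C_target: float = 1e-10
    a_iso: float = 15.0
    base_linewidth: float = 1.5
    center_field: float = 3350.0
    sweep_width: float = 120.0
    n_points: int = 2048
    noise_sigma: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_2B_target < 0 or self.tau_2C_target < 0:
            raise SimulationError("tau targets must be >= 0")
        if self.base_linewidth <= 0:
            raise SimulationError("base_linewidth must be > 0")
        if self.a_iso <= 0:
            raise SimulationError("a_iso must be > 0")

    def widths(self) -> dict[int, float]:
        """mI -> peak-to-peak linewidth ΔH(mI) in gauss."""
        b = -self.tau_2B_target / (2.0 * TAU_PREFACTOR)
        c = self.tau_2C_target / (2.0 * TAU_PREFACTOR)
        w = {mI: self.base_linewidth + b * mI + c * mI**2 for mI in (1, 0, -1)}
        if min(w.values()) <= 0:
            raise SimulationError(
                f"tau targets give non-positive linewidth(s) {w}; "
                "increase base_linewidth or reduce tau"
            )
        return w


@dataclass
class OrderedPowderParams:
    """Axially ordered powder generator parameters."""

    S_target: float = 0.6
    a_o_target: float = 14.3
    line_broadening: float = 1.0
    center_field: float = 3350.0
    sweep_width: float = 120.0
    n_points: int = 2048
    n_orientations: int = 400
    noise_sigma: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.S_target < 1.0:
            raise SimulationError(f"S_target must lie in (0, 1), got {self.S_target}")
        if self.n_orientations < 200:
            raise SimulationError("n_orientations must be >= 200")
        if self.line_broadening <= 0:
            raise SimulationError("line_broadening must be > 0")
        t_par, t_perp = splittings_from_order(self.S_target, self.a_o_target)
        if not t_par > t_perp > 0:
            raise SimulationError(
                f"(S={self.S_target}, a_o={self.a_o_target}) gives unphysical "
                f"splittings T'par={t_par:.3f}, T'perp={t_perp:.3f} G"
            )


@dataclass
class RigidLimitParams:
    """Rigid-limit (frozen sample) powder generator parameters."""

    A_tensor: tuple[float, float, float] = (6.0, 6.0, 34.0)  # (Axx, Ayy, Azz) G
    g_anisotropy: Optional[tuple[float, float, float]] = None
    line_broadening: float = 1.5
    center_field: float = 3350.0
    sweep_width: float = 200.0
    n_points: int = 2048
    n_orientations: int = 400
    noise_sigma: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        axx, ayy, azz = self.A_tensor
        if min(self.A_tensor) <= 0:
            raise SimulationError("hyperfine tensor components must be positive")
        if azz < axx or azz < ayy:
            raise SimulationError(
                f"tensor ordering violated: need Azz >= Axx, Ayy, got {self.A_tensor}"
            )
        if self.n_orientations < 200:
            raise SimulationError("n_orientations must be >= 200")
        if self.line_broadening <= 0:
            raise SimulationError("line_broadening must be > 0")


def splittings_from_order(S: float, a_o: float) -> tuple[float, float]:
    """Invert (S, a₀) to effective splittings (T′∥, T′⊥) in gauss.

    Solves S·a₀/0.5407 = T′∥ − T′⊥ together with T′∥ + 2T′⊥ = 3a₀.
    """
    delta = S * a_o / S_COEFFICIENT
    t_par = a_o + 2.0 * delta / 3.0
    t_perp = a_o - delta / 3.0
    return t_par, t_perp


def _field_axis(center: float, width: float, n: int) -> np.ndarray:
    return np.linspace(center - width / 2.0, center + width / 2.0, n)


def _lorentzian_derivative(field: np.ndarray, position: float, pp_width: float) -> np.ndarray:
    """First derivative of a unit-area Lorentzian absorption line.

    ``pp_width`` is the derivative's peak-to-peak width; the half-width at
    half-maximum is Γ = √3·pp_width/2 and the peak-to-peak amplitude scales
    as Γ⁻² — the property that makes the amplitude-ratio τ formulas exact.
    """
    gamma = np.sqrt(3.0) * pp_width / 2.0
    x = field - position
    return -(2.0 / np.pi) * gamma * x / (x * x + gamma * gamma) ** 2


def _gaussian_derivative_kernel_sum(
    field: np.ndarray,
    positions: np.ndarray,
    weights: np.ndarray,
    pp_width: float,
) -> np.ndarray:
    """Sum of weighted derivative-of-Gaussian lines at the given positions.

    The stick positions are deposited onto the field grid with linear
    (two-bin) interpolation and convolved once with the analytic kernel;
    with kernel widths well above the grid step this is numerically
    indistinguishable from the direct sum and orders of magnitude faster.
    Positions falling outside the sweep are ignored.
    """
    sigma = pp_width / 2.0  # derivative extrema of a Gaussian sit at ±σ
    step = field[1] - field[0]
    idx = (positions - field[0]) / step
    i0 = np.floor(idx).astype(int)
    frac = idx - i0
    grid = np.zeros(field.size)
    valid = (i0 >= 0) & (i0 < field.size - 1)
    np.add.at(grid, i0[valid], weights[valid] * (1.0 - frac[valid]))
    np.add.at(grid, i0[valid] + 1, weights[valid] * frac[valid])
    half = int(np.ceil(6.0 * sigma / step))
    x = np.arange(-half, half + 1) * step
    kernel = (-x / sigma**2) * np.exp(-0.5 * (x / sigma) ** 2) / (
        sigma * np.sqrt(2.0 * np.pi)
    )
    return np.convolve(grid, kernel, mode="same")


def _finalize(
    field: np.ndarray,
    intensity: np.ndarray,
    noise_sigma: float,
    seed: int,
    meta: SpectrumMeta,
) -> Spectrum:
    peak = np.max(np.abs(intensity))
    if peak > 0:
        intensity = intensity / peak
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, intensity.size)
    return Spectrum(field, intensity, meta)


def simulate_fast_isotropic(
    p: FastMotionParams, meta: Optional[SpectrumMeta] = None
) -> Spectrum:
    """Three-line motional-narrowing spectrum with prescribed τ2B/τ2C.

    Line positions: mI = +1 at low field (center − a_iso), mI = 0 at the
    center, mI = −1 at high field.  Amplitudes follow ΔH(mI)⁻².
    """
    widths = p.widths()
    field = _field_axis(p.center_field, p.sweep_width, p.n_points)
    intensity = np.zeros_like(field)
    for mI, width in widths.items():
        position = p.center_field - mI * p.a_iso
        intensity += _lorentzian_derivative(field, position, width) / 3.0
    meta = meta or SpectrumMeta(
        temperature_K=310.0, spin_label="16-PC", sweep_center_G=p.center_field
    )
    return _finalize(field, intensity, p.noise_sigma, p.seed, meta)


def simulate_ordered_powder(
    p: OrderedPowderParams, meta: Optional[SpectrumMeta] = None
) -> Spectrum:
    """Axially ordered three-manifold powder spectrum with prescribed (S, a₀)."""
    t_par, t_perp = splittings_from_order(p.S_target, p.a_o_target)
    field = _field_axis(p.center_field, p.sweep_width, p.n_points)
    # Gauss-Legendre quadrature in cosθ on [0, 1]: the sinθdθ powder weight
    # is uniform in cosθ; nodes cluster at both turning points.
    u, w = np.polynomial.legendre.leggauss(p.n_orientations)
    u = 0.5 * (u + 1.0)
    w = 0.5 * w
    t_eff = np.sqrt(t_par**2 * u**2 + t_perp**2 * (1.0 - u**2))
    intensity = np.zeros_like(field)
    for mI in (-1, 0, 1):
        if mI == 0:
            intensity += _gaussian_derivative_kernel_sum(
                field, np.array([p.center_field]), np.array([1.0 / 3.0]),
                p.line_broadening,
            )
        else:
            intensity += _gaussian_derivative_kernel_sum(
                field, p.center_field - mI * t_eff, w / 3.0, p.line_broadening
            )
    meta = meta or SpectrumMeta(
        temperature_K=310.0, spin_label="5-PC", sweep_center_G=p.center_field
    )
    return _finalize(field, intensity, p.noise_sigma, p.seed, meta)


def simulate_rigid_powder(
    p: RigidLimitParams, meta: Optional[SpectrumMeta] = None
) -> Spectrum:
    """Rigid-limit full powder spectrum; outermost extrema ≈ 2Azz apart.

    g anisotropy, when supplied, shifts each orientation's resonance by the
    first-order offset B₀(1 − g(θ,φ)/g_iso); at X band the spectrum is
    splitting-dominated and the default ignores it.
    """
    axx, ayy, azz = p.A_tensor
    field = _field_axis(p.center_field, p.sweep_width, p.n_points)
    u, wu = np.polynomial.legendre.leggauss(p.n_orientations)
    u = 0.5 * (u + 1.0)  # cosθ in [0, 1]
    wu = 0.5 * wu
    n_phi = max(64, p.n_orientations // 4)
    phi, wphi = np.polynomial.legendre.leggauss(n_phi)
    phi = 0.25 * np.pi * (phi + 1.0)  # φ in [0, π/2]; octant suffices by symmetry
    wphi = wphi / np.sum(wphi)
    uu = u[:, None]
    pp = phi[None, :]
    a_eff = np.sqrt(
        azz**2 * uu**2
        + (1.0 - uu**2) * (axx**2 * np.cos(pp) ** 2 + ayy**2 * np.sin(pp) ** 2)
    )
    weights = (wu[:, None] * wphi[None, :]).ravel()
    positions = a_eff.ravel()
    offsets = np.zeros_like(positions)
    if p.g_anisotropy is not None:
        gxx, gyy, gzz = p.g_anisotropy
        g_eff = np.sqrt(
            gzz**2 * uu**2
            + (1.0 - uu**2) * (gxx**2 * np.cos(pp) ** 2 + gyy**2 * np.sin(pp) ** 2)
        )
        g_iso = (gxx + gyy + gzz) / 3.0
        offsets = (p.center_field * (1.0 - g_eff / g_iso)).ravel()
    intensity = np.zeros_like(field)
    for mI in (-1, 0, 1):
        intensity += _gaussian_derivative_kernel_sum(
            field,
            p.center_field + offsets - mI * positions,
            weights / 3.0,
            p.line_broadening,
        )
    meta = meta or SpectrumMeta(
        temperature_K=134.0, spin_label="5-PC", sweep_center_G=p.center_field
    )
    return _finalize(field, intensity, p.noise_sigma, p.seed, meta)
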