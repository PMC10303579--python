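"""Physical observables derived from measured spectral features.

* order parameter ``S = 0.5407 (T′∥ − T′⊥)/a₀`` with
  ``a₀ = (T′∥ + 2T′⊥)/3`` (inputs are half the stored 2T′ separations);
* semi-cone angle from ``S = cosΘc (1 + cosΘc)/2``, inverted in closed form;
* rotational correlation times from the motional-narrowing amplitude-ratio
  formulas
  ``τ2B = 6.51e−10 · ΔH₀ · [√(h₀/h₋) − √(h₀/h₊)]`` and
  ``τ2C = 6.51e−10 · ΔH₀ · [√(h₀/h₋) + √(h₀/h₊) − 2]`` (seconds, ΔH₀ in G);
* motional anisotropy index ``|τ2C − τ2B|/τ2C`` (identical times for truly
  isotropic reorientation);
* polarity: rigid-limit 2Azz mapped to an approximate dielectric constant ε
  through a monotone piecewise-linear solvent calibration.  2Azz increases
  with local polarity, so membrane depth profiles of 2Azz read as
  hydration/polarity profiles.  The shipped calibration is an approximate,
  synthetic stand-in with typical doxyl-nitroxide magnitudes — replace it
  with your own solvent series for quantitative ε; raw 2Azz should always
  be reported alongside ε.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .features import LineFeatures, SplittingFeatures
from .simulate import S_COEFFICIENT, TAU_PREFACTOR

__all__ = [
    "ObservableSet",
    "PolarityCalibration",
    "PolarityResult",
    "ObservableError",
    "DEFAULT_CALIBRATION",
    "order_parameter",
    "cone_angle",
    "cone_angle_to_order",
    "correlation_times",
    "anisotropy_index",
    "polarity_epsilon",
    "observables_from_features",
]


class ObservableError(ValueError):
    """Unphysical input to an observable calculation."""


@dataclass
class ObservableSet:
    """Per-spectrum derived observables (τ stored in seconds)."""

    S: Optional[float] = None
    a_o: Optional[float] = None
    theta_c_deg: Optional[float] = None
    tau_2B: Optional[float] = None
    tau_2C: Optional[float] = None
    anisotropy_pct: Optional[float] = None
    two_A_zz: Optional[float] = None
    epsilon_estimate: Optional[float] = None

    @property
    def tau_2B_ns(self) -> Optional[float]:
        return None if self.tau_2B is None else self.tau_2B * 1e9

    @property
    def tau_2C_ns(self) -> Optional[float]:
        return None if self.tau_2C is None else self.tau_2C * 1e9


def order_parameter(sf: SplittingFeatures) -> tuple[float, float]:
    """Order parameter S and isotropic splitting a₀ (gauss) from 2T′ values."""
    t_par = sf.two_T_parallel / 2.0
    t_perp = sf.two_T_perp / 2.0
    if not t_par >= t_perp > 0:
        raise ObservableError(
            f"unphysical splittings T'par={t_par:.3f} < T'perp={t_perp:.3f} G"
        )
    a_o = (t_par + 2.0 * t_perp) / 3.0
    S = S_COEFFICIENT * (t_par - t_perp) / a_o
    return S, a_o


def cone_angle(S: float) -> float:
    """Semi-cone angle Θc (degrees) of restricted wobbling for order parameter S.

    Inverts S = cosΘc (1 + cosΘc)/2 through the positive quadratic root
    cosΘc = (−1 + √(1 + 8S))/2.
    """
    if not 0.0 <= S <= 1.0:
        raise ObservableError(f"S must lie in [0, 1], got {S}")
    cos_theta = (-1.0 + math.sqrt(1.0 + 8.0 * S)) / 2.0
    return math.degrees(math.acos(cos_theta))


def cone_angle_to_order(theta_c_deg: float) -> float:
    """Forward relation S = cosΘc (1 + cosΘc)/2."""
    c = math.cos(math.radians(theta_c_deg))
    return c * (1.0 + c) / 2.0


def correlation_times(lf: LineFeatures) -> tuple[float, float]:
    """Rotational correlation times (τ2B, τ2C) in seconds."""
    if min(lf.h_plus, lf.h_zero, lf.h_minus) <= 0 or lf.delta_H0 <= 0:
        raise ObservableError("amplitudes and central linewidth must be positive")
    r_minus = math.sqrt(lf.h_zero / lf.h_minus)
    r_plus = math.sqrt(lf.h_zero / lf.h_plus)
    tau_2b = TAU_PREFACTOR * lf.delta_H0 * (r_minus - r_plus)
    tau_2c = TAU_PREFACTOR * lf.delta_H0 * (r_minus + r_plus - 2.0)
    return tau_2b, tau_2c


def anisotropy_index(tau_2B: float, tau_2C: float) -> float:
    """Motional anisotropy |τ2C − τ2B|/τ2C as a percentage.

    Defined as 0 when both times vanish (the strict isotropic fast limit).
    """
    if tau_2C == 0:
        if tau_2B == 0:
            return 0.0
        raise ObservableError("anisotropy index undefined for tau_2C = 0")
    return 100.0 * abs(tau_2C - tau_2B) / tau_2C


@dataclass
class PolarityCalibration:
    """Solvent reference series mapping 2Azz (gauss) to dielectric constant ε."""

    points: Sequence[tuple[str, float, float]]  # (solvent, epsilon, two_A_zz)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ObservableError("calibration needs at least two reference points")
        ordered = sorted(self.points, key=lambda p: p[1])
        azz = [p[2] for p in ordered]
        if any(b - a <= 0 for a, b in zip(azz, azz[1:])):
            raise ObservableError("2Azz must increase strictly with epsilon")
        self.points = tuple(ordered)

    @property
    def azz_values(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])

    @property
    def epsilon_values(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


#: Approximate doxyl-type solvent series (synthetic stand-in, replace with a
#: measured calibration for quantitative work).
DEFAULT_CALIBRATION = PolarityCalibration(
    points=[
        ("apolar_hydrocarbon", 2.0, 66.2),
        ("short_chain_alcohol", 24.0, 70.0),
        ("water", 78.5, 72.6),
    ]
)


@dataclass(frozen=True)
class PolarityResult:
    epsilon: float
    two_A_zz: float
    out_of_range: bool


def polarity_epsilon(
    two_A_zz: float, cal: PolarityCalibration = DEFAULT_CALIBRATION
) -> PolarityResult:
    """Estimate ε by monotone piecewise-linear interpolation of the calibration.

    Queries outside the calibrated 2Azz range clamp to the boundary ε and
    set ``out_of_range``.
    """
    azz = cal.azz_values
    eps = cal.epsilon_values
    out = not (azz[0] <= two_A_zz <= azz[-1])
    value = float(np.interp(two_A_zz, azz, eps))
    return PolarityResult(epsilon=value, two_A_zz=two_A_zz, out_of_range=out)


def observables_from_features(
    line_features: Optional[LineFeatures] = None,
    splitting_features: Optional[SplittingFeatures] = None,
    two_A_zz: Optional[float] = None,
    calibration: Optional[PolarityCalibration] = None,
) -> ObservableSet:
    """Assemble an :class:`ObservableSet` from whichever features are available."""
    obs = ObservableSet()
    if splitting_features is not None:
        obs.S, obs.a_o = order_parameter(splitting_features)
        obs.theta_c_deg = cone_angle(min(max(obs.S, 0.0), 1.0))
    if line_features is not None:
        obs.tau_2B, obs.tau_2C = correlation_times(line_features)
        if obs.tau_2C != 0:
            obs.anisotropy_pct = anisotropy_index(obs.tau_2B, obs.tau_2C)
    if two_A_zz is not None:
        obs.two_A_zz = two_A_zz
        result = polarity_epsilon(two_A_zz, calibration or DEFAULT_CALIBRATION)
        obs.epsilon_estimate = result.epsilon
    return obs
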