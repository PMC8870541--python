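"""Closed-form physics of an object sliding with kinetic friction on an
inclined channel.

The object (a small cube) is launched along a straight gutter with speed
``v0`` and decelerates uniformly under gravity and kinetic friction.  With
slope angle ``alpha`` (positive = uphill away from the striker) and kinetic
friction coefficient ``mu``, the deceleration magnitude is

    dec = g * (sin(alpha) + mu * cos(alpha))

which yields the optimal launch speed to stop exactly at distance ``d``,

    v_opt = sqrt(2 * g * d * (sin(alpha) + mu * cos(alpha)))

its inverse, the stopping distance ``d = v0**2 / (2 * dec)``, and the
friction coefficient implied by an observed (launch speed, distance) pair,

    mu = (v**2 / (2 * d * g) - sin(alpha)) / cos(alpha).

Object mass cancels everywhere: both the decelerating force and the
momentum are proportional to mass, so none of these functions takes one.

All angles are accepted in degrees at the API boundary (the experimental
slopes are -10, 0 and +10 degrees) and converted internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class NonStoppingError(ValueError):
    """The launched object never stops: sin(alpha) + mu*cos(alpha) <= 0."""


class DegenerateSlopeError(ValueError):
    """Slope at +/-90 degrees: the channel is vertical."""


class EpisodeTooShortError(ValueError):
    """Simulated slide has too few samples before the object stops."""


@dataclass(frozen=True)
class SurfaceCondition:
    """Sliding surface: slope in degrees, kinetic friction coefficient, label.

    Parameters
    ----------
    slope_alpha:
        Channel inclination in degrees; positive slopes rise away from the
        striker, so the object slides uphill.
    mu:
        Dimensionless kinetic friction coefficient, >= 0.
    material_label:
        Free-text surface material (e.g. ``"aluminum"``, ``"balsa"``).
    """

    slope_alpha: float
    mu: float
    material_label: str = ""

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if not abs(self.slope_alpha) < 90:
            raise ValueError(f"|slope| must be < 90 degrees, got {self.slope_alpha}")

    @property
    def friction_factor(self) -> float:
        """sin(alpha) + mu*cos(alpha); must be > 0 for the object to stop."""
        a = math.radians(self.slope_alpha)
        return math.sin(a) + self.mu * math.cos(a)


@dataclass(frozen=True)
class PhysicalConstants:
    """Gravitational acceleration (m/s^2) and sample interval (s).

    The default ``dt`` of 0.004 s corresponds to the 250 Hz motion-capture
    rate of the experimental setup.
    """

    g: float = 9.81
    dt: float = 0.004

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class SlideEpisode:
    """One sliding episode: uniformly sampled position along the channel.

    Positions are measured in metres along the channel axis, zero at the
    launch point (the object's front edge at rest) and positive toward the
    target.
    """

    times: np.ndarray
    positions: np.ndarray
    v0: float
    condition: SurfaceCondition
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) < 3:
            raise ValueError("an episode needs at least 3 samples")


@dataclass(frozen=True)
class FrictionEstimate:
    """Result of fitting a parabola to one sliding episode.

    ``poly_coeffs`` are the (A, B, C) of y = A t^2 + B t + C over the fitted
    window, ``deceleration`` the positive magnitude -2A, and ``mu`` the
    kinetic friction coefficient implied by the slope and gravity.
    """

    poly_coeffs: tuple[float, float, float]
    deceleration: float
    mu: float
    n_samples: int


def _check_stopping(condition: SurfaceCondition) -> float:
    f = condition.friction_factor
    if f <= 0:
        raise NonStoppingError(
            "object never stops: sin(alpha) + mu*cos(alpha) = "
            f"{f:.6g} <= 0 for slope {condition.slope_alpha} deg, mu {condition.mu}"
        )
    return f


def deceleration_from_mu(
    condition: SurfaceCondition, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """Deceleration magnitude g*(sin(alpha) + mu*cos(alpha)) in m/s^2.

    Raises :class:`NonStoppingError` when friction cannot overcome a
    downhill slope (the object would accelerate forever).
    """
    return constants.g * _check_stopping(condition)


def mu_from_deceleration(dec: float, alpha: float, g: float = 9.81) -> float:
    """Kinetic friction coefficient from an observed deceleration.

    Inverts ``dec = g*(sin(alpha) + mu*cos(alpha))`` as
    ``mu = (dec/g - sin(alpha)) / cos(alpha)``.

    Parameters
    ----------
    dec:
        Deceleration magnitude, m/s^2 (>= 0).
    alpha:
        Slope in degrees; +/-90 is degenerate (no normal force component).
    """
    if dec < 0:
        raise ValueError(f"deceleration magnitude must be >= 0, got {dec}")
    a = math.radians(alpha)
    c = math.cos(a)
    if abs(c) < 1e-12:
        raise DegenerateSlopeError("cos(alpha) = 0: slope of +/-90 degrees")
    return (dec / g - math.sin(a)) / c


def optimal_cube_speed(
    d: float, condition: SurfaceCondition, g: float = 9.81
) -> float:
    """Launch speed (m/s) that stops the object exactly at distance ``d``.

    v_opt = sqrt(2*g*d*(sin(alpha) + mu*cos(alpha))).  Strictly increasing
    in d, mu and alpha over their valid ranges.
    """
    if d < 0:
        raise ValueError(f"target distance must be >= 0, got {d}")
    if d == 0:
        return 0.0
    return math.sqrt(2.0 * g * d * _check_stopping(condition))


def stopping_distance(
    v0: float, condition: SurfaceCondition, g: float = 9.81
) -> float:
    """Distance (m) travelled before stopping: v0^2 / (2*g*(sin a + mu cos a)).

    Exact inverse of :func:`optimal_cube_speed`; independent of object mass.
    """
    if v0 < 0:
        raise ValueError(f"launch speed must be >= 0, got {v0}")
    return v0 * v0 / (2.0 * g * _check_stopping(condition))


def subjective_mu(
    v_impact: float, d_target: float, alpha: float, g: float = 9.81
) -> float:
    """Friction coefficient implied by launching at ``v_impact`` to stop at
    ``d_target``.

    mu = (v^2/(2*d*g) - sin(alpha)) / cos(alpha).

    Fed with the *target* distance this is the mover's belief about
    friction (their internal model); fed with the distance the object
    *actually* travelled it returns the objective coefficient of the
    surface.
    """
    if d_target <= 0:
        raise ValueError(f"distance must be > 0, got {d_target}")
    a = math.radians(alpha)
    c = math.cos(a)
    if abs(c) < 1e-12:
        raise DegenerateSlopeError("cos(alpha) = 0: slope of +/-90 degrees")
    return (v_impact * v_impact / (2.0 * d_target * g) - math.sin(a)) / c


def simulate_slide(
    v0: float,
    condition: SurfaceCondition,
    constants: PhysicalConstants = PhysicalConstants(),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    tail: float = 0.1,
) -> SlideEpisode:
    """Simulate one sliding episode under uniform deceleration.

    Noiseless positions follow y(t) = v0*t - dec*t^2/2 until the object
    stops at t = v0/dec, then stay constant for an extra ``tail`` seconds.
    With ``noise_sd`` > 0, i.i.d. Gaussian position noise (metres) is added
    to every sample, reproducibly for a given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dec = deceleration_from_mu(condition, constants)
    t_stop = v0 / dec
    n_moving = int(math.floor(t_stop / constants.dt))
    if n_moving < 3:
        raise EpisodeTooShortError(
            f"only {n_moving} samples before stop (v0={v0:.4g} m/s, "
            f"dec={dec:.4g} m/s^2, dt={constants.dt} s); need >= 3"
        )
    n = n_moving + 1 + int(round(tail / constants.dt))
    times = np.arange(n) * constants.dt
    positions = np.where(
        times < t_stop,
        v0 * times - 0.5 * dec * times**2,
        v0 * t_stop - 0.5 * dec * t_stop**2,
    )
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, noise_sd, size=n)
    return SlideEpisode(times=times, positions=positions, v0=v0, condition=condition,
                        constants=constants)


def fit_friction(
    episode: SlideEpisode,
    speed_threshold: float = 0.04,
    g: float | None = None,
) -> FrictionEstimate:
    """Estimate the kinetic friction coefficient from one sliding episode.

    A second-order polynomial y = A t^2 + B t + C is fitted to the object's
    position over the window from its initial maximum speed until it stops;
    the deceleration is the (negated) second derivative ``dec = -2A`` and
    mu follows from the slope and gravity.

    The fitting window starts at the speed maximum (unfiltered
    finite-difference speed) and initially ends at the last sample whose
    speed exceeds ``speed_threshold`` (the same 0.04 m/s threshold used for
    movement-onset detection), excluding the boundary sample whose central
    difference already straddles the stop.  Because position noise makes
    that threshold crossing unreliable, the window end is then refined:
    the stop time is re-estimated from the fitted parabola's vertex
    (-B / 2A, where the fitted speed reaches zero) and the fit repeated on
    the refined window until the end index is stable.  On noiseless data
    the first window already covers exactly the parabolic segment, so the
    refinement is a no-op and mu is recovered to machine precision.
    """
    dt = float(episode.times[1] - episode.times[0])
    g_eff = episode.constants.g if g is None else g
    speed = np.gradient(episode.positions, dt)
    i_peak = int(np.argmax(speed))
    above = np.nonzero(speed[i_peak:] > speed_threshold)[0]
    if len(above) == 0:
        raise ValueError("object speed never exceeds the threshold")
    i_last = i_peak + int(above[-1])
    # the central difference at i_last mixes moving and resting samples;
    # drop it so a noiseless parabola is fitted exactly
    i_end = max(i_last - 1, i_peak + 2)
    i_end = min(i_end, len(episode.times) - 1)

    coeffs = None
    for _ in range(5):
        t = episode.times[i_peak : i_end + 1]
        y = episode.positions[i_peak : i_end + 1]
        if len(t) < 3:
            raise EpisodeTooShortError("fewer than 3 samples in the sliding window")
        coeffs = np.polynomial.polynomial.polyfit(t, y, 2)  # [C, B, A]
        if coeffs[2] >= 0:  # not decelerating; keep the threshold window
            break
        t_stop = -coeffs[1] / (2.0 * coeffs[2])
        i_new = int(math.floor(t_stop / dt)) - 1
        i_new = min(max(i_new, i_peak + 2), len(episode.times) - 1)
        if i_new == i_end:
            break
        i_end = i_new

    a = float(coeffs[2])
    dec = -2.0 * a
    mu = mu_from_deceleration(abs(dec), episode.condition.slope_alpha, g_eff)
    return FrictionEstimate(
        poly_coeffs=(a, float(coeffs[1]), float(coeffs[0])),
        deceleration=abs(dec),
        mu=mu,
        n_samples=i_end - i_peak + 1,
    )
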