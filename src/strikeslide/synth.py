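"""Synthetic motion-capture sessions from a simulated adaptive participant.

The generator produces everything the downstream analysis consumes —
fingertip and limb marker trajectories, object sliding episodes, block
designs — together with exact ground truth, so each detector and estimator
can be validated against planted values.

The simulated participant holds one *subjective* friction coefficient per
surface material.  On every trial it launches the object at the speed that
would be optimal if its belief were true, observes where the object
actually stops, computes the friction coefficient implied by that outcome,
and moves its belief a fraction ``learning_rate`` toward it
(feedback-error learning).  Because the implied coefficient equals the
objective one, the belief error decays geometrically by a factor
``(1 - learning_rate)`` per trial, which is what makes the spatial-error
series exponential in form.

Strike kinematics use minimum-jerk profiles: a backward arming movement
(full bell-shaped speed profile, ending at rest at maximal retraction)
followed by a forward strike whose speed rises monotonically and peaks
exactly at object contact (the first half of a minimum-jerk profile), then
an impact transient in which most of the speed is lost within ~15 ms, and
a decaying follow-through.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from strikeslide.design import ExperimentDesign
from strikeslide.physics import (
    PhysicalConstants,
    SurfaceCondition,
    deceleration_from_mu,
    simulate_slide,
    stopping_distance,
    subjective_mu,
)

WRIST = "wrist"
FOREARM = "forearm"

#: Default true kinetic friction coefficients per surface material
#: (group-mean values measured from object decelerations).
TRUE_MU = {"aluminum": 0.37, "balsa": 0.47}

#: Joint-amplitude parameterization: amplitude(deg) = intercept + slope * v
#: where v is the commanded fingertip speed at impact (m/s).  Intercepts
#: differ by motor strategy (wrist-strategy movers recruit the wrist more,
#: forearm-strategy movers the forearm); slopes are shared.
AMPLITUDE_INTERCEPTS = {
    WRIST: {"forearm": -1.2, "wrist": 13.2, "index": 2.0},
    FOREARM: {"forearm": 5.0, "wrist": 1.3, "index": 2.0},
}
AMPLITUDE_SLOPES = {"forearm": 9.0, "wrist": 7.9, "index": 3.0}

#: Energy-transfer parameterization: cube launch speed =
#: gain * (fingertip speed at impact - offset).  Offsets differ by
#: strategy: wrist-strategy movers need a higher fingertip speed for the
#: same launch speed because less limb mass is behind the impact.
TRANSFER_PARAMS = {WRIST: (1.0 / 0.87, 1.16), FOREARM: (1.0 / 0.94, 0.61)}

#: Absolute link angles at the contact posture, degrees from the x axis
#: (the forearm roughly perpendicular to the channel, distal chain nearly
#: aligned with it so the strike pushes along +y).
CONTACT_POSTURE = {"forearm": 15.0, "hand": 5.0, "index": 0.0}


@dataclass(frozen=True)
class ParticipantProfile:
    """Everything that characterizes one simulated participant."""

    subjective_mu0: float = 0.28  # initial friction belief, shared across materials
    learning_rate: float = 0.4  # fraction of belief error corrected per trial
    strategy: str = FOREARM  # "wrist" or "forearm"
    body_mass: float = 70.0  # kg
    forearm_length: float = 0.26  # m
    hand_length: float = 0.19  # m, wrist to 3rd metacarpal head
    index_length: float = 0.07  # m, metacarpal head to fingertip
    motor_noise_sd: float = 0.05  # m/s, additive on launch speed
    marker_noise_sd: float = 0.0  # m, i.i.d. per marker coordinate
    generalizes: bool = True  # False: belief resets to mu0 at each block start

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.strategy not in (WRIST, FOREARM):
            raise ValueError(f"strategy must be 'wrist' or 'forearm', got {self.strategy!r}")
        for name in ("body_mass", "forearm_length", "hand_length", "index_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class StrikeTrajectory:
    """Fingertip position along the channel axis for one strike."""

    times: np.ndarray
    positions: np.ndarray  # m, 0 at the object's face
    contact_index: int
    impact_speed: float  # m/s, peak forward speed, reached at contact
    arming_end_index: int


@dataclass(frozen=True)
class LimbTrajectory:
    """Planar marker set for one strike: elbow, wrist, mcp, fingertip."""

    times: np.ndarray
    markers: dict  # name -> (n, 3) array, metres
    contact_index: int
    arming_end_index: int
    impact_speed: float
    amplitudes: dict  # joint name -> planted angular amplitude, degrees
    contact_angles: dict  # joint name -> joint angle at contact, degrees


@dataclass
class TrialRecord:
    """One trial: condition metadata plus (optional) raw time series."""

    participant: int
    group: int
    block: int
    trial: int  # 1-based within block
    trial_global: int
    slope: float  # degrees
    material: str
    target_distance: float  # m
    dt: float
    times: np.ndarray | None = None
    markers: dict | None = None  # marker name -> (n, 3)
    cube_y: np.ndarray | None = None  # object front-edge position, m


@dataclass
class TrialGroundTruth:
    contact_time: float
    contact_index: int
    launch_speed: float
    finger_impact_speed: float
    true_mu: float
    subjective_mu_pre: float
    stop_position: float
    spatial_error_pct: float
    amplitudes: dict  # joint -> degrees (empty when kinematics skipped)


@dataclass
class Session:
    participant: int
    profile: ParticipantProfile
    design: ExperimentDesign
    trials: list  # of TrialRecord
    ground_truth: list  # of TrialGroundTruth


# ---------------------------------------------------------------------------
# minimum-jerk primitives


def _minjerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]: rest-to-rest, unit amplitude."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _half_minjerk(tau: np.ndarray) -> np.ndarray:
    """First half of a minimum-jerk profile rescaled to [0, 1]; its slope is
    maximal (= 1.875) at tau = 1, i.e. speed peaks at the end."""
    return 2.0 * _minjerk(tau / 2.0)


_PEAK_SLOPE = 1.875  # d/dtau of _half_minjerk at tau = 1


def _post_contact_speed_scale(
    t_after: np.ndarray, transient: float, residual: float, follow_tau: float
) -> np.ndarray:
    """Multiplicative speed scale after contact.

    The collision is impulsive: a fraction ``1 - residual`` of the speed
    collapses exponentially with time constant ``transient / 3.75`` (so
    ~98% of the loss is complete within ``transient`` seconds, the ~15 ms
    contact duration), superposed on a slow exponential follow-through of
    the remaining fraction.  The sharp initial force peak is what contact
    detection keys on."""
    tau_impact = transient / 3.75
    return (1.0 - residual) * np.exp(-t_after / tau_impact) + residual * np.exp(
        -t_after / follow_tau
    )


def simulate_strike_kinematics(
    impact_speed: float,
    dt: float = 0.004,
    retreat_amplitude: float = 0.15,
    seed: int | np.random.Generator | None = None,
    noise_sd: float = 0.0,
    hold: float = 0.05,
    arming_duration: float = 0.35,
    transient_duration: float = 0.015,
    transient_residual: float = 0.25,
    follow_tau: float = 0.05,
    post_duration: float = 0.25,
) -> StrikeTrajectory:
    """Generate a fingertip trajectory along the channel axis.

    Phases: hold at the object face (position 0) → minimum-jerk retreat to
    ``-retreat_amplitude`` (arming; ends at rest) → forward strike whose
    speed rises monotonically and peaks at exactly ``impact_speed`` when
    the fingertip returns to 0 (contact) → ~15 ms impact transient in
    which (1 - transient_residual) of the speed is lost → exponentially
    decaying follow-through.

    Contact falls exactly on a sample; the hold phase absorbs the grid
    rounding.  Raises ``ValueError`` if ``dt`` is too coarse to place two
    samples inside the impact transient.
    """
    if impact_speed <= 0:
        raise ValueError("impact_speed must be > 0")
    if dt > transient_duration / 2:
        raise ValueError(
            f"dt = {dt} s cannot represent a {transient_duration * 1e3:.0f} ms "
            "impact transient with >= 2 samples"
        )
    strike_duration = _PEAK_SLOPE * retreat_amplitude / impact_speed
    t_contact_raw = hold + arming_duration + strike_duration
    k_contact = int(math.ceil(t_contact_raw / dt))
    hold_eff = hold + (k_contact * dt - t_contact_raw)
    t_arm_start = hold_eff
    t_strike_start = hold_eff + arming_duration
    t_contact = k_contact * dt

    n = k_contact + int(round(post_duration / dt)) + 1
    times = np.arange(n) * dt
    y = np.zeros(n)

    arm = (times >= t_arm_start) & (times < t_strike_start)
    y[arm] = -retreat_amplitude * _minjerk((times[arm] - t_arm_start) / arming_duration)
    strike = (times >= t_strike_start) & (times <= t_contact)
    y[strike] = -retreat_amplitude * (
        1.0 - _half_minjerk((times[strike] - t_strike_start) / strike_duration)
    )

    post = times > t_contact
    t_after = times[post] - t_contact
    scale = _post_contact_speed_scale(
        t_after, transient_duration, transient_residual, follow_tau
    )
    # integrate the post-contact speed impact_speed * scale(t)
    v_post = impact_speed * scale
    y_post = np.concatenate([[0.0], np.cumsum((v_post[1:] + v_post[:-1]) / 2.0 * dt)])
    first_seg = impact_speed * (1.0 + scale[0]) / 2.0 * t_after[0]
    y[post] = first_seg + y_post

    arming_end_index = int(round(t_strike_start / dt))
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n)
    return StrikeTrajectory(
        times=times,
        positions=y,
        contact_index=k_contact,
        impact_speed=impact_speed,
        arming_end_index=arming_end_index,
    )


def energy_transfer(finger_speed_at_impact: float, transfer: tuple[float, float]) -> float:
    """Cube launch speed from fingertip speed at impact.

    ``launch = gain * (finger_speed - offset)``, clipped at 0.  The affine
    form mirrors the observed linear regulation of fingertip speed against
    optimal launch speed; the offset is the fingertip speed below which no
    effective energy is transferred.
    """
    gain, offset = transfer
    if gain <= 0:
        raise ValueError("gain must be > 0")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    return max(gain * (finger_speed_at_impact - offset), 0.0)


def invert_energy_transfer(launch_speed: float, transfer: tuple[float, float]) -> float:
    """Fingertip impact speed needed for a desired launch speed."""
    gain, offset = transfer
    return launch_speed / gain + offset


def joint_amplitudes_deg(strategy: str, impact_speed: float) -> dict:
    """Planted angular amplitudes (degrees) for the three joints, affine in
    the commanded fingertip impact speed with strategy-specific intercepts."""
    icepts = AMPLITUDE_INTERCEPTS[strategy]
    amp = {
        j: max(icepts[j] + AMPLITUDE_SLOPES[j] * impact_speed, 0.5)
        for j in ("forearm", "wrist", "index")
    }
    return amp


def simulate_limb_markers(
    strategy: str,
    impact_speed: float,
    profile: ParticipantProfile,
    dt: float = 0.004,
    seed: int | np.random.Generator | None = None,
    noise_sd: float = 0.0,
    hold: float = 0.05,
    arming_duration: float = 0.35,
    transient_duration: float = 0.015,
    transient_residual: float = 0.25,
    follow_tau: float = 0.05,
    post_duration: float = 0.25,
    amplitudes: dict | None = None,
) -> LimbTrajectory:
    """Generate planar limb markers for one strike.

    The arm is a three-link chain (forearm, hand, index finger) pivoting
    about a fixed elbow in the horizontal plane — the task constrains the
    elbow to rest on the table.  Joint angles follow the same
    hold/arming/strike/transient phases as the fingertip generator, with
    per-joint angular amplitudes affine in the commanded impact speed
    (see :data:`AMPLITUDE_INTERCEPTS`).  The strike duration is solved so
    the fingertip speed along the channel axis at contact equals
    ``impact_speed`` exactly in the continuous construction.

    Returns marker series for ``elbow``, ``wrist``, ``mcp`` (3rd
    metacarpal head; the index axis is taken from this marker to the
    fingertip) and ``fingertip``; z is identically zero before noise.
    """
    if amplitudes is None:
        amplitudes = joint_amplitudes_deg(strategy, impact_speed)
    d_f = math.radians(amplitudes["forearm"])
    d_w = math.radians(amplitudes["wrist"])
    d_i = math.radians(amplitudes["index"])
    phi_f_c = math.radians(CONTACT_POSTURE["forearm"])
    phi_h_c = math.radians(CONTACT_POSTURE["hand"])
    phi_i_c = math.radians(CONTACT_POSTURE["index"])
    lf, lh, li = profile.forearm_length, profile.hand_length, profile.index_length

    # fingertip y-velocity at contact from the joint rates (Jacobian along
    # the channel axis), with half-minimum-jerk peak rate 1.875 * amp / T
    geom = (
        lf * d_f * math.cos(phi_f_c)
        + lh * (d_f + d_w) * math.cos(phi_h_c)
        + li * (d_f + d_w + d_i) * math.cos(phi_i_c)
    )
    strike_duration = _PEAK_SLOPE * geom / impact_speed

    t_contact_raw = hold + arming_duration + strike_duration
    k_contact = int(math.ceil(t_contact_raw / dt))
    hold_eff = hold + (k_contact * dt - t_contact_raw)
    t_arm_start = hold_eff
    t_strike_start = hold_eff + arming_duration
    t_contact = k_contact * dt
    n = k_contact + int(round(post_duration / dt)) + 1
    times = np.arange(n) * dt

    # shared phase progress p(t): 0 at the contact posture, -1 fully armed
    progress = np.zeros(n)
    arm = (times >= t_arm_start) & (times < t_strike_start)
    progress[arm] = -_minjerk((times[arm] - t_arm_start) / arming_duration)
    strike = (times >= t_strike_start) & (times <= t_contact)
    progress[strike] = -(1.0 - _half_minjerk((times[strike] - t_strike_start) / strike_duration))

    # post-contact: each joint keeps rotating with a collapsing rate
    post = times > t_contact
    t_after = times[post] - t_contact
    scale = _post_contact_speed_scale(t_after, transient_duration, transient_residual, follow_tau)
    rate_peak = _PEAK_SLOPE / strike_duration  # progress rate at contact, 1/s
    v_post = rate_peak * scale
    p_post = np.concatenate([[0.0], np.cumsum((v_post[1:] + v_post[:-1]) / 2.0 * dt)])
    progress[post] = rate_peak * (1.0 + scale[0]) / 2.0 * t_after[0] + p_post

    phi_f = phi_f_c + d_f * progress
    phi_h = phi_h_c + (d_f + d_w) * progress
    phi_i = phi_i_c + (d_f + d_w + d_i) * progress

    def chain(phi):
        return np.stack([np.cos(phi), np.sin(phi)], axis=-1)

    wrist_xy = lf * chain(phi_f)
    mcp_xy = wrist_xy + lh * chain(phi_h)
    tip_xy = mcp_xy + li * chain(phi_i)
    # place the elbow so the fingertip sits at the object face (0, 0) at contact
    offset = -tip_xy[k_contact]
    markers = {}
    for name, xy in (
        ("elbow", np.zeros((n, 2))),
        ("wrist", wrist_xy),
        ("mcp", mcp_xy),
        ("fingertip", tip_xy),
    ):
        m = np.zeros((n, 3))
        m[:, :2] = xy + offset
        markers[name] = m

    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        for m in markers.values():
            m += rng.normal(0.0, noise_sd, size=m.shape)

    # signed joint angles at contact, matching the analysis convention
    # (angle rotating the proximal axis onto the distal one, CCW positive)
    contact_angles = {
        "forearm": math.degrees(phi_f_c) - 90.0,
        "wrist": math.degrees(phi_h_c - phi_f_c),
        "index": math.degrees(phi_i_c - phi_h_c),
    }
    return LimbTrajectory(
        times=times,
        markers=markers,
        contact_index=k_contact,
        arming_end_index=int(round(t_strike_start / dt)),
        impact_speed=impact_speed,
        amplitudes=dict(amplitudes),
        contact_angles=contact_angles,
    )


# ---------------------------------------------------------------------------
# session simulation


def _clamped_friction_factor(mu: float, slope_deg: float, floor: float = 0.02) -> float:
    a = math.radians(slope_deg)
    return max(math.sin(a) + mu * math.cos(a), floor)


def simulate_participant_session(
    profile: ParticipantProfile,
    design: ExperimentDesign,
    constants: PhysicalConstants = PhysicalConstants(),
    seed: int | np.random.SeedSequence | None = 0,
    true_mu: dict | None = None,
    include_kinematics: bool = True,
    participant: int = 1,
) -> Session:
    """Simulate a full experimental session for one participant.

    Per trial the agent computes the launch speed that would be optimal
    under its subjective friction coefficient for the block's material
    (plus Gaussian motor noise), the object slides under the *true*
    coefficient, and the belief is updated a fraction ``learning_rate``
    toward the coefficient implied by the observed stopping distance.
    With ``profile.generalizes`` False the belief is reset to
    ``subjective_mu0`` at every block start (a non-generalizing learner,
    useful as a planted negative control for block-transition tests).

    All randomness derives from ``seed`` via ``numpy.random.SeedSequence``
    spawning: one child stream per trial (motor noise), plus one for
    marker noise when kinematics are generated.

    With ``include_kinematics`` False only scalar outcomes and ground
    truth are produced (two orders of magnitude faster; used for
    cohort-scale adaptation analyses).
    """
    if true_mu is None:
        true_mu = dict(TRUE_MU)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    trial_seeds = root.spawn(design.n_trials)
    transfer = TRANSFER_PARAMS[profile.strategy]

    belief = {m: profile.subjective_mu0 for m in true_mu}
    trials: list[TrialRecord] = []
    truths: list[TrialGroundTruth] = []
    current_block = None
    for block, trial_in_block, t_global in design.iter_trials():
        if block.number != current_block:
            current_block = block.number
            if not profile.generalizes:
                belief = {m: profile.subjective_mu0 for m in true_mu}
        rng = np.random.default_rng(trial_seeds[t_global - 1])
        mu_t = true_mu[block.material]
        cond = SurfaceCondition(block.slope, mu_t, block.material)
        f_sub = _clamped_friction_factor(belief[block.material], block.slope)
        v_plan = math.sqrt(2.0 * constants.g * block.target_distance * f_sub)
        v0 = v_plan + rng.normal(0.0, profile.motor_noise_sd) if profile.motor_noise_sd > 0 else v_plan
        dec = deceleration_from_mu(cond, constants)
        v0 = max(v0, 4.0 * dec * constants.dt)  # keep >= 3 samples before stop
        finger_speed = invert_energy_transfer(v0, transfer)

        episode = None
        if include_kinematics:
            try:
                episode = simulate_slide(v0, cond, constants)
            except Exception as exc:
                raise RuntimeError(
                    f"trial {t_global} (block {block.number}): {exc}"
                ) from exc
            traveled = float(episode.positions[-1])
        else:
            # identical to the sampled slide's final plateau: the simulated
            # positions are capped at the closed-form stopping point
            traveled = stopping_distance(v0, cond, constants.g)
        err_pct = 100.0 * (traveled - block.target_distance) / block.target_distance
        mu_observed = subjective_mu(v0, traveled, block.slope, constants.g)
        pre = belief[block.material]
        belief[block.material] = pre + profile.learning_rate * (mu_observed - pre)

        record = TrialRecord(
            participant=participant,
            group=design.group_id,
            block=block.number,
            trial=trial_in_block,
            trial_global=t_global,
            slope=block.slope,
            material=block.material,
            target_distance=block.target_distance,
            dt=constants.dt,
        )
        amplitudes: dict = {}
        contact_index = -1
        contact_time = math.nan
        if include_kinematics:
            limb = simulate_limb_markers(
                profile.strategy,
                finger_speed,
                profile,
                dt=constants.dt,
                seed=rng,
                noise_sd=profile.marker_noise_sd,
            )
            contact_index = limb.contact_index
            contact_time = float(limb.times[contact_index])
            amplitudes = limb.amplitudes
            n_limb = len(limb.times)
            n_slide = len(episode.positions)
            n = max(n_limb, contact_index + n_slide)
            times = np.arange(n) * constants.dt
            markers = {}
            for name, m in limb.markers.items():
                full = np.repeat(m[-1:, :], n, axis=0)
                full[:n_limb] = m
                markers[name] = full
            cube = np.empty(n)
            cube[:contact_index] = 0.0
            m_end = min(n, contact_index + n_slide)
            cube[contact_index:m_end] = episode.positions[: m_end - contact_index]
            cube[m_end:] = episode.positions[-1]
            if profile.marker_noise_sd > 0:
                cube = cube + rng.normal(0.0, profile.marker_noise_sd, size=n)
            record.times = times
            record.markers = markers
            record.cube_y = cube
        truths.append(
            TrialGroundTruth(
                contact_time=contact_time,
                contact_index=contact_index,
                launch_speed=v0,
                finger_impact_speed=finger_speed,
                true_mu=mu_t,
                subjective_mu_pre=pre,
                stop_position=traveled,
                spatial_error_pct=err_pct,
                amplitudes=amplitudes,
            )
        )
        trials.append(record)
    return Session(participant=participant, profile=profile, design=design,
                   trials=trials, ground_truth=truths)


def performance_table(session: Session):
    """Tidy per-trial performance table for one session (ground-truth based)."""
    import pandas as pd

    rows = []
    for rec, gt in zip(session.trials, session.ground_truth):
        rows.append(
            {
                "participant": rec.participant,
                "group": rec.group,
                "block": rec.block,
                "trial": rec.trial,
                "trial_global": rec.trial_global,
                "slope_deg": rec.slope,
                "material": rec.material,
                "target_m": rec.target_distance,
                "launch_speed": gt.launch_speed,
                "finger_impact_speed": gt.finger_impact_speed,
                "stop_position_m": gt.stop_position,
                "spatial_error_pct": gt.spatial_error_pct,
                "true_mu": gt.true_mu,
                "subjective_mu_pre": gt.subjective_mu_pre,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    n_participants: int = 33,
    seed: int | None = 0,
    profile: ParticipantProfile | None = None,
    constants: PhysicalConstants = PhysicalConstants(),
    include_kinematics: bool = False,
    trials_per_block: int = 10,
    groups: list[int] | None = None,
):
    """Simulate a cohort, cycling participants through the four
    counterbalancing groups; returns a list of :class:`Session`."""
    from strikeslide.design import make_design

    if profile is None:
        profile = ParticipantProfile()
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(n_participants)
    sessions = []
    for p in range(n_participants):
        group = groups[p] if groups is not None else (p % 4) + 1
        d = make_design(group, trials_per_block)
        sessions.append(
            simulate_participant_session(
                profile,
                d,
                constants,
                seed=seeds[p],
                include_kinematics=include_kinematics,
                participant=p + 1,
            )
        )
    return sessions
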