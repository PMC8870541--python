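"""Planar joint angles, segmental kinetic energy at impact, and
motor-strategy analysis.

The striking arm is treated as a planar chain pivoting about a fixed elbow
(the task keeps the elbow on the table): forearm (elbow → wrist), hand
(wrist → 3rd metacarpal head) and index finger (metacarpal head →
fingertip), all projected onto the horizontal plane.

Kinetic energy at impact uses the standard rigid-body decomposition —
translational energy of each segment's centre of mass plus rotational
energy about it:

    KE_forearm = 1/2 m_F (r_F w_F)^2 + 1/2 I_F w_F^2
    KE_hand    = 1/2 m_H |v_wrist + w_h x r_H|^2 + 1/2 I_H w_h^2
    KE_total   = KE_forearm + KE_hand
    KE_cube    = 1/2 m_cube v_cube^2

where ``w_F`` is the forearm angular velocity about the elbow, ``v_wrist``
the wrist velocity produced by that rotation (the forearm's translation
entering the hand's energy), ``w_h`` the absolute angular velocity of the
hand and ``r`` centre-of-mass distances from the proximal joint.  Segment
masses, centre-of-mass positions and moments of inertia come from a
configurable anthropometric fraction table (reference values from the
de Leva adjustments of Zatsiorsky's tables).  The index finger's mass is
negligible and excluded.  Only translational object energy is counted:
the channel blocks rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

WRIST = "wrist"
FOREARM = "forearm"

#: Default anthropometric fractions (male reference values): per segment,
#: mass as a fraction of body mass, centre-of-mass distance and radius of
#: gyration (about the COM, for rotation in the horizontal plane) as
#: fractions of segment length measured from the proximal joint.
DEFAULT_FRACTIONS = {
    "forearm": {"mass": 0.0162, "com": 0.4574, "gyration": 0.276},
    "hand": {"mass": 0.0061, "com": 0.7900, "gyration": 0.628},
}

#: Mass of the slid object, kg.
CUBE_MASS = 0.046


class DegenerateGeometryError(ValueError):
    """Two chain markers coincide after projection; angles are undefined."""


@dataclass(frozen=True)
class JointAngles:
    """Joint angles in degrees from horizontal-plane projections.

    ``theta_forearm`` is the angle between the channel axis (y) and the
    forearm axis; ``theta_wrist`` between forearm and hand axes;
    ``theta_index`` between hand and finger axes.  All signed, in
    (-180, 180].
    """

    theta_forearm: float
    theta_wrist: float
    theta_index: float


@dataclass(frozen=True)
class SegmentParameters:
    mass: float  # kg
    com_distance: float  # m from proximal joint
    inertia: float  # kg m^2 about the COM
    length: float  # m


@dataclass(frozen=True)
class AnthropometricModel:
    forearm: SegmentParameters
    hand: SegmentParameters


@dataclass(frozen=True)
class KEProfile:
    ke_forearm: float  # J
    ke_hand: float  # J
    ke_total: float  # J
    ke_cube: float  # J
    efficiency: float  # ke_cube / ke_total
    physically_valid: bool  # efficiency in [0, 1]


@dataclass(frozen=True)
class StrategyAssignment:
    participant: object
    cluster: str  # "wrist" | "forearm"
    features: np.ndarray


def _signed_angle(v_from: np.ndarray, v_to: np.ndarray) -> float:
    """Signed angle (degrees) rotating ``v_from`` onto ``v_to`` in the plane."""
    n_from = np.hypot(*v_from)
    n_to = np.hypot(*v_to)
    if n_from < 1e-9 or n_to < 1e-9:
        raise DegenerateGeometryError("coincident projected markers")
    cross = v_from[0] * v_to[1] - v_from[1] * v_to[0]
    dot = v_from[0] * v_to[0] + v_from[1] * v_to[1]
    return math.degrees(math.atan2(cross, dot))


def joint_angles(
    elbow, wrist, mcp, fingertip, y_axis=(0.0, 1.0)
) -> JointAngles:
    """Joint angles at one sample from projected marker positions.

    Markers are given as 2-D (or 3-D, z ignored) coordinates in the setup
    frame whose y axis is aligned with the channel.
    """
    elbow, wrist, mcp, fingertip = (
        np.asarray(p, dtype=float)[:2] for p in (elbow, wrist, mcp, fingertip)
    )
    y_axis = np.asarray(y_axis, dtype=float)[:2]
    forearm_axis = wrist - elbow
    hand_axis = mcp - wrist
    finger_axis = fingertip - mcp
    return JointAngles(
        theta_forearm=_signed_angle(y_axis, forearm_axis),
        theta_wrist=_signed_angle(forearm_axis, hand_axis),
        theta_index=_signed_angle(hand_axis, finger_axis),
    )


def joint_angle_series(markers: dict, y_axis=(0.0, 1.0)) -> pd.DataFrame:
    """Joint angles for every sample of a marker set.

    ``markers`` maps ``elbow``/``wrist``/``mcp``/``fingertip`` to (n, 3)
    arrays.  Angles are computed vectorially (unwrapped is left to the
    caller; amplitudes over a strike never approach the branch cut).
    """
    e = np.asarray(markers["elbow"])[:, :2]
    w = np.asarray(markers["wrist"])[:, :2]
    m = np.asarray(markers["mcp"])[:, :2]
    f = np.asarray(markers["fingertip"])[:, :2]

    def angles(v_from, v_to):
        cross = v_from[:, 0] * v_to[:, 1] - v_from[:, 1] * v_to[:, 0]
        dot = np.sum(v_from * v_to, axis=1)
        return np.degrees(np.arctan2(cross, dot))

    y = np.broadcast_to(np.asarray(y_axis, dtype=float)[:2], e.shape)
    fa, ha, ia = w - e, m - w, f - m
    return pd.DataFrame(
        {
            "theta_forearm": angles(y, fa),
            "theta_wrist": angles(fa, ha),
            "theta_index": angles(ha, ia),
        }
    )


def angular_amplitude(angle_series: pd.DataFrame, idx_strike_start: int,
                      idx_contact: int) -> dict:
    """Per-joint angular amplitude (degrees, magnitude) over the strike.

    The amplitude is the signed change between the start of the striking
    movement (the arming end) and contact, reported as a magnitude.
    """
    if not 0 <= idx_strike_start <= idx_contact < len(angle_series):
        raise ValueError("strike indices out of range")
    delta = angle_series.iloc[idx_contact] - angle_series.iloc[idx_strike_start]
    return {
        "forearm": float(abs(delta["theta_forearm"])),
        "wrist": float(abs(delta["theta_wrist"])),
        "index": float(abs(delta["theta_index"])),
    }


def segment_parameters(
    body_mass: float,
    forearm_length: float,
    hand_length: float,
    fractions: dict | None = None,
) -> AnthropometricModel:
    """Derive segment masses, COM positions and inertias from body mass and
    segment lengths via an anthropometric fraction table."""
    if body_mass <= 0 or forearm_length <= 0 or hand_length <= 0:
        raise ValueError("body mass and segment lengths must be > 0")
    if fractions is None:
        fractions = DEFAULT_FRACTIONS

    def build(name: str, length: float) -> SegmentParameters:
        f = fractions[name]
        mass = f["mass"] * body_mass
        return SegmentParameters(
            mass=mass,
            com_distance=f["com"] * length,
            inertia=mass * (f["gyration"] * length) ** 2,
            length=length,
        )

    return AnthropometricModel(
        forearm=build("forearm", forearm_length),
        hand=build("hand", hand_length),
    )


def kinetic_energy_at_impact(
    theta_wrist_deg: float,
    omega_forearm: float,
    omega_wrist: float,
    model: AnthropometricModel,
    cube_mass: float = CUBE_MASS,
    cube_speed: float = 0.0,
    use_full_lengths: bool = False,
) -> KEProfile:
    """Upper-limb and object kinetic energy at the moment of impact.

    Parameters
    ----------
    theta_wrist_deg:
        Wrist angle at impact (between forearm and hand axes), degrees.
    omega_forearm, omega_wrist:
        Joint angular velocities at impact, rad/s; the hand's absolute
        angular velocity is their sum (fixed-elbow planar chain).
    use_full_lengths:
        Replace centre-of-mass distances by full segment lengths in the
        translational terms (a literal point-mass-at-the-distal-end
        variant; default off).
    """
    if cube_mass <= 0:
        raise ValueError("cube mass must be > 0")
    if cube_speed < 0:
        raise ValueError("cube speed must be >= 0")
    fore, hand = model.forearm, model.hand
    r_f = fore.length if use_full_lengths else fore.com_distance
    r_h = hand.length if use_full_lengths else hand.com_distance
    w_f = omega_forearm
    w_h = omega_forearm + omega_wrist

    ke_forearm = 0.5 * fore.mass * (r_f * w_f) ** 2 + 0.5 * fore.inertia * w_f**2

    # wrist velocity from forearm rotation, plus hand-COM velocity about
    # the wrist; the tangential directions differ by the wrist angle
    v_wrist = fore.length * w_f
    v_com_rel = r_h * w_h
    cos_rel = math.cos(math.radians(theta_wrist_deg))
    v_com_sq = v_wrist**2 + v_com_rel**2 + 2.0 * v_wrist * v_com_rel * cos_rel
    ke_hand = 0.5 * hand.mass * v_com_sq + 0.5 * hand.inertia * w_h**2

    ke_total = ke_forearm + ke_hand
    ke_cube = 0.5 * cube_mass * cube_speed**2
    efficiency = ke_cube / ke_total if ke_total > 0 else math.inf
    return KEProfile(
        ke_forearm=ke_forearm,
        ke_hand=ke_hand,
        ke_total=ke_total,
        ke_cube=ke_cube,
        efficiency=efficiency,
        physically_valid=bool(0.0 <= efficiency <= 1.0),
    )


def angular_velocities_at(
    angle_series: pd.DataFrame, idx: int, dt: float, window: int = 3
) -> dict:
    """Joint angular velocities (rad/s) from an unfiltered finite
    difference over a ``window``-sample span ending at ``idx``."""
    if window < 2:
        raise ValueError("window must span >= 2 samples")
    i0 = max(idx - window + 1, 0)
    span = (idx - i0) * dt
    if span <= 0:
        raise ValueError("window collapses to a single sample")
    out = {}
    for joint, col in (("forearm", "theta_forearm"), ("wrist", "theta_wrist"),
                       ("index", "theta_index")):
        out[joint] = math.radians(
            float(angle_series[col].iloc[idx] - angle_series[col].iloc[i0])
        ) / span
    return out


def cluster_strategies(
    features: pd.DataFrame,
    wrist_columns: list[str] | None = None,
    seed: int = 0,
) -> list[StrategyAssignment]:
    """K-means (K = 2) strategy clustering on joint angular amplitudes.

    ``features`` is a participants × features table of angular amplitudes
    (degrees), typically 3 joints × conditions from the last trial of each
    condition.  Features are z-scored before clustering.  The cluster
    whose members have the greater mean raw wrist amplitude (columns
    selected by ``wrist_columns``, default: names containing "wrist") is
    labelled ``"wrist"``, the other ``"forearm"``.
    """
    if len(features) < 2:
        raise ValueError("clustering needs >= 2 participants")
    x = features.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValueError("all features are constant across participants")
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(z)

    if wrist_columns is None:
        wrist_columns = [c for c in features.columns if "wrist" in str(c).lower()]
    wrist_vals = (
        features[wrist_columns].to_numpy(dtype=float).mean(axis=1)
        if wrist_columns
        else x.mean(axis=1)
    )
    mean0 = wrist_vals[labels == 0].mean()
    mean1 = wrist_vals[labels == 1].mean()
    name = {0: WRIST if mean0 >= mean1 else FOREARM}
    name[1] = FOREARM if name[0] == WRIST else WRIST
    return [
        StrategyAssignment(participant=p, cluster=name[l], features=x[i])
        for i, (p, l) in enumerate(zip(features.index, labels))
    ]


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    retained: bool  # R^2 > 0.75


def fit_linear_vs_optimal_speed(x, y, r2_threshold: float = 0.75) -> LinearFit:
    """Ordinary least squares of a movement parameter on optimal launch
    speed; retained iff R² exceeds ``r2_threshold``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("optimal-speed values are constant; slope undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 0.0
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        retained=bool(r2 > r2_threshold),
    )
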