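"""Phase segmentation and contact detection from unfiltered kinematics.

Each trial is segmented into three phases from the fingertip and object
speed along the channel axis (positive toward the target): the *arming*
phase (fingertip retreats from the object, ending at rest at maximal
extension), the *striking* phase (speed rises to its maximum at impact)
and the *sliding* phase of the object.

No low-pass filtering is applied anywhere: the ~15 ms collision transient
that contact detection relies on would be destroyed by the cutoffs in
common use for limb kinematics.  Speeds and accelerations are plain
finite differences (``numpy.gradient``: central differences in the
interior, one-sided at the endpoints).

Contact is detected inside the window between maximal fingertip speed and
the start of object motion: each fingertip acceleration sample in the
window is normalized by the window's most negative acceleration, and the
sample immediately *preceding* the first normalized value above 0.4 is
taken as the contact instant.  The 40% criterion skips the shallow
decelerations that sometimes precede contact and cannot fail to fire,
because the minimizer itself normalizes to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from strikeslide.synth import TrialRecord


class SegmentationError(RuntimeError):
    """A sub-detector failed; the message names the trial and phase."""


class NoOnsetError(SegmentationError):
    """The object never exceeded the movement-onset speed threshold."""

    def __init__(self, msg: str, max_speed: float):
        super().__init__(msg)
        self.max_speed = max_speed


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds for the segmentation detectors.

    ``onset_threshold`` (m/s) is the object-speed criterion for movement
    onset; ``stop_threshold`` reuses the same value for stop detection
    (the onset rule run backwards).  ``contact_fraction`` is the
    normalized-deceleration criterion.  ``arming_epsilon`` (m/s) and
    ``arming_consecutive`` define the sustained negative-speed rule for
    the arming start.
    """

    onset_threshold: float = 0.04
    stop_threshold: float = 0.04
    contact_fraction: float = 0.4
    arming_epsilon: float = 0.02
    arming_consecutive: int = 3
    #: the object cannot have moved less than this (m) after onset; used as
    #: a lower bound on the onset index because a launched object covers
    #: several millimetres per sample while marker noise is sub-millimetre
    onset_position_guard: float = 0.0025


@dataclass(frozen=True)
class SegmentedTrial:
    idx_arming_start: int
    idx_arming_end: int
    idx_maxFS: int
    idx_minCS: int
    idx_contact: int
    idx_cube_onset: int
    idx_cube_stop: int
    finger_speed_at_impact: float  # m/s
    initial_cube_speed: float  # m/s, max object speed after onset
    final_front_edge_position: float  # m

    def __post_init__(self) -> None:
        ordered = (
            self.idx_arming_start < self.idx_arming_end <= self.idx_maxFS
            <= self.idx_contact < self.idx_cube_onset <= self.idx_cube_stop
        )
        if not ordered:
            raise SegmentationError(
                "index ordering violated: "
                f"arming {self.idx_arming_start}..{self.idx_arming_end}, "
                f"maxFS {self.idx_maxFS}, contact {self.idx_contact}, "
                f"onset {self.idx_cube_onset}, stop {self.idx_cube_stop}"
            )


def axial_speed(positions: np.ndarray, dt: float) -> np.ndarray:
    """Finite-difference speed of a position series, m/s.

    Central differences in the interior, one-sided differences at the two
    endpoints (``numpy.gradient``).  Deliberately unfiltered.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 1 or len(positions) < 2:
        raise ValueError("need a 1-D series of >= 2 samples")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return np.gradient(positions, dt)


def detect_cube_onset(cube_speed: np.ndarray, threshold: float = 0.04) -> int:
    """First index at which the object's speed exceeds ``threshold`` (m/s).

    Raises :class:`NoOnsetError` (carrying the maximum observed speed)
    when the object never moves fast enough.
    """
    cube_speed = np.asarray(cube_speed, dtype=float)
    above = np.nonzero(cube_speed > threshold)[0]
    if len(above) == 0:
        raise NoOnsetError(
            f"object speed never exceeds {threshold} m/s "
            f"(max observed {cube_speed.max():.4g} m/s)",
            max_speed=float(cube_speed.max()),
        )
    return int(above[0])


def detect_contact(
    finger_accel: np.ndarray,
    idx_start: int,
    idx_end: int,
    fraction: float = 0.4,
) -> int:
    """Contact index from the fingertip deceleration transient.

    Within ``[idx_start, idx_end]`` (typically max fingertip speed to
    object-motion onset), accelerations are normalized by the window's
    minimum (most negative) value; the index immediately preceding the
    first normalized value above ``fraction`` is returned.  Normalized
    values are positive only for decelerations, so shallow pre-contact
    dips below the criterion are skipped by construction and the search
    set is provably nonempty (the minimizer normalizes to exactly 1).
    """
    finger_accel = np.asarray(finger_accel, dtype=float)
    if not 0 <= idx_start < idx_end < len(finger_accel):
        raise SegmentationError(
            f"invalid contact-search interval [{idx_start}, {idx_end}] "
            f"for a series of length {len(finger_accel)}"
        )
    window = finger_accel[idx_start : idx_end + 1]
    a_min = window.min()
    if a_min >= 0:
        raise SegmentationError(
            "no deceleration inside the contact-search interval "
            f"(min acceleration {a_min:.4g} m/s^2)"
        )
    normalized = window / a_min  # > 0 only where decelerating
    # A crossing counts if it is the window minimizer itself (normalized
    # exactly 1, so the set is provably nonempty) or is confirmed by the
    # next sample also crossing.  A genuine collision decelerates for
    # several consecutive samples, whereas differentiation noise produces
    # isolated spikes; adjacent central-difference acceleration samples
    # share no raw positions, so confirmation squares the false-alarm
    # probability without moving the detection on clean data.
    crossing = normalized > fraction
    confirmed = crossing & (
        np.append(crossing[1:], False) | (normalized >= 1.0)
    )
    first = int(np.nonzero(confirmed)[0][0])
    return idx_start + first - 1


def _sustained_crossing(mask: np.ndarray, k: int) -> int | None:
    """First index starting a run of >= k consecutive True values."""
    if k <= 1:
        idx = np.nonzero(mask)[0]
        return int(idx[0]) if len(idx) else None
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= k:
            return i - k + 1
    return None


def segment_trial(
    trial: TrialRecord,
    params: SegmentationParams = SegmentationParams(),
) -> SegmentedTrial:
    """Segment one trial into arming / striking / sliding phases.

    Consumes the fingertip marker's channel-axis (y) coordinate and the
    object position from a :class:`~strikeslide.synth.TrialRecord` (or any
    object with ``markers['fingertip']``, ``cube_y`` and ``dt``).

    Detection rules, in order:

    * arming start — first sustained fingertip retreat (speed below
      ``-arming_epsilon`` for ``arming_consecutive`` samples);
    * arming end — first return of fingertip speed to >= 0 after the
      arming start (rest at maximal extension);
    * object onset — the last upward crossing of the onset threshold
      before the object's speed peak (equivalent to the plain first
      crossing on clean data, but immune to noise-induced early
      crossings while the object is still at rest);
    * max fingertip speed — argmax between arming end and object onset;
    * min object speed — last minimizer of object speed between max
      fingertip speed and onset;
    * contact — :func:`detect_contact` on the window from max fingertip
      speed to object onset (the window must include the onset sample,
      where the collision deceleration lives);
    * object stop — first index after the object's speed peak with
      sustained speed below the stop threshold.
    """
    if trial.markers is None or trial.cube_y is None:
        raise SegmentationError(f"trial {trial.trial_global}: no kinematic series")
    dt = trial.dt
    finger_y = np.asarray(trial.markers["fingertip"])[:, 1]
    cube_y = np.asarray(trial.cube_y, dtype=float)
    fs = axial_speed(finger_y, dt)
    cs = axial_speed(cube_y, dt)
    fa = axial_speed(fs, dt)  # acceleration

    label = f"trial {trial.trial_global} (block {trial.block})"

    # --- arming
    i_arm = _sustained_crossing(fs < -params.arming_epsilon, params.arming_consecutive)
    if i_arm is None:
        raise SegmentationError(f"{label}: no arming phase (finger never retreats)")
    rest = np.nonzero(fs[i_arm:] >= 0)[0]
    if len(rest) == 0:
        raise SegmentationError(f"{label}: arming never ends (no return to rest)")
    i_arm_end = i_arm + int(rest[0])

    # --- object onset: last sub-threshold sample before the speed peak
    try:
        detect_cube_onset(cs, params.onset_threshold)  # validates motion exists
    except NoOnsetError as exc:
        raise NoOnsetError(f"{label}: {exc}", exc.max_speed) from None
    i_peak_cs = int(np.argmax(cs))
    below = np.nonzero(cs[: i_peak_cs + 1] <= params.onset_threshold)[0]
    i_onset = int(below[-1]) + 1 if len(below) else int(
        detect_cube_onset(cs, params.onset_threshold)
    )
    # position guard: the object's accumulated displacement cannot still be
    # at noise level after onset, so the last sample within
    # ``onset_position_guard`` of the rest position bounds onset from below
    rest = float(np.median(cube_y[: max(5, i_arm)]))
    still = np.nonzero(cube_y[: i_peak_cs + 1] - rest <= params.onset_position_guard)[0]
    if len(still):
        i_onset = max(i_onset, int(still[-1]))
    i_onset = min(i_onset, i_peak_cs)

    # --- fingertip speed peak and object speed minimum
    if i_onset <= i_arm_end:
        raise SegmentationError(f"{label}: object onset precedes arming end")
    i_max_fs = i_arm_end + int(np.argmax(fs[i_arm_end : i_onset + 1]))
    cs_win = cs[i_max_fs : i_onset + 1]
    i_min_cs = i_max_fs + int(len(cs_win) - 1 - np.argmin(cs_win[::-1]))

    # --- contact
    win_start = max(i_arm_end, min(i_max_fs, i_onset - 3))
    i_contact = detect_contact(fa, win_start, i_onset, params.contact_fraction)
    i_contact = max(i_contact, win_start)
    if i_contact >= i_onset:
        i_contact = i_onset - 1
    i_max_fs = min(i_max_fs, i_contact)  # report peak speed up to contact
    i_min_cs = max(i_min_cs, i_max_fs)

    # --- object stop
    i_stop_rel = _sustained_crossing(
        cs[i_peak_cs:] < params.stop_threshold, params.arming_consecutive
    )
    i_stop = i_peak_cs + i_stop_rel if i_stop_rel is not None else len(cs) - 1

    initial_cube_speed = float(np.max(cs[i_onset:]))
    return SegmentedTrial(
        idx_arming_start=i_arm,
        idx_arming_end=i_arm_end,
        idx_maxFS=i_max_fs,
        idx_minCS=i_min_cs,
        idx_contact=i_contact,
        idx_cube_onset=i_onset,
        idx_cube_stop=i_stop,
        finger_speed_at_impact=float(fs[i_contact]),
        initial_cube_speed=initial_cube_speed,
        final_front_edge_position=float(np.median(cube_y[max(i_stop, len(cube_y) - 5):])),
    )
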