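"""Exercise protocol definitions.

The measurement campaign uses three hip-driven resistance exercises
(squat, knee-up, reverse lunge), each performed under two conditions:

* ``max``   — maximum-effort bout with no pace constraint, short duration;
* ``const`` — metronome-paced bout at a fixed cadence, longer duration,
  run until the participant can no longer hold the pace.

The durations and target cadences are fixed study constants; the
initial-speed window (number of opening repetitions averaged for the IS
metric) is likewise protocol-bound.
"""

from __future__ import annotations

from dataclasses import dataclass

EXERCISES = ("squat", "kneeup", "lunge")
CONDITIONS = ("max", "const")


@dataclass(frozen=True)
class ExerciseProtocol:
    """One (exercise, condition) cell of the measurement protocol.

    Parameters
    ----------
    exercise : str
        One of ``squat``, ``kneeup``, ``lunge``.
    condition : str
        ``max`` (self-paced, maximal effort) or ``const`` (metronome paced).
    duration : float
        Bout length in seconds.
    target_rpm : float or None
        Metronome cadence in repetitions per minute; ``None`` for the
        ``max`` condition.
    initial_speed_window_reps : int
        Number of opening repetitions averaged for the initial-speed metric.
    nominal_max_rpm : float
        Typical self-paced cadence for this exercise; used only as the
        expected-pace prior for peak detection in the ``max`` condition.
    """

    exercise: str
    condition: str
    duration: float
    target_rpm: float | None
    initial_speed_window_reps: int
    nominal_max_rpm: float

    def __post_init__(self) -> None:
        if self.exercise not in EXERCISES:
            raise ValueError(f"unknown exercise {self.exercise!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.condition == "const" and (self.target_rpm is None or self.target_rpm <= 0):
            raise ValueError("const condition requires target_rpm > 0")

    @property
    def expected_interval_s(self) -> float:
        """Expected flexion-to-flexion interval (s), the pace prior."""
        rpm = self.target_rpm if self.condition == "const" else self.nominal_max_rpm
        return 60.0 / rpm

    @property
    def key(self) -> str:
        return f"{self.exercise}:{self.condition}"


# Study constants: duration [s], cadence [RPM], IS window [reps].
# Self-paced squats average ~8.5 reps per 10 s (50.8 RPM); knee-ups are the
# fastest movement, lunges the slowest.
PROTOCOLS: dict[str, ExerciseProtocol] = {
    p.key: p
    for p in (
        ExerciseProtocol("squat", "max", 45.0, None, 10, nominal_max_rpm=50.8),
        ExerciseProtocol("kneeup", "max", 60.0, None, 30, nominal_max_rpm=140.0),
        ExerciseProtocol("lunge", "max", 60.0, None, 10, nominal_max_rpm=52.0),
        ExerciseProtocol("squat", "const", 90.0, 60.0, 10, nominal_max_rpm=50.8),
        ExerciseProtocol("kneeup", "const", 180.0, 132.0, 30, nominal_max_rpm=140.0),
        ExerciseProtocol("lunge", "const", 120.0, 48.0, 10, nominal_max_rpm=52.0),
    )
}


def get_protocol(exercise: str, condition: str) -> ExerciseProtocol:
    """Look up the study protocol for an (exercise, condition) pair."""
    key = f"{exercise}:{condition}"
    try:
        return PROTOCOLS[key]
    except KeyError:
        raise KeyError(f"no protocol {key!r}; known: {sorted(PROTOCOLS)}") from None


def parse_protocol(spec: str) -> ExerciseProtocol:
    """Parse an ``exercise:condition`` string (e.g. ``squat:const``)."""
    try:
        exercise, condition = spec.split(":")
    except ValueError:
        raise ValueError(f"protocol spec {spec!r} is not 'exercise:condition'") from None
    return get_protocol(exercise, condition)
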