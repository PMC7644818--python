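"""Quality control: the cross-method acceptance gate and artifact flags.

The two repeat-distance estimators are independent enough that their
agreement is a usable acceptance criterion: an analysis is accepted only if
the Method 1 and Method 2 repeat distances deviate by less than 9% (the
threshold is configurable).  The deviation is symmetric — |m1 - m2| divided
by the mean of the two — because neither method is privileged as the
reference.

A second automated flag marks compressed-grana fixation artifacts: stacks
whose repeat distance falls strictly below 13 nm are too tight to
accommodate photosystem II with its lumenal protrusion and indicate
preparation damage rather than native structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .method1 import Method1Result
from .method2 import Method2Result

DEFAULT_GATE_THRESHOLD = 0.09
COMPRESSED_REPEAT_NM = 13.0


@dataclass(frozen=True)
class CrossValVerdict:
    """Outcome of the cross-method repeat-distance comparison."""

    repeat_m1_nm: float
    repeat_m2_nm: float
    threshold_fraction: float
    deviation_fraction: float = field(init=False)
    accepted: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.repeat_m1_nm <= 0 or self.repeat_m2_nm <= 0:
            raise ValidationError("repeat distances must be positive")
        if not (0 < self.threshold_fraction):
            raise ValidationError("threshold must be positive")
        dev = abs(self.repeat_m1_nm - self.repeat_m2_nm) / (
            0.5 * (self.repeat_m1_nm + self.repeat_m2_nm)
        )
        object.__setattr__(self, "deviation_fraction", dev)
        object.__setattr__(self, "accepted", dev < self.threshold_fraction)


@dataclass(frozen=True)
class QcFlags:
    """Automated per-granum artifact flags.

    ``operator_pass`` records the human visual triage verdict (tissue /
    cell / organelle integrity), which is outside the scope of automated
    analysis; it defaults to True (pass) when no operator field is given.
    """

    compressed: bool
    sinusoid_quality_low: bool = False
    segmentation_failed: bool = False
    operator_pass: bool = True


def cross_validate(
    m1: Method1Result | float,
    m2: Method2Result | float,
    threshold: float = DEFAULT_GATE_THRESHOLD,
) -> CrossValVerdict:
    """Gate one granum on the agreement of its two repeat estimates."""
    r1 = m1.repeat_nm if isinstance(m1, Method1Result) else float(m1)
    r2 = m2.repeat_nm if isinstance(m2, Method2Result) else float(m2)
    return CrossValVerdict(repeat_m1_nm=r1, repeat_m2_nm=r2, threshold_fraction=threshold)


def flag_compressed(repeat_nm: float, threshold_nm: float = COMPRESSED_REPEAT_NM) -> bool:
    """True when the repeat distance is strictly below the artifact bound."""
    if repeat_nm <= 0:
        raise ValidationError("repeat distance must be positive")
    return repeat_nm < threshold_nm


def make_flags(
    repeat_nm: float,
    fit_r_squared: float,
    r2_floor: float = 0.5,
    operator_pass: bool = True,
) -> QcFlags:
    return QcFlags(
        compressed=flag_compressed(repeat_nm),
        sinusoid_quality_low=fit_r_squared < r2_floor,
        operator_pass=operator_pass,
    )
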