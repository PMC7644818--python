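"""Ground-truth geometries for grana stacks and stroma lamellae.

Widths are in nanometres.  A granum is modelled as ``n_layers`` parallel
thylakoid discs: each disc contributes a bright (in HPF contrast) band of
width ``lm_nm`` — two membranes plus the enclosed lumen, indistinguishable
from each other in HPF images — separated from the next disc by a dark
stromal gap of width ``gap_nm``.  The vertical period of the stack, the
*repeat distance*, runs from the middle of one stromal gap to the middle of
the next and is therefore exactly ``gap_nm + lm_nm``.

A stroma lamella is a single unstacked membrane–lumen–membrane band of
total width ``total_nm``; in microwave-fixation contrast the two dark
membranes and the bright lumen are individually resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

_COMPONENT_TOL = 1e-9


@dataclass(frozen=True)
class GranaGeometry:
    """Geometry of one granum stack (all widths in nm)."""

    gap_nm: float
    lm_nm: float
    n_layers: int = 10
    diameter_nm: float = 200.0
    tilt_deg: float = 0.0
    membrane_nm: float | None = None
    lumen_nm: float | None = None
    repeat_nm: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.gap_nm > 0 and self.lm_nm > 0):
            raise ValidationError(
                f"stromal gap and lumen+membranes widths must be positive, "
                f"got gap={self.gap_nm}, lm={self.lm_nm}"
            )
        if self.diameter_nm <= 0:
            raise ValidationError(f"diameter_nm must be positive, got {self.diameter_nm}")
        if int(self.n_layers) != self.n_layers or self.n_layers < 3:
            raise ValidationError(f"n_layers must be an integer >= 3, got {self.n_layers}")
        if not (-90.0 <= self.tilt_deg < 90.0):
            raise ValidationError(f"tilt_deg must lie in [-90, 90), got {self.tilt_deg}")
        if (self.membrane_nm is None) != (self.lumen_nm is None):
            raise ValidationError("membrane_nm and lumen_nm must be given together")
        if self.membrane_nm is not None:
            if self.membrane_nm < 0 or self.lumen_nm < 0:
                raise ValidationError("membrane_nm and lumen_nm must be non-negative")
            if abs(2.0 * self.membrane_nm + self.lumen_nm - self.lm_nm) > _COMPONENT_TOL:
                raise ValidationError(
                    f"2*membrane + lumen = {2 * self.membrane_nm + self.lumen_nm} "
                    f"does not equal lm_nm = {self.lm_nm}"
                )
        object.__setattr__(self, "repeat_nm", self.gap_nm + self.lm_nm)


@dataclass(frozen=True)
class LamellaGeometry:
    """Geometry of one stroma lamella (membrane-lumen-membrane band)."""

    total_nm: float
    length_nm: float = 200.0
    tilt_deg: float = 0.0
    membrane_nm: float | None = None
    lumen_nm: float | None = None

    def __post_init__(self) -> None:
        if self.total_nm <= 0:
            raise ValidationError(f"total_nm must be positive, got {self.total_nm}")
        if self.length_nm <= 0:
            raise ValidationError(f"length_nm must be positive, got {self.length_nm}")
        if not (-90.0 <= self.tilt_deg < 90.0):
            raise ValidationError(f"tilt_deg must lie in [-90, 90), got {self.tilt_deg}")
        if (self.membrane_nm is None) != (self.lumen_nm is None):
            raise ValidationError("membrane_nm and lumen_nm must be given together")
        if self.membrane_nm is not None:
            if self.membrane_nm < 0 or self.lumen_nm < 0:
                raise ValidationError("membrane_nm and lumen_nm must be non-negative")
            if abs(2.0 * self.membrane_nm + self.lumen_nm - self.total_nm) > _COMPONENT_TOL:
                raise ValidationError(
                    f"2*membrane + lumen = {2 * self.membrane_nm + self.lumen_nm} "
                    f"does not equal total_nm = {self.total_nm}"
                )


def make_grana_truth(
    gap_nm: float,
    lm_nm: float,
    n_layers: int = 10,
    diameter_nm: float = 200.0,
    tilt_deg: float = 0.0,
    membrane_nm: float | None = None,
    lumen_nm: float | None = None,
) -> GranaGeometry:
    """Build a validated granum ground truth; repeat_nm is derived as gap+lm."""
    return GranaGeometry(
        gap_nm=gap_nm,
        lm_nm=lm_nm,
        n_layers=n_layers,
        diameter_nm=diameter_nm,
        tilt_deg=tilt_deg,
        membrane_nm=membrane_nm,
        lumen_nm=lumen_nm,
    )


def make_lamella_truth(
    total_nm: float,
    length_nm: float = 200.0,
    tilt_deg: float = 0.0,
    membrane_nm: float | None = None,
    lumen_nm: float | None = None,
) -> LamellaGeometry:
    """Build a validated lamella ground truth."""
    return LamellaGeometry(
        total_nm=total_nm,
        length_nm=length_nm,
        tilt_deg=tilt_deg,
        membrane_nm=membrane_nm,
        lumen_nm=lumen_nm,
    )
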