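"""Domain types for labelling, chimerism and reporter-dilution observations.

Three experimental clocks coexist in this analysis and are kept in
separate types to prevent conflation:

* labelling data: t=0 is the start of BrdU administration,
* chimerism data: t=0 is the bone-marrow transplant (BMT),
* dilution data: t=0 is tamoxifen treatment.

Fractions are stored as proportions in [0, 1]; the CSV readers accept a
``percent`` flag for tables recorded on the 0-100 scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Cohort(str, enum.Enum):
    """Mouse age cohort at the time of labelling."""

    YOUNG = "young"
    OLD = "old"


class Subset(str, enum.Enum):
    """Gated T cell population."""

    TCM = "TCM"
    TEM = "TEM"
    NAIVE_CD4 = "naive_CD4"
    DP1 = "DP1"


class Lineage(str, enum.Enum):
    """Host- or donor-derived cells in a busulfan chimera."""

    HOST = "host"
    DONOR = "donor"


#: Tolerance for the additive consistency of the four labelling fractions.
CONSISTENCY_TOL = 1e-6

#: Last admissible sampling day in the standard 21 d pulse + 14 d chase design.
MAX_LABEL_DAY = 35.0


class ValidationError(ValueError):
    """An observation violated a domain invariant."""


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValidationError(f"{name}={value!r} outside [0, 1]")


@dataclass(frozen=True)
class LabellingObservation:
    """One mouse x subset x lineage x timepoint BrdU/Ki67 record.

    ``frac_brdu`` is the BrdU+ fraction of the whole population;
    ``frac_brdu_in_ki67hi`` / ``frac_brdu_in_ki67lo`` are the BrdU+
    fractions within the Ki67-high and Ki67-low gates, and
    ``frac_ki67hi`` the Ki67-high fraction.  When all four are supplied
    they must satisfy

        frac_brdu = frac_ki67hi * frac_brdu_in_ki67hi
                    + (1 - frac_ki67hi) * frac_brdu_in_ki67lo
    """

    mouse_id: str
    cohort: Cohort
    subset: Subset
    lineage: Lineage
    t_label: float
    frac_brdu: float
    frac_brdu_in_ki67hi: float
    frac_brdu_in_ki67lo: float
    frac_ki67hi: float
    n_events: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_label <= MAX_LABEL_DAY):
            raise ValidationError(
                f"t_label={self.t_label} outside [0, {MAX_LABEL_DAY}]"
            )
        for name in (
            "frac_brdu",
            "frac_brdu_in_ki67hi",
            "frac_brdu_in_ki67lo",
            "frac_ki67hi",
        ):
            _check_fraction(name, getattr(self, name))
        if self.n_events <= 0:
            raise ValidationError(f"n_events={self.n_events} must be positive")
        k = self.frac_ki67hi
        implied = k * self.frac_brdu_in_ki67hi + (1.0 - k) * self.frac_brdu_in_ki67lo
        if abs(implied - self.frac_brdu) > CONSISTENCY_TOL:
            raise ValidationError(
                "inconsistent fractions: frac_brdu="
                f"{self.frac_brdu:.8f} but gates imply {implied:.8f}"
            )


@dataclass(frozen=True)
class ChimerismObservation:
    """Donor fraction of one subset in one mouse at ``t_bmt`` days post BMT."""

    mouse_id: str
    t_bmt: float
    subset: Subset
    donor_fraction: float

    def __post_init__(self) -> None:
        if self.t_bmt < 0:
            raise ValidationError(f"t_bmt={self.t_bmt} must be >= 0")
        _check_fraction("donor_fraction", self.donor_fraction)


@dataclass(frozen=True)
class DilutionObservation:
    """Reporter-positive (mTom+ or YFP+) fraction at ``t_tam`` days post tamoxifen."""

    mouse_id: str
    t_tam: float
    subset: Subset
    labelled_fraction: float

    def __post_init__(self) -> None:
        if self.t_tam < 0:
            raise ValidationError(f"t_tam={self.t_tam} must be >= 0")
        _check_fraction("labelled_fraction", self.labelled_fraction)


def _default_sample_times() -> list:
    return [2.0, 4.0, 7.0, 10.0, 14.0, 17.0, 21.0, 24.0, 28.0, 31.0, 35.0]


@dataclass
class ExperimentDesign:
    """Sampling design of a BrdU pulse-chase experiment.

    Defaults follow the standard design: label for 21 days, chase for a
    further 14, two mice per timepoint.  ``events_per_sample`` is the
    flow-cytometry counting depth used by the noise model.
    """

    pulse_end: float = 21.0
    chase_end: float = 35.0
    sample_times: list = field(default_factory=_default_sample_times)
    mice_per_timepoint: int = 2
    events_per_sample: int = 5000

    def __post_init__(self) -> None:
        if not (0 < self.pulse_end < self.chase_end):
            raise ValidationError("need 0 < pulse_end < chase_end")
        for t in self.sample_times:
            if not (0.0 <= t <= self.chase_end):
                raise ValidationError(
                    f"sample time {t} outside [0, {self.chase_end}]"
                )
        if self.mice_per_timepoint <= 0 or self.events_per_sample <= 0:
            raise ValidationError("mice_per_timepoint and events_per_sample must be positive")
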