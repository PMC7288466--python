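"""Cell-cycle phase durations from snapshots of an asynchronous culture.

An exponentially growing population has a stationary age distribution
f(a) = 2*alpha*exp(-alpha*a) on [0, T], where T is the doubling time and
alpha = ln 2 / T the specific growth rate.  Because young cells outnumber
old ones 2:1, the fraction of cells observed in a terminal phase is not
proportional to that phase's length; the Williams (1971) equation corrects
for this.  Given

* the fraction of cells in cytokinesis (f_C) and in mitosis+cytokinesis
  (f_MC),
* the fraction labeled after an EdU pulse of length t (L), and
* the minimum chase time at which one cell shows two labeled nuclei (t_2N),

the durations of C, M, G2, S and G1 are obtained in that order:

    x(y)  = -ln(1 - y/2) / alpha          (cumulative time to phase start)
    C     = T - x(1 - f_C)
    M     = (T - x(1 - f_MC)) - C
    G2    = t_2N - M
    S     = (1/alpha) * ln(L + e^{alpha*Z}) - (Z + t)   (Stanners & Till, 1960)
    G1    = T - (S + Z),   with Z = G2 + M + C

All durations are in hours.  Inputs are *fractions* in [0, 1]; percent
conversion belongs to the interface layer (CLI), never here.  Degenerate or
mutually contradictory observations raise named errors instead of being
clamped — a negative phase means the counts are wrong, and silently
truncating would hide that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import (
    DomainError,
    InconsistentObservationError,
    LabelingTooLowError,
    OriminError,
)

__all__ = [
    "GrowthModel",
    "PopulationSnapshot",
    "PhaseDurations",
    "CcuBreakdown",
    "cumulative_time_to_phase_start",
    "duration_cytokinesis",
    "duration_mitosis",
    "duration_g2",
    "duration_s",
    "duration_g1",
    "estimate_all",
    "to_ccu",
]

_LN2 = math.log(2.0)

#: phases in cycle order
PHASES = ("g1", "s", "g2", "m", "c")


def _check_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class GrowthModel:
    """Exponential growth of an asynchronous population.

    Parameters
    ----------
    doubling_time : float
        Population doubling time T, in hours.  Must be positive.

    The specific growth rate alpha = ln 2 / T is derived on access and can
    never disagree with the doubling time.
    """

    doubling_time: float

    def __post_init__(self) -> None:
        _check_finite("doubling_time", self.doubling_time)
        if self.doubling_time <= 0:
            raise DomainError(
                f"doubling_time must be > 0 h, got {self.doubling_time}"
            )

    @property
    def growth_rate(self) -> float:
        """Specific growth rate alpha = ln 2 / T, per hour."""
        return _LN2 / self.doubling_time


@dataclass(frozen=True)
class PopulationSnapshot:
    """Observed fractions and pulse timings of one asynchronous culture.

    Attributes
    ----------
    frac_cytokinesis : float
        Fraction of cells in cytokinesis (f_C), in [0, 1).
    frac_mitosis_plus_cyto : float
        Fraction in mitosis or cytokinesis (f_MC), in [0, 1); must be >= f_C
        since the cytokinesis cells are a subset.
    frac_edu_labeled : float
        Fraction of cells with EdU-labeled nuclei after the pulse (L), [0, 1].
    pulse_duration : float
        EdU pulse length t, hours, > 0.
    time_to_two_labeled_nuclei : float
        Minimum chase time until a single cell shows two labeled nuclei
        (t_2N = G2 + M), hours, > 0.
    """

    frac_cytokinesis: float
    frac_mitosis_plus_cyto: float
    frac_edu_labeled: float
    pulse_duration: float
    time_to_two_labeled_nuclei: float

    def __post_init__(self) -> None:
        f_c = _check_finite("frac_cytokinesis", self.frac_cytokinesis)
        f_mc = _check_finite("frac_mitosis_plus_cyto", self.frac_mitosis_plus_cyto)
        lab = _check_finite("frac_edu_labeled", self.frac_edu_labeled)
        for name, frac in (
            ("frac_cytokinesis", f_c),
            ("frac_mitosis_plus_cyto", f_mc),
        ):
            if not 0.0 <= frac < 1.0:
                raise DomainError(f"{name} must lie in [0, 1), got {frac}")
        if not 0.0 <= lab <= 1.0:
            raise DomainError(f"frac_edu_labeled must lie in [0, 1], got {lab}")
        if f_mc < f_c:
            raise InconsistentObservationError(
                "frac_mitosis_plus_cyto "
                f"({f_mc}) < frac_cytokinesis ({f_c}): the M+C cells must "
                "include the cytokinesis cells"
            )
        if _check_finite("pulse_duration", self.pulse_duration) <= 0:
            raise DomainError(
                f"pulse_duration must be > 0 h, got {self.pulse_duration}"
            )
        if _check_finite(
            "time_to_two_labeled_nuclei", self.time_to_two_labeled_nuclei
        ) <= 0:
            raise DomainError(
                "time_to_two_labeled_nuclei must be > 0 h, got "
                f"{self.time_to_two_labeled_nuclei}"
            )


@dataclass(frozen=True)
class PhaseDurations:
    """Durations of the five phases, in hours; all non-negative."""

    g1: float
    s: float
    g2: float
    m: float
    c: float

    def __post_init__(self) -> None:
        for name in PHASES:
            value = _check_finite(name, getattr(self, name))
            if value < 0:
                raise DomainError(f"phase {name} must be >= 0 h, got {value}")

    @property
    def z(self) -> float:
        """Z = G2 + M + C, the post-synthesis remainder of the cycle."""
        return self.g2 + self.m + self.c

    @property
    def total(self) -> float:
        """G1 + S + Z; equals the doubling time for a consistent estimate."""
        return self.g1 + self.s + self.z

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PHASES}


@dataclass(frozen=True)
class CcuBreakdown:
    """Phase lengths as fractions of one cell-cycle unit (ccu).

    One ccu is the population doubling time, so the five fractions sum to 1
    (enforced to 1e-9).
    """

    g1: float
    s: float
    g2: float
    m: float
    c: float

    def __post_init__(self) -> None:
        total = sum(getattr(self, name) for name in PHASES)
        if abs(total - 1.0) > 1e-9:
            raise DomainError(
                f"ccu fractions must sum to 1 (got {total!r}); the phase "
                "durations do not add up to the doubling time"
            )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PHASES}


def cumulative_time_to_phase_start(y: float, growth: GrowthModel) -> float:
    """Williams (1971): cumulative time x to reach the start of a phase.

    ``y`` is the cumulative proportion of cells *up to* the phase in
    question (a fraction of one).  Under the stationary age distribution,

        x = -ln(1 - y/2) / alpha

    which runs from x(0) = 0 to x(1) = T.
    """
    _check_finite("y", y)
    if not 0.0 <= y <= 1.0:
        raise DomainError(f"y must lie in [0, 1], got {y}")
    alpha = growth.growth_rate
    # y = 1 gives -ln(1/2)/alpha = T exactly up to rounding; use log1p for
    # accuracy near y = 0.
    return -math.log1p(-y / 2.0) / alpha


def duration_cytokinesis(f_c: float, growth: GrowthModel) -> float:
    """Duration of cytokinesis from the fraction of cells observed in C."""
    _check_finite("frac_cytokinesis", f_c)
    if not 0.0 <= f_c < 1.0:
        raise DomainError(
            f"frac_cytokinesis must lie in [0, 1), got {f_c}; a whole "
            "population in cytokinesis is a degenerate observation"
        )
    return growth.doubling_time - cumulative_time_to_phase_start(1.0 - f_c, growth)


def duration_mitosis(f_mc: float, c: float, growth: GrowthModel) -> float:
    """Duration of mitosis from f_MC and the cytokinesis duration ``c``."""
    _check_finite("frac_mitosis_plus_cyto", f_mc)
    if not 0.0 <= f_mc < 1.0:
        raise DomainError(
            f"frac_mitosis_plus_cyto must lie in [0, 1), got {f_mc}"
        )
    if c < 0:
        raise DomainError(f"cytokinesis duration must be >= 0 h, got {c}")
    mc = growth.doubling_time - cumulative_time_to_phase_start(1.0 - f_mc, growth)
    m = mc - c
    if m < 0:
        raise InconsistentObservationError(
            f"frac_mitosis_plus_cyto ({f_mc}) implies M+C = {mc:.6g} h, "
            f"less than the cytokinesis duration {c:.6g} h derived from "
            "frac_cytokinesis; the two counts contradict each other"
        )
    return m


def duration_g2(t_2n: float, m: float) -> float:
    """G2 = (time to two labeled nuclei) - (mitosis duration)."""
    _check_finite("time_to_two_labeled_nuclei", t_2n)
    if t_2n <= 0:
        raise DomainError(
            f"time_to_two_labeled_nuclei must be > 0 h, got {t_2n}"
        )
    if m < 0:
        raise DomainError(f"mitosis duration must be >= 0 h, got {m}")
    g2 = t_2n - m
    if g2 < 0:
        raise InconsistentObservationError(
            f"time_to_two_labeled_nuclei ({t_2n:.6g} h) is shorter than the "
            f"mitosis duration ({m:.6g} h) derived from the phase fractions"
        )
    return g2


def duration_s(lab: float, z: float, t: float, growth: GrowthModel) -> float:
    """Stanners & Till (1960): S-phase duration from the labeled fraction.

        S = (1/alpha) * ln(L + e^{alpha*Z}) - (Z + t)

    ``lab`` is the labeled fraction L after a pulse of ``t`` hours and
    ``z`` = G2 + M + C.  L too small for any non-negative S raises
    :class:`LabelingTooLowError`; L so large that S + Z would exceed the
    doubling time raises :class:`InconsistentObservationError`.
    """
    _check_finite("frac_edu_labeled", lab)
    if not 0.0 <= lab <= 1.0:
        raise DomainError(f"frac_edu_labeled must lie in [0, 1], got {lab}")
    if z < 0:
        raise DomainError(f"Z must be >= 0 h, got {z}")
    _check_finite("pulse_duration", t)
    if t <= 0:
        raise DomainError(f"pulse_duration must be > 0 h, got {t}")
    alpha = growth.growth_rate
    s = math.log(lab + math.exp(alpha * z)) / alpha - (z + t)
    if s < 0:
        raise LabelingTooLowError(
            f"frac_edu_labeled ({lab}) after a {t} h pulse implies a negative "
            f"S-phase ({s:.6g} h) given Z = {z:.6g} h: too few labeled cells "
            "for the reported pulse and Z"
        )
    if s + z > growth.doubling_time + 1e-9:
        raise InconsistentObservationError(
            f"S + Z = {s + z:.6g} h exceeds the doubling time "
            f"{growth.doubling_time:.6g} h: frac_edu_labeled ({lab}) is too "
            "high to be consistent with the phase fractions"
        )
    return s


def duration_g1(s: float, z: float, growth: GrowthModel) -> float:
    """G1 = T - (S + Z)."""
    if s < 0 or z < 0:
        raise DomainError(f"S and Z must be >= 0 h, got S={s}, Z={z}")
    g1 = growth.doubling_time - (s + z)
    if g1 < 0:
        raise InconsistentObservationError(
            f"S + Z = {s + z:.6g} h exceeds the doubling time "
            f"{growth.doubling_time:.6g} h, leaving a negative G1"
        )
    return g1


def estimate_all(
    snapshot: PopulationSnapshot, growth: GrowthModel
) -> PhaseDurations:
    """Run the full pipeline C -> M -> G2 -> S -> G1.

    Errors raised by a stage are re-raised with the stage name prefixed, so
    a contradictory input is reported against the phase whose computation
    exposed it.
    """

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except OriminError as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    c = stage("cytokinesis", duration_cytokinesis, snapshot.frac_cytokinesis, growth)
    m = stage("mitosis", duration_mitosis, snapshot.frac_mitosis_plus_cyto, c, growth)
    g2 = stage("G2", duration_g2, snapshot.time_to_two_labeled_nuclei, m)
    z = g2 + m + c
    s = stage(
        "S",
        duration_s,
        snapshot.frac_edu_labeled,
        z,
        snapshot.pulse_duration,
        growth,
    )
    g1 = stage("G1", duration_g1, s, z, growth)
    return PhaseDurations(g1=g1, s=s, g2=g2, m=m, c=c)


def to_ccu(durations: PhaseDurations, growth: GrowthModel) -> CcuBreakdown:
    """Express each phase as a fraction of the doubling time (ccu).

    Requires the durations to fill the doubling time (|total - T| <= 1e-9 h);
    anything else means they came from inconsistent inputs.
    """
    t = growth.doubling_time
    if abs(durations.total - t) > 1e-9:
        raise InconsistentObservationError(
            f"phase durations total {durations.total!r} h but the doubling "
            f"time is {t!r} h; cannot express as cell-cycle units"
        )
    return CcuBreakdown(**{k: v / t for k, v in durations.as_dict().items()})
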