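"""Minimum number of replication origins (MO) per chromosome.

Replication forks move bidirectionally from each fired origin, so k origins
firing at the start of S-phase can copy at most 2*k*v*S base pairs in an
S-phase of S minutes at fork rate v.  The smallest k able to finish a
chromosome of N bp is therefore

    MO = ceil( N / (2 * v * S) )

with v in bp/min.  The ceiling applies only to true fractions: an exact
integer quotient is *not* bumped.

Replication stress is modelled as a multiplier on the fork rate only
(S-phase duration is held fixed, the robustness assumption): 2/3 of the
wild-type rate for mild stress, 1/3 for harsh stress.  Stress can therefore
only raise MO.

All arithmetic is exact rational (:mod:`fractions`).  Several published
table cells sit within 0.5% of a ceiling boundary, where binary floating
point could flip the result; rates like 3.06 kb/min and S-phases like
138.6 min are decimal numbers and are kept exact throughout.  The kb -> bp
conversion factor is exactly 1000.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd

from .errors import DomainError

__all__ = [
    "Chromosome",
    "ReplicationParams",
    "CombingInput",
    "STRESS_FACTORS",
    "minimum_origins",
    "stressed_minimum_origins",
    "combing_origins",
    "genome_mo_table",
]

#: stress scenario -> multiplier applied to the fork rate
STRESS_FACTORS: Mapping[str, Fraction] = {
    "none": Fraction(1),
    "mild": Fraction(2, 3),
    "harsh": Fraction(1, 3),
}


def as_fraction(value, name: str = "value") -> Fraction:
    """Convert a number to an exact Fraction.

    Floats are interpreted through their shortest decimal representation
    (``str``), so 3.06 means exactly 306/100 rather than the nearest binary
    double.  Strings and Decimals are taken verbatim.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, (int, numbers.Integral)):
        return Fraction(int(value))
    if isinstance(value, float):
        if not math.isfinite(value):
            raise DomainError(f"{name} must be finite, got {value!r}")
        return Fraction(str(value))
    try:
        return Fraction(value)
    except (ValueError, TypeError) as exc:
        raise DomainError(f"cannot interpret {name}={value!r} as a number") from exc


@dataclass(frozen=True)
class Chromosome:
    """A chromosome identified by name, with its length in base pairs."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if not isinstance(self.length, (int, numbers.Integral)) or isinstance(
            self.length, bool
        ):
            raise DomainError(
                f"chromosome {self.name!r}: length must be an integer bp "
                f"count, got {self.length!r}"
            )
        if self.length < 1:
            raise DomainError(
                f"chromosome {self.name!r}: length must be >= 1 bp, got "
                f"{self.length}"
            )


@dataclass(frozen=True)
class ReplicationParams:
    """Replication-kinetics parameters of one organism.

    Parameters
    ----------
    fork_rate : number
        Mean replication-fork rate v, kb per minute.
    s_phase : number
        S-phase duration S, minutes.
    stress_factor : number, default 1
        Multiplier on the fork rate, in (0, 1]; see :data:`STRESS_FACTORS`.
    """

    fork_rate: Fraction
    s_phase: Fraction
    stress_factor: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fork_rate", as_fraction(self.fork_rate, "fork_rate"))
        object.__setattr__(self, "s_phase", as_fraction(self.s_phase, "s_phase"))
        object.__setattr__(
            self, "stress_factor", as_fraction(self.stress_factor, "stress_factor")
        )
        if self.fork_rate <= 0:
            raise DomainError(f"fork_rate must be > 0 kb/min, got {self.fork_rate}")
        if self.s_phase <= 0:
            raise DomainError(f"s_phase must be > 0 min, got {self.s_phase}")
        if not 0 < self.stress_factor <= 1:
            raise DomainError(
                f"stress_factor must lie in (0, 1], got {self.stress_factor}"
            )

    @property
    def effective_rate_bp_min(self) -> Fraction:
        """Stress-adjusted fork rate in bp/min (exact)."""
        return 1000 * self.fork_rate * self.stress_factor

    @property
    def capacity_bp(self) -> Fraction:
        """2 * v_eff * S: bp one origin replicates in a full S-phase."""
        return 2 * self.effective_rate_bp_min * self.s_phase

    def under_stress(self, scenario: str) -> "ReplicationParams":
        """Same parameters with the scenario's rate multiplier applied."""
        if scenario not in STRESS_FACTORS:
            raise DomainError(
                f"unknown stress scenario {scenario!r}; expected one of "
                f"{sorted(STRESS_FACTORS)}"
            )
        return replace(self, stress_factor=STRESS_FACTORS[scenario])


@dataclass(frozen=True)
class CombingInput:
    """A chromosome plus the mean inter-origin distance from DNA combing."""

    chromosome: Chromosome
    iod: Fraction  # kb

    def __post_init__(self) -> None:
        object.__setattr__(self, "iod", as_fraction(self.iod, "iod"))
        if self.iod <= 0:
            raise DomainError(f"inter-origin distance must be > 0 kb, got {self.iod}")


def minimum_origins(chrom: Chromosome, params: ReplicationParams) -> int:
    """MO = ceil(N / (2 * v_eff * S)), computed exactly."""
    return math.ceil(Fraction(chrom.length) / params.capacity_bp)


def stressed_minimum_origins(
    chrom: Chromosome, params: ReplicationParams, scenario: str
) -> int:
    """MO under a named stress scenario ('mild' = 2/3 v, 'harsh' = 1/3 v)."""
    return minimum_origins(chrom, params.under_stress(scenario))


def combing_origins(inp: CombingInput) -> int:
    """Origins fired on average, Oc = ceil(N / IOD), with IOD in kb."""
    return math.ceil(Fraction(inp.chromosome.length) / (1000 * inp.iod))


def genome_mo_table(
    karyotype: Iterable[Chromosome],
    params: ReplicationParams,
    scenarios: Iterable[str] = (),
) -> pd.DataFrame:
    """One MO row per chromosome, in input order.

    Returns a DataFrame with columns ``chromosome``, ``length_bp``, ``mo``
    and, for each requested scenario, ``mo_<scenario>``.  An empty karyotype
    yields an empty table with the same columns.
    """
    scenarios = list(scenarios)
    for scenario in scenarios:
        if scenario not in STRESS_FACTORS or scenario == "none":
            raise DomainError(
                f"unknown stress scenario {scenario!r}; expected 'mild' or 'harsh'"
            )
    rows = []
    for chrom in karyotype:
        row = {
            "chromosome": chrom.name,
            "length_bp": chrom.length,
            "mo": minimum_origins(chrom, params),
        }
        for scenario in scenarios:
            row[f"mo_{scenario}"] = stressed_minimum_origins(chrom, params, scenario)
        rows.append(row)
    columns = ["chromosome", "length_bp", "mo"] + [f"mo_{s}" for s in scenarios]
    return pd.DataFrame(rows, columns=columns)
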