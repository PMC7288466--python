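"""Forward simulator for an asynchronous exponentially growing population.

This is the synthetic-data generator and the independent oracle for the
phase-duration estimator: given *known* phase lengths it produces the
observables the estimator consumes (f_C, f_MC, L, t, t_2N), so a round trip
``estimate_all(simulate_snapshot(cfg))`` must recover the truth up to
Monte-Carlo error.

Model
-----
Cell ages are drawn from the stationary age density of exponential growth,
f(a) = 2*alpha*e^{-alpha*a} on [0, T], by inverse CDF:  a = -ln(1 - u/2)/alpha
with u ~ U[0, 1).  Phase lengths are deterministic (no cell-to-cell
variability), so phase is an interval lookup on the cumulative boundaries
[0, G1, G1+S, G1+S+G2, G1+S+G2+M, T], half-open on the left.

The population is censused at the *start* of the EdU pulse: a cell is
labeled iff it is in S at any moment of the pulse, i.e. its age lies in
(G1 - t, G1 + S].  This convention makes the expected labeled fraction
exactly the Stanners-Till closed form e^{alpha(S+Z+t)} - e^{alpha*Z}
(growth during the short pulse is not modelled, matching the equation's own
assumption).  It requires t <= G1 and t <= Z; configurations outside that
window would break the closed form and are rejected.

The chase observable t_2N is emitted noiselessly as G2 + M — it is treated
as a directly measured scalar, not re-derived from discrete sampling times.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .cellcycle import (
    GrowthModel,
    PhaseDurations,
    PopulationSnapshot,
    estimate_all,
)
from .errors import DomainError, UnsupportedConfigurationError

__all__ = [
    "SimulationConfig",
    "sample_cell_ages",
    "classify_phase",
    "simulate_snapshot",
    "expected_fractions",
    "recovery_standard_errors",
]

_PHASE_LABELS = ("G1", "S", "G2", "M", "C")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one synthetic population.

    ``detection_probability`` thins the labeled cells (EdU detection below
    100% efficiency); the default 1.0 matches the closed-form model.
    """

    durations: PhaseDurations
    n_cells: int
    pulse_duration: float
    seed: int
    detection_probability: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise DomainError(f"n_cells must be >= 1, got {self.n_cells}")
        if not isinstance(self.seed, (int, np.integer)):
            raise DomainError(f"seed must be an integer, got {self.seed!r}")
        if self.durations.s <= 0:
            raise UnsupportedConfigurationError(
                "S must be > 0 h: with no S-phase the labeled fraction "
                "cannot identify it"
            )
        if not 0 < self.pulse_duration <= self.durations.z:
            raise UnsupportedConfigurationError(
                f"pulse_duration ({self.pulse_duration} h) must lie in "
                f"(0, Z] with Z = {self.durations.z:.6g} h; a longer pulse "
                "lets a labeled cell divide during labeling, outside the "
                "closed-form model"
            )
        if self.pulse_duration > self.durations.g1:
            raise UnsupportedConfigurationError(
                f"pulse_duration ({self.pulse_duration} h) exceeds G1 "
                f"({self.durations.g1:.6g} h); the labeling window would "
                "truncate at age 0 and the labeled-fraction equation no "
                "longer inverts exactly"
            )
        if not 0 < self.detection_probability <= 1:
            raise DomainError(
                "detection_probability must lie in (0, 1], got "
                f"{self.detection_probability}"
            )


def sample_cell_ages(growth: GrowthModel, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` ages from the stationary age distribution on [0, T]."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return -np.log1p(-u / 2.0) / growth.growth_rate


def classify_phase(age: float, durations: PhaseDurations) -> str:
    """Phase label of a cell of the given age.

    Intervals are half-open [lo, hi) on the cumulative boundaries, so a
    zero-length phase is never reported; the final instant ``age == T``
    belongs to cytokinesis.
    """
    total = durations.total
    if not 0.0 <= age <= total:
        raise DomainError(f"age {age} outside [0, {total}]")
    bounds = [
        durations.g1,
        durations.g1 + durations.s,
        durations.g1 + durations.s + durations.g2,
        durations.g1 + durations.s + durations.g2 + durations.m,
    ]
    return _PHASE_LABELS[min(bisect_right(bounds, age), 4)]


def simulate_snapshot(config: SimulationConfig) -> PopulationSnapshot:
    """Simulate one pulse-labeling experiment and return its observables."""
    d = config.durations
    growth = GrowthModel(d.total)
    rng = np.random.default_rng(config.seed)
    u = rng.random(config.n_cells)
    ages = -np.log1p(-u / 2.0) / growth.growth_rate

    mc_start = d.g1 + d.s + d.g2
    c_start = mc_start + d.m
    f_c = float(np.mean(ages >= c_start))
    f_mc = float(np.mean(ages >= mc_start))

    labeled = (ages > d.g1 - config.pulse_duration) & (ages <= d.g1 + d.s)
    if config.detection_probability < 1.0:
        detected = rng.random(config.n_cells) < config.detection_probability
        labeled &= detected
    lab = float(np.mean(labeled))

    return PopulationSnapshot(
        frac_cytokinesis=f_c,
        frac_mitosis_plus_cyto=f_mc,
        frac_edu_labeled=lab,
        pulse_duration=config.pulse_duration,
        time_to_two_labeled_nuclei=d.g2 + d.m,
    )


def expected_fractions(
    durations: PhaseDurations, pulse_duration: float
) -> dict[str, float]:
    """Closed-form expectations of the simulated observables.

    A phase spanning ages [a_lo, a_hi) has stationary probability
    2*(e^{-alpha*a_lo} - e^{-alpha*a_hi}).
    """
    growth = GrowthModel(durations.total)
    alpha = growth.growth_rate
    total = durations.total

    def span(lo: float, hi: float) -> float:
        return 2.0 * (math.exp(-alpha * lo) - math.exp(-alpha * hi))

    mc_start = durations.g1 + durations.s + durations.g2
    lab_lo = durations.g1 - pulse_duration
    if lab_lo < 0:
        raise UnsupportedConfigurationError(
            "pulse_duration exceeds G1; no closed form for the labeled "
            "fraction in this regime"
        )
    return {
        "frac_cytokinesis": span(total - durations.c, total),
        "frac_mitosis_plus_cyto": span(mc_start, total),
        "frac_edu_labeled": span(lab_lo, durations.g1 + durations.s),
    }


def recovery_standard_errors(
    durations: PhaseDurations, pulse_duration: float, n_cells: int
) -> dict[str, float]:
    """Delta-method standard errors of each estimated phase at sample size n.

    The observed fractions (f_C, f_MC, L) are means of indicators over the
    same cells: f_C-cells are a subset of f_MC-cells, and labeled cells
    (ages <= G1+S) are disjoint from M+C cells (ages >= G1+S+G2).  The
    covariance of the estimated durations follows from the exact multinomial
    covariance of the indicators and a numerical Jacobian of the estimation
    pipeline.
    """
    exp = expected_fractions(durations, pulse_duration)
    p = np.array(
        [
            exp["frac_cytokinesis"],
            exp["frac_mitosis_plus_cyto"],
            exp["frac_edu_labeled"],
        ]
    )
    cov = np.empty((3, 3))
    for i in range(3):
        cov[i, i] = p[i] * (1 - p[i])
    cov[0, 1] = cov[1, 0] = p[0] * (1 - p[1])  # C nested in M+C
    cov[0, 2] = cov[2, 0] = -p[0] * p[2]  # disjoint
    cov[1, 2] = cov[2, 1] = -p[1] * p[2]  # disjoint
    cov /= n_cells

    growth = GrowthModel(durations.total)
    t_2n = durations.g2 + durations.m

    def pipeline(x: np.ndarray) -> np.ndarray:
        snap = PopulationSnapshot(
            frac_cytokinesis=float(x[0]),
            frac_mitosis_plus_cyto=float(x[1]),
            frac_edu_labeled=float(x[2]),
            pulse_duration=pulse_duration,
            time_to_two_labeled_nuclei=t_2n,
        )
        est = estimate_all(snap, growth)
        return np.array([est.g1, est.s, est.g2, est.m, est.c])

    jac = np.empty((5, 3))
    h = 1e-6
    for j in range(3):
        hi = p.copy()
        lo = p.copy()
        hi[j] += h
        lo[j] -= h
        jac[:, j] = (pipeline(hi) - pipeline(lo)) / (2 * h)

    variances = np.einsum("ij,jk,ik->i", jac, cov, jac)
    ses = np.sqrt(np.maximum(variances, 0.0))
    return dict(zip(("g1", "s", "g2", "m", "c"), ses.tolist()))
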