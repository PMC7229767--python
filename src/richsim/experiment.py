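"""Replicated sampling experiments over a grid of inventory effort.

Runs the two-phase Monte-Carlo study: sample virtual communities at each
effort level (days of inventory), with and without ultra-rare error species,
compute every requested richness estimator on every replicate, and summarize
per-cell medians.  Each (scenario, effort level, replicate) cell uses an
independent RNG child stream spawned from the master seed, so no sample is
recycled between effort levels and any run is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .community import (
    DEFAULT_SPEC,
    DistributionSpec,
    IncidenceMatrix,
    draw_abundance_profile,
    simulate_incidence,
    with_error_species,
)
from .errors import EstimatorDomainError, ParameterError
from . import estimators as _est
from .estimators import ESTIMATORS, tabulate_frequencies

__all__ = [
    "DEFAULT_EFFORT_LEVELS",
    "ExperimentDesign",
    "run_replicates",
    "summarize_medians",
    "frequency_histogram",
]

# Effort grid of the simulation study, in days.
DEFAULT_EFFORT_LEVELS = (
    5, 7, 10, 15, 20, 25, 50, 75, 100, 125, 150, 175, 200,
    300, 400, 500, 600, 700, 800, 900, 1000,
)

_SCENARIOS = ("error_free", "with_errors")

RAW_COLUMNS = [
    "scenario", "distribution", "effort_level", "replicate", "estimator",
    "S_obs", "Q1", "Q2", "Q3", "Q4", "estimate", "n_error_detected",
    "fallback_used",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Full specification of one replication study.

    Defaults reproduce the study conditions: 100 real species with
    log-normal mean abundances (mu=1.5, sigma=2.0), 10 error species a
    factor 1e-6 rarer, 100 replicates per effort level, and the 21-level
    effort grid from 5 to 1000 days.
    """

    scenario: Literal["error_free", "with_errors"] = "error_free"
    effort_levels: tuple[int, ...] = DEFAULT_EFFORT_LEVELS
    n_replicates: int = 100
    n_real: int = 100
    n_error: int = 10
    error_factor: float = 1e-6
    spec: DistributionSpec = field(default_factory=lambda: DEFAULT_SPEC)
    estimators: tuple[str, ...] = ESTIMATORS
    master_seed: int = 0
    community_mode: Literal["per_replicate", "shared"] = "per_replicate"
    sim_method: Literal["bernoulli", "poisson"] = "bernoulli"
    ice_threshold: int = 10

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        levels = tuple(int(t) for t in self.effort_levels)
        if not levels or any(b <= a for a, b in zip(levels, levels[1:])):
            raise ParameterError("effort levels must be non-empty and strictly increasing")
        if min(levels) < 1:
            raise ParameterError("effort levels must be >= 1 day")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if self.error_factor <= 0:
            raise ParameterError("error_factor must be > 0")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ParameterError(f"unknown estimators: {sorted(unknown)}")
        object.__setattr__(self, "effort_levels", levels)
        object.__setattr__(self, "estimators", tuple(self.estimators))

    def _profile(self, seq: np.random.SeedSequence):
        prof = draw_abundance_profile(self.spec, self.n_real, np.random.default_rng(seq))
        if self.scenario == "with_errors":
            prof = with_error_species(prof, self.n_error, self.error_factor)
        return prof


def _cell_seed(design: ExperimentDesign, level: int, replicate: int) -> np.random.SeedSequence:
    scenario_code = _SCENARIOS.index(design.scenario)
    return np.random.SeedSequence(
        entropy=design.master_seed, spawn_key=(scenario_code, level, replicate)
    )


def run_replicates(design: ExperimentDesign) -> pd.DataFrame:
    """Run the full grid and return one record per (level, replicate, estimator).

    Estimator domain errors (e.g. jackknife at T=1) are recorded as missing
    estimates, never aborts.  Fully reproducible from ``design.master_seed``.
    """
    shared_profile = None
    if design.community_mode == "shared":
        shared_profile = design._profile(
            np.random.SeedSequence(entropy=design.master_seed, spawn_key=(9, 0, 0))
        )
    dist_label = _distribution_label(design.spec)
    records: list[dict] = []
    for level in design.effort_levels:
        for rep in range(design.n_replicates):
            seq = _cell_seed(design, level, rep)
            prof_seq, sim_seq = seq.spawn(2)
            profile = shared_profile if shared_profile is not None else design._profile(prof_seq)
            matrix = simulate_incidence(
                profile, level, np.random.default_rng(sim_seq), method=design.sim_method
            )
            counts = tabulate_frequencies(matrix)
            n_err = matrix.n_error_detected()
            base = {
                "scenario": design.scenario,
                "distribution": dist_label,
                "effort_level": level,
                "replicate": rep,
                "S_obs": counts.S_obs,
                "Q1": counts.q(1),
                "Q2": counts.q(2),
                "Q3": counts.q(3),
                "Q4": counts.q(4),
                "n_error_detected": n_err,
            }
            for name in design.estimators:
                try:
                    if name == "ice":
                        res = _est.ice(matrix, infrequent_threshold=design.ice_threshold)
                    else:
                        res = getattr(_est, name)(counts)
                    est, fb = res.estimate, res.fallback_used
                except EstimatorDomainError:
                    est, fb = np.nan, False
                records.append({**base, "estimator": name, "estimate": est,
                                "fallback_used": fb})
    return pd.DataFrame.from_records(records, columns=RAW_COLUMNS)


def summarize_medians(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-(scenario, estimator, effort level) medians of the raw results.

    Missing estimates (domain errors) are excluded, with the count of valid
    replicates reported as ``n_ok``; an all-missing cell keeps a NaN median.
    Means are reported alongside but the median is the summary statistic.
    """
    if raw.empty:
        raise ParameterError("raw results table is empty")
    grouped = raw.groupby(["scenario", "estimator", "effort_level"], sort=True)
    summary = grouped.agg(
        n_ok=("estimate", "count"),
        median_estimate=("estimate", "median"),
        mean_estimate=("estimate", "mean"),
        median_Q1=("Q1", "median"),
        median_Q2=("Q2", "median"),
        frac_replicates_with_error_species=(
            "n_error_detected", lambda s: float((s >= 1).mean())
        ),
    ).reset_index()
    return summary


def frequency_histogram(matrix: IncidenceMatrix) -> dict[int, int]:
    """Detections-per-species histogram: k -> number of species seen in k units.

    Identical to the ``Q_k`` vector of the sample; exposed for inventory-style
    frequency plots.  Never-detected species are omitted.
    """
    return dict(tabulate_frequencies(matrix).Q)


def _distribution_label(spec: DistributionSpec) -> str:
    if spec.family == "lognormal":
        return f"lognormal(mu={spec.mu:g},sigma={spec.sigma:g})"
    return f"gamma(alpha={spec.alpha:g},beta={spec.beta:g})"
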