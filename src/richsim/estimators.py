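"""Nonparametric incidence-based species-richness estimators.

All estimators start from the incidence frequency counts of a reference
sample: ``T`` sampling units, ``S_obs`` observed species, and ``Q_k`` = the
number of species detected in exactly ``k`` units (``Q_1`` = uniques,
``Q_2`` = duplicates).  Each adds to ``S_obs`` an estimate of ``Q_0``, the
species present but never detected:

* ``chao2`` — classic lower-bound estimator
  ``S_obs + [(T-1)/T] * Q1^2 / (2 Q2)``, with the always-defined
  bias-corrected form ``Q1 (Q1-1) / (2 (Q2+1))`` when ``Q2 = 0``.
* ``ice`` — incidence coverage-based estimator: inflates the infrequent
  species count by the estimated sample coverage
  ``C = 1 - Q1 / N_infreq`` and a coefficient of variation term.
* ``jackknife1`` / ``jackknife2`` — first/second-order leave-one-unit-out
  bias reductions.
* ``chiu_chao`` — singleton-corrected Chao2: replaces the observed ``Q1``
  (inflatable by rare errors) with a Good–Turing prediction from
  ``Q2, Q3, Q4`` before applying the Chao2 formula.

Estimators see observed species only; all-zero rows are dropped when
frequencies are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import IncidenceMatrix
from .errors import EstimatorDomainError, FormatError

__all__ = [
    "FrequencyCounts",
    "RichnessEstimate",
    "tabulate_frequencies",
    "chao2",
    "ice",
    "jackknife1",
    "jackknife2",
    "chiu_chao",
    "ESTIMATORS",
    "compute_estimates",
]


@dataclass(frozen=True)
class FrequencyCounts:
    """Incidence frequency counts ``Q_1 .. Q_T`` of a reference sample.

    ``Q`` maps ``k`` to the number of species detected in exactly ``k``
    units; zero counts may be omitted.  Invariant: ``sum(Q_k) == S_obs``.
    """

    T: int
    S_obs: int
    Q: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.T < 1:
            raise EstimatorDomainError(f"T must be >= 1, got {self.T}")
        q = {int(k): int(v) for k, v in self.Q.items() if v != 0}
        for k, v in q.items():
            if k < 1 or k > self.T or v < 0:
                raise FormatError(f"invalid frequency count Q_{k} = {v} with T = {self.T}")
        if sum(q.values()) != self.S_obs:
            raise FormatError(
                f"sum of Q_k ({sum(q.values())}) must equal S_obs ({self.S_obs})"
            )
        object.__setattr__(self, "Q", q)

    def q(self, k: int) -> int:
        """``Q_k``, zero when absent."""
        return self.Q.get(k, 0)

    @property
    def total_incidences(self) -> int:
        """Total number of detections, ``sum k * Q_k``."""
        return sum(k * v for k, v in self.Q.items())


@dataclass(frozen=True)
class RichnessEstimate:
    """A point estimate of species richness with its intermediates.

    ``components`` exposes named intermediates (e.g. the undetected-species
    term, sample coverage, corrected singleton count); ``fallback_used``
    records whether a degenerate-case branch fired.
    """

    estimator: str
    estimate: float
    components: dict[str, float] = field(default_factory=dict)
    fallback_used: bool = False


def tabulate_frequencies(matrix: IncidenceMatrix) -> FrequencyCounts:
    """Count ``S_obs`` and ``Q_k`` from an incidence matrix.

    Rows with no detections are excluded from ``S_obs`` and every ``Q_k``.
    """
    sums = matrix.row_sums()
    observed = sums[sums > 0]
    counts = np.bincount(observed, minlength=matrix.T + 1)
    q = {int(k): int(counts[k]) for k in range(1, matrix.T + 1) if counts[k]}
    return FrequencyCounts(T=matrix.T, S_obs=int(observed.size), Q=q)


def chao2(counts: FrequencyCounts) -> RichnessEstimate:
    """Chao2 estimator; bias-corrected branch when there are no duplicates."""
    T, q1, q2 = counts.T, counts.q(1), counts.q(2)
    factor = (T - 1) / T
    if q2 > 0:
        q0 = factor * q1**2 / (2.0 * q2)
        fallback = False
    else:
        q0 = factor * q1 * (q1 - 1) / (2.0 * (q2 + 1))
        fallback = True
    return RichnessEstimate(
        "chao2", counts.S_obs + q0, {"q0_hat": q0}, fallback_used=fallback
    )


def jackknife1(counts: FrequencyCounts) -> RichnessEstimate:
    """First-order jackknife, ``S_obs + Q1 (T-1)/T``. Requires ``T >= 2``."""
    if counts.T < 2:
        raise EstimatorDomainError("jackknife1 requires at least 2 sampling units")
    q0 = counts.q(1) * (counts.T - 1) / counts.T
    return RichnessEstimate("jackknife1", counts.S_obs + q0, {"q0_hat": q0})


def jackknife2(counts: FrequencyCounts) -> RichnessEstimate:
    """Second-order jackknife. Requires ``T >= 3``; can fall below ``S_obs``."""
    T = counts.T
    if T < 3:
        raise EstimatorDomainError("jackknife2 requires at least 3 sampling units")
    q0 = counts.q(1) * (2 * T - 3) / T - counts.q(2) * (T - 2) ** 2 / (T * (T - 1))
    return RichnessEstimate("jackknife2", counts.S_obs + q0, {"q0_hat": q0})


def ice(matrix: IncidenceMatrix, infrequent_threshold: int = 10) -> RichnessEstimate:
    """Incidence coverage-based estimator (ICE).

    Species are split at ``infrequent_threshold`` incidences (default 10,
    the conventional cut).  With ``S_infreq`` infrequent species holding
    ``N_infreq`` incidences across ``T_infreq`` units, sample coverage is
    ``C = 1 - Q1/N_infreq`` and

        S_hat = S_freq + S_infreq / C + (Q1 / C) * gamma^2,

    where ``gamma^2`` is the squared coefficient of variation of incidence,
    ``max{(S_infreq/C) * (T_infreq/(T_infreq-1)) * sum k(k-1)Q_k / N_infreq^2 - 1, 0}``
    with the sum over infrequent ``k`` only.  When every infrequent species
    is a unique, coverage is zero and the estimator falls back to
    :func:`chao2` (flagged via ``fallback_used``).
    """
    if infrequent_threshold < 1:
        raise EstimatorDomainError("infrequent_threshold must be >= 1")
    sums = matrix.row_sums()
    obs_mask = sums > 0
    s_obs = int(obs_mask.sum())
    if s_obs == 0:
        return RichnessEstimate("ice", 0.0, {"C": float("nan")})
    infreq_mask = obs_mask & (sums <= infrequent_threshold)
    s_infreq = int(infreq_mask.sum())
    s_freq = s_obs - s_infreq
    if s_infreq == 0:
        return RichnessEstimate("ice", float(s_obs), {"C": 1.0, "gamma2": 0.0})
    n_infreq = int(sums[infreq_mask].sum())
    q1 = int((sums == 1).sum())  # uniques are always infrequent (threshold >= 1)
    coverage = 1.0 - q1 / n_infreq
    if coverage == 0.0:
        fb = chao2(tabulate_frequencies(matrix))
        return RichnessEstimate("ice", fb.estimate, dict(fb.components, C=0.0), True)
    # units holding at least one infrequent species; >= 2 whenever C > 0
    t_infreq = int(matrix.values[infreq_mask].any(axis=0).sum())
    ssq = int(np.sum(sums[infreq_mask] * (sums[infreq_mask] - 1)))
    gamma2 = max(
        (s_infreq / coverage) * (t_infreq / (t_infreq - 1)) * ssq / n_infreq**2 - 1.0,
        0.0,
    )
    est = s_freq + s_infreq / coverage + (q1 / coverage) * gamma2
    return RichnessEstimate(
        "ice",
        est,
        {
            "C": coverage,
            "gamma2": gamma2,
            "S_infreq": float(s_infreq),
            "N_infreq": float(n_infreq),
            "T_infreq": float(t_infreq),
        },
    )


def estimate_true_singletons(counts: FrequencyCounts) -> float:
    """Good–Turing prediction of the true unique count from ``Q2, Q3, Q4``.

    Rare errors inflate ``Q1`` but hardly ever recur, so ``Q2``–``Q4`` stay
    clean.  Pooling the Good–Turing detection-rate estimate over those
    classes, ``rate = (3 Q3 + 4 Q4) / (Q2 + Q3)``, and inverting
    ``E[2 Q2] / E[Q1] = rate`` gives

        Q1_hat = 2 Q2 (Q2 + Q3) / (3 Q3 + 4 Q4),

    which is exact when all species share one detection rate.  Undefined
    when ``Q3 = Q4 = 0`` (no information about the rate of rare species).
    """
    q2, q3, q4 = counts.q(2), counts.q(3), counts.q(4)
    denom = 3 * q3 + 4 * q4
    if denom == 0:
        raise EstimatorDomainError(
            "true-singleton estimate undefined when Q3 = Q4 = 0"
        )
    return 2.0 * q2 * (q2 + q3) / denom


def chiu_chao(counts: FrequencyCounts) -> RichnessEstimate:
    """Singleton-corrected Chao2 for error-prone incidence data.

    Spurious records show up as spurious *species*, inflating both the
    observed richness and the unique count.  The corrected estimator
    replaces the observed ``Q1`` with the :func:`estimate_true_singletons`
    prediction ``Q1_hat`` throughout:

        S_hat = (S_obs - Q1 + Q1_hat) + [(T-1)/T] * Q1_hat^2 / (2 Q2),

    i.e. the presumed-spurious uniques are removed from the observed count
    and the Chao2 correction is driven by the predicted true uniques.  The
    estimate can therefore fall below ``S_obs`` (and does, in error-free
    samples where ``Q1_hat`` underpredicts genuine uniques).  Outside the
    window of validity (``Q3 = Q4 = 0``) it returns the plain Chao2 estimate
    with ``fallback_used=True``.
    """
    if counts.q(3) == 0 and counts.q(4) == 0:
        base = chao2(counts)
        return RichnessEstimate(
            "chiu_chao", base.estimate, dict(base.components), fallback_used=True
        )
    q1_hat = estimate_true_singletons(counts)
    T, q2 = counts.T, counts.q(2)
    factor = (T - 1) / T
    if q2 > 0:
        q0 = factor * q1_hat**2 / (2.0 * q2)
    else:  # unreachable when Q3 or Q4 > 0 came from a real sample, kept for safety
        q0 = factor * q1_hat * (q1_hat - 1) / (2.0 * (q2 + 1))
    est = counts.S_obs - counts.q(1) + q1_hat + q0
    return RichnessEstimate("chiu_chao", est, {"q1_hat": q1_hat, "q0_hat": q0})


ESTIMATORS = ("chao2", "ice", "jackknife1", "jackknife2", "chiu_chao")


def compute_estimates(
    matrix: IncidenceMatrix,
    estimators: tuple[str, ...] = ESTIMATORS,
    ice_threshold: int = 10,
) -> list[RichnessEstimate]:
    """Run the named estimators on one incidence matrix.

    Frequency-count estimators share a single tabulation; ICE works from the
    matrix itself because its coverage terms need the unit layout.
    """
    counts = tabulate_frequencies(matrix)
    out: list[RichnessEstimate] = []
    for name in estimators:
        if name == "ice":
            out.append(ice(matrix, infrequent_threshold=ice_threshold))
        elif name == "chao2":
            out.append(chao2(counts))
        elif name == "jackknife1":
            out.append(jackknife1(counts))
        elif name == "jackknife2":
            out.append(jackknife2(counts))
        elif name == "chiu_chao":
            out.append(chiu_chao(counts))
        else:
            raise EstimatorDomainError(f"unknown estimator {name!r}")
    return out
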