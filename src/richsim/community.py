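"""Virtual communities and simulated incidence sampling.

A community is a set of species, each with a mean abundance per effort unit
(a day of inventory work).  Detections follow a Poisson mixed model: species
``i`` contributes ``X_ij ~ Poisson(lambda_i)`` individuals on day ``j`` and is
recorded present when ``X_ij >= 1``, so the per-day detection probability is
``p_i = 1 - exp(-lambda_i)``.  Mean abundances are drawn from a log-normal or
gamma distribution across species; "error" species — stand-ins for
misidentifications or bad georeferences — are added with mean abundances a
fixed factor (default one millionth) of the real-species mean, which makes
them essentially invisible until the sample becomes very large.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "DistributionSpec",
    "AbundanceProfile",
    "IncidenceMatrix",
    "draw_abundance_profile",
    "with_error_species",
    "detection_probability",
    "simulate_incidence",
]


@dataclass(frozen=True)
class DistributionSpec:
    """Cross-species distribution of mean abundances.

    Exactly one family's parameters are set: ``lognormal`` uses ``mu`` and
    ``sigma`` (mean and s.d. of the natural log of the mean abundance);
    ``gamma`` uses ``alpha`` (shape) and ``beta`` (scale).
    """

    family: Literal["lognormal", "gamma"]
    mu: float | None = None
    sigma: float | None = None
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.family == "lognormal":
            if self.mu is None or self.sigma is None:
                raise ParameterError("lognormal spec requires mu and sigma")
            if self.alpha is not None or self.beta is not None:
                raise ParameterError("lognormal spec must not set alpha/beta")
            if not self.sigma > 0:
                raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        elif self.family == "gamma":
            if self.alpha is None or self.beta is None:
                raise ParameterError("gamma spec requires alpha and beta")
            if self.mu is not None or self.sigma is not None:
                raise ParameterError("gamma spec must not set mu/sigma")
            if not (self.alpha > 0 and self.beta > 0):
                raise ParameterError("gamma shape and scale must be > 0")
        else:
            raise ParameterError(f"unknown family {self.family!r}")

    @classmethod
    def lognormal(cls, mu: float, sigma: float) -> "DistributionSpec":
        return cls(family="lognormal", mu=mu, sigma=sigma)

    @classmethod
    def gamma(cls, alpha: float, beta: float) -> "DistributionSpec":
        return cls(family="gamma", alpha=alpha, beta=beta)

    @property
    def theoretical_mean(self) -> float:
        """E[lambda] of the family: ``exp(mu + sigma^2/2)`` or ``alpha * beta``."""
        if self.family == "lognormal":
            return float(np.exp(self.mu + self.sigma**2 / 2.0))
        return float(self.alpha * self.beta)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "lognormal":
            return rng.lognormal(mean=self.mu, sigma=self.sigma, size=n)
        return rng.gamma(shape=self.alpha, scale=self.beta, size=n)


# Default community of the simulation study: log-normal mean abundances,
# mu = 1.5 and sigma = 2.0 on the log scale.
DEFAULT_SPEC = DistributionSpec.lognormal(1.5, 2.0)


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-species mean daily abundances with real/error labels."""

    lambdas: np.ndarray
    is_error: np.ndarray
    spec: DistributionSpec

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        err = np.asarray(self.is_error, dtype=bool)
        if lam.ndim != 1 or err.ndim != 1 or lam.shape != err.shape:
            raise ParameterError("lambdas and is_error must be 1-D and equal length")
        if np.any(lam < 0) or not np.all(np.isfinite(lam)):
            raise ParameterError("all mean abundances must be finite and >= 0")
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "is_error", err)

    @property
    def n_species(self) -> int:
        return self.lambdas.size

    @property
    def n_real(self) -> int:
        return int((~self.is_error).sum())

    @property
    def n_error(self) -> int:
        return int(self.is_error.sum())

    def species_ids(self) -> list[str]:
        """Stable ids: ``sp0001..`` for real species, ``err01..`` for error species."""
        ids, n_r, n_e = [], 0, 0
        for flag in self.is_error:
            if flag:
                n_e += 1
                ids.append(f"err{n_e:02d}")
            else:
                n_r += 1
                ids.append(f"sp{n_r:04d}")
        return ids


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary species-by-effort-unit detection table.

    Rows are species (including never-detected ones, kept as all-zero rows so
    the true community size is preserved); columns are effort units (days).
    ``T`` is the number of columns.
    """

    values: np.ndarray
    species_ids: Sequence[str]
    unit_ids: Sequence[str]
    is_error: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ParameterError("incidence values must be a 2-D matrix")
        if not np.isin(vals, (0, 1)).all():
            raise ParameterError("incidence matrix must be binary (0/1)")
        if vals.shape[1] < 1:
            raise ParameterError("incidence matrix needs at least one effort unit")
        if len(self.species_ids) != vals.shape[0]:
            raise ParameterError("species_ids length must match row count")
        if len(self.unit_ids) != vals.shape[1]:
            raise ParameterError("unit_ids length must match column count")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ParameterError("species ids must be unique")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ParameterError("unit ids must be unique")
        object.__setattr__(self, "values", vals.astype(np.uint8))
        object.__setattr__(self, "species_ids", list(self.species_ids))
        object.__setattr__(self, "unit_ids", list(self.unit_ids))
        if self.is_error is not None:
            err = np.asarray(self.is_error, dtype=bool)
            if err.shape != (vals.shape[0],):
                raise ParameterError("is_error must have one flag per species row")
            object.__setattr__(self, "is_error", err)

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    def row_sums(self) -> np.ndarray:
        """Incidence (number of units with a detection) per species."""
        return self.values.sum(axis=1).astype(int)

    def observed(self) -> "IncidenceMatrix":
        """Submatrix of species with at least one detection."""
        mask = self.values.any(axis=1)
        return IncidenceMatrix(
            self.values[mask],
            [s for s, m in zip(self.species_ids, mask) if m],
            self.unit_ids,
            None if self.is_error is None else self.is_error[mask],
        )

    def n_error_detected(self) -> int:
        """Number of error-flagged species with at least one detection (0 if unlabeled)."""
        if self.is_error is None:
            return 0
        return int((self.values.any(axis=1) & self.is_error).sum())


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_abundance_profile(
    spec: DistributionSpec,
    n_species: int,
    rng_seed: int | np.random.Generator | np.random.SeedSequence,
) -> AbundanceProfile:
    """Draw ``n_species`` real-species mean abundances from ``spec``.

    Reproducible for a fixed integer seed; all species are flagged real.
    """
    if n_species < 0:
        raise ParameterError(f"n_species must be >= 0, got {n_species}")
    rng = _as_rng(rng_seed)
    lam = spec.draw(int(n_species), rng)
    return AbundanceProfile(lam, np.zeros(int(n_species), dtype=bool), spec)


def with_error_species(
    profile: AbundanceProfile,
    n_error: int,
    magnitude_factor: float,
    reference: Literal["theoretical", "realized"] = "theoretical",
) -> AbundanceProfile:
    """Append ``n_error`` error species at a fixed fraction of the real-species mean.

    Each error species gets the same mean abundance
    ``magnitude_factor * m`` where ``m`` is the theoretical mean of the
    generating distribution (default) or, with ``reference="realized"``, the
    realized mean of this profile's real species.  The default keeps the error
    rate identical across replicates.
    """
    if magnitude_factor <= 0:
        raise ParameterError(f"magnitude_factor must be > 0, got {magnitude_factor}")
    if n_error < 0:
        raise ParameterError(f"n_error must be >= 0, got {n_error}")
    if profile.n_error:
        raise ParameterError("profile already contains error species")
    if n_error == 0:
        return profile
    if reference == "theoretical":
        base = profile.spec.theoretical_mean
    elif reference == "realized":
        if profile.n_real == 0:
            raise ParameterError("realized reference needs at least one real species")
        base = float(profile.lambdas[~profile.is_error].mean())
    else:
        raise ParameterError(f"unknown reference {reference!r}")
    err_lambda = magnitude_factor * base
    lam = np.concatenate([profile.lambdas, np.full(n_error, err_lambda)])
    flags = np.concatenate([profile.is_error, np.ones(n_error, dtype=bool)])
    return replace(profile, lambdas=lam, is_error=flags)


def detection_probability(lam: float | np.ndarray) -> float | np.ndarray:
    """Per-unit detection probability ``P[Poisson(lambda) >= 1] = 1 - exp(-lambda)``."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ParameterError("mean abundance must be >= 0")
    out = -np.expm1(-lam_arr)
    return float(out) if np.isscalar(lam) or lam_arr.ndim == 0 else out


def simulate_incidence(
    profile: AbundanceProfile,
    n_days: int,
    rng_seed: int | np.random.Generator | np.random.SeedSequence,
    method: Literal["bernoulli", "poisson"] = "bernoulli",
) -> IncidenceMatrix:
    """Simulate a binary species-by-day incidence matrix from ``profile``.

    Cells are independent.  ``method="poisson"`` draws a daily abundance per
    cell and thresholds it at 1; ``method="bernoulli"`` draws the indicator
    directly with p = 1 - exp(-lambda).  The two are distributionally
    identical; the Bernoulli path is the fast default.  Never-detected species
    are kept as all-zero rows.
    """
    if n_days < 1:
        raise ParameterError(f"n_days must be >= 1, got {n_days}")
    rng = _as_rng(rng_seed)
    shape = (profile.n_species, int(n_days))
    if method == "bernoulli":
        p = detection_probability(profile.lambdas)
        cells = rng.random(shape) < np.asarray(p).reshape(-1, 1)
    elif method == "poisson":
        counts = rng.poisson(lam=profile.lambdas.reshape(-1, 1), size=shape)
        cells = counts >= 1
    else:
        raise ParameterError(f"unknown simulation method {method!r}")
    units = [f"day{j + 1:04d}" for j in range(int(n_days))]
    return IncidenceMatrix(
        cells.astype(np.uint8), profile.species_ids(), units, profile.is_error.copy()
    )
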