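"""Gamma prior specifications for the rate precision parameter.

Eight recipes map the GLM scale statistics to the shape and rate of the
gamma prior on the precision of each lattice cell's rate, differing in
which statistic is used and how it is grouped (by education, by age and
education, or pooled).  ``G(a, b)`` is parameterized as shape ``a`` and
rate ``b`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import PriorStatistics

SPEC_NAMES = (
    "final",
    "model1",
    "model2",
    "model3",
    "model4",
    "model5",
    "model6",
    "model7",
)


class PriorSpecError(ValueError):
    """A statistic required by a spec is zero or negative."""


@dataclass(frozen=True)
class PriorSpec:
    """Instantiated gamma prior for the rate precision.

    ``shape`` and ``rate`` are (A, E) arrays broadcast over countries and
    periods; ``grouping`` records how the underlying statistic was pooled.
    """

    name: str
    shape: np.ndarray  # (A, E)
    rate: np.ndarray  # (A, E)
    grouping: str

    def __post_init__(self):
        if not (np.all(self.shape > 0) and np.all(self.rate > 0)):
            raise PriorSpecError(
                f"prior spec {self.name!r}: shape and rate must be positive"
            )

    @property
    def prior_mean(self) -> np.ndarray:
        """Prior mean of the precision, shape/rate."""
        return self.shape / self.rate


def _check(name: str, statistic: str, value) -> None:
    if not np.all(np.asarray(value) > 0):
        raise PriorSpecError(
            f"prior spec {name!r}: statistic {statistic!r} must be strictly "
            f"positive, got {value!r}"
        )


def make_prior_spec(name: str, stats: PriorStatistics, n_ages: int = 7) -> PriorSpec:
    """Instantiate one named prior recipe from the GLM scale statistics."""
    E = len(stats.sigma_e)
    A = n_ages
    ones = np.ones((A, E))

    def by_e(vec):
        return np.broadcast_to(np.asarray(vec)[None, :], (A, E)).copy()

    if name == "final":
        _check(name, "sigma_e", stats.sigma_e)
        return PriorSpec(name, by_e(1.0 / stats.sigma_e), by_e(2.0 * stats.sigma_e), "education")
    if name == "model1":
        _check(name, "var_mean_ratio", stats.var_mean_ratio)
        _check(name, "sigma2_pooled", stats.sigma2_pooled)
        # moment-matched to the SE distribution: alpha = mean^2/var, beta = mean/var
        mean = stats.sigma2_pooled / stats.var_mean_ratio
        alpha = mean / stats.var_mean_ratio
        beta = 1.0 / stats.var_mean_ratio
        return PriorSpec(name, alpha * ones, beta * ones, "pooled")
    if name == "model2":
        _check(name, "mu_e", stats.mu_e)
        _check(name, "sigma2_e", stats.sigma2_e)
        return PriorSpec(name, by_e(1.0 / stats.mu_e), by_e(stats.sigma2_e), "education")
    if name == "model3":
        _check(name, "sigma2_e", stats.sigma2_e)
        return PriorSpec(name, by_e(1.0 / stats.sigma2_e), by_e(stats.sigma2_e), "education")
    if name == "model4":
        _check(name, "sigma2_pooled", stats.sigma2_pooled)
        return PriorSpec(
            name, ones / stats.sigma2_pooled, ones * stats.sigma2_pooled, "pooled"
        )
    if name == "model5":
        _check(name, "sigma2_est", stats.sigma2_est)
        sigma_est = float(np.sqrt(stats.sigma2_est))
        return PriorSpec(name, ones / sigma_est, ones * stats.sigma2_est, "pooled")
    if name == "model6":
        _check(name, "sigma_ae", stats.sigma_ae)
        sae = np.asarray(stats.sigma_ae)
        if sae.shape != (A, E):
            raise PriorSpecError(
                f"prior spec 'model6': sigma_ae shape {sae.shape} != ({A}, {E})"
            )
        return PriorSpec(name, 1.0 / sae, sae.copy(), "age-education")
    if name == "model7":
        _check(name, "sigma_e", stats.sigma_e)
        return PriorSpec(name, by_e(1.0 / stats.sigma_e), by_e(stats.sigma_e), "education")
    raise ValueError(f"unknown prior spec name {name!r}; choose from {SPEC_NAMES}")


def enumerate_prior_specs(stats: PriorStatistics, n_ages: int = 7) -> list:
    """All eight prior specifications, final model first."""
    return [make_prior_spec(name, stats, n_ages) for name in SPEC_NAMES]
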