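"""Synthetic worlds: ground-truth fertility surfaces and emulated inputs.

A "world" is a known education- and age-specific fertility surface plus
the four input streams the estimation pipeline consumes:

* survey observations (DHS-like: partial age schedules, Poisson
  sampling noise, a 30-year recall window per survey wave),
* a benchmark ASFR schedule (UN-WPP-like: the weighted aggregate of the
  truth, optionally perturbed),
* education composition weights (WIC-like: shares summing to one within
  each country-period-age cell, expanding education over time),
* previously published education-specific TFRs for sub-Saharan African
  countries.

True age schedules follow a scaled gamma-density curve over age-group
midpoints: smooth, strictly positive and hump-shaped, with an
education-specific level multiplier and peak-age shift (postponement)
and a log-linear decline across periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import (
    AGE_MIDPOINTS,
    DEFAULT_PERIODS,
    EDUCATION_LEVELS,
    REGIONS,
    AlignmentError,
    Lattice,
    period_start,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A WorldConfig field is invalid; the message names the field."""


#: Region-specific scale of the no-education total fertility rate in the
#: first period (births per woman).  Magnitudes follow the broad regional
#: ordering of historical fertility levels.
DEFAULT_BASE_LEVEL = {
    "sub-Saharan Africa": 7.0,
    "North Africa": 6.5,
    "West Asia": 6.0,
    "Europe": 3.0,
    "Central Asia": 5.0,
    "South & Southeast Asia": 6.0,
    "Latin America": 5.5,
}

#: Multiplicative fertility level by education (No/Primary/Secondary/Higher).
DEFAULT_EDUCATION_GRADIENT = (1.0, 0.92, 0.65, 0.45)

#: Peak-age shift per education in years (postponement with education).
DEFAULT_POSTPONEMENT_SHIFT = (0.0, 0.5, 2.0, 4.0)

#: Education composition at the first and last period (shares of women in
#: No/Primary/Secondary/Higher education); linear expansion in between.
DEFAULT_WEIGHT_START = (0.55, 0.30, 0.12, 0.03)
DEFAULT_WEIGHT_END = (0.10, 0.22, 0.45, 0.23)


def _default_countries():
    regions = (
        "sub-Saharan Africa",
        "sub-Saharan Africa",
        "North Africa",
        "South & Southeast Asia",
        "Latin America",
        "Europe",
    )
    names = (
        "Country A",
        "Country B",
        "Country C",
        "Country D",
        "Country E",
        "Country F",
    )
    return dict(zip(names, regions))


def _default_survey_years(countries):
    # three waves per country, staggered so overlapping periods are
    # observed by more than one survey
    base = [1992, 2003, 2014]
    out = {}
    for i, c in enumerate(countries):
        out[c] = [y + (i % 3) for y in base]
    return out


@dataclass(frozen=True)
class WorldConfig:
    """Generative settings of a synthetic world.

    Defaults describe a desk-scale world of 6 countries across 4 regions
    (2 sub-Saharan African), 10 five-year periods, 7 age groups and the 4
    DHS attainment categories — 1,680 lattice cells.
    """

    region_assignment: dict = field(default_factory=_default_countries)
    periods: tuple = DEFAULT_PERIODS
    age_groups: tuple = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")
    education_levels: tuple = EDUCATION_LEVELS
    base_level: dict = field(default_factory=lambda: dict(DEFAULT_BASE_LEVEL))
    education_gradient: tuple = DEFAULT_EDUCATION_GRADIENT
    decline_rate: float = 0.06
    postponement_shift: tuple = DEFAULT_POSTPONEMENT_SHIFT
    peak_age: float = 26.0
    schedule_shape: float = 6.0
    weight_start_shares: tuple = DEFAULT_WEIGHT_START
    weight_end_shares: tuple = DEFAULT_WEIGHT_END
    survey_years: dict | None = None
    recall_window: int = 30
    exposure_scale: float = 600.0
    min_exposure: float = 5.0
    benchmark_noise_sd: float = 0.0
    prev_etfr_noise_sd: float = 0.05
    seed: int = 0

    @property
    def n_countries(self) -> int:
        return len(self.region_assignment)

    def validate(self) -> None:
        if not self.region_assignment:
            raise ConfigurationError("region_assignment: no countries configured")
        for c, r in self.region_assignment.items():
            if r not in REGIONS:
                raise ConfigurationError(
                    f"region_assignment: {c!r} -> {r!r} is not one of the 7 regions"
                )
        if len(self.education_levels) != len(self.education_gradient):
            raise ConfigurationError(
                "education_gradient: needs one entry per education level"
            )
        if len(self.postponement_shift) != len(self.education_levels):
            raise ConfigurationError(
                "postponement_shift: needs one entry per education level"
            )
        for name in ("decline_rate",):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be non-negative")
        for name in ("exposure_scale", "peak_age", "schedule_shape"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}: must be strictly positive")
        if any(g <= 0 for g in self.education_gradient):
            raise ConfigurationError("education_gradient: entries must be positive")
        for r in set(self.region_assignment.values()):
            if self.base_level.get(r, 0) <= 0:
                raise ConfigurationError(f"base_level: missing or non-positive for {r!r}")
        for p in self.periods:
            period_start(p)
        if self.benchmark_noise_sd < 0 or self.prev_etfr_noise_sd < 0:
            raise ConfigurationError("noise sd fields must be non-negative")

    def lattice(self) -> Lattice:
        return Lattice(
            countries=tuple(self.region_assignment),
            regions=dict(self.region_assignment),
            periods=tuple(self.periods),
            age_groups=tuple(self.age_groups),
            education_levels=tuple(self.education_levels),
        )

    def resolved_survey_years(self) -> dict:
        if self.survey_years is not None:
            return self.survey_years
        return _default_survey_years(tuple(self.region_assignment))


@dataclass
class SyntheticWorld:
    """A generated world: the truth plus all emulated input streams."""

    truth: np.ndarray  # (C, Y, A, E) EAFR, births/woman/yr
    weights: np.ndarray  # (C, Y, A, E), sums to 1 over E
    benchmark: pd.DataFrame  # Country, Year, Age Group, Value
    surveys: pd.DataFrame  # long survey observations
    prev_etfr: pd.DataFrame  # Country, Year, Education, Value (SSA only)
    config: WorldConfig

    @property
    def lattice(self) -> Lattice:
        return self.config.lattice()

    def true_etfr(self) -> np.ndarray:
        """(C, Y, E) education-specific TFR implied by the truth."""
        return 5.0 * self.truth.sum(axis=2)

    def true_asfr(self) -> np.ndarray:
        """(C, Y, A) weight-aggregated ASFR implied by the truth."""
        return (self.truth * self.weights).sum(axis=3)

    def write_csvs(self, outdir) -> dict:
        """Write all streams (and the truth) as long-format CSVs."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lat = self.lattice
        paths = {
            "truth": outdir / "truth_eafr.csv",
            "weights": outdir / "weights.csv",
            "benchmark": outdir / "benchmark_asfr.csv",
            "surveys": outdir / "survey_eafr.csv",
            "prev_etfr": outdir / "prev_etfr_ssa.csv",
        }
        lat.frame(self.truth).to_csv(paths["truth"], index=False)
        lat.frame(self.weights).to_csv(paths["weights"], index=False)
        self.benchmark.to_csv(paths["benchmark"], index=False)
        self.surveys.to_csv(paths["surveys"], index=False)
        self.prev_etfr.to_csv(paths["prev_etfr"], index=False)
        return paths


# ---- generators ---------------------------------------------------------


def _schedule(peak_age: float, shape: float) -> np.ndarray:
    """Normalized hump-shaped weights over the 7 age-group midpoints.

    Gamma density with its mode at ``peak_age``, supported above age 10;
    normalized to sum to 1 so that 5 x sum(rates) equals the target ETFR.
    """
    loc = 10.0
    scale = (peak_age - loc) / (shape - 1.0)
    dens = stats.gamma.pdf(AGE_MIDPOINTS, a=shape, loc=loc, scale=scale)
    return dens / dens.sum()


def generate_true_schedules(config: WorldConfig) -> np.ndarray:
    """Ground-truth EAFR lattice (C, Y, A, E) implied by the config."""
    config.validate()
    lat = config.lattice()
    C, Y, A, E = lat.shape
    out = np.empty((C, Y, A, E))
    for ci, c in enumerate(lat.countries):
        level0 = config.base_level[config.region_assignment[c]]
        for ei in range(E):
            sched = _schedule(
                config.peak_age + config.postponement_shift[ei], config.schedule_shape
            )
            for yi in range(Y):
                etfr = (
                    level0
                    * config.education_gradient[ei]
                    * np.exp(-config.decline_rate * yi)
                )
                out[ci, yi, :, ei] = etfr / 5.0 * sched
    return out


def generate_weights(config: WorldConfig) -> np.ndarray:
    """Education composition weights (C, Y, A, E), summing to 1 over E.

    Shares interpolate linearly from the start to the end composition
    across periods (education expansion); the highest education level has
    zero weight at ages 15-19, after which the cell is renormalized.
    """
    config.validate()
    lat = config.lattice()
    C, Y, A, E = lat.shape
    if E == 1:
        return np.ones((C, Y, A, E))
    start = np.asarray(config.weight_start_shares[:E], dtype=float)
    end = np.asarray(config.weight_end_shares[:E], dtype=float)
    start = start / start.sum()
    end = end / end.sum()
    t = np.linspace(0.0, 1.0, Y)[:, None]  # (Y, 1)
    shares = (1 - t) * start[None, :] + t * end[None, :]  # (Y, E)
    w = np.broadcast_to(shares[None, :, None, :], (C, Y, A, E)).copy()
    # nobody has completed higher education in the 15-19 age group
    if E == len(EDUCATION_LEVELS):
        w[:, :, 0, -1] = 0.0
    w /= w.sum(axis=3, keepdims=True)
    return w


def generate_benchmark(
    truth: np.ndarray,
    weights: np.ndarray,
    noise_sd: float,
    seed: int,
    lattice: Lattice,
) -> pd.DataFrame:
    """Emulated UN-style benchmark ASFR: the weighted truth plus noise.

    Noise is normal with sd ``noise_sd``, redrawn where it would make a
    rate non-positive, so benchmark consistency with the weighted truth
    holds exactly when ``noise_sd`` is 0.
    """
    truth = np.asarray(truth)
    weights = np.asarray(weights)
    if truth.shape != weights.shape:
        raise AlignmentError(
            f"truth shape {truth.shape} != weights shape {weights.shape}"
        )
    if truth.shape != lattice.shape:
        raise AlignmentError(f"lattice {lattice.shape} != arrays {truth.shape}")
    asfr = (truth * weights).sum(axis=3)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = asfr + rng.normal(0.0, noise_sd, size=asfr.shape)
        for _ in range(100):
            bad = noisy <= 0
            if not bad.any():
                break
            noisy[bad] = asfr[bad] + rng.normal(0.0, noise_sd, size=int(bad.sum()))
        asfr = noisy
    return lattice.marginal_frame(asfr, ("country", "period", "age_group"))


def generate_surveys(truth: np.ndarray, config: WorldConfig) -> pd.DataFrame:
    """DHS-like survey observations with Poisson birth counts.

    Each survey wave observes the periods inside its recall window; the
    person-years of exposure in a cell scale with the education share of
    the population, so rare education-age combinations yield sparse or
    missing observations (the partial schedules the GLM must complete).
    """
    config.validate()
    lat = config.lattice()
    weights = generate_weights(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    survey_years = config.resolved_survey_years()
    rows = []
    for ci, c in enumerate(lat.countries):
        years = survey_years.get(c, [])
        if not years:
            logger.warning("country %s has no survey waves; contributes no rows", c)
            continue
        for sy in years:
            for yi, p in enumerate(lat.periods):
                p0 = period_start(p)
                if p0 < sy - config.recall_window or p0 >= sy:
                    continue
                for ai, a in enumerate(lat.age_groups):
                    for ei, e in enumerate(lat.education_levels):
                        exposure = config.exposure_scale * weights[ci, yi, ai, ei]
                        if exposure < config.min_exposure:
                            continue  # too few women to tabulate
                        births = rng.poisson(exposure * truth[ci, yi, ai, ei])
                        rows.append(
                            (
                                c,
                                lat.regions[c],
                                p,
                                a,
                                e,
                                births / exposure,
                                int(births),
                                exposure,
                                sy,
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "Country",
            "Region",
            "Year",
            "Age Group",
            "Education",
            "Value",
            "Births",
            "Exposure",
            "SurveyYear",
        ],
    )


def generate_prev_etfr(
    truth: np.ndarray,
    ssa_countries: list,
    noise_sd: float,
    seed: int,
    lattice: Lattice,
) -> pd.DataFrame:
    """Previously published SSA education-specific TFRs: 5 x age sums + noise."""
    allowed = set(lattice.ssa_countries())
    bad = [c for c in ssa_countries if c not in allowed]
    if bad:
        raise ValueError(
            f"countries {bad} are not configured as sub-Saharan Africa"
        )
    rng = np.random.default_rng(seed)
    cidx = lattice.axis_index("country")
    rows = []
    for c in ssa_countries:
        ci = cidx[c]
        for yi, p in enumerate(lattice.periods):
            for ei, e in enumerate(lattice.education_levels):
                etfr = 5.0 * truth[ci, yi, :, ei].sum()
                if noise_sd > 0:
                    val = etfr + rng.normal(0.0, noise_sd)
                    while val <= 0:
                        val = etfr + rng.normal(0.0, noise_sd)
                else:
                    val = etfr
                rows.append((c, p, e, val))
    return pd.DataFrame(rows, columns=["Country", "Year", "Education", "Value"])


def generate_world(config: WorldConfig | None = None, **overrides) -> SyntheticWorld:
    """Generate a complete synthetic world from a config (or the defaults)."""
    if config is None:
        config = WorldConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    lat = config.lattice()
    truth = generate_true_schedules(config)
    weights = generate_weights(config)
    seeds = np.random.SeedSequence([config.seed, 23]).generate_state(2)
    benchmark = generate_benchmark(
        truth, weights, config.benchmark_noise_sd, int(seeds[0]) % (2**31), lat
    )
    surveys = generate_surveys(truth, config)
    prev = generate_prev_etfr(
        truth,
        list(lat.ssa_countries()),
        config.prev_etfr_noise_sd,
        int(seeds[1]) % (2**31),
        lat,
    )
    return SyntheticWorld(
        truth=truth,
        weights=weights,
        benchmark=benchmark,
        surveys=surveys,
        prev_etfr=prev,
        config=config,
    )
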