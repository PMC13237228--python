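"""Holdout validation of the benchmark constraint.

Because the model is benchmarked to an authoritative age-specific
fertility schedule, its out-of-sample behaviour is assessed by deleting
benchmark values — either a random fraction of all (country, period,
age) cells or every cell of named countries — refitting, and counting
how many deleted values fall inside the central 50/80/90% credible
intervals of the corresponding aggregated-rate posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import EAFRModel, ModelInputs, PosteriorDraws

DEFAULT_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.30)
DEFAULT_LEVELS = (0.50, 0.80, 0.90)


@dataclass(frozen=True)
class HoldoutPlan:
    """Which benchmark cells are withheld from the refit."""

    kind: str  # "random_fraction" | "countries"
    held_out_keys: tuple  # of (country, period, age_group)
    seed: int = 0
    fraction: float | None = None
    countries: tuple | None = None

    @property
    def label(self) -> str:
        if self.kind == "random_fraction":
            return f"{self.fraction:.0%} omitted"
        return "omit " + ", ".join(self.countries)


@dataclass
class CoverageReport:
    """Fractions of held-out benchmark values inside central intervals."""

    plan_label: str
    levels: tuple
    covered: dict = field(default_factory=dict)  # level -> int
    total: int = 0

    def fraction(self, level: float) -> float:
        return self.covered[level] / self.total if self.total else np.nan

    def row(self) -> dict:
        out = {"Plan": self.plan_label, "Total": self.total}
        for lv in self.levels:
            out[f"{lv:.0%} CI"] = self.fraction(lv)
        return out

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "Plan": self.plan_label,
                "Level": lv,
                "Covered": self.covered[lv],
                "Total": self.total,
                "Fraction": self.fraction(lv),
            }
            for lv in self.levels
        ]
        return pd.DataFrame(rows)


def make_holdout(
    inputs: ModelInputs,
    kind: str = "random_fraction",
    fraction: float | None = None,
    countries=None,
    seed: int = 0,
) -> tuple:
    """Build a holdout plan and the reduced-benchmark model inputs.

    Random holdouts sample observed benchmark cells uniformly without
    stratification; country holdouts remove every benchmark cell of the
    named countries.
    """
    lat = inputs.lattice
    bench = inputs.benchmark.copy()
    obs = np.argwhere(np.isfinite(bench))
    if kind == "random_fraction":
        if fraction is None or not (0.0 < fraction < 1.0):
            raise ValueError(f"fraction must be in (0, 1), got {fraction}")
        rng = np.random.default_rng(seed)
        n_hold = int(round(fraction * len(obs)))
        take = rng.choice(len(obs), size=n_hold, replace=False)
        held = obs[np.sort(take)]
    elif kind == "countries":
        if not countries:
            raise ValueError("countries kind needs a non-empty country list")
        cidx = lat.axis_index("country")
        unknown = [c for c in countries if c not in cidx]
        if unknown:
            raise ValueError(f"unknown countries {unknown}")
        wanted = {cidx[c] for c in countries}
        held = obs[np.isin(obs[:, 0], list(wanted))]
    else:
        raise ValueError(f"unknown holdout kind {kind!r}")

    keys = tuple(
        (lat.countries[c], lat.periods[y], lat.age_groups[a]) for c, y, a in held
    )
    bench[tuple(held.T)] = np.nan
    reduced = ModelInputs(
        lattice=lat,
        init_mean=inputs.init_mean,
        weights=inputs.weights,
        benchmark=bench,
        prior_stats=inputs.prior_stats,
        prior_spec=inputs.prior_spec,
        prev_etfr=inputs.prev_etfr,
        tau_asfr=inputs.tau_asfr,
        etfr_bounds=inputs.etfr_bounds,
    )
    plan = HoldoutPlan(
        kind=kind,
        held_out_keys=keys,
        seed=seed,
        fraction=fraction,
        countries=tuple(countries) if countries else None,
    )
    return plan, reduced


def coverage(
    draws: PosteriorDraws,
    held_out: dict | pd.DataFrame,
    levels=DEFAULT_LEVELS,
    label: str = "",
) -> CoverageReport:
    """Count held-out benchmark values inside central posterior intervals.

    ``held_out`` maps (country, period, age_group) keys to benchmark
    values (or is a long DataFrame with those columns plus Value).
    """
    lat = draws.lattice
    if isinstance(held_out, pd.DataFrame):
        held_out = {
            (r["Country"], r["Year"], r["Age Group"]): r["Value"]
            for _, r in held_out.iterrows()
        }
    cidx = lat.axis_index("country")
    yidx = lat.axis_index("period")
    aidx = lat.axis_index("age_group")
    missing = [k for k in held_out if k[0] not in cidx or k[1] not in yidx or k[2] not in aidx]
    if missing:
        raise KeyError(f"held-out keys not on the posterior lattice: {missing}")
    asfr = draws.flat(draws.asfr)  # (S, C, Y, A)
    report = CoverageReport(plan_label=label, levels=tuple(levels), total=len(held_out))
    for lv in levels:
        alpha = (1.0 - lv) / 2.0
        n_in = 0
        for (c, y, a), val in held_out.items():
            cell = asfr[:, cidx[c], yidx[y], aidx[a]]
            lo, hi = np.quantile(cell, [alpha, 1.0 - alpha])
            n_in += int(lo <= val <= hi)
        report.covered[lv] = n_in
    return report


def run_validation_suite(
    inputs: ModelInputs,
    plans: list | None = None,
    levels=DEFAULT_LEVELS,
    seed: int = 0,
    fractions=DEFAULT_FRACTIONS,
    countries=None,
    per_country: bool = True,
    **mcmc_params,
) -> tuple:
    """Refit under each holdout plan and tabulate interval coverage.

    Without an explicit plan list, builds the default fraction ladder
    (and, if ``countries`` is given, one all-cells-of-country plan per
    name).  Returns ``(table, reports)`` where the table has one row per
    plan and one column per interval level.  Country plans additionally
    report coverage restricted to the omitted country's own cells when
    ``per_country`` is set.
    """
    lat = inputs.lattice
    specs = []
    if plans is None:
        for i, f in enumerate(fractions):
            specs.append(dict(kind="random_fraction", fraction=f, seed=seed + i))
        for j, c in enumerate(countries or ()):
            specs.append(dict(kind="countries", countries=[c], seed=seed + 1000 + j))
    else:
        specs = plans

    bench = inputs.benchmark
    reports = []
    rows = []
    for i, sp in enumerate(specs):
        plan, reduced = make_holdout(inputs, **sp)
        held_vals = {
            k: bench[
                lat.axis_index("country")[k[0]],
                lat.axis_index("period")[k[1]],
                lat.axis_index("age_group")[k[2]],
            ]
            for k in plan.held_out_keys
        }
        model = EAFRModel(random_state=seed + 7919 * (i + 1), **mcmc_params)
        model.fit(reduced)
        rep = coverage(model.draws_, held_vals, levels, label=plan.label)
        reports.append(rep)
        row = rep.row()
        row["MaxRhat"] = model.rhat_max_
        rows.append(row)
        if plan.kind == "countries" and per_country:
            for c in plan.countries:
                sub = {k: v for k, v in held_vals.items() if k[0] == c}
                sub_rep = coverage(
                    model.draws_, sub, levels, label=f"{plan.label} ({c} cells only)"
                )
                reports.append(sub_rep)
                rows.append({**sub_rep.row(), "MaxRhat": model.rhat_max_})
    return pd.DataFrame(rows), reports


def compare_alt_benchmark(
    draws: PosteriorDraws,
    alt_benchmark: pd.DataFrame,
    levels=(0.50, 0.80, 0.90, 0.95),
) -> CoverageReport:
    """Fraction of an alternative benchmark inside the posterior intervals.

    Same computation as :func:`coverage`, applied to a complete
    alternative schedule (e.g. a newer revision of the benchmark series)
    rather than held-out rows, and including the 95% level.
    """
    held = {
        (r["Country"], r["Year"], r["Age Group"]): r["Value"]
        for _, r in alt_benchmark.iterrows()
    }
    return coverage(draws, held, levels=levels, label="alternative benchmark")
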