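"""Core lattice types, long-format CSV I/O and validation.

Every quantity in the package lives on (a margin of) the rectangular
country x period x age-group x education lattice.  Rates are stored as
dense numpy arrays with axes in that order; long-format pandas tables
are the interchange format on disk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven UN regions used for joint estimation.
REGIONS = (
    "sub-Saharan Africa",
    "North Africa",
    "West Asia",
    "Europe",
    "Central Asia",
    "South & Southeast Asia",
    "Latin America",
)

#: Five-year reproductive age groups.
AGE_GROUPS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")

#: Highest educational attainment categories.
EDUCATION_LEVELS = (
    "No Education",
    "Primary Education",
    "Secondary Education",
    "Higher Education",
)

#: Five-year periods of the historical reconstruction.
DEFAULT_PERIODS = tuple(f"{y}-{y + 5}" for y in range(1970, 2020, 5))

#: Midpoints of the five-year age groups, in years of age.
AGE_MIDPOINTS = np.arange(17.5, 50.0, 5.0)

ESTIMATE_COLUMNS = (
    "Country",
    "Age Group",
    "Education",
    "Year",
    "Upper_CI",
    "Lower_CI",
    "Median",
)

_PERIOD_RE = re.compile(r"^(\d{4})-(\d{4})$")


class VocabularyError(ValueError):
    """A label falls outside one of the closed vocabularies."""


class SchemaError(ValueError):
    """A table is missing expected columns."""


class AlignmentError(ValueError):
    """Two tables do not share the same lattice."""


def period_start(label: str) -> int:
    """Return the first calendar year of a ``"YYYY-YYYY"`` period label."""
    m = _PERIOD_RE.match(label)
    if m is None:
        raise VocabularyError(f"malformed period label {label!r}; expected 'YYYY-YYYY'")
    lo, hi = int(m.group(1)), int(m.group(2))
    if hi - lo != 5:
        raise VocabularyError(f"period label {label!r} does not span 5 years")
    return lo


@dataclass(frozen=True)
class Lattice:
    """The rectangular crossing of countries, periods, ages and educations.

    Parameters
    ----------
    countries
        Ordered country labels.
    regions
        Mapping country -> region; regions must come from :data:`REGIONS`.
    periods, age_groups, education_levels
        Ordered closed vocabularies for the remaining axes.
    """

    countries: tuple
    regions: dict
    periods: tuple = DEFAULT_PERIODS
    age_groups: tuple = AGE_GROUPS
    education_levels: tuple = EDUCATION_LEVELS

    def __post_init__(self):
        for c in self.countries:
            r = self.regions.get(c)
            if r not in REGIONS:
                raise VocabularyError(
                    f"country {c!r} has region {r!r}, not one of {REGIONS}"
                )
        for p in self.periods:
            period_start(p)

    @property
    def shape(self) -> tuple:
        return (
            len(self.countries),
            len(self.periods),
            len(self.age_groups),
            len(self.education_levels),
        )

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def axis_index(self, axis: str) -> dict:
        labels = {
            "country": self.countries,
            "period": self.periods,
            "age_group": self.age_groups,
            "education": self.education_levels,
        }[axis]
        return {lab: i for i, lab in enumerate(labels)}

    def region_of(self, country: str) -> str:
        return self.regions[country]

    def ssa_countries(self) -> tuple:
        return tuple(
            c for c in self.countries if self.regions[c] == "sub-Saharan Africa"
        )

    # ---- frame <-> array converters -------------------------------------

    def frame(self, values: np.ndarray, value_col: str = "Value") -> pd.DataFrame:
        """Long-format DataFrame for a full (C, Y, A, E) array."""
        arr = np.asarray(values)
        if arr.shape != self.shape:
            raise AlignmentError(f"array shape {arr.shape} != lattice {self.shape}")
        c, y, a, e = np.meshgrid(
            np.arange(arr.shape[0]),
            np.arange(arr.shape[1]),
            np.arange(arr.shape[2]),
            np.arange(arr.shape[3]),
            indexing="ij",
        )
        countries = np.asarray(self.countries)[c.ravel()]
        return pd.DataFrame(
            {
                "Country": countries,
                "Region": [self.regions[cc] for cc in countries],
                "Year": np.asarray(self.periods)[y.ravel()],
                "Age Group": np.asarray(self.age_groups)[a.ravel()],
                "Education": np.asarray(self.education_levels)[e.ravel()],
                value_col: arr.ravel(),
            }
        )

    def marginal_frame(self, values: np.ndarray, axes: tuple, value_col: str = "Value") -> pd.DataFrame:
        """Long-format frame for an array over a subset of axes (in lattice order)."""
        labels = {
            "country": self.countries,
            "period": self.periods,
            "age_group": self.age_groups,
            "education": self.education_levels,
        }
        colname = {
            "country": "Country",
            "period": "Year",
            "age_group": "Age Group",
            "education": "Education",
        }
        arr = np.asarray(values)
        expect = tuple(len(labels[a]) for a in axes)
        if arr.shape != expect:
            raise AlignmentError(f"array shape {arr.shape} != {expect} for axes {axes}")
        grids = np.meshgrid(*[np.arange(n) for n in expect], indexing="ij")
        out = {}
        for ax, g in zip(axes, grids):
            out[colname[ax]] = np.asarray(labels[ax])[g.ravel()]
        out[value_col] = arr.ravel()
        return pd.DataFrame(out)

    def array(self, df: pd.DataFrame, value_col: str = "Value") -> np.ndarray:
        """Dense (C, Y, A, E) array from a long table; missing cells -> NaN."""
        return self._to_array(
            df, ("Country", "Year", "Age Group", "Education"), value_col
        )

    def benchmark_array(self, df: pd.DataFrame, value_col: str = "Value") -> np.ndarray:
        """Dense (C, Y, A) array from a (country, period, age) table."""
        return self._to_array(df, ("Country", "Year", "Age Group"), value_col)

    def etfr_array(self, df: pd.DataFrame, value_col: str = "Value") -> np.ndarray:
        """Dense (C, Y, E) array from a (country, period, education) table."""
        return self._to_array(df, ("Country", "Year", "Education"), value_col)

    def _to_array(self, df, key_cols, value_col):
        missing = [c for c in key_cols + (value_col,) if c not in df.columns]
        if missing:
            raise SchemaError(f"table lacks columns {missing}")
        idx = {
            "Country": self.axis_index("country"),
            "Year": self.axis_index("period"),
            "Age Group": self.axis_index("age_group"),
            "Education": self.axis_index("education"),
        }
        shape = []
        pos = []
        for col in key_cols:
            mapping = idx[col]
            labels = df[col].to_numpy()
            unknown = set(labels) - set(mapping)
            if unknown:
                raise VocabularyError(
                    f"unknown {col} labels {sorted(unknown)}; expected {list(mapping)}"
                )
            pos.append(np.array([mapping[v] for v in labels]))
            shape.append(len(mapping))
        out = np.full(tuple(shape), np.nan)
        out[tuple(pos)] = df[value_col].to_numpy(dtype=float)
        return out


# ---- validation ---------------------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_lattice`; empty lists mean a valid table."""

    missing_cells: list = field(default_factory=list)
    duplicate_keys: list = field(default_factory=list)
    negative_values: list = field(default_factory=list)
    weight_sum_violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.missing_cells
            or self.duplicate_keys
            or self.negative_values
            or self.weight_sum_violations
        )


def validate_lattice(
    df: pd.DataFrame,
    lattice: Lattice,
    kind: str = "rates",
    value_col: str = "Value",
    weight_tol: float = 1e-9,
) -> ValidationReport:
    """Check a long-format table against the full lattice.

    ``kind="weights"`` additionally checks that weights sum to 1 within
    each (country, period, age group) cell.
    """
    report = ValidationReport()
    key_cols = ["Country", "Year", "Age Group", "Education"]
    keys = list(map(tuple, df[key_cols].to_numpy()))
    seen = set()
    for k in keys:
        if k in seen:
            report.duplicate_keys.append(k)
        seen.add(k)
    expected = {
        (c, y, a, e)
        for c in lattice.countries
        for y in lattice.periods
        for a in lattice.age_groups
        for e in lattice.education_levels
    }
    report.missing_cells = sorted(expected - seen)
    neg = df[df[value_col] < 0]
    report.negative_values = list(map(tuple, neg[key_cols].to_numpy()))
    if kind == "weights":
        sums = df.groupby(["Country", "Year", "Age Group"], sort=False)[value_col].sum()
        bad = sums[(sums - 1.0).abs() > weight_tol]
        report.weight_sum_violations = [
            (*k, float(v - 1.0)) for k, v in bad.items()
        ]
    return report


# ---- published-schema estimates file ------------------------------------


def write_estimates(summary: pd.DataFrame, path) -> None:
    """Write a posterior-summary table in the published workbook schema.

    The file carries exactly the columns ``Country, Age Group, Education,
    Year, Upper_CI, Lower_CI, Median`` in that order, one row per
    (country, age group, education, period).
    """
    missing = [c for c in ESTIMATE_COLUMNS if c not in summary.columns]
    if missing:
        raise SchemaError(f"summary lacks columns {missing}")
    bad = summary[
        (summary["Lower_CI"] > summary["Median"])
        | (summary["Median"] > summary["Upper_CI"])
    ]
    if len(bad):
        raise ValueError(f"{len(bad)} rows violate Lower_CI <= Median <= Upper_CI")
    summary.loc[:, list(ESTIMATE_COLUMNS)].to_csv(path, index=False)


def read_estimates(path, lattice: Lattice | None = None) -> pd.DataFrame:
    """Read an estimates file written by :func:`write_estimates`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if tuple(df.columns) != ESTIMATE_COLUMNS:
        raise SchemaError(
            f"expected columns {list(ESTIMATE_COLUMNS)}, found {list(df.columns)}"
        )
    if lattice is not None:
        _check_vocab(df["Education"], lattice.education_levels, "Education")
        _check_vocab(df["Age Group"], lattice.age_groups, "Age Group")
        _check_vocab(df["Year"], lattice.periods, "Year")
    return df


def read_long_csv(path, lattice: Lattice, value_col: str = "Value") -> pd.DataFrame:
    """Read a long-format table, validating labels against the vocabularies."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"Country", "Year", "Age Group", "Education", value_col}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)}")
    _check_vocab(df["Education"], lattice.education_levels, "Education")
    _check_vocab(df["Age Group"], lattice.age_groups, "Age Group")
    _check_vocab(df["Year"], lattice.periods, "Year")
    _check_vocab(df["Country"], lattice.countries, "Country")
    return df


# common synonyms mapped to the DHS attainment vocabulary, for error hints
_EDUCATION_SYNONYMS = {
    "tertiary": "Higher Education",
    "post-secondary": "Higher Education",
    "university": "Higher Education",
    "none": "No Education",
    "no school": "No Education",
}


def _check_vocab(series: pd.Series, vocab: tuple, name: str) -> None:
    unknown = sorted(set(series) - set(vocab))
    if unknown:
        hint = ""
        if name == "Education":
            sugg = _EDUCATION_SYNONYMS.get(str(unknown[0]).lower())
            if sugg is None:
                from difflib import get_close_matches

                close = get_close_matches(str(unknown[0]), vocab, n=1, cutoff=0.0)
                sugg = close[0] if close else None
            if sugg:
                hint = f"; did you mean {sugg!r}?"
        raise VocabularyError(f"unknown {name} labels {unknown}{hint}")
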