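"""Step 1: survey cleaning, GLM completion of partial age schedules, and
the scale statistics that parameterize the precision priors.

Survey birth histories observe only part of each country's fertility
surface (each wave covers roughly the 30 years before it, and sparse
education-age cells go unobserved).  A fixed-structure GLM with main
effects for education, region, age group, country and period plus the
two-way interactions education x age, period x age, region x age,
region x period and region x country is fit to the pooled observations
and used to predict a complete education- and age-specific rate lattice.
Those predictions are the prior centers and initial values of the
Bayesian step; their prediction standard errors feed the precision
priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import linalg
from sklearn.base import BaseEstimator

from .lattice import Lattice


def _estimable_columns(X: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Indices of a maximal linearly independent column subset.

    Columns are scanned in design order (main effects before the
    interactions that follow them) and kept when their residual norm
    after projection on the kept set exceeds ``tol`` relative to their
    own norm.  Working from the Gram matrix keeps the selection
    invariant to row order of the observations.
    """
    G = X.T @ X
    p = G.shape[0]
    kept: list = []
    L = np.zeros((p, p))  # growing Cholesky factor of G[kept, kept]
    for j in range(p):
        gjj = G[j, j]
        if gjj <= 0:
            continue
        k = len(kept)
        if k:
            y = linalg.solve_triangular(L[:k, :k], G[kept, j], lower=True)
            r2 = gjj - y @ y
        else:
            y = np.empty(0)
            r2 = gjj
        if r2 > (tol**2) * gjj:
            L[k, :k] = y
            L[k, k] = np.sqrt(r2)
            kept.append(j)
    return np.asarray(kept, dtype=int)

GLM_FORMULA = (
    "Education + Region + Q('Age Group') + Country + Year"
    " + Education:Q('Age Group') + Year:Q('Age Group')"
    " + Region:Q('Age Group') + Region:Year + Region:Country"
)

_RATE_EPS = 1e-6  # floor added to rates for the log-Gaussian fallback


@dataclass(frozen=True)
class CleanConfig:
    """Deterministic operationalization of the survey cleaning rules.

    * ``max_births_higher_ed``: reported birth counts above this are
      implausible for higher-educated women and the row is dropped.
    * ``outlier_rate_ceiling``: hard ceiling on a plausible age-specific
      rate (births per woman per year).
    * ``mad_multiplier``: rows deviating from their country-education-age
      median by more than this many robust (normal-consistent MAD)
      deviations are dropped.
    """

    max_births_higher_ed: int = 30
    outlier_rate_ceiling: float = 1.0
    mad_multiplier: float = 5.0

    def __post_init__(self):
        if (
            self.max_births_higher_ed <= 0
            or self.outlier_rate_ceiling <= 0
            or self.mad_multiplier <= 0
        ):
            raise ValueError("all cleaning thresholds must be positive")


def clean_observations(
    raw: pd.DataFrame, cfg: CleanConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cleaning rules; returns (kept rows, removed rows + reason)."""
    cfg = cfg or CleanConfig()
    df = raw.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    if "Births" in df.columns:
        rule1 = (df["Education"] == "Higher Education") & (
            df["Births"] > cfg.max_births_higher_ed
        )
    else:
        rule1 = pd.Series(False, index=df.index)
    reasons[rule1] = "higher-education birth count above threshold"

    rule2 = (df["Value"] > cfg.outlier_rate_ceiling) & ~rule1
    reasons[rule2] = "rate above plausibility ceiling"

    # robust screen, iterated to a fixed point so cleaning is idempotent
    rule3 = pd.Series(False, index=df.index)
    for _ in range(10):
        keep = ~(rule1 | rule2 | rule3)
        sub = df[keep]
        med = sub.groupby(["Country", "Education", "Age Group"], sort=False)[
            "Value"
        ].transform("median")
        mad = 1.4826 * (sub["Value"] - med).abs().groupby(
            [sub["Country"], sub["Education"], sub["Age Group"]], sort=False
        ).transform("median")
        new = (mad > 0) & ((sub["Value"] - med).abs() > cfg.mad_multiplier * mad)
        if not new.any():
            break
        rule3.loc[new[new].index] = True
    reasons[rule3] = "robust outlier vs country-education-age median"

    removed_mask = rule1 | rule2 | rule3
    removed = df[removed_mask].copy()
    removed["Reason"] = reasons[removed_mask]
    return df[~removed_mask].copy(), removed


class GLMInitializer(BaseEstimator):
    """Fixed-structure GLM that completes the fertility-rate lattice.

    Parameters
    ----------
    lattice : Lattice
        The full country x period x age x education lattice to predict.
    family : {"auto", "poisson", "gaussian"}
        ``"poisson"`` fits birth counts with a log link and a
        log-exposure offset; ``"gaussian"`` fits log(rate + 1e-6).
        ``"auto"`` uses Poisson when birth counts and exposures are
        present.
    clean : CleanConfig or None
        Cleaning rules applied before fitting (None disables cleaning).

    Attributes
    ----------
    predicted_ : ndarray of shape (C, Y, A, E)
        Predicted rates on the full lattice (strictly positive).
    se_ : ndarray of shape (C, Y, A, E)
        Delta-method standard errors of the predicted rates.
    deviance_ : float
    converged_ : bool
    removed_ : DataFrame
        Rows dropped by cleaning, with reasons.
    """

    def __init__(self, lattice: Lattice, family: str = "auto", clean=CleanConfig()):
        self.lattice = lattice
        self.family = family
        self.clean = clean

    def fit(self, observations: pd.DataFrame, y=None):
        obs = observations
        if self.clean is not None:
            obs, removed = clean_observations(obs, self.clean)
            self.removed_ = removed
        else:
            self.removed_ = obs.iloc[0:0]
        if obs.empty:
            raise ValueError("no observations left after cleaning")
        for col in ("Education", "Region", "Age Group", "Country", "Year", "Value"):
            if col not in obs.columns:
                raise ValueError(f"observations lack required column {col!r}")
        for col in ("Education", "Age Group", "Country", "Year"):
            vocab = {
                "Education": self.lattice.education_levels,
                "Age Group": self.lattice.age_groups,
                "Country": self.lattice.countries,
                "Year": self.lattice.periods,
            }[col]
            if len(set(obs[col])) < 2 and len(vocab) > 1:
                # a single observed level of a multi-level factor cannot
                # anchor its main effect; warn via the fit result instead
                pass

        data = self._with_categories(obs)
        family = self.family
        if family == "auto":
            family = (
                "poisson"
                if {"Births", "Exposure"} <= set(obs.columns)
                and obs["Exposure"].gt(0).all()
                else "gaussian"
            )
        self.family_used_ = family

        X = patsy.dmatrix(GLM_FORMULA, data, return_type="dataframe")
        self.design_info_ = X.design_info
        Xarr = np.asarray(X)
        keep = _estimable_columns(Xarr)
        self.n_aliased_columns_ = Xarr.shape[1] - keep.size
        Xarr = Xarr[:, keep]
        if family == "poisson":
            model = sm.GLM(
                data["Births"].to_numpy(dtype=float),
                Xarr,
                family=sm.families.Poisson(),
                offset=np.log(data["Exposure"].to_numpy(dtype=float)),
            )
        else:
            model = sm.GLM(
                np.log(data["Value"].to_numpy(dtype=float) + _RATE_EPS),
                Xarr,
                family=sm.families.Gaussian(),
            )
        res = model.fit(maxiter=300)
        self.result_ = res
        self.deviance_ = float(res.deviance)
        self.converged_ = bool(getattr(res, "converged", True))

        full = self._with_categories(self.lattice.frame(np.zeros(self.lattice.shape)))
        (Xp,) = patsy.build_design_matrices([self.design_info_], full)
        Xp = np.asarray(Xp)[:, keep]
        eta = Xp @ res.params
        cov = np.asarray(res.cov_params())
        var_eta = np.einsum("ij,jk,ik->i", Xp, cov, Xp)
        var_eta = np.clip(var_eta, 0.0, None)
        rate = np.exp(eta)
        if family == "gaussian":
            rate = np.clip(rate - _RATE_EPS, _RATE_EPS, None)
        se = rate * np.sqrt(var_eta)  # delta method on the log scale
        shape = self.lattice.shape
        rate = rate.reshape(shape)
        se = se.reshape(shape)
        # cells whose factor combination is inestimable from the observed
        # design get the region x education x age marginal rate instead,
        # so the Bayesian step always receives a finite, plausible center
        unstable = (
            (np.sqrt(var_eta.reshape(shape)) > 5.0)
            | (rate < 1e-7)
            | (rate > 5.0)
            | ~np.isfinite(rate)
        )
        self.aliased_cells_ = unstable
        if unstable.any():
            rate, se = self._fallback(obs, rate, se, unstable)
        se = np.clip(se, 1e-10, None)
        self.predicted_ = np.clip(rate, 1e-8, None)
        self.se_ = se
        return self

    def _fallback(self, obs, rate, se, unstable):
        """Region x education x age marginal rates for inestimable cells."""
        lat = self.lattice
        marg = obs.groupby(["Region", "Education", "Age Group"], sort=False)[
            "Value"
        ].mean()
        overall = float(obs["Value"].mean())
        good = ~unstable
        for ei, e in enumerate(lat.education_levels):
            med_se = (
                float(np.median(se[..., ei][good[..., ei]]))
                if good[..., ei].any()
                else float(np.median(se[good])) if good.any() else 1e-3
            )
            for ci, c in enumerate(lat.countries):
                r = lat.regions[c]
                for ai, a in enumerate(lat.age_groups):
                    cells = unstable[ci, :, ai, ei]
                    if not cells.any():
                        continue
                    val = marg.get((r, e, a), np.nan)
                    if not np.isfinite(val) or val <= 0:
                        val = overall
                    rate[ci, cells, ai, ei] = max(val, 1e-6)
                    se[ci, cells, ai, ei] = med_se
        return rate, se

    def _with_categories(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        cats = {
            "Education": self.lattice.education_levels,
            "Region": tuple(dict.fromkeys(self.lattice.regions.values())),
            "Age Group": self.lattice.age_groups,
            "Country": self.lattice.countries,
            "Year": self.lattice.periods,
        }
        for col, levels in cats.items():
            out[col] = pd.Categorical(out[col], categories=levels)
        return out

    def predict_frame(self) -> pd.DataFrame:
        """The completed lattice as a long-format table."""
        return self.lattice.frame(self.predicted_)


@dataclass(frozen=True)
class PriorStatistics:
    """Scale statistics of the GLM fit that parameterize precision priors.

    All SD/variance statistics are sample statistics (ddof=1) of the
    delta-method prediction standard errors, grouped as named; sigma2_est
    is the variance of the predicted rates themselves; sigma_etfr_e4 is
    the SD of the derived education-specific TFR for the highest
    education level.
    """

    sigma_e: np.ndarray  # (E,) SD of SEs by education
    mu_e: np.ndarray  # (E,) mean of SEs by education
    sigma2_e: np.ndarray  # (E,) variance of SEs by education
    sigma2_pooled: float  # pooled variance of SEs
    sigma_pooled: float  # pooled SD of SEs
    sigma2_est: float  # variance of the predicted rates
    sigma_ae: np.ndarray  # (A, E) SD of SEs by age x education
    sigma_etfr_e4: float  # SD of derived ETFR, highest education
    var_mean_ratio: float  # variance / mean of the SEs (pooled)

    def frame(self, lattice: Lattice) -> pd.DataFrame:
        """Small long table of all statistics (for the priors CSV)."""
        rows = []
        for ei, e in enumerate(lattice.education_levels):
            rows += [
                ("sigma_e", e, "", float(self.sigma_e[ei])),
                ("mu_e", e, "", float(self.mu_e[ei])),
                ("sigma2_e", e, "", float(self.sigma2_e[ei])),
            ]
        for ai, a in enumerate(lattice.age_groups):
            for ei, e in enumerate(lattice.education_levels):
                rows.append(("sigma_ae", e, a, float(self.sigma_ae[ai, ei])))
        rows += [
            ("sigma2_pooled", "", "", self.sigma2_pooled),
            ("sigma_pooled", "", "", self.sigma_pooled),
            ("sigma2_est", "", "", self.sigma2_est),
            ("sigma_etfr_e4", "", "", self.sigma_etfr_e4),
            ("var_mean_ratio", "", "", self.var_mean_ratio),
        ]
        return pd.DataFrame(rows, columns=["Statistic", "Education", "Age Group", "Value"])


def derive_prior_statistics(
    predicted: np.ndarray, se: np.ndarray, lattice: Lattice
) -> PriorStatistics:
    """Compute all precision-prior scale statistics from a GLM fit."""
    predicted = np.asarray(predicted, dtype=float)
    se = np.asarray(se, dtype=float)
    if predicted.shape != lattice.shape or se.shape != lattice.shape:
        raise ValueError("predicted/se must cover the full lattice")
    C, Y, A, E = lattice.shape
    if C * Y * A == 0:
        raise ValueError("empty lattice")

    def sd(x):
        x = np.asarray(x).ravel()
        if x.size == 0:
            raise ValueError("empty statistic group")
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    sigma_e = np.array([sd(se[..., ei]) for ei in range(E)])
    mu_e = np.array([float(np.mean(se[..., ei])) for ei in range(E)])
    sigma2_e = sigma_e**2
    sigma_pooled = sd(se)
    sigma_ae = np.array(
        [[sd(se[:, :, ai, ei]) for ei in range(E)] for ai in range(A)]
    )
    etfr_e4 = 5.0 * predicted[..., E - 1].sum(axis=2)  # (C, Y)
    mean_se = float(np.mean(se))
    return PriorStatistics(
        sigma_e=sigma_e,
        mu_e=mu_e,
        sigma2_e=sigma2_e,
        sigma2_pooled=sigma_pooled**2,
        sigma_pooled=sigma_pooled,
        sigma2_est=sd(predicted) ** 2,
        sigma_ae=sigma_ae,
        sigma_etfr_e4=sd(etfr_e4),
        var_mean_ratio=sigma_pooled**2 / mean_se if mean_se > 0 else 0.0,
    )
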