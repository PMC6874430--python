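"""Cross-sectional rate estimation: OLS of a per-individual percentage on age.

Each species' rate of increase (e.g. "% γH2AX-positive cells per year") is
the ordinary-least-squares slope of the per-individual percentage against
age across the individuals of that species.  Because the study is
cross-sectional — one timepoint per animal — the slope is a population
rate, not a within-individual trajectory.

Exposed in a statsmodels-like shape: :class:`RateModel` is constructed
from data and its :meth:`~RateModel.fit` returns a :class:`SpeciesRateFit`
results object carrying the slope, intercept, R², standard error, 95%
confidence interval and a ``summary()``.  :func:`fit_rate` and
:func:`fit_all_species` are thin functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["SpeciesRateFit", "RateModel", "fit_rate", "fit_all_species"]

STATISTIC_COLUMNS = {
    "gh2ax_positivity": "pct_gh2ax_positive",
    "short_telomere": "pct_short_telomeres",
}


@dataclass(frozen=True)
class SpeciesRateFit:
    """OLS results for one species' percentage-vs-age regression.

    ``slope`` is in % per year, ``intercept`` in % at age 0.  ``r_squared``
    is ``None`` (with ``r_squared_defined=False``) when the response has
    zero variance, never silently 0 or 1.  ``slope_se`` and ``ci95`` come
    from the t distribution with n−2 degrees of freedom and are NaN for
    exactly two points (zero residual degrees of freedom).
    """

    species: str
    statistic: str
    slope: float
    intercept: float
    r_squared: float | None
    r_squared_defined: bool
    n_individuals: int
    slope_se: float
    ci95: tuple[float, float]

    def summary(self) -> str:
        r2 = f"{self.r_squared:.4f}" if self.r_squared_defined else "undefined (zero variance)"
        return (
            f"Rate fit: {self.species} / {self.statistic}\n"
            f"  n individuals : {self.n_individuals}\n"
            f"  slope         : {self.slope:.4f} %/yr "
            f"(SE {self.slope_se:.4f}, 95% CI [{self.ci95[0]:.4f}, {self.ci95[1]:.4f}])\n"
            f"  intercept     : {self.intercept:.4f} %\n"
            f"  R^2           : {r2}"
        )


class RateModel:
    """OLS model of a per-individual percentage against age for one species."""

    def __init__(self, ages, values, species: str = "", statistic: str = ""):
        self.ages = np.asarray(ages, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.species = species
        self.statistic = statistic
        if self.ages.shape != self.values.shape or self.ages.ndim != 1:
            raise ValueError("ages and values must be matching 1D arrays")
        if self.ages.size < 2:
            raise ValueError("need at least 2 individuals to fit a rate")
        if np.unique(self.ages).size < 2:
            raise ValueError("all ages identical: the rate is unidentifiable")

    @classmethod
    def from_dataframe(
        cls, summaries: pd.DataFrame, species: str, statistic: str
    ) -> "RateModel":
        col = STATISTIC_COLUMNS[statistic]
        sub = summaries[summaries["species"] == species]
        return cls(sub["age"], sub[col], species=species, statistic=statistic)

    def fit(self) -> SpeciesRateFit:
        x, y = self.ages, self.values
        n = x.size
        xbar, ybar = x.mean(), y.mean()
        sxx = float(((x - xbar) ** 2).sum())
        slope = float(((x - xbar) * (y - ybar)).sum() / sxx)
        intercept = float(ybar - slope * xbar)

        resid = y - (intercept + slope * x)
        ssr = float((resid**2).sum())
        sst = float(((y - ybar) ** 2).sum())
        if sst > 0:
            r_squared, defined = 1.0 - ssr / sst, True
        else:
            r_squared, defined = None, False

        if n > 2:
            sigma2 = ssr / (n - 2)
            se = float(np.sqrt(sigma2 / sxx))
            tcrit = float(stats.t.ppf(0.975, n - 2))
            ci = (slope - tcrit * se, slope + tcrit * se)
        else:
            se, ci = float("nan"), (float("nan"), float("nan"))

        return SpeciesRateFit(
            species=self.species,
            statistic=self.statistic,
            slope=slope,
            intercept=intercept,
            r_squared=r_squared,
            r_squared_defined=defined,
            n_individuals=n,
            slope_se=se,
            ci95=ci,
        )


def fit_rate(ages, values, species: str = "", statistic: str = "") -> SpeciesRateFit:
    """OLS slope/intercept/R² of percentage vs age (see :class:`RateModel`)."""
    return RateModel(ages, values, species=species, statistic=statistic).fit()


def fit_all_species(summaries: pd.DataFrame) -> list[SpeciesRateFit]:
    """One rate fit per (species, statistic) present in an individual-summary table.

    Species with fewer than 2 individuals (or no age spread) are skipped
    with a logged warning rather than failing the whole run.  Output order
    is deterministic: sorted by (species, statistic).
    """
    fits: list[SpeciesRateFit] = []
    for species in sorted(summaries["species"].unique()):
        for statistic in sorted(STATISTIC_COLUMNS):
            if STATISTIC_COLUMNS[statistic] not in summaries.columns:
                continue
            try:
                model = RateModel.from_dataframe(summaries, species, statistic)
            except ValueError as exc:
                logger.warning("skipping %s / %s: %s", species, statistic, exc)
                continue
            fits.append(model.fit())
    return fits


def rate_fits_to_frame(fits: list[SpeciesRateFit]) -> pd.DataFrame:
    """Tabular view of a list of rate fits (one row per fit)."""
    return pd.DataFrame(
        [
            {
                "species": f.species,
                "statistic": f.statistic,
                "slope": f.slope,
                "intercept": f.intercept,
                "r_squared": f.r_squared if f.r_squared_defined else np.nan,
                "r_squared_defined": f.r_squared_defined,
                "n_individuals": f.n_individuals,
                "slope_se": f.slope_se,
                "ci95_low": f.ci95[0],
                "ci95_high": f.ci95[1],
            }
            for f in fits
        ]
    )
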