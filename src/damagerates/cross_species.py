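"""Cross-species regression of damage/telomere rates against species traits.

Relates the per-species cross-sectional rates to species-level covariates
(maximum lifespan, average lifespan, body weight, heart rate):

* linear trendline ``y = m·x + c`` (OLS);
* power-law trendline ``y = a·x^b``, fitted as OLS of ``ln y`` on ``ln x``
  with R² reported on the log-log scale (the spreadsheet power-trendline
  convention); an R² of the back-transformed curve on the original scale
  is also carried as a clearly separate diagnostic;
* rate-vs-rate correlation (the same linear estimator with both axes
  being rates);
* a multivariate linear model predicting lifespan from both rates, with
  per-coefficient t tests and an overall F test;
* the "very old individual" abundance metric: the fraction of sampled
  ages strictly above 70% of the species' maximum lifespan.

Model/Results shape: :class:`TrendModel` / :class:`LifespanRegression`
build from data and ``fit()`` returns :class:`CrossSpeciesFit` /
:class:`MultivariateFit` results objects; module-level ``fit_*`` functions
are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesTraits",
    "CrossSpeciesFit",
    "MultivariateFit",
    "OldAbundance",
    "TrendModel",
    "LifespanRegression",
    "fit_linear_trend",
    "fit_power_trend",
    "correlate_rates",
    "fit_multivariate",
    "old_abundance",
    "load_traits",
    "example_traits_path",
    "DEFAULT_EXCLUDED_SPECIES",
]

# Species held out of cross-species fits by default (re-included by flag).
# Very long-lived reptiles are plotted separately from the bird/mammal
# comparison because so few individuals are available.
DEFAULT_EXCLUDED_SPECIES = ("loggerhead sea turtle",)

TRAITS_COLUMNS = ["species", "max_lifespan_years", "avg_lifespan_years", "body_weight", "heart_rate_bpm"]


@dataclass(frozen=True)
class SpeciesTraits:
    """Species-level covariates; missing values are allowed (NaN) and flagged."""

    species: str
    max_lifespan: float
    avg_lifespan: float
    body_weight: float = float("nan")
    heart_rate: float = float("nan")

    def __post_init__(self) -> None:
        if np.isfinite(self.max_lifespan) and np.isfinite(self.avg_lifespan):
            if not self.max_lifespan >= self.avg_lifespan > 0:
                raise ValueError(
                    f"{self.species}: need max_lifespan >= avg_lifespan > 0"
                )


@dataclass(frozen=True)
class CrossSpeciesFit:
    """A fitted cross-species trendline.

    ``coefficients`` is ``(slope m, intercept c)`` for the linear model and
    ``(a, b)`` for the power model ``y = a·x^b``.  ``r_squared`` is on the
    fitting scale (log-log for the power model); ``r_squared_original`` is
    the optional back-transformed diagnostic for power fits.
    """

    model: str  # "linear" | "power"
    predictor: str
    response: str
    coefficients: tuple[float, float]
    r_squared: float | None
    r_squared_defined: bool
    n_species: int
    r_squared_original: float | None = None

    @property
    def slope(self) -> float:
        """Linear slope m, or the power-law exponent b."""
        return self.coefficients[0] if self.model == "linear" else self.coefficients[1]

    def summary(self) -> str:
        if self.model == "linear":
            eq = f"y = {self.coefficients[0]:.4g}*x + {self.coefficients[1]:.4g}"
        else:
            eq = f"y = {self.coefficients[0]:.4g} * x^{self.coefficients[1]:.4g}"
        r2 = f"{self.r_squared:.4f}" if self.r_squared_defined else "undefined (zero variance)"
        lines = [
            f"{self.model.capitalize()} trendline: {self.response} vs {self.predictor}",
            f"  n species : {self.n_species}",
            f"  fit       : {eq}",
            f"  R^2       : {r2}" + (" (log-log scale)" if self.model == "power" else ""),
        ]
        if self.model == "power" and self.r_squared_original is not None:
            lines.append(f"  R^2 (original scale, diagnostic): {self.r_squared_original:.4f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class MultivariateFit:
    """Multivariate OLS results: coefficients, SEs, t-test p-values, F test, R²."""

    response: str
    predictors: tuple[str, ...]
    params: dict
    bse: dict
    pvalues: dict
    f_pvalue: float
    r_squared: float
    n_species: int

    def summary(self) -> str:
        lines = [
            f"Multivariate linear model: {self.response} ~ " + " + ".join(self.predictors),
            f"  n species : {self.n_species}",
            f"  R^2       : {self.r_squared:.4f}",
            f"  model p (F test) : {self.f_pvalue:.4f}",
        ]
        for name in ("const", *self.predictors):
            lines.append(
                f"  {name:<28s} coef {self.params[name]: .5g}  "
                f"SE {self.bse[name]:.5g}  p {self.pvalues[name]:.4f}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class OldAbundance:
    """Abundance of very old individuals: ages strictly above 0.7 × max lifespan."""

    species: str
    cutoff_age: float
    n_old: int
    n_total: int
    fraction_old: float


def _complete_pairs(x, y, context: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1D vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < len(x):
        logger.info("%s: dropping %d species with missing values", context, int(len(x) - keep.sum()))
    return x[keep], y[keep]


class TrendModel:
    """Two-variable cross-species trendline (linear or power-law)."""

    def __init__(self, x, y, model: str = "linear", predictor: str = "x", response: str = "y"):
        if model not in ("linear", "power"):
            raise ValueError("model must be 'linear' or 'power'")
        self.x, self.y = _complete_pairs(x, y, f"{model} trend {response} vs {predictor}")
        self.model = model
        self.predictor = predictor
        self.response = response
        if self.x.size < 3:
            raise ValueError("need at least 3 complete species pairs")
        if model == "power" and (np.any(self.x <= 0) or np.any(self.y <= 0)):
            raise ValueError("power-law fit requires strictly positive x and y")

    def fit(self) -> CrossSpeciesFit:
        if self.model == "linear":
            xf, yf = self.x, self.y
        else:
            xf, yf = np.log(self.x), np.log(self.y)

        if np.unique(xf).size < 2:
            raise ValueError("predictor is constant: trendline is unidentifiable")
        xbar, ybar = xf.mean(), yf.mean()
        sxx = float(((xf - xbar) ** 2).sum())
        slope = float(((xf - xbar) * (yf - ybar)).sum() / sxx)
        intercept = float(ybar - slope * xbar)
        ssr = float(((yf - (intercept + slope * xf)) ** 2).sum())
        sst = float(((yf - ybar) ** 2).sum())
        if sst > 0:
            r2, defined = 1.0 - ssr / sst, True
        else:
            r2, defined = None, False

        r2_orig = None
        if self.model == "power":
            coeffs = (float(np.exp(intercept)), slope)
            yhat = coeffs[0] * self.x ** coeffs[1]
            sst_o = float(((self.y - self.y.mean()) ** 2).sum())
            if sst_o > 0:
                r2_orig = 1.0 - float(((self.y - yhat) ** 2).sum()) / sst_o
        else:
            coeffs = (slope, intercept)

        return CrossSpeciesFit(
            model=self.model,
            predictor=self.predictor,
            response=self.response,
            coefficients=coeffs,
            r_squared=r2,
            r_squared_defined=defined,
            n_species=int(self.x.size),
            r_squared_original=r2_orig,
        )


def fit_linear_trend(x, y, predictor: str = "x", response: str = "y") -> CrossSpeciesFit:
    """Linear trendline ``y = m·x + c`` across species (OLS)."""
    return TrendModel(x, y, "linear", predictor, response).fit()


def fit_power_trend(x, y, predictor: str = "x", response: str = "y") -> CrossSpeciesFit:
    """Power-law trendline ``y = a·x^b``: OLS of ln y on ln x, R² on the log scale."""
    return TrendModel(x, y, "power", predictor, response).fit()


def correlate_rates(rate_a, rate_b, name_a: str = "rate_a", name_b: str = "rate_b") -> CrossSpeciesFit:
    """Rate-vs-rate association: the linear estimator with both axes being rates."""
    return fit_linear_trend(rate_a, rate_b, predictor=name_a, response=name_b)


class LifespanRegression:
    """Multivariate OLS of a lifespan response on per-species rate predictors."""

    def __init__(self, data: pd.DataFrame, response: str, predictors: list[str]):
        cols = [response, *predictors]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        frame = data[cols].dropna()
        n, p = len(frame), len(predictors)
        if n < p + 2:
            raise ValueError(
                f"need at least {p + 2} complete species for {p} predictors, got {n}"
            )
        design = sm.add_constant(frame[predictors].to_numpy(dtype=float))
        if np.linalg.matrix_rank(design) < design.shape[1]:
            collinear = _collinear_columns(frame[predictors])
            raise ValueError(f"singular design: collinear predictors {collinear}")
        self.frame = frame
        self.response = response
        self.predictors = list(predictors)

    def fit(self) -> MultivariateFit:
        X = sm.add_constant(self.frame[self.predictors].astype(float))
        res = sm.OLS(self.frame[self.response].astype(float), X).fit()
        names = ["const", *self.predictors]
        return MultivariateFit(
            response=self.response,
            predictors=tuple(self.predictors),
            params={k: float(res.params[k]) for k in names},
            bse={k: float(res.bse[k]) for k in names},
            pvalues={k: float(res.pvalues[k]) for k in names},
            f_pvalue=float(res.f_pvalue),
            r_squared=float(res.rsquared),
            n_species=int(res.nobs),
        )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name a minimal set of predictors whose removal restores full rank."""
    cols = list(X.columns)
    culprits = []
    for col in cols:
        reduced = sm.add_constant(X.drop(columns=[col]).to_numpy(dtype=float))
        if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
            culprits.append(col)
    return culprits or cols


def fit_multivariate(data: pd.DataFrame, response: str, predictors: list[str]) -> MultivariateFit:
    """Multivariate linear regression with t and F tests (see :class:`LifespanRegression`)."""
    return LifespanRegression(data, response, predictors).fit()


def old_abundance(ages, max_lifespan: float, species: str = "") -> OldAbundance:
    """Fraction of sampled individuals strictly older than 70% of max lifespan.

    Ties at the cutoff count as not old ("age above the value").
    """
    arr = np.asarray(ages, dtype=float)
    if arr.size == 0:
        raise ValueError("empty age list")
    if not max_lifespan > 0:
        raise ValueError("max_lifespan must be positive")
    cutoff = 0.7 * max_lifespan
    n_old = int(np.count_nonzero(arr > cutoff))
    return OldAbundance(
        species=species,
        cutoff_age=cutoff,
        n_old=n_old,
        n_total=int(arr.size),
        fraction_old=n_old / arr.size,
    )


def load_traits(path) -> pd.DataFrame:
    """Read a species-traits table (CSV with the standard column names)."""
    df = pd.read_csv(path)
    missing = [c for c in TRAITS_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"traits table missing columns: {missing}")
    return df


def example_traits_path():
    """Path of the bundled illustrative species-traits table (synthetic example)."""
    from importlib.resources import files

    return files("damagerates.data") / "example_species_traits.csv"


def plot_trend(fit: CrossSpeciesFit, x, y, path) -> None:
    """Scatter of species points with the fitted trendline, saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(x, y, color="tab:blue")
    grid = np.linspace(np.nanmin(x), np.nanmax(x), 200)
    if fit.model == "linear":
        ax.plot(grid, fit.coefficients[0] * grid + fit.coefficients[1], "k-")
    else:
        grid = grid[grid > 0]
        ax.plot(grid, fit.coefficients[0] * grid ** fit.coefficients[1], "k-")
    r2 = f"{fit.r_squared:.3f}" if fit.r_squared_defined else "undef."
    ax.set_xlabel(fit.predictor)
    ax.set_ylabel(fit.response)
    ax.set_title(f"{fit.model} fit, R² = {r2}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
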