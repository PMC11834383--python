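"""Random-slope hierarchical regression of demographic structure on a covariate.

One model per explanatory variable:

    y_ij = b_int + u_int_i + (b_expl + u_expl_i) * Z_ij + e_ij

with y the z-normalised descriptor of population i in year j, Z the
z-normalised covariate, u_int_i ~ N(0, sigma_int^2) population random
intercepts, u_expl_i ~ N(0, sigma_expl^2) population random slopes
(independent of the intercepts), and e_ij ~ N(0, sigma_resid^2). Both
variables are normalised over the pooled population-years so fixed slopes
are comparable across covariates. The marginal Gaussian likelihood is
maximised directly (statsmodels MixedLM, ML) and the fixed slope carries a
Wald-type 95% interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning


def z_normalise(values) -> np.ndarray:
    """Centre and scale to sample sd 1 over non-missing entries.

    Missing values stay missing. A zero-variance input is degenerate
    (the slope would be unidentifiable) and raises.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise ValueError("degenerate covariate: fewer than 2 observed values")
    sd = np.std(x[obs], ddof=1)
    if sd == 0:
        raise ValueError("degenerate covariate: zero variance")
    out = np.full_like(x, np.nan)
    out[obs] = (x[obs] - np.mean(x[obs])) / sd
    return out


@dataclass
class RandomSlopeResults:
    """Estimates from :meth:`RandomSlopeModel.fit`."""

    response_name: str
    covariate_name: str
    beta_int: float
    beta_expl: float
    sigma_u_int: float
    sigma_u_expl: float
    sigma_resid: float
    slope_interval: tuple
    per_population_slopes: dict
    n_obs: int
    n_populations: int
    singular: bool
    converged: bool
    _sm_result: object = field(default=None, repr=False)

    def summary(self) -> str:
        lo, hi = self.slope_interval
        return "\n".join([
            f"Random-slope model: {self.response_name} ~ {self.covariate_name}",
            f"  n_obs: {self.n_obs}   populations: {self.n_populations}"
            + ("   [singular]" if self.singular else ""),
            f"  beta_int    = {self.beta_int:+.3f}",
            f"  beta_expl   = {self.beta_expl:+.3f}  95% CI [{lo:+.3f}, {hi:+.3f}]",
            f"  sigma_u_int = {self.sigma_u_int:.3f}",
            f"  sigma_u_expl= {self.sigma_u_expl:.3f}",
            f"  sigma_resid = {self.sigma_resid:.3f}",
        ])

    def to_row(self) -> dict:
        lo, hi = self.slope_interval
        return {
            "response": self.response_name, "covariate": self.covariate_name,
            "beta_expl": self.beta_expl, "ci_low": lo, "ci_high": hi,
            "beta_int": self.beta_int, "sigma_u_int": self.sigma_u_int,
            "sigma_u_expl": self.sigma_u_expl, "sigma_resid": self.sigma_resid,
            "n_obs": self.n_obs, "n_populations": self.n_populations,
            "singular": self.singular,
        }


class RandomSlopeModel:
    """Gaussian hierarchical regression with population random intercepts
    and independent random slopes, one covariate at a time.

    Parameters
    ----------
    data : DataFrame
        One row per population-year with columns for the response, the
        covariate and ``population_id``. Rows with a missing covariate or
        response are dropped for this model only.
    response, covariate : str
        Column names; both are z-normalised over the pooled rows here.
    """

    def __init__(self, data: pd.DataFrame, response: str, covariate: str,
                 group: str = "population_id", normalise: bool = True):
        df = data[[group, response, covariate]].dropna().copy()
        if df[group].nunique() < 2:
            raise ValueError("need >= 2 populations")
        if len(df) < 10:
            raise ValueError("need >= 10 rows")
        df["_y"] = z_normalise(df[response]) if normalise else df[response].to_numpy(float)
        df["_z"] = z_normalise(df[covariate]) if normalise else df[covariate].to_numpy(float)
        self.data = df
        self.response = response
        self.covariate = covariate
        self.group = group

    def fit(self, allow_correlated: bool = False) -> RandomSlopeResults:
        """Maximise the marginal likelihood (ML, not REML).

        A variance component estimated at (numerically) zero flags the fit
        as singular rather than erroring. ``allow_correlated`` switches to a
        full 2x2 random-effect covariance.
        """
        df = self.data
        if allow_correlated:
            model = smf.mixedlm("_y ~ _z", df, groups=df[self.group], re_formula="~_z")
        else:
            model = smf.mixedlm(
                "_y ~ _z", df, groups=df[self.group],
                re_formula="1", vc_formula={"slope": "0 + _z"},
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(reml=False, method=["lbfgs", "powell"])
        if not res.converged:
            raise RuntimeError(f"mixed model failed to converge:\n{res.summary()}")

        beta_int = float(res.params["Intercept"])
        beta_expl = float(res.params["_z"])
        se = float(res.bse["_z"])
        interval = (beta_expl - 1.96 * se, beta_expl + 1.96 * se)
        scale = float(res.scale)
        sigma_int = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
        if allow_correlated:
            sigma_slope = float(np.sqrt(max(res.cov_re.iloc[1, 1], 0.0)))
        else:
            sigma_slope = float(np.sqrt(max(res.vcomp[0], 0.0)))
        # an sd this far below the residual scale is a boundary (zero) estimate
        singular = bool(min(sigma_int, sigma_slope) < 1e-2 * np.sqrt(scale))

        slopes = {}
        for pop, re_vals in res.random_effects.items():
            u = float(re_vals.get("slope", re_vals.get("_z", 0.0)))
            slopes[pop] = beta_expl + u

        return RandomSlopeResults(
            response_name=self.response, covariate_name=self.covariate,
            beta_int=beta_int, beta_expl=beta_expl,
            sigma_u_int=sigma_int, sigma_u_expl=sigma_slope,
            sigma_resid=float(np.sqrt(scale)),
            slope_interval=interval, per_population_slopes=slopes,
            n_obs=len(df), n_populations=df[self.group].nunique(),
            singular=singular, converged=bool(res.converged), _sm_result=res,
        )


def fit_all_covariates(
    summaries: pd.DataFrame,
    covariates_wide: pd.DataFrame,
    descriptor: str = "prop_subadult",
    covariate_names=None,
) -> pd.DataFrame:
    """One random-slope fit per covariate; one output row per fit."""
    df = summaries
    if "passes_filters" in df.columns:
        df = df[df["passes_filters"].astype(bool)]
    merged = df.merge(covariates_wide, on=["population_id", "year"], how="left")
    names = covariate_names or [
        c for c in covariates_wide.columns if c not in ("population_id", "year")
    ]
    rows = []
    for name in names:
        try:
            res = RandomSlopeModel(merged, descriptor, name).fit()
            rows.append(res.to_row())
        except (ValueError, RuntimeError) as err:
            rows.append({"response": descriptor, "covariate": name, "error": str(err)})
    return pd.DataFrame(rows)
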