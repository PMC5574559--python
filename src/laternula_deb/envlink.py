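"""Linear-model link between reconstructed food availability and covariates.

Reconstructed daily ``f`` is averaged into the (roughly monthly) periods
of the sediment-trap and chlorophyll record, and a small candidate set of
ordinary linear models is compared by maximum-likelihood AIC and
likelihood-ratio tests.  Chlorophyll and POC flux are strongly collinear
proxies of the same bloom signal and are never entered together.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["align_periods", "compare_models", "CANDIDATE_MODELS"]

# candidate mean structures; chlorophyll and POC never co-occur
CANDIDATE_MODELS: dict[str, list[str]] = {
    "chl_x_litho": ["chl", "litho_flux", "chl:litho_flux"],
    "chl_plus_litho": ["chl", "litho_flux"],
    "poc_x_litho": ["poc_flux", "litho_flux", "poc_flux:litho_flux"],
    "poc_plus_litho": ["poc_flux", "litho_flux"],
    "chl": ["chl"],
    "poc": ["poc_flux"],
    "litho": ["litho_flux"],
    "intercept": [],
}

# nested pairs for likelihood-ratio tests (reduced, full)
_NESTED_PAIRS = [
    ("chl_plus_litho", "chl_x_litho"),
    ("chl", "chl_plus_litho"),
    ("litho", "chl_plus_litho"),
    ("poc_plus_litho", "poc_x_litho"),
    ("poc", "poc_plus_litho"),
    ("litho", "poc_plus_litho"),
    ("intercept", "chl"),
    ("intercept", "poc"),
    ("intercept", "litho"),
]


def align_periods(f_daily: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Average a daily f series into the covariate record's periods.

    ``f_daily`` has columns date, f; ``covariates`` has period_start,
    period_end plus any covariate columns.  Periods without any overlapping
    f days are dropped; an empty overlap raises.
    """
    if not {"date", "f"} <= set(f_daily.columns):
        raise ValueError("f series needs columns date, f")
    if not {"period_start", "period_end"} <= set(covariates.columns):
        raise ValueError("covariates need columns period_start, period_end")
    f_daily = f_daily.copy()
    f_daily["date"] = pd.to_datetime(f_daily["date"])
    rows = []
    for _, row in covariates.iterrows():
        start = pd.to_datetime(row["period_start"])
        end = pd.to_datetime(row["period_end"])
        if end < start:
            raise ValueError("period_end before period_start")
        mask = (f_daily["date"] >= start) & (f_daily["date"] <= end)
        if not mask.any():
            continue
        out = dict(row)
        out["f"] = float(f_daily.loc[mask, "f"].mean())
        rows.append(out)
    if not rows:
        raise ValueError("no overlap between the f series and the covariate periods")
    table = pd.DataFrame(rows)
    starts = pd.to_datetime(table["period_start"])
    if not starts.is_monotonic_increasing:
        raise ValueError("covariate periods must be ordered")
    return table


def _design(table: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(table))]
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[term].to_numpy(float))
    return np.column_stack(cols)


def compare_models(table: pd.DataFrame, response: str = "f") -> dict:
    """Fit the candidate linear models and rank them by AIC.

    Returns a dict with a ``ranking`` DataFrame (model, k, aic, delta_aic,
    r_squared, loglik), per-model fitted coefficient Series, and
    likelihood-ratio p-values for the nested pairs.  Gaussian ML is used
    throughout so AIC values are comparable across mean structures.
    """
    n = len(table)
    if n < 8:
        raise ValueError("need at least 8 periods to fit the interaction models")
    y = table[response].to_numpy(dtype=float)
    fits: dict[str, sm.regression.linear_model.RegressionResultsWrapper] = {}
    for name, terms in CANDIDATE_MODELS.items():
        X = _design(table, terms)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(f"dropping rank-deficient model {name!r}")
            continue
        fits[name] = sm.OLS(y, X).fit()
    records = []
    for name, res in fits.items():
        records.append({
            "model": name,
            "k": int(res.df_model + 2),  # mean parameters + error variance
            "aic": float(res.aic),
            "r_squared": float(res.rsquared),
            "loglik": float(res.llf),
        })
    ranking = pd.DataFrame(records).sort_values("aic", ignore_index=True)
    ranking["delta_aic"] = ranking["aic"] - ranking["aic"].iloc[0]

    from scipy.stats import chi2
    lrt = {}
    for reduced, full in _NESTED_PAIRS:
        if reduced not in fits or full not in fits:
            continue
        stat = 2.0 * (fits[full].llf - fits[reduced].llf)
        df = len(CANDIDATE_MODELS[full]) - len(CANDIDATE_MODELS[reduced])
        lrt[(reduced, full)] = float(chi2.sf(max(stat, 0.0), df))
    coef = {name: pd.Series(res.params,
                            index=["intercept"] + CANDIDATE_MODELS[name])
            for name, res in fits.items()}
    return {"ranking": ranking, "coefficients": coef, "lrt_pvalues": lrt,
            "best": ranking["model"].iloc[0]}
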