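"""Group-level statistics: mixed models, BIC Bayes factors, correlations.

The epoch contrast (pre- vs post-recruitment) on a per-discharge metric
is fit as a linear mixed-effects model, metric ~ 1 + epoch with a
random intercept and slope per seizure, delegated to statsmodels.  The
evidence for the fixed effect is summarized by a Bayes factor computed
from the models' BIC via their sum-of-squares decomposition:

    BIC_H1 = n ln((SS_error + SS_response) / SS_total) + k ln(n)
    BIC_H0 = n ln(SS_error / SS_total) + k ln(n)
    BF = exp(dBIC / 2) = ((SS_error + SS_response) / SS_error)^(n/2)

with k = 2 (intercept and slope).  SS_response is defined operationally
as the reduction in residual sum of squares from the null
(intercept-only fixed effects) to the alternative fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
import statsmodels.formula.api as smf

__all__ = [
    "BayesFactorInputs",
    "bayes_factor_from_bic",
    "log_bayes_factor_from_bic",
    "fit_epoch_mixed_model",
    "discharge_correlations",
]


@dataclass
class BayesFactorInputs:
    ss_error: float
    ss_response: float
    ss_total: float
    n: int
    k: int = 2

    def validate(self) -> None:
        if min(self.ss_error, self.ss_response, self.ss_total) < 0:
            raise ValueError("sums of squares must be non-negative")
        if self.ss_total <= 0:
            raise ValueError("SS_total must be positive")
        if self.ss_error == 0:
            raise ValueError("SS_error = 0: BIC undefined")
        if self.n < self.k:
            raise ValueError("n must be at least k")


def log_bayes_factor_from_bic(inputs: BayesFactorInputs) -> float:
    """Natural log of the Bayes factor; safe for large n."""
    inputs.validate()
    return 0.5 * inputs.n * float(
        np.log1p(inputs.ss_response / inputs.ss_error)
    )


def bayes_factor_from_bic(inputs: BayesFactorInputs) -> float:
    """BF = exp((BIC_H1 - BIC_H0)/2), computed in log space.

    Note the direction convention is exactly as printed: H1's BIC in
    the numerator of dBIC, so BF > 1 when the response term adds
    explained variance on top of the error term.  SS_response = 0 gives
    BF = 1 identically.
    """
    return float(np.exp(log_bayes_factor_from_bic(inputs)))


def fit_epoch_mixed_model(
    table: pd.DataFrame,
    metric: str = "value",
    epoch_col: str = "epoch",
    group_col: str = "seizure",
) -> dict:
    """Fixed effect of epoch with random intercept + slope per seizure.

    Fits ``metric ~ 1 + epoch + (1 + epoch | seizure)`` by ML via
    statsmodels MixedLM.  A singular random-slope fit triggers a
    warning and a fallback to a random-intercept-only model (flagged in
    the result).  Returns the slope estimate, its t and p, the SS
    decomposition feeding :func:`bayes_factor_from_bic`, and the BF.
    """
    df = table[[metric, epoch_col, group_col]].dropna().copy()
    groups = df[group_col].unique()
    if groups.size < 2:
        raise ValueError("need at least 2 seizures for a mixed model")
    if df[epoch_col].nunique() < 2:
        raise ValueError("epoch column is constant; contrast undefined")
    for g in groups:
        if df.loc[df[group_col] == g, epoch_col].nunique() < 2:
            raise ValueError(f"seizure {g!r} lacks one of the epochs")
    df["__epoch"] = (df[epoch_col].astype(str) == "post").astype(float)
    y = df[metric].to_numpy(dtype=float)
    n = y.size

    def _fit(re_formula: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                f"{metric} ~ __epoch", df, groups=df[group_col], re_formula=re_formula
            )
            return md.fit(reml=False)

    fallback = False
    try:
        res = _fit("~__epoch")
        if np.any(~np.isfinite(res.bse.iloc[:2])) or not res.converged:
            raise np.linalg.LinAlgError("singular random-slope fit")
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn(
            "random-slope fit singular; falling back to random intercept only",
            stacklevel=2,
        )
        fallback = True
        res = _fit("~1")
    # refit without the fixed epoch effect for the SS decomposition;
    # residuals are taken against the marginal (fixed-effects) predictions
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md0 = smf.mixedlm(
                f"{metric} ~ 1", df, groups=df[group_col], re_formula="~1"
            )
            null_intercept = float(md0.fit(reml=False).fe_params.iloc[0])
    except np.linalg.LinAlgError:
        # singular Hessian when the intercept variance collapses; the
        # intercept-only fixed-effects prediction is the grand mean
        null_intercept = float(y.mean())

    fe = np.asarray(res.fe_params)
    fitted_alt = fe[0] + fe[1] * df["__epoch"].to_numpy()
    ss_alt = float(np.sum((y - fitted_alt) ** 2))
    ss_null = float(np.sum((y - null_intercept) ** 2))
    ss_response = max(ss_null - ss_alt, 0.0)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    bf_inputs = BayesFactorInputs(
        ss_error=ss_alt, ss_response=ss_response, ss_total=ss_total, n=n
    )
    return {
        "slope": float(res.fe_params["__epoch"]),
        "t": float(res.tvalues["__epoch"]),
        "p": float(res.pvalues["__epoch"]),
        "n": n,
        "ss_error": ss_alt,
        "ss_response": ss_response,
        "ss_total": ss_total,
        "log_bf": log_bayes_factor_from_bic(bf_inputs),
        "random_slope_fallback": fallback,
    }


def discharge_correlations(
    table: pd.DataFrame,
    x: str = "mua_peak",
    y: str = "bhf_peak",
    epoch_col: str = "epoch",
) -> pd.DataFrame:
    """Pearson correlations between two per-discharge amplitude columns,
    overall and within each epoch.  Returns rows (scope, r, p, n)."""
    df = table[[c for c in {x, y, epoch_col} if c in table.columns]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 discharges")
    scopes: list[tuple[str, pd.DataFrame]] = [("all", df)]
    if epoch_col in df.columns:
        scopes += [(str(e), g) for e, g in df.groupby(epoch_col)]
    rows = []
    for scope, g in scopes:
        if len(g) < 3:
            continue
        if g[x].std() == 0 or g[y].std() == 0:
            raise ValueError(f"zero variance in scope {scope!r}")
        r, p = pearsonr(g[x], g[y])
        rows.append((scope, float(r), float(p), len(g)))
    return pd.DataFrame(rows, columns=["scope", "r", "p", "n"])
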